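# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of `bloodshift`. It is the package's own account of
its science; every number quoted here is computed by the test suite or the
acceptance script at run time.

## The measurement model

Bulk blood RNA-seq observes, per transcript *t* and sample *s*, fragments
drawn from a mixture over leukocyte populations *c*:

```
E[mature count(t, s)] ∝ Σ_c  π(c, s) · B(t, c) · R(g(s), c, t)
```

* `π(c, s)` — the sample's cell proportions (measured independently by
  flow cytometry in a real cohort),
* `B(t, c)` — the per-cell expression programme of population *c*,
* `R(g, c, t)` — a per-group, per-cell regulation multiplier: the "active
  transcription" signal that the analysis chain tries to isolate.

Sequencing is compositional: each library is rescaled so that the expected
mature output is a constant library size. A planted k-fold cell-count
change therefore appears in the bulk as slightly less than k — the rest of
the transcriptome renormalises — and all closed-form expectations in
`SimTruth` include this factor.

## The simulator

`synthetic.generate_cohort` realises the model for a three-group cohort
(RAA n=19, RAC n=20, C n=20 by default, mirroring a typical acute /
chronic / control design):

* **Cell counts.** Absolute counts per population are Gamma draws with
  shape `concentration × weight(c, g)` and a common scale, where
  `weight = baseline fraction × planted multiplier`. The normalised vector
  is then exactly Dirichlet(concentration × weights); the default
  concentration of 200 gives per-population CVs of 7–22%, in the range of
  day-to-day differential-count variability. Baseline fractions follow a
  standard whole-blood differential (neutrophils 55%, CD4⁺ 15%, CD8⁺ 8%,
  B 5%, NK 5%, monocytes 12% split 9/1/2 into classical / intermediate /
  nonclassical). The flow-cytometry table reports subset counts with
  consistent parents (CD3 = CD4+CD8; lymphocytes = CD3+B+NK; monocytes =
  sum of subsets); double-negative/double-positive T cells and iNKT cells
  are not modelled.
* **Signatures.** Per-transcript abundance is log-normal (σ=1.2) shared
  across cell types with per-type log-normal jitter (σ=0.3). A marker
  transcript's baseline in its own type is set to `spec_fold` (default
  10×) times its maximum across the other types. Per-cell RNA yield is
  treated as equal across populations (configurable in principle via the
  signature matrix itself).
* **Counts.** Negative-binomial via Gamma–Poisson with a common dispersion
  (default 0.1, a typical human-cohort value; the Poisson limit is used
  below 10⁻¹²). Expected mature library size: 10⁶ fragments.
* **Pre-mRNA.** Each transcript carries a per-group intronic-read fraction
  *f* (baseline 0.1). Induced transcription adds nascent RNA on top of the
  mature pool, so the total count is inflated to `μ/(1−f)` before a
  binomial split into exonic and intronic reads; the exonic expectation
  therefore equals the mixture expectation regardless of *f*, while the
  intronic/exonic ratio is `f/(1−f)`. Exonic + intronic reproduce the
  realised total exactly.

### The canonical scenario

`default_acute_scenario` plants the acute-phase picture: CD4⁺ count
× 1/1.5 and CD8⁺ × 1/1.3; classical and intermediate monocytes × 1.3; the
eight MN-set transcripts up-regulated 2.5× per cell in their marker
population; pre-mRNA fraction raised from 0.1 to 0.4 on the down-regulated
(lymphocyte-marker) transcripts; all chronic-group multipliers at 1, with
sampling months spread over 3–15 (integers, ties allowed — 13 distinct
time points across 20 samples). The L/MN gene symbols are planted as
markers: the L set on CD4⁺/CD8⁺ T cells, CD14/GYG1/FCGR1A/FCGR2A/IRAK3 on
classical monocytes and ANXA3/ARG1/MMP9 on neutrophils (their actual
lineages). The resulting MN-set bulk fold (geometric mean ≈ 2.4–2.9
against a monocyte count fold ≈ 1.25) sits inside the 1.8–4.6× range such
marker sets show in acute cohorts.

## Analysis defaults and numerical choices

| Parameter | Default | Rationale |
|---|---|---|
| Detection threshold | mean FPKM ≥ 0.1 | standard presence filter; mean across samples (an "any-sample" mode exists) |
| Basal expression | mean FPKM > 0.5 | strict comparator distinguishes the basal set from mere detection |
| ANOVA gate | q < 10⁻⁵ | genome-wide stringency for a ~10⁵-transcript screen; configurable |
| Fold pseudocount | 0.1 | the detection floor; stabilises ratios of weak transcripts |
| Pattern count | 2 | the down (A) / up (B) dichotomy; correlation distance + average linkage |
| Time-course screen | \|R\| > 0.7, p < 0.01 | magnitude-thresholded: acutely elevated transcripts *decay*, so informative correlations are negative |
| L/MN standardisation | fold over all-sample mean | keeps the index positive and scale-free per gene; control-mean fold and shifted z-score available |
| Exon/intron pseudocount | 1 | finite scores for genes without intronic signal; per-gene ratios compared by Mann–Whitney (robust to the heavy right tail) |
| Attribution τ | 0.5 log₂ | separates a count-tracking marker drop (discordance ≈ 0.3–0.4) from severalfold active regulation (≈ 1.0); direction conflicts are *indeterminate* |

Other numerical details: constant transcripts get F=0, p=1 in the ANOVA
(no variance decomposition exists) and are excluded, with a logged
message, from correlation clustering and the Spearman screen; BH
adjustment is step-up with stable tie handling; Welch tests use
Satterthwaite degrees of freedom; zero-variance clustering inputs where
all profiles coincide are reported as a degenerate cut rather than a
fabricated two-way split.

## What the simulator does and does not emulate

It emulates: mixture-driven bulk expression with compositional
renormalisation, overdispersed counts, marker specificity, planted
composition vs regulation effects, pre-mRNA read splits, realistic
cell-count noise, and a chronic group at control levels. It does **not**
emulate read-level artefacts (mappability, GC bias, positional coverage),
correlated co-regulation modules, per-cell-type RNA-content differences,
neutrophil granule RNA degradation, globin carry-over, or isoform-level
switching. Passing the recovery suite therefore demonstrates the
*statistical machinery* is correct and calibrated under the stated
generative model — not that any particular real cohort satisfies that
model.

A consequence of 10× marker specificity in a neutrophil-dominated mixture
is heavy dilution: a pure 1.5-fold CD4 count drop yields only a ~1.3-fold
bulk marker drop, which at n≈20/group rarely clears the q<10⁻⁵ gate. The
simulated differential screen is therefore dominated by the strong MN
up-regulation; the down-regulated set's structure properties are
validated against the planted truth sets, which is also how the
acceptance script reports them.

## Problem sizes

The shipped tests and the acceptance script run the cohort analyses at
2000 transcripts and 59 samples, with 50–100 replicate seeds for the
recovery-rate properties and a 500-null time-course screen — sizes at
which every planted effect is comfortably identifiable and a full run of
suite plus script completes in well under two minutes on one core. The
mixture-mean convergence check uses dispersion 0.02: at the default 0.1
the per-transcript replicate-noise floor (√(0.1/20) ≈ 7% with 20
samples) exceeds the 5% band whatever the depth, so a lower dispersion is
needed to isolate the mixture/renormalisation arithmetic that the check
is about.

## Known limitations

* FPKM uses plain exonic length (no effective-length correction) and no
  TPM/median-of-ratios alternatives.
* The attribution rule is a two-source fold comparison, not a full
  deconvolution; overlapping marker sets or populations absent from the
  count table are out of scope.
* The L/MN standardisation rule is the module's central documented
  assumption: "standardised expression" admits several readings
  (fold-over-mean, fold-over-control, z-score), and while the default is
  scale-free and positive, group means of the index do depend on the rule
  chosen. All three are implemented; cross-rule agreement is not
  guaranteed.
* Whether the exon/intron score should be aggregated per gene (as here)
  or pooled per set is a genuine open choice; per-gene ratios with a
  rank test were chosen for robustness and both the pseudocount and the
  aggregation samples are configurable.
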
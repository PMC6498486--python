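# bloodshift

Analysis toolkit for the **systemic blood-transcriptome response** to an
acute intracranial event (aneurysmal subarachnoid hemorrhage). Bulk blood
RNA-seq confounds two biological signals: the *composition* of circulating
leukocytes changes (lymphopenia, monocytosis), and the cells themselves
change their *per-cell transcription*. `bloodshift` implements the analysis
chain that separates them, and ships a cell-mixture cohort simulator with
planted ground truth so every statistic can be validated end to end.

Intended users: bioinformaticians analysing three-group blood cohorts
(acute patients **RAA**, chronic/convalescent patients **RAC**, controls
**C**) with transcript-level count or FPKM matrices plus a flow-cytometry
cell-count table.

## What it computes

1. **Quantification** — FPKM from exonic counts and transcript lengths,
   detection filter (mean FPKM ≥ 0.1; basal expression > 0.5), and the
   `log2(1 + x)` transform.
2. **Differential screen** — per-transcript one-way ANOVA over
   RAA/RAC/C, Benjamini–Hochberg FDR (gate `q < 10⁻⁵`), pairwise linear
   fold changes, two-cluster pattern assignment (correlation distance,
   average linkage; pattern **A** = down in RAA, **B** = up), and a Spearman
   time-course screen over the chronic samples (hits at |R| > 0.7,
   p < 0.01).
3. **L/MN index** — per sample,

   ```
   L/MN(s) = mean_{g∈L} sf(g,s) / mean_{g∈MN} sf(g,s),   sf(g,s) = x(g,s) / mean_s' x(g,s')
   ```

   with L = {BCL11B, CCR7, CD2, CD27, CD3D, CD3E, CD8A, KLRB1} and
   MN = {ANXA3, ARG1, CD14, GYG1, FCGR1A, FCGR2A, IRAK3, MMP9};
   two-sided Welch t-tests between groups. Low values = lymphocyte
   depression with myeloid activation.
4. **Transcript structure** — biotype composition of a transcript set, and
   the per-gene exon/intron ratio score
   `(Σ exonic + 1)/(Σ intronic + 1)` with a Mann–Whitney comparison
   between gene sets (a low score = large unspliced pre-mRNA fraction).
5. **Attribution** — for a marker population, compare the cell-count fold
   with the geometric-mean marker expression fold:
   `discordance = |log₂(expression fold) − log₂(count fold)|`;
   ≤ 0.5 → *composition_driven*, > 0.5 with a larger same-direction
   expression change → *actively_regulated*.
6. **Simulator** — bulk counts as negative-binomial draws around a
   cell-proportion-weighted mixture of per-cell-type signature profiles,
   with planted per-group cell-count multipliers, per-cell regulation
   multipliers and pre-mRNA fractions, plus the matching flow-cytometry
   table and closed-form expected folds (`SimTruth`).

## Worked example

```bash
bloodshift all --seed 3 --outdir run1 --n-transcripts 1200
```

simulates the default acute-phase scenario (19/20/20 samples; CD4⁺ count
× 1/1.5, CD8⁺ × 1/1.3, classical+intermediate monocytes × 1.3, MN-set
transcripts up-regulated 2.5× per cell, chronic group at control levels)
and runs every stage. `run1/attribution.json` then contains:

```
population   count_fold  expression_fold  discordance  verdict
CD4          0.570       0.734            0.365        composition_driven
monocytes    0.979       2.339            1.256        actively_regulated
```

Read: the CD4 marker drop (0.73×) tracks the CD4 count change —
composition-driven; the MN marker rise (2.3×, per-marker envelope
1.8–2.8×) far exceeds the monocyte count change — active per-cell
regulation. `run1/lmn_summary.json` shows the depressed acute
index: L/MN group means 0.54 (RAA) vs 1.58 (C) with RAC back at 1.52.
The acceptance script (below) additionally contrasts the exon/intron
scores of the planted down- vs up-regulated gene sets (median ≈ 1.5 for
the pre-mRNA-elevated down-regulated genes vs ≈ 9.0 for the up-regulated
set, Mann–Whitney p < 10⁻⁴); at this demo size the significance-gated
pattern sets in `run1/exon_intron_summary.json` contain too few
down-regulated genes for that contrast — see `docs/methods.md` on
detection power under marker dilution.

The same stages are available as library calls (`bloodshift.generate_cohort`,
`anova_screen`, `lmn_index`, `exon_intron_score`, `attribute`, …); every
output is plain TSV/JSON next to a `manifest.json` with the seed and
per-file checksums.

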
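"""Synthetic bulk-blood cohort generator with known ground truth.

Bulk blood RNA-seq measures a mixture: each sample's expression profile is
a cell-count-weighted sum of the expression programmes of the circulating
leukocyte populations. This module simulates that process for a three-group
cohort — acute-phase patients (RAA, n=19), chronic-phase patients (RAC,
n=20) and controls (C, n=20) — so that every downstream statistic can be
checked against planted truth:

1. a transcript **annotation** with biotypes, exonic/intronic lengths and
   cell-type marker tags;
2. per-cell-type **signature** profiles, with marker transcripts enriched a
   configurable factor (default 10x) over every other cell type;
3. per-sample **cell counts** drawn around group means scaled by planted
   per-group multipliers (the composition effect);
4. bulk **counts**: expected mature abundance is the proportion-weighted
   mixture of signatures times planted per-cell regulation multipliers (the
   active transcription effect), rescaled to a constant expected library
   size. A per-transcript pre-mRNA fraction adds nascent reads on top of
   the mature pool (induced transcription produces unspliced RNA, it does
   not remove mature reads); the realised total is a negative-binomial draw
   split binomially into exonic (mature) and intronic (nascent) reads.

The per-sample rescaling to constant library size mirrors the compositional
nature of sequencing: a planted k-fold cell-count change produces a bulk
marker fold slightly below k because the rest of the transcriptome
renormalises. :class:`SimTruth` carries the closed-form expected folds that
account for this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .lmn import GeneSetDefinition, L_GENES_DEFAULT, MN_GENES_DEFAULT
from .quantify import ExpressionMatrix

__all__ = [
    "CELL_TYPES",
    "BIOTYPES",
    "BASELINE_CELL_FRACTIONS",
    "CohortDesign",
    "SimTruth",
    "Scenario",
    "generate_annotation",
    "generate_signatures",
    "generate_cohort",
    "default_acute_scenario",
    "timecourse_dataset",
]

CELL_TYPES = (
    "CD4T",
    "CD8T",
    "B",
    "NK",
    "MONO_CLASSICAL",
    "MONO_INTERMEDIATE",
    "MONO_NONCLASSICAL",
    "NEUTROPHIL",
)

#: Supported transcript biotype vocabulary (an operational subset of the
#: full Ensembl/Vega catalogue; "other" pools the long tail).
BIOTYPES = (
    "protein_coding",
    "retained_intron",
    "processed_transcript",
    "lincRNA",
    "antisense",
    "other",
)

#: Typical whole-blood leukocyte composition (fractions of total WBC) used
#: as the control-group mean. Neutrophils dominate whole blood; the
#: mononuclear fractions follow standard differential-count ranges.
BASELINE_CELL_FRACTIONS = {
    "CD4T": 0.15,
    "CD8T": 0.08,
    "B": 0.05,
    "NK": 0.05,
    "MONO_CLASSICAL": 0.09,
    "MONO_INTERMEDIATE": 0.01,
    "MONO_NONCLASSICAL": 0.02,
    "NEUTROPHIL": 0.55,
}

#: Default biotype mixture for generated annotations, patterned on the
#: composition of transcripts expressed in blood at basal conditions
#: (about half protein-coding, with retained-intron and processed
#: transcripts the largest noncoding classes).
DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.502,
    "retained_intron": 0.217,
    "processed_transcript": 0.120,
    "lincRNA": 0.060,
    "antisense": 0.040,
    "other": 0.061,
}

#: Gene symbols given to the first marker transcripts of each cell type so
#: that the L/MN gene sets exist in every generated cohort. CD8A and KLRB1
#: tag cytotoxic/NK-like T cells; the monocyte set splits into classical
#: monocyte markers and the neutrophil-associated ANXA3/ARG1/MMP9.
DEFAULT_MARKER_GENES = {
    "CD4T": ("BCL11B", "CCR7", "CD2", "CD27", "CD3D", "CD3E"),
    "CD8T": ("CD8A", "KLRB1"),
    "MONO_CLASSICAL": ("CD14", "GYG1", "FCGR1A", "FCGR2A", "IRAK3"),
    "NEUTROPHIL": ("ANXA3", "ARG1", "MMP9"),
}

GROUP_ORDER = ("RAA", "RAC", "C")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(
    n_transcripts: int,
    biotype_mix: dict[str, float] | None = None,
    marker_config: dict[str, int] | None = None,
    seed: int = 0,
    marker_genes: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Generate a transcript annotation table.

    Returns a DataFrame indexed by ``transcript_id`` with columns
    ``gene_id``, ``biotype``, ``exonic_length``, ``intronic_length`` and
    ``marker_of`` (cell-type label or ``NONE``). Marker transcripts are
    forced to ``protein_coding`` (cell-surface marker genes are coding) and
    take their gene symbol from ``marker_genes`` where provided, so that
    named gene sets (e.g. the L/MN sets) resolve in the simulated cohort.

    Deterministic for a fixed ``seed``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be positive")
    mix = dict(DEFAULT_BIOTYPE_MIX if biotype_mix is None else biotype_mix)
    probs = np.array(list(mix.values()), dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("biotype_mix must be a non-negative, normalisable vector")
    probs = probs / probs.sum()
    marker_config = dict(marker_config or {})
    unknown = set(marker_config) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"marker_config references unknown cell types: {sorted(unknown)}")
    n_markers = sum(marker_config.values())
    if n_markers > n_transcripts:
        raise ValueError("marker demand exceeds n_transcripts")

    rng = np.random.default_rng(seed)
    biotypes = rng.choice(list(mix.keys()), size=n_transcripts, p=probs)
    exonic = np.maximum(
        np.round(rng.lognormal(mean=math.log(1500.0), sigma=0.7, size=n_transcripts)), 200
    ).astype(int)
    # ~15% of transcripts are single-exon (no intronic sequence)
    has_intron = rng.random(n_transcripts) >= 0.15
    intronic = np.where(
        has_intron,
        np.round(rng.lognormal(mean=math.log(8000.0), sigma=1.0, size=n_transcripts)),
        0,
    ).astype(int)

    marker_of = np.array(["NONE"] * n_transcripts, dtype=object)
    gene_ids = np.array([f"G{i:05d}" for i in range(n_transcripts)], dtype=object)
    if n_markers:
        chosen = rng.choice(n_transcripts, size=n_markers, replace=False)
        pos = 0
        named = marker_genes if marker_genes is not None else DEFAULT_MARKER_GENES
        for cell_type in CELL_TYPES:
            count = marker_config.get(cell_type, 0)
            names = list(named.get(cell_type, ())) if named else []
            for j in range(count):
                idx = chosen[pos]
                marker_of[idx] = cell_type
                biotypes[idx] = "protein_coding"
                if j < len(names):
                    gene_ids[idx] = names[j]
                pos += 1

    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotypes,
            "exonic_length": exonic,
            "intronic_length": intronic,
            "marker_of": marker_of,
        },
        index=pd.Index([f"TX{i:05d}" for i in range(n_transcripts)], name="transcript_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def generate_signatures(
    annotation: pd.DataFrame,
    seed: int = 0,
    spec_fold: float = 10.0,
    abundance_sigma: float = 1.2,
    celltype_sigma: float = 0.3,
) -> pd.DataFrame:
    """Per-cell-type baseline expression profiles (transcripts x cell types).

    A shared log-normal abundance per transcript is jittered independently
    per cell type; marker transcripts are then raised in their own cell
    type to exactly ``spec_fold`` times the maximum across the other types,
    which is the marker-specificity invariant the attribution logic relies
    on. Values are arbitrary per-cell expression units (per-cell RNA yield
    is treated as equal across cell types).
    """
    if spec_fold <= 1:
        raise ValueError("spec_fold must exceed 1")
    n = len(annotation)
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=1.0, sigma=abundance_sigma, size=n)
    jitter = rng.lognormal(mean=0.0, sigma=celltype_sigma, size=(n, len(CELL_TYPES)))
    sig = base[:, None] * jitter

    marker_of = annotation["marker_of"].to_numpy()
    for k, cell_type in enumerate(CELL_TYPES):
        rows = np.flatnonzero(marker_of == cell_type)
        if len(rows) == 0:
            continue
        others = np.delete(sig[rows], k, axis=1).max(axis=1)
        sig[rows, k] = spec_fold * others
    return pd.DataFrame(sig, index=annotation.index, columns=list(CELL_TYPES))


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------


def _default_group_sizes() -> dict[str, int]:
    return {"RAA": 19, "RAC": 20, "C": 20}


@dataclass
class CohortDesign:
    """Planted parameters for one simulated cohort.

    ``cellcount_multiplier[group][cell_type]`` scales that group's mean
    absolute count of the cell type (controls are fixed at 1).
    ``regulation_multiplier[group][cell_type][transcript_id]`` scales the
    per-cell expression of a transcript within a cell type — the "active
    regulation" effect that bulk folds cannot distinguish from composition
    without the cell-count table. ``premrna_override[group][transcript_id]``
    replaces the baseline pre-mRNA (intronic read) fraction for chosen
    transcripts in chosen groups.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    cellcount_multiplier: dict[str, dict[str, float]] = field(default_factory=dict)
    regulation_multiplier: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    premrna_baseline: float = 0.1
    premrna_override: dict[str, dict[str, float]] = field(default_factory=dict)
    months_since_event: np.ndarray | None = None  # one value per RAC sample
    dispersion: float = 0.1
    library_size: float = 1e6
    total_wbc: float = 7000.0  # cells per microlitre
    concentration: float = 200.0  # Dirichlet-like concentration for proportions
    seed: int = 0

    def validate(self) -> None:
        for group, sizes in self.group_sizes.items():
            if sizes < 1:
                raise ValueError(f"group {group} must have at least one sample")
        for group, per_ct in self.cellcount_multiplier.items():
            for ct, m in per_ct.items():
                if ct not in CELL_TYPES:
                    raise ValueError(f"unknown cell type {ct!r} in cellcount_multiplier")
                if m <= 0:
                    raise ValueError("cell-count multipliers must be positive")
                if group == "C" and m != 1.0:
                    raise ValueError("control-group multipliers must be identically 1")
        for group, per_ct in self.regulation_multiplier.items():
            for ct, per_t in per_ct.items():
                if ct not in CELL_TYPES:
                    raise ValueError(f"unknown cell type {ct!r} in regulation_multiplier")
                for tid, m in per_t.items():
                    if m <= 0:
                        raise ValueError("regulation multipliers must be positive")
                    if group == "C" and m != 1.0:
                        raise ValueError("control-group multipliers must be identically 1")
        if not (0.0 <= self.premrna_baseline < 1.0):
            raise ValueError("premrna_baseline must lie in [0, 1)")
        for group, per_t in self.premrna_override.items():
            for tid, f in per_t.items():
                if not (0.0 <= f < 1.0):
                    raise ValueError("premrna fractions must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.total_wbc <= 0 or self.concentration <= 0:
            raise ValueError("total_wbc and concentration must be positive")
        if self.months_since_event is not None:
            m = np.asarray(self.months_since_event, dtype=float)
            if len(m) != self.group_sizes.get("RAC", 0):
                raise ValueError("months_since_event must have one entry per RAC sample")
            if (m <= 0).any():
                raise ValueError("months_since_event must be positive")

    # -- helpers ------------------------------------------------------------

    def count_multiplier(self, group: str, cell_type: str) -> float:
        return self.cellcount_multiplier.get(group, {}).get(cell_type, 1.0)

    def regulation_matrix(self, group: str, transcript_ids: pd.Index) -> np.ndarray:
        """Dense (transcripts x cell types) regulation multiplier matrix."""
        reg = np.ones((len(transcript_ids), len(CELL_TYPES)))
        per_ct = self.regulation_multiplier.get(group, {})
        if per_ct:
            pos = {t: i for i, t in enumerate(transcript_ids)}
            for ct, per_t in per_ct.items():
                k = CELL_TYPES.index(ct)
                for tid, m in per_t.items():
                    if tid not in pos:
                        raise KeyError(f"regulation references unknown transcript {tid}")
                    reg[pos[tid], k] = m
        return reg

    def premrna_vector(self, group: str, transcript_ids: pd.Index) -> np.ndarray:
        frac = np.full(len(transcript_ids), self.premrna_baseline)
        over = self.premrna_override.get(group, {})
        if over:
            pos = {t: i for i, t in enumerate(transcript_ids)}
            for tid, f in over.items():
                if tid not in pos:
                    raise KeyError(f"premrna override references unknown transcript {tid}")
                frac[pos[tid]] = f
        return frac


@dataclass
class SimTruth:
    """Planted parameters plus closed-form expectations for recovery tests."""

    design: CohortDesign
    expected_group_means: pd.DataFrame  # transcripts x groups, expected bulk counts
    expected_folds: pd.DataFrame  # transcripts x "A_vs_B" columns
    expected_count_folds: pd.DataFrame  # cell types x "A_vs_B" columns
    cell_proportions: pd.DataFrame  # samples x cell types (realised)


@dataclass
class Scenario:
    """A ready-to-simulate bundle: annotation, signatures, design, gene sets."""

    annotation: pd.DataFrame
    signatures: pd.DataFrame
    design: CohortDesign
    genesets: GeneSetDefinition
    marker_sets: dict[str, list[str]]  # population label -> marker transcript ids


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _expected_proportions(design: CohortDesign, group: str) -> np.ndarray:
    w = np.array(
        [BASELINE_CELL_FRACTIONS[ct] * design.count_multiplier(group, ct) for ct in CELL_TYPES]
    )
    return w / w.sum()


def expected_group_mean(
    design: CohortDesign, signatures: pd.DataFrame, group: str
) -> pd.Series:
    """Closed-form expected mature (exonic) count per transcript and group.

    Mixture of signatures weighted by the group's expected cell
    proportions and regulation multipliers, rescaled so the expected
    mature library size equals ``design.library_size``. Nascent
    (intronic) reads are added on top of this at generation time and do
    not enter the expectation, so expected exonic folds equal the
    mixture-formula ratio regardless of the pre-mRNA fractions.
    """
    p = _expected_proportions(design, group)
    reg = design.regulation_matrix(group, signatures.index)
    raw = (signatures.to_numpy() * reg) @ p
    return pd.Series(design.library_size * raw / raw.sum(), index=signatures.index)


def generate_cohort(
    annotation: pd.DataFrame,
    signatures: pd.DataFrame,
    design: CohortDesign,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate one cohort.

    Returns ``(exonic_counts, intronic_counts, cell_counts, truth)``.
    Exonic + intronic counts sum exactly to the realised total count per
    transcript and sample. The cell-count table follows the flow-cytometry
    convention: absolute counts (cells/uL) for the lymphocyte and monocyte
    subsets with parent totals.
    """
    design.validate()
    if not signatures.index.equals(annotation.index):
        missing = annotation.index.difference(signatures.index)
        if len(missing):
            raise KeyError(f"signatures missing transcripts: {list(missing[:5])}")
        signatures = signatures.loc[annotation.index]
    if (signatures.to_numpy() < 0).any():
        raise ValueError("signatures must be non-negative")

    rng = np.random.default_rng(design.seed)
    groups_present = [g for g in GROUP_ORDER if g in design.group_sizes] + [
        g for g in design.group_sizes if g not in GROUP_ORDER
    ]

    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g in groups_present:
        for i in range(design.group_sizes[g]):
            sample_ids.append(f"{g}_{i + 1:02d}")
            sample_groups.append(g)
    samples = pd.DataFrame({"group": sample_groups}, index=pd.Index(sample_ids, name="sample_id"))
    samples["months_since_event"] = np.nan
    if "RAC" in design.group_sizes:
        months = design.months_since_event
        if months is None:
            months = np.round(np.linspace(3.0, 15.0, design.group_sizes["RAC"]))
        rac_ids = samples.index[samples["group"] == "RAC"]
        samples.loc[rac_ids, "months_since_event"] = np.asarray(months, dtype=float)

    n_t = len(annotation)
    n_s = len(samples)
    n_c = len(CELL_TYPES)

    # --- absolute cell counts: Gamma draws whose normalised vector is
    #     Dirichlet(concentration * weights) around the group's mean mix
    shape = np.empty((n_s, n_c))
    for j, g in enumerate(sample_groups):
        w = np.array(
            [BASELINE_CELL_FRACTIONS[ct] * design.count_multiplier(g, ct) for ct in CELL_TYPES]
        )
        shape[j] = design.concentration * w
    cell_counts_abs = rng.gamma(shape, design.total_wbc / design.concentration)
    proportions = cell_counts_abs / cell_counts_abs.sum(axis=1, keepdims=True)

    # --- expected bulk counts per sample (mixture, renormalised to library)
    sig = signatures.to_numpy()
    mu = np.empty((n_t, n_s))
    for g in groups_present:
        cols = [j for j, gg in enumerate(sample_groups) if gg == g]
        eff = sig * design.regulation_matrix(g, annotation.index)
        raw = eff @ proportions[cols].T  # (n_t, n_g)
        mu[:, cols] = design.library_size * raw / raw.sum(axis=0, keepdims=True)

    # --- pre-mRNA adds nascent (intronic) reads ON TOP of the mature pool:
    #     the mixture expectation mu governs the exonic output, so the total
    #     is inflated to mu / (1 - f) before the binomial exon/intron split.
    frac = np.empty((n_t, n_s))
    for g in groups_present:
        cols = [j for j, gg in enumerate(sample_groups) if gg == g]
        frac[:, cols] = design.premrna_vector(g, annotation.index)[:, None]
    mu_total = mu / (1.0 - frac)

    # --- negative-binomial totals via Gamma-Poisson; Poisson limit at d->0
    if design.dispersion > 1e-12:
        lam = rng.gamma(1.0 / design.dispersion, mu_total * design.dispersion)
    else:
        lam = mu_total
    total = rng.poisson(lam)

    # --- binomial thinning at the pre-mRNA fraction; exonic + intronic
    #     reproduce the realised total exactly
    intronic = rng.binomial(total, frac)
    exonic = total - intronic

    exonic_em = ExpressionMatrix(
        pd.DataFrame(exonic, index=annotation.index, columns=samples.index),
        samples,
        unit="counts",
    )
    intronic_em = ExpressionMatrix(
        pd.DataFrame(intronic, index=annotation.index, columns=samples.index),
        samples,
        unit="counts",
    )

    cell_table = _cell_count_table(cell_counts_abs, samples)

    # --- closed-form truth
    means = pd.DataFrame(
        {g: expected_group_mean(design, signatures, g) for g in groups_present}
    )
    pairs = [p for p in (("RAA", "C"), ("RAC", "C"), ("RAA", "RAC")) if set(p) <= set(groups_present)]
    if not pairs:
        pairs = list(combinations(groups_present, 2))
    folds = pd.DataFrame(
        {f"{a}_vs_{b}": means[a] / means[b] for a, b in pairs}
    )
    count_folds = pd.DataFrame(
        {
            f"{a}_vs_{b}": [
                design.count_multiplier(a, ct) / design.count_multiplier(b, ct)
                for ct in CELL_TYPES
            ]
            for a, b in pairs
        },
        index=list(CELL_TYPES),
    )
    truth = SimTruth(
        design=design,
        expected_group_means=means,
        expected_folds=folds,
        expected_count_folds=count_folds,
        cell_proportions=pd.DataFrame(
            proportions, index=samples.index, columns=list(CELL_TYPES)
        ),
    )
    return exonic_em, intronic_em, cell_table, truth


def _cell_count_table(cell_counts_abs: np.ndarray, samples: pd.DataFrame) -> pd.DataFrame:
    """Flow-cytometry style table: subset counts with consistent parents."""
    cols = {ct: cell_counts_abs[:, k] for k, ct in enumerate(CELL_TYPES)}
    cd3 = cols["CD4T"] + cols["CD8T"]
    lymph = cd3 + cols["B"] + cols["NK"]
    mono = cols["MONO_CLASSICAL"] + cols["MONO_INTERMEDIATE"] + cols["MONO_NONCLASSICAL"]
    table = pd.DataFrame(
        {
            "lymphocytes": lymph,
            "CD3": cd3,
            "CD4": cols["CD4T"],
            "CD8": cols["CD8T"],
            "monocytes": mono,
            "mono_classical": cols["MONO_CLASSICAL"],
            "mono_intermediate": cols["MONO_INTERMEDIATE"],
            "mono_nonclassical": cols["MONO_NONCLASSICAL"],
            "neutrophils": cols["NEUTROPHIL"],
        },
        index=samples.index,
    )
    table.insert(0, "group", samples["group"])
    return table


# ---------------------------------------------------------------------------
# the canonical recovery scenario
# ---------------------------------------------------------------------------


def default_acute_scenario(seed: int = 0, n_transcripts: int = 2000) -> Scenario:
    """The canonical acute-phase scenario with planted composition and
    regulation effects.

    In the acute group (RAA) relative to controls:

    * CD4+ T-cell count scaled by 1/1.5 and CD8+ by 1/1.3 (lymphopenia);
    * classical and intermediate monocyte counts scaled by 1.3;
    * MN-set transcripts actively up-regulated 2.5x per cell in their
      marker cell type (monocyte activation that composition alone cannot
      explain);
    * lymphocyte-marker transcripts (the down-regulated set) carry an
      elevated pre-mRNA fraction of 0.4 versus the 0.1 baseline.

    The chronic group (RAC) has all multipliers at 1 — by several months
    after the event the blood profile has returned to the control state —
    with sampling months spread over 3–15.
    """
    child = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    marker_config = {
        "CD4T": 10,
        "CD8T": 6,
        "B": 4,
        "NK": 4,
        "MONO_CLASSICAL": 9,
        "MONO_INTERMEDIATE": 3,
        "MONO_NONCLASSICAL": 3,
        "NEUTROPHIL": 7,
    }
    annotation = generate_annotation(
        n_transcripts, marker_config=marker_config, seed=int(child[0])
    )
    signatures = generate_signatures(annotation, seed=int(child[1]))

    by_symbol = {}
    marker_sets: dict[str, list[str]] = {ct: [] for ct in CELL_TYPES}
    for tid, row in annotation[annotation["marker_of"] != "NONE"].iterrows():
        marker_sets[row["marker_of"]].append(tid)
        by_symbol.setdefault(row["gene_id"], tid)
    genesets = GeneSetDefinition(
        transcript_map={
            sym: by_symbol[sym]
            for sym in L_GENES_DEFAULT + MN_GENES_DEFAULT
            if sym in by_symbol
        }
    )
    if len(genesets.transcript_map) != len(L_GENES_DEFAULT) + len(MN_GENES_DEFAULT):
        raise RuntimeError("named L/MN marker genes were not all placed in the annotation")

    # active regulation of MN transcripts in their own (marker) cell type
    mn_regulation: dict[str, dict[str, float]] = {}
    for sym in MN_GENES_DEFAULT:
        tid = genesets.transcript_map[sym]
        ct = annotation.at[tid, "marker_of"]
        mn_regulation.setdefault(ct, {})[tid] = 2.5

    down_set = marker_sets["CD4T"] + marker_sets["CD8T"]
    design = CohortDesign(
        cellcount_multiplier={
            "RAA": {
                "CD4T": 1.0 / 1.5,
                "CD8T": 1.0 / 1.3,
                "MONO_CLASSICAL": 1.3,
                "MONO_INTERMEDIATE": 1.3,
            },
            "RAC": {},
        },
        regulation_multiplier={"RAA": mn_regulation},
        premrna_baseline=0.1,
        premrna_override={"RAA": {tid: 0.4 for tid in down_set}},
        seed=int(child[2]),
    )
    design.validate()
    return Scenario(
        annotation=annotation,
        signatures=signatures,
        design=design,
        genesets=genesets,
        marker_sets={k: v for k, v in marker_sets.items() if v},
    )


# ---------------------------------------------------------------------------
# time-course fixture generator
# ---------------------------------------------------------------------------


def timecourse_dataset(
    n_null: int = 500,
    n_samples: int = 20,
    decay_log2: float = 2.0,
    noise_sd: float = 0.3,
    baseline_log2: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, str]:
    """Chronic-phase samples with one planted decaying transcript.

    Sampling months are integers spread over 3–15 (ties allowed, as in a
    real chronic cohort). The planted transcript starts ``decay_log2``
    log2-units above its late-time level and relaxes linearly back toward
    it; the ``n_null`` remaining transcripts fluctuate around a constant
    level with the same log-normal noise. Returns the FPKM matrix (RAC
    samples only) and the planted transcript id.
    """
    rng = np.random.default_rng(seed)
    months = np.round(np.linspace(3.0, 15.0, n_samples))
    ids = [f"NULL{i:04d}" for i in range(n_null)] + ["PLANTED"]
    log2x = baseline_log2 + rng.normal(0.0, noise_sd, size=(n_null + 1, n_samples))
    log2x[-1] += decay_log2 * (1.0 - (months - 3.0) / 12.0)
    samples = pd.DataFrame(
        {"group": "RAC", "months_since_event": months},
        index=pd.Index([f"RAC_{i + 1:02d}" for i in range(n_samples)], name="sample_id"),
    )
    values = pd.DataFrame(2.0**log2x, index=pd.Index(ids, name="transcript_id"), columns=samples.index)
    return ExpressionMatrix(values, samples, unit="FPKM"), "PLANTED"
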
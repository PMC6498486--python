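"""The L/MN index: a lymphocyte-to-monocyte/neutrophil expression ratio.

The index summarises, per blood sample, the balance between a lymphocyte
gene set (L: BCL11B, CCR7, CD2, CD27, CD3D, CD3E, CD8A, KLRB1) and a
monocyte-and-neutrophil gene set (MN: ANXA3, ARG1, CD14, GYG1, FCGR1A,
FCGR2A, IRAK3, MMP9). For each gene the expression level is first
standardised to a fold over a reference level; the index is then

    L/MN(s) = mean over L genes of standardized fold(g, s)
            / mean over MN genes of standardized fold(g, s)

Low values indicate a depressed lymphocyte transcriptional programme with
concurrent myeloid activation — the signature of the acute phase after an
aneurysm rupture. Groups are compared on the per-sample index values by
two-sided Welch t-tests (unequal variances, Satterthwaite degrees of
freedom).

The standardisation rule is the one genuinely open choice here: the default
divides each gene by its across-all-samples mean, which keeps the index
positive and makes it invariant to the overall scale of each gene. A fold
over the control-group mean and a shifted z-score are available as
alternatives; see ``standardize_folds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

__all__ = [
    "L_GENES_DEFAULT",
    "MN_GENES_DEFAULT",
    "GeneSetDefinition",
    "LMNResult",
    "standardize_folds",
    "lmn_values",
    "compare_groups",
    "lmn_index",
]

L_GENES_DEFAULT = ("BCL11B", "CCR7", "CD2", "CD27", "CD3D", "CD3E", "CD8A", "KLRB1")
MN_GENES_DEFAULT = ("ANXA3", "ARG1", "CD14", "GYG1", "FCGR1A", "FCGR2A", "IRAK3", "MMP9")


@dataclass
class GeneSetDefinition:
    """The two gene sets plus the symbol-to-transcript mapping.

    ``transcript_map`` maps each gene symbol to the measured transcript id
    (a specific transcriptional variant when the analysis is run at
    transcript resolution). When omitted, symbols are assumed to be matrix
    row ids themselves.
    """

    l_genes: tuple[str, ...] = L_GENES_DEFAULT
    mn_genes: tuple[str, ...] = MN_GENES_DEFAULT
    transcript_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.l_genes) & set(self.mn_genes)
        if overlap:
            raise ValueError(f"L and MN sets must be disjoint; shared: {sorted(overlap)}")
        if not self.l_genes or not self.mn_genes:
            raise ValueError("both gene sets must be non-empty")

    def transcript_of(self, symbol: str) -> str:
        return self.transcript_map.get(symbol, symbol)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.l_genes + self.mn_genes


def standardize_folds(
    fpkm: ExpressionMatrix,
    genesets: GeneSetDefinition,
    rule: str = "overall_mean",
    control_group: str = "C",
    zscore_shift: float = 3.0,
) -> pd.DataFrame:
    """Per-gene, per-sample standardised fold for the two gene sets.

    Rules
    -----
    ``overall_mean`` (default)
        ``fold(g, s) = x(g, s) / mean over all samples of x(g, .)``
    ``control_mean``
        fold over the mean of the control-group samples.
    ``zscore``
        ``(x - mean) / sd + zscore_shift``, floored at a small positive
        value so the downstream ratio stays defined. The shift keeps the
        typical value positive; this rule is not scale-free per gene in the
        same sense as the fold rules and exists for sensitivity analyses.

    Returns a genes-by-samples DataFrame indexed by gene symbol.
    """
    rows = {}
    for symbol in genesets.all_genes:
        tid = genesets.transcript_of(symbol)
        if tid not in fpkm.transcript_ids:
            raise KeyError(f"gene {symbol} maps to transcript {tid} absent from matrix")
        rows[symbol] = fpkm.values.loc[tid]
    x = pd.DataFrame(rows).T
    x.index.name = "gene"

    if rule == "overall_mean":
        ref = x.mean(axis=1)
        if (ref <= 0).any():
            bad = ref.index[ref <= 0]
            raise ValueError(f"gene(s) with all-zero expression: {list(bad)}")
        return x.div(ref, axis=0)
    if rule == "control_mean":
        ctrl = [s for s in fpkm.sample_ids if fpkm.samples.at[s, "group"] == control_group]
        if not ctrl:
            raise ValueError(f"no samples in control group {control_group!r}")
        ref = x[ctrl].mean(axis=1)
        if (ref <= 0).any():
            raise ValueError("control-group mean is zero for some gene")
        return x.div(ref, axis=0)
    if rule == "zscore":
        sd = x.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant gene cannot be z-scored")
        z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0) + zscore_shift
        return z.clip(lower=0.05)
    raise ValueError(f"unknown standardisation rule {rule!r}")


def lmn_values(std_folds: pd.DataFrame, genesets: GeneSetDefinition) -> pd.Series:
    """Per-sample L/MN index from standardised folds.

    ``L/MN(s) = mean_L fold / mean_MN fold``; raises if the MN mean is
    zero anywhere (cannot happen under the default fold rule with
    expressed genes).
    """
    l_mean = std_folds.loc[list(genesets.l_genes)].mean(axis=0)
    mn_mean = std_folds.loc[list(genesets.mn_genes)].mean(axis=0)
    if (mn_mean <= 0).any():
        raise ValueError("MN-set mean standardised fold is non-positive")
    out = l_mean / mn_mean
    out.name = "lmn"
    return out


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Welch t-tests on per-sample index values between groups.

    Returns one row per pair with the t statistic, Satterthwaite degrees
    of freedom and the p value.
    """
    groups = groups.loc[values.index]
    if pairs is None:
        labels = list(dict.fromkeys(groups))
        pairs = list(combinations(labels, 2))
    records = []
    for a, b in pairs:
        xa = values[groups == a].to_numpy()
        xb = values[groups == b].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a if len(xa) < 2 else b} has < 2 samples")
        res = stats.ttest_ind(xa, xb, equal_var=False)
        records.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(records)


@dataclass
class LMNResult:
    """Per-sample L/MN values with group summaries and Welch comparisons."""

    values: pd.Series
    group_stats: pd.DataFrame  # index group; columns mean, sd, n
    comparisons: pd.DataFrame  # Welch t-test table from compare_groups


def lmn_index(
    fpkm: ExpressionMatrix,
    genesets: GeneSetDefinition | None = None,
    rule: str = "overall_mean",
    pairs: list[tuple[str, str]] | None = None,
) -> LMNResult:
    """End-to-end L/MN computation: standardise, ratio, compare groups."""
    if genesets is None:
        genesets = GeneSetDefinition()
    folds = standardize_folds(fpkm, genesets, rule=rule)
    vals = lmn_values(folds, genesets)
    if (vals <= 0).any():
        raise ValueError("L/MN values must be positive")
    grp = fpkm.groups.loc[vals.index]
    group_stats = (
        vals.groupby(grp).agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    )
    comparisons = compare_groups(vals, grp, pairs=pairs)
    return LMNResult(values=vals, group_stats=group_stats, comparisons=comparisons)
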
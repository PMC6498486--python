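"""Differential transcript screening across the three clinical groups.

Per transcript, a classical one-way ANOVA on ``log2(1 + FPKM)`` with
clinical status (RAA / RAC / C) as the factor, Benjamini–Hochberg FDR
adjustment over all tested transcripts, pairwise linear fold changes on
group-mean FPKM, a two-cluster pattern assignment of the significant
transcripts (correlation distance, average linkage) and a Spearman
time-course screen over the chronic-phase samples.

The FDR gate defaults to ``q < 1e-5`` and is configurable. Pattern A is
the cluster whose mean acute-vs-control change is downward (lymphocyte
programme); pattern B is the upward (myeloid) cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionMatrix

__all__ = [
    "anova_screen",
    "bh_adjust",
    "fold_changes",
    "PatternAssignment",
    "assign_patterns",
    "timecourse_screen",
]

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = (("RAA", "C"), ("RAC", "C"), ("RAA", "RAC"))


def anova_screen(
    logmatrix: ExpressionMatrix,
    q_threshold: float = 1e-5,
) -> pd.DataFrame:
    """One-way ANOVA per transcript with BH-adjusted q values.

    Returns a DataFrame indexed by transcript with columns ``F``, ``p``,
    ``q`` and ``significant`` (q below the gate). Transcripts constant
    across all samples have no between/within variance decomposition; they
    are reported with ``F = 0, p = 1``.
    """
    if logmatrix.unit != "log2FPKMp1":
        raise ValueError(f"anova_screen expects log2FPKMp1, got {logmatrix.unit!r}")
    groups = logmatrix.groups
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    blocks = []
    for g in labels:
        cols = [s for s in logmatrix.sample_ids if groups[s] == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        blocks.append(logmatrix.values[cols].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows handled explicitly below
        res = stats.f_oneway(*blocks, axis=1)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    constant = logmatrix.values.nunique(axis=1).to_numpy() == 1
    bad = ~np.isfinite(F) | constant
    F[bad] = 0.0
    p[bad] = 1.0
    q = bh_adjust(p)
    return pd.DataFrame(
        {"F": F, "p": p, "q": q, "significant": q < q_threshold},
        index=logmatrix.transcript_ids,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values.

    ``q(i) = min_{j: p(j) >= p(i)} m * p(j) / rank(j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(
    fpkm: ExpressionMatrix,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Pairwise linear fold changes of group-mean FPKM.

    ``fold(a/b) = (mean_a + pseudocount) / (mean_b + pseudocount)``; the
    default pseudocount of 0.1 (the detection floor) stabilises ratios of
    weakly expressed transcripts. Returns columns ``fold_<A>_vs_<B>``.
    """
    if fpkm.unit != "FPKM":
        raise ValueError(f"fold_changes expects FPKM, got {fpkm.unit!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    groups = fpkm.groups
    means = {}
    for a, b in pairs:
        for g in (a, b):
            if g not in means:
                cols = [s for s in fpkm.sample_ids if groups[s] == g]
                if not cols:
                    raise ValueError(f"empty group {g!r}")
                means[g] = fpkm.values[cols].mean(axis=1)
    out = {}
    for a, b in pairs:
        out[f"fold_{a}_vs_{b}"] = (means[a] + pseudocount) / (means[b] + pseudocount)
    return pd.DataFrame(out, index=fpkm.transcript_ids)


@dataclass
class PatternAssignment:
    """Two-cluster pattern labels with dendrogram leaf order.

    ``labels`` maps transcripts to ``"A"`` (down in RAA vs C) or ``"B"``
    (up); ``degenerate`` flags inputs whose profiles were effectively
    identical, where a two-way cut would be fabricated — all transcripts
    then share one label.
    """

    labels: pd.Series
    leaf_order: list[str]
    degenerate: bool
    excluded: list[str]


def assign_patterns(
    logmatrix: ExpressionMatrix,
    n_clusters: int = 2,
    contrast: tuple[str, str] = ("RAA", "C"),
) -> PatternAssignment:
    """Cluster significant transcripts into expression patterns.

    Hierarchical clustering with distance ``1 - Pearson correlation``
    across samples and average linkage, cut into ``n_clusters`` (default
    2, the A/B patterns). The cluster with the lower mean
    ``contrast[0] - contrast[1]`` log difference is labelled A (down), the
    other B. Zero-variance rows cannot enter a correlation distance and
    are excluded with a logged warning.
    """
    X = logmatrix.values
    var = X.var(axis=1)
    excluded = list(X.index[var == 0])
    if excluded:
        logger.warning("excluding %d zero-variance transcript(s) from clustering", len(excluded))
        X = X.loc[var > 0]
    if len(X) < 2:
        raise ValueError("need at least 2 variable transcripts to cluster")

    dist = pdist(X.to_numpy(), metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = hierarchy.linkage(dist, method="average")
    leaf_order = [X.index[i] for i in hierarchy.leaves_list(Z)]

    if np.max(dist) < 1e-12:
        labels = pd.Series("A", index=X.index, name="pattern")
        return PatternAssignment(labels, leaf_order, degenerate=True, excluded=excluded)

    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    if len(np.unique(flat)) < n_clusters:
        labels = pd.Series("A", index=X.index, name="pattern")
        return PatternAssignment(labels, leaf_order, degenerate=True, excluded=excluded)

    groups = logmatrix.groups
    a_cols = [s for s in logmatrix.sample_ids if groups[s] == contrast[0]]
    b_cols = [s for s in logmatrix.sample_ids if groups[s] == contrast[1]]
    if not a_cols or not b_cols:
        raise ValueError(f"contrast groups {contrast} not present")
    delta = X[a_cols].mean(axis=1) - X[b_cols].mean(axis=1)

    # order clusters by mean contrast: most-downregulated cluster is A
    cluster_delta = {c: delta[flat == c].mean() for c in np.unique(flat)}
    order = sorted(cluster_delta, key=cluster_delta.get)
    names = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    labels = pd.Series([names[c] for c in flat], index=X.index, name="pattern")
    return PatternAssignment(labels, leaf_order, degenerate=False, excluded=excluded)


def timecourse_screen(
    fpkm: ExpressionMatrix,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Spearman screen of expression against months since the event.

    Runs on the chronic-phase (RAC) samples of ``fpkm``; each transcript's
    abundance is rank-correlated with the sampling time. A transcript is a
    hit when ``|R|`` exceeds ``r_threshold`` and ``p < p_threshold`` (the
    magnitude is thresholded: transcripts elevated acutely decay, so the
    informative correlations are negative). Constant transcripts have no
    defined rank correlation and are excluded with a logged message.

    Returns a DataFrame with columns ``R``, ``p``, ``direction`` and
    ``is_hit`` for every testable transcript.
    """
    rac = [s for s in fpkm.sample_ids if fpkm.samples.at[s, "group"] == "RAC"]
    if len(rac) < 5:
        raise ValueError("need at least 5 chronic-phase samples with time values")
    if "months_since_event" not in fpkm.samples.columns:
        raise ValueError("sample sheet lacks a months_since_event column")
    months = fpkm.samples.loc[rac, "months_since_event"].astype(float)
    if months.isna().any():
        raise ValueError("months_since_event missing for some RAC samples")
    X = fpkm.values[rac]

    records = []
    n_constant = 0
    t = months.to_numpy()
    for tid, row in X.iterrows():
        x = row.to_numpy()
        if np.all(x == x[0]):
            n_constant += 1
            continue
        r, p = stats.spearmanr(x, t)
        records.append(
            {
                "transcript_id": tid,
                "R": float(r),
                "p": float(p),
                "direction": "down" if r < 0 else "up",
                "is_hit": bool(abs(r) > r_threshold and p < p_threshold),
            }
        )
    if n_constant:
        logger.info("excluded %d constant transcript(s) from time-course screen", n_constant)
    return pd.DataFrame.from_records(records).set_index("transcript_id") if records else pd.DataFrame(
        columns=["R", "p", "direction", "is_hit"]
    )
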
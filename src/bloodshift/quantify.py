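"""Abundance quantification for bulk blood RNA-seq count matrices.

This module owns the :class:`ExpressionMatrix` container used throughout the
package and the three standard quantification steps applied before any
statistics:

* :func:`compute_fpkm` — length- and depth-normalise fragment counts to FPKM
  (fragments per kilobase of transcript per million mapped fragments),
* :func:`detection_filter` — select transcripts whose average abundance
  clears a detection (``>= 0.1`` FPKM) or basal-expression (``> 0.5`` FPKM)
  threshold,
* :func:`log_transform` — the variance-stabilising ``log2(1 + x)`` transform
  under which group comparisons by ANOVA are performed.

All matrices are transcripts (rows) by samples (columns); sample metadata
(group label, months since the event for chronic-phase samples) travels with
the matrix so downstream group statistics cannot lose track of the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNITS",
    "ExpressionMatrix",
    "compute_fpkm",
    "detection_filter",
    "log_transform",
]

#: Recognised unit tags, in the order the pipeline produces them.
UNITS = ("counts", "FPKM", "log2FPKMp1")

GROUPS = ("RAA", "RAC", "C")


@dataclass
class ExpressionMatrix:
    """A transcripts-by-samples abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame with transcript ids as the index and sample ids as
        columns. All entries must be finite and non-negative.
    samples
        Sample sheet indexed by sample id, with at least a ``group`` column
        (labels such as RAA / RAC / C) and optionally a
        ``months_since_event`` column for chronic-phase samples.
    unit
        One of ``counts``, ``FPKM`` or ``log2FPKMp1``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if "group" not in self.samples.columns:
            raise ValueError("sample sheet must carry a 'group' column")
        if not self.values.columns.equals(self.samples.index):
            # tolerate re-ordered metadata, but every sample must be described
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample sheet does not describe the matrix columns")
            self.samples = self.samples.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.samples["group"].isna().any():
            raise ValueError("every sample needs a group label")

    # -- convenience accessors -------------------------------------------------

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def group_samples(self, group: str) -> list[str]:
        ids = [s for s in self.sample_ids if self.samples.at[s, "group"] == group]
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return ids

    def subset_transcripts(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.transcript_ids)
        if missing:
            raise KeyError(f"transcripts absent from matrix: {sorted(missing)[:5]}")
        return replace(self, values=self.values.loc[ids])

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids], self.unit)


def compute_fpkm(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame,
    total_fragments: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert fragment counts to FPKM.

    ``FPKM(t, s) = count(t, s) / (exonic_length(t)/1e3 * total_fragments(s)/1e6)``

    Only the exonic (mature-transcript) length enters the denominator;
    intronic reads are quantified separately by the transcript-structure
    module and are not part of the mature abundance estimate.

    Parameters
    ----------
    counts
        Count-unit matrix.
    annotation
        Transcript annotation indexed by transcript id with an
        ``exonic_length`` column in base pairs (>= 1).
    total_fragments
        Per-sample mapped-fragment totals. Defaults to the column sums of
        ``counts`` (i.e. the provided matrix is the whole library).
    """
    if counts.unit != "counts":
        raise ValueError(f"compute_fpkm expects counts, got unit {counts.unit!r}")
    missing = counts.transcript_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(f"transcripts missing from annotation: {list(missing[:5])}")
    lengths = annotation.loc[counts.transcript_ids, "exonic_length"].astype(float)
    if (lengths < 1).any():
        raise ValueError("exonic_length must be >= 1 bp for every transcript")
    if total_fragments is None:
        total_fragments = counts.values.sum(axis=0)
    total_fragments = pd.Series(total_fragments).loc[counts.sample_ids].astype(float)
    if (total_fragments <= 0).any():
        bad = total_fragments.index[total_fragments <= 0]
        raise ValueError(f"zero-depth sample(s): {list(bad)}")
    denom = np.outer(lengths / 1e3, total_fragments / 1e6)
    fpkm = counts.values / denom
    return ExpressionMatrix(fpkm, counts.samples, unit="FPKM")


def detection_filter(
    fpkm: ExpressionMatrix,
    threshold: float = 0.1,
    strict: bool = False,
    mode: str = "mean",
) -> pd.Index:
    """Return transcripts whose abundance clears an FPKM threshold.

    The detection screen keeps transcripts with mean FPKM ``>= 0.1``
    (``strict=False``); the basal-expression screen uses ``> 0.5``
    (``strict=True`` with ``threshold=0.5``).

    Parameters
    ----------
    mode
        ``"mean"`` compares the across-sample mean to the threshold;
        ``"any"`` keeps a transcript if any single sample clears it.
    """
    if fpkm.unit != "FPKM":
        raise ValueError(f"detection_filter expects FPKM, got unit {fpkm.unit!r}")
    if mode == "mean":
        stat = fpkm.values.mean(axis=1)
    elif mode == "any":
        stat = fpkm.values.max(axis=1)
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    keep = stat > threshold if strict else stat >= threshold
    return fpkm.transcript_ids[keep.to_numpy()]


def log_transform(fpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(1 + x)``; strictly monotone and invertible."""
    if fpkm.unit != "FPKM":
        raise ValueError(f"log_transform expects FPKM, got unit {fpkm.unit!r}")
    return ExpressionMatrix(np.log2(1.0 + fpkm.values), fpkm.samples, unit="log2FPKMp1")
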
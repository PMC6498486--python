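"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is text: TSV matrices with a JSON sidecar carrying the unit tag
and provenance (seed), a GTF export of the generated annotation (exon
features; introns are the within-transcript gaps), a sample sheet, the
flow-cytometry cell-count table, a two-column gene-set file and JSON truth
tables.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .lmn import GeneSetDefinition
from .quantify import ExpressionMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_cell_counts",
    "read_cell_counts",
    "write_gene_sets",
    "read_gene_sets",
    "write_gtf",
    "read_gtf",
    "write_json",
    "read_json",
]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def write_matrix(em: ExpressionMatrix, path: str | Path, seed: int | None = None) -> None:
    """TSV matrix (rows=transcripts, cols=samples) + ``<path>.meta.json``.

    The sidecar carries the unit tag and, when given, the generating seed,
    so a re-read matrix cannot silently change units.
    """
    path = Path(path)
    em.values.to_csv(path, sep="\t", index_label="transcript_id")
    meta = {"unit": em.unit}
    if seed is not None:
        meta["seed"] = int(seed)
    write_json(meta, path.with_suffix(path.suffix + ".meta.json"))


def read_matrix(path: str | Path, samples: pd.DataFrame) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="transcript_id")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    unit = read_json(meta_path)["unit"] if meta_path.exists() else "counts"
    return ExpressionMatrix(values, samples.loc[values.columns], unit=unit)


# ---------------------------------------------------------------------------
# sample sheet / cell counts
# ---------------------------------------------------------------------------


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "group" not in samples.columns:
        raise ValueError("sample sheet needs a 'group' column")
    return samples


def write_cell_counts(cellcounts: pd.DataFrame, path: str | Path) -> None:
    cellcounts.to_csv(path, sep="\t", index_label="sample_id")


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def write_gene_sets(genesets: GeneSetDefinition, path: str | Path) -> None:
    """Two-column TSV (symbol, set in {L, MN}) with optional transcript_id."""
    rows = []
    for sym in genesets.l_genes:
        rows.append((sym, "L", genesets.transcript_map.get(sym, "")))
    for sym in genesets.mn_genes:
        rows.append((sym, "MN", genesets.transcript_map.get(sym, "")))
    pd.DataFrame(rows, columns=["symbol", "set", "transcript_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path: str | Path) -> GeneSetDefinition:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"symbol", "set"} <= set(df.columns):
        raise ValueError("gene-set file needs 'symbol' and 'set' columns")
    l_genes = tuple(df.loc[df["set"] == "L", "symbol"])
    mn_genes = tuple(df.loc[df["set"] == "MN", "symbol"])
    mapping = {}
    if "transcript_id" in df.columns:
        for _, row in df.iterrows():
            if row["transcript_id"]:
                mapping[row["symbol"]] = row["transcript_id"]
    return GeneSetDefinition(l_genes=l_genes, mn_genes=mn_genes, transcript_map=mapping)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(annotation: pd.DataFrame, path: str | Path, source: str = "bloodshift") -> None:
    """Write the annotation as GTF exon features on a synthetic contig.

    Transcripts are laid head-to-tail on ``chr1`` with a 1 kb gap. A
    transcript with intronic sequence is written as two exons separated by
    a gap of its intronic length, so ``read_gtf`` recovers exonic and
    intronic lengths exactly from coordinates alone.
    """
    lines = []
    pos = 1
    for tid, row in annotation.iterrows():
        exonic = int(row["exonic_length"])
        intronic = int(row["intronic_length"])
        attrs = (
            f'gene_id "{row["gene_id"]}"; transcript_id "{tid}"; '
            f'transcript_biotype "{row["biotype"]}"'
        )
        if row["marker_of"] != "NONE":
            attrs += f'; marker_of "{row["marker_of"]}"'
        if intronic > 0:
            e1 = max(exonic // 2, 1)
            e2 = exonic - e1
            start1, end1 = pos, pos + e1 - 1
            start2 = end1 + intronic + 1
            end2 = start2 + e2 - 1
            tx_end = end2
            exons = [(start1, end1), (start2, end2)]
        else:
            tx_end = pos + exonic - 1
            exons = [(pos, tx_end)]
        lines.append(
            f"chr1\t{source}\ttranscript\t{pos}\t{tx_end}\t.\t+\t.\t{attrs};"
        )
        for i, (s, e) in enumerate(exons, start=1):
            lines.append(
                f"chr1\t{source}\texon\t{s}\t{e}\t.\t+\t.\t{attrs}; "
                f'exon_number "{i}";'
            )
        pos = tx_end + 1001
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Reconstruct the annotation table from a GTF file.

    Exonic length is the sum of exon lengths; intronic length is the sum
    of within-transcript gaps between consecutive exons. The biotype is
    taken from ``transcript_biotype`` (falling back to ``gene_biotype``)
    and the marker tag from the optional ``marker_of`` attribute.
    """
    records: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "exon":
            continue
        attrs = dict(_ATTR_RE.findall(fields[8]))
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ValueError("GTF exon feature without transcript_id")
        rec = records.setdefault(
            tid,
            {
                "gene_id": attrs.get("gene_id", tid),
                "biotype": attrs.get("transcript_biotype", attrs.get("gene_biotype", "other")),
                "marker_of": attrs.get("marker_of", "NONE"),
                "exons": [],
            },
        )
        rec["exons"].append((int(fields[3]), int(fields[4])))
    if not records:
        raise ValueError(f"no exon features found in {path}")
    rows = []
    for tid, rec in records.items():
        exons = sorted(rec["exons"])
        exonic = sum(e - s + 1 for s, e in exons)
        intronic = sum(max(exons[i + 1][0] - exons[i][1] - 1, 0) for i in range(len(exons) - 1))
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": rec["gene_id"],
                "biotype": rec["biotype"],
                "exonic_length": exonic,
                "intronic_length": intronic,
                "marker_of": rec["marker_of"],
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
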
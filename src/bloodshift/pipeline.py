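"""End-to-end orchestration: simulate -> quantify -> de -> lmn -> structure -> attribute.

Each stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be run together or one at a time from the CLI. A
JSON manifest records the seed, the thresholds and a SHA-256 checksum of
every output file; runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, attribution, diffexpr, io, lmn, quantify, structure, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "de", "lmn", "structure", "attribute")


class PipelineError(RuntimeError):
    """A stage failed or its inputs from an earlier stage are missing."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All knobs for one pipeline run.

    Thresholds mirror the analysis defaults: detection at mean FPKM >= 0.1,
    basal expression at > 0.5, ANOVA significance gate at q < 1e-5, fold
    gate at 2, time-course screen at |R| > 0.7 and p < 0.01, attribution
    discordance threshold tau = 0.5 log2 units.
    """

    outdir: Path = Path("bloodshift_run")
    seed: int = 1
    n_transcripts: int = 2000
    detection_threshold: float = 0.1
    basal_threshold: float = 0.5
    fdr_q: float = 1e-5
    fold_gate: float = 2.0
    r_threshold: float = 0.7
    p_threshold: float = 0.01
    tau: float = 0.5
    fold_pseudocount: float = 0.1
    ei_pseudocount: float = 1.0
    lmn_rule: str = "overall_mean"
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for name in (
            "detection_threshold",
            "basal_threshold",
            "fdr_q",
            "r_threshold",
            "p_threshold",
            "tau",
            "fold_pseudocount",
            "ei_pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.r_threshold > 1:
            raise ValueError("r_threshold cannot exceed 1")
        if self.n_transcripts < 100:
            raise ValueError("n_transcripts below 100 leaves no room for the marker sets")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["stages"] = list(d["stages"])
        return d


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _require(cfg: RunConfig, stage: str, *names: str) -> list[Path]:
    paths = [cfg.outdir / n for n in names]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise PipelineError(
            stage, f"missing input(s) {missing}; run the producing stage first"
        )
    return paths


def _load_samples(cfg: RunConfig, stage: str) -> pd.DataFrame:
    (path,) = _require(cfg, stage, "samples.tsv")
    return io.read_sample_sheet(path)


def _stage_simulate(cfg: RunConfig) -> list[Path]:
    scenario = synthetic.default_acute_scenario(cfg.seed, n_transcripts=cfg.n_transcripts)
    exonic, intronic, cells, truth = synthetic.generate_cohort(
        scenario.annotation, scenario.signatures, scenario.design
    )
    out = cfg.outdir
    scenario.annotation.to_csv(out / "annotation.tsv", sep="\t")
    io.write_gtf(scenario.annotation, out / "annotation.gtf")
    io.write_matrix(exonic, out / "exonic_counts.tsv", seed=cfg.seed)
    io.write_matrix(intronic, out / "intronic_counts.tsv", seed=cfg.seed)
    io.write_sample_sheet(exonic.samples, out / "samples.tsv")
    io.write_cell_counts(cells, out / "cell_counts.tsv")
    io.write_gene_sets(scenario.genesets, out / "gene_sets.tsv")
    io.write_json(
        {
            "seed": cfg.seed,
            "expected_folds": {
                c: truth.expected_folds[c].to_dict() for c in truth.expected_folds
            },
            "expected_count_folds": {
                c: truth.expected_count_folds[c].to_dict()
                for c in truth.expected_count_folds
            },
            "marker_sets": scenario.marker_sets,
        },
        out / "truth.json",
    )
    return sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")


def _stage_quantify(cfg: RunConfig) -> list[Path]:
    samples = _load_samples(cfg, "quantify")
    _require(cfg, "quantify", "exonic_counts.tsv", "annotation.tsv")
    annotation = pd.read_csv(cfg.outdir / "annotation.tsv", sep="\t", index_col="transcript_id")
    counts = io.read_matrix(cfg.outdir / "exonic_counts.tsv", samples)
    fpkm = quantify.compute_fpkm(counts, annotation)
    detected = quantify.detection_filter(fpkm, cfg.detection_threshold)
    fpkm = fpkm.subset_transcripts(detected)
    logm = quantify.log_transform(fpkm)
    io.write_matrix(fpkm, cfg.outdir / "fpkm.tsv", seed=cfg.seed)
    io.write_matrix(logm, cfg.outdir / "log2_fpkm.tsv", seed=cfg.seed)
    (cfg.outdir / "detected_transcripts.txt").write_text("\n".join(detected) + "\n")
    return [
        cfg.outdir / "fpkm.tsv",
        cfg.outdir / "fpkm.tsv.meta.json",
        cfg.outdir / "log2_fpkm.tsv",
        cfg.outdir / "log2_fpkm.tsv.meta.json",
        cfg.outdir / "detected_transcripts.txt",
    ]


def _stage_de(cfg: RunConfig) -> list[Path]:
    samples = _load_samples(cfg, "de")
    _require(cfg, "de", "fpkm.tsv", "log2_fpkm.tsv")
    fpkm = io.read_matrix(cfg.outdir / "fpkm.tsv", samples)
    logm = io.read_matrix(cfg.outdir / "log2_fpkm.tsv", samples)
    res = diffexpr.anova_screen(logm, q_threshold=cfg.fdr_q)
    folds = diffexpr.fold_changes(fpkm, pseudocount=cfg.fold_pseudocount)
    table = res.join(folds)
    sig = table.index[table["significant"]]
    table["pattern"] = "none"
    leaf_order: list[str] = []
    if len(sig) >= 2:
        patterns = diffexpr.assign_patterns(logm.subset_transcripts(sig))
        table.loc[patterns.labels.index, "pattern"] = patterns.labels
        leaf_order = patterns.leaf_order
    table.to_csv(cfg.outdir / "de_results.tsv", sep="\t", index_label="transcript_id")
    (cfg.outdir / "pattern_leaf_order.txt").write_text("\n".join(leaf_order) + "\n")
    tc = diffexpr.timecourse_screen(
        fpkm, r_threshold=cfg.r_threshold, p_threshold=cfg.p_threshold
    )
    tc[tc["is_hit"]].to_csv(cfg.outdir / "timecourse_hits.tsv", sep="\t")
    return [
        cfg.outdir / "de_results.tsv",
        cfg.outdir / "pattern_leaf_order.txt",
        cfg.outdir / "timecourse_hits.tsv",
    ]


def _stage_lmn(cfg: RunConfig) -> list[Path]:
    samples = _load_samples(cfg, "lmn")
    _require(cfg, "lmn", "fpkm.tsv", "gene_sets.tsv")
    fpkm = io.read_matrix(cfg.outdir / "fpkm.tsv", samples)
    genesets = io.read_gene_sets(cfg.outdir / "gene_sets.tsv")
    result = lmn.lmn_index(fpkm, genesets, rule=cfg.lmn_rule)
    out = result.values.to_frame()
    out["group"] = fpkm.groups
    out.to_csv(cfg.outdir / "lmn_values.tsv", sep="\t", index_label="sample_id")
    io.write_json(
        {
            "seed": cfg.seed,
            "group_means": result.group_stats["mean"].to_dict(),
            "comparisons": result.comparisons.to_dict(orient="records"),
        },
        cfg.outdir / "lmn_summary.json",
    )
    return [cfg.outdir / "lmn_values.tsv", cfg.outdir / "lmn_summary.json"]


def _stage_structure(cfg: RunConfig) -> list[Path]:
    samples = _load_samples(cfg, "structure")
    _require(
        cfg, "structure", "annotation.tsv", "fpkm.tsv", "de_results.tsv",
        "exonic_counts.tsv", "intronic_counts.tsv",
    )
    annotation = pd.read_csv(cfg.outdir / "annotation.tsv", sep="\t", index_col="transcript_id")
    fpkm = io.read_matrix(cfg.outdir / "fpkm.tsv", samples)
    de = pd.read_csv(cfg.outdir / "de_results.tsv", sep="\t", index_col="transcript_id")
    regulated = de.index[de["significant"]]
    if len(regulated) == 0:
        raise PipelineError("structure", "no significant transcripts to profile")
    basal = quantify.detection_filter(fpkm, cfg.basal_threshold, strict=True)
    prof_reg = structure.biotype_profile(regulated, annotation)
    prof_basal = structure.biotype_profile(basal, annotation)
    prof = prof_reg.join(prof_basal, lsuffix="_regulated", rsuffix="_basal", how="outer").fillna(0)
    prof.to_csv(cfg.outdir / "biotype_profile.tsv", sep="\t")

    exonic = io.read_matrix(cfg.outdir / "exonic_counts.tsv", samples)
    intronic = io.read_matrix(cfg.outdir / "intronic_counts.tsv", samples)
    up = [t for t in regulated if de.at[t, "pattern"] == "B"]
    down = [t for t in regulated if de.at[t, "pattern"] == "A"]
    if not up or not down:
        raise PipelineError("structure", "need both up- and downregulated transcripts")
    raa = [s for s in exonic.sample_ids if exonic.samples.at[s, "group"] == "RAA"]
    comp = structure.exon_intron_score(
        exonic,
        intronic,
        genes_a=sorted({annotation.at[t, "gene_id"] for t in up}),
        genes_b=sorted({annotation.at[t, "gene_id"] for t in down}),
        pseudocount=cfg.ei_pseudocount,
        annotation=annotation,
        samples=raa,
    )
    comp.per_gene.to_csv(cfg.outdir / "exon_intron_scores.tsv", sep="\t", index_label="gene_id")
    io.write_json(
        {
            "seed": cfg.seed,
            "median_ratio_up": comp.median_a,
            "median_ratio_down": comp.median_b,
            "mannwhitney_u": comp.u_statistic,
            "p_value": comp.p_value,
        },
        cfg.outdir / "exon_intron_summary.json",
    )
    return [
        cfg.outdir / "biotype_profile.tsv",
        cfg.outdir / "exon_intron_scores.tsv",
        cfg.outdir / "exon_intron_summary.json",
    ]


def _stage_attribute(cfg: RunConfig) -> list[Path]:
    samples = _load_samples(cfg, "attribute")
    _require(cfg, "attribute", "fpkm.tsv", "cell_counts.tsv", "truth.json")
    fpkm = io.read_matrix(cfg.outdir / "fpkm.tsv", samples)
    cells = io.read_cell_counts(cfg.outdir / "cell_counts.tsv")
    marker_sets = io.read_json(cfg.outdir / "truth.json")["marker_sets"]
    genesets = io.read_gene_sets(cfg.outdir / "gene_sets.tsv")
    populations = {  # cell-count column -> marker transcript ids compared to it
        "CD4": marker_sets.get("CD4T", []),
        "monocytes": [genesets.transcript_of(s) for s in genesets.mn_genes],
    }
    rows = []
    for column, candidates in populations.items():
        markers = [t for t in candidates if t in set(fpkm.transcript_ids)]
        if not markers:
            raise PipelineError("attribute", f"no detected markers for {column}")
        cf = attribution.count_fold(cells, column, "RAA", "C")
        mf = attribution.marker_fold(fpkm, markers, "RAA", "C", pseudocount=cfg.fold_pseudocount)
        verdict = attribution.attribute(cf, mf, population=column, tau=cfg.tau)
        rows.append(dataclasses.asdict(verdict))
    table = pd.DataFrame(rows).set_index("population")
    table.to_csv(cfg.outdir / "attribution.tsv", sep="\t")
    io.write_json({"seed": cfg.seed, "verdicts": rows}, cfg.outdir / "attribution.json")
    return [cfg.outdir / "attribution.tsv", cfg.outdir / "attribution.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "de": _stage_de,
    "lmn": _stage_lmn,
    "structure": _stage_structure,
    "attribute": _stage_attribute,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in order and write ``manifest.json``.

    Returns the manifest dict. A stage failure raises
    :class:`PipelineError` carrying the stage name.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "bloodshift",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs}
        }
    io.write_json(manifest, cfg.outdir / "manifest.json")
    return manifest
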
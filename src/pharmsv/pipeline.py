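"""End-to-end orchestration: config, stage logging, and summary reports.

``run_pipeline`` chains the stages — ingest, record filters, interval
clustering, gene assignment + functional classification, regulatory
overlap + co-expression, per-individual burdens, eQTL cross-reference and
the non-coding attribution — with per-stage input/output record counts
logged and conserved (every dropped record carries a reason code).  A
stage failure aborts with the stage name and a manifest of the outputs
produced so far.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attribution as attr_mod
from .annotate import AnnotatedSV, FunctionalClass, annotate_svs, annotation_frame, density_table
from .burden import BurdenReport, expected_burden
from .eqtl_xref import eqtl_report, match_eqtl, read_eqtl_tsv
from .genome_model import GeneSet, load_gene_models
from .regulatory import (
    DEFAULT_TISSUES,
    coexpression_filter,
    filter_tfbs,
    hits_frame,
    overlap_tfbs,
    read_expression_tsv,
    read_tfbs_bed,
)
from .sv_cluster import cluster_cohort
from .sv_ingest import POPULATIONS, filter_sv_records, read_sv_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial-output manifest."""

    def __init__(self, stage: str, manifest: list[str], cause: Exception):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {cause} "
                         f"(outputs so far: {manifest})")


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    annotation: str = ""
    annotation_format: str = "gtf"
    panel: str = ""
    sv_table: str = ""
    sv_dialect: str = "tsv"
    tfbs_bed: str | None = None
    expression: str | None = None
    eqtls: str | None = None

    tissue_panel: tuple[str, ...] = DEFAULT_TISSUES
    tfbs_min_score: int = 200
    tfbs_min_studies: int = 2
    expression_threshold: float = 1.0
    maf_common: float = 0.01
    near_bp: int = 100
    min_overlap: float = 0.99
    max_dist: int = 0
    flank: int = 0
    populations: tuple[str, ...] = POPULATIONS
    seed: int = 1
    n_individuals: int = 100_000
    n_snv_adme: float = attr_mod.DEFAULT_N_SNV_ADME
    n_snv_targets: float = attr_mod.DEFAULT_N_SNV_TARGETS
    out_dir: str | None = None

    def validate(self) -> None:
        if not self.tissue_panel:
            raise ConfigError("tissue_panel must be non-empty")
        if not (0 <= self.min_overlap <= 1):
            raise ConfigError("min_overlap must lie in [0, 1]")
        if not (0 <= self.maf_common <= 1):
            raise ConfigError("maf_common must lie in [0, 1]")
        if self.near_bp < 0 or self.max_dist < 0 or self.flank < 0:
            raise ConfigError("near_bp, max_dist and flank must be >= 0")
        if self.expression_threshold < 0 or self.tfbs_min_score < 0:
            raise ConfigError("thresholds must be >= 0")
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissue_panel", "populations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["tissue_panel"] = list(self.tissue_panel)
        d["populations"] = list(self.populations)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    gene_set: GeneSet
    sv_table: object
    clusters: list
    annotated: list[AnnotatedSV]
    annotated_frame: pd.DataFrame
    density: object
    regulatory_hits: list
    burden_reports: dict[str, BurdenReport]
    eqtl_matches: list
    eqtl_table: pd.DataFrame
    attribution: dict
    summary: dict
    stage_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Report helpers


def format_percent(x: float, headline: bool = False) -> str:
    """Headline shares round to the nearest integer, table cells to 0.1."""
    return f"{round(x)}%" if headline else f"{x:.1f}%"


def partition_summary(n_total: int, n_exonic: int,
                      n_tfbs_overlap: int | None = None) -> dict:
    """Coding/non-coding bookkeeping for a pharmacogenomic SV set.

    Given the total SV count and the exonic count, reports the coding
    share (exact and as the rounded headline percentage) and the
    non-coding remainder; optionally the share of non-coding SVs that
    overlap >= 1 TFBS.
    """
    if not (0 <= n_exonic <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_exonic <= n_total, n_total > 0")
    coding_pct = 100.0 * n_exonic / n_total
    out = {
        "n_total": n_total,
        "n_coding": n_exonic,
        "n_noncoding": n_total - n_exonic,
        "coding_pct": coding_pct,
        "coding_pct_headline": round(coding_pct),
        "noncoding_pct": 100.0 - coding_pct,
    }
    if n_tfbs_overlap is not None:
        if not (0 <= n_tfbs_overlap <= out["n_noncoding"]):
            raise ValueError("n_tfbs_overlap must not exceed the non-coding count")
        out["n_tfbs_overlap"] = n_tfbs_overlap
        out["tfbs_pct"] = round(100.0 * n_tfbs_overlap / out["n_noncoding"], 1)
    return out


def summarize_counts(annotated: list[AnnotatedSV]) -> dict:
    """Totals, coding split, rarity split per gene family, and size medians."""
    df = annotation_frame(annotated)
    if df.empty:
        return {"n_total": 0}
    loci = df.drop_duplicates(subset=["sv_id", "gene_id"])
    n_total = len(loci)
    n_coding = int(loci["coding"].sum())
    out = partition_summary(n_total, n_coding) if n_total else {"n_total": 0}
    out["functional_class_counts"] = (
        df["functional_class"].value_counts().to_dict()
    )
    rar = (
        df[df["rarity"] != ""]
        .groupby(["panel_class", "rarity"])["sv_id"].nunique()
        .unstack(fill_value=0)
    )
    out["rarity_by_class"] = {
        cls: dict(row) for cls, row in rar.iterrows()
    }
    sizes = loci.groupby("sv_type")["size_bp"].median()
    out["median_size_by_type"] = {k: float(v) for k, v in sizes.items()}
    return out


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on the configured inputs; see the module docstring."""
    config.validate()
    manifest: list[str] = []
    stage_log: list[dict] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def log_stage(stage: str, n_in, n_out):
        logger.info("stage %-12s: %s -> %s records", stage, n_in, n_out)
        stage_log.append({"stage": stage, "n_in": n_in, "n_out": n_out})

    def emit(name: str, df: pd.DataFrame):
        if out_dir is not None:
            path = out_dir / name
            df.to_csv(path, sep="\t", index=False)
            manifest.append(str(path))

    stage = "load_genes"
    try:
        gene_set = load_gene_models(
            config.annotation, config.panel, fmt=config.annotation_format,
            flank=config.flank,
        )
        log_stage(stage, "-", len(gene_set))

        stage = "ingest"
        raw = read_sv_table(config.sv_table, dialect=config.sv_dialect)
        log_stage(stage, raw.n_input, len(raw))

        stage = "filter"
        table = filter_sv_records(raw)
        if not table.conserved():
            raise RuntimeError("record-count conservation violated after filtering")
        log_stage(stage, len(raw), len(table))

        stage = "cluster"
        clusters = cluster_cohort(table, max_dist=config.max_dist)
        log_stage(stage, len(table), len(clusters))

        stage = "annotate"
        annotated = annotate_svs(clusters, gene_set)
        ann_df = annotation_frame(annotated)
        emit("annotated_svs.tsv", ann_df)
        log_stage(stage, len(clusters), len(annotated))

        stage = "density"
        density = density_table(
            annotated, gene_set, compare=[("ADME", "target")], by="panel_group",
        )
        emit("density.tsv", density.per_gene)
        log_stage(stage, len(annotated), len(density.per_gene))

        stage = "regulatory"
        hits = []
        noncoding = [a for a in annotated if not a.coding]
        if config.tfbs_bed and config.expression:
            peaks = read_tfbs_bed(config.tfbs_bed)
            kept_peaks = filter_tfbs(peaks, config.tfbs_min_score,
                                     config.tfbs_min_studies)
            pairs = overlap_tfbs(noncoding, kept_peaks)
            expr = read_expression_tsv(config.expression)
            hits = coexpression_filter(
                pairs, expr, tissues=config.tissue_panel,
                threshold=config.expression_threshold, gene_set=gene_set,
            )
            emit("regulatory_hits.tsv", hits_frame(hits))
            log_stage(stage, len(pairs), len(hits))
        else:
            log_stage(stage, 0, 0)

        stage = "burden"
        burden_reports = {"global": expected_burden(annotated, "global")}
        for pop in config.populations:
            burden_reports[pop] = expected_burden(annotated, pop)
        burden_df = pd.concat(
            [r.table.assign(population=p) for p, r in burden_reports.items()],
            ignore_index=True,
        )
        emit("burden.tsv", burden_df)
        log_stage(stage, len(annotated), len(burden_df))

        stage = "eqtl"
        matches, eqtl_df = [], pd.DataFrame()
        if config.eqtls:
            eqtls = read_eqtl_tsv(config.eqtls)
            matches = match_eqtl(eqtls, clusters, near_bp=config.near_bp,
                                 min_overlap=config.min_overlap)
            eqtl_df = eqtl_report(matches, annotated, hits)
            emit("eqtl_report.tsv", eqtl_df)
            log_stage(stage, len(eqtls), len(eqtl_df))
        else:
            log_stage(stage, 0, 0)

        stage = "attribution"
        seen: set[str] = set()
        n_ncsv = 0.0
        for h in hits:
            if h.sv.sv_id in seen or h.sv.af is None:
                continue
            seen.add(h.sv.sv_id)
            n_ncsv += 2.0 * h.sv.af
        glob = burden_reports["global"]
        n_csv_adme = glob.total(group="ADME")
        n_csv_targets = glob.total(group="target")
        frac = attr_mod.noncoding_share(
            n_ncsv, n_csv_adme, n_csv_targets,
            n_snv_adme=config.n_snv_adme, n_snv_targets=config.n_snv_targets,
        )
        attribution = {
            "n_ncsv": n_ncsv,
            "n_csv_adme": n_csv_adme,
            "n_csv_targets": n_csv_targets,
            "n_snv_adme": config.n_snv_adme,
            "n_snv_targets": config.n_snv_targets,
            "noncoding_share": frac,
            "noncoding_share_pct": format_percent(100 * frac),
        }
        log_stage(stage, "-", 1)

        stage = "summary"
        summary = summarize_counts(annotated)
        summary["n_regulatory_svs"] = len(seen)
        summary["stage_log"] = stage_log
        summary["removed_by_reason"] = table.removed_by_reason
        if out_dir is not None:
            path = out_dir / "summary.json"
            path.write_text(json.dumps(
                {"summary": summary, "attribution": attribution},
                indent=1, default=str))
            manifest.append(str(path))
    except Exception as exc:  # abort with the stage name + partial manifest
        raise PipelineError(stage, manifest, exc) from exc

    return PipelineResult(
        gene_set=gene_set, sv_table=table, clusters=clusters,
        annotated=annotated, annotated_frame=ann_df, density=density,
        regulatory_hits=hits, burden_reports=burden_reports,
        eqtl_matches=matches, eqtl_table=eqtl_df,
        attribution=attribution, summary=summary, stage_log=stage_log,
    )
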
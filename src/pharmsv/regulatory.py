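"""Regulatory interpretation of non-coding SVs via TFBS overlap + co-expression.

Non-coding SVs are intersected with transcription-factor ChIP-seq cluster
peaks.  Peaks are first filtered for reproducibility: peak score >= 200 and
observation in at least two contributing studies.  An (SV, TF) pair is then
retained only when the impacted gene and the TF are both expressed (median
expression >= threshold, default 1 TPM) in at least one tissue of the
configured panel — by default nine tissues of pharmacokinetic or
pharmacodynamic importance.  The direction hint is qualitative only:
deleting a binding site ablates TF input, duplicating it may amplify it.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotate import AnnotatedSV
from .genome_model import GeneSet
from .sv_ingest import SVType

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 200
DEFAULT_MIN_STUDIES = 2
DEFAULT_EXPRESSION_THRESHOLD = 1.0
#: tissues of major pharmacokinetic/pharmacodynamic importance
DEFAULT_TISSUES = (
    "liver", "kidney", "small intestine", "stomach", "colon",
    "lung", "brain", "heart", "adipose",
)

_DIRECTION = {
    SVType.DEL: "ablation",
    SVType.DUP: "gain",
    SVType.MCNV: "gain",
    SVType.INS: "insertion-disruption",
    SVType.CPX: "complex",
    SVType.INV: "complex",
}


@dataclass(frozen=True)
class TFBSPeak:
    """A TF ChIP-seq cluster interval with score and study support."""

    tf_name: str
    chrom: str
    start: int
    end: int
    peak_score: int
    studies_observed: int
    studies_total: int

    def __post_init__(self):
        if self.peak_score < 0:
            raise ValueError("peak_score must be >= 0")
        if not (0 <= self.studies_observed <= self.studies_total):
            raise ValueError("studies_observed must lie in [0, studies_total]")


@dataclass
class RegulatoryHit:
    """A non-coding SV hitting a TFBS with tissue co-expression support."""

    sv: AnnotatedSV
    gene_id: str
    tf_name: str
    tissues_supported: tuple[str, ...]
    direction_hint: str

    def __post_init__(self):
        if not self.tissues_supported:
            raise ValueError("retained hits must have >= 1 supporting tissue")


def read_tfbs_bed(source) -> list[TFBSPeak]:
    """Read peaks from BED 5+ (chrom, start, end, tf_name, score, studies k/N)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(
        source, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "tf", "score", "studies"],
        dtype={"chrom": str, "tf": str, "studies": str},
    )
    peaks = []
    for row in df.itertuples(index=False):
        obs, tot = (int(x) for x in row.studies.split("/"))
        peaks.append(TFBSPeak(row.tf, row.chrom, int(row.start), int(row.end),
                              int(row.score), obs, tot))
    return peaks


def write_tfbs_bed(peaks: Sequence[TFBSPeak], path_or_buf=None):
    rows = [(p.chrom, p.start, p.end, p.tf_name, p.peak_score,
             f"{p.studies_observed}/{p.studies_total}") for p in peaks]
    df = pd.DataFrame(rows)
    if path_or_buf is None:
        return df.to_csv(sep="\t", index=False, header=False)
    df.to_csv(path_or_buf, sep="\t", index=False, header=False)


def filter_tfbs(
    peaks: Iterable[TFBSPeak],
    min_score: int = DEFAULT_MIN_SCORE,
    min_studies: int = DEFAULT_MIN_STUDIES,
) -> list[TFBSPeak]:
    """Keep reproducible peaks: score >= min_score, observed in >= min_studies."""
    return [p for p in peaks
            if p.peak_score >= min_score and p.studies_observed >= min_studies]


def overlap_tfbs(
    noncoding_svs: Sequence[AnnotatedSV],
    peaks: Sequence[TFBSPeak],
    gene_set: GeneSet | None = None,
    restrict_to_gene: bool = False,
    flank: int = 0,
) -> list[tuple[AnnotatedSV, str]]:
    """(SV, TF) pairs where the SV interval intersects >= 1 peak of that TF.

    Per-SV TF lists are deduplicated (two peaks of one TF under one SV give
    one pair).  With ``restrict_to_gene`` the evaluated region is the
    intersection of the SV with the gene span +/- flank, for very large SVs
    that extend far beyond the gene.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, idx)
    pairs: list[tuple[AnnotatedSV, str]] = []
    for sv in noncoding_svs:
        if sv.coding:
            raise ValueError(f"{sv.sv_id}: TFBS overlap is defined for non-coding SVs")
        start, end = sv.sv.start, sv.sv.end
        if sv.sv.sv_type == SVType.INS:
            end = start + 1
        if restrict_to_gene:
            if gene_set is None:
                raise ValueError("restrict_to_gene requires a gene_set")
            g = gene_set[sv.gene_id]
            start = max(start, max(0, g.span_start - flank))
            end = min(end, g.span_end + flank)
            if start >= end:
                continue
        tree = trees.get(sv.sv.chrom)
        if tree is None:
            continue
        tfs = sorted({peaks[iv.data].tf_name for iv in tree.overlap(start, end)})
        pairs.extend((sv, tf) for tf in tfs)
    return pairs


def read_expression_tsv(source) -> pd.DataFrame:
    """Gene/TF x tissue median-expression matrix (first column = symbol)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    if df.columns.duplicated().any():
        raise ValueError("duplicate tissue names in expression matrix")
    return df


def coexpression_filter(
    pairs: Sequence[tuple[AnnotatedSV, str]],
    expr: pd.DataFrame,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    gene_set: GeneSet | None = None,
) -> list[RegulatoryHit]:
    """Retain (SV, TF) pairs with gene-TF co-expression in >= 1 panel tissue.

    A tissue supports a hit when both the impacted gene and the TF reach
    the expression threshold there.  Gene symbols are looked up through
    ``gene_set`` when given (otherwise gene_ids index the matrix directly);
    pairs whose gene or TF is absent from the matrix are dropped with a
    logged count.
    """
    missing = [t for t in tissues if t not in expr.columns]
    if missing:
        raise ValueError(f"tissues absent from expression matrix: {missing}")
    dropped = 0
    hits: list[RegulatoryHit] = []
    for sv, tf in pairs:
        symbol = gene_set.symbol_of(sv.gene_id) if gene_set is not None else sv.gene_id
        if symbol not in expr.index or tf not in expr.index:
            dropped += 1
            continue
        g_row, t_row = expr.loc[symbol, list(tissues)], expr.loc[tf, list(tissues)]
        supported = tuple(t for t in tissues
                          if g_row[t] >= threshold and t_row[t] >= threshold)
        if supported:
            direction = _DIRECTION[sv.sv.sv_type]
            if sv.component == "del":
                direction = "ablation"
            hits.append(RegulatoryHit(sv, sv.gene_id, tf, supported, direction))
    if dropped:
        logger.info("coexpression_filter: dropped %d pairs absent from matrix", dropped)
    return hits


def hits_frame(hits: Sequence[RegulatoryHit]) -> pd.DataFrame:
    rows = [{
        "sv_id": h.sv.sv_id, "gene_id": h.gene_id, "sv_type": h.sv.type_label,
        "tf_name": h.tf_name, "tissues": ";".join(h.tissues_supported),
        "direction_hint": h.direction_hint, "af": h.sv.af,
    } for h in hits]
    return pd.DataFrame(rows)
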
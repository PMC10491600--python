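"""Gene assignment, coding status and functional classification of SVs.

An SV is *coding* when its interval touches at least one exon of the gene
it is assigned to (insertions: the insertion point lies inside an exon).
Coding SVs are classified into putative functional consequences:

LOF (loss of function)
    deletions touching an exon; exonic insertions; inversions with at least
    one breakpoint inside the gene span that span an exon; partial
    duplications whose duplicated exonic length is not a multiple of 3
    (frameshift under the tandem in-place assumption).
IGD (increased gene dosage)
    duplications that contain the entire gene span.
UNKNOWN
    frame-preserving partial duplications, whole-gene inversions with both
    breakpoints outside the span (the transcription unit is preserved),
    complex rearrangements touching exons, and UTR-only events when a CDS
    annotation is available.
NONE
    non-coding SVs (intronic or up-/downstream of the gene body).

Multi-allelic CNVs are decomposed into deletion-like and duplication-like
frequency components and each non-zero component is classified under the
corresponding DEL/DUP rules, so one MCNV locus can yield both an LOF and an
IGD annotation (with separate frequencies).

SVs spanning several panel genes are annotated once per gene.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneModel, GeneSet, panel_group
from .sv_cluster import ClusteredSV
from .sv_ingest import SVType, decompose_mcnv, SVRecord

logger = logging.getLogger(__name__)

COMMON_MAF = 0.01  # common/rare boundary on the reported SV frequency


class FunctionalClass(str, Enum):
    LOF = "LOF"
    IGD = "IGD"
    UNKNOWN = "UNKNOWN"
    NONE = "NONE"


@dataclass
class AnnotatedSV:
    """A (clustered SV, gene) pair with coding flag and functional class.

    ``component`` is None for simple types and "del"/"dup" for the
    decomposed parts of an MCNV; ``af`` is the frequency of that component.
    """

    sv: ClusteredSV
    gene_id: str
    panel_class: str
    coding: bool
    functional_class: FunctionalClass
    af: float | None
    af_by_pop: dict[str, float] = field(default_factory=dict)
    component: str | None = None
    size_bp: int | None = None

    @property
    def sv_id(self) -> str:
        return self.sv.cluster_id

    @property
    def rarity(self) -> str:
        return rarity_class(self.af) if self.af is not None else "rare"

    @property
    def type_label(self) -> str:
        if self.component:
            return f"MCNV ({self.component.upper()})"
        return self.sv.sv_type.value


def rarity_class(af: float) -> str:
    """"common" iff the reported SV frequency is >= 1%, else "rare".

    The reported alternate-allele/SV frequency is used directly (a 99.5%
    deletion is common); cohort tables report SV frequencies rather than
    folded minor-allele frequencies.
    """
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"frequency {af} outside [0, 1]")
    return "common" if af >= COMMON_MAF else "rare"


def set_coding_status(sv, gene: GeneModel) -> bool:
    """True iff the SV interval intersects >= 1 exon of the gene.

    Insertions count as coding only when the insertion point itself falls
    inside an exon.
    """
    start, end = sv.start, sv.end
    if getattr(sv, "sv_type", None) == SVType.INS:
        end = start + 1
    return gene.overlaps_exon(start, end)


def _classify_interval(
    start: int, end: int, sv_type: SVType, gene: GeneModel
) -> FunctionalClass:
    coding = gene.overlaps_exon(start, end)
    if sv_type == SVType.INS:
        coding = gene.overlaps_exon(start, start + 1)
    if not coding:
        return FunctionalClass.NONE
    # UTR-only events are uninterpretable when CDS annotation is available
    if gene.cds is not None and not gene.overlaps_cds(start, end):
        return FunctionalClass.UNKNOWN

    if sv_type == SVType.DEL:
        return FunctionalClass.LOF
    if sv_type == SVType.INS:
        return FunctionalClass.LOF
    if sv_type == SVType.INV:
        breakpoint_inside = (
            gene.span_start < start < gene.span_end
            or gene.span_start < end < gene.span_end
        )
        return FunctionalClass.LOF if breakpoint_inside else FunctionalClass.UNKNOWN
    if sv_type == SVType.DUP:
        if start <= gene.span_start and end >= gene.span_end:
            return FunctionalClass.IGD
        dup_bases = gene.exonic_overlap_bp(start, end, coding_only=True)
        return FunctionalClass.LOF if dup_bases % 3 != 0 else FunctionalClass.UNKNOWN
    if sv_type == SVType.CPX:
        return FunctionalClass.UNKNOWN
    raise ValueError(f"cannot classify sv_type {sv_type}")


def classify_function(sv, gene: GeneModel, component: str | None = None) -> FunctionalClass:
    """Functional class of an SV (or MCNV component) against one gene.

    For MCNVs ``component`` selects the decomposed part: "del" applies the
    deletion rules, "dup" the duplication rules (IGD when the interval
    contains the whole gene span, partial-duplication frame rules
    otherwise).
    """
    sv_type = sv.sv_type
    if sv_type == SVType.MCNV:
        if component not in ("del", "dup"):
            raise ValueError("MCNV classification requires component 'del' or 'dup'")
        sv_type = SVType.DEL if component == "del" else SVType.DUP
    elif component is not None:
        raise ValueError("component only applies to MCNV records")
    return _classify_interval(sv.start, sv.end, sv_type, gene)


def annotate_svs(clusters: list[ClusteredSV], gene_set: GeneSet) -> list[AnnotatedSV]:
    """Assign clustered SVs to panel genes and classify each (SV, gene) pair.

    MCNVs with a non-zero deletion-like and/or duplication-like frequency
    component yield one annotation per component.  Clusters overlapping no
    panel gene are dropped here (the pipeline counts them).
    """
    out: list[AnnotatedSV] = []
    for sv in clusters:
        q_end = sv.start + 1 if sv.sv_type == SVType.INS else sv.end
        for gene_id, _ in gene_set.query(sv.chrom, sv.start, q_end):
            gene = gene_set[gene_id]
            coding = set_coding_status(sv, gene)
            if sv.sv_type == SVType.MCNV:
                rec = SVRecord(
                    sv_id=sv.cluster_id, chrom=sv.chrom, start=sv.start, end=sv.end,
                    sv_type=SVType.MCNV, mcnv_spectrum=sv.mcnv_spectrum or {2: 1.0},
                )
                del_af, dup_af = decompose_mcnv(rec)
                components = [(c, af) for c, af in (("del", del_af), ("dup", dup_af)) if af > 0]
                if not components:
                    components = [("del", 0.0)]
                for comp, af in components:
                    out.append(
                        AnnotatedSV(
                            sv=sv, gene_id=gene_id, panel_class=gene.panel_class,
                            coding=coding,
                            functional_class=classify_function(sv, gene, comp),
                            af=af,
                            af_by_pop={p: min(1.0, v) for p, v in sv.af_by_pop.items()},
                            component=comp, size_bp=sv.length_bp,
                        )
                    )
            else:
                out.append(
                    AnnotatedSV(
                        sv=sv, gene_id=gene_id, panel_class=gene.panel_class,
                        coding=coding,
                        functional_class=_classify_interval(sv.start, sv.end, sv.sv_type, gene),
                        af=sv.af_global, af_by_pop=dict(sv.af_by_pop),
                        size_bp=sv.length_bp,
                    )
                )
    return out


def annotation_frame(annotated: list[AnnotatedSV]) -> pd.DataFrame:
    """One row per SV x gene (x MCNV component) annotation."""
    rows = []
    for a in annotated:
        rows.append({
            "sv_id": a.sv_id, "gene_id": a.gene_id, "panel_class": a.panel_class,
            "panel_group": panel_group(a.panel_class),
            "chrom": a.sv.chrom, "start": a.sv.start, "end": a.sv.end,
            "sv_type": a.type_label, "coding": a.coding,
            "functional_class": a.functional_class.value,
            "af": a.af, "rarity": a.rarity if a.af is not None else "",
            "size_bp": a.size_bp,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-kb density and group comparisons


@dataclass
class DensityTable:
    """Per-gene SV counts with per-kb normalization, plus group comparisons."""

    per_gene: pd.DataFrame
    comparisons: pd.DataFrame


def density_table(
    annotated: list[AnnotatedSV],
    gene_set: GeneSet,
    compare: list[tuple[str, str]] | None = None,
    by: str = "panel_group",
) -> DensityTable:
    """Per-gene SV density (SVs/kb of gene span) with rank-sum comparisons.

    A multi-gene SV counts once for every gene it overlaps; MCNV components
    of one locus count once.  ``compare`` lists (group_a, group_b) pairs of
    ``by`` labels (panel_group or panel_class) tested with a two-sided
    Wilcoxon rank-sum test; raw p-values are reported.  Genes with no SVs
    enter with count 0.  Empty groups skip their comparison with a warning.
    """
    counts: dict[str, set[str]] = {g.gene_id: set() for g in gene_set}
    for a in annotated:
        counts[a.gene_id].add(a.sv_id)
    rows = []
    for g in gene_set:
        n = len(counts[g.gene_id])
        rows.append({
            "gene_id": g.gene_id, "symbol": g.symbol,
            "panel_class": g.panel_class, "panel_group": panel_group(g.panel_class),
            "n_sv": n, "gene_length_kb": g.gene_length_kb,
            "sv_per_kb": n / g.gene_length_kb,
        })
    per_gene = pd.DataFrame(rows)

    comp_rows = []
    for a_lbl, b_lbl in compare or []:
        xa = per_gene.loc[per_gene[by] == a_lbl, "sv_per_kb"].to_numpy()
        xb = per_gene.loc[per_gene[by] == b_lbl, "sv_per_kb"].to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            warnings.warn(f"empty group in comparison {a_lbl} vs {b_lbl}; skipped")
            continue
        stat, p = stats.ranksums(xa, xb)
        comp_rows.append({
            "group_a": a_lbl, "group_b": b_lbl, "n_a": len(xa), "n_b": len(xb),
            "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
            "statistic": float(stat), "p_value": float(p),
        })
    return DensityTable(per_gene=per_gene, comparisons=pd.DataFrame(comp_rows))
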
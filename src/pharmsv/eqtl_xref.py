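"""Cross-referencing external SV-eQTL records with the cohort's SVs.

Each eQTL interval is matched to the nearest same-chromosome cohort SV
(bed_closest-like semantics).  Two criteria are evaluated and reported
separately: *near* — both breakpoints within ``near_bp`` (default 100 bp)
of the SV's — and *included* — reciprocal overlap fraction above
``min_overlap`` (default 0.99), i.e. the intersection covers more than
99% of BOTH intervals so that only near-identical calls are accepted.
Insertion eQTLs are matched by insertion-point distance alone, with the
overlap fraction defined as 1 when the points are near.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import AnnotatedSV
from .regulatory import RegulatoryHit
from .sv_ingest import SVType, parse_sv_type

logger = logging.getLogger(__name__)

DEFAULT_NEAR_BP = 100
DEFAULT_MIN_OVERLAP = 0.99


@dataclass
class EQTLRecord:
    """One external SV-eQTL association (consumed, never estimated here).

    ``beta`` is the effect size of the SV-expression correlation (sign =
    direction of expression change); ``bh_p`` the BH-adjusted p-value,
    optionally supplied on the -log10 scale via ``neg_log10_bh``.
    """

    eqtl_id: str
    chrom: str
    start: int
    end: int
    sv_type: SVType
    gene: str
    tissue: str
    beta: float
    bh_p: float

    def __post_init__(self):
        if not (0.0 < self.bh_p <= 1.0):
            raise ValueError(f"{self.eqtl_id}: adjusted p {self.bh_p} outside (0, 1]")

    @property
    def neg_log10_bh(self) -> float:
        import math
        return -math.log10(self.bh_p)


def read_eqtl_tsv(source) -> list[EQTLRecord]:
    """Read eQTL TSV (eqtl_id, chrom, start, end, sv_type, gene, tissue,
    beta, bh_p | neg_log10_bh)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        if hasattr(row, "bh_p"):
            bh = float(row.bh_p)
        else:
            bh = 10 ** (-float(row.neg_log10_bh))
        out.append(EQTLRecord(
            eqtl_id=str(getattr(row, "eqtl_id", f"eqtl{i}")),
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            sv_type=parse_sv_type(row.sv_type), gene=row.gene, tissue=row.tissue,
            beta=float(row.beta), bh_p=bh,
        ))
    return out


@dataclass
class MatchResult:
    """An eQTL matched (or not) against the cohort SV set."""

    eqtl: EQTLRecord
    sv_id: str | None
    d_start: int | None = None
    d_end: int | None = None
    overlap: float = 0.0
    same_type: bool = False
    near: bool = False
    included: bool = False


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def match_eqtl(
    eqtls: Sequence[EQTLRecord],
    svs: Sequence,
    near_bp: int = DEFAULT_NEAR_BP,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[MatchResult]:
    """Match each eQTL to its nearest same-chromosome SV.

    ``svs`` may be SVRecords or ClusteredSVs (anything with chrom, start,
    end, sv_type and an id).  The nearest SV minimizes the larger of the
    two breakpoint distances.  ``near`` requires both |dstart| and |dend|
    <= near_bp; ``included`` requires reciprocal overlap > min_overlap.
    eQTLs with no same-chromosome SV yield sv_id None.
    """
    by_chrom: dict[str, list] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(sv)

    results = []
    for q in eqtls:
        candidates = by_chrom.get(q.chrom, [])
        if not candidates:
            results.append(MatchResult(eqtl=q, sv_id=None))
            continue
        is_point = q.sv_type == SVType.INS

        def key(sv):
            ds = abs(sv.start - q.start)
            de = abs(sv.end - q.end) if not is_point else ds
            return (max(ds, de), getattr(sv, "sv_id", None) or sv.cluster_id)

        best = min(candidates, key=key)
        sv_id = getattr(best, "sv_id", None) or best.cluster_id
        d_start = abs(best.start - q.start)
        d_end = d_start if is_point else abs(best.end - q.end)
        near = d_start <= near_bp and d_end <= near_bp
        if is_point:
            overlap = 1.0 if near else 0.0
        else:
            overlap = _reciprocal_overlap((q.start, q.end), (best.start, best.end))
        results.append(MatchResult(
            eqtl=q, sv_id=sv_id, d_start=d_start, d_end=d_end,
            overlap=overlap, same_type=(best.sv_type == q.sv_type),
            near=near, included=overlap > min_overlap,
        ))
    return results


def eqtl_report(
    matches: Sequence[MatchResult],
    annotated: Sequence[AnnotatedSV],
    regulatory_hits: Sequence[RegulatoryHit] = (),
) -> pd.DataFrame:
    """Expression-associated pharmacogene SVs: one row per (gene, SV type).

    Only included (reciprocal-overlap) matches enter; excluded eQTLs are
    counted in the log.  Rows carry coding status from the annotation,
    affected TFBSs for non-coding entries, the tissue list and the
    beta / significance ranges over contributing eQTL records.
    """
    ann_by_sv: dict[str, list[AnnotatedSV]] = {}
    for a in annotated:
        ann_by_sv.setdefault(a.sv_id, []).append(a)
    tfs_by_sv: dict[str, set[str]] = {}
    for h in regulatory_hits:
        tfs_by_sv.setdefault(h.sv.sv_id, set()).add(h.tf_name)

    grouped: dict[tuple[str, str], dict] = {}
    n_excluded = 0
    for m in matches:
        if m.sv_id is None or not m.included:
            n_excluded += 1
            continue
        key = (m.eqtl.gene, m.eqtl.sv_type.value)
        entry = grouped.setdefault(key, {
            "gene": m.eqtl.gene, "sv_type": m.eqtl.sv_type.value,
            "sv_ids": set(), "tissues": set(), "betas": [], "neg_log10_bh": [],
            "n_matched": 0, "same_type": 0,
        })
        entry["sv_ids"].add(m.sv_id)
        entry["tissues"].add(m.eqtl.tissue)
        entry["betas"].append(m.eqtl.beta)
        entry["neg_log10_bh"].append(m.eqtl.neg_log10_bh)
        entry["n_matched"] += 1
        entry["same_type"] += int(m.same_type)
    if n_excluded:
        logger.info("eqtl_report: %d eQTLs unmatched or below overlap cutoff", n_excluded)

    rows = []
    for entry in grouped.values():
        anns = [a for sv_id in entry["sv_ids"] for a in ann_by_sv.get(sv_id, [])]
        coding = any(a.coding for a in anns) if anns else None
        tfs = sorted({tf for sv_id in entry["sv_ids"] for tf in tfs_by_sv.get(sv_id, set())})
        rows.append({
            "gene": entry["gene"], "sv_type": entry["sv_type"],
            "sv_function": ("" if coding is None else ("coding" if coding else "non-coding")),
            "affected_tfbs": ";".join(tfs) if (coding is False) else "",
            "tissues": ";".join(sorted(entry["tissues"])),
            "beta_min": min(entry["betas"]), "beta_max": max(entry["betas"]),
            "neg_log10_bh_min": min(entry["neg_log10_bh"]),
            "neg_log10_bh_max": max(entry["neg_log10_bh"]),
            "n_matched": entry["n_matched"],
            "n_same_type": entry["same_type"],
            "matched_sv_ids": ";".join(sorted(entry["sv_ids"])),
        })
    df = pd.DataFrame(rows, columns=[
        "gene", "sv_type", "sv_function", "affected_tfbs", "tissues",
        "beta_min", "beta_max", "neg_log10_bh_min", "neg_log10_bh_max",
        "n_matched", "n_same_type", "matched_sv_ids",
    ])
    return df.sort_values(["gene", "sv_type"]).reset_index(drop=True) if not df.empty else df
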
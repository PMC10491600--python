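"""Interval aggregation of neighbouring SV calls.

Overlapping and directly adjacent (bookended) intervals of the same SV type
are merged into clusters, mirroring merge-with-max_dist=0 semantics: in
half-open coordinates two intervals belong together when the gap between
them is at most ``max_dist`` bp, so [100,200) and [200,300) merge while
[100,200) and [201,300) do not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sv_ingest import CohortSVTable, SVRecord, SVType


@dataclass
class ClusteredSV:
    """A merged SV interval with its member call ids.

    The representative allele frequency is the maximum over members by
    default (``freq_mode="max"``), avoiding double-counting of overlapping
    call fragments; ``freq_mode="sum"`` is available where fragments are
    known to be distinct alleles.
    """

    cluster_id: str
    chrom: str
    start: int
    end: int
    sv_type: SVType
    members: tuple[str, ...]
    gene_id: str | None = None
    af_global: float | None = None
    af_by_pop: dict[str, float] = field(default_factory=dict)
    mcnv_spectrum: dict[int, float] | None = None
    length_bp: int | None = None
    singleton: bool = False

    def __post_init__(self):
        if self.length_bp is None:
            self.length_bp = self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def cluster_intervals(
    records: Sequence[tuple[str, int, int, str]], max_dist: int = 0
) -> list[tuple[int, int, tuple[str, ...]]]:
    """Merge intervals whose gap is <= max_dist bp.

    ``records`` are (chrom, start, end, id) tuples sharing one chromosome
    (mixed chromosomes raise).  Returns (start, end, member_ids) clusters,
    internally sorted by (start, end, id) so the result is independent of
    input order; output intervals are pairwise separated by > max_dist and
    every input id appears in exactly one cluster.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    records = list(records)
    if not records:
        return []
    chroms = {r[0] for r in records}
    if len(chroms) > 1:
        raise ValueError(f"mixed chromosomes in one clustering batch: {sorted(chroms)}")
    items = sorted(((s, e, i) for _, s, e, i in records), key=lambda t: (t[0], t[1], t[2]))
    clusters: list[tuple[int, int, tuple[str, ...]]] = []
    cur_s, cur_e, cur_ids = items[0][0], items[0][1], [items[0][2]]
    for s, e, i in items[1:]:
        if s - cur_e <= max_dist:  # overlap or within-gap
            cur_e = max(cur_e, e)
            cur_ids.append(i)
        else:
            clusters.append((cur_s, cur_e, tuple(cur_ids)))
            cur_s, cur_e, cur_ids = s, e, [i]
    clusters.append((cur_s, cur_e, tuple(cur_ids)))
    return clusters


def _representative(members: list[SVRecord], freq_mode: str):
    """Representative frequency data for a cluster of member records."""
    with_af = [m for m in members if m.af_global is not None]
    if not with_af:
        rep = members[0]
        af = None
    elif freq_mode == "sum":
        af = min(1.0, sum(m.af_global for m in with_af))
        rep = max(with_af, key=lambda m: m.af_global)
    else:
        rep = max(with_af, key=lambda m: m.af_global)
        af = rep.af_global
    af_by_pop: dict[str, float] = {}
    for m in members:
        for pop, v in m.af_by_pop.items():
            if freq_mode == "sum":
                af_by_pop[pop] = min(1.0, af_by_pop.get(pop, 0.0) + v)
            else:
                af_by_pop[pop] = max(af_by_pop.get(pop, 0.0), v)
    return af, af_by_pop, rep


def cluster_cohort(
    table: CohortSVTable, max_dist: int = 0, freq_mode: str = "max"
) -> list[ClusteredSV]:
    """Cluster a whole cohort genome-wide per (chromosome, SV type).

    Insertions cluster by their 1-bp insertion-point interval.  The merged
    record keeps the member set, representative frequencies and — for MCNVs
    — the spectrum of the highest-frequency member.
    """
    by_key: dict[tuple[str, SVType], list[SVRecord]] = {}
    for r in table.records:
        by_key.setdefault((r.chrom, r.sv_type), []).append(r)

    out: list[ClusteredSV] = []
    for (chrom, sv_type), recs in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        by_id = {r.sv_id: r for r in recs}
        merged = cluster_intervals(
            [(r.chrom, r.start, r.end, r.sv_id) for r in recs], max_dist=max_dist
        )
        for start, end, ids in merged:
            members = [by_id[i] for i in ids]
            af, af_by_pop, rep = _representative(members, freq_mode)
            spectrum = rep.mcnv_spectrum if sv_type == SVType.MCNV else None
            length = max(m.length_bp for m in members) if sv_type == SVType.INS else end - start
            out.append(
                ClusteredSV(
                    cluster_id=f"{chrom}_{sv_type.value}_{start}_{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    members=ids,
                    af_global=af,
                    af_by_pop=af_by_pop,
                    mcnv_spectrum=spectrum,
                    length_bp=length,
                    singleton=all(m.singleton for m in members),
                )
            )
    return out
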
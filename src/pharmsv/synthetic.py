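"""Synthetic cohorts with planted ground truth for every pipeline stage.

Generates all five pipeline inputs — gene annotation + panel table, cohort
SV table, TFBS peak BED, gene/TF x tissue expression matrix, and SV-eQTL
table — with known truth: each planted SV satisfies a geometric definition
(e.g. a "whole-gene duplication" strictly contains its gene span), each
planted regulatory hit is realized exactly at the expression threshold, and
each eQTL either copies an SV interval or is displaced far enough to fail
both the breakpoint-distance and the reciprocal-overlap criteria.

Everything is deterministic under a seed.  Allele frequencies come from a
rare-heavy Beta(0.2, 20) mixed with configurable common point masses, so
both rarity strata (<1% / >=1%) are populated, matching cohorts where the
vast majority of SVs are rare but a handful of pharmacogene CNVs reach
high frequencies.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GeneSet
from .regulatory import DEFAULT_TISSUES, TFBSPeak, write_tfbs_bed
from .sv_ingest import (
    POPULATIONS,
    CohortSVTable,
    SVRecord,
    SVType,
    write_sv_tsv,
)

DEFAULT_CLASS_MIX = {
    "CYP": 0.08, "NR": 0.06, "SLC": 0.08, "ABC": 0.05,
    "phase1": 0.05, "phase2": 0.06,
    "ion_channel": 0.14, "membrane_receptor": 0.16, "enzyme": 0.14,
    "transporter": 0.08, "olfactory": 0.10,
}

DEFAULT_QUOTAS = {
    "exonic_del": 6, "intronic_del": 6, "whole_gene_dup": 4,
    "partial_dup_frameshift": 3, "partial_dup_inframe": 3,
    "exonic_ins": 4, "intronic_ins": 4, "whole_gene_inv": 2,
    "breakpoint_inv": 2, "cpx_exonic": 2, "mcnv_mixed": 3,
}

COMMON_AF_MASSES = (0.054, 0.155, 0.259, 0.845)
DEFAULT_TFS = ("CTCF", "RAD21", "FOS", "JUND", "HNF4A", "RXRA", "SP1", "MAFK")


# ---------------------------------------------------------------------------
# Genome


@dataclass
class SyntheticGenome:
    gtf: str
    panel_tsv: str
    gene_set: GeneSet
    params: dict


def generate_genome(
    n_genes: int = 50,
    exons_per_gene: tuple[int, int] = (2, 8),
    class_mix: dict[str, float] | None = None,
    chrom: str = "chr1",
    chrom_length: int | None = None,
    exon_len: tuple[int, int] = (100, 1200),
    intron_len: tuple[int, int] = (300, 4000),
    intergenic: tuple[int, int] = (8000, 30000),
    seed: int = 1,
) -> SyntheticGenome:
    """Place non-overlapping genes with valid exon structures on one chromosome.

    Panel classes are drawn from ``class_mix`` (probabilities over ADME
    families, drug-target classes and "olfactory").  Raises when the genes
    cannot be packed into ``chrom_length``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mix = class_mix or DEFAULT_CLASS_MIX
    labels = sorted(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    gs = GeneSet()
    gtf_lines: list[str] = []
    panel_lines = ["gene\tclass"]
    cursor = 10_000
    for i in range(n_genes):
        gene_id = f"G{i:04d}"
        symbol = f"SYN{i}"
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for j in range(n_ex):
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(intron_len[0], intron_len[1] + 1))
        cls = labels[int(rng.choice(len(labels), p=probs))]
        gene = GeneModel(gene_id=gene_id, symbol=symbol, chrom=chrom,
                         strand=strand, exons=tuple(exons), panel_class=cls)
        gs.add(gene)
        for k, (s, e) in enumerate(exons, start=1):
            gtf_lines.append(
                f"{chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1"; '
                f'gene_name "{symbol}"; exon_number "{k}";'
            )
        panel_lines.append(f"{gene_id}\t{cls}")
        cursor = exons[-1][1] + int(rng.integers(intergenic[0], intergenic[1] + 1))
        if chrom_length is not None and cursor > chrom_length:
            raise ValueError(
                f"infeasible packing: gene {i + 1}/{n_genes} exceeds "
                f"chromosome length {chrom_length}"
            )
    params = {"n_genes": n_genes, "seed": seed, "chrom": chrom,
              "class_mix": mix, "exons_per_gene": list(exons_per_gene)}
    return SyntheticGenome(
        gtf="\n".join(gtf_lines) + "\n",
        panel_tsv="\n".join(panel_lines) + "\n",
        gene_set=gs,
        params=params,
    )


# ---------------------------------------------------------------------------
# SV cohort


@dataclass
class SyntheticCohort:
    table: CohortSVTable
    sv_tsv: str
    #: one row per planted truth assertion:
    #: sv_id, kind, gene_id, coding, functional_class, component
    truth: pd.DataFrame
    params: dict

    def truth_json(self) -> str:
        return json.dumps(
            {"params": self.params,
             "truth": self.truth.to_dict(orient="records")},
            indent=1, default=str,
        )


def _draw_af(rng, common_prob: float, common_masses) -> float:
    if rng.random() < common_prob:
        return float(rng.choice(common_masses))
    return float(np.clip(rng.beta(0.2, 20), 1e-4, 0.999))


def _pop_afs(rng, af: float) -> dict[str, float]:
    return {p: float(np.clip(af * rng.lognormal(0.0, 0.25), 0.0, 1.0))
            for p in POPULATIONS}


def generate_sv_cohort(
    gene_set: GeneSet,
    n_background: int = 60,
    quotas: dict[str, int] | None = None,
    common_prob: float = 0.12,
    common_masses=COMMON_AF_MASSES,
    n_failing_filter: int = 5,
    n_excluded_type: int = 4,
    seed: int = 1,
) -> SyntheticCohort:
    """Plant SVs with known gene assignment, coding status and functional class.

    ``quotas`` maps geometric kinds to counts.  Supported kinds and their
    planted truth (coding flag, functional class after classification):

    =======================  =======  ==================
    exonic_del               coding   LOF
    exonic_ins               coding   LOF
    breakpoint_inv           coding   LOF (one breakpoint inside the span)
    partial_dup_frameshift   coding   LOF (duplicated exonic bases % 3 != 0)
    partial_dup_inframe      coding   UNKNOWN
    whole_gene_inv           coding   UNKNOWN (breakpoints outside the span)
    cpx_exonic               coding   UNKNOWN
    whole_gene_dup           coding   IGD (contains the gene span)
    mcnv_mixed               coding   LOF (del part) + IGD (dup part)
    intronic_del             non-coding  NONE
    intronic_ins             non-coding  NONE
    =======================  =======  ==================

    At most one planted SV per (gene, SV type), so clustering with
    max_dist=0 never merges planted variants.  Background SVs are placed in
    intergenic space (no panel-gene overlap); additional records with
    non-PASS filter status or unresolved/translocation types are appended
    to exercise the record-level filters, tagged in the truth table with
    kind "filtered_status" / "filtered_type".
    """
    quotas = dict(DEFAULT_QUOTAS if quotas is None else quotas)
    rng = np.random.default_rng(seed)
    genes = sorted(gene_set, key=lambda g: g.span_start)
    multi_exon = [g for g in genes if len(g.exons) >= 2]
    if not genes:
        raise ValueError("gene_set is empty")

    used: set[tuple[str, SVType]] = set()
    records: list[SVRecord] = []
    truth_rows: list[dict] = []
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"sv{counter[0]:04d}"

    def pick_gene(pool, sv_type: SVType) -> GeneModel:
        order = rng.permutation(len(pool))
        for idx in order:
            g = pool[int(idx)]
            if (g.gene_id, sv_type) not in used:
                used.add((g.gene_id, sv_type))
                return g
        raise ValueError(f"quota infeasible: no free gene for type {sv_type.value}")

    def add(kind, gene, chrom, start, end, sv_type, *, coding, fclass,
            component=None, length=None, spectrum=None, af=None,
            filters=frozenset({"PASS"})):
        af = _draw_af(rng, common_prob, common_masses) if af is None else af
        rec = SVRecord(
            sv_id=next_id(), chrom=chrom, start=start, end=end, sv_type=sv_type,
            filters=filters, length_bp=length,
            af_global=af, af_by_pop=_pop_afs(rng, af),
            mcnv_spectrum=spectrum, singleton=af < 5e-5,
        )
        records.append(rec)
        if isinstance(fclass, (list, tuple)):
            for fc, comp in fclass:
                truth_rows.append({
                    "sv_id": rec.sv_id, "kind": kind,
                    "gene_id": gene.gene_id if gene else "",
                    "coding": coding, "functional_class": fc, "component": comp,
                })
        else:
            truth_rows.append({
                "sv_id": rec.sv_id, "kind": kind,
                "gene_id": gene.gene_id if gene else "",
                "coding": coding, "functional_class": fclass,
                "component": component or "",
            })
        return rec

    def rint(lo, hi):
        return int(rng.integers(lo, hi + 1))

    for kind, n in quotas.items():
        for _ in range(n):
            if kind == "exonic_del":
                g = pick_gene(genes, SVType.DEL)
                s, e = g.exons[rint(0, len(g.exons) - 1)]
                add(kind, g, g.chrom, s - rint(5, 30), e + rint(5, 30),
                    SVType.DEL, coding=True, fclass="LOF")
            elif kind == "intronic_del":
                g = pick_gene(multi_exon, SVType.DEL)
                i = rint(0, len(g.exons) - 2)
                gap_s, gap_e = g.exons[i][1], g.exons[i + 1][0]
                length = min(gap_e - gap_s - 20, rint(50, 2000))
                start = gap_s + 10
                add(kind, g, g.chrom, start, start + length,
                    SVType.DEL, coding=False, fclass="NONE")
            elif kind == "whole_gene_dup":
                g = pick_gene(genes, SVType.DUP)
                add(kind, g, g.chrom, max(0, g.span_start - rint(60, 400)),
                    g.span_end + rint(60, 400),
                    SVType.DUP, coding=True, fclass="IGD")
            elif kind in ("partial_dup_frameshift", "partial_dup_inframe"):
                g = pick_gene(genes, SVType.DUP)
                s, e = g.exons[0]
                exon_len = e - s
                k = rint(4, min(exon_len - 1, 200))
                if kind == "partial_dup_frameshift":
                    if k % 3 == 0:
                        k += 1
                else:
                    k -= k % 3
                add(kind, g, g.chrom, max(0, s - rint(50, 300)), s + k,
                    SVType.DUP, coding=True,
                    fclass="LOF" if kind == "partial_dup_frameshift" else "UNKNOWN")
            elif kind == "exonic_ins":
                g = pick_gene(genes, SVType.INS)
                s, e = g.exons[rint(0, len(g.exons) - 1)]
                p = rint(s + 2, e - 2)
                add(kind, g, g.chrom, p, p + 1, SVType.INS,
                    coding=True, fclass="LOF", length=rint(60, 500))
            elif kind == "intronic_ins":
                g = pick_gene(multi_exon, SVType.INS)
                i = rint(0, len(g.exons) - 2)
                p = rint(g.exons[i][1] + 10, g.exons[i + 1][0] - 10)
                add(kind, g, g.chrom, p, p + 1, SVType.INS,
                    coding=False, fclass="NONE", length=rint(60, 500))
            elif kind == "whole_gene_inv":
                g = pick_gene(genes, SVType.INV)
                add(kind, g, g.chrom, max(0, g.span_start - rint(60, 400)),
                    g.span_end + rint(60, 400),
                    SVType.INV, coding=True, fclass="UNKNOWN")
            elif kind == "breakpoint_inv":
                g = pick_gene(multi_exon, SVType.INV)
                start = rint(g.exons[0][1] + 5, g.exons[1][0] - 5)
                add(kind, g, g.chrom, start, g.span_end + rint(60, 300),
                    SVType.INV, coding=True, fclass="LOF")
            elif kind == "cpx_exonic":
                g = pick_gene(genes, SVType.CPX)
                s, e = g.exons[rint(0, len(g.exons) - 1)]
                add(kind, g, g.chrom, s - rint(5, 30), e + rint(5, 30),
                    SVType.CPX, coding=True, fclass="UNKNOWN")
            elif kind == "mcnv_mixed":
                g = pick_gene(genes, SVType.MCNV)
                del_af = round(float(rng.uniform(0.05, 0.5)), 3)
                dup_af = round(float(rng.uniform(0.05, 0.4)), 3)
                spectrum = {0: del_af, 2: round(1 - del_af - dup_af, 3), 3: dup_af}
                add(kind, g, g.chrom, max(0, g.span_start - rint(60, 400)),
                    g.span_end + rint(60, 400), SVType.MCNV, coding=True,
                    fclass=[("LOF", "del"), ("IGD", "dup")],
                    spectrum=spectrum, af=del_af + dup_af,
                    filters=frozenset({"MULTIALLELIC"}))
            else:
                raise ValueError(f"unknown quota kind {kind!r}")

    # background SVs in intergenic space (overlapping no panel gene)
    chrom = genes[0].chrom
    gaps = []
    for a, b in zip(genes, genes[1:]):
        if b.span_start - a.span_end > 400:
            gaps.append((a.span_end + 100, b.span_start - 100))
    bg_types = [SVType.DEL, SVType.DUP, SVType.INS, SVType.INV, SVType.CPX]
    for _ in range(n_background):
        lo, hi = gaps[rint(0, len(gaps) - 1)]
        t = bg_types[rint(0, len(bg_types) - 1)]
        if t == SVType.INS:
            p = rint(lo, hi - 2)
            add("background", None, chrom, p, p + 1, t, coding=False,
                fclass="NONE", length=rint(60, 400))
        else:
            length = min(hi - lo - 2, rint(50, 1500))
            start = rint(lo, hi - length - 1)
            add("background", None, chrom, start, start + length, t,
                coding=False, fclass="NONE")

    # records the filters must remove
    for _ in range(n_failing_filter):
        lo, hi = gaps[rint(0, len(gaps) - 1)]
        start = rint(lo, hi - 200)
        add("filtered_status", None, chrom, start, start + 150, SVType.DEL,
            coding=False, fclass="REMOVED", filters=frozenset({"LOW_CALL_RATE"}))
    for j in range(n_excluded_type):
        lo, hi = gaps[rint(0, len(gaps) - 1)]
        start = rint(lo, hi - 200)
        add("filtered_type", None, chrom, start, start + 150,
            SVType.BND_UNRESOLVED if j % 2 == 0 else SVType.CTX,
            coding=False, fclass="REMOVED")

    table = CohortSVTable(records=records, source="synthetic",
                          n_input=len(records))
    truth = pd.DataFrame(truth_rows)
    params = {"seed": seed, "quotas": quotas, "n_background": n_background,
              "common_prob": common_prob,
              "common_masses": list(common_masses)}
    return SyntheticCohort(table=table, sv_tsv=write_sv_tsv(table),
                           truth=truth, params=params)


def write_sv_vcf(table: CohortSVTable, path: str, chrom_lengths: dict[str, int] | None = None):
    """Emit the cohort as a VCF 4.2 text file (readable back via pysam)."""
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for r in table.records:
        chroms[r.chrom] = max(chroms.get(r.chrom, 0), r.end + 1000)
    lines = ["##fileformat=VCFv4.2"]
    for c, ln in sorted(chroms.items()):
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines += [
        '##FILTER=<ID=MULTIALLELIC,Description="Multi-allelic site">',
        '##FILTER=<ID=LOW_CALL_RATE,Description="Low call rate">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=CN_FREQ,Number=1,Type=String,Description="MCNV copy-state frequencies">',
    ]
    for pop in POPULATIONS:
        lines.append(f'##INFO=<ID={pop}_AF,Number=1,Type=Float,'
                     f'Description="{pop} allele frequency">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in table.records:
        # SVLEN only for insertions: htslib derives the record end from
        # SVLEN when present, which would fight the END field for
        # interval types (their length is end - start anyway)
        info = [f"END={r.end}", f"SVTYPE={r.sv_type.value}"]
        if r.sv_type == SVType.INS:
            info.append(f"SVLEN={r.length_bp}")
        if r.af_global is not None:
            info.append(f"AF={r.af_global:g}")
        for pop, v in sorted(r.af_by_pop.items()):
            info.append(f"{pop}_AF={v:g}")
        if r.mcnv_spectrum is not None:
            info.append("CN_FREQ=" + ",".join(
                f"{cn}:{f:g}" for cn, f in sorted(r.mcnv_spectrum.items())))
        filt = ";".join(sorted(r.filters)) or "PASS"
        lines.append("\t".join([
            r.chrom, str(r.start + 1), r.sv_id, "N", f"<{r.sv_type.value}>",
            ".", filt, ";".join(info),
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regulatory layers


@dataclass
class SyntheticRegulatory:
    peaks: list[TFBSPeak]
    tfbs_bed: str
    expression_tsv: str
    expression: pd.DataFrame
    #: planted (sv_id, gene_id, tf, tissue) quadruples
    truth: pd.DataFrame
    params: dict


def generate_regulatory_layers(
    gene_set: GeneSet,
    noncoding_svs: list[tuple[str, str, str, int, int]],
    n_planted: int = 5,
    tfs=DEFAULT_TFS,
    tissues=DEFAULT_TISSUES,
    threshold: float = 1.0,
    n_low_score: int = 4,
    n_single_study: int = 4,
    n_dead_tf: int = 2,
    seed: int = 1,
) -> SyntheticRegulatory:
    """Plant TFBS peaks + a co-expression design with exact recovery truth.

    ``noncoding_svs`` are (sv_id, gene_id, chrom, start, end) candidates
    (intronic SVs already assigned to genes).  ``n_planted`` of them get a
    reproducible peak (score >= 200, >= 2 studies) and a co-expressed
    (gene, TF, tissue) design cell; decoy peaks straddle the score and
    study-count boundaries, and ``n_dead_tf`` peaks use a TF expressed
    nowhere so the pair survives overlap but dies at co-expression.
    Baseline expression is uniform below the threshold, so recovery of the
    planted hits is exact at that threshold.
    """
    rng = np.random.default_rng(seed)
    if n_planted > len(noncoding_svs):
        raise ValueError("not enough non-coding SVs to plant hits in")
    order = rng.permutation(len(noncoding_svs))
    chosen = [noncoding_svs[int(i)] for i in order[:n_planted]]
    others = [noncoding_svs[int(i)] for i in order[n_planted:]]

    peaks: list[TFBSPeak] = []
    truth_rows = []

    def peak_in(sv, tf, score, obs):
        _, _, chrom, start, end = sv
        width = int(rng.integers(40, 160))
        if end - start <= 2:  # insertion point
            p_start = max(0, start - width // 2)
            p_end = start + 1 + width // 2
        else:
            p_start = int(rng.integers(start, max(start + 1, end - 10)))
            p_end = min(end, p_start + width)
            p_end = max(p_end, p_start + 5)
        peaks.append(TFBSPeak(tf, chrom, p_start, p_end, score, obs, 1264))

    for i, sv in enumerate(chosen):
        tf = tfs[i % len(tfs)]
        tissue = tissues[i % len(tissues)]
        peak_in(sv, tf, int(rng.integers(200, 1000)), int(rng.integers(2, 9)))
        truth_rows.append({"sv_id": sv[0], "gene_id": sv[1],
                           "tf": tf, "tissue": tissue})

    pool = others if others else chosen
    for i in range(n_low_score):
        peak_in(pool[i % len(pool)], tfs[i % len(tfs)],
                int(rng.integers(50, 200)), int(rng.integers(2, 9)))
    for i in range(n_single_study):
        peak_in(pool[(i + 1) % len(pool)], tfs[(i + 2) % len(tfs)],
                int(rng.integers(200, 1000)), 1)
    for i in range(n_dead_tf):
        peak_in(pool[(i + 2) % len(pool)], "TFDEAD",
                int(rng.integers(200, 1000)), int(rng.integers(2, 9)))

    symbols = sorted({g.symbol for g in gene_set})
    row_names = symbols + sorted(set(tfs)) + ["TFDEAD"]
    expr = pd.DataFrame(
        rng.uniform(0.0, 0.5 * threshold, size=(len(row_names), len(tissues))),
        index=row_names, columns=list(tissues),
    )
    for row in truth_rows:
        symbol = gene_set.symbol_of(row["gene_id"])
        expr.loc[symbol, row["tissue"]] = float(rng.uniform(5, 50))
        expr.loc[row["tf"], row["tissue"]] = float(rng.uniform(5, 50))
    expr.loc["TFDEAD", :] = 0.0

    truth = pd.DataFrame(truth_rows)
    params = {"seed": seed, "n_planted": n_planted, "threshold": threshold}
    return SyntheticRegulatory(
        peaks=peaks,
        tfbs_bed=write_tfbs_bed(peaks),
        expression_tsv=expr.to_csv(sep="\t"),
        expression=expr,
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# eQTLs


@dataclass
class SyntheticEQTLs:
    eqtl_tsv: str
    #: eqtl_id, sv_id, matched flag
    truth: pd.DataFrame
    params: dict


def generate_eqtls(
    svs,
    match_fraction: float = 0.23,
    gene_by_sv: dict[str, str] | None = None,
    tissues=DEFAULT_TISSUES,
    matched_jitter: tuple[int, int] = (0, 0),
    seed: int = 1,
) -> SyntheticEQTLs:
    """One eQTL per input SV; a ``match_fraction`` share copy the SV interval.

    Matched eQTLs reproduce the SV breakpoints within ``matched_jitter`` bp.
    Unmatched eQTLs are shifted by max(150 bp, 5% of the SV length) so they
    fail both the 100 bp breakpoint criterion and the 99% reciprocal
    overlap criterion.  ``gene_by_sv`` supplies target-gene labels (default
    a placeholder per SV).
    """
    if not (0.0 <= match_fraction <= 1.0):
        raise ValueError("match_fraction must lie in [0, 1]")
    svs = list(svs)
    rng = np.random.default_rng(seed)
    n = len(svs)
    n_match = int(round(match_fraction * n))
    order = rng.permutation(n)

    rows, truth_rows = [], []
    for k, idx in enumerate(order):
        sv = svs[int(idx)]
        sv_id = getattr(sv, "sv_id", None) or sv.cluster_id
        matched = k < n_match
        length = max(1, sv.end - sv.start)
        if matched:
            j = int(rng.integers(matched_jitter[0], matched_jitter[1] + 1))
            start, end = sv.start + j, sv.end + j
        else:
            shift = max(150, int(np.ceil(0.05 * length)))
            shift *= 1 if rng.random() < 0.5 else -1
            start, end = max(0, sv.start + shift), max(1, sv.end + shift)
        gene = (gene_by_sv or {}).get(sv_id, f"gene_of_{sv_id}")
        rows.append({
            "eqtl_id": f"eqtl_{sv_id}", "chrom": sv.chrom,
            "start": start, "end": end, "sv_type": sv.sv_type.value,
            "gene": gene, "tissue": tissues[k % len(tissues)],
            "beta": round(float(rng.normal(0, 0.6)), 3) or 0.1,
            "bh_p": float(10 ** -rng.uniform(1.5, 5)),
        })
        truth_rows.append({"eqtl_id": rows[-1]["eqtl_id"], "sv_id": sv_id,
                           "matched": matched})
    df = pd.DataFrame(rows)
    return SyntheticEQTLs(
        eqtl_tsv=df.to_csv(sep="\t", index=False),
        truth=pd.DataFrame(truth_rows),
        params={"seed": seed, "match_fraction": match_fraction, "n": n},
    )
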
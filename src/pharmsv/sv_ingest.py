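"""Cohort structural-variant tables: parsing, record-level filters, frequencies.

Consumes gnomAD-style cohort summaries in either VCF (via pysam) or a
documented TSV dialect, normalizes coordinates to 0-based half-open, and
applies the record-level inclusion rules: retained records carry filter
status PASS and/or MULTIALLELIC only, are not unresolved breakpoint
junctions (BND) or reciprocal translocations (CTX), and affect more than
50 bp.  Multi-allelic CNV (MCNV) loci carry a copy-number frequency
spectrum which :func:`decompose_mcnv` splits into deletion-like and
duplication-like frequency components.

TSV dialect columns
-------------------
sv_id, chrom, start, end, sv_type, filter (semicolon-joined), length,
af, af_afr, af_amr, af_eas, af_eur, af_oth, mcnv_spectrum
("cn:freq,cn:freq,..."), singleton (0/1).  Empty per-population cells mean
"not reported" (distinct from zero).

VCF INFO keys (configurable via ``info_keys``): END, SVTYPE, SVLEN, AF,
{POP}_AF per population, CN_FREQ (comma list "cn:freq,...") for MCNVs.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "OTH")
ALLOWED_FILTERS = frozenset({"PASS", "MULTIALLELIC"})
MIN_SV_LENGTH = 50  # SVs are defined as events affecting >50 bp


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    CPX = "CPX"
    MCNV = "MCNV"
    BND_UNRESOLVED = "BND"
    CTX = "CTX"


#: aliases seen in public call sets
_TYPE_ALIASES = {
    "BND": SVType.BND_UNRESOLVED,
    "BND_UNRESOLVED": SVType.BND_UNRESOLVED,
    "CTX": SVType.CTX,
    "MCNV": SVType.MCNV,
    "CNV": SVType.MCNV,
}

EXCLUDED_TYPES = frozenset({SVType.BND_UNRESOLVED, SVType.CTX})


def parse_sv_type(s: str) -> SVType:
    s = s.strip().upper()
    if s in _TYPE_ALIASES:
        return _TYPE_ALIASES[s]
    return SVType(s)


def _check_freq(x: float, what: str) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{what} {x} outside [0, 1]")
    return x


@dataclass
class SVRecord:
    """One cohort-level SV with coordinates, type, filters and frequencies.

    ``length_bp`` is end - start for interval types; for insertions the
    record is stored as a 1-bp interval at the insertion point and
    ``length_bp`` is the reported insert size.
    """

    sv_id: str
    chrom: str
    start: int
    end: int
    sv_type: SVType
    filters: frozenset[str] = frozenset({"PASS"})
    length_bp: int | None = None
    af_global: float | None = None
    af_by_pop: dict[str, float] = field(default_factory=dict)
    mcnv_spectrum: dict[int, float] | None = None
    singleton: bool = False

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"{self.sv_id}: invalid interval [{self.start}, {self.end})")
        if self.length_bp is None:
            self.length_bp = self.end - self.start
        if self.length_bp < 0:
            raise ValueError(f"{self.sv_id}: negative length {self.length_bp}")
        if self.af_global is not None:
            self.af_global = _check_freq(self.af_global, f"{self.sv_id} af")
        self.af_by_pop = {
            p: _check_freq(v, f"{self.sv_id} af[{p}]") for p, v in self.af_by_pop.items()
        }
        if (self.mcnv_spectrum is not None) != (self.sv_type == SVType.MCNV):
            raise ValueError(
                f"{self.sv_id}: mcnv_spectrum must be present iff sv_type is MCNV"
            )
        if self.mcnv_spectrum is not None:
            tot = sum(self.mcnv_spectrum.values())
            if tot > 1 + 1e-9:
                raise ValueError(f"{self.sv_id}: MCNV spectrum sums to {tot} > 1")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CohortSVTable:
    """Ordered SV records plus provenance (source, per-reason filter tallies)."""

    records: list[SVRecord] = field(default_factory=list)
    source: str = ""
    removed_by_reason: dict[str, int] = field(default_factory=dict)
    n_input: int | None = None
    #: raw rows that could not be typed (flagged, never crash)
    flagged: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.sv_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sv_id in cohort table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def conserved(self) -> bool:
        """input count == retained + sum of removals (when input count known)."""
        if self.n_input is None:
            return True
        return self.n_input == len(self.records) + sum(self.removed_by_reason.values())


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_spectrum(s: str) -> dict[int, float]:
    out = {}
    for part in s.split(","):
        cn, freq = part.split(":")
        out[int(cn)] = float(freq)
    return out


def _spectrum_str(spec: dict[int, float]) -> str:
    return ",".join(f"{cn}:{freq:g}" for cn, freq in sorted(spec.items()))


def read_sv_table(source, dialect: str = "tsv", info_keys: dict | None = None) -> CohortSVTable:
    """Read a cohort SV table from TSV or VCF into normalized records."""
    if dialect == "tsv":
        return _read_tsv(source)
    if dialect == "vcf":
        return _read_vcf(source, info_keys or {})
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(source) -> CohortSVTable:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    table = CohortSVTable(source="tsv")
    for row in df.itertuples(index=False):
        try:
            sv_type = parse_sv_type(row.sv_type)
        except ValueError:
            table.flagged.append({"sv_id": row.sv_id, "sv_type": row.sv_type,
                                  "reason": "unknown sv_type"})
            logger.warning("flagging %s: unknown sv_type %r", row.sv_id, row.sv_type)
            continue
        af_by_pop = {}
        for pop in POPULATIONS:
            cell = getattr(row, f"af_{pop.lower()}", "")
            if cell != "":
                af_by_pop[pop] = float(cell)
        spectrum = None
        if getattr(row, "mcnv_spectrum", ""):
            spectrum = _parse_spectrum(row.mcnv_spectrum)
        table.records.append(
            SVRecord(
                sv_id=row.sv_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                sv_type=sv_type,
                filters=frozenset(row.filter.split(";")) if row.filter else frozenset(),
                length_bp=int(row.length) if getattr(row, "length", "") else None,
                af_global=float(row.af) if row.af != "" else None,
                af_by_pop=af_by_pop,
                mcnv_spectrum=spectrum,
                singleton=str(getattr(row, "singleton", "0")) in ("1", "True", "true"),
            )
        )
    table.n_input = len(table.records) + len(table.flagged)
    if table.flagged:
        table.removed_by_reason["unknown_type_flagged"] = len(table.flagged)
    return table


def _read_vcf(path: str, info_keys: dict) -> CohortSVTable:
    keys = {
        "svtype": "SVTYPE", "svlen": "SVLEN", "af": "AF", "cn_freq": "CN_FREQ",
        **info_keys,
    }
    table = CohortSVTable(source=str(path))
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            raw_type = info.get(keys["svtype"], "")
            try:
                sv_type = parse_sv_type(str(raw_type))
            except ValueError:
                table.flagged.append({"sv_id": rec.id, "sv_type": str(raw_type),
                                      "reason": "unknown sv_type"})
                continue
            af = info.get(keys["af"])
            if isinstance(af, tuple):
                af = af[0]
            af_by_pop = {}
            for pop in POPULATIONS:
                v = info.get(info_keys.get(pop, f"{pop}_AF"))
                if v is not None:
                    af_by_pop[pop] = v[0] if isinstance(v, tuple) else float(v)
            svlen = info.get(keys["svlen"])
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            start, end = rec.start, rec.stop  # pysam: already 0-based half-open
            if sv_type == SVType.INS:
                end = start + 1
            spectrum = None
            cn = info.get(keys["cn_freq"])
            if cn is not None:
                spectrum = _parse_spectrum(cn if isinstance(cn, str) else ",".join(cn))
            table.records.append(
                SVRecord(
                    sv_id=rec.id or f"{rec.chrom}_{rec.pos}",
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    filters=frozenset(rec.filter.keys()) or frozenset({"PASS"}),
                    length_bp=abs(int(svlen)) if svlen is not None else None,
                    af_global=None if af is None else float(af),
                    af_by_pop=af_by_pop,
                    mcnv_spectrum=spectrum,
                )
            )
    table.n_input = len(table.records) + len(table.flagged)
    if table.flagged:
        table.removed_by_reason["unknown_type_flagged"] = len(table.flagged)
    return table


def write_sv_tsv(table: CohortSVTable, path_or_buf=None):
    rows = []
    for r in table.records:
        rows.append({
            "sv_id": r.sv_id, "chrom": r.chrom, "start": r.start, "end": r.end,
            "sv_type": r.sv_type.value if r.sv_type != SVType.BND_UNRESOLVED else "BND",
            "filter": ";".join(sorted(r.filters)),
            "length": r.length_bp,
            "af": "" if r.af_global is None else f"{r.af_global:g}",
            **{f"af_{p.lower()}": ("" if p not in r.af_by_pop else f"{r.af_by_pop[p]:g}")
               for p in POPULATIONS},
            "mcnv_spectrum": "" if r.mcnv_spectrum is None else _spectrum_str(r.mcnv_spectrum),
            "singleton": int(r.singleton),
        })
    df = pd.DataFrame(rows)
    if path_or_buf is None:
        return df.to_csv(sep="\t", index=False)
    df.to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering


def filter_sv_records(
    table: CohortSVTable,
    allowed_filters: frozenset[str] = ALLOWED_FILTERS,
    excluded_types: frozenset[SVType] = EXCLUDED_TYPES,
    min_length: int = MIN_SV_LENGTH,
) -> CohortSVTable:
    """Apply record-level inclusion rules; removal reasons are tallied.

    Retained records have filter status within ``allowed_filters``
    (PASS / MULTIALLELIC), a resolved SV type (no breakpoint junctions or
    reciprocal translocations), and affect more than ``min_length`` bp.
    Idempotent: filtering a filtered table removes nothing further.
    """
    kept: list[SVRecord] = []
    removed: dict[str, int] = {}
    for r in table.records:
        if r.filters - allowed_filters or not r.filters:
            removed["filter_status"] = removed.get("filter_status", 0) + 1
        elif r.sv_type in excluded_types:
            removed["excluded_type"] = removed.get("excluded_type", 0) + 1
        elif r.length_bp < min_length:
            removed["too_short"] = removed.get("too_short", 0) + 1
        else:
            kept.append(r)
    merged_removed = dict(table.removed_by_reason)
    for k, v in removed.items():
        merged_removed[k] = merged_removed.get(k, 0) + v
    return CohortSVTable(
        records=kept,
        source=table.source,
        removed_by_reason=merged_removed,
        n_input=table.n_input if table.n_input is not None else len(table.records),
        flagged=list(table.flagged),
    )


# ---------------------------------------------------------------------------
# MCNV decomposition


def decompose_mcnv(record: SVRecord, expected_cn: int = 2) -> tuple[float, float]:
    """Split an MCNV copy-number spectrum into (del_like_af, dup_like_af).

    Spectrum keys are copy-number states on the same scale as
    ``expected_cn`` (default: diploid reference 2).  States below the
    reference contribute to the deletion-like frequency, states above it to
    the duplication-like frequency; the reference state contributes to
    neither, so del + dup + ref conserves the total spectrum mass.
    """
    if record.mcnv_spectrum is None:
        raise ValueError(f"{record.sv_id}: no MCNV spectrum to decompose")
    del_af = sum(f for cn, f in record.mcnv_spectrum.items() if cn < expected_cn)
    dup_af = sum(f for cn, f in record.mcnv_spectrum.items() if cn > expected_cn)
    return (min(del_af, 1.0), min(dup_af, 1.0))
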
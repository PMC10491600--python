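"""Gene models for pharmacogene panels.

Loads exon structures from GTF/GFF or BED12, joins them with a panel table
(gene -> ADME family, drug-target class, or comparison panel such as
"olfactory") and provides interval queries against gene spans and exons.

All coordinates are internally 0-based half-open; GTF/GFF input (1-based
inclusive) is converted on read, BED is taken as-is.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: ADME gene families (drug absorption/distribution/metabolism/excretion).
ADME_CLASSES = frozenset({"NR", "CYP", "SLC", "ABC", "phase1", "phase2", "other_adme"})
#: Pharmacodynamic drug-target classes.
TARGET_CLASSES = frozenset(
    {"ion_channel", "membrane_receptor", "enzyme", "transporter", "other_target"}
)
VALID_PANEL_CLASSES = ADME_CLASSES | TARGET_CLASSES | {"olfactory", "none"}


def panel_group(panel_class: str) -> str:
    """Map a fine-grained panel class to its top-level group.

    Returns one of ``"ADME"``, ``"target"``, ``"olfactory"`` or ``"none"``.
    """
    if panel_class in ADME_CLASSES:
        return "ADME"
    if panel_class in TARGET_CLASSES:
        return "target"
    if panel_class == "olfactory":
        return "olfactory"
    return "none"


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class ExonInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class GeneModel:
    """A gene with its exon structure and pharmacogene panel class.

    ``span`` is the union extent of the exons plus a configurable flank on
    each side, and is the interval used to assign SVs to the gene.
    ``gene_length_kb`` (span length / 1000) is the denominator for per-kb SV
    density.  ``cds`` optionally restricts the coding portion of exons; when
    present, exon-overlapping SVs that touch no CDS base are treated as
    UTR-only downstream.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    panel_class: str = "none"
    flank: int = 0
    cds: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id}: exons not sorted/disjoint at [{s2}, {e2})"
                )
        if self.cds is not None:
            self.cds = tuple((int(s), int(e)) for s, e in self.cds)

    @property
    def span_start(self) -> int:
        return max(0, self.exons[0][0] - self.flank)

    @property
    def span_end(self) -> int:
        return self.exons[-1][1] + self.flank

    @property
    def span(self) -> tuple[int, int]:
        return (self.span_start, self.span_end)

    @property
    def gene_length_kb(self) -> float:
        return (self.span_end - self.span_start) / 1000.0

    def overlaps_exon(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.exons)

    def overlaps_cds(self, start: int, end: int) -> bool:
        if self.cds is None:
            return self.overlaps_exon(start, end)
        return any(s < end and start < e for s, e in self.cds)

    def exonic_overlap_bp(self, start: int, end: int, coding_only: bool = False) -> int:
        """Total bases of [start, end) falling in exons (or CDS if requested)."""
        blocks = self.cds if (coding_only and self.cds is not None) else self.exons
        return sum(max(0, min(e, end) - max(s, start)) for s, e in blocks)


@dataclass
class GeneSet:
    """Panel genes keyed by id with an interval index over their spans."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    #: panel genes that could not be resolved in the annotation
    missing: list[dict] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            old = self.genes[gene.gene_id]
            if (old.chrom, old.exons) != (gene.chrom, gene.exons):
                raise ValueError(
                    f"duplicate gene_id {gene.gene_id} with conflicting coordinates"
                )
            return
        self.genes[gene.gene_id] = gene
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.span_start, gene.span_end, gene.gene_id
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def symbol_of(self, gene_id: str) -> str:
        return self.genes[gene_id].symbol

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, bool]]:
        """Genes whose span intersects [start, end), with an exon-overlap flag.

        Returned sorted by gene span start then gene_id for determinism.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end):
            gene = self.genes[iv.data]
            hits.append((gene.gene_id, gene.overlaps_exon(start, end)))
        hits.sort(key=lambda h: (self.genes[h[0]].span_start, h[0]))
        return hits

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "panel_class": g.panel_class,
                    "flank": g.flank,
                    "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
                    "cds": ""
                    if g.cds is None
                    else ",".join(f"{s}-{e}" for s, e in g.cds),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "GeneSet":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
        gs = cls()
        for row in df.itertuples(index=False):
            exons = tuple(
                tuple(map(int, p.split("-"))) for p in row.exons.split(",")
            )
            cds = None
            if getattr(row, "cds", ""):
                cds = tuple(tuple(map(int, p.split("-"))) for p in row.cds.split(","))
            gs.add(
                GeneModel(
                    gene_id=row.gene_id,
                    symbol=row.symbol,
                    chrom=row.chrom,
                    strand=row.strand,
                    exons=exons,
                    panel_class=row.panel_class,
                    flank=int(row.flank),
                    cds=cds,
                )
            )
        return gs


def gene_interval_query(
    gene_set: GeneSet, chrom: str, start: int, end: int
) -> list[tuple[str, bool]]:
    """Functional alias for :meth:`GeneSet.query`."""
    return gene_set.query(chrom, start, end)


# ---------------------------------------------------------------------------
# Annotation readers


def _iter_lines(source) -> Iterable[tuple[int, str]]:
    if isinstance(source, str) and "\n" not in source:
        fh: TextIO = open(source)
    elif isinstance(source, str):
        fh = io.StringIO(source)
    else:
        fh = source
    try:
        for i, line in enumerate(fh, start=1):
            yield i, line.rstrip("\n")
    finally:
        fh.close()


def _parse_gtf(source, gene_key: str, transcript_mode: str):
    """Collect exon (and CDS) intervals per gene from GTF/GFF text.

    Returns ``{gene_id: (symbol, chrom, strand, exons, cds)}`` with exons
    taken from the canonical (longest by summed exon length) transcript, or
    the union over all transcripts when ``transcript_mode == "union"``.
    """
    per_tx: dict[tuple[str, str], dict] = {}
    for lineno, line in _iter_lines(source):
        if not line or line.startswith("#"):
            continue
        if line.count("\t") < 8:
            raise AnnotationParseError(lineno, f"expected 9 tab-separated fields: {line[:60]!r}")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise AnnotationParseError(lineno, str(exc)) from exc
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            gene_id = feat.attributes[gene_key][0]
        except KeyError as exc:
            raise AnnotationParseError(lineno, f"missing attribute {gene_key!r}") from exc
        tx_id = (feat.attributes.get("transcript_id") or [gene_id])[0]
        symbol = (feat.attributes.get("gene_name") or [gene_id])[0]
        rec = per_tx.setdefault(
            (gene_id, tx_id),
            {"symbol": symbol, "chrom": feat.seqid, "strand": feat.strand or ".",
             "exons": [], "cds": []},
        )
        interval = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if interval[0] >= interval[1]:
            raise AnnotationParseError(lineno, f"empty feature interval {interval}")
        rec["exons" if feat.featuretype == "exon" else "cds"].append(interval)

    def merged(intervals):
        out = []
        for s, e in sorted(intervals):
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return tuple((s, e) for s, e in out)

    by_gene: dict[str, dict] = {}
    for (gene_id, tx_id), rec in per_tx.items():
        by_gene.setdefault(gene_id, []).append(rec)
    out = {}
    for gene_id, txs in by_gene.items():
        if transcript_mode == "union":
            exons = merged([iv for t in txs for iv in t["exons"]])
            cds = merged([iv for t in txs for iv in t["cds"]])
        else:  # canonical: longest summed exon length, stable tie-break
            txs = sorted(
                txs,
                key=lambda t: (-sum(e - s for s, e in t["exons"]), t["chrom"]),
            )
            exons = merged(txs[0]["exons"])
            cds = merged(txs[0]["cds"])
        rec = txs[0]
        out[gene_id] = (rec["symbol"], rec["chrom"], rec["strand"], exons,
                        cds if cds else None)
    return out


def _parse_bed12(source):
    out = {}
    for lineno, line in _iter_lines(source):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AnnotationParseError(lineno, "BED12 requires 12 columns")
        try:
            chrom, start = fields[0], int(fields[1])
            name, strand = fields[3], fields[5]
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationParseError(lineno, str(exc)) from exc
        if len(block_sizes) != len(block_starts):
            raise AnnotationParseError(lineno, "blockSizes/blockStarts length mismatch")
        exons = tuple(
            (start + bs, start + bs + sz) for bs, sz in zip(block_starts, block_sizes)
        )
        if name in out and (out[name][1], out[name][3]) != (chrom, exons):
            raise ValueError(f"duplicate gene_id {name} with conflicting coordinates")
        out[name] = (name, chrom, strand, exons, None)
    return out


def read_panel_table(source) -> pd.DataFrame:
    """Read a 2+-column gene->class TSV (header optional columns gene, class)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if "gene" in cols and "class" in cols:
        df = df.rename(columns=dict(zip(df.columns, cols)))
    else:  # headerless
        if hasattr(source, "seek"):
            source.seek(0)
        df = pd.read_csv(source, sep="\t", header=None, dtype=str,
                         keep_default_na=False)
        df = df.rename(columns={0: "gene", 1: "class"})
    return df[["gene", "class"]]


def load_gene_models(
    annotation,
    panel_table,
    fmt: str = "gtf",
    gene_key: str = "gene_id",
    transcript_mode: str = "canonical",
    flank: int = 0,
) -> GeneSet:
    """Build a :class:`GeneSet` from annotation + panel table.

    Parameters
    ----------
    annotation : path, text or open handle of GTF/GFF (``fmt="gtf"``) or
        BED12 (``fmt="bed12"``).
    panel_table : path/handle/DataFrame with columns gene (id or symbol)
        and class.
    transcript_mode : "canonical" keeps the longest transcript's exons;
        "union" merges exons over all transcripts.
    flank : bp added on each side of the exon union for SV assignment.

    Panel genes absent from the annotation are recorded on
    :attr:`GeneSet.missing` (and logged), never silently dropped.
    """
    if fmt == "gtf":
        models = _parse_gtf(annotation, gene_key, transcript_mode)
    elif fmt == "bed12":
        models = _parse_bed12(annotation)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    panel = panel_table if isinstance(panel_table, pd.DataFrame) else read_panel_table(panel_table)
    by_symbol = {m[0]: gid for gid, m in models.items()}

    gs = GeneSet()
    for row in panel.itertuples(index=False):
        gid = row.gene if row.gene in models else by_symbol.get(row.gene)
        if gid is None:
            rec = {"gene": row.gene, "class": getattr(row, "_1", row[1]),
                   "reason": "absent from annotation"}
            gs.missing.append(rec)
            logger.warning("panel gene %s not found in annotation", row.gene)
            continue
        symbol, chrom, strand, exons, cds = models[gid]
        gs.add(
            GeneModel(
                gene_id=gid,
                symbol=symbol,
                chrom=chrom,
                strand=strand,
                exons=exons,
                panel_class=row[1],
                flank=flank,
                cds=cds,
            )
        )
    return gs
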
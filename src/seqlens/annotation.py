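"""Gene annotation import and strand-aware interval arithmetic.

Internal convention: all coordinates are 0-based, half-open ``[start, end)``.
1-based inclusive coordinates appear only at the parse/print boundary (GTF
files and user-facing ``chrom:start-end`` query strings, which follow the
genome-browser convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pyranges as pr

logger = logging.getLogger(__name__)

_COORD_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)(?::(?P<strand>[+-.]))?$"
)


class AnnotationError(ValueError):
    """Raised for unparseable annotation input or failed lookups."""


@dataclass(frozen=True)
class GenomicRegion:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_query_string(self) -> str:
        """Render in 1-based inclusive browser convention."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure (union across transcripts)."""

    gene_id: str
    symbol: str
    region: GenomicRegion
    exons: tuple[GenomicRegion, ...]
    biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: exon list empty")
        for ex in self.exons:
            if ex.chrom != self.region.chrom or ex.strand != self.region.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex} on different chrom/strand"
                )
            if ex.start < self.region.start or ex.end > self.region.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex} outside gene bounds"
                )


@dataclass
class AnnotationStore:
    """Gene models indexed by id and by symbol; one annotation source at a time.

    Symbol lookups preserve ambiguity: all genes sharing a symbol are
    returned, position-sorted.
    """

    genes: dict[str, GeneModel] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    _by_symbol: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene
        self._by_symbol.setdefault(gene.symbol, []).append(gene.gene_id)

    def by_id(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_symbol(self, symbol: str) -> list[GeneModel]:
        hits = [self.genes[g] for g in self._by_symbol.get(symbol, [])]
        return sorted(hits, key=lambda g: (g.region.chrom, g.region.start))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def genes_overlapping(self, region: GenomicRegion) -> list[GeneModel]:
        hits = [g for g in self if g.region.overlaps(region)]
        return sorted(hits, key=lambda g: (g.region.chrom, g.region.start))


# ---------------------------------------------------------------------------
# import_annotation
# ---------------------------------------------------------------------------

def import_annotation(
    path: str | Path, contig_lengths: dict[str, int] | None = None
) -> AnnotationStore:
    """Load a GTF or BED annotation into an :class:`AnnotationStore`.

    GTF gene/exon features are merged per ``gene_id``; BED12 blocks become
    exons; BED6 lines become single-exon genes. GTF 1-based inclusive
    coordinates are converted to internal 0-based half-open. Exons extending
    beyond their gene's declared bounds are clamped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        store = _import_gtf(path)
    elif suffix == ".bed":
        store = _import_bed(path)
    else:
        raise AnnotationError(
            f"unrecognized annotation format {suffix!r}: expected .gtf or .bed"
        )
    if contig_lengths:
        store.contig_lengths = dict(contig_lengths)
        for gene in store:
            clen = store.contig_lengths.get(gene.region.chrom)
            if clen is not None and gene.region.end > clen:
                raise AnnotationError(
                    f"gene {gene.gene_id} extends past contig "
                    f"{gene.region.chrom} length {clen}"
                )
    return store


def _import_gtf(path: Path) -> AnnotationStore:
    try:
        ranges = pr.read_gtf(str(path)).df
    except Exception as exc:  # pyranges reports the offending line
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc
    if "gene_id" not in ranges.columns:
        raise AnnotationError(f"GTF {path} has no gene_id attributes")

    store = AnnotationStore()
    genes_df = ranges[ranges["Feature"] == "gene"]
    exons_df = ranges[ranges["Feature"] == "exon"]
    if exons_df.empty and genes_df.empty:
        raise AnnotationError(f"GTF {path} contains no gene or exon features")

    bounds: dict[str, dict] = {}
    for row in genes_df.itertuples():
        bounds[row.gene_id] = {
            "chrom": row.Chromosome,
            "start": int(row.Start),
            "end": int(row.End),
            "strand": row.Strand,
            "symbol": getattr(row, "gene_name", None) or row.gene_id,
            "biotype": getattr(row, "gene_biotype", None),
        }

    exons_by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for row in exons_df.itertuples():
        exons_by_gene.setdefault(row.gene_id, []).append(
            (row.Chromosome, int(row.Start), int(row.End), row.Strand)
        )

    all_ids = list(dict.fromkeys(list(bounds) + list(exons_by_gene)))
    for gid in all_ids:
        exons = exons_by_gene.get(gid)
        info = bounds.get(gid)
        if info is None:
            # no explicit gene feature: infer bounds from the exons
            chrom, _, _, strand = exons[0]
            info = {
                "chrom": chrom,
                "start": min(e[1] for e in exons),
                "end": max(e[2] for e in exons),
                "strand": strand,
                "symbol": gid,
                "biotype": None,
            }
        region = GenomicRegion(
            info["chrom"], info["start"], info["end"], info["strand"], name=gid
        )
        if exons is None:
            exon_regions = (replace(region, name=None),)
        else:
            exon_regions = []
            for chrom, start, end, strand in sorted(exons, key=lambda e: e[1]):
                if start < region.start or end > region.end:
                    logger.warning(
                        "gene %s: exon [%d, %d) outside gene bounds "
                        "[%d, %d); clamping",
                        gid, start, end, region.start, region.end,
                    )
                    start = max(start, region.start)
                    end = min(end, region.end)
                exon_regions.append(GenomicRegion(chrom, start, end, strand))
            exon_regions = tuple(exon_regions)
        biotype = info["biotype"]
        if biotype is not None and not isinstance(biotype, str):
            biotype = None
        store.add(GeneModel(gid, info["symbol"], region, exon_regions, biotype))
    return store


def _import_bed(path: Path) -> AnnotationStore:
    try:
        df = pr.read_bed(str(path)).df
    except Exception as exc:
        raise AnnotationError(f"failed to parse BED {path}: {exc}") from exc
    store = AnnotationStore()
    is_bed12 = "BlockCount" in df.columns
    for i, row in enumerate(df.itertuples()):
        name = getattr(row, "Name", None) or f"bed_{i}"
        strand = getattr(row, "Strand", ".") or "."
        region = GenomicRegion(
            row.Chromosome, int(row.Start), int(row.End), strand, name=name
        )
        if is_bed12:
            sizes = [int(x) for x in str(row.BlockSizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.BlockStarts).rstrip(",").split(",")]
            exons = tuple(
                GenomicRegion(
                    region.chrom, region.start + s, region.start + s + L, strand
                )
                for s, L in zip(starts, sizes)
            )
        else:
            exons = (GenomicRegion(region.chrom, region.start, region.end, strand),)
        store.add(GeneModel(name, name, region, exons))
    return store


# ---------------------------------------------------------------------------
# resolve_query
# ---------------------------------------------------------------------------

def resolve_query(store: AnnotationStore, query: str) -> list[GenomicRegion]:
    """Resolve a gene id, symbol, or 1-based ``chrom:start-end[:strand]``
    string to internal half-open regions, position-sorted."""
    query = query.strip()
    if query in store.genes:
        return [store.genes[query].region]
    symbol_hits = store.by_symbol(query)
    if symbol_hits:
        return [g.region for g in symbol_hits]

    m = _COORD_RE.match(query)
    if m is None:
        raise AnnotationError(f"query {query!r} matched no gene and is not a "
                              "chrom:start-end coordinate string")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or start1 > end1:
        raise AnnotationError(
            f"malformed coordinate query {query!r}: need 1 <= start <= end"
        )
    strand = m.group("strand") or "."
    return [GenomicRegion(m.group("chrom"), start1 - 1, end1, strand)]


# ---------------------------------------------------------------------------
# exon_union / flank_region
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicRegion],
) -> list[GenomicRegion]:
    """Merge overlapping/adjacent same-chrom intervals into a disjoint,
    sorted list. Strand of the first interval is carried through."""
    ivs = sorted(intervals, key=lambda r: (r.chrom, r.start))
    merged: list[GenomicRegion] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = replace(prev, end=iv.end)
        else:
            merged.append(iv)
    return merged


def exon_union(gene: GeneModel) -> tuple[list[GenomicRegion], int]:
    """Merged disjoint exon intervals of a gene and their total length (bp).

    The union length is the gene length used for RPKM.
    """
    merged = merge_intervals(gene.exons)
    return merged, sum(len(iv) for iv in merged)


def flank_region(
    region: GenomicRegion,
    upstream: int,
    downstream: int,
    anchor: str = "body",
    contig_length: int | None = None,
) -> GenomicRegion:
    """Extend or re-anchor a region, strand-aware.

    ``anchor="body"`` extends ``upstream`` bp before the 5' end and
    ``downstream`` bp after the 3' end. ``anchor="tss"`` returns a window of
    length ``upstream + downstream`` centered on the strand-aware
    transcription start (requires a stranded region). Results are clamped to
    ``[0, contig_length)`` with a logged warning.
    """
    if upstream < 0 or downstream < 0:
        raise AnnotationError("flank sizes must be non-negative")
    if anchor == "tss":
        if region.strand not in ("+", "-"):
            raise AnnotationError(
                "anchor='tss' requires a stranded (+/-) region"
            )
        tss = region.start if region.strand == "+" else region.end
        if region.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
    elif anchor == "body":
        if region.strand == "-":
            start, end = region.start - downstream, region.end + upstream
        else:
            start, end = region.start - upstream, region.end + downstream
    else:
        raise AnnotationError(f"unknown anchor {anchor!r}")

    clamped_start = max(0, start)
    clamped_end = end if contig_length is None else min(end, contig_length)
    if clamped_start != start or clamped_end != end:
        logger.warning(
            "flank of %s clamped to [%d, %d) at contig edge",
            region, clamped_start, clamped_end,
        )
    return replace(region, start=clamped_start, end=clamped_end)


def regions_to_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED6."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t0\t{r.strand}\n"
            )
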
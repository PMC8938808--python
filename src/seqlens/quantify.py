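"""Read counting over genes and custom regions, and abundance scales.

Counts come straight from indexed BAMs, so abundances can be computed
on-the-fly for regions that carry no annotation at all (e.g. candidate long
non-coding RNAs). A read (or fragment) counts for a feature iff its aligned
bases overlap the feature's interval(s) by at least ``min_overlap_bp``; it
is counted at most once per feature even when it touches several of the
feature's exons, and a read spanning two genes counts for both.

Normalization follows the DESeq median-of-ratios scheme: the size factor of
sample *s* is the median over features of ``count_{f,s} / geomean_f`` where
``geomean_f`` is the feature's geometric mean count across samples (features
with a zero geometric mean are excluded). RPKM uses the exon-union length
for genes and the span for plain regions.

Features are never hard-filtered: quality flags (LOW_COUNT, SHORT,
ZERO_IN_ALL) are attached so filtering stays a downstream, user-driven
choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel, GenomicRegion, exon_union
from .registry import DatasetInstance, validate_instance

logger = logging.getLogger(__name__)

SCALES = ("raw", "normalized", "rpkm", "log2raw", "log2normalized", "log2rpkm")

FLAG_LOW_COUNT = "LOW_COUNT"
FLAG_SHORT = "SHORT"
FLAG_ZERO_IN_ALL = "ZERO_IN_ALL"


class QuantifyError(RuntimeError):
    pass


@dataclass
class CountingParams:
    """The counting contract: which alignments qualify and what counts as an
    overlap."""

    min_mapq: int = 10
    count_fragments: bool = False
    include_duplicates: bool = False
    min_overlap_bp: int = 1
    stranded: str = "none"  # {none, forward, reverse}

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_overlap_bp < 1:
            raise ValueError("min_mapq >= 0 and min_overlap_bp >= 1 required")
        if self.stranded not in ("none", "forward", "reverse"):
            raise ValueError(f"unknown strandedness {self.stranded!r}")


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-feature lengths and flags."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lengths: np.ndarray
    flags: list[set[str]] = field(default_factory=list)
    conditions: list[str] | None = None  # per-sample condition labels

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths, dtype=int)
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.counts.shape != (nf, ns):
            raise QuantifyError(
                f"counts shape {self.counts.shape} != ({nf}, {ns})"
            )
        if self.lengths.shape != (nf,) or np.any(self.lengths <= 0):
            raise QuantifyError("lengths must be positive, one per feature")
        if np.any(self.counts < 0):
            raise QuantifyError("negative counts")
        if not self.flags:
            self.flags = [set() for _ in range(nf)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class ExpressionTable:
    """Real-valued expression at a named scale; same shape as CountMatrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str
    lengths: np.ndarray | None = None
    flags: list[set[str]] | None = None
    conditions: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.scale.startswith("log2") and np.any(self.values < 0):
            raise QuantifyError(f"negative values on scale {self.scale}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# read-level counting
# ---------------------------------------------------------------------------

def _read_passes(read: pysam.AlignedSegment, params: CountingParams) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_qcfail:
        return False
    if read.is_duplicate and not params.include_duplicates:
        return False
    if read.mapping_quality < params.min_mapq:
        return False
    return True


def _strand_ok(read: pysam.AlignedSegment, strand: str, mode: str) -> bool:
    if mode == "none" or strand == ".":
        return True
    read_strand = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        read_strand = "+" if read_strand == "-" else "-"
    return (read_strand == strand) == (mode == "forward")


def _read_key(read: pysam.AlignedSegment, params: CountingParams):
    if params.count_fragments:
        return read.query_name
    mate = 1 if read.is_read1 else (2 if read.is_read2 else 0)
    return (read.query_name, mate)


def _overlap_bp(
    blocks: list[tuple[int, int]], intervals: Sequence[tuple[int, int]]
) -> int:
    total = 0
    for bs, be in blocks:
        for fs, fe in intervals:
            lo, hi = max(bs, fs), min(be, fe)
            if lo < hi:
                total += hi - lo
    return total


def _count_feature(
    bam: pysam.AlignmentFile,
    chrom: str,
    intervals: Sequence[tuple[int, int]],
    strand: str,
    params: CountingParams,
) -> int:
    from .signal import aligned_blocks

    if chrom not in bam.references:
        logger.warning("contig %r absent from BAM %s; count 0", chrom,
                       bam.filename.decode() if bam.filename else "?")
        return 0
    counted: set = set()
    for fs, fe in intervals:
        for read in bam.fetch(chrom, fs, fe):
            if not _read_passes(read, params):
                continue
            if not _strand_ok(read, strand, params.stranded):
                continue
            key = _read_key(read, params)
            if key in counted:
                continue
            if _overlap_bp(aligned_blocks(read), intervals) >= params.min_overlap_bp:
                counted.add(key)
    return len(counted)


def count_reads(
    bam_path: str | Path,
    regions: Sequence[GenomicRegion],
    params: CountingParams | None = None,
) -> np.ndarray:
    """Count qualifying reads/fragments per region from an indexed BAM."""
    params = params or CountingParams()
    counts = np.zeros(len(regions), dtype=int)
    if not regions:
        return counts
    with _open_indexed(bam_path) as bam:
        for i, region in enumerate(regions):
            counts[i] = _count_feature(
                bam, region.chrom, [(region.start, region.end)],
                region.strand, params,
            )
    return counts


def gene_counts(
    bam_path: str | Path,
    genes: Sequence[GeneModel],
    params: CountingParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene counts over exon-union intervals, plus union lengths.

    A read overlapping several genes is counted for each of them; no
    ambiguity resolution is attempted.
    """
    params = params or CountingParams()
    counts = np.zeros(len(genes), dtype=int)
    lengths = np.zeros(len(genes), dtype=int)
    with _open_indexed(bam_path) as bam:
        for i, gene in enumerate(genes):
            union, ulen = exon_union(gene)
            lengths[i] = ulen
            counts[i] = _count_feature(
                bam, gene.region.chrom,
                [(e.start, e.end) for e in union],
                gene.region.strand, params,
            )
    return counts, lengths


def _open_indexed(bam_path: str | Path) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(str(bam_path))
    if not bam.has_index():
        bam.close()
        raise QuantifyError(
            f"BAM {bam_path} has no index; run 'samtools index' first"
        )
    return bam


# ---------------------------------------------------------------------------
# normalization and scales
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """DESeq median-of-ratios size factors, one per sample.

    Features whose geometric mean across samples is zero (any zero count)
    are excluded from the median.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    finite = np.all(np.isfinite(logc), axis=1)
    if not np.any(finite):
        raise QuantifyError(
            "no feature has all-positive counts; cannot compute "
            "median-of-ratios size factors (quantify more features)"
        )
    log_geomean = logc[finite].mean(axis=1)
    factors = np.exp(
        np.median(logc[finite] - log_geomean[:, None], axis=0)
    )
    return factors


def transform_counts(
    counts: CountMatrix,
    scale: str,
    factors: np.ndarray | None = None,
    library_sizes: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> ExpressionTable:
    """Convert raw counts to the requested expression scale.

    normalized = count / size factor; RPKM = count / (length_kb x
    library_size_millions); log2 scales apply ``log2(x + pseudocount)``.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")
    base = scale[4:] if scale.startswith("log2") else scale
    mat = counts.counts.astype(float)
    if base == "raw":
        values = mat
    elif base == "normalized":
        if factors is None:
            raise QuantifyError(f"scale {scale!r} requires size factors")
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (len(counts.sample_ids),) or np.any(factors <= 0):
            raise QuantifyError("size factors must be positive, one per sample")
        values = mat / factors[None, :]
    elif base == "rpkm":
        if library_sizes is None:
            raise QuantifyError(f"scale {scale!r} requires library_sizes")
        library_sizes = np.asarray(library_sizes, dtype=float)
        if library_sizes.shape != (len(counts.sample_ids),):
            raise QuantifyError("one library size per sample required")
        kb = counts.lengths.astype(float) / 1e3
        values = mat / (kb[:, None] * (library_sizes[None, :] / 1e6))
    if scale.startswith("log2"):
        values = np.log2(values + pseudocount)
    return ExpressionTable(
        feature_ids=list(counts.feature_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        scale=scale,
        lengths=counts.lengths,
        flags=counts.flags,
        conditions=counts.conditions,
    )


def assign_flags(
    counts: CountMatrix,
    low_count_max: int = 10,
    short_bp: int = 200,
) -> list[set[str]]:
    """Attach quality flags; features are flagged, never removed.

    LOW_COUNT: maximum count across samples below ``low_count_max``;
    SHORT: feature length below ``short_bp``; ZERO_IN_ALL: zero everywhere.
    """
    flags: list[set[str]] = []
    maxima = counts.counts.max(axis=1) if counts.counts.size else np.array([])
    for i in range(len(counts.feature_ids)):
        f: set[str] = set()
        if maxima[i] < low_count_max:
            f.add(FLAG_LOW_COUNT)
        if counts.lengths[i] < short_bp:
            f.add(FLAG_SHORT)
        if maxima[i] == 0:
            f.add(FLAG_ZERO_IN_ALL)
        flags.append(f)
    counts.flags = flags
    return flags


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_count_matrix(
    instance: DatasetInstance,
    genes: Sequence[GeneModel],
    params: CountingParams | None = None,
) -> CountMatrix:
    """Gene-level count matrix over all selected samples (columns in
    instance order, grouped by condition)."""
    params = params or CountingParams()
    report = validate_instance(instance, {"bam"})
    if not report.passed:
        raise QuantifyError(
            "instance does not validate for BAM (abundance calculation "
            f"requires BAM files):\n{report}"
        )
    samples = instance.all_samples()
    cols, lengths = [], None
    for sample in samples:
        try:
            c, lengths = gene_counts(sample.bam_path, genes, params)
        except QuantifyError as exc:
            raise QuantifyError(f"sample {sample.sample_id}: {exc}") from exc
        cols.append(c)
    cm = CountMatrix(
        feature_ids=[g.gene_id for g in genes],
        sample_ids=[s.sample_id for s in samples],
        counts=np.column_stack(cols) if cols else np.zeros((len(genes), 0), int),
        lengths=lengths,
        conditions=[s.condition for s in samples],
    )
    assign_flags(cm)
    return cm


def quantify_regions(
    instance: DatasetInstance,
    genes: Sequence[GeneModel],
    regions: Sequence[GenomicRegion] = (),
    scale: str = "raw",
    params: CountingParams | None = None,
    pseudocount: float = 1.0,
) -> ExpressionTable:
    """Quantify genes plus optional custom (possibly non-annotated) regions
    across an instance, at any supported scale.

    Size factors are computed from the gene-level matrix only; custom
    regions are normalized with those gene-derived factors and appended
    without influencing them. RPKM uses each sample's library size.
    """
    params = params or CountingParams()
    if regions and not genes:
        raise QuantifyError(
            "custom regions are normalized with gene-derived size factors; "
            "provide the gene annotation as well"
        )
    gene_cm = build_count_matrix(instance, genes, params)
    samples = instance.all_samples()

    if regions:
        cols = [count_reads(s.bam_path, regions, params) for s in samples]
        region_counts = np.column_stack(cols)
        region_ids = [
            r.name or r.to_query_string() for r in regions
        ]
        region_lengths = np.array([len(r) for r in regions])
        cm = CountMatrix(
            feature_ids=list(gene_cm.feature_ids) + region_ids,
            sample_ids=gene_cm.sample_ids,
            counts=np.vstack([gene_cm.counts, region_counts]),
            lengths=np.concatenate([gene_cm.lengths, region_lengths]),
            conditions=gene_cm.conditions,
        )
        assign_flags(cm)
    else:
        cm = gene_cm

    factors = library_sizes = None
    base = scale[4:] if scale.startswith("log2") else scale
    if base == "normalized":
        factors = size_factors(gene_cm)
    if base == "rpkm":
        library_sizes = np.array([s.get_library_size() for s in samples])
    return transform_counts(
        cm, scale, factors=factors, library_sizes=library_sizes,
        pseudocount=pseudocount,
    )
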
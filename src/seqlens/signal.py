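"""Coverage extraction, binned profiles, and per-condition averaging.

Per-base read depth is read from pre-normalized BigWig tracks or computed
from BAM alignments. Profiles are binned to a fixed length, optionally
oriented 5'->3', and averaged across the replicates of each biological
condition with a dispersion band — the data behind condition-averaged
signal plots and track-style neighborhood views.

Depth from BAM counts primary, QC-pass, non-duplicate alignments. Spliced
alignments (``N`` CIGAR operations) contribute depth only to their aligned
segments; deletions (``D``) count as covered, insertions and soft clips do
not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pyBigWig
import pysam

from .annotation import AnnotationStore, GenomicRegion, exon_union
from .registry import DatasetInstance, SampleRecord

logger = logging.getLogger(__name__)

#: CIGAR operations that consume reference bases and count as covered.
_COVERED_OPS = frozenset({0, 2, 7, 8})  # M, D, =, X
#: CIGAR operations that consume reference bases without coverage.
_SKIP_OPS = frozenset({3})  # N


class SignalError(RuntimeError):
    pass


@dataclass
class CoverageVector:
    """Per-base coverage over a region; ``scale`` is raw depth or
    per-million-normalized signal."""

    region: GenomicRegion
    values: np.ndarray
    scale: str = "raw"  # {raw, per_million}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region),):
            raise SignalError(
                f"coverage length {self.values.shape} != region length "
                f"{len(self.region)}"
            )
        if np.any(self.values < 0):
            raise SignalError("negative coverage values")


@dataclass
class BinnedProfile:
    sample_id: str
    region: GenomicRegion
    n_bins: int
    values: np.ndarray
    oriented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_bins,):
            raise SignalError("binned profile length != n_bins")


@dataclass
class ConditionProfile:
    """Mean binned profile across a condition's replicates, with a
    dispersion band (half-width; SD or SE across samples per bin)."""

    condition: str
    n: int
    mean: np.ndarray
    band: np.ndarray
    per_sample: list[BinnedProfile] | None = None


# ---------------------------------------------------------------------------
# extract_coverage
# ---------------------------------------------------------------------------

def extract_coverage(
    sample: SampleRecord, region: GenomicRegion, source: str = "bigwig"
) -> CoverageVector:
    """Per-base coverage of ``region`` for one sample.

    ``source="bigwig"`` reads the pre-normalized signal track directly
    (scale ``per_million``; intervals absent from the file are 0).
    ``source="bam"`` computes raw depth of primary, QC-pass, non-duplicate
    alignments.
    """
    if source == "bigwig":
        if sample.bigwig_path is None:
            raise SignalError(f"sample {sample.sample_id}: no BigWig configured")
        values = _bigwig_coverage(sample.bigwig_path, region)
        return CoverageVector(region, values, scale="per_million")
    if source == "bam":
        if sample.bam_path is None:
            raise SignalError(f"sample {sample.sample_id}: no BAM configured")
        values = bam_depth(sample.bam_path, region)
        return CoverageVector(region, values, scale="raw")
    raise ValueError(f"unknown source {source!r}")


def _bigwig_coverage(path: Path, region: GenomicRegion) -> np.ndarray:
    try:
        bw = pyBigWig.open(str(path))
    except (OSError, RuntimeError) as exc:
        raise SignalError(f"cannot open BigWig {path}: {exc}") from exc
    try:
        chroms = bw.chroms()
        if region.chrom not in chroms:
            raise SignalError(
                f"contig {region.chrom!r} absent from BigWig {path}"
            )
        if region.end > chroms[region.chrom]:
            raise SignalError(
                f"region {region} beyond contig length "
                f"{chroms[region.chrom]} in {path}"
            )
        values = bw.values(region.chrom, region.start, region.end, numpy=True)
    finally:
        bw.close()
    return np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)


def bam_depth(bam_path: str | Path, region: GenomicRegion) -> np.ndarray:
    """Raw per-base depth over a region from a coordinate-sorted BAM."""
    depth_diff = np.zeros(len(region) + 1, dtype=float)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if region.chrom not in bam.references:
            raise SignalError(
                f"contig {region.chrom!r} absent from BAM {bam_path}"
            )
        for read in bam.fetch(region.chrom, region.start, region.end):
            if not _use_read(read):
                continue
            for start, end in aligned_blocks(read):
                lo = max(start, region.start) - region.start
                hi = min(end, region.end) - region.start
                if lo < hi:
                    depth_diff[lo] += 1
                    depth_diff[hi] -= 1
    return np.cumsum(depth_diff[:-1])


def _use_read(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_qcfail
        or read.is_duplicate
    )


def aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals covered by a read: M/=/X and D consume and cover;
    N consumes without covering; I/S/H/P consume nothing."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in _COVERED_OPS:
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op in _SKIP_OPS:
            pos += length
    return blocks


# ---------------------------------------------------------------------------
# bin_profile
# ---------------------------------------------------------------------------

def bin_profile(
    cov: CoverageVector,
    n_bins: int,
    sample_id: str = "",
    oriented: bool = True,
) -> BinnedProfile:
    """Split a coverage vector into ``n_bins`` near-equal contiguous spans
    (remainder bases go to the leftmost bins) and average within each.

    If the region is on the ``-`` strand and orientation is requested, the
    values are reversed so index 0 is the 5' end.
    """
    L = len(cov.region)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > L:
        raise SignalError(f"n_bins={n_bins} exceeds region length {L}")
    base, rem = divmod(L, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    sums = np.add.reduceat(cov.values, edges[:-1])
    values = sums / sizes
    flip = oriented and cov.region.strand == "-"
    if flip:
        values = values[::-1]
    return BinnedProfile(
        sample_id=sample_id,
        region=cov.region,
        n_bins=n_bins,
        values=values,
        oriented=flip,
    )


# ---------------------------------------------------------------------------
# average_by_condition
# ---------------------------------------------------------------------------

def average_by_condition(
    instance: DatasetInstance,
    region: GenomicRegion,
    n_bins: int = 200,
    source: str = "bigwig",
    band: str = "sd",
    oriented: bool = True,
) -> list[ConditionProfile]:
    """Binned coverage profiles averaged per biological condition.

    BAM-derived depth is scaled to per-million using each sample's library
    size before averaging, so conditions with different sequencing depths
    are comparable; BigWig tracks are assumed pre-normalized. The band is
    the per-bin sample SD (default) or SE; it is all-zero for single-sample
    conditions.
    """
    if band not in ("sd", "se"):
        raise ValueError("band must be 'sd' or 'se'")
    profiles: list[ConditionProfile] = []
    for condition in instance.conditions:
        per_sample: list[BinnedProfile] = []
        for sample in instance.samples_of(condition):
            try:
                cov = extract_coverage(sample, region, source=source)
            except SignalError as exc:
                raise SignalError(f"sample {sample.sample_id}: {exc}") from exc
            if source == "bam":
                cov.values = cov.values * (1e6 / sample.get_library_size())
                cov.scale = "per_million"
            per_sample.append(
                bin_profile(cov, n_bins, sample.sample_id, oriented=oriented)
            )
        stack = np.vstack([p.values for p in per_sample])
        mean = stack.mean(axis=0)
        n = stack.shape[0]
        if n == 1:
            half = np.zeros_like(mean)
        else:
            half = stack.std(axis=0, ddof=1)
            if band == "se":
                half = half / np.sqrt(n)
        profiles.append(
            ConditionProfile(condition, n, mean, half, per_sample=per_sample)
        )
    return profiles


# ---------------------------------------------------------------------------
# neighborhood_profile
# ---------------------------------------------------------------------------

def neighborhood_profile(
    instance: DatasetInstance,
    window: GenomicRegion,
    bin_width: int,
    store: AnnotationStore,
    source: str = "bigwig",
    band: str = "sd",
):
    """Track-style view of a larger window: fixed-width bins (the last bin
    may be short), unoriented, averaged per condition, plus a gene glyph
    table (genes overlapping the window with their exon sub-intervals) for
    rendering beneath the averaged tracks.
    """
    import pandas as pd

    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if len(window) < bin_width:
        raise SignalError("window shorter than bin_width")
    edges = list(range(0, len(window), bin_width)) + [len(window)]
    edges = np.unique(edges)
    n_bins = len(edges) - 1
    sizes = np.diff(edges)

    profiles: list[ConditionProfile] = []
    for condition in instance.conditions:
        rows = []
        for sample in instance.samples_of(condition):
            cov = extract_coverage(sample, window, source=source)
            if source == "bam":
                cov.values = cov.values * (1e6 / sample.get_library_size())
            sums = np.add.reduceat(cov.values, edges[:-1])
            rows.append(sums / sizes)
        stack = np.vstack(rows)
        mean = stack.mean(axis=0)
        n = stack.shape[0]
        if n == 1:
            half = np.zeros_like(mean)
        else:
            half = stack.std(axis=0, ddof=1)
            if band == "se":
                half = half / np.sqrt(n)
        profiles.append(ConditionProfile(condition, n, mean, half))

    glyph_rows = []
    for gene in store.genes_overlapping(window):
        union, _ = exon_union(gene)
        glyph_rows.append(
            {
                "gene_id": gene.gene_id,
                "symbol": gene.symbol,
                "chrom": gene.region.chrom,
                "start": gene.region.start,
                "end": gene.region.end,
                "strand": gene.region.strand,
                "exons": ",".join(f"{e.start}-{e.end}" for e in union),
            }
        )
    glyphs = pd.DataFrame(
        glyph_rows,
        columns=["gene_id", "symbol", "chrom", "start", "end", "strand", "exons"],
    )
    return profiles, glyphs


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def profiles_to_tsv(profiles: list[ConditionProfile], path: str | Path) -> None:
    """Write condition profiles as TSV: bin_index, then per-condition mean
    and band columns."""
    import pandas as pd

    data: dict[str, np.ndarray] = {}
    for p in profiles:
        data[f"{p.condition}_mean"] = p.mean
        data[f"{p.condition}_band"] = p.band
    df = pd.DataFrame(data)
    df.insert(0, "bin_index", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def condition_mean_coverage(
    instance: DatasetInstance, region: GenomicRegion, source: str = "bigwig"
) -> dict[str, CoverageVector]:
    """Unbinned per-condition mean coverage (per-million scale)."""
    out: dict[str, CoverageVector] = {}
    for condition in instance.conditions:
        vecs = []
        for sample in instance.samples_of(condition):
            cov = extract_coverage(sample, region, source=source)
            if source == "bam":
                cov.values = cov.values * (1e6 / sample.get_library_size())
            vecs.append(cov.values)
        out[condition] = CoverageVector(
            region, np.vstack(vecs).mean(axis=0), scale="per_million"
        )
    return out


def coverage_to_bedgraph(cov: CoverageVector, path: str | Path) -> None:
    """Write a coverage vector as bedGraph (run-length encoded)."""
    r = cov.region
    vals = cov.values
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(vals)]])
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{r.chrom}\t{r.start + s}\t{r.start + e}\t{v:g}\n")
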
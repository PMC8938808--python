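"""Deterministic synthetic RNA-Seq dataset generator.

Builds a complete toy dataset — multi-contig genome sizes, a GTF with
multi-exon genes on both strands, per-sample sorted+indexed BAMs, matching
per-million-normalized BigWig tracks, a manifest, and truth tables — so
every other module is testable without downloading anything.

Per-gene counts are drawn from a negative binomial with a common dispersion
phi and a known differentially-expressed subset; each counted read is then
placed uniformly over the exon union of its gene (fully exonic, single ``M``
CIGAR), so the true per-gene count is recoverable exactly by counting the
emitted BAM. A configurable number of unannotated "novel" single-exon
regions (lincRNA-like transcription outside the GTF) is simulated the same
way. Reads carry placeholder bases; no error model or quality strings are
simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyBigWig
import pysam
import yaml

from .annotation import GeneModel, GenomicRegion, exon_union
from .quantify import CountMatrix

logger = logging.getLogger(__name__)


class FixtureError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the toy dataset.

    Defaults: a 2-contig x 100 kb genome, 20 genes of 1-3 exons, two
    conditions with 3 replicates each, negative-binomial counts at baseline
    mean 100 with dispersion phi = 0.1, 10% of genes differentially
    expressed at |log2FC| = 2, 50 bp reads.
    """

    n_contigs: int = 2
    contig_length_bp: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 3)
    conditions: dict[str, int] = field(
        default_factory=lambda: {"control": 3, "treated": 3}
    )
    baseline_mean: float = 100.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    read_length: int = 50
    n_novel_regions: int = 2
    novel_mean: float = 80.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length_bp < 1 or self.n_genes < 1:
            raise FixtureError("genome/gene counts must be positive")
        if not self.conditions:
            raise FixtureError("at least one condition required")
        for cond, n in self.conditions.items():
            if n < 1:
                raise FixtureError(
                    f"condition {cond!r} has {n} replicates; need >= 1"
                )
        if not (0.0 <= self.de_fraction <= 1.0):
            raise FixtureError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise FixtureError("baseline_mean > 0 and nb_dispersion >= 0")
        if self.read_length < 1:
            raise FixtureError("read_length must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_rep{i + 1}"
            for cond, n in self.conditions.items()
            for i in range(n)
        ]

    @property
    def sample_conditions(self) -> list[str]:
        return [
            cond for cond, n in self.conditions.items() for _ in range(n)
        ]


@dataclass
class TruthTables:
    """Ground truth the generator guarantees about its outputs."""

    counts: CountMatrix  # genes x samples, true per-gene read counts
    de_labels: np.ndarray  # bool per gene
    true_lfc: np.ndarray  # signed log2FC per gene (0 where not DE)
    genes: list[GeneModel]
    novel_regions: list[GenomicRegion]
    novel_counts: np.ndarray  # novel regions x samples
    library_sizes: dict[str, int]
    contig_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# genome / gene layout
# ---------------------------------------------------------------------------

def _layout_genes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[GenomicRegion], dict[str, int]]:
    """Place disjoint gene models (and novel regions) in fixed slots across
    contigs, so no read can overlap two features."""
    contigs = {f"chr{i + 1}": config.contig_length_bp
               for i in range(config.n_contigs)}
    n_features = config.n_genes + config.n_novel_regions
    min_exon = max(200, 2 * config.read_length)
    slots: list[tuple[str, int, int]] = []
    per_contig = -(-n_features // config.n_contigs)  # ceil
    margin = 500
    for chrom, clen in contigs.items():
        slot_len = (clen - 2 * margin) // per_contig
        if slot_len < min_exon + 200:
            raise FixtureError(
                "contigs too short for the requested number of features"
            )
        for i in range(per_contig):
            slots.append((chrom, margin + i * slot_len,
                          margin + i * slot_len + slot_len))
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom, lo, hi = slots[g]
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(config.exons_per_gene[0],
                             config.exons_per_gene[1] + 1))
        exons: list[GenomicRegion] = []
        pos = lo
        budget = hi - lo - 100
        for e in range(k):
            remaining_min = (k - e - 1) * (min_exon + 100)
            max_len = min(min_exon + 200, budget - (pos - lo) - remaining_min)
            exon_len = int(rng.integers(min_exon, max(min_exon + 1, max_len)))
            exons.append(GenomicRegion(chrom, pos, pos + exon_len, strand))
            pos += exon_len + int(rng.integers(100, 300))
            if pos >= hi - 100:
                break
        exons = [e for e in exons if e.end <= hi]
        gid = f"g{g + 1:03d}"
        region = GenomicRegion(chrom, exons[0].start, exons[-1].end, strand,
                               name=gid)
        genes.append(GeneModel(gid, f"GENE{g + 1}", region, tuple(exons),
                               biotype="protein_coding"))
    novel: list[GenomicRegion] = []
    for r in range(config.n_novel_regions):
        chrom, lo, hi = slots[config.n_genes + r]
        length = min(1000, hi - lo - 100)
        novel.append(GenomicRegion(chrom, lo, lo + length, ".",
                                   name=f"novel{r + 1}"))
    return genes, novel, contigs


# ---------------------------------------------------------------------------
# simulate_counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: float, phi: float, size: int
) -> np.ndarray:
    if phi <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTables]:
    """Draw the true count matrix: per gene g and condition c, counts are
    NB(mean = baseline * 2^(lfc_g * [c is not the first condition]),
    dispersion phi). Bit-for-bit reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    genes, novel, contigs = _layout_genes(config, rng)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    de_labels = np.zeros(config.n_genes, dtype=bool)
    de_labels[de_idx] = True
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    true_lfc = np.where(de_labels, signs * config.de_log2fc, 0.0)

    reference = next(iter(config.conditions))
    cols: list[np.ndarray] = []
    for cond, n_rep in config.conditions.items():
        treated = cond != reference
        mu = config.baseline_mean * np.power(
            2.0, true_lfc * (1.0 if treated else 0.0)
        )
        block = np.column_stack(
            [
                _nb_draw(rng, mu[g], config.nb_dispersion, n_rep)
                for g in range(config.n_genes)
            ]
        ).T  # genes x replicates
        cols.append(block)
    counts = np.hstack(cols)

    novel_counts = np.column_stack(
        [
            _nb_draw(rng, config.novel_mean, config.nb_dispersion,
                     len(config.sample_ids))
            for _ in range(config.n_novel_regions)
        ]
    ).T if config.n_novel_regions else np.zeros((0, len(config.sample_ids)),
                                                dtype=int)

    cm = CountMatrix(
        feature_ids=[g.gene_id for g in genes],
        sample_ids=config.sample_ids,
        counts=counts,
        lengths=np.array([exon_union(g)[1] for g in genes]),
        conditions=config.sample_conditions,
    )
    lib = {
        sid: int(counts[:, j].sum() + novel_counts[:, j].sum())
        for j, sid in enumerate(config.sample_ids)
    }
    truth = TruthTables(
        counts=cm,
        de_labels=de_labels,
        true_lfc=true_lfc,
        genes=genes,
        novel_regions=novel,
        novel_counts=novel_counts,
        library_sizes=lib,
        contig_lengths=contigs,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _place_reads(
    rng: np.random.Generator,
    intervals: list[GenomicRegion],
    count: int,
    read_length: int,
) -> np.ndarray:
    """Uniform read starts over an exon union, each read fully inside one
    interval."""
    capacity = np.array(
        [max(0, len(iv) - read_length + 1) for iv in intervals], dtype=float
    )
    if capacity.sum() <= 0:
        raise FixtureError("feature shorter than the read length")
    probs = capacity / capacity.sum()
    which = rng.choice(len(intervals), size=count, p=probs)
    offsets = rng.integers(0, capacity[which].astype(int))
    starts = np.array([intervals[i].start for i in which]) + offsets
    return np.sort(starts.astype(int))


def _write_gtf(path: Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            r = gene.region
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}"; '
                f'gene_biotype "{gene.biotype or "protein_coding"}";'
            )
            fh.write(
                f"{r.chrom}\tseqlens\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
            for ex in gene.exons:
                fh.write(
                    f"{ex.chrom}\tseqlens\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs} transcript_id "
                    f'"{gene.gene_id}.t1";\n'
                )


def _write_bam(
    path: Path,
    reads: list[tuple[str, int, str]],
    contigs: dict[str, int],
    read_length: int,
) -> None:
    """Write sorted+indexed single-end BAM; reads are (chrom, start, name)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": L} for c, L in contigs.items()],
    }
    order = {c: i for i, c in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for chrom, start, name in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.reference_id = order[chrom]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, read_length)]
            a.query_sequence = "A" * read_length
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))


def _write_bigwig(
    path: Path,
    depth_by_contig: dict[str, np.ndarray],
    contigs: dict[str, int],
    library_size: int,
) -> None:
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(contigs.items()))
    scale = 1e6 / library_size
    for chrom in contigs:
        vals = depth_by_contig[chrom] * scale
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(vals)]])
        keep = vals[starts] != 0
        if not np.any(keep):
            continue
        bw.addEntries(
            [chrom] * int(keep.sum()),
            [int(s) for s in starts[keep]],
            ends=[int(e) for e in ends[keep]],
            values=[float(v) for v in vals[starts[keep]]],
        )
    bw.close()


def make_toy_dataset(
    config: SimConfig | None = None, out_dir: str | Path = "toy"
) -> tuple[Path, TruthTables]:
    """Emit the complete toy dataset under ``out_dir``.

    Writes ``chrom.sizes``, ``genes.gtf``, per-sample ``<sample>.bam``
    (+ ``.bai``) and ``<sample>.bw``, ``manifest.yaml``, and truth TSVs
    (``truth_counts.tsv``, ``truth_de.tsv``, ``truth_novel_counts.tsv``).
    Counting the emitted BAMs reproduces the truth count matrix exactly.
    """
    config = config or SimConfig()
    _, truth = simulate_counts(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the placement stream is separate from the count stream, but derived
    # from the same seed so the whole dataset is one deterministic draw
    rng = np.random.default_rng(config.seed + 1_000_003)

    contigs = truth.contig_lengths
    with open(out / "chrom.sizes", "w") as fh:
        for c, L in contigs.items():
            fh.write(f"{c}\t{L}\n")
    _write_gtf(out / "genes.gtf", truth.genes)

    unions = {g.gene_id: exon_union(g)[0] for g in truth.genes}
    sample_entries = []
    for j, sid in enumerate(config.sample_ids):
        reads: list[tuple[str, int, str]] = []
        depth = {c: np.zeros(L) for c, L in contigs.items()}
        serial = 0
        for i, gene in enumerate(truth.genes):
            c = int(truth.counts.counts[i, j])
            if c == 0:
                continue
            starts = _place_reads(rng, unions[gene.gene_id], c,
                                  config.read_length)
            for s in starts:
                reads.append((gene.region.chrom, int(s), f"{sid}.{serial}"))
                serial += 1
                depth[gene.region.chrom][s:s + config.read_length] += 1
        for r, region in enumerate(truth.novel_regions):
            c = int(truth.novel_counts[r, j])
            if c == 0:
                continue
            starts = _place_reads(rng, [region], c, config.read_length)
            for s in starts:
                reads.append((region.chrom, int(s), f"{sid}.{serial}"))
                serial += 1
                depth[region.chrom][s:s + config.read_length] += 1
        libsize = len(reads)
        assert libsize == truth.library_sizes[sid]
        _write_bam(out / f"{sid}.bam", reads, contigs, config.read_length)
        _write_bigwig(out / f"{sid}.bw", depth, contigs, libsize)
        sample_entries.append(
            {
                "sample_id": sid,
                "condition": config.sample_conditions[j],
                "bam_path": f"{sid}.bam",
                "bigwig_path": f"{sid}.bw",
                "library_size": libsize,
            }
        )

    manifest = {
        "dataset_id": "toy",
        "genome_id": "toygenome",
        "annotation_path": "genes.gtf",
        "chrom_sizes_path": "chrom.sizes",
        "samples": sample_entries,
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))

    truth.counts.to_dataframe().rename_axis("gene_id").to_csv(
        out / "truth_counts.tsv", sep="\t"
    )
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in truth.genes],
            "is_de": truth.de_labels,
            "true_log2fc": truth.true_lfc,
        }
    ).to_csv(out / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.novel_counts,
        index=[r.name for r in truth.novel_regions],
        columns=config.sample_ids,
    ).rename_axis("region").to_csv(out / "truth_novel_counts.tsv", sep="\t")
    logger.info("toy dataset written to %s (%d samples, %d genes)",
                out, len(config.sample_ids), config.n_genes)
    return manifest_path, truth


# ---------------------------------------------------------------------------
# special-purpose fixtures
# ---------------------------------------------------------------------------

def make_spliced_fixture(out_dir: str | Path) -> Path:
    """A tiny BAM exercising CIGAR depth rules: spliced (N), deletion (D),
    insertion (I) and soft-clipped (S) alignments on one 1 kb contig.

    Reads (all on chr1): 20M100N20M at 100; 10M5D10M at 300; 10M5I10M at
    400; 5S20M at 500.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "spliced.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 1000}]}
    specs = [
        ("spliced", 100, [(0, 20), (3, 100), (0, 20)]),
        ("deletion", 300, [(0, 10), (2, 5), (0, 10)]),
        ("insertion", 400, [(0, 10), (1, 5), (0, 10)]),
        ("softclip", 500, [(4, 5), (0, 20)]),
    ]
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, start, cig in specs:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cig
            qlen = sum(L for op, L in cig if op in (0, 1, 4))
            a.query_sequence = "A" * qlen
            bam.write(a)
    pysam.index(str(path))
    return path


def make_paired_fixture(out_dir: str | Path) -> Path:
    """A hand-built paired-end BAM (5 fragments / 10 reads) on one 1 kb
    contig, for fragment-counting semantics. Each fragment f_i has read1 at
    100*i and read2 at 100*i + 60, both 40M."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "paired.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 1000}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i in range(1, 6):
            for mate in (1, 2):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"frag{i}"
                a.reference_id = 0
                a.reference_start = 100 * i + (0 if mate == 1 else 60)
                a.mapping_quality = 60
                a.cigartuples = [(0, 40)]
                a.query_sequence = "A" * 40
                a.flag = (
                    0x1 | 0x2
                    | (0x40 if mate == 1 else 0x80)
                    | (0x20 if mate == 1 else 0x10)
                )
                a.next_reference_id = 0
                a.next_reference_start = 100 * i + (60 if mate == 1 else 0)
                bam.write(a)
    pysam.index(str(path))
    return path
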
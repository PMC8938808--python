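import numpy as np
import pysam
import pytest

from seqlens import create_instance, import_annotation, load_manifest
from seqlens.fixtures import SimConfig, make_toy_dataset


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """The default toy dataset, generated once per session."""
    out = tmp_path_factory.mktemp("toy")
    manifest_path, truth = make_toy_dataset(SimConfig(seed=42), out)
    return {"dir": out, "manifest_path": manifest_path, "truth": truth}


@pytest.fixture(scope="session")
def toy_manifest(toy):
    return load_manifest(toy["manifest_path"])


@pytest.fixture(scope="session")
def toy_instance(toy, toy_manifest):
    return create_instance(toy_manifest, manifest_path=toy["manifest_path"])


@pytest.fixture(scope="session")
def toy_store(toy, toy_manifest):
    return import_annotation(toy_manifest.annotation_path,
                             toy["truth"].contig_lengths)


@pytest.fixture(scope="session")
def toy_genes(toy, toy_store):
    """Gene models in generator order."""
    return [toy_store.by_id(g.gene_id) for g in toy["truth"].genes]


def write_bam(path, reads, contigs, paired=False):
    """Hand-build a small sorted+indexed BAM.

    ``reads`` are dicts with chrom, start, cigar (tuples), and optional
    name, mapq, flag.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": L} for c, L in contigs.items()],
    }
    order = {c: i for i, c in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r["chrom"]], r["start"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.get("name", f"r{i}")
            a.reference_id = order[r["chrom"]]
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigartuples = r["cigar"]
            qlen = sum(L for op, L in r["cigar"] if op in (0, 1, 4))
            a.query_sequence = "A" * qlen
            a.flag = r.get("flag", 0)
            bam.write(a)
    pysam.index(str(path))
    return path


def naive_region_count(bam_path, region, min_mapq=10, min_overlap=1):
    """Independent oracle: scan every read in the file and test overlap of
    its aligned reference bases with the region."""
    from seqlens.signal import aligned_blocks

    n = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_qcfail or read.is_duplicate):
                continue
            if read.mapping_quality < min_mapq:
                continue
            if bam.get_reference_name(read.reference_id) != region.chrom:
                continue
            overlap = sum(
                max(0, min(e, region.end) - max(s, region.start))
                for s, e in aligned_blocks(read)
            )
            if overlap >= min_overlap:
                n += 1
    return n


def naive_depth(bam_path, region):
    """Independent oracle: per-read per-base accumulation of depth."""
    from seqlens.signal import aligned_blocks

    depth = np.zeros(len(region))
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_qcfail or read.is_duplicate):
                continue
            if bam.get_reference_name(read.reference_id) != region.chrom:
                continue
            for s, e in aligned_blocks(read):
                for pos in range(max(s, region.start), min(e, region.end)):
                    depth[pos - region.start] += 1
    return depth
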
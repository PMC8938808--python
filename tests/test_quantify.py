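import numpy as np
import pytest

from seqlens.annotation import GeneModel, GenomicRegion
from seqlens.fixtures import make_paired_fixture
from seqlens.quantify import (
    CountMatrix,
    CountingParams,
    QuantifyError,
    assign_flags,
    count_reads,
    gene_counts,
    quantify_regions,
    size_factors,
    transform_counts,
)

from .conftest import naive_region_count, write_bam


def _cm(counts, lengths=None, samples=None, conditions=None):
    counts = np.atleast_2d(np.asarray(counts))
    nf, ns = counts.shape
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(nf)],
        sample_ids=samples or [f"s{j}" for j in range(ns)],
        counts=counts,
        lengths=np.asarray(lengths) if lengths is not None
        else np.full(nf, 1000),
        conditions=conditions,
    )


class TestCountReads:
    @pytest.fixture()
    def bam(self, tmp_path):
        reads = [
            {"chrom": "chr1", "start": s, "cigar": [(0, 50)]}
            for s in (100, 120, 140, 160, 180)
        ]
        # one read abutting the region end [100, 230): starts exactly at 230
        reads.append({"chrom": "chr1", "start": 230, "cigar": [(0, 50)]})
        # low-quality read inside
        reads.append({"chrom": "chr1", "start": 110, "cigar": [(0, 50)],
                      "mapq": 3, "name": "lowq"})
        # duplicate inside
        reads.append({"chrom": "chr1", "start": 115, "cigar": [(0, 50)],
                      "flag": 0x400, "name": "dup"})
        return write_bam(tmp_path / "c.bam", reads, {"chr1": 1000})

    def test_reads_fully_inside_region(self, bam):
        (n,) = count_reads(bam, [GenomicRegion("chr1", 100, 230)])
        assert n == 5  # mapq/duplicate filtered, abutting read excluded

    def test_abutting_read_not_counted(self, bam):
        (n,) = count_reads(bam, [GenomicRegion("chr1", 95, 100)])
        assert n == 0

    def test_include_duplicates_and_low_mapq(self, bam):
        params = CountingParams(min_mapq=0, include_duplicates=True)
        (n,) = count_reads(bam, [GenomicRegion("chr1", 100, 230)], params)
        assert n == 7

    def test_min_overlap_threshold(self, bam):
        # read at 100 covers [100,150): overlap with [140,300) is 10 bp
        region = GenomicRegion("chr1", 140, 300)
        n10 = count_reads(bam, [region], CountingParams(min_overlap_bp=10))[0]
        n11 = count_reads(bam, [region], CountingParams(min_overlap_bp=11))[0]
        assert n10 - n11 == 1

    def test_empty_region_list(self, bam):
        assert count_reads(bam, []).size == 0

    def test_absent_contig_counts_zero(self, bam):
        (n,) = count_reads(bam, [GenomicRegion("chrX", 0, 100)])
        assert n == 0

    def test_unindexed_bam_instructs_to_index(self, tmp_path, bam):
        import shutil

        raw = tmp_path / "noindex.bam"
        shutil.copy(bam, raw)
        with pytest.raises(QuantifyError, match="index"):
            count_reads(raw, [GenomicRegion("chr1", 0, 10)])

    def test_fragment_counting_on_paired_fixture(self, tmp_path):
        bam = make_paired_fixture(tmp_path)
        region = GenomicRegion("chr1", 0, 1000)
        per_read = count_reads(bam, [region],
                               CountingParams(count_fragments=False))[0]
        per_frag = count_reads(bam, [region],
                               CountingParams(count_fragments=True))[0]
        assert (per_read, per_frag) == (10, 5)

    def test_matches_naive_scan_on_random_regions(self, toy):
        rng = np.random.default_rng(3)
        sid = list(toy["truth"].library_sizes)[1]
        bam = toy["dir"] / f"{sid}.bam"
        regions = []
        for _ in range(30):
            chrom = rng.choice(list(toy["truth"].contig_lengths))
            L = toy["truth"].contig_lengths[chrom]
            start = int(rng.integers(0, L - 2000))
            length = int(rng.integers(50, 2000))
            regions.append(GenomicRegion(chrom, start, start + length))
        ours = count_reads(bam, regions)
        naive = [naive_region_count(bam, r) for r in regions]
        assert np.array_equal(ours, naive)


class TestGeneCounts:
    def test_exonic_counted_intronic_not(self, tmp_path):
        exons = (GenomicRegion("chr1", 100, 200, "+"),
                 GenomicRegion("chr1", 400, 500, "+"))
        gene = GeneModel("g1", "G1",
                         GenomicRegion("chr1", 100, 500, "+"), exons)
        reads = [
            {"chrom": "chr1", "start": s, "cigar": [(0, 50)]}
            for s in (100, 120, 150, 400, 410, 420, 440)  # 7 exonic
        ] + [
            {"chrom": "chr1", "start": s, "cigar": [(0, 50)]}
            for s in (250, 270, 300)  # 3 fully intronic
        ]
        bam = write_bam(tmp_path / "g.bam", reads, {"chr1": 1000})
        counts, lengths = gene_counts(bam, [gene])
        assert counts[0] == 7
        assert lengths[0] == 200

    def test_exon_spanning_read_counted_once(self, tmp_path):
        exons = (GenomicRegion("chr1", 100, 200, "+"),
                 GenomicRegion("chr1", 300, 400, "+"))
        gene = GeneModel("g1", "G1",
                         GenomicRegion("chr1", 100, 400, "+"), exons)
        # spliced read touching both exons
        reads = [{"chrom": "chr1", "start": 180,
                  "cigar": [(0, 20), (3, 100), (0, 20)]}]
        bam = write_bam(tmp_path / "s.bam", reads, {"chr1": 1000})
        counts, _ = gene_counts(bam, [gene])
        assert counts[0] == 1

    def test_shared_exon_read_counted_for_both_genes(self, tmp_path):
        shared = GenomicRegion("chr1", 100, 200, "+")
        g1 = GeneModel("g1", "A", GenomicRegion("chr1", 100, 200, "+"),
                       (shared,))
        g2 = GeneModel("g2", "B", GenomicRegion("chr1", 100, 300, "+"),
                       (shared, GenomicRegion("chr1", 250, 300, "+")))
        bam = write_bam(
            tmp_path / "sh.bam",
            [{"chrom": "chr1", "start": 120, "cigar": [(0, 50)]}],
            {"chr1": 1000},
        )
        counts, _ = gene_counts(bam, [g1, g2])
        assert counts.tolist() == [1, 1]

    def test_zero_overlap_gene(self, tmp_path):
        gene = GeneModel("g1", "G1", GenomicRegion("chr1", 800, 900, "+"),
                         (GenomicRegion("chr1", 800, 900, "+"),))
        bam = write_bam(
            tmp_path / "z.bam",
            [{"chrom": "chr1", "start": 0, "cigar": [(0, 50)]}],
            {"chr1": 1000},
        )
        counts, _ = gene_counts(bam, [gene])
        assert counts[0] == 0

    def test_master_identity_on_toy(self, toy, toy_instance, toy_genes):
        """Counting the generator's BAMs recovers its truth matrix exactly."""
        from seqlens.quantify import build_count_matrix

        cm = build_count_matrix(toy_instance, toy_genes)
        assert np.array_equal(cm.counts, toy["truth"].counts.counts)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        assert np.allclose(size_factors(_cm([[5, 5], [9, 9]])), 1.0)

    def test_two_gene_worked_example(self):
        f = size_factors(_cm([[2, 4], [2, 4]]))
        assert np.allclose(f, [np.sqrt(0.5), np.sqrt(2.0)], atol=1e-9)

    def test_zero_geomean_feature_excluded(self):
        f = size_factors(_cm([[0, 4], [2, 2]]))
        assert np.allclose(f, [1.0, 1.0])

    def test_no_positive_feature_rejected(self):
        with pytest.raises(QuantifyError, match="features"):
            size_factors(_cm([[0, 4], [2, 0]]))

    def test_scaled_sample_recovers_scale(self):
        rng = np.random.default_rng(4)
        base = rng.integers(1, 500, size=(50, 1))
        c = 3.0
        f = size_factors(np.hstack([base, (base * c).astype(int)]).astype(float))
        assert np.isclose(f[1] / f[0], c)


class TestTransform:
    def test_rpkm_formula(self):
        t = transform_counts(
            _cm([[10]], lengths=[1000]), "rpkm", library_sizes=[1_000_000]
        )
        assert np.isclose(t.values[0, 0], 10.0, atol=1e-9)

    def test_log2_pseudocount_of_zero(self):
        t = transform_counts(_cm([[0]]), "log2raw")
        assert t.values[0, 0] == 0.0

    def test_normalized_division(self):
        t = transform_counts(_cm([[8]]), "normalized", factors=[2.0])
        assert t.values[0, 0] == 4.0

    def test_raw_identity(self):
        cm = _cm([[3, 7], [0, 2]])
        t = transform_counts(cm, "raw")
        assert np.array_equal(t.values, cm.counts)

    def test_missing_requirements_rejected(self):
        with pytest.raises(QuantifyError, match="factors"):
            transform_counts(_cm([[1]]), "normalized")
        with pytest.raises(QuantifyError, match="library"):
            transform_counts(_cm([[1]]), "rpkm")


class TestFlags:
    def test_all_zero_gene(self):
        cm = _cm([[0, 0]])
        (flags,) = assign_flags(cm)
        assert flags == {"LOW_COUNT", "ZERO_IN_ALL"}

    def test_short_region(self):
        cm = _cm([[50, 50]], lengths=[150])
        (flags,) = assign_flags(cm)
        assert flags == {"SHORT"}

    def test_max_at_threshold_not_low(self):
        cm = _cm([[5, 12]])
        (flags,) = assign_flags(cm)
        assert "LOW_COUNT" not in flags

    def test_flags_never_remove_features(self):
        cm = _cm([[0, 0], [100, 100]])
        assign_flags(cm)
        assert len(cm.feature_ids) == 2


class TestQuantifyRegions:
    def test_novel_region_counts_match_truth_and_rpkm_formula(
        self, toy, toy_instance, toy_genes
    ):
        truth = toy["truth"]
        table = quantify_regions(
            toy_instance, toy_genes, truth.novel_regions, scale="raw"
        )
        novel_rows = table.values[len(toy_genes):]
        assert np.array_equal(novel_rows, truth.novel_counts)

        rpkm = quantify_regions(
            toy_instance, toy_genes, truth.novel_regions, scale="rpkm"
        )
        lib = np.array([
            truth.library_sizes[s] for s in rpkm.sample_ids
        ])
        i = len(toy_genes)  # first novel region
        L = len(truth.novel_regions[0])
        expected = truth.novel_counts[0] / (L / 1e3 * lib / 1e6)
        assert np.allclose(rpkm.values[i], expected, atol=1e-9)

    def test_raw_scale_equals_gene_counts(self, toy, toy_instance, toy_genes):
        table = quantify_regions(toy_instance, toy_genes, scale="raw")
        assert np.array_equal(table.values, toy["truth"].counts.counts)
        assert table.sample_ids == list(toy["truth"].library_sizes)

    def test_region_without_genes_rejected(self, toy_instance):
        with pytest.raises(QuantifyError, match="size factors"):
            quantify_regions(
                toy_instance, [], [GenomicRegion("chr1", 0, 100)]
            )

    def test_instance_without_bam_rejected(self, tmp_path, toy):
        import yaml

        from seqlens.registry import create_instance, load_manifest

        sid = list(toy["truth"].library_sizes)[0]
        manifest = tmp_path / "m.yaml"
        manifest.write_text(yaml.safe_dump({
            "dataset_id": "d", "genome_id": "g",
            "annotation_path": "a.gtf",
            "samples": [{
                "sample_id": sid, "condition": "c",
                "bigwig_path": str(toy["dir"] / f"{sid}.bw"),
            }],
        }))
        inst = create_instance(load_manifest(manifest))
        region = GenomicRegion("chr1", 800, 900, "+")
        gene = GeneModel("g1", "G1", region, (region,))
        with pytest.raises(QuantifyError, match="BAM"):
            quantify_regions(inst, [gene], [GenomicRegion("chr1", 0, 100)])

    def test_doubling_reads_doubles_counts_keeps_rpkm(self, tmp_path):
        """Duplicate every read (counted via include_duplicates): raw counts
        double while RPKM is invariant when the library size doubles too."""
        gene_region = GenomicRegion("chr1", 100, 600, "+")
        gene = GeneModel("g1", "G1", gene_region, (gene_region,))
        reads = [
            {"chrom": "chr1", "start": s, "cigar": [(0, 50)], "name": f"r{s}"}
            for s in range(100, 500, 40)
        ]
        dups = [dict(r, flag=0x400, name=r["name"] + "d") for r in reads]
        single = write_bam(tmp_path / "one.bam", reads, {"chr1": 1000})
        doubled = write_bam(tmp_path / "two.bam", reads + dups, {"chr1": 1000})
        params = CountingParams(include_duplicates=True)
        c1, L = gene_counts(single, [gene], params)
        c2, _ = gene_counts(doubled, [gene], params)
        assert c2[0] == 2 * c1[0]
        lib1 = len(reads)
        cm1 = _cm([[c1[0]]], lengths=[L[0]])
        cm2 = _cm([[c2[0]]], lengths=[L[0]])
        r1 = transform_counts(cm1, "rpkm", library_sizes=[lib1])
        r2 = transform_counts(cm2, "rpkm", library_sizes=[2 * lib1])
        assert np.allclose(r1.values, r2.values, atol=1e-12)
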
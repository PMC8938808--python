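import numpy as np
import pytest
from scipy import stats

from seqlens.dgea import (
    ContrastSpec,
    DgeaError,
    adjust_fdr,
    combine_pvalues,
    dgea_from_counts,
    estimate_dispersion,
    filter_results,
    run_dgea,
)
from seqlens.dgea import test_nb as nb_wald_test
from seqlens.dgea import test_welch as welch_log_test
from seqlens.fixtures import SimConfig, simulate_counts
from seqlens.quantify import size_factors

CONTRAST = ContrastSpec("control", "treated")
GROUPS_3V3 = np.array(["control"] * 3 + ["treated"] * 3)


def _sim(n_genes=2000, de_fraction=0.0, seed=1, **kw):
    cfg = SimConfig(
        n_genes=n_genes, n_contigs=8, contig_length_bp=400_000,
        de_fraction=de_fraction, nb_dispersion=0.1, seed=seed,
        n_novel_regions=0, **kw,
    )
    return simulate_counts(cfg)


class TestDispersion:
    def test_constant_counts_zero(self):
        counts = np.tile([[10.0], [20.0]], (1, 6))
        assert estimate_dispersion(counts, GROUPS_3V3) == 0.0

    def test_moment_formula_per_gene(self):
        """A gene with within-group mean 10 and variance 30 has a raw
        method-of-moments dispersion (30 - 10) / 10**2 = 0.2."""
        # groups (7, 10, 13) v (7, 10, 13): mean 10, var 9 per group -> 0 floor?
        # build var 30: (4, 10, 16) has var 36; use values with var 30
        g = np.array([[10 - np.sqrt(30), 10, 10 + np.sqrt(30)]])
        assert np.isclose(g.var(ddof=1), 30.0)
        counts = np.hstack([g, g])
        phi_g = (30.0 - 10.0) / 10.0**2
        assert np.isclose(phi_g, 0.2)
        # the common estimate applies a median-bias correction upward
        est = estimate_dispersion(counts, GROUPS_3V3)
        assert est >= phi_g

    def test_recovery_on_simulated_data(self):
        cm, _ = _sim(seed=5)
        f = size_factors(cm.counts.astype(float))
        phi = estimate_dispersion(cm.counts / f, np.asarray(cm.conditions))
        assert 0.05 <= phi <= 0.2

    def test_single_replicate_everywhere_rejected(self):
        with pytest.raises(DgeaError):
            estimate_dispersion(np.array([[1.0, 2.0]]),
                                np.array(["a", "b"]))


class TestNb:
    def test_identical_large_means_p_one(self):
        counts = np.tile([[500.0]], (1, 6))
        p = nb_wald_test(counts, GROUPS_3V3, CONTRAST, phi=0.1)
        assert np.isclose(p[0], 1.0)

    def test_all_zero_gene_p_one(self):
        p = nb_wald_test(np.zeros((1, 6)), GROUPS_3V3, CONTRAST, phi=0.1)
        assert p[0] == 1.0

    def test_contrast_swap_preserves_p(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(100, size=(50, 6)).astype(float)
        p_fwd = nb_wald_test(counts, GROUPS_3V3, CONTRAST, 0.1)
        p_rev = nb_wald_test(counts, GROUPS_3V3,
                        ContrastSpec("treated", "control"), 0.1)
        assert np.allclose(p_fwd, p_rev)

    def test_poisson_limit_matches_phi_zero(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(50, size=(20, 6)).astype(float)
        p0 = nb_wald_test(counts, GROUPS_3V3, CONTRAST, 0.0)
        p_small = nb_wald_test(counts, GROUPS_3V3, CONTRAST, 1e-12)
        assert np.allclose(p0, p_small)

    def test_agrees_with_parametric_bootstrap(self):
        """Wald p-values match a seeded parametric-bootstrap null within the
        combined Monte-Carlo and asymptotic-approximation error (<= 0.03
        absolute at mean ~100, 3v3; measured approximation error ~0.017)."""
        rng = np.random.default_rng(8)
        phi, r, n = 0.1, 10.0, 3
        mu = 100.0

        def zstat(a, b):
            ma, mb = a.mean(-1), b.mean(-1)
            v = ((ma + phi * ma**2) / (n * ma**2)
                 + (mb + phi * mb**2) / (n * mb**2))
            return (np.log(mb) - np.log(ma)) / np.sqrt(v)

        B = 4000
        for _ in range(20):
            a = rng.negative_binomial(r, r / (r + mu), n).astype(float)
            b = rng.negative_binomial(r, r / (r + mu), n).astype(float)
            counts = np.concatenate([a, b])[None, :]
            (p_impl,) = nb_wald_test(counts, GROUPS_3V3, CONTRAST, phi)
            pooled = counts.mean()
            za = rng.negative_binomial(
                r, r / (r + pooled), (B, n)).astype(float)
            zb = rng.negative_binomial(
                r, r / (r + pooled), (B, n)).astype(float)
            z_null = zstat(za, zb)
            z_obs = zstat(a[None, :], b[None, :])[0]
            p_boot = (1 + np.sum(np.abs(z_null) >= abs(z_obs))) / (B + 1)
            assert abs(p_impl - p_boot) <= 0.03


class TestWelch:
    def test_identical_constant_groups(self):
        counts = np.tile([[4.0]], (1, 6))
        assert welch_log_test(counts, GROUPS_3V3, CONTRAST)[0] == 1.0

    def test_identical_varying_groups(self):
        counts = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        assert np.isclose(welch_log_test(counts, GROUPS_3V3, CONTRAST)[0], 1.0)

    def test_matches_textbook_formula(self):
        """Welch t and p for log2 values (1,2,3) v (4,5,6) computed from the
        closed-form statistic and Welch-Satterthwaite df."""
        la = np.array([1.0, 2.0, 3.0])
        lb = np.array([4.0, 5.0, 6.0])
        counts = np.concatenate([2**la - 1, 2**lb - 1])[None, :]
        (p_impl,) = welch_log_test(counts, GROUPS_3V3, CONTRAST, pseudocount=1.0)
        se = np.sqrt(la.var(ddof=1) / 3 + lb.var(ddof=1) / 3)
        t = (lb.mean() - la.mean()) / se
        df = (la.var(ddof=1) / 3 + lb.var(ddof=1) / 3) ** 2 / (
            (la.var(ddof=1) / 3) ** 2 / 2 + (lb.var(ddof=1) / 3) ** 2 / 2
        )
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert np.isclose(p_impl, p_hand, atol=1e-12)

    def test_contrast_swap_preserves_p(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(100, size=(50, 6)).astype(float)
        p_fwd = welch_log_test(counts, GROUPS_3V3, CONTRAST)
        p_rev = welch_log_test(counts, GROUPS_3V3,
                           ContrastSpec("treated", "control"))
        assert np.allclose(p_fwd, p_rev)


class TestCombine:
    def test_fisher_worked_example(self):
        # X = -2(ln 0.5 + ln 0.5) = 2.7726; chi2 sf with 4 df, closed form
        # sf(x) = exp(-x/2) * (1 + x/2)
        x = -2 * (np.log(0.5) + np.log(0.5))
        expected = np.exp(-x / 2) * (1 + x / 2)
        got = combine_pvalues(np.array([[0.5, 0.5]]), "fisher")
        assert np.isclose(got[0], expected, atol=1e-9)
        assert np.isclose(got[0], 0.5966, atol=5e-5)

    def test_all_ones_combine_to_one(self):
        p = np.ones((3, 4))
        for method in ("fisher", "simes", "min", "max"):
            assert np.allclose(combine_pvalues(p, method), 1.0)

    def test_degenerate_weights_pass_through(self):
        p = np.array([[0.013, 0.7], [0.4, 0.2]])
        got = combine_pvalues(p, "weighted", weights=np.array([1.0, 0.0]))
        assert np.allclose(got, p[:, 0])

    def test_simes_worked_example(self):
        got = combine_pvalues(np.array([[0.01, 0.04]]), "simes")
        assert np.isclose(got[0], 0.02, atol=1e-12)

    def test_fisher_single_test_identity(self):
        p = np.array([[0.37], [0.008]])
        assert np.allclose(combine_pvalues(p, "fisher"), p.ravel(),
                           atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_pvalues(np.array([[0.5, 1.5]]), "fisher")
        with pytest.raises(ValueError):
            combine_pvalues(np.array([[0.5, 0.5]]), "weighted")
        with pytest.raises(ValueError):
            combine_pvalues(np.array([[0.5, 0.5]]), "weighted",
                            weights=np.array([0.9, 0.5]))


class TestBH:
    def test_single_p_unchanged(self):
        assert np.allclose(adjust_fdr(np.array([0.05])), [0.05])

    def test_step_up_by_hand_three(self):
        q = adjust_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-9)

    def test_step_up_by_hand_four(self):
        q = adjust_fdr(np.array([0.005, 0.01, 0.03, 0.04]))
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04], atol=1e-9)

    def test_monotone_in_p_and_permutation_invariant(self):
        rng = np.random.default_rng(10)
        p = rng.random(100)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = rng.permutation(100)
        assert np.allclose(adjust_fdr(p[perm]), q[perm])


class TestPipeline:
    def test_equal_means_give_zero_lfc(self):
        counts = np.tile([[40.0], [80.0]], (1, 6))
        from .test_quantify import _cm

        cm = _cm(counts, conditions=list(GROUPS_3V3))
        table = dgea_from_counts(cm, CONTRAST)
        assert np.allclose(table.df["log2fc"], 0.0)

    def test_single_replicate_condition_named_in_error(self, toy_manifest):
        from seqlens.registry import create_instance

        inst = create_instance(toy_manifest, {
            "control": ["control_rep1", "control_rep2"],
            "treated": ["treated_rep1"],
        })
        from seqlens.quantify import CountMatrix

        cm = CountMatrix(
            feature_ids=["g"], sample_ids=[s.sample_id for s in
                                           inst.all_samples()],
            counts=np.array([[5, 6, 7]]), lengths=np.array([100]),
            conditions=[s.condition for s in inst.all_samples()],
        )
        with pytest.raises(DgeaError, match="treated"):
            dgea_from_counts(cm, CONTRAST)

    def test_single_test_bypasses_combination(self):
        cm, _ = _sim(n_genes=100, seed=2)
        table = dgea_from_counts(cm, CONTRAST, tests=("welch",))
        assert table.combination is None
        assert np.allclose(table.df["p_combined"], table.df["p_welch"])

    def test_de_genes_rank_first(self):
        cm, truth = _sim(n_genes=300, de_fraction=0.1, seed=3)
        table = dgea_from_counts(cm, CONTRAST)
        top = np.argsort(table.df["p_combined"].values)[:10]
        assert truth.de_labels[top].all()
        # signed effect recovered
        est = table.df["log2fc"].values[truth.de_labels]
        assert np.all(np.sign(est) == np.sign(
            truth.true_lfc[truth.de_labels]))

    def test_run_dgea_from_instance_matches_counts_path(
        self, toy, toy_instance, toy_genes
    ):
        table = run_dgea(toy_instance, toy_genes, CONTRAST)
        direct = dgea_from_counts(toy["truth"].counts, CONTRAST)
        assert np.allclose(table.df["p_combined"], direct.df["p_combined"])

    def test_ma_data_columns(self):
        cm, _ = _sim(n_genes=50, seed=4)
        ma = dgea_from_counts(cm, CONTRAST).ma_data()
        assert list(ma.columns) == ["A", "M", "passes_filter"]


class TestFilter:
    @pytest.fixture()
    def table(self):
        cm, _ = _sim(n_genes=200, de_fraction=0.1, seed=12)
        return dgea_from_counts(cm, CONTRAST)

    def test_no_criteria_all_pass(self, table):
        assert filter_results(table).df["passes_filter"].all()

    def test_max_q_predicate(self, table):
        out = filter_results(table, max_q=0.05).df
        assert (out["passes_filter"] == (out["q_value"] <= 0.05)).all()

    def test_exclude_flags_overrides_q(self, table):
        table.df.iloc[0, table.df.columns.get_loc("flags")] = {"LOW_COUNT"}
        out = filter_results(table, exclude_flags={"LOW_COUNT"}).df
        assert not out["passes_filter"].iloc[0]

    def test_rows_never_deleted(self, table):
        out = filter_results(table, max_q=1e-30)
        assert len(out.df) == len(table.df)
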
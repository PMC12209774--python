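import numpy as np
import pytest
from scipy.stats import chisquare

from hijackscan import (
    NullScoreSet,
    ScanConfig,
    SimulationSpec,
    bh_correct,
    build_context,
    build_null,
    empirical_pvalues,
    simulate_cohort,
)


def bh_oracle(p):
    """Direct min-over-suffix implementation of step-up BH."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


@pytest.fixture(scope="module")
def ctx():
    bundle, _ = simulate_cohort(SimulationSpec(n_samples=20, n_genes=30,
                                               n_hijack_events=1,
                                               n_amplification_decoys=1,
                                               n_breakpoint_decoys=3, rng_seed=5))
    return build_context(bundle)


class TestBuildNull:
    def test_length_contract(self, ctx):
        cfg = ScanConfig(niter=2)
        null = build_null(ctx, cfg, master_seed=1)
        assert len(null.scores) == 2 * null.n_genes
        assert null.n_genes > 0

    def test_deterministic_given_seed(self, ctx):
        cfg = ScanConfig(niter=3)
        a = build_null(ctx, cfg, master_seed=11)
        b = build_null(ctx, cfg, master_seed=11)
        np.testing.assert_array_equal(a.scores, b.scores)
        c = build_null(ctx, cfg, master_seed=12)
        assert not np.array_equal(a.scores, c.scores)

    def test_pseudo_candidate_count_uniform_on_1_2_3(self, ctx):
        """k is drawn uniformly from {1,2,3}: chi-square on ~10,000 draws."""
        niter = int(np.ceil(10_000 / len(ctx.genes)))
        null = build_null(ctx, ScanConfig(niter=niter), master_seed=2)
        counts = np.bincount(null.k_values, minlength=4)[1:4]
        assert counts.sum() >= 10_000
        assert chisquare(counts).pvalue > 1e-3

    def test_null_scores_match_naive_rescoring(self, ctx):
        """Spot-check the incremental mu/sigma update against direct scoring."""
        cfg = ScanConfig(niter=1)
        null = build_null(ctx, cfg, master_seed=4)
        from hijackscan.fdr import null_eligible_gene_rows
        rows = null_eligible_gene_rows(ctx, cfg)
        rng = np.random.default_rng([4, 0])
        for pos, row in enumerate(rows):
            gid = ctx.genes[row].gene_id
            ref = ctx.ref_idx[gid]
            vals = ctx.logexpr[row, ref]
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(vals), size=k, replace=False)
            rest = np.delete(vals, chosen)
            mu, sigma = rest.mean(), rest.std()
            total = 0.0
            for c in chosen:
                t = (vals[c] - mu) / (sigma + cfg.sigma_floor)
                s_ovx = np.log(t - 1) if t > 2 else -2 * np.log(3 - t)
                s_ase = ctx.ase.get((gid, ctx.samples[ref[c]]), (0.0, 0))[0]
                dele = ctx.deleted[row, ref[c]]
                total += (cfg.w_overexpression * s_ovx + cfg.w_ase * s_ase
                          - cfg.w_deletion * dele)
            assert null.scores[pos] == pytest.approx(5 * total / (k + 4), rel=1e-9)


class TestEmpiricalPvalues:
    def null(self, scores):
        return NullScoreSet(np.array(scores, dtype=float), niter=1, master_seed=0,
                            n_genes=len(scores))

    def test_above_all_nulls(self):
        p = empirical_pvalues([100.0], self.null(np.arange(99)))
        assert p[0] == pytest.approx(1 / 100)

    def test_below_all_nulls(self):
        p = empirical_pvalues([-100.0], self.null(np.arange(99)))
        assert p[0] == 1.0

    def test_tie_counted_into_numerator(self):
        scores = np.arange(99, dtype=float)  # contains exactly one 98
        p = empirical_pvalues([98.0], self.null(scores))
        assert p[0] == pytest.approx(2 / 100)

    def test_in_unit_interval_and_antimonotone(self):
        rng = np.random.default_rng(0)
        null = self.null(rng.normal(size=500))
        obs = np.sort(rng.normal(size=50))
        p = empirical_pvalues(obs, null)
        assert np.all((p > 0) & (p <= 1))
        assert np.all(np.diff(p) <= 0)  # higher score, smaller p


class TestBhCorrect:
    def test_textbook_case(self):
        np.testing.assert_allclose(bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_min_over_suffix_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = int(rng.integers(1, 201))
            p = rng.uniform(1e-12, 1.0, size=m)
            np.testing.assert_allclose(bh_correct(p), bh_oracle(p), rtol=0, atol=0)

    def test_agrees_with_scipy(self):
        from scipy.stats import false_discovery_control
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-9, 1, size=200)
        np.testing.assert_allclose(bh_correct(p),
                                   np.minimum(false_discovery_control(p), 1.0),
                                   rtol=1e-12)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.001, 1, size=50)
        perm = rng.permutation(50)
        q = bh_correct(p)
        q_perm = bh_correct(p[perm])
        np.testing.assert_allclose(q[perm], q_perm)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_correct([0.0, 0.5])
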
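import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hijackscan import (
    AllelicSnpCount,
    Breakend,
    GeneAnnotation,
    GenomicInterval,
    ReferenceDistribution,
    ScanConfig,
    ScoredEnhancer,
    aggregate_scores,
    ase_score,
    build_neighborhood,
    combine_sample_score,
    deletion_indicator,
    enhancer_score,
    hijacked_enhancers,
    overexpression_score,
    reference_distribution,
    snp_llr,
)


def bb_logpmf_oracle(k, n, mean, conc):
    """Independent beta-binomial log-pmf via log-gamma arithmetic."""
    a, b = mean * conc, (1.0 - mean) * conc
    lg = math.lgamma
    return (lg(n + 1) - lg(k + 1) - lg(n - k + 1)
            + lg(k + a) + lg(n - k + b) - lg(n + a + b)
            + lg(a + b) - lg(a) - lg(b))


def llr_oracle(ref, alt, cfg: ScanConfig):
    n = ref + alt
    lo, hi = cfg.mono_means
    l_mono = np.logaddexp(bb_logpmf_oracle(ref, n, hi, cfg.bb_concentration),
                          bb_logpmf_oracle(ref, n, lo, cfg.bb_concentration)) - math.log(2)
    l_bi = bb_logpmf_oracle(ref, n, cfg.bi_mean, cfg.bb_concentration)
    return float(np.clip(l_mono - l_bi, -cfg.llr_clamp, cfg.llr_clamp))


class TestOverexpressionScore:
    def ref(self, mu, sigma):
        return ReferenceDistribution("G", mu, sigma, 20)

    def test_continuous_at_t2(self, config):
        # E chosen so that t == 2 exactly: e = mu + 2*(sigma+0.3)
        mu, sigma = 1.0, 0.5
        e = mu + 2 * (sigma + config.sigma_floor)
        s, t = overexpression_score(math.exp(e) - 0.5, self.ref(mu, sigma), config)
        assert t == pytest.approx(2.0)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert math.log(2.0 - 1.0) == -2 * math.log(3.0 - 2.0) == 0.0

    def test_at_reference_mean(self, config):
        mu = 1.0
        s, t = overexpression_score(math.exp(mu) - 0.5, self.ref(mu, 0.4), config)
        assert t == pytest.approx(0.0)
        assert s == pytest.approx(-2 * math.log(3), abs=1e-12)

    def test_all_silent_references(self, config):
        """References all at 0 TPM: mu = ln 0.5, sigma = 0; candidate at 10 TPM."""
        ref = reference_distribution("G", [0.0] * 12)
        assert ref.mu == pytest.approx(math.log(0.5))
        assert ref.sigma == 0.0
        s, t = overexpression_score(10.0, ref, config)
        t_expected = (math.log(10.5) - math.log(0.5)) / 0.3
        assert t == pytest.approx(t_expected)
        assert s == pytest.approx(math.log(t_expected - 1))

    def test_strictly_increasing_in_expression(self, config):
        ref = self.ref(0.5, 0.6)
        tpms = np.linspace(0, 50, 200)
        scores = [overexpression_score(e, ref, config)[0] for e in tpms]
        assert np.all(np.diff(scores) > 0)


class TestSnpLlr:
    def test_symmetry_grid(self, config):
        for a in range(0, 31, 5):
            for b in range(0, 31, 5):
                if a + b == 0:
                    continue
                assert snp_llr(a, b, config) == pytest.approx(snp_llr(b, a, config), abs=1e-12)

    def test_signs(self, config):
        assert snp_llr(20, 0, config) > 0
        assert snp_llr(10, 10, config) < 0

    def test_matches_log_gamma_oracle(self, config):
        for a, b in [(20, 0), (10, 10), (0, 7), (29, 1), (15, 15), (3, 2), (100, 1)]:
            assert snp_llr(a, b, config) == pytest.approx(llr_oracle(a, b, config), abs=1e-9)

    def test_clamped_at_extreme_monoallelic_depth(self, config):
        assert snp_llr(5000, 0, config) == config.llr_clamp
        # balanced counts converge to a finite density ratio (overdispersion
        # caps the biallelic evidence), staying negative but above the clamp
        assert -config.llr_clamp < snp_llr(5000, 5000, config) < 0


class TestAseScore:
    GENE = GeneAnnotation("G", "G", GenomicInterval("1", 0, 1000))

    def snp(self, ref, alt, pos=100):
        return AllelicSnpCount("S", "G", "1", pos, ref, alt)

    def test_no_snps_is_zero(self, config):
        assert ase_score([], 2.0, self.GENE, config) == (0.0, 0)

    def test_sex_chromosome_gated(self, config):
        gx = GeneAnnotation("G", "G", GenomicInterval("X", 0, 1000), is_sex_chrom=True)
        assert ase_score([self.snp(30, 0)], 2.0, gx, config) == (0.0, 0)

    def test_imprinted_gated(self, config):
        gi = GeneAnnotation("G", "G", GenomicInterval("1", 0, 1000), is_imprinted=True)
        assert ase_score([self.snp(30, 0)], 2.0, gi, config) == (0.0, 0)

    @pytest.mark.parametrize("cn,gated", [(1.0, True), (2.0, False), (4.0, False),
                                          (4.5, True), (0.0, True)])
    def test_copy_number_gate(self, config, cn, gated):
        s, n = ase_score([self.snp(30, 0)], cn, self.GENE, config)
        assert (s == 0.0 and n == 0) if gated else (s > 0 and n == 1)

    def test_average_with_plus_two_damping(self, config):
        snps = [self.snp(28, 2, pos=100), self.snp(16, 14, pos=200)]
        s, n = ase_score(snps, 2.0, self.GENE, config)
        expected = (snp_llr(28, 2, config) + snp_llr(16, 14, config)) / 4.0
        assert n == 2
        assert s == pytest.approx(expected)


class TestHijackedEnhancers:
    """Toy locus: gene in TAD [1-2 Mb) on chr1; donor TAD [5-6 Mb) on chr2."""

    GENE = GeneAnnotation("G", "G", GenomicInterval("1", 1_400_000, 1_420_000))
    TADS = [GenomicInterval("1", 1_000_000, 2_000_000),
            GenomicInterval("2", 5_000_000, 6_000_000)]
    ENH_DONOR = ScoredEnhancer(GenomicInterval("2", 5_500_000, 5_510_000), 5.0)
    ENH_BEYOND = ScoredEnhancer(GenomicInterval("2", 6_200_000, 6_210_000), 9.0)
    ENH_SELF = ScoredEnhancer(GenomicInterval("1", 1_800_000, 1_810_000), 7.0)

    def nb(self, config):
        return build_neighborhood(self.GENE, self.TADS, config)

    def junction(self, side_a="left", side_b="right", pos_b=5_200_000):
        return Breakend("S1", "1", 1_450_000, side_a, "2", pos_b, side_b)

    def test_no_breakends_empty(self, config):
        assert hijacked_enhancers(self.GENE, self.nb(config), [],
                                  [self.ENH_DONOR], self.TADS, config) == []

    def test_collects_enhancer_on_retained_flank_up_to_tad_boundary(self, config):
        got = hijacked_enhancers(self.GENE, self.nb(config), [self.junction()],
                                 [self.ENH_DONOR, self.ENH_BEYOND, self.ENH_SELF],
                                 self.TADS, config)
        # donor enhancer in the window [5.2 Mb, 6 Mb); the one past the TAD
        # boundary and the one inside the gene's own TAD are excluded
        assert got == [self.ENH_DONOR]

    def test_gene_must_be_on_retained_side(self, config):
        # right-retained at 1.45 Mb does not carry the gene body (ends at 1.42 Mb)
        got = hijacked_enhancers(self.GENE, self.nb(config),
                                 [self.junction(side_a="right")],
                                 [self.ENH_DONOR], self.TADS, config)
        assert got == []

    def test_wrong_partner_flank_excluded(self, config):
        # left-retained at 5.2 Mb keeps [5.0, 5.2] only: enhancer at 5.5 Mb lost
        got = hijacked_enhancers(self.GENE, self.nb(config),
                                 [self.junction(side_b="left")],
                                 [self.ENH_DONOR], self.TADS, config)
        assert got == []

    def test_unknown_orientation_uses_union(self, config):
        got = hijacked_enhancers(self.GENE, self.nb(config),
                                 [self.junction(side_a=None, side_b=None)],
                                 [self.ENH_DONOR], self.TADS, config)
        assert got == [self.ENH_DONOR]

    def test_intra_tad_junction_cannot_self_hijack(self, config):
        intra = Breakend("S1", "1", 1_450_000, "left", "1", 1_900_000, "right")
        got = hijacked_enhancers(self.GENE, self.nb(config), [intra],
                                 [self.ENH_SELF], self.TADS, config)
        assert got == []

    def test_deduplicated_across_breakends(self, config):
        two = [self.junction(), self.junction(pos_b=5_300_000)]
        got = hijacked_enhancers(self.GENE, self.nb(config), two,
                                 [self.ENH_DONOR], self.TADS, config)
        assert got == [self.ENH_DONOR]


class TestEnhancerScore:
    def test_empty_is_zero(self):
        assert enhancer_score([]) == 0.0

    def test_rank_weighted_sum(self):
        enh = [ScoredEnhancer(GenomicInterval("1", i, i + 1), s)
               for i, s in enumerate([3.0, 2.0, 1.0])]
        assert enhancer_score(enh) == pytest.approx(3 / 1 + 2 / 2 + 1 / 3)

    def test_order_invariant(self):
        a = [ScoredEnhancer(GenomicInterval("1", i, i + 1), s)
             for i, s in enumerate([1.0, 3.0, 2.0])]
        assert enhancer_score(a) == pytest.approx(13 / 3)

    @given(st.lists(st.floats(0, 100), max_size=12), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, scores, extra):
        enh = [ScoredEnhancer(GenomicInterval("1", i, i + 1), s)
               for i, s in enumerate(scores)]
        base = enhancer_score(enh)
        more = enh + [ScoredEnhancer(GenomicInterval("1", 999, 1000), extra)]
        assert enhancer_score(more) >= base
        assert base <= sum(scores) + 1e-9


class TestCombineAndAggregate:
    @pytest.mark.parametrize("cn,expected", [(1.0, 1), (2.0, 0), (1.4, 1), (1.5, 0)])
    def test_deletion_indicator(self, config, cn, expected):
        assert deletion_indicator(cn, config) == expected

    def test_default_weights(self, config):
        ss = combine_sample_score("G", "S", 1.0, 3.0, 1.0, 1, 1.0, [], 0, config)
        assert ss.combined == pytest.approx(7.0)
        ss_del = combine_sample_score("G", "S", 1.0, 3.0, 1.0, 1, 1.0, [], 1, config)
        assert ss_del.combined == pytest.approx(6.0)
        zero = combine_sample_score("G", "S", 0.0, 0.0, 0.0, 0, 0.0, [], 0, config)
        assert zero.combined == 0.0

    def test_aggregate_single_sample_identity(self):
        assert aggregate_scores([7.0]) == pytest.approx(7.0)

    def test_aggregate_two_samples(self):
        assert aggregate_scores([7.0, 3.0]) == pytest.approx(50 / 6)
        assert aggregate_scores([7.0, -7.0]) == 0.0

    def test_aggregate_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_scores([])

    def test_aggregate_increasing_in_any_component(self):
        base = aggregate_scores([1.0, 2.0, 3.0])
        assert aggregate_scores([1.0, 2.5, 3.0]) > base


def test_cn_correction_cancels(config):
    """Doubling a gene's CN and TPM together leaves the score unchanged."""
    ref = ReferenceDistribution("G", 0.8, 0.4, 20)
    from hijackscan import copy_number_correct
    s1, t1 = overexpression_score(copy_number_correct(30.0, 2.0), ref, config)
    s2, t2 = overexpression_score(copy_number_correct(60.0, 4.0), ref, config)
    assert abs(s1 - s2) < 1e-12 and abs(t1 - t2) < 1e-12
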
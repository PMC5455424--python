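"""Score-panel construction: normalization, scoring, shrinkage, moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsmatch.panel import (
    PanelValidationError,
    SnpDefinition,
    build_panel,
    compute_score,
    compute_scores,
    expected_log_score_moments,
    genotype_odds_ratios,
    james_stein_shrink,
    relative_calibration,
)


def hwe_weights(p):
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


class TestGenotypeOddsRatios:
    def test_null_effect_gives_identity(self):
        t = genotype_odds_ratios(1.0, 0.3)
        assert (t.g0, t.g1, t.g2, t.mu) == pytest.approx((1.0, 1.0, 1.0, 1.0), abs=1e-15)

    def test_worked_example(self):
        # mu = 0.7^2 + 2*0.3*0.7*1.2 + 0.09*1.44 = 1.1236
        t = genotype_odds_ratios(1.2, 0.3)
        assert t.mu == pytest.approx(1.1236, abs=1e-12)
        assert (t.g0, t.g1, t.g2) == pytest.approx((0.8900, 1.0680, 1.2816), abs=5e-5)

    def test_rare_allele_limit(self):
        t = genotype_odds_ratios(1.2, 1e-9)
        assert (t.g0, t.g1, t.g2) == pytest.approx((1.0, 1.2, 1.44), rel=1e-6)

    def test_monotone_triples(self):
        up = genotype_odds_ratios(1.3, 0.4)
        assert up.g0 <= up.g1 <= up.g2
        down = genotype_odds_ratios(0.8, 0.4)
        assert down.g0 >= down.g1 >= down.g2

    @pytest.mark.parametrize("r,p", [(0.0, 0.3), (-1.0, 0.3), (1.2, 0.0), (1.2, 1.0)])
    def test_domain_errors_name_the_snp(self, r, p):
        with pytest.raises(PanelValidationError, match="rsX"):
            genotype_odds_ratios(r, p, rsid="rsX")

    @settings(max_examples=200, deadline=None)
    @given(
        r=st.floats(0.2, 5.0),
        p=st.floats(0.001, 0.999),
    )
    def test_mean_unity_invariant(self, r, p):
        t = genotype_odds_ratios(r, p)
        mean = hwe_weights(p) @ t.as_array()
        assert mean == pytest.approx(1.0, abs=1e-12)


class TestBuildPanel:
    def test_single_snp_panel(self):
        panel = build_panel([SnpDefinition("rs1", "A", "C", 1.2, 0.3)])
        assert len(panel) == 1
        assert panel.triples[0].mu == pytest.approx(1.1236)

    def test_empty_panel_rejected(self):
        with pytest.raises(PanelValidationError, match="empty"):
            build_panel([])

    def test_duplicate_rsid_rejected(self):
        d = SnpDefinition("rs1", "A", "C", 1.2, 0.3)
        with pytest.raises(PanelValidationError, match="duplicate"):
            build_panel([d, d])

    def test_ambiguous_strand_warns_but_keeps(self):
        defs = [SnpDefinition("rs1", "A", "T", 1.1, 0.4)]
        with pytest.warns(UserWarning, match="strand-ambiguous"):
            panel = build_panel(defs)
        assert len(panel) == 1
        with pytest.raises(PanelValidationError, match="strict_strand"):
            build_panel(defs, strict_strand=True)

    def test_shrunk_panel_uses_shrunk_effects(self):
        defs = [
            SnpDefinition(f"rs{i}", "A", "C", per_allele_or=r, raf=0.3, se_log_or=0.05)
            for i, r in enumerate([1.05, 1.1, 1.2, 1.3])
        ]
        panel = build_panel(defs, shrink=True)
        assert panel.shrinkage_applied
        assert 0 < panel.shrinkage_fraction < 1
        raw = np.log([d.per_allele_or for d in defs])
        # shrunk effects are strictly between each raw value and the mean
        spread_raw = raw - raw.mean()
        spread_new = panel._log_r - panel._log_r.mean()
        assert np.all(np.abs(spread_new) < np.abs(spread_raw) + 1e-12)
        assert panel._log_r.mean() == pytest.approx(raw.mean())


class TestComputeScore:
    def test_all_missing_scores_population_average(self, small_panel):
        s = compute_score([None, None], small_panel)
        assert s.score == pytest.approx(1.0)
        assert s.n_missing == 2

    def test_product_of_triples(self, small_panel):
        # 1.2816 * (1.1 / 1.1025) = 1.27869...
        s = compute_score([2, 1], small_panel)
        expect = (1.2**2 / 1.1236) * (1.1 / 1.1025)
        assert s.score == pytest.approx(expect, rel=1e-10)
        assert s.score == pytest.approx(1.2787, abs=1e-4)

    def test_null_snp_always_scores_one(self):
        panel = build_panel([SnpDefinition("rs1", "A", "C", 1.0, 0.3)])
        for g in (0, 1, 2):
            assert compute_score([g], panel).score == pytest.approx(1.0)

    def test_invalid_genotype_names_sample_and_snp(self, small_panel):
        with pytest.raises(ValueError, match="rs2"):
            compute_scores(np.array([[0.0, 3.0]]), small_panel, sample_ids=["W1"])

    def test_order_invariance(self, rng):
        defs = [
            SnpDefinition(f"rs{i}", "A", "C", float(r), float(p))
            for i, (r, p) in enumerate(zip(rng.uniform(0.9, 1.4, 12), rng.uniform(0.1, 0.9, 12)))
        ]
        g = rng.integers(0, 3, size=12).astype(float)
        perm = rng.permutation(12)
        s1 = compute_score(g, build_panel(defs))
        s2 = compute_score(g[perm], build_panel([defs[i] for i in perm]))
        assert s1.log_score == pytest.approx(s2.log_score, abs=1e-12)


class TestJamesStein:
    def test_zero_ses_no_shrinkage(self):
        b = [0.1, 0.2, 0.3, 0.4]
        shrunk, frac = james_stein_shrink(b, [0.0] * 4)
        assert shrunk == pytest.approx(b)
        assert frac == 0.0

    def test_zero_spread_full_shrinkage(self):
        with pytest.warns(UserWarning, match="zero between-SNP spread"):
            shrunk, frac = james_stein_shrink([0.2] * 5, [0.05] * 5)
        assert shrunk == pytest.approx([0.2] * 5)
        assert frac == 1.0

    def test_formula_on_k4_example(self):
        b = np.array([0.1, 0.2, 0.3, 0.4])
        s = np.array([0.05] * 4)
        shrunk, frac = james_stein_shrink(b, s)
        # brute-force formula evaluation
        c = max(0.0, 1.0 - (4 - 3) * np.mean(s**2) / np.sum((b - b.mean()) ** 2))
        assert frac == pytest.approx(1.0 - c, abs=1e-15)
        assert shrunk == pytest.approx(b.mean() + c * (b - b.mean()), abs=1e-15)

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            james_stein_shrink([0.1, 0.2, 0.3], [0.05] * 3)


class TestMoments:
    def test_null_panel_degenerate(self):
        panel = build_panel(
            [SnpDefinition(f"rs{i}", "A", "C", 1.0, 0.3) for i in range(3)]
        )
        m = expected_log_score_moments(panel)
        assert m["sd_log_score"] == 0.0
        assert m["or_per_sd"] == 1.0
        assert m["expected_iq_or"] == 1.0

    def test_single_snp_exact_enumeration(self):
        r, p = 1.2, 0.3
        panel = build_panel([SnpDefinition("rs1", "A", "C", r, p)])
        m = expected_log_score_moments(panel)
        t = genotype_odds_ratios(r, p)
        logs = np.log(t.as_array())
        w = hwe_weights(p)
        mean = w @ logs
        var = w @ (logs - mean) ** 2
        assert m["mean_log_score"] == pytest.approx(mean, abs=1e-12)
        assert m["var_log_score"] == pytest.approx(var, abs=1e-12)
        assert m["sd_log_score"] == pytest.approx(0.1182, abs=2e-4)
        assert m["or_per_sd"] == pytest.approx(1.125, abs=5e-4)

    def test_monte_carlo_agrees_with_analytic(self, rng):
        defs = [
            SnpDefinition(f"rs{i}", "A", "C", float(r), float(p))
            for i, (r, p) in enumerate(zip(rng.uniform(1.02, 1.3, 30), rng.uniform(0.1, 0.9, 30)))
        ]
        panel = build_panel(defs)
        m = expected_log_score_moments(panel)
        n = 50_000
        p = np.array([d.raf for d in defs])
        G = rng.binomial(2, p[None, :], size=(n, 30)).astype(float)
        log_s = G @ panel._log_r - panel._log_mu.sum()
        assert log_s.mean() == pytest.approx(m["mean_log_score"], abs=4 * m["sd_log_score"] / np.sqrt(n))
        assert log_s.std() == pytest.approx(m["sd_log_score"], rel=0.02)


def test_relative_calibration_ratio_of_logs():
    assert relative_calibration(1.5, 1.6) == pytest.approx(np.log(1.5) / np.log(1.6))
    assert round(100 * relative_calibration(1.5, 1.6)) == 86
    with pytest.raises(ValueError):
        relative_calibration(0.0, 1.6)
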
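"""Closed-form layer: burst statistics, production moments, steady states."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from burstlangevin import (
    GeneParams,
    MomentFlavor,
    Regime,
    burst_size_mrna_legacy,
    burst_statistics,
    classify_regime,
    compose_burst_variance,
    negative_production_fraction,
    production_moments,
    sd_error_percent,
    steady_state_moments,
    variance_error_map,
)


class TestBurstStatistics:
    def test_reference_gene_burst_sizes(self, fig1_params):
        st = burst_statistics(fig1_params)
        assert st.b_m_bar == pytest.approx(2.0)
        assert st.b_p_bar == pytest.approx(10.0)
        assert st.b_p0_bar == pytest.approx(100.0 / 11.0)
        assert st.q == pytest.approx(1.0 / 3.0)
        assert st.var_bm == pytest.approx(6.0)  # b^2 + b
        assert st.var_bp == pytest.approx(110.0)
        assert st.freq_m == pytest.approx(5.0)

    def test_no_transcription_degenerates(self):
        p = GeneParams(k_g=5, gamma_g=95, k_m=0.0, gamma_m=10, k_p=100, gamma_p=1)
        st = burst_statistics(p)
        assert st.b_m_bar == 0.0
        assert st.var_bm == 0.0
        assert st.q == 1.0

    def test_burst_size_round_trip(self):
        # choose k_m so that b_m = 8 with k_g=5, gamma_g=100 -> k_m = 8*105
        p = GeneParams.from_burst_sizes(
            k_g=5, gamma_g=100, gamma_m=10, gamma_p=1, b_m=8, b_p=10
        )
        assert p.k_m == pytest.approx(840.0)
        assert burst_statistics(p).b_m_bar == pytest.approx(8.0)

    def test_legacy_definition_differs(self, fig1_params):
        # k_m/gamma_g deviates from k_m/(k_g+gamma_g) whenever k_g > 0
        assert burst_size_mrna_legacy(fig1_params) == pytest.approx(200.0 / 95.0)
        assert burst_size_mrna_legacy(fig1_params) > fig1_params.b_m

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            GeneParams(k_g=0, gamma_g=95, k_m=200, gamma_m=10, k_p=100, gamma_p=1)
        with pytest.raises(ValueError):
            GeneParams(k_g=5, gamma_g=95, k_m=-1, gamma_m=10, k_p=100, gamma_p=1)
        with pytest.raises(ValueError):
            GeneParams(k_g=5, gamma_g=95, k_m=200, gamma_m=10, k_p=100, gamma_p=1,
                       n_copies=0)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "gg, gm, gp, kg, expected",
        [
            (100.0, 10.0, 1.0, 5.0, Regime.BOTH_BURSTS),  # boundary equality bursts
            (1.0, 1.0, 1.0, 1.0, Regime.NO_BURST),
            (0.1, 10.0, 1.0, 0.1, Regime.PROTEIN_BURST),
            (10.0, 1.0, 1.0, 5.0, Regime.MRNA_BURST),
            (95.0, 10.0, 1.0, 5.0, Regime.PROTEIN_BURST),  # 9.5 < 10: mRNA side fails
        ],
    )
    def test_labels(self, gg, gm, gp, kg, expected):
        p = GeneParams(k_g=kg, gamma_g=gg, k_m=10, gamma_m=gm, k_p=10, gamma_p=gp)
        info = classify_regime(p)
        assert info.label is expected
        assert info.ratio_gm == pytest.approx(gg / gm)
        assert info.ratio_mp == pytest.approx(gm / gp)

    def test_threshold_must_exceed_one(self, fig1_params):
        with pytest.raises(ValueError):
            classify_regime(fig1_params, threshold=1.0)


class TestProductionMoments:
    def test_both_bursts_reference_step(self):
        # k_g=5, b_m=2, b_p=10, tau=0.03 -> mean 3, SD about 13.5
        p = GeneParams.from_burst_sizes(5, 95, 10, 1, b_m=2, b_p=10)
        pm = production_moments(Regime.BOTH_BURSTS, p, tau=0.03)
        assert pm.delta == pytest.approx(3.0)
        assert pm.var == pytest.approx(183.0)
        assert math.sqrt(pm.var) == pytest.approx(13.5, abs=0.05)

    @pytest.mark.parametrize("regime", [Regime.MRNA_BURST, Regime.BOTH_BURSTS,
                                        Regime.PROTEIN_BURST, Regime.NO_BURST])
    def test_moments_linear_in_tau(self, regime, scan_params):
        small = production_moments(regime, scan_params, tau=1e-7, g=1)
        big = production_moments(regime, scan_params, tau=2e-7, g=1)
        assert big.delta == pytest.approx(2 * small.delta)
        assert big.var == pytest.approx(2 * small.var)
        assert small.delta < 1e-2 and small.var < 1e-2

    def test_inactive_gene_produces_nothing(self, scan_params):
        pm = production_moments(Regime.PROTEIN_BURST, scan_params, tau=0.1, g=0)
        assert pm.delta == 0.0 and pm.var == 0.0

    def test_protein_burst_needs_gene_state(self, scan_params):
        with pytest.raises(ValueError):
            production_moments(Regime.PROTEIN_BURST, scan_params, tau=0.1)


class TestComposeBurstVariance:
    def test_matches_poisson_geometric_closed_form(self):
        # Poisson events (var=mean=k_g*tau), geometric sizes (var=b^2+b)
        kg, tau, b = 5.0, 0.07, 3.0
        e = kg * tau
        v = compose_burst_variance(e, e, b, b * b + b)
        assert v == pytest.approx(kg * tau * b * (2 * b + 1))

    def test_deterministic_production_has_zero_variance(self):
        assert compose_burst_variance(4.0, 0.0, 3.0, 0.0) == 0.0

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            compose_burst_variance(-1.0, 1.0, 1.0, 1.0)

    def test_monte_carlo_compound_sum_oracle(self):
        # brute-force compound sum: E ~ Poisson(4), sizes ~ Geometric(mean 3)
        rng = np.random.default_rng(20240917)
        n = 10**6
        e_mean, b_mean = 4.0, 3.0
        q = 1.0 / (1.0 + b_mean)  # geometric on {0,1,...} with mean (1-q)/q
        events = rng.poisson(e_mean, size=n)
        total = np.zeros(n)
        # draw sizes grouped by event count for speed
        max_e = events.max()
        for e in range(1, max_e + 1):
            idx = events == e
            k = int(idx.sum())
            if k:
                total[idx] = rng.geometric(q, size=(k, e)).sum(axis=1) - e
        sample_var = total.var(ddof=1)
        expected = compose_burst_variance(e_mean, e_mean, b_mean, b_mean**2 + b_mean)
        # 3 Monte-Carlo SEs of a variance estimate (and well within 1%)
        mc_se = math.sqrt(np.var((total - total.mean()) ** 2, ddof=1) / n)
        assert abs(sample_var - expected) < 3 * mc_se
        assert abs(sample_var - expected) / expected < 0.01


class TestSteadyStateMoments:
    def test_reference_gene_means(self, fig1_params):
        mom = steady_state_moments(fig1_params)
        assert mom.p_bar == pytest.approx(100.0)
        assert mom.m_bar == pytest.approx(1.0)

    def test_no_translation(self, fig1_params):
        p = GeneParams(**{**fig1_params.__dict__, "k_p": 0.0})
        mom = steady_state_moments(p)
        assert mom.p_bar == 0.0
        assert mom.var_p == 0.0

    def test_switching_preset_low_state_mean(self):
        # gamma_g=100, k_m=200, gamma_m=10, k_p=100, gamma_p=1 at k_g=3:
        # p_bar = (3/103)*(200/10)*(100/1)
        p = GeneParams(k_g=3, gamma_g=100, k_m=200, gamma_m=10, k_p=100, gamma_p=1)
        assert steady_state_moments(p).p_bar == pytest.approx(3 / 103 * 20 * 100)

    def test_fraction_bounds(self, fig1_params, scan_params, cheap_params):
        for p in (fig1_params, scan_params, cheap_params):
            mom = steady_state_moments(p)
            for f in (mom.F0, mom.F1, mom.F2):
                assert 0.0 < f <= 1.0

    def test_burst_approx_requires_valid_regime(self, fig1_params):
        with pytest.raises(ValueError):
            steady_state_moments(fig1_params, MomentFlavor.BURST_APPROX)
        with pytest.raises(ValueError):
            steady_state_moments(fig1_params, MomentFlavor.BURST_APPROX,
                                 Regime.NO_BURST)

    @pytest.mark.parametrize("regime", [Regime.MRNA_BURST, Regime.BOTH_BURSTS,
                                        Regime.PROTEIN_BURST])
    def test_approximations_converge_to_lna(self, regime):
        # as gamma_g -> inf with b_m fixed, F0,F1,F2 -> 1 and the burst
        # variance collapses onto the exact LNA expression
        gm = 1.0 if regime is Regime.MRNA_BURST else 100.0
        p = GeneParams.from_burst_sizes(
            k_g=5, gamma_g=1e8, gamma_m=gm, gamma_p=1, b_m=2, b_p=10
        )
        mom = steady_state_moments(p)
        assert mom.F0 == pytest.approx(1.0, rel=1e-5)
        assert mom.F1 == pytest.approx(1.0, rel=1e-5)
        assert mom.F2 == pytest.approx(1.0, rel=1e-5)
        if regime is Regime.PROTEIN_BURST:
            # protein-burst formula additionally needs gamma_m >> gamma_p
            p = GeneParams.from_burst_sizes(
                k_g=5, gamma_g=1e8, gamma_m=1e6, gamma_p=1, b_m=2, b_p=10
            )
        err = sd_error_percent(p, regime)
        if regime is Regime.BOTH_BURSTS:
            # b_p vs b_p0 difference survives at finite gamma_m/gamma_p
            assert abs(err) < 5.0
        else:
            assert abs(err) < 0.1


class TestVarianceErrorMap:
    def test_mrna_corner_error(self):
        # gamma_g=10, gamma_m=gamma_p=1 with k_g=5, b_m=2, b_p=10
        p = GeneParams.from_burst_sizes(
            k_g=5, gamma_g=10, gamma_m=1, gamma_p=1, b_m=2, b_p=10
        )
        info = classify_regime(p)
        assert info.label is Regime.MRNA_BURST
        assert sd_error_percent(p, info) == pytest.approx(12.5, abs=0.1)

    def test_map_regions(self):
        df = variance_error_map(
            gamma_g_values=np.logspace(0, 3, 16),
            gamma_m_values=np.logspace(0, 2, 12),
        )
        assert set(df.columns) == {"gamma_g", "gamma_m", "regime", "error_percent"}
        no_burst = df[df.regime == "no_burst"]
        assert len(no_burst) > 0
        assert (no_burst.error_percent == 0.0).all()
        both = df[df.regime == "both_bursts"]
        assert both.error_percent.abs().max() <= 6.5

    def test_time_unit_invariance(self):
        # rescaling all rates by a common factor leaves the % error unchanged
        base = GeneParams.from_burst_sizes(
            k_g=5, gamma_g=40, gamma_m=2, gamma_p=1, b_m=2, b_p=10
        )
        scaled = GeneParams(
            k_g=base.k_g * 7, gamma_g=base.gamma_g * 7, k_m=base.k_m * 7,
            gamma_m=base.gamma_m * 7, k_p=base.k_p * 7, gamma_p=base.gamma_p * 7,
        )
        r1, r2 = classify_regime(base), classify_regime(scaled)
        assert r1.label is r2.label
        assert sd_error_percent(base, r1) == pytest.approx(
            sd_error_percent(scaled, r2), rel=1e-12
        )


class TestNegativeProductionFraction:
    def test_reference_step_is_near_forty_percent(self):
        assert negative_production_fraction(3.0, math.sqrt(183.0)) == pytest.approx(
            0.40, abs=0.005
        )

    def test_far_right_gaussian(self):
        assert negative_production_fraction(100.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_matches_normal_cdf(self):
        assert negative_production_fraction(0.0, 10.0) == pytest.approx(
            norm.cdf(-0.05)
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            negative_production_fraction(1.0, 0.0)
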
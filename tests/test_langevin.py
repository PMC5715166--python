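"""Burst Langevin stepper: accumulator, tau selection, step moments, driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from burstlangevin import (
    GeneParams,
    Regime,
    StepConfig,
    SystemState,
    apply_negative_accumulator,
    bl_simulate,
    langevin_step,
    production_moments,
    select_tau,
)


class TestNegativeAccumulator:
    @pytest.mark.parametrize(
        "raw, deficit, expected",
        [
            (-5, 0, (0, -5)),   # negative draw stored, production silenced
            (8, -5, (3, 0)),    # burst fires once the balance turns positive
            (0, 0, (0, 0)),
            (3, -7, (0, -4)),
            (7, -7, (0, 0)),
        ],
    )
    def test_examples(self, raw, deficit, expected):
        assert apply_negative_accumulator(raw, deficit) == expected

    @given(st_.lists(st_.integers(min_value=-50, max_value=80), max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_signs(self, raws):
        deficit = 0
        applied_total = 0
        for raw in raws:
            applied, deficit = apply_negative_accumulator(raw, deficit)
            assert applied >= 0
            assert deficit <= 0
            applied_total += applied
        # cumulative applied + final deficit == cumulative raw production
        assert applied_total + deficit == sum(raws)

    def test_positive_deficit_rejected(self):
        with pytest.raises(ValueError):
            apply_negative_accumulator(1, 2)


class TestSelectTau:
    def test_reference_hand_evaluation(self, scan_params):
        # p=100, eps=0.03, k_g=5, b_m=2, b_p=10, gamma_p=1:
        #   burst bound max(eps*p, b_p)/R = 10/100 = 0.1
        #   degradation mean bound max(eps*p,1)/(gamma_p*p) = 3/100 = 0.03
        #   degradation variance bound 9/100 = 0.09  -> tau = 0.03
        tau, crit = select_tau(
            SystemState(p=100), scan_params, Regime.BOTH_BURSTS,
            rng=np.random.default_rng(0),
        )
        assert tau == pytest.approx(0.03)
        assert crit is None

    def test_whole_burst_at_low_copy_number(self, scan_params):
        # eps*p <= 1 and b_p > 1: the burst bound relaxes to b_p/R = 1/(k_g*b_m)
        tau, crit = select_tau(
            SystemState(p=0), scan_params, Regime.BOTH_BURSTS,
            rng=np.random.default_rng(0),
        )
        assert tau == pytest.approx(1.0 / (5 * 2))
        assert crit is None

    def test_critical_clock_can_fire(self, scan_params):
        # p below n_critical: degradation becomes critical and the
        # exponential clock sometimes beats the leap
        rng = np.random.default_rng(1)
        fired = 0
        for _ in range(200):
            tau, crit = select_tau(
                SystemState(p=5), scan_params, Regime.BOTH_BURSTS, rng=rng
            )
            assert tau > 0
            if crit is not None:
                assert crit == "protein_degradation"
                fired += 1
        assert 0 < fired < 200

    def test_all_propensities_zero_returns_remaining_time(self):
        p = GeneParams(k_g=5, gamma_g=95, k_m=0.0, gamma_m=10, k_p=0.0, gamma_p=1)
        tau, crit = select_tau(
            SystemState(p=0), p, Regime.BOTH_BURSTS, t_remaining=7.5,
            rng=np.random.default_rng(0),
        )
        assert tau == 7.5 and crit is None

    def test_extra_channels_tighten_tau(self, scan_params):
        loose, _ = select_tau(SystemState(p=100), scan_params,
                              Regime.BOTH_BURSTS, rng=np.random.default_rng(0))
        tight, _ = select_tau(SystemState(p=100), scan_params,
                              Regime.BOTH_BURSTS,
                              extra_channels=[(10000.0, 1)],
                              rng=np.random.default_rng(0))
        assert tight < loose


class TestLangevinStep:
    def test_silenced_production_only_advances_time(self):
        p = GeneParams(k_g=5, gamma_g=95, k_m=0.0, gamma_m=10, k_p=0.0, gamma_p=1)
        s0 = SystemState(p=0)
        s1 = langevin_step(s0, 0.05, Regime.BOTH_BURSTS, p,
                           np.random.default_rng(0))
        assert (s1.g, s1.m, s1.p) == (0, 0, 0)
        assert s1.t == pytest.approx(0.05)

    def test_step_production_moments_match_closed_form(self):
        # negligible degradation (gamma_p ~ 0) so the committed change IS the
        # applied production; the raw Gaussian draw is recovered through the
        # accumulator identity raw = applied + new_deficit - old_deficit.
        # Mean of the applied production and variance of the raw draws must
        # match the compound-burst closed forms within Monte-Carlo error.
        params = GeneParams.from_burst_sizes(
            k_g=5, gamma_g=95, gamma_m=10, gamma_p=1e-12, b_m=2, b_p=10
        )
        rng = np.random.default_rng(2024)
        tau = 0.03
        pm = production_moments(Regime.BOTH_BURSTS, params, tau)
        n = 40_000
        p_pin = 10**6
        deficit = 0
        applied = np.empty(n)
        raws = np.empty(n)
        for i in range(n):
            s = SystemState(p=p_pin, deficit_p=deficit)
            out = langevin_step(s, tau, Regime.BOTH_BURSTS, params, rng)
            applied[i] = out.p - p_pin
            raws[i] = applied[i] + out.deficit_p - deficit
            deficit = out.deficit_p
        assert (applied >= 0).all()
        se_mean = math.sqrt(pm.var / n)
        assert abs(applied.mean() - pm.delta) < 3 * se_mean
        se_var = math.sqrt(np.var((raws - raws.mean()) ** 2, ddof=1) / n)
        assert abs(raws.var(ddof=1) - pm.var) < 3 * se_var
        # the raw draws reproduce the ~40% negative-draw fraction
        assert (raws <= -1).mean() == pytest.approx(0.40, abs=0.02)

    def test_halving_limit_raises(self):
        # no production at all, degradation mean >> p even after one halving
        dead = GeneParams(k_g=5, gamma_g=100, k_m=0.0, gamma_m=10, k_p=100,
                          gamma_p=1)
        s = SystemState(p=50)
        with pytest.raises(RuntimeError):
            langevin_step(s, 100.0, Regime.BOTH_BURSTS, dead,
                          np.random.default_rng(3),
                          StepConfig(max_halvings=1))


class TestDriver:
    def test_same_seed_reproduces(self, fig1_params):
        a = bl_simulate(fig1_params, Regime.BOTH_BURSTS, t_end=20.0, seed=9)
        b = bl_simulate(fig1_params, Regime.BOTH_BURSTS, t_end=20.0, seed=9)
        c = bl_simulate(fig1_params, Regime.BOTH_BURSTS, t_end=20.0, seed=10)
        assert a.states.equals(b.states)
        assert not a.states.equals(c.states)

    @pytest.mark.parametrize("regime", [Regime.BOTH_BURSTS, Regime.MRNA_BURST,
                                        Regime.PROTEIN_BURST, Regime.NO_BURST])
    def test_counts_never_negative(self, regime):
        presets = {
            Regime.BOTH_BURSTS: GeneParams.from_burst_sizes(5, 100, 10, 1, 2, 10),
            Regime.MRNA_BURST: GeneParams.from_burst_sizes(5, 50, 1, 1, 2, 10),
            Regime.PROTEIN_BURST: GeneParams(k_g=0.5, gamma_g=0.5, k_m=20,
                                             gamma_m=10, k_p=100, gamma_p=1),
            Regime.NO_BURST: GeneParams(k_g=2, gamma_g=4, k_m=10, gamma_m=2,
                                        k_p=4, gamma_p=1),
        }
        traj = bl_simulate(presets[regime], regime, t_end=50.0, seed=31,
                           sample_grid=np.linspace(0.25, 50.0, 200))
        vals = traj.states.to_numpy()
        assert np.nanmin(vals) >= 0.0
        assert traj.meta["regime"] == regime.value

    def test_untracked_species_reported_as_na(self, fig1_params):
        traj = bl_simulate(fig1_params, Regime.BOTH_BURSTS, t_end=5.0, seed=1)
        assert traj.states.g.isna().all()
        assert traj.states.m.isna().all()
        assert traj.states.p.notna().all()

    def test_reference_gene_mean_near_hundred(self, fig1_params):
        # quick ensemble: BL in both-bursts mode should sit near p_bar=100
        from burstlangevin.experiments import ensemble_steady_state

        s = ensemble_steady_state("bl", fig1_params, regime=Regime.BOTH_BURSTS,
                                  n_points=600, samples_per_point=4,
                                  seed_base=77)
        assert abs(s.mean - 100.0) < max(4 * s.stderr_mean, 3.0)
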
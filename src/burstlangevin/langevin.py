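"""Burst-aware chemical Langevin propagation of gene expression.

The scheme folds an entire burst regime into a single Gaussian production
channel: over a step ``tau`` the bursting species receives a draw from
``Normal(Delta(tau), sigma_Delta(tau))`` with the compound burst moments of
:func:`burstlangevin.model_core.production_moments`, rounded to an integer
and passed through a negative-production accumulator (a Gaussian draw that
rounds negative is stored as a deficit and released against later positive
draws, which preserves the production mean while keeping counts physical).
Degradation uses the ordinary chemical-Langevin Gaussian with mean and
variance ``gamma*y*tau``.

Step-size selection follows tau-leaping practice: the burst channel is bound
by ``max(eps*y, b_bar)/rate`` (so a whole average burst fits in one step even
at low copy number), every other channel by the usual mean and variance
bounds ``max(eps*y,1)/|mu|`` and ``max(eps*y,1)^2/sigma^2``.  Channels whose
propensity changes drastically with one firing -- gene switching, and any
degradation of a species below ``n_critical`` copies -- are critical: an
exponential clock with the summed critical propensity competes with the leap,
and when it wins the step is shortened and exactly one critical event fires
on top of it.  A step that would drive a count negative is retried with
half the step size (up to ``max_halvings``).

Depending on the regime the tracked state shrinks: BOTH_BURSTS tracks the
protein alone; MRNA_BURST tracks mRNA (bursting) and protein (plain CLE);
PROTEIN_BURST tracks the gene state and protein; NO_BURST tracks everything
with plain CLE (that regime is better served by the exact SSA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .gillespie import Trajectory, deterministic_initial
from .model_core import (
    GeneParams,
    Regime,
    RegimeInfo,
    classify_regime,
    production_moments,
    _as_regime,
)

__all__ = [
    "SystemState",
    "StepConfig",
    "apply_negative_accumulator",
    "select_tau",
    "langevin_step",
    "bl_simulate",
]


@dataclass(frozen=True)
class SystemState:
    """Instantaneous simulator state.

    ``deficit_m``/``deficit_p`` are the pending negative-production
    accumulators (always <= 0 between committed steps).  Species a regime
    does not track are simply carried unchanged.
    """

    t: float = 0.0
    g: int = 0
    m: int = 0
    p: int = 0
    deficit_m: int = 0
    deficit_p: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.p < 0 or self.g < 0:
            raise ValueError("counts must be non-negative")
        if self.deficit_m > 0 or self.deficit_p > 0:
            raise ValueError("deficits are accumulators of negative production (<= 0)")


@dataclass(frozen=True)
class StepConfig:
    """Tunables of the adaptive stepper."""

    epsilon: float = 0.03
    n_critical: int = 10
    max_halvings: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.n_critical < 1:
            raise ValueError("n_critical must be >= 1")
        if self.max_halvings < 1:
            raise ValueError("max_halvings must be >= 1")


def apply_negative_accumulator(raw_production: int, deficit: int) -> tuple[int, int]:
    """Apply the negative-production deficit to one raw production draw.

    Returns ``(applied, new_deficit)`` with ``applied >= 0``,
    ``new_deficit <= 0`` and conservation
    ``applied + new_deficit == raw_production + deficit``.
    """
    if deficit > 0:
        raise ValueError("deficit must be <= 0")
    total = raw_production + deficit
    if total > 0:
        return total, 0
    return 0, total


def _burst_channel(regime: Regime, params: GeneParams, state: SystemState):
    """(species, rate, mean burst size, variance rate) of the burst channel."""
    n = params.n_copies
    if regime is Regime.BOTH_BURSTS:
        R = n * params.k_g * params.b_m * params.b_p
        return "p", R, params.b_p, R * (2.0 * params.b_m * params.b_p + 2.0 * params.b_p + 1.0)
    if regime is Regime.MRNA_BURST:
        R = n * params.k_g * params.b_m
        return "m", R, params.b_m, R * (2.0 * params.b_m + 1.0)
    if regime is Regime.PROTEIN_BURST:
        R = state.g * params.k_m * params.b_p
        return "p", R, params.b_p, R * (2.0 * params.b_p + 1.0)
    return None


def _channel_table(regime: Regime, params: GeneParams, state: SystemState):
    """Non-burst channels as (name, species, propensity, nu, is_critical_always)."""
    chans = []
    if regime is Regime.MRNA_BURST:
        chans.append(("mrna_degradation", "m", params.gamma_m * state.m, -1, False))
        chans.append(("translation", "p", params.k_p * state.m, +1, False))
        chans.append(("protein_degradation", "p", params.gamma_p * state.p, -1, False))
    elif regime is Regime.BOTH_BURSTS:
        chans.append(("protein_degradation", "p", params.gamma_p * state.p, -1, False))
    elif regime is Regime.PROTEIN_BURST:
        chans.append(("gene_on", "g", params.k_g * (params.n_copies - state.g), +1, True))
        chans.append(("gene_off", "g", params.gamma_g * state.g, -1, True))
        chans.append(("protein_degradation", "p", params.gamma_p * state.p, -1, False))
    else:  # NO_BURST
        chans.append(("gene_on", "g", params.k_g * (params.n_copies - state.g), +1, True))
        chans.append(("gene_off", "g", params.gamma_g * state.g, -1, True))
        chans.append(("transcription", "m", params.k_m * state.g, +1, False))
        chans.append(("mrna_degradation", "m", params.gamma_m * state.m, -1, False))
        chans.append(("translation", "p", params.k_p * state.m, +1, False))
        chans.append(("protein_degradation", "p", params.gamma_p * state.p, -1, False))
    return chans


def select_tau(
    state: SystemState,
    params: GeneParams,
    regime: "Regime | RegimeInfo",
    cfg: StepConfig = StepConfig(),
    extra_channels=(),
    t_remaining: float = math.inf,
    rng: "np.random.Generator | None" = None,
):
    """Adaptive step size, and which critical channel (if any) fires.

    Returns ``(tau, critical)`` where ``critical`` is the name of the single
    critical reaction to apply (drawn when the exponential critical clock
    beats the leap bound) or ``None``.  ``extra_channels`` are additional
    ``(propensity, nu_p)`` pairs acting on the protein, folded into the
    non-burst bounds.  With every propensity zero, ``tau`` is the remaining
    time.
    """
    regime = _as_regime(regime)
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    eps = cfg.epsilon
    counts = {"g": state.g, "m": state.m, "p": state.p}
    tau = t_remaining
    burst = _burst_channel(regime, params, state)
    if burst is not None:
        species, R, b_bar, _ = burst
        if R > 0.0:
            tau = min(tau, max(eps * counts[species], b_bar) / R)
    if regime is Regime.PROTEIN_BURST or regime is Regime.NO_BURST:
        tau = min(tau, 0.1 / max(params.k_g, params.gamma_g))
    # per-species mean/variance bounds over non-burst, non-critical channels
    chans = _channel_table(regime, params, state)
    chans = chans + [("extra", "p", a, nu, False) for (a, nu) in extra_channels]
    criticals = []
    mu = {"m": 0.0, "p": 0.0}
    s2 = {"m": 0.0, "p": 0.0}
    for name, species, a, nu, always_crit in chans:
        if a <= 0.0:
            continue
        is_crit = always_crit or (
            nu < 0 and species in ("m", "p") and counts[species] < cfg.n_critical
        )
        if is_crit:
            criticals.append((name, a))
        elif species in mu:
            mu[species] += nu * a
            s2[species] += nu * nu * a
    for species in ("m", "p"):
        c = max(eps * counts[species], 1.0)
        if abs(mu[species]) > 0.0:
            tau = min(tau, c / abs(mu[species]))
        if s2[species] > 0.0:
            tau = min(tau, c * c / s2[species])
    crit_sum = sum(a for _, a in criticals)
    if crit_sum > 0.0:
        tau_c = rng.exponential(1.0 / crit_sum)
        if tau_c < tau:
            u = rng.random() * crit_sum
            acc = 0.0
            for name, a in criticals:
                acc += a
                if u < acc:
                    return tau_c, name
            return tau_c, criticals[-1][0]
    return tau, None


def _round_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def langevin_step(
    state: SystemState,
    tau: float,
    regime: "Regime | RegimeInfo",
    params: GeneParams,
    rng: np.random.Generator,
    cfg: StepConfig = StepConfig(),
    switch_gene: bool = True,
) -> SystemState:
    """One committed Euler-Maruyama step of length ``tau``.

    Draw order: burst/CLE production, then degradation, species m before p.
    Production draws pass through the per-species deficit accumulator.  In
    PROTEIN_BURST (or NO_BURST) mode the gene state flips as a Bernoulli jump
    with probability ``k_g*tau`` (off->on) or ``gamma_g*tau`` (on->off);
    drivers that already treat switching as a critical reaction pass
    ``switch_gene=False``.  A provisionally negative count triggers the
    half-tau retry, redrawing everything at ``tau/2``; exceeding
    ``max_halvings`` raises.
    """
    regime = _as_regime(regime)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if regime in (Regime.PROTEIN_BURST, Regime.NO_BURST):
        cap = 0.1 / max(params.k_g, params.gamma_g)
        if switch_gene and tau > cap:
            tau = cap
    tau0 = tau
    for _ in range(cfg.max_halvings + 1):
        g, m, p = state.g, state.m, state.p
        def_m, def_p = state.deficit_m, state.deficit_p
        # gene switching (Bernoulli contract) first, so production sees g(t)
        g_new = g
        if switch_gene and regime in (Regime.PROTEIN_BURST, Regime.NO_BURST):
            u = rng.random()
            if g < params.n_copies and u < params.k_g * (params.n_copies - g) * tau:
                g_new = g + 1
            elif g > 0 and u < params.k_g * (params.n_copies - g) * tau + params.gamma_g * g * tau:
                g_new = g - 1
        burst = _burst_channel(regime, params, state)
        raw_m = raw_p = 0
        if burst is not None:
            species, R, _, vrate = burst
            if R > 0.0:
                draw = _round_away(rng.normal(R * tau, math.sqrt(vrate * tau)))
                if species == "m":
                    raw_m = draw
                else:
                    raw_p = draw
        deg_m = deg_p = 0
        for name, species, a, nu, _always in _channel_table(regime, params, state):
            if a <= 0.0 or name in ("gene_on", "gene_off"):
                continue
            is_crit = nu < 0 and (state.m if species == "m" else state.p) < cfg.n_critical
            if is_crit:
                continue  # handled by the critical clock in the driver
            mu = a * tau
            # below ~5 expected events the rounded Gaussian loses sub-integer
            # mass; draw the exact Poisson count instead
            if mu < 5.0:
                draw = int(rng.poisson(mu))
            else:
                draw = _round_away(rng.normal(mu, math.sqrt(mu)))
            if nu > 0:
                if species == "m":
                    raw_m += draw
                else:
                    raw_p += draw
            else:
                if species == "m":
                    deg_m += draw
                else:
                    deg_p += draw
        app_m, ndef_m = apply_negative_accumulator(raw_m, def_m)
        app_p, ndef_p = apply_negative_accumulator(raw_p, def_p)
        m_new = m + app_m - deg_m
        p_new = p + app_p - deg_p
        if m_new >= 0 and p_new >= 0:
            return SystemState(
                t=state.t + tau, g=g_new, m=m_new, p=p_new,
                deficit_m=ndef_m, deficit_p=ndef_p,
            )
        tau *= 0.5
    raise RuntimeError(
        f"half-tau retry exceeded {cfg.max_halvings} halvings "
        f"(state={state}, tau0={tau0:g})"
    )


# ---------------------------------------------------------------------------
# trajectory driver (numba-backed)
# ---------------------------------------------------------------------------

def _run_sampled(
    regime: Regime,
    params: GeneParams,
    cfg: StepConfig,
    st: list,
    duration: float,
    sample_times: np.ndarray,
    out_g: np.ndarray,
    out_m: np.ndarray,
    out_p: np.ndarray,
) -> None:
    """Advance [g, m, p, def_m, def_p] recording last-commit-hold samples."""
    eps, ncrit, maxh = cfg.epsilon, cfg.n_critical, cfg.max_halvings
    if regime is Regime.BOTH_BURSTS:
        p, dp, status = K.bl_both_run(
            params.n_copies * params.k_g, params.b_m, params.b_p, params.gamma_p,
            st[2], st[4], duration, eps, ncrit, maxh, sample_times, out_p,
        )
        st[2], st[4] = p, dp
    elif regime is Regime.MRNA_BURST:
        m, p, dm, dp, status = K.bl_mrna_run(
            params.n_copies * params.k_g, params.b_m, params.gamma_m,
            params.k_p, params.gamma_p,
            st[1], st[2], st[3], st[4], duration, eps, ncrit, maxh,
            sample_times, out_m, out_p,
        )
        st[1], st[2], st[3], st[4] = m, p, dm, dp
    elif regime is Regime.PROTEIN_BURST:
        g, p, dp, status = K.bl_protein_run(
            params.k_g, params.gamma_g, params.k_m, params.b_p, params.gamma_p,
            params.n_copies, st[0], st[2], st[4], duration, eps, ncrit, maxh,
            sample_times, out_g, out_p,
        )
        st[0], st[2], st[4] = g, p, dp
    else:
        g, m, p, dm, dp, status = K.bl_noburst_run(
            params.k_g, params.gamma_g, params.k_m, params.gamma_m,
            params.k_p, params.gamma_p, params.n_copies,
            st[0], st[1], st[2], st[3], st[4], duration, eps, ncrit, maxh,
            sample_times, out_g, out_m, out_p,
        )
        st[0], st[1], st[2], st[3], st[4] = g, m, p, dm, dp
    if status != K.STATUS_OK:
        raise RuntimeError(
            f"half-tau retry exceeded {cfg.max_halvings} halvings in regime "
            f"{regime.value} (state g={st[0]} m={st[1]} p={st[2]})"
        )


def bl_simulate(
    params: GeneParams,
    regime: "Regime | RegimeInfo | None" = None,
    t_end: float = 10.0,
    initial: "SystemState | None" = None,
    cfg: "StepConfig | None" = None,
    sample_grid=None,
    seed: "int | None" = None,
) -> Trajectory:
    """Simulate one burst-Langevin trajectory up to ``t_end``.

    ``regime=None`` auto-classifies from the rate separation.  The state is
    recorded on ``sample_grid`` with last-commit hold (steps are not
    truncated at sample times); untracked species are reported as NA.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    cfg = cfg or StepConfig()
    regime = _as_regime(regime) if regime is not None else classify_regime(params).label
    seed = cfg.rng_seed if seed is None else int(seed)
    if initial is None:
        g0, m0, p0 = deterministic_initial(params)
        initial = SystemState(g=g0, m=m0, p=p0)
    if sample_grid is None:
        sample_grid = np.linspace(t_end / 200.0, t_end, 200)
    grid = np.asarray(sample_grid, dtype=float)
    K.seed_rng(seed)
    st = [int(initial.g), int(initial.m), int(initial.p),
          int(initial.deficit_m), int(initial.deficit_p)]
    tracked = {
        Regime.BOTH_BURSTS: ("p",),
        Regime.MRNA_BURST: ("m", "p"),
        Regime.PROTEIN_BURST: ("g", "p"),
        Regime.NO_BURST: ("g", "m", "p"),
    }[regime]
    out_g = np.zeros(grid.size, dtype=np.int64)
    out_m = np.zeros(grid.size, dtype=np.int64)
    out_p = np.zeros(grid.size, dtype=np.int64)
    _run_sampled(regime, params, cfg, st, K.BIG, grid - initial.t,
                 out_g, out_m, out_p)
    states = pd.DataFrame(
        {"g": out_g.astype(float), "m": out_m.astype(float),
         "p": out_p.astype(float)}
    )
    for col in ("g", "m", "p"):
        if col not in tracked:
            states[col] = np.nan
    return Trajectory(
        times=grid,
        states=states,
        seed=seed,
        params=params.__dict__.copy(),
        meta={"simulator": "burst_langevin", "regime": regime.value,
              "epsilon": cfg.epsilon, "n_critical": cfg.n_critical,
              "t_end": t_end},
    )
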
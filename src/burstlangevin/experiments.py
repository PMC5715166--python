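"""Validation drivers: steady-state ensembles, Langevin-vs-SSA error grids,
switching dynamics and distribution overlays.

Every driver is reproducible from ``(parameters, seed_base)``: replica seeds
are derived from the base seed with a splittable seed sequence, and both
simulators consume them in the same order.

Steady-state protocol
---------------------
Each replica is an independent trajectory started from the rounded
deterministic fixed point and burned in for ``t_relax`` (default 20 protein
lifetimes, far beyond the slowest relaxation of these models), then read out
``samples_per_point`` times at a decorrelation spacing (default 3 protein
lifetimes).  Standard errors are estimated by delete-one-replica jackknife,
so correlation of readouts within a replica cannot understate them.  The
number of readouts per replica is chosen from the analytic coefficient of
variation of the LNA steady state before any simulation runs, to hit a
requested relative standard error; it is never adjusted afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from . import _kernels as K
from .gillespie import deterministic_initial
from .langevin import StepConfig
from .model_core import (
    GeneParams,
    MomentFlavor,
    Regime,
    _as_regime,
    classify_regime,
    steady_state_moments,
)
from .regulation import RegulatedNetworkParams, effective_downstream_burst_size

__all__ = [
    "EnsembleSummary",
    "ErrorGrid",
    "NetworkGrid",
    "OverlayResult",
    "ensemble_steady_state",
    "mean_error_grid",
    "grid_fig3",
    "grid_fig5",
    "network_ensemble",
    "network_mean_grid",
    "switching_dynamics",
    "distribution_overlay",
    "readouts_for_target_se",
]


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Sample statistics of independent steady-state readouts."""

    n_points: int
    samples_per_point: int
    mean: float
    sd: float
    stderr_mean: float
    stderr_sd: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    params: dict
    regime: str
    seed_base: int
    samples: "np.ndarray | None" = None
    mean_m: "float | None" = None


def _jackknife(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, SD and their delete-one-replica jackknife standard errors.

    ``samples`` has shape (n_replicas, k).  The SD is the plain n-1 sample SD
    of the pooled readouts.
    """
    n, k = samples.shape
    total = samples.size
    x = samples.astype(float)
    S = x.sum()
    Q = (x * x).sum()
    mean = S / total
    var = (Q - total * mean * mean) / (total - 1)
    sd = math.sqrt(max(var, 0.0))
    if n < 2 or total - k < 2:
        return mean, sd, float("nan"), float("nan")
    s_i = x.sum(axis=1)
    q_i = (x * x).sum(axis=1)
    n_i = total - k
    mean_i = (S - s_i) / n_i
    var_i = (Q - q_i - n_i * mean_i * mean_i) / (n_i - 1)
    sd_i = np.sqrt(np.clip(var_i, 0.0, None))
    se_mean = math.sqrt((n - 1) / n * np.sum((mean_i - mean_i.mean()) ** 2))
    se_sd = math.sqrt((n - 1) / n * np.sum((sd_i - sd_i.mean()) ** 2))
    return mean, sd, se_mean, se_sd


def readouts_for_target_se(
    params: GeneParams,
    n_points: int,
    target_rel_se: float,
    max_readouts: int = 25,
) -> int:
    """Readouts per replica needed for a target per-simulator relative SE.

    Uses the analytic LNA coefficient of variation of the steady-state
    protein number; decorrelation-spaced readouts are counted as independent
    for this sizing (the realized stderr is estimated by jackknife anyway).
    """
    mom = steady_state_moments(params, MomentFlavor.LNA_EXACT)
    if mom.p_bar <= 0:
        return 1
    cv = math.sqrt(mom.var_p) / mom.p_bar
    n_eff = (cv / target_rel_se) ** 2
    return int(np.clip(math.ceil(n_eff / n_points), 1, max_readouts))


def _sample_matrix_ssa(
    params: GeneParams, seeds: np.ndarray, t_relax: float, k: int, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    kg, gg, km, gm, kp, gp = (
        params.k_g, params.gamma_g, params.k_m,
        params.gamma_m, params.k_p, params.gamma_p,
    )
    n = params.n_copies
    g0, m0, p0 = deterministic_initial(params)
    out_p = np.empty((seeds.size, k), dtype=np.int64)
    out_m = np.empty((seeds.size, k), dtype=np.int64)
    for i, s in enumerate(seeds):
        K.seed_rng(int(s))
        g, m, p = K.ssa_run(kg, gg, km, gm, kp, gp, n, g0, m0, p0, t_relax)
        out_p[i, 0] = p
        out_m[i, 0] = m
        for j in range(1, k):
            g, m, p = K.ssa_run(kg, gg, km, gm, kp, gp, n, g, m, p, spacing)
            out_p[i, j] = p
            out_m[i, j] = m
    return out_p, out_m


def _sample_matrix_bl(
    params: GeneParams,
    regime: Regime,
    cfg: StepConfig,
    seeds: np.ndarray,
    t_relax: float,
    k: int,
    spacing: float,
) -> tuple[np.ndarray, "np.ndarray | None"]:
    g0, m0, p0 = deterministic_initial(params)
    eps, nc, mh = cfg.epsilon, cfg.n_critical, cfg.max_halvings
    times = t_relax + spacing * np.arange(k, dtype=float)
    out_p = np.empty((seeds.size, k), dtype=np.int64)
    out_m: "np.ndarray | None" = None
    if regime is Regime.BOTH_BURSTS:
        nkg, bm, bp, gp = (params.n_copies * params.k_g, params.b_m,
                           params.b_p, params.gamma_p)
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            _, _, st = K.bl_both_run(nkg, bm, bp, gp, p0, 0, K.BIG,
                                     eps, nc, mh, times, out_p[i])
            _check(st)
    elif regime is Regime.MRNA_BURST:
        out_m = np.empty((seeds.size, k), dtype=np.int64)
        nkg, bm = params.n_copies * params.k_g, params.b_m
        gm, kp, gp = params.gamma_m, params.k_p, params.gamma_p
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            st = K.bl_mrna_run(nkg, bm, gm, kp, gp, m0, p0, 0, 0, K.BIG,
                               eps, nc, mh, times, out_m[i], out_p[i])[-1]
            _check(st)
    elif regime is Regime.PROTEIN_BURST:
        kg, gg, km = params.k_g, params.gamma_g, params.k_m
        bp, gp, n = params.b_p, params.gamma_p, params.n_copies
        scratch_g = np.empty(k, dtype=np.int64)
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            st = K.bl_protein_run(kg, gg, km, bp, gp, n, g0, p0, 0, K.BIG,
                                  eps, nc, mh, times, scratch_g, out_p[i])[-1]
            _check(st)
    else:
        out_m = np.empty((seeds.size, k), dtype=np.int64)
        kg, gg, km, gm, kp, gp = (
            params.k_g, params.gamma_g, params.k_m,
            params.gamma_m, params.k_p, params.gamma_p,
        )
        n = params.n_copies
        scratch_g = np.empty(k, dtype=np.int64)
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            st = K.bl_noburst_run(kg, gg, km, gm, kp, gp, n, g0, m0, p0, 0, 0,
                                  K.BIG, eps, nc, mh, times, scratch_g,
                                  out_m[i], out_p[i])[-1]
            _check(st)
    return out_p, out_m


def _check(status: int) -> None:
    if status != K.STATUS_OK:
        raise RuntimeError("half-tau retry limit exceeded")


def _histogram(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hi = int(samples.max())
    if hi <= 1000:
        edges = np.arange(-0.5, hi + 1.5)
    else:
        edges = np.histogram_bin_edges(samples, bins=200)
    counts, edges = np.histogram(samples, bins=edges)
    return counts, edges


def ensemble_steady_state(
    simulator: str,
    params: GeneParams,
    regime: "Regime | None" = None,
    n_points: int = 2000,
    t_relax: "float | None" = None,
    samples_per_point: int = 1,
    sample_spacing: "float | None" = None,
    cfg: "StepConfig | None" = None,
    seed_base: int = 0,
    keep_samples: bool = True,
) -> EnsembleSummary:
    """Steady-state ensemble with either the exact SSA or the burst Langevin.

    ``simulator`` is ``"ssa"`` or ``"bl"``.  ``n_points`` independent
    trajectories use seeds derived from ``seed_base``; each is read out
    ``samples_per_point`` times after burn-in.
    """
    if simulator not in ("ssa", "bl"):
        raise ValueError("simulator must be 'ssa' or 'bl'")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    regime = _as_regime(regime) if regime is not None else classify_regime(params).label
    cfg = cfg or StepConfig()
    t_relax = 20.0 / params.gamma_p if t_relax is None else float(t_relax)
    spacing = 3.0 / params.gamma_p if sample_spacing is None else float(sample_spacing)
    seeds = K.spawn_seeds(seed_base, n_points)
    if simulator == "ssa":
        samples, samples_m = _sample_matrix_ssa(
            params, seeds, t_relax, samples_per_point, spacing
        )
    else:
        samples, samples_m = _sample_matrix_bl(
            params, regime, cfg, seeds, t_relax, samples_per_point, spacing
        )
    mean, sd, se_mean, se_sd = _jackknife(samples)
    counts, edges = _histogram(samples)
    return EnsembleSummary(
        n_points=n_points,
        samples_per_point=samples_per_point,
        mean=mean,
        sd=sd,
        stderr_mean=se_mean,
        stderr_sd=se_sd,
        histogram=counts,
        bin_edges=edges,
        params=params.__dict__.copy(),
        regime=regime.value,
        seed_base=int(seed_base),
        samples=samples if keep_samples else None,
        mean_m=float(samples_m.mean()) if samples_m is not None else None,
    )


# ---------------------------------------------------------------------------
# Langevin-vs-SSA error grids
# ---------------------------------------------------------------------------

@dataclass
class ErrorGrid:
    """Per-cell % differences of the burst Langevin against the exact SSA."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    error_mean: np.ndarray  # % , signed, shape (len(axis1), len(axis2))
    error_sd: np.ndarray
    se_error_mean: np.ndarray
    se_error_sd: np.ndarray
    mean_bl: np.ndarray
    mean_ssa: np.ndarray
    sd_bl: np.ndarray
    sd_ssa: np.ndarray
    reference: str = "SSA"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.axis1_values):
            for j, v2 in enumerate(self.axis2_values):
                rows.append((v1, v2, self.error_mean[i, j], self.error_sd[i, j],
                             self.se_error_mean[i, j], self.se_error_sd[i, j],
                             self.mean_ssa[i, j], self.mean_bl[i, j]))
        return pd.DataFrame(rows, columns=[
            self.axis1_name, self.axis2_name, "error_mean_pct", "error_sd_pct",
            "se_error_mean_pct", "se_error_sd_pct", "mean_ssa", "mean_bl",
        ])


def _cell_params(fixed: dict, **axis_values) -> GeneParams:
    spec = dict(fixed)
    spec.update(axis_values)
    k_g, gamma_g = spec["k_g"], spec["gamma_g"]
    gamma_m, gamma_p = spec["gamma_m"], spec["gamma_p"]
    k_m = spec["k_m"] if "k_m" in spec else spec["b_m"] * (k_g + gamma_g)
    k_p = spec["k_p"] if "k_p" in spec else spec["b_p"] * gamma_m
    return GeneParams(k_g=k_g, gamma_g=gamma_g, k_m=k_m, gamma_m=gamma_m,
                      k_p=k_p, gamma_p=gamma_p,
                      n_copies=int(spec.get("n_copies", 1)))


def mean_error_grid(
    axis1: tuple[str, "list | np.ndarray"],
    axis2: tuple[str, "list | np.ndarray"],
    fixed_params: dict,
    n_points: int = 2000,
    seed_base: int = 0,
    regime: "Regime | None" = None,
    cfg: "StepConfig | None" = None,
    target_rel_se: float = 0.005,
    min_readouts: int = 1,
) -> ErrorGrid:
    """Scan two parameter axes and compare BL vs SSA steady-state statistics.

    Axis names may be rate constants (``k_g``) or burst sizes (``b_m``,
    ``b_p``; the matching rate is back-solved per cell).  Per-cell errors are
    ``100*(stat_BL - stat_SSA)/stat_SSA`` with jackknife SEs combined in
    quadrature.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    shape = (vals1.size, vals2.size)
    em = np.zeros(shape)
    es = np.zeros(shape)
    sem = np.zeros(shape)
    ses = np.zeros(shape)
    mb = np.zeros(shape)
    ms = np.zeros(shape)
    sb = np.zeros(shape)
    ss = np.zeros(shape)
    cell_seeds = K.spawn_seeds(seed_base, 2 * shape[0] * shape[1]).reshape(
        shape[0], shape[1], 2
    )
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            params = _cell_params(fixed_params, **{name1: v1, name2: v2})
            k = max(readouts_for_target_se(params, n_points, target_rel_se),
                    min_readouts)
            common = dict(n_points=n_points, samples_per_point=k,
                          regime=regime, cfg=cfg, keep_samples=False)
            s_bl = ensemble_steady_state(
                "bl", params, seed_base=int(cell_seeds[i, j, 0]), **common)
            s_ssa = ensemble_steady_state(
                "ssa", params, seed_base=int(cell_seeds[i, j, 1]), **common)
            em[i, j] = 100.0 * (s_bl.mean - s_ssa.mean) / s_ssa.mean
            es[i, j] = 100.0 * (s_bl.sd - s_ssa.sd) / s_ssa.sd
            sem[i, j] = 100.0 * math.hypot(s_bl.stderr_mean, s_ssa.stderr_mean) / s_ssa.mean
            ses[i, j] = 100.0 * math.hypot(s_bl.stderr_sd, s_ssa.stderr_sd) / s_ssa.sd
            mb[i, j], ms[i, j] = s_bl.mean, s_ssa.mean
            sb[i, j], ss[i, j] = s_bl.sd, s_ssa.sd
    return ErrorGrid(name1, vals1, name2, vals2, em, es, sem, ses, mb, ms, sb, ss)


def grid_fig3(n_points: int = 2000, seed_base: int = 0, **kwargs) -> ErrorGrid:
    """Gene-activation-rate x protein-burst-size scan (k_m fixed at 100)."""
    fixed = {"gamma_g": 100.0, "gamma_m": 10.0, "gamma_p": 1.0, "k_m": 100.0}
    return mean_error_grid(
        ("k_g", [3.0, 10.0, 100.0]), ("b_p", [1.0, 10.0, 100.0]),
        fixed, n_points=n_points, seed_base=seed_base, **kwargs,
    )


def grid_fig5(n_points: int = 2000, seed_base: int = 0, **kwargs) -> ErrorGrid:
    """mRNA-burst-size x protein-burst-size scan at k_g = 5."""
    fixed = {"k_g": 5.0, "gamma_g": 100.0, "gamma_m": 10.0, "gamma_p": 1.0}
    return mean_error_grid(
        ("b_m", [1.0, 8.0, 30.0]), ("b_p", [1.0, 10.0, 100.0]),
        fixed, n_points=n_points, seed_base=seed_base, **kwargs,
    )


# ---------------------------------------------------------------------------
# network ensembles and grid
# ---------------------------------------------------------------------------

def _network_initial(net: RegulatedNetworkParams) -> tuple[int, int]:
    up, dn = net.upstream, net.downstream
    p1 = int(round(up.n_copies * up.k_g * up.b_m * up.b_p / up.gamma_p))
    bm2 = effective_downstream_burst_size(p1, net)
    p2 = int(round(dn.k_g * bm2 * dn.b_p / dn.gamma_p))
    return p1, p2


def network_ensemble(
    simulator: str,
    net: RegulatedNetworkParams,
    n_points: int = 2000,
    t_relax: "float | None" = None,
    samples_per_point: int = 1,
    sample_spacing: "float | None" = None,
    cfg: "StepConfig | None" = None,
    seed_base: int = 0,
) -> EnsembleSummary:
    """Steady-state ensemble of the downstream protein p2 (BL or SSA)."""
    if simulator not in ("ssa", "bl"):
        raise ValueError("simulator must be 'ssa' or 'bl'")
    up, dn = net.upstream, net.downstream
    cfg = cfg or StepConfig()
    t_relax = 20.0 / dn.gamma_p if t_relax is None else float(t_relax)
    spacing = 3.0 / dn.gamma_p if sample_spacing is None else float(sample_spacing)
    seeds = K.spawn_seeds(seed_base, n_points)
    p1_0, p2_0 = _network_initial(net)
    k = samples_per_point
    out = np.empty((n_points, k), dtype=np.int64)
    if simulator == "bl":
        times = t_relax + spacing * np.arange(k, dtype=float)
        scratch_p1 = np.empty(k, dtype=np.int64)
        args = (up.n_copies * up.k_g, up.b_m, up.b_p, up.gamma_p,
                dn.k_g, dn.gamma_g, dn.k_m, net.k_l, dn.b_p, dn.gamma_p,
                dn.n_copies, float(net.K), float(net.n_H))
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            st = K.bl_net_run(*args, p1_0, p2_0, 0, 0, K.BIG,
                              cfg.epsilon, cfg.n_critical, cfg.max_halvings,
                              times, scratch_p1, out[i])[-1]
            _check(st)
    else:
        g1_0 = int(round(up.g_bar))
        m1_0 = int(round(up.m_bar))
        g2_0 = int(round(dn.g_bar))
        bm2 = effective_downstream_burst_size(p1_0, net)
        m2_0 = int(round(dn.k_g * bm2 / dn.gamma_m))
        args = (up.k_g, up.gamma_g, up.k_m, up.gamma_m, up.k_p, up.gamma_p,
                up.n_copies,
                dn.k_g, dn.gamma_g, dn.k_m, dn.gamma_m, dn.k_p, dn.gamma_p,
                dn.n_copies, float(net.K), float(net.n_H), float(net.k_l))
        for i, s in enumerate(seeds):
            K.seed_rng(int(s))
            state = K.ssa_net_run(*args, g1_0, m1_0, p1_0, g2_0, m2_0, p2_0, t_relax)
            out[i, 0] = state[5]
            for j in range(1, k):
                state = K.ssa_net_run(*args, *state, spacing)
                out[i, j] = state[5]
    mean, sd, se_mean, se_sd = _jackknife(out)
    counts, edges = _histogram(out)
    return EnsembleSummary(
        n_points=n_points, samples_per_point=k, mean=mean, sd=sd,
        stderr_mean=se_mean, stderr_sd=se_sd, histogram=counts, bin_edges=edges,
        params={"upstream": up.__dict__.copy(), "downstream": dn.__dict__.copy(),
                "K": net.K, "n_H": net.n_H, "k_l": net.k_l},
        regime="network_both_bursts", seed_base=int(seed_base), samples=None,
    )


@dataclass
class NetworkGrid:
    b_m1_values: np.ndarray
    b_p1_values: np.ndarray
    mean_p2_bl: np.ndarray
    mean_p2_ssa: np.ndarray
    error_mean: np.ndarray  # signed %
    se_error_mean: np.ndarray


def network_mean_grid(
    base_net: RegulatedNetworkParams,
    b_m1_values=(1.0, 8.0, 30.0),
    b_p1_values=(1.0, 10.0, 100.0),
    n_points: int = 2000,
    seed_base: int = 0,
    cfg: "StepConfig | None" = None,
    target_rel_se: float = 0.005,
    min_readouts: int = 1,
) -> NetworkGrid:
    """Scan upstream burst sizes; compare downstream mean p2, BL vs SSA."""
    b_m1_values = np.asarray(b_m1_values, dtype=float)
    b_p1_values = np.asarray(b_p1_values, dtype=float)
    shape = (b_m1_values.size, b_p1_values.size)
    mb = np.zeros(shape)
    ms = np.zeros(shape)
    em = np.zeros(shape)
    sem = np.zeros(shape)
    cell_seeds = K.spawn_seeds(seed_base, 2 * shape[0] * shape[1]).reshape(
        shape[0], shape[1], 2
    )
    up0 = base_net.upstream
    for i, bm1 in enumerate(b_m1_values):
        for j, bp1 in enumerate(b_p1_values):
            up = GeneParams.from_burst_sizes(
                k_g=up0.k_g, gamma_g=up0.gamma_g, gamma_m=up0.gamma_m,
                gamma_p=up0.gamma_p, b_m=bm1, b_p=bp1, n_copies=up0.n_copies,
            )
            net = RegulatedNetworkParams(
                upstream=up, downstream=base_net.downstream,
                K=base_net.K, n_H=base_net.n_H, k_l=base_net.k_l,
            )
            # readouts sized on the upstream CV (the slow, noisy species)
            k = max(readouts_for_target_se(up, n_points, target_rel_se),
                    min_readouts)
            s_bl = network_ensemble("bl", net, n_points=n_points,
                                    samples_per_point=k, cfg=cfg,
                                    seed_base=int(cell_seeds[i, j, 0]))
            s_ssa = network_ensemble("ssa", net, n_points=n_points,
                                     samples_per_point=k, cfg=cfg,
                                     seed_base=int(cell_seeds[i, j, 1]))
            mb[i, j], ms[i, j] = s_bl.mean, s_ssa.mean
            em[i, j] = 100.0 * (s_bl.mean - s_ssa.mean) / s_ssa.mean
            sem[i, j] = 100.0 * math.hypot(s_bl.stderr_mean, s_ssa.stderr_mean) / s_ssa.mean
    return NetworkGrid(b_m1_values, b_p1_values, mb, ms, em, sem)


# ---------------------------------------------------------------------------
# switching dynamics
# ---------------------------------------------------------------------------

def switching_dynamics(
    params: GeneParams,
    kg_schedule: "list[tuple[float, float]]",
    t_end: float,
    n_trajectories: int = 2000,
    sample_grid=None,
    seed_base: int = 0,
    cfg: "StepConfig | None" = None,
    regime: "Regime | None" = None,
    burn_in: "float | None" = None,
) -> pd.DataFrame:
    """Ensemble mean +- SD over time for BL and SSA under a k_g(t) schedule.

    ``kg_schedule`` lists ``(switch_time, new_k_g)`` pairs; before the first
    switch the gene runs at ``params.k_g``.  Both simulators re-read k_g (and
    the k_g-dependent mRNA burst size) at every schedule boundary.  Each
    trajectory is first equilibrated at the initial k_g for ``burn_in``
    (default 10 protein lifetimes) before the schedule clock starts, so t=0
    corresponds to the pre-switch steady state.  Returns a tidy frame with
    columns time, mean_bl, sd_bl, mean_ssa, sd_ssa.
    """
    cfg = cfg or StepConfig()
    regime = _as_regime(regime) if regime is not None else classify_regime(params).label
    if regime is not Regime.BOTH_BURSTS:
        raise NotImplementedError("switching dynamics driver supports BOTH_BURSTS mode")
    if sample_grid is None:
        sample_grid = np.linspace(t_end / 100.0, t_end, 100)
    grid = np.asarray(sample_grid, dtype=float)
    switches = sorted(kg_schedule)
    seeds = K.spawn_seeds(seed_base, 2 * n_trajectories).reshape(n_trajectories, 2)

    def kg_at(t: float) -> float:
        kg = params.k_g
        for ts, val in switches:
            if t >= ts:
                kg = val
        return kg

    g0, m0, p0 = deterministic_initial(params)
    bp = params.b_p
    gm, gp = params.gamma_m, params.gamma_p
    burn = 10.0 / gp if burn_in is None else float(burn_in)
    bl = np.empty((n_trajectories, grid.size), dtype=np.int64)
    sa = np.empty((n_trajectories, grid.size), dtype=np.int64)

    def bm_at(kg: float) -> float:
        # the mRNA burst size tracks the current activation rate
        return params.k_m / (kg + params.gamma_g)

    # constant-k_g windows; BL samples use last-commit hold inside each window
    bounds = [0.0] + [ts for ts, _ in switches if 0.0 < ts < t_end] + [t_end]
    windows = []  # (start, end, kg, sample_times_rel, sample_indices)
    for w0, w1 in zip(bounds[:-1], bounds[1:]):
        mask = (grid > w0) & (grid <= w1)
        windows.append((w0, w1, kg_at(w0), grid[mask] - w0, np.where(mask)[0]))

    none = np.empty(0, dtype=float)
    none_out = np.empty(0, dtype=np.int64)
    for r in range(n_trajectories):
        # burst Langevin trajectory
        K.seed_rng(int(seeds[r, 0]))
        p, dp = p0, 0
        if burn > 0:
            p, dp, st = K.bl_both_run(params.n_copies * params.k_g,
                                      bm_at(params.k_g), bp, gp, p, dp, burn,
                                      cfg.epsilon, cfg.n_critical,
                                      cfg.max_halvings, none, none_out)
            _check(st)
        for w0, w1, kg, times, idx in windows:
            out = np.empty(times.size, dtype=np.int64)
            p, dp, st = K.bl_both_run(params.n_copies * kg, bm_at(kg), bp, gp,
                                      p, dp, w1 - w0, cfg.epsilon,
                                      cfg.n_critical, cfg.max_halvings,
                                      times, out)
            _check(st)
            bl[r, idx] = out
        # SSA trajectory
        K.seed_rng(int(seeds[r, 1]))
        g, m, p = g0, m0, p0
        if burn > 0:
            g, m, p = K.ssa_run(params.k_g, params.gamma_g, params.k_m, gm,
                                params.k_p, gp, params.n_copies, g, m, p, burn)
        for w0, w1, kg, times, idx in windows:
            t_prev = 0.0
            for j, tq in zip(idx, times):
                g, m, p = K.ssa_run(kg, params.gamma_g, params.k_m, gm,
                                    params.k_p, gp, params.n_copies,
                                    g, m, p, tq - t_prev)
                sa[r, j] = p
                t_prev = tq
            if w1 - w0 > t_prev:
                g, m, p = K.ssa_run(kg, params.gamma_g, params.k_m, gm,
                                    params.k_p, gp, params.n_copies,
                                    g, m, p, w1 - w0 - t_prev)
    return pd.DataFrame({
        "time": grid,
        "mean_bl": bl.mean(axis=0),
        "sd_bl": bl.std(axis=0, ddof=1),
        "mean_ssa": sa.mean(axis=0),
        "sd_ssa": sa.std(axis=0, ddof=1),
    })


# ---------------------------------------------------------------------------
# distribution overlays
# ---------------------------------------------------------------------------

@dataclass
class OverlayResult:
    total_variation: float
    modes_a: np.ndarray
    modes_b: np.ndarray
    bin_centers: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray


def _modes(density: np.ndarray, centers: np.ndarray, smooth: int) -> np.ndarray:
    sm = uniform_filter1d(density, size=max(smooth, 1), mode="constant")
    padded = np.concatenate(([0.0], sm, [0.0]))
    peaks, _ = find_peaks(padded, prominence=0.05 * padded.max())
    return centers[peaks - 1]


def distribution_overlay(
    summary_a: EnsembleSummary, summary_b: EnsembleSummary, smooth: "int | None" = None
) -> OverlayResult:
    """Align two ensemble histograms; report TV distance and mode locations.

    Summaries must come from the same parameterization.  Histograms are
    re-binned onto a common integer grid; the total-variation distance is
    ``0.5 * sum |p_i - q_i|`` over the normalized densities; modes are peaks
    of the lightly smoothed densities.
    """
    if summary_a.params != summary_b.params:
        raise ValueError("overlay requires summaries from identical parameters")
    sa = summary_a.samples
    sb = summary_b.samples
    if sa is None or sb is None:
        raise ValueError("overlay requires summaries built with keep_samples=True")
    hi = int(max(sa.max(), sb.max()))
    edges = np.arange(-0.5, hi + 1.5)
    da, _ = np.histogram(sa, bins=edges, density=False)
    db, _ = np.histogram(sb, bins=edges, density=False)
    pa = da / da.sum()
    pb = db / db.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth is None:
        smooth = max(3, hi // 50)
    return OverlayResult(
        total_variation=0.5 * float(np.abs(pa - pb).sum()),
        modes_a=_modes(pa, centers, smooth),
        modes_b=_modes(pb, centers, smooth),
        bin_centers=centers,
        density_a=pa,
        density_b=pb,
    )
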
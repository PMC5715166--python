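"""Exact stochastic simulation (Gillespie direct method) of gene expression.

Ground-truth oracle for the burst Langevin scheme: the full three-species
telegraph model is simulated event by event over its six reaction channels
(gene on/off, transcription, mRNA decay, translation, protein decay), and the
two-gene repression network over twelve.  Waiting times are exponential in
the total propensity and the firing channel is chosen proportionally to its
propensity, so trajectories follow the exact chemical master equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .model_core import GeneParams

__all__ = ["Trajectory", "ssa_simulate", "ssa_simulate_network", "deterministic_initial"]


@dataclass
class Trajectory:
    """A sampled stochastic trajectory plus the metadata to reproduce it."""

    times: np.ndarray
    states: pd.DataFrame
    seed: int
    params: dict
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        """Write times+states as TSV with a JSON metadata sidecar."""
        import json

        out = self.states.copy()
        out.insert(0, "time", self.times)
        out.to_csv(path, sep="\t", index=False)
        sidecar = {"seed": int(self.seed), "params": self.params, **self.meta}
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def deterministic_initial(params: GeneParams) -> tuple[int, int, int]:
    """Rounded deterministic fixed point (g, m, p) used to start burn-in."""
    g0 = int(round(params.g_bar))
    m0 = int(round(params.m_bar))
    p0 = int(round(params.p_bar))
    return g0, m0, p0


def _initial_tuple(initial, params: GeneParams) -> tuple[int, int, int]:
    if initial is None:
        return deterministic_initial(params)
    if hasattr(initial, "g"):
        return int(initial.g), int(initial.m), int(initial.p)
    g, m, p = initial
    return int(g), int(m), int(p)


def ssa_simulate(
    params: GeneParams,
    t_end: float,
    initial=None,
    seed: int = 0,
    sample_grid=None,
    max_events: int = 2_000_000,
) -> Trajectory:
    """Exact SSA of a single gene up to ``t_end``.

    With ``sample_grid`` given, the state is recorded at those times
    (last-event hold); otherwise every reaction event is recorded (bounded by
    ``max_events``).  A state with zero total propensity is absorbing: the
    trajectory is held constant to ``t_end``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    g, m, p = _initial_tuple(initial, params)
    if min(g, m, p) < 0 or g > params.n_copies:
        raise ValueError("initial counts must be non-negative with g <= n_copies")
    K.seed_rng(int(seed))
    kg, gg, km, gm, kp, gp = (
        params.k_g, params.gamma_g, params.k_m,
        params.gamma_m, params.k_p, params.gamma_p,
    )
    if sample_grid is not None:
        grid = np.asarray(sample_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("sample_grid times must be strictly increasing")
        rows = np.empty((grid.size, 3), dtype=np.int64)
        t_prev = 0.0
        for i, tq in enumerate(grid):
            g, m, p = K.ssa_run(kg, gg, km, gm, kp, gp, params.n_copies,
                                g, m, p, tq - t_prev)
            rows[i] = (g, m, p)
            t_prev = tq
        if t_end > t_prev:
            g, m, p = K.ssa_run(kg, gg, km, gm, kp, gp, params.n_copies,
                                g, m, p, t_end - t_prev)
        times = grid
        states = pd.DataFrame(rows, columns=["g", "m", "p"])
    else:
        times_list = [0.0]
        rows = [(g, m, p)]
        rng = np.random.default_rng(int(seed))
        t = 0.0
        # event-resolved loop in python (used on small systems only)
        while len(times_list) < max_events:
            a = np.array([
                kg * (params.n_copies - g), gg * g, km * g, gm * m, kp * m, gp * p,
            ])
            a0 = a.sum()
            if a0 <= 0:
                break
            t += float(rng.exponential(1.0 / a0))
            if t >= t_end:
                break
            ch = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
            dg, dm, dp = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                          (0, -1, 0), (0, 0, 1), (0, 0, -1)][ch]
            g, m, p = g + dg, m + dm, p + dp
            times_list.append(t)
            rows.append((g, m, p))
        else:
            raise RuntimeError("event cap exceeded; pass a sample_grid instead")
        times = np.array(times_list)
        states = pd.DataFrame(rows, columns=["g", "m", "p"])
    return Trajectory(
        times=times,
        states=states,
        seed=int(seed),
        params=params.__dict__.copy(),
        meta={"simulator": "ssa", "t_end": t_end},
    )


def ssa_simulate_network(
    net,
    t_end: float,
    initial=None,
    seed: int = 0,
    sample_grid=None,
) -> Trajectory:
    """Exact SSA of the two-gene repression network (twelve channels).

    ``net`` is a :class:`~burstlangevin.regulation.RegulatedNetworkParams`.
    State is recorded on ``sample_grid`` (default: 201 evenly spaced times).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    up, dn = net.upstream, net.downstream
    if initial is None:
        g1, m1, p1 = deterministic_initial(up)
        g2, m2, p2 = 0, 0, 0
    else:
        g1, m1, p1, g2, m2, p2 = (int(v) for v in initial)
    if sample_grid is None:
        sample_grid = np.linspace(t_end / 200.0, t_end, 200)
    grid = np.asarray(sample_grid, dtype=float)
    K.seed_rng(int(seed))
    rows = np.empty((grid.size, 6), dtype=np.int64)
    t_prev = 0.0
    for i, tq in enumerate(grid):
        g1, m1, p1, g2, m2, p2 = K.ssa_net_run(
            up.k_g, up.gamma_g, up.k_m, up.gamma_m, up.k_p, up.gamma_p, up.n_copies,
            dn.k_g, dn.gamma_g, dn.k_m, dn.gamma_m, dn.k_p, dn.gamma_p, dn.n_copies,
            float(net.K), float(net.n_H), float(net.k_l),
            g1, m1, p1, g2, m2, p2, tq - t_prev,
        )
        rows[i] = (g1, m1, p1, g2, m2, p2)
        t_prev = tq
    states = pd.DataFrame(rows, columns=["g1", "m1", "p1", "g2", "m2", "p2"])
    return Trajectory(
        times=grid,
        states=states,
        seed=int(seed),
        params={"upstream": up.__dict__.copy(), "downstream": dn.__dict__.copy(),
                "K": net.K, "n_H": net.n_H, "k_l": net.k_l},
        meta={"simulator": "ssa_network", "t_end": t_end},
    )
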
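"""Two-gene network: downstream transcription repressed by the upstream protein.

The upstream gene expresses protein ``p1`` following the standard telegraph
model; the downstream gene's transcription rate is modulated by ``p1``
through a Hill function with threshold ``K`` and cooperativity ``n_H``
(negative ``n_H`` encodes activation), plus a leak rate ``k_l``:

    transcription propensity (active downstream gene) = k_m2 * K^n/(K^n + p1^n) + k_l

The leak is a transcription rate added to the Hill-modulated rate *before*
burst-size conversion, so the effective downstream mRNA burst size is
``(k_m2*Hill + k_l)/(k_g2 + gamma_g2)``.  Both the exact SSA and the burst
Langevin simulator use this identical convention, so it cancels in all
error comparisons between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .gillespie import Trajectory, deterministic_initial, ssa_simulate_network
from .langevin import StepConfig
from .model_core import GeneParams, Regime, _as_regime

__all__ = [
    "RegulatedNetworkParams",
    "hill_fraction",
    "downstream_transcription_rate",
    "effective_downstream_burst_size",
    "network_bl_simulate",
]


@dataclass(frozen=True)
class RegulatedNetworkParams:
    upstream: GeneParams
    downstream: GeneParams
    K: float
    n_H: float
    k_l: float = 0.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be strictly positive")
        if self.k_l < 0:
            raise ValueError("k_l must be non-negative")


def hill_fraction(p1: float, K: float, n_H: float) -> float:
    """Hill occupancy ``K^n/(K^n + p1^n)``.

    Repression (``n_H > 0``): monotone decreasing in p1, 1 at p1=0, 1/2 at
    p1=K.  Activation (``n_H < 0``): 0 at p1=0 by continuous limit.  With
    ``n_H = 0`` the factor is identically 1/2.
    """
    if p1 < 0:
        raise ValueError("p1 must be non-negative")
    return float(K_hill(float(p1), float(K), float(n_H)))


# direct alias onto the jit kernel so SSA/Langevin/python all share one formula
K_hill = K._hill


def downstream_transcription_rate(g2: int, p1: float, net: RegulatedNetworkParams) -> float:
    """Effective downstream transcription propensity ``g2*(k_m2*Hill + k_l)``."""
    if g2 not in range(net.downstream.n_copies + 1):
        raise ValueError("g2 must lie in {0,...,n_copies}")
    dn = net.downstream
    return g2 * (dn.k_m * hill_fraction(p1, net.K, net.n_H) + net.k_l)


def effective_downstream_burst_size(p1: float, net: RegulatedNetworkParams) -> float:
    """Effective mRNA burst size of the repressed gene at a given p1."""
    dn = net.downstream
    return (
        dn.n_copies
        * (dn.k_m * hill_fraction(p1, net.K, net.n_H) + net.k_l)
        / (dn.k_g + dn.gamma_g)
    )


def network_bl_simulate(
    net: RegulatedNetworkParams,
    regimes: "tuple | None" = None,
    t_end: float = 10.0,
    initial=None,
    cfg: "StepConfig | None" = None,
    sample_grid=None,
    seed: int = 0,
) -> Trajectory:
    """Coupled burst-Langevin simulation of the repression network.

    Both genes are propagated in BOTH_BURSTS mode (only p1 and p2 tracked)
    with a shared adaptive step ``tau = min(tau_upstream, tau_downstream)``;
    the downstream burst production moments are recomputed each step from the
    current p1.  Other per-gene regime combinations are not supported.
    """
    if regimes is not None:
        labels = tuple(_as_regime(r) for r in regimes)
        if any(lab is not Regime.BOTH_BURSTS for lab in labels):
            raise NotImplementedError(
                "network burst-Langevin supports BOTH_BURSTS mode for both genes"
            )
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    cfg = cfg or StepConfig()
    up, dn = net.upstream, net.downstream
    if initial is None:
        _, _, p1 = deterministic_initial(up)
        p2 = 0
    else:
        p1, p2 = (int(v) for v in initial)
    if sample_grid is None:
        sample_grid = np.linspace(t_end / 200.0, t_end, 200)
    grid = np.asarray(sample_grid, dtype=float)
    K.seed_rng(int(seed))
    out_p1 = np.empty(grid.size, dtype=np.int64)
    out_p2 = np.empty(grid.size, dtype=np.int64)
    status = K.bl_net_run(
        up.n_copies * up.k_g, up.b_m, up.b_p, up.gamma_p,
        dn.k_g, dn.gamma_g, dn.k_m, net.k_l, dn.b_p, dn.gamma_p, dn.n_copies,
        float(net.K), float(net.n_H),
        p1, p2, 0, 0, K.BIG,
        cfg.epsilon, cfg.n_critical, cfg.max_halvings,
        grid, out_p1, out_p2,
    )[-1]
    if status != 0:
        raise RuntimeError("half-tau retry limit exceeded in network simulation")
    states = pd.DataFrame(
        {
            "g1": np.nan, "m1": np.nan, "p1": out_p1,
            "g2": np.nan, "m2": np.nan, "p2": out_p2,
        }
    )
    return Trajectory(
        times=grid,
        states=states,
        seed=int(seed),
        params={"upstream": up.__dict__.copy(), "downstream": dn.__dict__.copy(),
                "K": net.K, "n_H": net.n_H, "k_l": net.k_l},
        meta={"simulator": "burst_langevin_network", "t_end": t_end},
    )


# re-exported here so network users get the exact reference from one place
__all__.append("ssa_simulate_network")
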
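"""Closed-form statistics for the telegraph gene-expression model with bursts.

The model is the standard three-stage description of gene expression: a gene
promoter switches between an inactive and an active state with rates ``k_g``
(activation) and ``gamma_g`` (deactivation); the active gene transcribes mRNA
at rate ``k_m``; mRNA degrades at rate ``gamma_m`` and is translated at rate
``k_p`` per transcript; protein degrades at rate ``gamma_p``.  When the active
promoter state is short-lived (``gamma_g >> gamma_m``) mRNA appears in
geometric bursts of mean size ``b_m = k_m/(k_g + gamma_g)``; when mRNA is
short-lived (``gamma_m >> gamma_p``) protein appears in geometric bursts of
mean size ``b_p = k_p/gamma_m``.

This module holds everything that can be written down in closed form:

* burst sizes, burst frequencies and their variances,
* the mean/variance of burst production accumulated over a Langevin step
  ``tau`` (compound Poisson-geometric statistics) for each burst regime,
* steady-state means and variances, both the exact linear-noise-approximation
  (LNA) expressions and the burst approximations used by the Langevin scheme,
* the analytic error map comparing the two variance flavours,
* the probability that a Gaussian production draw rounds to a negative
  integer (the artifact the negative-production accumulator removes).

Rates are in reciprocal time units; molecule numbers are dimensionless counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GeneParams",
    "BurstStatistics",
    "Regime",
    "RegimeInfo",
    "ProductionMoments",
    "MomentFlavor",
    "SteadyStateMoments",
    "burst_statistics",
    "burst_size_mrna_legacy",
    "classify_regime",
    "production_moments",
    "compose_burst_variance",
    "steady_state_moments",
    "sd_error_percent",
    "variance_error_map",
    "negative_production_fraction",
]


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneParams:
    """Kinetic constants of a single gene (all rates strictly positive).

    Parameters
    ----------
    k_g, gamma_g
        Promoter activation / deactivation rates.
    k_m, gamma_m
        Transcription rate from the active promoter; mRNA degradation rate.
    k_p, gamma_p
        Translation rate per mRNA; protein degradation rate.
    n_copies
        Gene copy number (the activation propensity is ``k_g * (n - g)``).
    """

    k_g: float
    gamma_g: float
    k_m: float
    gamma_m: float
    k_p: float
    gamma_p: float
    n_copies: int = 1

    def __post_init__(self) -> None:
        for name in ("k_g", "gamma_g", "gamma_m", "gamma_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # k_m and k_p may be zero (silenced transcription/translation) which
        # is useful for degenerate checks; negative rates are never valid.
        for name in ("k_m", "k_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_copies < 1 or int(self.n_copies) != self.n_copies:
            raise ValueError("n_copies must be an integer >= 1")

    # -- convenience accessors used all over the package -------------------
    @property
    def g_bar(self) -> float:
        """Mean number of active gene copies, n*k_g/(k_g+gamma_g)."""
        return self.n_copies * self.k_g / (self.k_g + self.gamma_g)

    @property
    def b_m(self) -> float:
        """Mean mRNA burst size k_m/(k_g+gamma_g)."""
        return self.k_m / (self.k_g + self.gamma_g)

    @property
    def b_p(self) -> float:
        """Mean protein burst size k_p/gamma_m."""
        return self.k_p / self.gamma_m

    @property
    def b_p0(self) -> float:
        """Finite-lifetime protein burst size k_p/(gamma_m+gamma_p)."""
        return self.k_p / (self.gamma_m + self.gamma_p)

    @property
    def m_bar(self) -> float:
        return self.g_bar * self.k_m / self.gamma_m

    @property
    def p_bar(self) -> float:
        return self.m_bar * self.k_p / self.gamma_p

    @classmethod
    def from_burst_sizes(
        cls,
        k_g: float,
        gamma_g: float,
        gamma_m: float,
        gamma_p: float,
        b_m: float,
        b_p: float,
        n_copies: int = 1,
    ) -> "GeneParams":
        """Back-solve k_m and k_p from target burst sizes.

        ``k_m = b_m * (k_g + gamma_g)`` and ``k_p = b_p * gamma_m``, the
        inversion used throughout the parameter scans.
        """
        return cls(
            k_g=k_g,
            gamma_g=gamma_g,
            k_m=b_m * (k_g + gamma_g),
            gamma_m=gamma_m,
            k_p=b_p * gamma_m,
            gamma_p=gamma_p,
            n_copies=n_copies,
        )


def burst_size_mrna_legacy(params: GeneParams) -> float:
    """Legacy mRNA burst size k_m/gamma_g (small-k_g limit).

    Exposed for comparison only; every computation in this package uses the
    k_m/(k_g+gamma_g) definition, which keeps the kinetic identity
    m_bar = k_g*b_m/gamma_m exact for any k_g.
    """
    return params.k_m / params.gamma_g


@dataclass(frozen=True)
class BurstStatistics:
    """Derived burst sizes, frequencies and their variances."""

    b_m_bar: float
    b_p_bar: float
    b_p0_bar: float
    q: float
    var_bm: float
    var_bp: float
    freq_m: float


def burst_statistics(params: GeneParams) -> BurstStatistics:
    """Burst sizes/frequencies implied by a parameter set.

    The mRNA burst size is geometric with stop probability
    ``q = 1/(1 + b_m)``; its variance is ``b_m^2 + b_m`` (and likewise for the
    protein burst size ``b_p``).  The mRNA burst frequency is ``n * k_g``.
    """
    b_m = params.b_m
    b_p = params.b_p
    return BurstStatistics(
        b_m_bar=b_m,
        b_p_bar=b_p,
        b_p0_bar=params.b_p0,
        q=1.0 / (1.0 + b_m),
        var_bm=b_m * b_m + b_m,
        var_bp=b_p * b_p + b_p,
        freq_m=params.n_copies * params.k_g,
    )


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

class Regime(enum.Enum):
    """Which species burst, decided by degradation-rate separation."""

    MRNA_BURST = "mrna_burst"
    PROTEIN_BURST = "protein_burst"
    BOTH_BURSTS = "both_bursts"
    NO_BURST = "no_burst"


@dataclass(frozen=True)
class RegimeInfo:
    label: Regime
    ratio_gm: float  # gamma_g / gamma_m
    ratio_mp: float  # gamma_m / gamma_p


def classify_regime(params: GeneParams, threshold: float = 10.0) -> RegimeInfo:
    """Classify the burst regime from rate-scale separation.

    mRNA bursts require ``gamma_g >= threshold * gamma_m``; protein bursts
    require ``gamma_m >= threshold * gamma_p``.  Equality counts as bursting.
    The default threshold of 10 is the separation the analytic error maps are
    drawn with.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    ratio_gm = params.gamma_g / params.gamma_m
    ratio_mp = params.gamma_m / params.gamma_p
    mrna = ratio_gm >= threshold
    prot = ratio_mp >= threshold
    if mrna and prot:
        label = Regime.BOTH_BURSTS
    elif mrna:
        label = Regime.MRNA_BURST
    elif prot:
        label = Regime.PROTEIN_BURST
    else:
        label = Regime.NO_BURST
    return RegimeInfo(label=label, ratio_gm=ratio_gm, ratio_mp=ratio_mp)


def _as_regime(regime: "Regime | RegimeInfo | None") -> "Regime | None":
    if regime is None:
        return None
    if isinstance(regime, RegimeInfo):
        return regime.label
    return Regime(regime)


# ---------------------------------------------------------------------------
# production moments over a Langevin step tau
# ---------------------------------------------------------------------------

def compose_burst_variance(
    e_bar: float, var_e: float, b_bar: float, var_b: float
) -> float:
    """Variance of a compound sum of ``e`` bursts of independent sizes ``b``.

    ``Var = e_bar * var_b + var_e * b_bar**2`` -- the law of total variance
    for sum_{l=1}^{e} b_l with events and sizes independent.
    """
    if min(e_bar, var_e, b_bar, var_b) < 0:
        raise ValueError("all compound-variance arguments must be >= 0")
    return e_bar * var_b + var_e * b_bar * b_bar


@dataclass(frozen=True)
class ProductionMoments:
    """Mean/variance of production accumulated over one step tau."""

    delta: float
    var: float
    e_bar: float
    var_e: float


def production_moments(
    regime: "Regime | RegimeInfo",
    params: GeneParams,
    tau: float,
    g: "int | None" = None,
    rate: "float | None" = None,
) -> ProductionMoments:
    """Production moments of the bursting species over a step ``tau``.

    Per regime (the species whose production the moments describe):

    * ``MRNA_BURST`` (y = mRNA): Poisson burst events at frequency ``n*k_g``,
      geometric sizes ``b_m`` -> Delta = n*k_g*tau*b_m,
      var = n*k_g*tau*b_m*(2*b_m+1).
    * ``BOTH_BURSTS`` (y = protein): protein burst events inherit the mRNA
      production statistics -> Delta = n*k_g*b_m*b_p*tau,
      var = n*k_g*b_m*tau*b_p*(2*b_m*b_p + 2*b_p + 1).
    * ``PROTEIN_BURST`` (y = protein, gene state ``g`` required): Poisson
      events at rate ``g*k_m`` -> Delta = g*k_m*tau*b_p,
      var = g*k_m*tau*b_p*(2*b_p+1).
    * ``NO_BURST``: plain chemical-Langevin moments Delta = rate*tau,
      var = rate*tau for a single channel; ``rate`` defaults to the mean-field
      protein production rate ``k_p*m_bar``.
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    label = _as_regime(regime)
    stats = burst_statistics(params)
    n = params.n_copies
    if label is Regime.MRNA_BURST:
        e_bar = n * params.k_g * tau
        var_e = e_bar
        var = compose_burst_variance(e_bar, var_e, stats.b_m_bar, stats.var_bm)
        return ProductionMoments(e_bar * stats.b_m_bar, var, e_bar, var_e)
    if label is Regime.BOTH_BURSTS:
        e_bar = n * params.k_g * stats.b_m_bar * tau
        var_e = n * params.k_g * stats.b_m_bar * tau * (2.0 * stats.b_m_bar + 1.0)
        var = compose_burst_variance(e_bar, var_e, stats.b_p_bar, stats.var_bp)
        return ProductionMoments(e_bar * stats.b_p_bar, var, e_bar, var_e)
    if label is Regime.PROTEIN_BURST:
        if g is None:
            raise ValueError("PROTEIN_BURST production moments need the gene state g")
        if g < 0 or g > n:
            raise ValueError("gene state g must lie in {0,...,n_copies}")
        e_bar = g * params.k_m * tau
        var_e = e_bar
        var = compose_burst_variance(e_bar, var_e, stats.b_p_bar, stats.var_bp)
        return ProductionMoments(e_bar * stats.b_p_bar, var, e_bar, var_e)
    # NO_BURST: one ordinary CLE channel.
    a = params.k_p * params.m_bar if rate is None else rate
    return ProductionMoments(a * tau, a * tau, a * tau, a * tau)


# ---------------------------------------------------------------------------
# steady-state moments: exact LNA vs burst approximations
# ---------------------------------------------------------------------------

class MomentFlavor(enum.Enum):
    LNA_EXACT = "lna_exact"
    BURST_APPROX = "burst_approx"


@dataclass(frozen=True)
class SteadyStateMoments:
    m_bar: float
    p_bar: float
    var_m: float
    var_p: float
    flavor: MomentFlavor
    F0: float
    F1: float
    F2: float


def _fractions(params: GeneParams) -> tuple[float, float, float]:
    kg, gg = params.k_g, params.gamma_g
    gm, gp = params.gamma_m, params.gamma_p
    F0 = gg * (gg + gm + gp + kg) / ((gg + gm + kg) * (gg + gp + kg))
    F1 = gg / (gg + gm + kg)
    F2 = gg / (gg + gp + kg)
    return F0, F1, F2


def steady_state_moments(
    params: GeneParams,
    flavor: "MomentFlavor | str" = MomentFlavor.LNA_EXACT,
    regime: "Regime | RegimeInfo | None" = None,
) -> SteadyStateMoments:
    """Analytic steady-state means and variances.

    The means are flavour-independent: ``m_bar = g_bar*k_m/gamma_m`` and
    ``p_bar = m_bar*k_p/gamma_p``.  The exact LNA variances are

        var_m = m_bar*(F1*b_m + 1)
        var_p = p_bar*(F0*b_m*b_p0 + b_p0 + 1)

    with the correction fractions F0, F1, F2 -> 1 as gamma_g -> inf.  The
    burst approximations drop the fractions the corresponding regime justifies:
    mRNA-burst uses var_p = p_bar*(b_m*b_p0 + b_p0 + 1); both-bursts uses
    p_bar*(b_m*b_p + b_p + 1); protein-burst keeps F2 and uses
    p_bar*(F2*b_m*b_p + b_p + 1).
    """
    flavor = MomentFlavor(flavor)
    label = _as_regime(regime)
    m_bar = params.m_bar
    p_bar = params.p_bar
    b_m, b_p, b_p0 = params.b_m, params.b_p, params.b_p0
    F0, F1, F2 = _fractions(params)
    var_m_lna = m_bar * (F1 * b_m + 1.0)
    var_p_lna = p_bar * (F0 * b_m * b_p0 + b_p0 + 1.0)
    if flavor is MomentFlavor.LNA_EXACT:
        var_m, var_p = var_m_lna, var_p_lna
    else:
        if label is None:
            raise ValueError("BURST_APPROX needs a regime")
        if label is Regime.NO_BURST:
            raise ValueError("no burst approximation exists for the NO_BURST regime")
        if label is Regime.MRNA_BURST:
            var_m = m_bar * (b_m + 1.0)
            var_p = p_bar * (b_m * b_p0 + b_p0 + 1.0)
        elif label is Regime.BOTH_BURSTS:
            var_m = m_bar * (b_m + 1.0)
            var_p = p_bar * (b_m * b_p + b_p + 1.0)
        else:  # PROTEIN_BURST: mRNA is not bursty, keep its LNA variance
            var_m = var_m_lna
            var_p = p_bar * (F2 * b_m * b_p + b_p + 1.0)
    return SteadyStateMoments(m_bar, p_bar, var_m, var_p, flavor, F0, F1, F2)


def sd_error_percent(params: GeneParams, regime: "Regime | RegimeInfo") -> float:
    """Signed % error of the burst-approximation protein SD vs the exact LNA SD.

    ``100*(sd_approx - sd_lna)/sd_lna``; zero for the NO_BURST regime, where
    no approximation is made.
    """
    label = _as_regime(regime)
    if label is Regime.NO_BURST:
        return 0.0
    lna = steady_state_moments(params, MomentFlavor.LNA_EXACT)
    approx = steady_state_moments(params, MomentFlavor.BURST_APPROX, label)
    sd_lna = math.sqrt(lna.var_p)
    return 100.0 * (math.sqrt(approx.var_p) - sd_lna) / sd_lna


def variance_error_map(
    gamma_g_values: "np.ndarray | None" = None,
    gamma_m_values: "np.ndarray | None" = None,
    k_g: float = 5.0,
    b_m: float = 2.0,
    b_p: float = 10.0,
    gamma_p: float = 1.0,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Analytic steady-state-SD error map over (gamma_g, gamma_m).

    At every grid point k_m and k_p are back-solved so the burst sizes stay
    fixed (k_m = b_m*(k_g+gamma_g), k_p = b_p*gamma_m), which also pins
    p_bar = k_g*b_m*b_p/gamma_p.  Each cell is classified into its regime and
    the regime-matched burst approximation is compared against the exact LNA
    SD.  NO_BURST cells report 0.

    Returns a long-form DataFrame with columns
    ``gamma_g, gamma_m, regime, error_percent``.  Default grid: 50x50
    logarithmic over gamma_g in [1, 1e3], gamma_m in [1, 1e2] (units of
    gamma_p).
    """
    if gamma_g_values is None:
        gamma_g_values = np.logspace(0, 3, 50) * gamma_p
    if gamma_m_values is None:
        gamma_m_values = np.logspace(0, 2, 50) * gamma_p
    rows = []
    for gm in np.asarray(gamma_m_values, dtype=float):
        for gg in np.asarray(gamma_g_values, dtype=float):
            params = GeneParams.from_burst_sizes(
                k_g=k_g, gamma_g=gg, gamma_m=gm, gamma_p=gamma_p, b_m=b_m, b_p=b_p
            )
            info = classify_regime(params, threshold)
            rows.append(
                (gg, gm, info.label.value, sd_error_percent(params, info))
            )
    return pd.DataFrame(rows, columns=["gamma_g", "gamma_m", "regime", "error_percent"])


def write_error_map_tsv(df: pd.DataFrame, path: str) -> None:
    """Serialize an error map in the package's TSV layout."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# negative-production probability
# ---------------------------------------------------------------------------

def negative_production_fraction(delta: float, sigma: float) -> float:
    """P[a Gaussian(delta, sigma) draw rounds to a negative integer].

    A draw rounds to <= -1 iff it is <= -0.5 (round half away from zero), so
    the probability is Phi((-0.5 - delta)/sigma).  This is the artifact the
    negative-production accumulator in the Langevin stepper removes.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    return float(norm.cdf((-0.5 - delta) / sigma))
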
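# Methods

## Model

A single gene is described by the telegraph three-stage model: the promoter
switches between an inactive and an active state with rates `k_g`
(activation) and `gamma_g` (deactivation); the active promoter transcribes
at rate `k_m`; mRNA degrades at `gamma_m` and is translated at `k_p` per
transcript; protein degrades at `gamma_p`.  All rates are reciprocal time;
we use the protein lifetime `1/gamma_p` as the natural time unit throughout
the bundled parameter sets.  An `n`-copy gene replaces the activation
propensity by `k_g (n - g)`.

Rate-scale separation defines four regimes, classified with a threshold of
10 (equality counts as bursting):

* mRNA bursts: `gamma_g >= 10 gamma_m` — the active state is short-lived,
  mRNA arrives in geometric bursts of mean `b_m = k_m/(k_g + gamma_g)` at
  frequency `k_g`.
* protein bursts: `gamma_m >= 10 gamma_p` — mRNA is short-lived, protein
  arrives in geometric bursts of mean `b_p = k_p/gamma_m` at the mRNA
  production rate.
* both / neither as the combinations of the above.

`b_m` uses the `k_m/(k_g + gamma_g)` definition rather than the small-`k_g`
form `k_m/gamma_g` (exposed separately as `burst_size_mrna_legacy`): only
the former keeps the kinetic identity `m_bar = k_g b_m / gamma_m` exact at
finite `k_g`.

## Burst production moments over a step

Production of the bursting species over a step `tau` is a compound sum of
burst events with independent sizes.  Means multiply
(`Delta = e_bar * b_bar`) and variances compose as

    sigma^2_Delta = e_bar * var(b) + var(e) * b_bar^2 .

Per regime (geometric sizes, `var(b) = b_bar^2 + b_bar`):

| regime   | e_bar            | var(e)                      | Delta                | sigma^2_Delta |
|----------|------------------|-----------------------------|----------------------|---------------|
| mRNA     | `k_g tau`        | `k_g tau`                   | `k_g tau b_m`        | `k_g tau b_m (2 b_m + 1)` |
| both     | `k_g b_m tau`    | `k_g b_m tau (2 b_m + 1)`   | `k_g b_m b_p tau`    | `k_g b_m tau b_p (2 b_m b_p + 2 b_p + 1)` |
| protein  | `g k_m tau`      | `g k_m tau`                 | `g k_m tau b_p`      | `g k_m tau b_p (2 b_p + 1)` |

With both bursts the protein burst-event count inherits the full mRNA
production variance, which is what couples the two burst layers.

## Steady-state moments

Means are `m_bar = g_bar k_m / gamma_m`, `p_bar = m_bar k_p / gamma_p` with
`g_bar = n k_g/(k_g + gamma_g)`.  The exact linear-noise-approximation (LNA)
variances are

    var_m = m_bar (F1 b_m + 1)
    var_p = p_bar (F0 b_m b_p0 + b_p0 + 1),     b_p0 = k_p/(gamma_m + gamma_p)

with correction fractions

    F0 = gamma_g (gamma_g + gamma_m + gamma_p + k_g)
         / ((gamma_g + gamma_m + k_g)(gamma_g + gamma_p + k_g))
    F1 = gamma_g / (gamma_g + gamma_m + k_g)
    F2 = gamma_g / (gamma_g + gamma_p + k_g)

all in (0, 1] and -> 1 as `gamma_g -> inf`.  The burst approximations drop
the fraction their regime justifies: mRNA-burst
`var_p = p_bar (b_m b_p0 + b_p0 + 1)`; both-bursts
`var_p = p_bar (b_m b_p + b_p + 1)`; protein-burst
`var_p = p_bar (F2 b_m b_p + b_p + 1)`.  The analytic error map evaluates
`100 (sd_approx - sd_lna)/sd_lna` over a logarithmic `(gamma_g, gamma_m)`
grid with `k_m`, `k_p` back-solved to hold `b_m`, `b_p` fixed; the grid
resolution (50x50 over `gamma_g in [1, 1e3]`, `gamma_m in [1, 1e2]`, units
of `gamma_p`) is this package's choice.  The error is invariant under
rescaling all six rates by a common factor, so the map depends only on
rate ratios.

## The burst Langevin stepper

Euler-Maruyama with integer states.  Per committed step:

1. **tau selection.**  The burst channel is bound by
   `max(eps*y, b_bar)/rate` — at high copy number the usual relative-change
   bound `eps*y`, at low copy number one whole average burst per step.
   Every other channel contributes the tau-leaping mean and variance bounds
   `max(eps*y, 1)/|mu|` and `max(eps*y, 1)^2/sigma^2` summed per species
   over non-critical channels.  `eps` defaults to 0.03, a common choice in tau-leaping practice.
2. **Critical reactions.**  Gene-switching channels are always critical;
   degradation of any species below `n_critical = 10` copies is critical.
   Critical channels are excluded from the leap; an exponential clock with
   the summed critical propensity competes with the leap and, when it wins,
   the step shortens to `tau_c`, the non-critical channels are still leaped
   over `tau_c`, and exactly one critical event fires (sampled
   proportionally to propensity).  Freezing the non-critical channels during
   `tau_c` instead would visibly bias production whenever critical events
   are frequent.  The burst-production channel is never classified critical:
   bursts are precisely what the whole-burst tau bound handles.
3. **Draws.**  Burst production `round(N(Delta, sigma_Delta))`, then the
   ordinary channels (degradation, and plain-CLE production where the
   regime tracks an upstream species), species m before p — the fixed order
   makes runs bit-reproducible from one seed.  Rounding is half away from
   zero, so a draw of exactly -0.5 becomes -1 (this convention defines the
   negative-production probability `Phi((-0.5 - Delta)/sigma)`).  All draws
   are integerized and states stay integer.  For an
   ordinary channel whose step mean `a*tau` is below 5 the exact Poisson
   count is drawn instead of the rounded Gaussian: rounding a Gaussian
   whose SD is below the integer grid loses the sub-half-integer mass
   (the bias scales as `e^(-2 pi^2 a tau)`) and we measured it inflating
   the protein-burst-regime mean by ~19% on a fast-switching gene, where
   the step-size cap makes degradation means of ~0.1 routine.  The burst
   channel keeps the Gaussian always — that approximation is the method
   under study, and its SD is far above the integer grid whenever bursts
   matter.
4. **Negative-production accumulator.**  A production draw that rounds
   negative is not applied; it is stored in a per-species deficit and the
   step's production is zero.  Later positive draws first fill the deficit;
   production fires once the balance turns positive.  Cumulative applied
   production plus the final deficit equals the cumulative raw draws, so the
   long-run production mean is preserved exactly.  The deficit persists
   across committed steps only (a retried step's draws are discarded
   wholesale).
5. **Half-tau retry.**  If any species would go negative after the committed
   update, all draws are discarded, tau is halved and everything is redrawn,
   up to `max_halvings = 20`; exceeding the limit is a hard error.  A
   critical event pushed beyond the halved horizon is dropped.  Splitting a
   step is distributionally consistent because every production and
   degradation moment is linear in tau.

Per regime the tracked state shrinks: both-bursts tracks `p` alone;
mRNA-burst tracks `(m, p)` with protein following plain CLE; protein-burst
tracks `(g, p)` with gene switching handled as critical events, so `g` is
piecewise constant within a step (tau is additionally capped at
`0.1/max(k_g, gamma_g)` to keep steps short against the switching
timescale); the no-burst regime is plain CLE on all three species — included
for completeness, though that regime is better served by the exact SSA.
The public `langevin_step` also offers the Bernoulli-switching contract
(`P(0->1) = k_g tau`, `P(1->0) = gamma_g tau`) for use without a critical
clock; the drivers disable it to avoid double-counting.

### Sampling convention (important)

The Langevin path is piecewise constant between commits, with each step's
production applied at the commit time.  Readouts use **last-commit hold**:
steps run naturally past a requested sample time and the state of the last
commit before it is recorded — the exact analogue of the SSA's last-event
hold.  Forcing a commit at the readout time would sample immediately after
a production lump and biases low-copy-number means upward by several
percent (we measured +7% at a mean of 5 before adopting the hold
convention; with it the bias is below the Monte-Carlo resolution of ~0.5%).
A truncated commit is still used where a rate constant changes mid-run
(schedule switches), which is harmless because step splitting is
distributionally exact.

## Exact reference simulator

Direct-method Gillespie over the six single-gene channels (twelve for the
two-gene network): exponential waiting times in the total propensity,
channel chosen proportionally.  A zero-propensity state is absorbing and
held to the end of the run.  Stationary statistics can come either from
many independent replicas read at a fixed time or from decorrelation-spaced
samples of longer runs; the drivers combine both (below).

## Two-gene repression network

The downstream gene's transcription propensity while active is
`k_m2 * K^n/(K^n + p1^n) + k_l`.  The leak `k_l` is a transcription rate
added to the Hill-modulated rate *before* burst-size conversion, i.e. the
effective downstream mRNA burst size is
`(k_m2*Hill + k_l)/(k_g2 + gamma_g2)`: with the bundled network parameters
this yields the fully-activated level `5 * (260/105) * 10 = 123.8` and a
basal level of `28.6` under saturating repression, matching the intended
operating points.  Reading the leak as a burst size instead would
contradict those levels by a factor of ~20.  Both SSA and Langevin use the
identical convention, so it cancels in every error comparison.  Negative
Hill coefficients encode activation (`Hill(0) = 0` by continuous limit);
`n_H = 0` degenerates to a constant factor 1/2, decoupling the genes.

The coupled Langevin driver supports both genes in both-bursts mode (the
regime of every bundled network parameterization), tracking only `(p1, p2)`
with a shared step `tau = min(tau_1, tau_2)` and the downstream burst
moments recomputed each step from the current `p1` (piecewise-constant
within the step; upstream noise enters only through the `p1` trajectory,
with no cross-covariance terms).  Other per-gene regime combinations raise
`NotImplementedError`.

## Ensemble protocol and error accounting

Steady-state comparisons use, per parameter cell, `n_points = 2000`
independent trajectories per simulator (distinct 31-bit seeds derived from
one base seed via a splittable seed sequence).  Each trajectory starts at
the rounded deterministic fixed point, burns in for `t_relax = 20/gamma_p`
(>= 20 protein lifetimes, far beyond the slowest relaxation of any bundled
parameter set, and enough to equilibrate the deficit accumulator), then is
read out `k` times at a spacing of `3/gamma_p` (correlation `e^-3 ~ 0.05`).
`k` is sized *before any simulation runs* from the analytic LNA coefficient
of variation to hit a requested relative standard error, and never adjusted
afterwards.  Standard errors of the mean and SD are delete-one-trajectory
jackknife estimates, so residual within-trajectory correlation cannot
understate them; mean/SD errors between simulators combine the two
jackknife SEs in quadrature.  A single-readout design would need five
times as many trajectories for the same resolution; a handful of
decorrelated readouts per trajectory gives it at a fraction of the burn-in
cost, which is what keeps the full validation within minutes on one CPU.

Distribution overlays re-bin both ensembles onto a common integer grid and
report the total-variation distance plus mode locations of the lightly
smoothed densities (uniform window, boundary-padded so a spike at zero
counts as a mode).

The switching-dynamics driver runs piecewise-constant `k_g(t)` schedules;
both simulators re-read `k_g` (and the `k_g`-dependent `b_m`) at each
boundary, and trajectories are pre-equilibrated at the initial `k_g` for
10 protein lifetimes so `t = 0` is the pre-switch steady state.

## Bundled parameter presets

`fig1`/`fig8` — the reference gene `k_g=5, gamma_g=95, k_m=200, gamma_m=10,
k_p=100, gamma_p=1` (`p_bar=100`, `b_m=2`, `b_p=10`; `fig8` carries the
showcase step `tau=0.03`, whose production draw is `N(3, 13.53)` with a
~40% negative-draw probability).  Note its `gamma_g/gamma_m = 9.5` sits
just below the strict regime threshold, so drivers pass
`Regime.BOTH_BURSTS` explicitly for it.  `fig3` — `k_g x b_p` scan at
`k_m=100`; `fig5` — `b_m x b_p` scan at `k_g=5`; `fig6` — the repression
network; `fig7` — the switching schedule `k_g: 3 -> 30 at t=7 -> 3 at
t=14`; `bimodal` — slow promoter `k_g=gamma_g=0.1, gamma_m=10, gamma_p=1`
with `k_m=20`, `b_p=10` chosen to separate the off (~0) and on (~200)
modes; the slow-switching condition fixes only the rate ratios, the
transcription scale is this package's choice.

## What the validation does and does not show

The comparisons certify the scheme against the *same* telegraph model
simulated exactly — intrinsic noise only, mass-action propensities,
exponential waiting times, one or two genes.  They do not probe extrinsic
noise, non-exponential promoter waiting times (chromatin/promoter states),
cell division, or resource competition between genes; for non-geometric
burst-size or non-Poisson event distributions the compound-variance
composition accepts arbitrary moments (`compose_burst_variance`), but no
bundled driver exercises that path.

## Known limitations

* Accuracy at very low copy number (`p_bar < ~3`) degrades as the Gaussian
  production draw departs from the underlying compound-Poisson law; this is
  inherent to any Langevin scheme.
* The SD of the both-bursts approximation exceeds the exact LNA by up to
  ~6.4% at the regime boundary (`gamma_g = 10 gamma_m`), and by more when
  `k_g` is comparable to `gamma_g` (where F0 is well below 1) — visible as
  SD errors up to ~15% at the `k_g = 100 = gamma_g` corner of the
  activation-rate scan.
* Euler-Maruyama only; no higher-order SDE integrators.
* No wall-clock benchmarking claims: runtimes depend on hardware and the
  numba compilation cache.
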
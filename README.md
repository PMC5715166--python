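# burstlangevin

Stochastic simulation of gene expression with transcriptional and
translational **bursts** folded directly into the chemical Langevin equation,
plus an exact Gillespie reference simulator, closed-form burst/LNA
steady-state statistics, a two-gene Hill-repression network, and the
experiment drivers that validate the scheme against the exact simulation.

## Who this is for

Modelers of gene regulatory circuits who need trajectory ensembles with
realistic copy-number noise but cannot afford event-by-event Gillespie
simulation.  When the gene's active state is short-lived, or mRNA is much
shorter-lived than protein, most reaction events belong to rapid bursts; the
burst Langevin equation integrates over them analytically and advances whole
bursts per step.

## The model and the method

The gene follows the telegraph three-stage model

    dg/dt = k_g (1 - g) - gamma_g g        (promoter on/off)
    dm/dt = k_m g       - gamma_m m        (transcription / mRNA decay)
    dp/dt = k_p m       - gamma_p p        (translation / protein decay)

with mean burst sizes b_m = k_m/(k_g + gamma_g) (geometric) and
b_p = k_p/gamma_m.  Over a Langevin step tau, burst production of a species
y is a compound sum of e_y Poisson-like burst events of geometric size, with

    Delta_y(tau)      = e_bar_y * b_bar_y
    sigma^2_Delta_y   = e_bar_y * var(b_y) + var(e_y) * b_bar_y^2

evaluated per regime (mRNA bursts only, protein bursts only, or both; e.g.
with both bursts Delta_p = k_g b_m b_p tau and
sigma^2 = k_g b_m tau b_p (2 b_m b_p + 2 b_p + 1)).  The update

    p(t+tau) = p(t) + round(N(Delta, sigma_Delta)) - round(N(gamma_p p tau, sqrt(gamma_p p tau)))

uses adaptive tau selection (one whole average burst allowed per step at low
copy number), critical-reaction interleaving for gene switching and
low-copy degradation, a half-tau retry on provisionally negative counts, and
a negative-production accumulator that stores Gaussian draws which round
negative and releases them against later draws, preserving the production
mean while keeping counts non-negative.

Closed-form steady-state variances are provided both from the exact linear
noise approximation (LNA) and from the regime-matched burst approximations,
e.g. sigma^2_p = p_bar (b_m b_p + b_p + 1) with both bursts.

## Worked example

```python
import burstlangevin as B

gene = B.GeneParams(k_g=5, gamma_g=95, k_m=200, gamma_m=10, k_p=100, gamma_p=1)
stats = B.burst_statistics(gene)
mom = B.steady_state_moments(gene)
print(f"b_m={stats.b_m_bar:.1f}  b_p={stats.b_p_bar:.1f}  p_bar={mom.p_bar:.1f}")

bl = B.ensemble_steady_state("bl", gene, regime=B.Regime.BOTH_BURSTS,
                             n_points=2000, samples_per_point=5, seed_base=11)
ssa = B.ensemble_steady_state("ssa", gene, n_points=2000,
                              samples_per_point=5, seed_base=12)
print(f"BL  mean={bl.mean:.1f} sd={bl.sd:.1f}")
print(f"SSA mean={ssa.mean:.1f} sd={ssa.sd:.1f}")
```

prints

```
b_m=2.0  b_p=10.0  p_bar=100.0
BL  mean=99.3 sd=50.8
SSA mean=100.5 sd=51.9
```

i.e. for this reference gene (mean protein 100, mRNA bursts of 2, protein
bursts of 10) the burst Langevin ensemble reproduces the exact simulator's
steady-state mean to ~1% and its standard deviation to ~2%, while tracking
only the protein instead of all three species.

A command-line interface mirrors the library:

```bash
burstlangevin simulate --preset fig1 --regime both_bursts --t-end 20 \
    --seed 1 --out traj.tsv
burstlangevin error-map --out map.tsv
burstlangevin compare --preset fig1 --n-points 2000 --seed 1 --out cmp.json
```

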
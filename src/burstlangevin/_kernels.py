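"""Numba-compiled inner loops shared by the simulator modules.

Everything here is an implementation detail: the public surfaces live in
``gillespie``, ``langevin`` and ``regulation``.  Kernels are written against
numba's global RNG; callers seed it once per trajectory via :func:`seed_rng`.
Draw order inside a Langevin step is fixed and documented: production first,
then degradation, species in m, p order, so a seed reproduces a run
bit-for-bit.

Sampling convention
-------------------
The burst-Langevin path is piecewise constant between committed steps, with
the step's production applied at the commit time.  Readouts therefore use
*last-commit hold*: steps run naturally past a sample time and the state of
the last commit before it is recorded (the analogue of the SSA's last-event
hold).  Forcing a commit exactly at a readout time would systematically
sample just after a production lump and bias low-copy means upward.  Each
``bl_*_run`` kernel takes a ``sample_times`` array (relative to the segment
start) and output buffers; with ``duration`` finite the final step is
truncated so the returned state sits exactly at ``duration`` (needed when a
rate constant changes there), otherwise the kernel stops once every sample
is recorded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e18  # sentinel duration: "run until all samples are recorded"

STATUS_OK = 0
STATUS_HALVINGS_EXCEEDED = 1


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one integer seed."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)).astype(np.int64)


NO_SAMPLES = np.empty(0, dtype=np.float64)


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _round_away(x):
    """Round half away from zero; -0.5 -> -1, matching the negative-draw rule."""
    if x >= 0.0:
        return np.int64(np.floor(x + 0.5))
    return np.int64(np.ceil(x - 0.5))


@njit(cache=True, inline="always")
def _count_draw(mu):
    """Integer event count for one ordinary (non-burst) channel over a step.

    Gaussian-with-rounding is the CLE limit and is unbiased only when its SD
    is well above the integer grid; below 5 expected events the exact
    Poisson count is drawn instead (rounding a narrow Gaussian loses the
    sub-half-integer probability mass and biases the channel low).
    """
    if mu <= 0.0:
        return np.int64(0)
    if mu < 5.0:
        return np.int64(np.random.poisson(mu))
    return _round_away(np.random.normal(mu, np.sqrt(mu)))


@njit(cache=True, inline="always")
def _accumulate(raw, deficit):
    """Pass a raw integer production through the negative-production deficit."""
    total = raw + deficit
    if total > 0:
        return total, np.int64(0)
    return np.int64(0), total


@njit(cache=True, inline="always")
def _hill(p1, K, nH):
    """Repression fraction K^n/(K^n + p1^n); nH<0 encodes activation."""
    if nH == 0.0:
        return 0.5
    if p1 <= 0.0:
        if nH > 0.0:
            return 1.0
        return 0.0
    return 1.0 / (1.0 + (p1 / K) ** nH)


# ---------------------------------------------------------------------------
# exact SSA (direct method)
# ---------------------------------------------------------------------------

@njit(cache=True)
def ssa_run(kg, gg, km, gm, kp, gp, ncop, g, m, p, duration):
    """Advance the six-channel single-gene SSA by ``duration``."""
    t = 0.0
    while True:
        a1 = kg * (ncop - g)
        a2 = gg * g
        a3 = km * g
        a4 = gm * m
        a5 = kp * m
        a6 = gp * p
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            break  # absorbing state: hold to the end of the segment
        t += np.random.exponential(1.0 / a0)
        if t >= duration:
            break
        r = np.random.random() * a0
        if r < a1:
            g += 1
        elif r < a1 + a2:
            g -= 1
        elif r < a1 + a2 + a3:
            m += 1
        elif r < a1 + a2 + a3 + a4:
            m -= 1
        elif r < a1 + a2 + a3 + a4 + a5:
            p += 1
        else:
            p -= 1
    return g, m, p


@njit(cache=True)
def ssa_net_run(
    kg1, gg1, km1, gm1, kp1, gp1, ncop1,
    kg2, gg2, km2, gm2, kp2, gp2, ncop2,
    K, nH, kl,
    g1, m1, p1, g2, m2, p2, duration,
):
    """Advance the twelve-channel repression-network SSA by ``duration``.

    The downstream transcription propensity is
    ``g2 * (km2 * K^n/(K^n + p1^n) + kl)`` -- leak added to the
    Hill-modulated transcription rate.
    """
    t = 0.0
    while True:
        a = np.empty(12)
        a[0] = kg1 * (ncop1 - g1)
        a[1] = gg1 * g1
        a[2] = km1 * g1
        a[3] = gm1 * m1
        a[4] = kp1 * m1
        a[5] = gp1 * p1
        a[6] = kg2 * (ncop2 - g2)
        a[7] = gg2 * g2
        a[8] = g2 * (km2 * _hill(1.0 * p1, K, nH) + kl)
        a[9] = gm2 * m2
        a[10] = kp2 * m2
        a[11] = gp2 * p2
        a0 = 0.0
        for j in range(12):
            a0 += a[j]
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t >= duration:
            break
        r = np.random.random() * a0
        acc = 0.0
        ch = 11
        for j in range(12):
            acc += a[j]
            if r < acc:
                ch = j
                break
        if ch == 0:
            g1 += 1
        elif ch == 1:
            g1 -= 1
        elif ch == 2:
            m1 += 1
        elif ch == 3:
            m1 -= 1
        elif ch == 4:
            p1 += 1
        elif ch == 5:
            p1 -= 1
        elif ch == 6:
            g2 += 1
        elif ch == 7:
            g2 -= 1
        elif ch == 8:
            m2 += 1
        elif ch == 9:
            m2 -= 1
        elif ch == 10:
            p2 += 1
        else:
            p2 -= 1
    return g1, m1, p1, g2, m2, p2


# ---------------------------------------------------------------------------
# burst Langevin drivers
# ---------------------------------------------------------------------------
#
# Shared structure of every driver:
#   1. recompute channel propensities from the current state,
#   2. pick tau: burst channels use max(eps*y, b)/rate, non-burst channels the
#      tau-leaping mean/variance bounds max(eps*y,1)/|mu| and
#      max(eps*y,1)^2/sigma2 (critical channels excluded from the bounds),
#   3. if critical channels exist, draw tau_c ~ Exp(sum of critical
#      propensities); when tau_c < tau the step is shortened to tau_c and one
#      critical event fires on top of the leap,
#   4. draw burst production as a Gaussian (rounded half away from zero,
#      through the per-species deficit accumulator) and every ordinary
#      channel via _count_draw (Gaussian, or exact Poisson below 5 expected
#      events); commit if no count goes negative, otherwise halve tau and
#      redraw (a critical event pushed beyond the halved horizon is dropped).


@njit(cache=True)
def bl_both_run(nkg, bm, bp, gp, p, def_p, duration, eps, ncrit, maxh,
                sample_times, out_p):
    """Both-bursts Langevin: protein only is tracked."""
    R = nkg * bm * bp
    vrate = R * (2.0 * bm * bp + 2.0 * bp + 1.0)
    t = 0.0
    si = 0
    ns = sample_times.size
    finite = duration < BIG
    while (finite and t < duration - 1e-12) or ((not finite) and si < ns):
        rem = duration - t
        a_deg = gp * p
        tau = rem
        if R > 0.0:
            tb = max(eps * p, bp) / R
            if tb < tau:
                tau = tb
        crit_sum = 0.0
        if p < ncrit:
            crit_sum = a_deg
        elif a_deg > 0.0:
            c = max(eps * p, 1.0)
            tnb = min(c / a_deg, c * c / a_deg)
            if tnb < tau:
                tau = tnb
        fire = False
        if crit_sum > 0.0:
            tc = np.random.exponential(1.0 / crit_sum)
            if tc < tau:
                tau = tc
                fire = True
        if tau > BIG / 2:  # absorbing: nothing can happen any more
            break
        committed = False
        pn = p
        ndef = def_p
        for _ in range(maxh + 1):
            raw = np.int64(0)
            if R > 0.0:
                raw = _round_away(np.random.normal(R * tau, np.sqrt(vrate * tau)))
            deg = np.int64(0)
            if p >= ncrit and a_deg > 0.0:
                deg = _count_draw(a_deg * tau)
            applied, ndef = _accumulate(raw, def_p)
            pn = p + applied - deg
            if fire:
                pn -= 1
            if pn >= 0:
                committed = True
                break
            tau *= 0.5
            fire = False
        if not committed:
            return p, def_p, STATUS_HALVINGS_EXCEEDED
        t_new = t + tau
        while si < ns and sample_times[si] < t_new - 1e-12:
            out_p[si] = p
            si += 1
        p = pn
        def_p = ndef
        t = t_new
    while si < ns:
        out_p[si] = p
        si += 1
    return p, def_p, STATUS_OK


@njit(cache=True)
def bl_mrna_run(nkg, bm, gm, kp, gp, m, p, def_m, def_p, duration, eps, ncrit,
                maxh, sample_times, out_m, out_p):
    """mRNA-burst Langevin: mRNA bursts, protein follows by plain CLE."""
    Rm = nkg * bm
    vrm = Rm * (2.0 * bm + 1.0)
    t = 0.0
    si = 0
    ns = sample_times.size
    finite = duration < BIG
    while (finite and t < duration - 1e-12) or ((not finite) and si < ns):
        rem = duration - t
        a_mdeg = gm * m
        a_pprod = kp * m
        a_pdeg = gp * p
        tau = rem
        if Rm > 0.0:
            tb = max(eps * m, bm) / Rm
            if tb < tau:
                tau = tb
        crit_sum = 0.0
        crit_m = m < ncrit
        crit_p = p < ncrit
        if crit_m:
            crit_sum += a_mdeg
        elif a_mdeg > 0.0:
            c = max(eps * m, 1.0)
            tnb = min(c / a_mdeg, c * c / a_mdeg)
            if tnb < tau:
                tau = tnb
        if crit_p:
            crit_sum += a_pdeg
        # protein channels (CLE production, possibly degradation)
        mu = a_pprod
        s2 = a_pprod
        if not crit_p:
            mu -= a_pdeg
            s2 += a_pdeg
        c = max(eps * p, 1.0)
        if abs(mu) > 0.0:
            tp = c / abs(mu)
            if tp < tau:
                tau = tp
        if s2 > 0.0:
            tp = c * c / s2
            if tp < tau:
                tau = tp
        fire = False
        u_crit = 0.0
        if crit_sum > 0.0:
            tc = np.random.exponential(1.0 / crit_sum)
            if tc < tau:
                tau = tc
                fire = True
                u_crit = np.random.random() * crit_sum
        if tau > BIG / 2:
            break
        committed = False
        mn = m
        pn = p
        ndef_m = def_m
        ndef_p = def_p
        for _ in range(maxh + 1):
            raw_m = np.int64(0)
            if Rm > 0.0:
                raw_m = _round_away(np.random.normal(Rm * tau, np.sqrt(vrm * tau)))
            deg_m = np.int64(0)
            if (not crit_m) and a_mdeg > 0.0:
                deg_m = _count_draw(a_mdeg * tau)
            raw_p = np.int64(0)
            if a_pprod > 0.0:
                raw_p = _count_draw(a_pprod * tau)
            deg_p = np.int64(0)
            if (not crit_p) and a_pdeg > 0.0:
                deg_p = _count_draw(a_pdeg * tau)
            app_m, ndef_m = _accumulate(raw_m, def_m)
            app_p, ndef_p = _accumulate(raw_p, def_p)
            mn = m + app_m - deg_m
            pn = p + app_p - deg_p
            if fire:
                if crit_m and u_crit < a_mdeg:
                    mn -= 1
                else:
                    pn -= 1
            if mn >= 0 and pn >= 0:
                committed = True
                break
            tau *= 0.5
            fire = False
        if not committed:
            return m, p, def_m, def_p, STATUS_HALVINGS_EXCEEDED
        t_new = t + tau
        while si < ns and sample_times[si] < t_new - 1e-12:
            out_m[si] = m
            out_p[si] = p
            si += 1
        m = mn
        p = pn
        def_m = ndef_m
        def_p = ndef_p
        t = t_new
    while si < ns:
        out_m[si] = m
        out_p[si] = p
        si += 1
    return m, p, def_m, def_p, STATUS_OK


@njit(cache=True)
def bl_protein_run(kg, gg, km, bp, gp, ncop, g, p, def_p, duration, eps, ncrit,
                   maxh, sample_times, out_g, out_p):
    """Protein-burst Langevin: the gene state is tracked, mRNA is skipped.

    Gene switching channels are always critical (single exponential events),
    so g is piecewise constant inside each Langevin step; tau is additionally
    capped at 0.1/max(kg, gg).
    """
    tau_cap = 0.1 / max(kg, gg)
    t = 0.0
    si = 0
    ns = sample_times.size
    finite = duration < BIG
    while (finite and t < duration - 1e-12) or ((not finite) and si < ns):
        rem = duration - t
        R = g * km * bp
        vrate = g * km * bp * (2.0 * bp + 1.0)
        a_deg = gp * p
        a_on = kg * (ncop - g)
        a_off = gg * g
        tau = rem
        if tau_cap < tau:
            tau = tau_cap
        if R > 0.0:
            tb = max(eps * p, bp) / R
            if tb < tau:
                tau = tb
        crit_sum = a_on + a_off
        crit_p = p < ncrit
        if crit_p:
            crit_sum += a_deg
        elif a_deg > 0.0:
            c = max(eps * p, 1.0)
            tnb = min(c / a_deg, c * c / a_deg)
            if tnb < tau:
                tau = tnb
        fire = False
        u_crit = 0.0
        if crit_sum > 0.0:
            tc = np.random.exponential(1.0 / crit_sum)
            if tc < tau:
                tau = tc
                fire = True
                u_crit = np.random.random() * crit_sum
        if tau > BIG / 2:
            break
        committed = False
        gn = g
        pn = p
        ndef = def_p
        for _ in range(maxh + 1):
            raw = np.int64(0)
            if R > 0.0:
                raw = _round_away(np.random.normal(R * tau, np.sqrt(vrate * tau)))
            deg = np.int64(0)
            if (not crit_p) and a_deg > 0.0:
                deg = _count_draw(a_deg * tau)
            applied, ndef = _accumulate(raw, def_p)
            gn = g
            pn = p + applied - deg
            if fire:
                if u_crit < a_on:
                    gn += 1
                elif u_crit < a_on + a_off:
                    gn -= 1
                else:
                    pn -= 1
            if pn >= 0:
                committed = True
                break
            tau *= 0.5
            fire = False
        if not committed:
            return g, p, def_p, STATUS_HALVINGS_EXCEEDED
        t_new = t + tau
        while si < ns and sample_times[si] < t_new - 1e-12:
            out_g[si] = g
            out_p[si] = p
            si += 1
        g = gn
        p = pn
        def_p = ndef
        t = t_new
    while si < ns:
        out_g[si] = g
        out_p[si] = p
        si += 1
    return g, p, def_p, STATUS_OK


@njit(cache=True)
def bl_noburst_run(kg, gg, km, gm, kp, gp, ncop, g, m, p, def_m, def_p,
                   duration, eps, ncrit, maxh, sample_times, out_g, out_m, out_p):
    """Plain chemical-Langevin propagation of all three species.

    No burst channel: every production/degradation channel contributes
    drift a*tau and Gaussian noise of variance a*tau.  Gene switching is
    critical, as are degradations at low copy number.
    """
    tau_cap = 0.1 / max(kg, gg)
    t = 0.0
    si = 0
    ns = sample_times.size
    finite = duration < BIG
    while (finite and t < duration - 1e-12) or ((not finite) and si < ns):
        rem = duration - t
        a_mprod = km * g
        a_mdeg = gm * m
        a_pprod = kp * m
        a_pdeg = gp * p
        a_on = kg * (ncop - g)
        a_off = gg * g
        crit_m = m < ncrit
        crit_p = p < ncrit
        crit_sum = a_on + a_off
        if crit_m:
            crit_sum += a_mdeg
        if crit_p:
            crit_sum += a_pdeg
        tau = rem
        if tau_cap < tau:
            tau = tau_cap
        # mRNA bounds
        mu = a_mprod
        s2 = a_mprod
        if not crit_m:
            mu -= a_mdeg
            s2 += a_mdeg
        c = max(eps * m, 1.0)
        if abs(mu) > 0.0:
            tm = c / abs(mu)
            if tm < tau:
                tau = tm
        if s2 > 0.0:
            tm = c * c / s2
            if tm < tau:
                tau = tm
        # protein bounds
        mu = a_pprod
        s2 = a_pprod
        if not crit_p:
            mu -= a_pdeg
            s2 += a_pdeg
        c = max(eps * p, 1.0)
        if abs(mu) > 0.0:
            tp = c / abs(mu)
            if tp < tau:
                tau = tp
        if s2 > 0.0:
            tp = c * c / s2
            if tp < tau:
                tau = tp
        fire = False
        u_crit = 0.0
        if crit_sum > 0.0:
            tc = np.random.exponential(1.0 / crit_sum)
            if tc < tau:
                tau = tc
                fire = True
                u_crit = np.random.random() * crit_sum
        if tau > BIG / 2:
            break
        committed = False
        gn = g
        mn = m
        pn = p
        ndef_m = def_m
        ndef_p = def_p
        for _ in range(maxh + 1):
            raw_m = np.int64(0)
            if a_mprod > 0.0:
                raw_m = _count_draw(a_mprod * tau)
            deg_m = np.int64(0)
            if (not crit_m) and a_mdeg > 0.0:
                deg_m = _count_draw(a_mdeg * tau)
            raw_p = np.int64(0)
            if a_pprod > 0.0:
                raw_p = _count_draw(a_pprod * tau)
            deg_p = np.int64(0)
            if (not crit_p) and a_pdeg > 0.0:
                deg_p = _count_draw(a_pdeg * tau)
            app_m, ndef_m = _accumulate(raw_m, def_m)
            app_p, ndef_p = _accumulate(raw_p, def_p)
            gn = g
            mn = m + app_m - deg_m
            pn = p + app_p - deg_p
            if fire:
                if u_crit < a_on:
                    gn += 1
                elif u_crit < a_on + a_off:
                    gn -= 1
                elif crit_m and u_crit < a_on + a_off + a_mdeg:
                    mn -= 1
                else:
                    pn -= 1
            if mn >= 0 and pn >= 0:
                committed = True
                break
            tau *= 0.5
            fire = False
        if not committed:
            return g, m, p, def_m, def_p, STATUS_HALVINGS_EXCEEDED
        t_new = t + tau
        while si < ns and sample_times[si] < t_new - 1e-12:
            out_g[si] = g
            out_m[si] = m
            out_p[si] = p
            si += 1
        g = gn
        m = mn
        p = pn
        def_m = ndef_m
        def_p = ndef_p
        t = t_new
    while si < ns:
        out_g[si] = g
        out_m[si] = m
        out_p[si] = p
        si += 1
    return g, m, p, def_m, def_p, STATUS_OK


@njit(cache=True)
def bl_net_run(
    nkg1, bm1, bp1, gp1,
    kg2, gg2, km2, kl, bp2, gp2, ncop2,
    K, nH,
    p1, p2, def1, def2, duration, eps, ncrit, maxh,
    sample_times, out_p1, out_p2,
):
    """Coupled both-bursts Langevin for the two-gene repression network.

    Both genes run in both-bursts mode (only p1 and p2 are tracked).  The
    downstream burst statistics are recomputed every step from the current
    p1 through the effective burst size
    ``bm2_eff = (km2*Hill(p1) + kl)/(kg2 + gg2)``, with p1 treated as
    piecewise constant within the shared step.
    """
    R1 = nkg1 * bm1 * bp1
    vr1 = R1 * (2.0 * bm1 * bp1 + 2.0 * bp1 + 1.0)
    t = 0.0
    si = 0
    ns = sample_times.size
    finite = duration < BIG
    while (finite and t < duration - 1e-12) or ((not finite) and si < ns):
        rem = duration - t
        bm2 = ncop2 * (km2 * _hill(1.0 * p1, K, nH) + kl) / (kg2 + gg2)
        R2 = kg2 * bm2 * bp2
        vr2 = R2 * (2.0 * bm2 * bp2 + 2.0 * bp2 + 1.0)
        a_d1 = gp1 * p1
        a_d2 = gp2 * p2
        tau = rem
        if R1 > 0.0:
            tb = max(eps * p1, bp1) / R1
            if tb < tau:
                tau = tb
        if R2 > 0.0:
            tb = max(eps * p2, bp2) / R2
            if tb < tau:
                tau = tb
        crit_sum = 0.0
        crit_1 = p1 < ncrit
        crit_2 = p2 < ncrit
        if crit_1:
            crit_sum += a_d1
        elif a_d1 > 0.0:
            c = max(eps * p1, 1.0)
            tnb = min(c / a_d1, c * c / a_d1)
            if tnb < tau:
                tau = tnb
        if crit_2:
            crit_sum += a_d2
        elif a_d2 > 0.0:
            c = max(eps * p2, 1.0)
            tnb = min(c / a_d2, c * c / a_d2)
            if tnb < tau:
                tau = tnb
        fire = False
        u_crit = 0.0
        if crit_sum > 0.0:
            tc = np.random.exponential(1.0 / crit_sum)
            if tc < tau:
                tau = tc
                fire = True
                u_crit = np.random.random() * crit_sum
        if tau > BIG / 2:
            break
        committed = False
        p1n = p1
        p2n = p2
        ndef1 = def1
        ndef2 = def2
        for _ in range(maxh + 1):
            raw1 = np.int64(0)
            if R1 > 0.0:
                raw1 = _round_away(np.random.normal(R1 * tau, np.sqrt(vr1 * tau)))
            deg1 = np.int64(0)
            if (not crit_1) and a_d1 > 0.0:
                deg1 = _count_draw(a_d1 * tau)
            raw2 = np.int64(0)
            if R2 > 0.0:
                raw2 = _round_away(np.random.normal(R2 * tau, np.sqrt(vr2 * tau)))
            deg2 = np.int64(0)
            if (not crit_2) and a_d2 > 0.0:
                deg2 = _count_draw(a_d2 * tau)
            app1, ndef1 = _accumulate(raw1, def1)
            app2, ndef2 = _accumulate(raw2, def2)
            p1n = p1 + app1 - deg1
            p2n = p2 + app2 - deg2
            if fire:
                if crit_1 and u_crit < a_d1:
                    p1n -= 1
                else:
                    p2n -= 1
            if p1n >= 0 and p2n >= 0:
                committed = True
                break
            tau *= 0.5
            fire = False
        if not committed:
            return p1, p2, def1, def2, STATUS_HALVINGS_EXCEEDED
        t_new = t + tau
        while si < ns and sample_times[si] < t_new - 1e-12:
            out_p1[si] = p1
            out_p2[si] = p2
            si += 1
        p1 = p1n
        p2 = p2n
        def1 = ndef1
        def2 = ndef2
        t = t_new
    while si < ns:
        out_p1[si] = p1
        out_p2[si] = p2
        si += 1
    return p1, p2, def1, def2, STATUS_OK
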
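"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the equilibration
oracle solves the two kinase equilibria by nested scipy root bracketing
over reaction extents, and the simulation oracle is a straightforward
re-implementation of the update scheme with explicit spike sums.
"""

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


def ak_extent(atp, adp, amp, k_ad):
    """Extent x of AMP+ATP -> 2ADP zeroing the AK residual (bracketed root)."""
    def g(x):
        return k_ad * (atp - x) * (amp - x) - (adp + 2.0 * x) ** 2

    lo, hi = -0.5 * adp, min(atp, amp)
    if g(lo) <= 0.0:
        return lo
    if g(hi) >= 0.0:
        return hi
    return brentq(g, lo, hi, xtol=1e-16, rtol=1e-15)


def brute_equilibrate(atp, adp, amp, arg, argp, k_ad, k_ph, enforce_ph=True):
    """Equilibration oracle in final-state coordinates.

    The final state is pinned by the three conserved pools (adenine
    A = atp+adp+amp, guanidino G = arg+argp, phosphoryl tally
    P = 3atp+2adp+amp+argp) plus the two equilibrium relations.  For a
    candidate final ArgP = y the conservation laws leave one unknown,
    the final ATP a (with d = P - y - A - 2a and m = A + a - (P - y - A)),
    which the AK relation determines by root bracketing; the ArgK
    residual is then a scalar function of y whose root is located by a
    sign-change scan plus brentq.  Entirely independent of the package's
    Newton/extent solver.
    """
    if not enforce_ph:
        xa = ak_extent(atp, adp, amp, k_ad)
        return atp - xa, adp + 2.0 * xa, amp - xa, arg, argp

    pool_a = atp + adp + amp
    pool_g = arg + argp
    tally = 3.0 * atp + 2.0 * adp + amp + argp

    def solve_adenine(y):
        """Final (a, d, m) satisfying AK and conservation for ArgP = y."""
        s = tally - y - pool_a          # = 2a + d
        if s < -1e-15 or s > 2.0 * pool_a + 1e-15:
            return None
        s = max(s, 0.0)

        def g(a):
            return k_ad * a * (pool_a + a - s) - (s - 2.0 * a) ** 2

        lo = max(0.0, s - pool_a)
        hi = 0.5 * s
        if hi < lo:
            return None
        if g(hi) <= 0.0:
            a = hi
        elif g(lo) >= 0.0:
            a = lo
        else:
            a = brentq(g, lo, hi, xtol=1e-16, rtol=1e-15)
        return a, s - 2.0 * a, pool_a + a - s

    def resid(y):
        sol = solve_adenine(y)
        if sol is None:
            return np.nan
        a, d, m = sol
        return k_ph * d * y - a * (pool_g - y)

    ys = np.linspace(0.0, pool_g, 2001)
    vals = np.array([resid(y) for y in ys])
    good = np.isfinite(vals)
    ys, vals = ys[good], vals[good]
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size:
        i = sign_change[0]
        y = brentq(resid, ys[i], ys[i + 1], xtol=1e-16, rtol=1e-15)
    else:  # boundary solution
        y = ys[np.argmin(np.abs(vals))]
    a, d, m = solve_adenine(y)
    return a, d, m, pool_g - y, y


def consumption_rate_oracle(t, spike_times_s, n_atp_mm, tau):
    """Spec-literal consumption sum (mM/s): sum over past spikes/components."""
    total = 0.0
    for ts in spike_times_s:
        if ts <= t:
            for n_mm, tj in zip(n_atp_mm, tau):
                total += n_mm / tj * np.exp((ts - t) / tj)
    return total


def integrated_cost_oracle(base_rate, spike_times_s, n_atp_mm, tau, t_end):
    """Numerical quadrature of the consumption rate from 0 to t_end."""
    def f(t):
        return base_rate + consumption_rate_oracle(t, spike_times_s, n_atp_mm, tau)

    pts = [ts for ts in spike_times_s if 0 < ts < t_end]
    val, _ = quad(f, 0.0, t_end, points=pts, limit=50 + 10 * len(pts))
    return val


def reference_simulate(n_steps, dt, spike_steps, n_atp_mm, tau, base_rate,
                       state0, k_ad, k_ph, enforce_ph, base_es, turnover,
                       base_prod, max_rate, cap_exp, record_stride):
    """Plain re-implementation of the integration scheme.

    Spikes are taken at their grid-aligned times; consumption is the
    explicit double sum over all past spikes (no accumulators); the
    production prefactor compensates the soft cap so capped rest
    production equals the rest consumption; equilibration uses the
    nested-bisection oracle.
    """
    atp, adp, amp, arg, argp, pi = state0
    pcc0 = turnover(base_es)
    r = base_prod / max_rate
    prefactor = base_prod / (1.0 - r**cap_exp) ** (1.0 / cap_exp) if base_prod else 0.0

    def cap(p):
        if p == 0.0:
            return 0.0
        return (p ** -cap_exp + max_rate ** -cap_exp) ** (-1.0 / cap_exp)

    rec = []
    for i in range(n_steps + 1):
        t = i * dt
        cons = base_rate
        for s in spike_steps:
            if s <= i:
                for n_mm, tj in zip(n_atp_mm, tau):
                    cons += n_mm / tj * np.exp((s - i) * dt / tj)
        es = atp / (adp * pi)
        p = cap(prefactor * turnover(es) / pcc0)
        if i % record_stride == 0:
            rec.append((t, atp, adp, amp, arg, argp, pi, cons, p))
        if i == n_steps:
            break
        net = p - cons
        atp += dt * net
        adp -= dt * net
        pi -= dt * net
        atp, adp, amp, arg, argp = brute_equilibrate(
            atp, adp, amp, arg, argp, k_ad, k_ph, enforce_ph)
    return np.array(rec)


def mad_flags_oracle(values):
    """Literal median/MAD screen written independently."""
    x = list(values)
    srt = sorted(x)
    n = len(srt)
    med = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    dev = sorted(abs(v - med) for v in x)
    mad = dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2])
    if mad == 0:
        return [v != med for v in x]
    return [v < med - 3 * mad or v > med + 3 * mad for v in x]
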
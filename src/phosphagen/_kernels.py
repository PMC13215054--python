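"""JIT-compiled numerical kernels: equilibration solver and time stepper.

These are implementation details; use :mod:`phosphagen.equilibration` and
:mod:`phosphagen.simulate` instead.  The equilibration solver works in
reaction extents (xA for AMP + ATP -> 2 ADP, xP for ADP + ArgP -> ATP + Arg)
so the three linear pool invariants hold by construction; a damped 2x2
Newton iteration is used, with an alternating exact-bisection fallback
whenever Newton leaves the feasible box.

Status codes: 0 ok, 1 not converged, 2 infeasible state, 3 negative
concentration not curable by local step subdivision.
"""

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=False)
def _rel_residuals(atp, adp, amp, arg, argp, k_ad, k_ph):
    s1 = max(abs(k_ad * atp * amp), adp * adp, _TINY)
    r1 = (k_ad * atp * amp - adp * adp) / s1
    s2 = max(abs(k_ph * adp * argp), abs(atp * arg), _TINY)
    r2 = (k_ph * adp * argp - atp * arg) / s2
    return r1, r2


@njit(cache=False)
def _bisect_ak(atp, adp, amp, k_ad):
    """Exact extent of AMP+ATP->2ADP equilibrating AK; g is decreasing."""
    lo = -0.5 * adp
    hi = min(atp, amp)
    for _ in range(120):
        x = 0.5 * (lo + hi)
        g = k_ad * (atp - x) * (amp - x) - (adp + 2.0 * x) ** 2
        if g > 0.0:
            lo = x
        else:
            hi = x
    return 0.5 * (lo + hi)


@njit(cache=False)
def _bisect_argk(atp, adp, arg, argp, k_ph):
    """Exact extent of ADP+ArgP->ATP+Arg equilibrating ArgK; g is decreasing."""
    lo = -min(atp, arg)
    hi = min(adp, argp)
    for _ in range(120):
        x = 0.5 * (lo + hi)
        g = k_ph * (adp - x) * (argp - x) - (atp + x) * (arg + x)
        if g > 0.0:
            lo = x
        else:
            hi = x
    return 0.5 * (lo + hi)


@njit(cache=False)
def _equilibrate_kernel(atp, adp, amp, arg, argp, k_ad, k_ph,
                        enforce_ph, tol, max_iter):
    """Return (atp, adp, amp, arg, argp, status, r1, r2, n_iter)."""
    if atp < 0.0 or adp < 0.0 or amp < 0.0 or arg < 0.0 or argp < 0.0:
        return atp, adp, amp, arg, argp, 2, 0.0, 0.0, 0

    xa = 0.0
    xp = 0.0
    n_it = 0
    for n_it in range(1, max_iter + 1):
        a = atp - xa + xp
        d = adp + 2.0 * xa - xp
        m = amp - xa
        g = arg + xp
        gp = argp - xp

        r1, r2 = _rel_residuals(a, d, m, g, gp, k_ad, k_ph)
        if not enforce_ph:
            r2 = 0.0
        if abs(r1) <= tol and abs(r2) <= tol:
            return a, d, m, g, gp, 0, r1, r2, n_it

        f1 = k_ad * a * m - d * d
        f2 = k_ph * d * gp - a * g
        j11 = -k_ad * (a + m) - 4.0 * d
        if enforce_ph:
            j12 = k_ad * m + 2.0 * d
            j21 = 2.0 * k_ph * gp + g
            j22 = -k_ph * (d + gp) - (a + g)
            det = j11 * j22 - j12 * j21
            if det == 0.0:
                break
            dxa = -(f1 * j22 - j12 * f2) / det
            dxp = -(j11 * f2 - f1 * j21) / det
        else:
            if j11 == 0.0:
                break
            dxa = -f1 / j11
            dxp = 0.0

        # damped update: stay inside the feasible box and reduce residuals
        old_norm = r1 * r1 + r2 * r2
        step = 1.0
        accepted = False
        for _ in range(60):
            ta = xa + step * dxa
            tp = xp + step * dxp
            a2 = atp - ta + tp
            d2 = adp + 2.0 * ta - tp
            m2 = amp - ta
            g2 = arg + tp
            gp2 = argp - tp
            if a2 >= 0.0 and d2 >= 0.0 and m2 >= 0.0 and g2 >= 0.0 and gp2 >= 0.0:
                q1, q2 = _rel_residuals(a2, d2, m2, g2, gp2, k_ad, k_ph)
                if not enforce_ph:
                    q2 = 0.0
                if q1 * q1 + q2 * q2 < old_norm:
                    xa, xp = ta, tp
                    accepted = True
                    break
            step *= 0.5
        if not accepted:
            break

    # fallback: alternating exact single-reaction bisections (Gauss-Seidel),
    # starting from wherever Newton got to
    a = atp - xa + xp
    d = adp + 2.0 * xa - xp
    m = amp - xa
    g = arg + xp
    gp = argp - xp
    for sweep in range(max_iter):
        r1, r2 = _rel_residuals(a, d, m, g, gp, k_ad, k_ph)
        if not enforce_ph:
            r2 = 0.0
        if abs(r1) <= tol and abs(r2) <= tol:
            return a, d, m, g, gp, 0, r1, r2, n_it + sweep
        x = _bisect_ak(a, d, m, k_ad)
        a -= x
        m -= x
        d += 2.0 * x
        if enforce_ph:
            x = _bisect_argk(a, d, g, gp, k_ph)
            a += x
            g += x
            d -= x
            gp -= x
    r1, r2 = _rel_residuals(a, d, m, g, gp, k_ad, k_ph)
    if not enforce_ph:
        r2 = 0.0
    if abs(r1) <= tol and abs(r2) <= tol:
        return a, d, m, g, gp, 0, r1, r2, n_it
    return a, d, m, g, gp, 1, r1, r2, n_it


@njit(cache=False)
def _pcc_hill_inverse(es, k_half, h):
    u = 1.0 / es
    return u**h / (k_half**h + u**h)


@njit(cache=False)
def _cap(p, max_rate, e):
    if p <= 0.0:
        return 0.0
    if p <= max_rate:
        s, l = p, max_rate
    else:
        s, l = max_rate, p
    r = s / l
    return s / (1.0 + r**e) ** (1.0 / e)


@njit(cache=False)
def _simulate_loop(n_steps, dt, spike_idx, heights, decays, base_rate,
                   state0, k_ad, k_ph, enforce_ph, equil_on, tol, max_iter,
                   base_es, hill_k, hill_h, prod_base_rate, max_rate, cap_exp,
                   prod_on, record_stride):
    """Operator-split integration: consume/produce (explicit Euler), then
    equilibrate.  Records state and rates every ``record_stride`` steps.

    Returns (rec_states, rec_cons, rec_prod, status, err_step).
    """
    n_rec = n_steps // record_stride + 1
    rec_states = np.empty((n_rec, 6))
    rec_cons = np.empty(n_rec)
    rec_prod = np.empty(n_rec)

    atp, adp, amp, arg, argp, pi = (state0[0], state0[1], state0[2],
                                    state0[3], state0[4], state0[5])
    acc = np.zeros(5)
    sp = 0
    n_spikes = spike_idx.size
    pcc_base = _pcc_hill_inverse(base_es, hill_k, hill_h)
    rec = 0

    for i in range(n_steps + 1):
        if i > 0:
            for j in range(5):
                acc[j] *= decays[j]
        while sp < n_spikes and spike_idx[sp] == i:
            for j in range(5):
                acc[j] += heights[j]
            sp += 1
        cons = base_rate
        for j in range(5):
            cons += acc[j]

        if adp <= 0.0 or pi <= 0.0:
            return rec_states, rec_cons, rec_prod, 2, i
        if prod_on:
            es = atp / (adp * pi)
            p = prod_base_rate * _pcc_hill_inverse(es, hill_k, hill_h) / pcc_base
            p = _cap(p, max_rate, cap_exp)
        else:
            p = 0.0

        if i % record_stride == 0:
            rec_states[rec, 0] = atp
            rec_states[rec, 1] = adp
            rec_states[rec, 2] = amp
            rec_states[rec, 3] = arg
            rec_states[rec, 4] = argp
            rec_states[rec, 5] = pi
            rec_cons[rec] = cons
            rec_prod[rec] = p
            rec += 1
        if i == n_steps:
            break

        # state update with local subdivision if a step would go negative
        done = False
        for attempt in range(11):
            n_sub = 1 << attempt
            h = dt / n_sub
            ta, td, tm, tg, tgp, tpi = atp, adp, amp, arg, argp, pi
            feasible = True
            for s in range(n_sub):
                if s == 0 and attempt == 0:
                    ps = p
                else:
                    if td <= 0.0 or tpi <= 0.0:
                        feasible = False
                        break
                    if prod_on:
                        es = ta / (td * tpi)
                        ps = prod_base_rate * _pcc_hill_inverse(es, hill_k, hill_h) / pcc_base
                        ps = _cap(ps, max_rate, cap_exp)
                    else:
                        ps = 0.0
                net = ps - cons
                ta += h * net
                td -= h * net
                tpi -= h * net
                if ta < 0.0 or td < 0.0 or tpi < 0.0:
                    feasible = False
                    break
                if equil_on:
                    ta, td, tm, tg, tgp, st, _, _, _ = _equilibrate_kernel(
                        ta, td, tm, tg, tgp, k_ad, k_ph, enforce_ph, tol, max_iter)
                    if st != 0:
                        return rec_states, rec_cons, rec_prod, st, i
            if feasible:
                atp, adp, amp, arg, argp, pi = ta, td, tm, tg, tgp, tpi
                done = True
                break
        if not done:
            return rec_states, rec_cons, rec_prod, 3, i

    return rec_states, rec_cons, rec_prod, 0, n_steps
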
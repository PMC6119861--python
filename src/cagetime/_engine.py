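"""Numba kernels: kinetic-signature evaluation, Gaussian likelihood, nested sampling.

Everything here is deliberately scalar/loop-structured so numba compiles it to
tight machine code; the public API in :mod:`cagetime.kinetic_models` and
:mod:`cagetime.evidence` wraps these kernels.

Model ids: 0=linear, 1=decay, 2=dip, 3=peak, 4=const (constant model, used as
an analytically tractable evidence test problem).
"""

import numpy as np
from numba import njit

MODEL_LINEAR = 0
MODEL_DECAY = 1
MODEL_DIP = 2
MODEL_PEAK = 3
MODEL_CONST = 4


@njit(cache=True)
def model_value(model_id, params, t):
    """Value of a kinetic signature at a single time point (minutes)."""
    if model_id == MODEL_LINEAR:
        return params[0] + params[1] * t
    elif model_id == MODEL_DECAY:
        return params[0] + params[1] * np.exp(-params[2] * t)
    elif model_id == MODEL_DIP:
        base = params[0]
        amp = params[1]
        ka = params[2]
        kb = params[3]
        ks = min(ka, kb)   # slow (recovery) rate
        kf = max(ka, kb)   # fast (drop) rate
        if kf - ks < 1e-9 * kf:
            # limit kf -> ks: shape ~ t*exp(-k t), max at t = 1/k
            k = 0.5 * (ks + kf)
            shape = k * t * np.exp(1.0 - k * t)
        else:
            tstar = np.log(kf / ks) / (kf - ks)
            smax = np.exp(-ks * tstar) - np.exp(-kf * tstar)
            shape = (np.exp(-ks * t) - np.exp(-kf * t)) / smax
        return base - amp * shape
    elif model_id == MODEL_PEAK:
        p1 = params[0]
        p2 = params[1]
        td = params[2]
        ts = params[3]
        r_rise = params[4]
        r_fall = params[5]
        tp = td + ts
        if t <= td:
            return p1
        elif t <= tp:
            # expm1(r(t-td))/expm1(r*ts), overflow-safe for large r*ts
            x = r_rise * (t - td)
            big = r_rise * ts
            ratio = np.exp(x - big) * np.expm1(-x) / np.expm1(-big)
            return p1 + p2 * ratio
        else:
            return p1 + p2 * np.exp(-r_fall * (t - tp))
    else:
        return params[0]


@njit(cache=True)
def eval_curve(model_id, params, times):
    out = np.empty(times.size)
    for j in range(times.size):
        out[j] = model_value(model_id, params, times[j])
    return out


@njit(cache=True)
def log_likelihood(model_id, params, times, obs, sd):
    """Sum over replicates and times of iid Gaussian log densities."""
    T = times.size
    R = obs.shape[0]
    ssr = 0.0
    for j in range(T):
        m = model_value(model_id, params, times[j])
        for r in range(R):
            d = obs[r, j] - m
            ssr += d * d
    n = R * T
    return -0.5 * n * np.log(2.0 * np.pi * sd * sd) - ssr / (2.0 * sd * sd)


@njit(cache=True)
def _logaddexp(a, b):
    if a > b:
        return a + np.log1p(np.exp(b - a))
    else:
        return b + np.log1p(np.exp(a - b))


@njit(cache=True)
def nested_run(model_id, lo, hi, times, obs, sd, n_live, n_steps, max_iter, seed):
    """Static nested sampling with a uniform box prior.

    Live-point replacement is a likelihood-constrained random walk started
    from a surviving live point, with a globally adapted step fraction.
    Returns (logZ, logZ_err, samples, sample_logl, sample_logwt, n_iter,
    converged); sample weights are exp(logwt - logZ) after normalisation.
    """
    np.random.seed(seed)
    d = lo.size
    live = np.empty((n_live, d))
    for i in range(n_live):
        for k in range(d):
            live[i, k] = lo[k] + (hi[k] - lo[k]) * np.random.random()
    logl = np.empty(n_live)
    for i in range(n_live):
        logl[i] = log_likelihood(model_id, live[i], times, obs, sd)

    cap = max_iter + n_live
    dead = np.empty((cap, d))
    dead_logl = np.empty(cap)
    dead_logwt = np.empty(cap)

    logZ = -1e300
    H = 0.0
    scale = 2.0                     # step size in units of live-point spread
    log_shrink = np.log1p(-np.exp(-1.0 / n_live))
    log_stop = np.log(1e-3)         # remaining-evidence tolerance
    it = 0
    converged = False
    prop = np.empty(d)
    step = np.empty(d)

    while it < max_iter:
        worst = 0
        for i in range(1, n_live):
            if logl[i] < logl[worst]:
                worst = i
        lstar = logl[worst]
        logwt = -it / n_live + log_shrink + lstar
        logz_new = _logaddexp(logZ, logwt)
        H = (np.exp(logwt - logz_new) * lstar
             + np.exp(logZ - logz_new) * (H + logZ) - logz_new)
        logZ = logz_new
        for k in range(d):
            dead[it, k] = live[worst, k]
        dead_logl[it] = lstar
        dead_logwt[it] = logwt

        # proposal scale from the per-dimension spread of the live points,
        # so steps track the shrinking likelihood-constrained region
        for k in range(d):
            m1 = 0.0
            for i in range(n_live):
                m1 += live[i, k]
            m1 /= n_live
            v = 0.0
            for i in range(n_live):
                dv = live[i, k] - m1
                v += dv * dv
            s = np.sqrt(v / n_live)
            smin = 1e-10 * (hi[k] - lo[k])
            step[k] = s if s > smin else smin

        src = worst
        if n_live > 1:
            while src == worst:
                src = np.random.randint(0, n_live)
        x = live[src].copy()
        lx = logl[src]
        nacc = 0
        for _ in range(n_steps):
            inside = True
            for k in range(d):
                prop[k] = x[k] + scale * step[k] * np.random.normal()
                if prop[k] < lo[k] or prop[k] > hi[k]:
                    inside = False
                    break
            if not inside:
                continue
            lp = log_likelihood(model_id, prop, times, obs, sd)
            if lp > lstar:
                for k in range(d):
                    x[k] = prop[k]
                lx = lp
                nacc += 1
        if nacc > n_steps // 2:
            scale = min(scale * 1.25, 10.0)
        elif nacc < max(1, n_steps // 4):
            scale = max(scale * 0.75, 0.01)
        for k in range(d):
            live[worst, k] = x[k]
        logl[worst] = lx
        it += 1

        lmax = logl[0]
        for i in range(1, n_live):
            if logl[i] > lmax:
                lmax = logl[i]
        if lmax - it / n_live < logZ + log_stop:
            converged = True
            break

    # fold in the remaining live points at the final prior volume
    log_xfinal = -it / n_live
    logw_live = log_xfinal - np.log(n_live)
    for i in range(n_live):
        logwt = logw_live + logl[i]
        logz_new = _logaddexp(logZ, logwt)
        H = (np.exp(logwt - logz_new) * logl[i]
             + np.exp(logZ - logz_new) * (H + logZ) - logz_new)
        logZ = logz_new
        for k in range(d):
            dead[it + i, k] = live[i, k]
        dead_logl[it + i] = logl[i]
        dead_logwt[it + i] = logwt

    n_stored = it + n_live
    if H < 0.0:
        H = 0.0
    logz_err = np.sqrt(H / n_live)
    return (logZ, logz_err, dead[:n_stored], dead_logl[:n_stored],
            dead_logwt[:n_stored], it, converged)


@njit(cache=True)
def conserved_support(values, present):
    """Pairwise precedence support counts.

    values: (genes, datasets) peak times; present: boolean mask. Entry
    (a, b) counts datasets where both present and t_p[a] < t_p[b] strictly
    (ties support neither direction).
    """
    g, d = values.shape
    supp = np.zeros((g, g), dtype=np.int64)
    for a in range(g):
        for b in range(g):
            if a == b:
                continue
            c = 0
            for j in range(d):
                if present[a, j] and present[b, j] and values[a, j] < values[b, j]:
                    c += 1
            supp[a, b] = c
    return supp


@njit(cache=True)
def count_conserved(values, present, quorum):
    g, _ = values.shape
    supp = conserved_support(values, present)
    n = 0
    for a in range(g):
        for b in range(g):
            if a != b and supp[a, b] >= quorum:
                n += 1
    return n


@njit(cache=True)
def permutation_counts(values, present, quorum, n_perm, seed):
    """Conserved-edge counts under within-column shuffles of present t_p."""
    np.random.seed(seed)
    g, d = values.shape
    work = values.copy()
    out = np.empty(n_perm, dtype=np.int64)
    # index lists of present rows per column
    for p in range(n_perm):
        for j in range(d):
            # Fisher-Yates over present entries of column j
            idx = np.empty(g, dtype=np.int64)
            m = 0
            for a in range(g):
                if present[a, j]:
                    idx[m] = a
                    m += 1
            for a in range(m - 1, 0, -1):
                b = np.random.randint(0, a + 1)
                tmp = work[idx[a], j]
                work[idx[a], j] = work[idx[b], j]
                work[idx[b], j] = tmp
        out[p] = count_conserved(work, present, quorum)
    return out
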
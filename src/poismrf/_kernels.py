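"""Numba-compiled MCMC kernels.

Hot loops of the Metropolis-within-Gibbs sampler: single-pixel random-walk
updates of the activity image (with incremental likelihood evaluation over
the sparse system-matrix column), log-scale random-walk updates of the
local variances tau_j, and the exact Gamma draw for the hyper-rate gamma.

All randomness uses numba's per-process ``np.random`` state, seeded once
through :func:`seed_rng`; with a fixed seed every chain is reproducible
bit-for-bit.  The sparse matrix is passed as raw CSC arrays
(``Aip, Arow, Aval``) and the neighbourhood graph as compressed adjacency
(``nbp, nbi, nbw``).
"""

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e308


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def site_energy(x, j, nbp, nbi, nbw):
    """S_j = sum over neighbours t of w_jt * |x_j - x_t|."""
    s = 0.0
    for k in range(nbp[j], nbp[j + 1]):
        s += nbw[k] * abs(x[j] - x[nbi[k]])
    return s


@njit(cache=True)
def total_energy(x, nbp, nbi, nbw):
    s = 0.0
    for j in range(x.size):
        s += site_energy(x, j, nbp, nbi, nbw)
    return s


@njit(cache=True)
def recompute_lam(x, Aip, Arow, Aval, lam):
    """Resynchronize lam = A @ x from scratch (kills incremental fp drift)."""
    lam[:] = 0.0
    for j in range(x.size):
        xj = x[j]
        if xj != 0.0:
            for k in range(Aip[j], Aip[j + 1]):
                lam[Arow[k]] += Aval[k] * xj


@njit(cache=True)
def poisson_loglik_k(y, lam):
    ll = 0.0
    for i in range(y.size):
        li = lam[i]
        yi = y[i]
        if li <= 0.0:
            if yi > 0.0:
                return NEG_INF
            ll -= li
        else:
            ll += yi * math.log(li) - li - math.lgamma(yi + 1.0)
    return ll


@njit(cache=True)
def log_joint_k(y, lam, x, tau, gamma, nbp, nbi, nbw, inhom, gamma_fixed, theta):
    """Unnormalized log posterior; must agree with the pure-Python evaluation."""
    ll = poisson_loglik_k(y, lam)
    if ll <= NEG_INF:
        return ll
    m = x.size
    for j in range(m):
        S = site_energy(x, j, nbp, nbi, nbw)
        ll += -math.log(2.0 * tau[j]) - S / tau[j]
    if inhom:
        for j in range(m):
            ll += math.log(gamma) - gamma * tau[j]
    else:
        ll += math.log(gamma) - gamma * tau[0]
    if not gamma_fixed:
        ll += math.log(theta) - theta * gamma
    return ll


@njit(cache=True)
def pixel_delta(j, xp, x, tau, lam, y, Aip, Arow, Aval, nbp, nbi, nbw):
    """Change in log posterior when pixel j moves from x[j] to xp.

    Likelihood part touches only column j's support; prior part touches
    only j and its neighbours (the pair term |x_j - x_t| appears once in
    S_j and once in S_t, with variances tau_j and tau_t respectively).
    """
    xo = x[j]
    dxv = xp - xo
    d = 0.0
    for k in range(Aip[j], Aip[j + 1]):
        i = Arow[k]
        a = Aval[k]
        nl = lam[i] + a * dxv
        if y[i] > 0.0:
            if nl <= 0.0:
                return NEG_INF
            if lam[i] <= 0.0:
                return -NEG_INF
            d += y[i] * math.log(nl / lam[i])
        d -= a * dxv
    for k in range(nbp[j], nbp[j + 1]):
        t = nbi[k]
        dd = nbw[k] * (abs(xp - x[t]) - abs(xo - x[t]))
        d -= dd / tau[j] + dd / tau[t]
    return d


@njit(cache=True)
def pixel_update(j, x, tau, lam, y, Aip, Arow, Aval, nbp, nbi, nbw, step):
    """One random-walk MH update of pixel j; mutates x and lam on acceptance."""
    xp = x[j] + step * np.random.normal()
    if xp < 0.0:
        return False
    d = pixel_delta(j, xp, x, tau, lam, y, Aip, Arow, Aval, nbp, nbi, nbw)
    if d >= 0.0 or np.random.random() < math.exp(d):
        dxv = xp - x[j]
        for k in range(Aip[j], Aip[j + 1]):
            lam[Arow[k]] += Aval[k] * dxv
        x[j] = xp
        return True
    return False


@njit(cache=True)
def tau_update(t, S, gamma, step, floor):
    """One log-scale random-walk MH update of a local variance.

    Target p(tau) propto tau^(-1) exp(-S/tau - gamma*tau) truncated to
    [floor, inf).  In theta = log tau the Jacobian cancels the tau^(-1)
    factor, so the log target is simply -S/tau - gamma*tau.
    """
    ltp = math.log(t) + step * np.random.normal()
    tp = math.exp(ltp)
    if tp < floor:
        return t, False
    d = (-S / tp - gamma * tp) - (-S / t - gamma * t)
    if d >= 0.0 or np.random.random() < math.exp(d):
        return tp, True
    return t, False


@njit(cache=True)
def global_tau_update(t, S_tot, m, gamma, step, floor):
    """Log-scale MH update of the single homogeneous variance.

    Target tau^(-m) exp(-S_tot/tau - gamma*tau); log-space target adds the
    Jacobian log tau, leaving exponent (1 - m) on tau.
    """
    lt = math.log(t)
    ltp = lt + step * np.random.normal()
    tp = math.exp(ltp)
    if tp < floor:
        return t, False
    d = (1.0 - m) * (ltp - lt) - S_tot * (1.0 / tp - 1.0 / t) - gamma * (tp - t)
    if d >= 0.0 or np.random.random() < math.exp(d):
        return tp, True
    return t, False


@njit(cache=True)
def draw_gamma(shape, rate):
    return np.random.gamma(shape, 1.0 / rate)


@njit(cache=True)
def sample_tau_chain(n_keep, thin, t0, S, gamma, step, floor):
    """Repeated tau updates at fixed local energy, thinned; for diagnostics."""
    out = np.empty(n_keep)
    t = t0
    for i in range(n_keep):
        for _ in range(thin):
            t, _acc = tau_update(t, S, gamma, step, floor)
        out[i] = t
    return out


@njit(cache=True)
def run_chain_kernel(
    y,
    x,
    tau,
    gamma0,
    lam,
    Aip,
    Arow,
    Aval,
    nbp,
    nbi,
    nbw,
    n_iter,
    burn_in,
    thin,
    step_x,
    tau_step,
    tau_floor,
    theta,
    inhom,
    sample_tau,
    gamma_fixed,
    random_scan,
    adapt_target,
    adapt_rate,
    out_x,
    out_tau,
    out_gamma,
    out_logpost,
):
    """Full Metropolis-within-Gibbs run; mutates x/tau/lam in place.

    Per iteration: sweep all pixels (random-walk MH, nonnegativity by
    outright rejection), then all variances (or the single global one),
    then an exact Gamma draw for gamma when it is sampled.  Pixel proposal
    scales adapt toward ``adapt_target`` acceptance during burn-in only,
    with a diminishing adaptation rate, and are frozen afterwards so the
    post-burn-in kernel is a fixed, valid MCMC kernel.
    """
    m = x.size
    gamma = gamma0
    acc_x = 0.0
    tot_x = 0.0
    acc_t = 0.0
    tot_t = 0.0
    keep = 0
    order = np.arange(m)
    for it in range(n_iter):
        if it % 100 == 0:
            recompute_lam(x, Aip, Arow, Aval, lam)
        adapting = it < burn_in
        ar = adapt_rate / (1.0 + 0.1 * it) ** 0.6
        if random_scan:
            order = np.random.permutation(m)
        for jj in range(m):
            j = order[jj]
            xp = x[j] + step_x[j] * np.random.normal()
            accepted = False
            if xp >= 0.0:
                d = pixel_delta(j, xp, x, tau, lam, y, Aip, Arow, Aval, nbp, nbi, nbw)
                if d >= 0.0 or np.random.random() < math.exp(d):
                    dxv = xp - x[j]
                    for k in range(Aip[j], Aip[j + 1]):
                        lam[Arow[k]] += Aval[k] * dxv
                    x[j] = xp
                    accepted = True
            tot_x += 1.0
            if accepted:
                acc_x += 1.0
            if adapting:
                if accepted:
                    step_x[j] *= math.exp(ar * (1.0 - adapt_target))
                else:
                    step_x[j] *= math.exp(-ar * adapt_target)
                if step_x[j] < 1e-6:
                    step_x[j] = 1e-6
                elif step_x[j] > 1e4:
                    step_x[j] = 1e4
        if sample_tau:
            if inhom:
                for j in range(m):
                    S = site_energy(x, j, nbp, nbi, nbw)
                    tau[j], a = tau_update(tau[j], S, gamma, tau_step, tau_floor)
                    tot_t += 1.0
                    if a:
                        acc_t += 1.0
            else:
                S_tot = total_energy(x, nbp, nbi, nbw)
                tnew, a = global_tau_update(tau[0], S_tot, m, gamma, tau_step, tau_floor)
                tau[:] = tnew
                tot_t += 1.0
                if a:
                    acc_t += 1.0
        if not gamma_fixed:
            if inhom:
                shape = m + 1.0
                rate = tau.sum() + theta
            else:
                shape = 2.0
                rate = tau[0] + theta
            gamma = draw_gamma(shape, rate)
        if it >= burn_in and (it - burn_in) % thin == 0:
            recompute_lam(x, Aip, Arow, Aval, lam)
            for j in range(m):
                out_x[keep, j] = x[j]
                out_tau[keep, j] = tau[j]
            out_gamma[keep] = gamma
            out_logpost[keep] = log_joint_k(
                y, lam, x, tau, gamma, nbp, nbi, nbw, inhom, gamma_fixed, theta
            )
            keep += 1
    acc_rate_x = acc_x / tot_x if tot_x > 0 else 0.0
    acc_rate_t = acc_t / tot_t if tot_t > 0 else 0.0
    return acc_rate_x, acc_rate_t, gamma, keep
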
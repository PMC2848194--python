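"""Compiled numeric kernels for the annealing optimizer.

The parameter vector layout throughout is ``theta = [alpha, beta, w_1..w_p]``
with the design matrix ``X`` holding the matching regulator series at times
1..T-1 (one column per active weight) and ``dg`` the observed one-step
changes g(2..T) - g(1..T-1). The energy is SSE/Var.

These kernels are also callable from plain Python; the analytic gradient is
cross-checked against finite differences in the test suite. Hot paths use
explicit loops over the time axis to avoid temporary allocations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: safety cap on restart cycles inside one fit
MAX_CYCLES = 64


@njit(cache=False)
def energy(X, dg, inv_var, theta):
    T, p = X.shape
    alpha = theta[0]
    beta = theta[1]
    acc = 0.0
    for t in range(T):
        u = -beta
        for j in range(p):
            u += X[t, j] * theta[2 + j]
        r = dg[t] - alpha * math.tanh(u)
        acc += r * r
    return acc * inv_var


@njit(cache=False)
def gradient(X, dg, inv_var, theta):
    """Analytic gradient of E = SSE/Var w.r.t. (alpha, beta, w...).

    With u(t) the tanh argument and r(t) the residual:
    dSSE/dalpha = -2 sum r*tanh(u); dSSE/dbeta = +2 alpha sum r*sech2(u);
    dSSE/dw_j   = -2 alpha sum r*sech2(u)*x_j.
    """
    T, p = X.shape
    alpha = theta[0]
    beta = theta[1]
    g = np.zeros(p + 2)
    for t in range(T):
        u = -beta
        for j in range(p):
            u += X[t, j] * theta[2 + j]
        th = math.tanh(u)
        r = dg[t] - alpha * th
        sech2 = 1.0 - th * th
        g[0] += -2.0 * r * th
        g[1] += 2.0 * alpha * r * sech2
        rs = -2.0 * alpha * r * sech2
        for j in range(p):
            g[2 + j] += rs * X[t, j]
    for j in range(p + 2):
        g[j] *= inv_var
    return g


@njit(cache=False)
def polish(X, dg, inv_var, theta0, lam0, max_iter):
    """Deterministic finishing descent from the annealed optimum.

    Adaptive step size: grow on success, halve on failure. Resolves the
    shallow valley along near-unidentifiable parameter combinations
    (e.g. alpha vs w when the tanh operates in its linear range) that the
    fixed-step stochastic phase crawls through.
    """
    p = theta0.shape[0]
    theta = theta0.copy()
    e_cur = energy(X, dg, inv_var, theta)
    cand = np.empty(p)
    lam = lam0
    for _ in range(max_iter):
        g = gradient(X, dg, inv_var, theta)
        gnorm = 0.0
        for j in range(p):
            gnorm += g[j] * g[j]
        if gnorm < 1e-28:
            break
        for j in range(p):
            cand[j] = theta[j] - lam * g[j]
        e_new = energy(X, dg, inv_var, cand)
        if np.isfinite(e_new) and e_new < e_cur:
            tmp = theta
            theta = cand
            cand = tmp
            e_cur = e_new
            lam *= 1.3
        else:
            lam *= 0.5
            if lam < 1e-16:
                break
    return theta, e_cur


@njit(cache=False)
def anneal(
    X,
    dg,
    inv_var,
    theta0,
    t_max,
    inner_iters,
    lam,
    kappa,
    sigma0,
    eps,
    n_c,
    n_f,
    max_cycles,
    seed,
):
    """SGD-enhanced simulated annealing for one gene / one structure.

    Mixed proposals: with probability 1 - P_gradient(t) a damped steepest
    descent step (theta - lam * grad E), otherwise an annealed Gaussian
    perturbation with scale sigma0 * t / t_max; Metropolis-Hastings
    acceptance exp(-dE / (kappa * t)); integer temperature countdown
    t_max -> 1; convergence when energies at n_c consecutive temperature
    pairs differ by < eps; then a multiplicative restart theta_best *
    U(0.75, 1.25) per coordinate, terminating after n_f consecutive
    restarts without improving the best energy by more than eps (or at the
    max_cycles cap).

    Returns (theta_best, e_best, cycle_best_energies, n_cycles).
    """
    np.random.seed(seed)
    p = theta0.shape[0]
    theta = theta0.copy()
    theta_new = np.empty(p)
    e_cur = energy(X, dg, inv_var, theta)
    theta_best = theta.copy()
    e_best = e_cur
    if max_cycles > MAX_CYCLES:
        max_cycles = MAX_CYCLES
    trace = np.empty(MAX_CYCLES)
    n_cycles = 0
    fails = 0
    e_temp = np.empty(t_max + 1)  # energy recorded at each temperature

    while n_cycles < max_cycles:
        t = t_max
        while t >= 1:
            p_gradient = 0.2 + 0.3 * t / t_max
            for _ in range(inner_iters):
                r = np.random.random()
                if r > p_gradient:
                    grad = gradient(X, dg, inv_var, theta)
                    for j in range(p):
                        theta_new[j] = theta[j] - lam * grad[j]
                else:
                    sigma = sigma0 * t / t_max
                    for j in range(p):
                        theta_new[j] = theta[j] + sigma * np.random.standard_normal()
                e_new = energy(X, dg, inv_var, theta_new)
                if not np.isfinite(e_new):
                    continue
                accept = False
                if e_new < e_cur:
                    accept = True
                else:
                    p_mh = np.exp((e_cur - e_new) / (kappa * t))
                    if np.random.random() < p_mh:
                        accept = True
                if accept:
                    tmp = theta
                    theta = theta_new
                    theta_new = tmp
                    e_cur = e_new
                    if e_cur < e_best:
                        e_best = e_cur
                        theta_best = theta.copy()
            e_temp[t] = e_cur
            # convergence over n_c consecutive temperature pairs
            if t_max - t >= n_c:
                converged = True
                for k in range(n_c):
                    if abs(e_temp[t + k + 1] - e_temp[t + k]) >= eps:
                        converged = False
                        break
                if converged:
                    break
            t -= 1

        prev_best = trace[n_cycles - 1] if n_cycles > 0 else np.inf
        trace[n_cycles] = e_best
        n_cycles += 1
        if e_best < prev_best - eps:
            fails = 0
        else:
            fails += 1
        if fails >= n_f:
            break
        # restart: multiplicative perturbation of the best state
        for j in range(p):
            theta[j] = theta_best[j] * np.random.uniform(0.75, 1.25)
        e_cur = energy(X, dg, inv_var, theta)

    return theta_best, e_best, trace[:n_cycles], n_cycles
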
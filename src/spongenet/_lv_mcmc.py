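"""Metropolis-within-Gibbs kernel for the sparse Lotka-Volterra state-space model.

Latent log-abundances n[i,m] follow the discrete Lotka-Volterra (Ricker-type)
map with process noise; observed counts are Poisson with log-rate
n[i,m] + log(N_m) + Pi_m. Interaction coefficients alpha[i,j] carry binary
inclusion indicators gamma[i,j] ~ Bernoulli(P) (Gibbs variable selection):
the gamma update marginalizes the Gaussian slab in closed form, which is the
collapsed form of the usual pseudo-prior construction and mixes without
tuning.

Everything in this module is numba-jit and operates on plain arrays; the
user-facing surface lives in :mod:`spongenet.core_lv`.

Update blocks per sweep
-----------------------
* n[i,m]  - single-site random-walk Metropolis; the outgoing-transition part
  of the ratio touches only species with an included link from i (plus i
  itself), and the interaction load X[i,m] = N[i,m] + sum_j g*a*N[j,m] is
  cached and updated incrementally.
* r[i]    - exact Gaussian conditional (the transition mean is linear in r).
* k[i]    - random-walk Metropolis on log k (Exp prior + Jacobian).
* sigma[i]- random-walk Metropolis on log sigma (half-normal prior).
* gamma/alpha[i,j] - collapsed Bernoulli draw, then alpha from its Gaussian
  conditional (included) or the slab prior (excluded).
* Pi[m]   - random-walk Metropolis (Poisson likelihood, normal prior).

Step sizes adapt toward ~40% acceptance during burn-in and are frozen after.
"""

import numpy as np
from numba import njit

__all__ = ["run_chain"]


@njit(inline="always")
def _compute_X(n_lat, N, alpha, gamma):
    S, M = n_lat.shape
    X = np.empty((S, M))
    for m in range(M):
        for i in range(S):
            acc = N[i, m]
            for j in range(S):
                if j != i and gamma[i, j] == 1:
                    acc += alpha[i, j] * N[j, m]
            X[i, m] = acc
    return X


@njit
def run_chain(
    y,            # (S, M) int64 counts
    logN,         # (M,) observed log totals (offsets)
    n_iter,
    burn_in,
    thin,
    seed,
    P,            # prior inclusion probability
    var_r,        # prior variance of r
    k_rate,       # Exp prior rate for k
    tau2,         # slab variance for alpha
    pi_sd,        # prior sd of Pi
    sigma_scale,  # half-normal scale for sigma
    init_sd,      # sd of the n[:,0] ~ N(log k, init_sd) anchor
    n0,           # (S, M) initial latent states
    r0,           # (S,) initial r
    k0,           # (S,) initial k
    sigma0,       # (S,) initial sigma
):
    np.random.seed(seed)
    S, M = y.shape
    n_lat = n0.copy()
    N = np.exp(n_lat)
    r = r0.copy()
    k = k0.copy()
    sigma = sigma0.copy()
    alpha = np.zeros((S, S))
    gamma = np.zeros((S, S), dtype=np.int64)
    pi = np.zeros(M)
    X = _compute_X(n_lat, N, alpha, gamma)
    colsum_y = np.zeros(M)
    for m in range(M):
        for i in range(S):
            colsum_y[m] += y[i, m]

    # adaptive step sizes
    step_n = np.full(S, 0.2)
    step_k = np.full(S, 0.2)
    step_s = np.full(S, 0.3)
    step_pi = 0.05
    step_cm = 0.1
    acc_cm = 0.0
    step_gl = 0.2
    acc_gl = 0.0
    acc_n = np.zeros(S)
    try_n = np.zeros(S)
    acc_k = np.zeros(S)
    acc_s = np.zeros(S)
    acc_pi = 0.0
    adapt_every = 50

    n_keep = (n_iter - burn_in) // thin
    r_draws = np.empty((n_keep, S))
    k_draws = np.empty((n_keep, S))
    s_draws = np.empty((n_keep, S))
    a_draws = np.empty((n_keep, S, S))
    g_draws = np.empty((n_keep, S, S), dtype=np.int64)
    pi_draws = np.empty((n_keep, M))
    n_mean = np.zeros((S, M))
    jumps = np.zeros((S, S), dtype=np.int64)
    kept = 0

    for it in range(n_iter):
        # --- latent states, single-site ---
        for m in range(M):
            off = logN[m] + pi[m]
            for i in range(S):
                cur = n_lat[i, m]
                prop = cur + step_n[i] * np.random.normal()
                Ncur = N[i, m]
                Nprop = np.exp(prop)
                d = y[i, m] * (prop - cur) - (np.exp(prop + off) - np.exp(cur + off))
                if m == 0:
                    lk = np.log(k[i])
                    d -= ((prop - lk) ** 2 - (cur - lk) ** 2) / (2.0 * init_sd * init_sd)
                else:
                    mu = n_lat[i, m - 1] + r[i] * (1.0 - X[i, m - 1] / k[i])
                    d -= ((prop - mu) ** 2 - (cur - mu) ** 2) / (2.0 * sigma[i] ** 2)
                if m < M - 1:
                    dN = Nprop - Ncur
                    for i2 in range(S):
                        if i2 == i:
                            w = 1.0
                        elif gamma[i2, i] == 1:
                            w = alpha[i2, i]
                        else:
                            continue
                        base = n_lat[i2, m] if i2 != i else 0.0
                        mu_old = (base if i2 != i else cur) + r[i2] * (
                            1.0 - X[i2, m] / k[i2]
                        )
                        mu_new = (base if i2 != i else prop) + r[i2] * (
                            1.0 - (X[i2, m] + w * dN) / k[i2]
                        )
                        nxt = n_lat[i2, m + 1]
                        d -= ((nxt - mu_new) ** 2 - (nxt - mu_old) ** 2) / (
                            2.0 * sigma[i2] ** 2
                        )
                try_n[i] += 1.0
                if np.log(np.random.random()) < d:
                    acc_n[i] += 1.0
                    n_lat[i, m] = prop
                    N[i, m] = Nprop
                    dN = Nprop - Ncur
                    X[i, m] += dN
                    for i2 in range(S):
                        if i2 != i and gamma[i2, i] == 1:
                            X[i2, m] += alpha[i2, i] * dN

        # --- growth rates r (conjugate) ---
        for i in range(S):
            s2 = sigma[i] ** 2
            sg2 = 0.0
            sgd = 0.0
            for m in range(1, M):
                g = 1.0 - X[i, m - 1] / k[i]
                dnm = n_lat[i, m] - n_lat[i, m - 1]
                sg2 += g * g
                sgd += g * dnm
            prec = 1.0 / var_r + sg2 / s2
            mu = (sgd / s2) / prec
            r[i] = mu + np.random.normal() / np.sqrt(prec)

        # --- carrying capacities k (MH on log k) ---
        for i in range(S):
            lk = np.log(k[i])
            lkp = lk + step_k[i] * np.random.normal()
            kp = np.exp(lkp)
            s2 = sigma[i] ** 2
            d = 0.0
            for m in range(1, M):
                dnm = n_lat[i, m] - n_lat[i, m - 1]
                e_old = dnm - r[i] * (1.0 - X[i, m - 1] / k[i])
                e_new = dnm - r[i] * (1.0 - X[i, m - 1] / kp)
                d -= (e_new * e_new - e_old * e_old) / (2.0 * s2)
            d -= ((n_lat[i, 0] - lkp) ** 2 - (n_lat[i, 0] - lk) ** 2) / (
                2.0 * init_sd * init_sd
            )
            d -= k_rate * (kp - k[i])
            d += lkp - lk  # Jacobian of the log transform
            if np.log(np.random.random()) < d:
                acc_k[i] += 1.0
                k[i] = kp

        # --- process noise sigma (MH on log sigma) ---
        for i in range(S):
            ls = np.log(sigma[i])
            lsp = ls + step_s[i] * np.random.normal()
            sp = np.exp(lsp)
            sse = 0.0
            for m in range(1, M):
                mu = n_lat[i, m - 1] + r[i] * (1.0 - X[i, m - 1] / k[i])
                e = n_lat[i, m] - mu
                sse += e * e
            d = -(M - 1) * (lsp - ls)
            d -= sse / 2.0 * (1.0 / (sp * sp) - 1.0 / (sigma[i] ** 2))
            d -= (sp * sp - sigma[i] ** 2) / (2.0 * sigma_scale * sigma_scale)
            d += lsp - ls
            if np.log(np.random.random()) < d:
                acc_s[i] += 1.0
                sigma[i] = sp

        # --- interaction links: collapsed gamma, then alpha ---
        for i in range(S):
            s2 = sigma[i] ** 2
            for j in range(S):
                if j == i:
                    continue
                if gamma[i, j] == 1:  # strip j's contribution from the load
                    for m in range(M):
                        X[i, m] -= alpha[i, j] * N[j, m]
                sxx = 0.0
                sxc = 0.0
                for m in range(1, M):
                    x = -(r[i] / k[i]) * N[j, m - 1]
                    c = n_lat[i, m] - n_lat[i, m - 1] - r[i] * (
                        1.0 - X[i, m - 1] / k[i]
                    )
                    sxx += x * x
                    sxc += x * c
                q = 1.0 / tau2 + sxx / s2
                mu = (sxc / s2) / q
                log_bf = -0.5 * np.log(tau2 * q) + 0.5 * mu * mu * q
                logit = np.log(P / (1.0 - P)) + log_bf
                if logit > 35.0:
                    p1 = 1.0
                elif logit < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logit))
                g_new = 1 if np.random.random() < p1 else 0
                if g_new != gamma[i, j]:
                    jumps[i, j] += 1
                gamma[i, j] = g_new
                if g_new == 1:
                    alpha[i, j] = mu + np.random.normal() / np.sqrt(q)
                    for m in range(M):
                        X[i, m] += alpha[i, j] * N[j, m]
                else:
                    alpha[i, j] = np.sqrt(tau2) * np.random.normal()

        # --- per-replicate offsets Pi (MH) ---
        for m in range(M):
            sN = 0.0
            for i in range(S):
                sN += N[i, m]
            cur = pi[m]
            prop = cur + step_pi * np.random.normal()
            d = colsum_y[m] * (prop - cur)
            d -= np.exp(logN[m]) * sN * (np.exp(prop) - np.exp(cur))
            d -= (prop * prop - cur * cur) / (2.0 * pi_sd * pi_sd)
            if np.log(np.random.random()) < d:
                acc_pi += 1.0
                pi[m] = prop

        # --- common-mode move: n[:,m] -= delta, Pi_m += delta ---
        # leaves the Poisson term invariant and mixes the replicate-level
        # scale the single-site updates explore poorly
        for m in range(M):
            delta = step_cm * np.random.normal()
            f = np.exp(-delta)
            d = -(2.0 * pi[m] * delta + delta * delta) / (2.0 * pi_sd * pi_sd)
            if m == 0:
                for i in range(S):
                    lk = np.log(k[i])
                    cur = n_lat[i, 0]
                    d -= ((cur - delta - lk) ** 2 - (cur - lk) ** 2) / (
                        2.0 * init_sd * init_sd
                    )
            else:
                for i in range(S):
                    mu = n_lat[i, m - 1] + r[i] * (1.0 - X[i, m - 1] / k[i])
                    cur = n_lat[i, m]
                    d -= ((cur - delta - mu) ** 2 - (cur - mu) ** 2) / (
                        2.0 * sigma[i] ** 2
                    )
            if m < M - 1:
                for i in range(S):
                    mu_old = n_lat[i, m] + r[i] * (1.0 - X[i, m] / k[i])
                    mu_new = (n_lat[i, m] - delta) + r[i] * (
                        1.0 - X[i, m] * f / k[i]
                    )
                    nxt = n_lat[i, m + 1]
                    d -= ((nxt - mu_new) ** 2 - (nxt - mu_old) ** 2) / (
                        2.0 * sigma[i] ** 2
                    )
            if np.log(np.random.random()) < d:
                acc_cm += 1.0
                pi[m] += delta
                for i in range(S):
                    n_lat[i, m] -= delta
                    N[i, m] *= f
                    X[i, m] *= f

        # --- global scale move: n -= delta, k *= exp(-delta), Pi += delta ---
        # the posterior is nearly flat along this direction (observations and
        # transitions are exactly invariant); only the Pi and k priors and
        # the transform Jacobian enter the ratio
        delta = step_gl * np.random.normal()
        f = np.exp(-delta)
        d = -S * delta  # Jacobian of k -> k * exp(-delta)
        for m in range(M):
            d -= (2.0 * pi[m] * delta + delta * delta) / (2.0 * pi_sd * pi_sd)
        for i in range(S):
            d -= k_rate * (k[i] * f - k[i])
        if np.log(np.random.random()) < d:
            acc_gl += 1.0
            for m in range(M):
                pi[m] += delta
                for i in range(S):
                    n_lat[i, m] -= delta
                    N[i, m] *= f
                    X[i, m] *= f
            for i in range(S):
                k[i] *= f

        # --- step-size adaptation (burn-in only) ---
        if it < burn_in and (it + 1) % adapt_every == 0:
            for i in range(S):
                rate = acc_n[i] / max(try_n[i], 1.0)
                step_n[i] *= np.exp(0.66 * (rate - 0.40))
                acc_n[i] = 0.0
                try_n[i] = 0.0
                rate = acc_k[i] / adapt_every
                step_k[i] *= np.exp(0.66 * (rate - 0.40))
                acc_k[i] = 0.0
                rate = acc_s[i] / adapt_every
                step_s[i] *= np.exp(0.66 * (rate - 0.40))
                acc_s[i] = 0.0
            rate = acc_pi / (adapt_every * M)
            step_pi *= np.exp(0.66 * (rate - 0.40))
            acc_pi = 0.0
            rate = acc_cm / (adapt_every * M)
            step_cm *= np.exp(0.66 * (rate - 0.40))
            acc_cm = 0.0
            rate = acc_gl / adapt_every
            step_gl *= np.exp(0.66 * (rate - 0.40))
            acc_gl = 0.0
            # refresh the load cache to kill accumulated float drift
            X = _compute_X(n_lat, N, alpha, gamma)

        # --- retain ---
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            r_draws[kept] = r
            k_draws[kept] = k
            s_draws[kept] = sigma
            a_draws[kept] = alpha
            g_draws[kept] = gamma
            pi_draws[kept] = pi
            n_mean += n_lat
            kept += 1

    if kept > 0:
        n_mean /= kept
    return r_draws, k_draws, s_draws, a_draws, g_draws, pi_draws, n_mean, jumps
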
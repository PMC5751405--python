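"""Numba kernels for the collapsed Gibbs sampler of a DP Gaussian mixture.

The model is a Dirichlet-process mixture of Gaussians with a conjugate base
measure: Normal-inverse-Wishart (full covariance) or per-dimension
Normal-inverse-chi-squared (diagonal covariance). Component parameters are
marginalised out, so the sampler's state is just the vector of component
indicators plus per-component sufficient statistics (count, sum, raw
second-moment matrix). Each sweep reassigns every point from its conditional:

    p(z_i = c | z_-i, x)  proportional to  n_c^{-i} * t_c(x_i)      (existing)
    p(z_i = new | ...)    proportional to  alpha   * t_0(x_i)       (new)

where t_c is the multivariate Student-t posterior predictive of component c
given its other members and t_0 the prior predictive. The concentration
parameter alpha can be resampled each sweep under a Gamma(1,1) prior using
the Escobar-West auxiliary-variable scheme.

All randomness flows through numba's RNG seeded once per call, so runs are
reproducible given the seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_PI = math.log(math.pi)


@njit(cache=True)
def _chol_lower(A):
    """Lower Cholesky factor of a small SPD matrix (diagonal floored)."""
    d = A.shape[0]
    L = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-300:
                    s = 1e-300
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L


@njit(cache=True)
def _posterior_niw(m, s, S, mu0, kappa0, nu0, Psi0):
    """Posterior NIW parameters (kappa_n, nu_n, mu_n, Psi_n) from raw stats."""
    d = mu0.shape[0]
    kn = kappa0 + m
    nun = nu0 + m
    mun = np.empty(d)
    Psin = Psi0.copy()
    if m > 0:
        for i in range(d):
            mun[i] = (kappa0 * mu0[i] + s[i]) / kn
        coef = kappa0 * m / kn
        for i in range(d):
            xbi = s[i] / m
            for j in range(d):
                xbj = s[j] / m
                Psin[i, j] += (
                    S[i, j]
                    - s[i] * s[j] / m
                    + coef * (xbi - mu0[i]) * (xbj - mu0[j])
                )
    else:
        for i in range(d):
            mun[i] = mu0[i]
    return kn, nun, mun, Psin


@njit(cache=True)
def logpred_full(x, m, s, S, mu0, kappa0, nu0, Psi0):
    """Log posterior-predictive density (multivariate Student-t) at x.

    For m = 0 this is the prior predictive: t with nu0-d+1 degrees of
    freedom, location mu0 and scale Psi0*(kappa0+1)/(kappa0*(nu0-d+1)).
    """
    d = x.shape[0]
    kn, nun, mun, Psin = _posterior_niw(m, s, S, mu0, kappa0, nu0, Psi0)
    df = nun - d + 1.0
    c = (kn + 1.0) / (kn * df)
    L = _chol_lower(Psin * c)
    # solve L y = x - mun
    y = np.empty(d)
    for i in range(d):
        acc = x[i] - mun[i]
        for j in range(i):
            acc -= L[i, j] * y[j]
        y[i] = acc / L[i, i]
    quad = 0.0
    logdet = 0.0
    for i in range(d):
        quad += y[i] * y[i]
        logdet += 2.0 * math.log(L[i, i])
    return (
        math.lgamma(0.5 * (df + d))
        - math.lgamma(0.5 * df)
        - 0.5 * d * math.log(df * math.pi)
        - 0.5 * logdet
        - 0.5 * (df + d) * math.log1p(quad / df)
    )


@njit(cache=True)
def logpred_diag(x, m, s, ss, mu0, kappa0, nu0, psi0):
    """Log posterior predictive under independent per-dimension NIX2 priors.

    Per dimension: sigma^2 ~ Inv-chi2(nu0, psi0_j/nu0)-style with scale
    psi0_j, mu | sigma^2 ~ N(mu0_j, sigma^2/kappa0); predictive is a
    univariate Student-t with nu0+m degrees of freedom.
    """
    d = x.shape[0]
    kn = kappa0 + m
    nun = nu0 + m
    out = 0.0
    for j in range(d):
        if m > 0:
            xb = s[j] / m
            scatter = ss[j] - s[j] * s[j] / m
            psin = psi0[j] + scatter + (kappa0 * m / kn) * (xb - mu0[j]) ** 2
            mun = (kappa0 * mu0[j] + s[j]) / kn
        else:
            psin = psi0[j]
            mun = mu0[j]
        scale = psin * (kn + 1.0) / (kn * nun)
        z2 = (x[j] - mun) ** 2 / scale
        out += (
            math.lgamma(0.5 * (nun + 1.0))
            - math.lgamma(0.5 * nun)
            - 0.5 * math.log(nun * math.pi * scale)
            - 0.5 * (nun + 1.0) * math.log1p(z2 / nun)
        )
    return out


@njit(cache=True)
def _mvlgamma(a, d):
    r = 0.25 * d * (d - 1) * LOG_PI
    for j in range(d):
        r += math.lgamma(a - 0.5 * j)
    return r


@njit(cache=True)
def _logdet_chol(A):
    L = _chol_lower(A)
    out = 0.0
    for i in range(A.shape[0]):
        out += 2.0 * math.log(L[i, i])
    return out


@njit(cache=True)
def _logmarg_full(m, s, S, mu0, kappa0, nu0, Psi0, logdet_psi0):
    """Log marginal likelihood of a component's members under the NIW prior."""
    if m == 0:
        return 0.0
    d = mu0.shape[0]
    kn, nun, _, Psin = _posterior_niw(m, s, S, mu0, kappa0, nu0, Psi0)
    return (
        -0.5 * m * d * LOG_PI
        + _mvlgamma(0.5 * nun, d)
        - _mvlgamma(0.5 * nu0, d)
        + 0.5 * nu0 * logdet_psi0
        - 0.5 * nun * _logdet_chol(Psin)
        + 0.5 * d * (math.log(kappa0) - math.log(kn))
    )


@njit(cache=True)
def _logmarg_diag(m, s, ss, mu0, kappa0, nu0, psi0):
    if m == 0:
        return 0.0
    d = mu0.shape[0]
    kn = kappa0 + m
    nun = nu0 + m
    out = 0.0
    for j in range(d):
        xb = s[j] / m
        scatter = ss[j] - s[j] * s[j] / m
        psin = psi0[j] + scatter + (kappa0 * m / kn) * (xb - mu0[j]) ** 2
        out += (
            -0.5 * m * LOG_PI
            + math.lgamma(0.5 * nun)
            - math.lgamma(0.5 * nu0)
            + 0.5 * (nu0 * math.log(psi0[j]) - nun * math.log(psin))
            + 0.5 * (math.log(kappa0) - math.log(kn))
        )
    return out


@njit(cache=True)
def run_gibbs(
    X,
    n_iter,
    burn_in,
    alpha_init,
    resample_alpha,
    a_alpha,
    b_alpha,
    kappa0,
    nu0,
    mu0,
    Psi0,
    psi0_diag,
    diag,
    max_init,
    seed,
):
    """Run the collapsed Gibbs sampler.

    Sweep 0 assigns points sequentially from the predictive (a CRP-style
    initialisation, capped at ``max_init`` components); subsequent sweeps
    reassign every point given all others. Among post-burn-in sweeps the
    assignment with the highest joint log posterior (CRP prior times
    component marginal likelihoods) is retained.

    Returns
    -------
    (best_z, k_samples, best_logp, alpha)
    """
    np.random.seed(seed)
    n, d = X.shape
    alpha = alpha_init

    z = np.full(n, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    csum = np.zeros((n, d))
    cS = np.zeros((n, d, d))
    css = np.zeros((n, d))
    high = 0  # slots [0, high) have ever been used
    k = 0

    logdet_psi0 = _logdet_chol(Psi0)

    best_z = np.zeros(n, dtype=np.int64)
    best_logp = -np.inf
    n_keep = n_iter - burn_in
    k_samples = np.zeros(n_keep, dtype=np.int64)

    slots = np.empty(n, dtype=np.int64)
    logw = np.empty(n + 1)

    for sweep in range(n_iter):
        init_sweep = sweep == 0
        for i in range(n):
            x = X[i]
            old = z[i]
            if old >= 0:
                counts[old] -= 1
                if counts[old] == 0:
                    k -= 1
                for a in range(d):
                    csum[old, a] -= x[a]
                    css[old, a] -= x[a] * x[a]
                if diag == 0:
                    for a in range(d):
                        for b in range(d):
                            cS[old, a, b] -= x[a] * x[b]

            nact = 0
            for c in range(high):
                if counts[c] > 0:
                    slots[nact] = c
                    if diag == 0:
                        lp = logpred_full(
                            x, counts[c], csum[c], cS[c], mu0, kappa0, nu0, Psi0
                        )
                    else:
                        lp = logpred_diag(
                            x, counts[c], csum[c], css[c], mu0, kappa0, nu0,
                            psi0_diag,
                        )
                    logw[nact] = math.log(counts[c]) + lp
                    nact += 1
            allow_new = (not init_sweep) or (nact < max_init)
            ntot = nact
            if allow_new:
                if diag == 0:
                    lp0 = logpred_full(
                        x, 0, csum[0], cS[0], mu0, kappa0, nu0, Psi0
                    )
                else:
                    lp0 = logpred_diag(
                        x, 0, csum[0], css[0], mu0, kappa0, nu0, psi0_diag
                    )
                logw[nact] = math.log(alpha) + lp0
                ntot += 1

            mx = logw[0]
            for c in range(1, ntot):
                if logw[c] > mx:
                    mx = logw[c]
            tot = 0.0
            for c in range(ntot):
                logw[c] = math.exp(logw[c] - mx)
                tot += logw[c]
            u = np.random.random() * tot
            acc = 0.0
            pick = ntot - 1
            for c in range(ntot):
                acc += logw[c]
                if u <= acc:
                    pick = c
                    break

            if pick < nact:
                slot = slots[pick]
            else:
                slot = -1
                for c in range(high):
                    if counts[c] == 0:
                        slot = c
                        break
                if slot < 0:
                    slot = high
                    high += 1
                k += 1
            z[i] = slot
            counts[slot] += 1
            for a in range(d):
                csum[slot, a] += x[a]
                css[slot, a] += x[a] * x[a]
            if diag == 0:
                for a in range(d):
                    for b in range(d):
                        cS[slot, a, b] += x[a] * x[b]

        if resample_alpha == 1:
            # Escobar & West (1995) auxiliary-variable update, Gamma(a,b) prior
            eta = np.random.beta(alpha + 1.0, float(n))
            bminlog = b_alpha - math.log(eta)
            odds = (a_alpha + k - 1.0) / (n * bminlog)
            if np.random.random() < odds / (1.0 + odds):
                alpha = np.random.gamma(a_alpha + k, 1.0 / bminlog)
            else:
                alpha = np.random.gamma(a_alpha + k - 1.0, 1.0 / bminlog)
            if alpha < 1e-6:
                alpha = 1e-6

        if sweep >= burn_in:
            # joint log posterior of the current assignment
            logp = (
                k * math.log(alpha)
                + math.lgamma(alpha)
                - math.lgamma(alpha + n)
            )
            for c in range(high):
                if counts[c] > 0:
                    logp += math.lgamma(float(counts[c]))
                    if diag == 0:
                        logp += _logmarg_full(
                            counts[c], csum[c], cS[c], mu0, kappa0, nu0, Psi0,
                            logdet_psi0,
                        )
                    else:
                        logp += _logmarg_diag(
                            counts[c], csum[c], css[c], mu0, kappa0, nu0,
                            psi0_diag,
                        )
            k_samples[sweep - burn_in] = k
            if logp > best_logp:
                best_logp = logp
                for i in range(n):
                    best_z[i] = z[i]

    return best_z, k_samples, best_logp, alpha
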
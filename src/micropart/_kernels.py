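"""Numba kernels for the single-site Gibbs / Metropolis-Hastings sampler.

All kernels mutate their state arrays in place and draw randomness from a
``np.random.Generator`` passed in, so the whole chain is reproducible from
one seed regardless of which kernels run. The residual vector ``r`` is
maintained incrementally: after every accepted coefficient move the fitted
contribution is folded back into ``r`` (and, for the microbiome block, into
the maintained fitted vector ``fit``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def gibbs_sweep(W, wsq, coef, inv_prior_var, r, sigma_e2, rng):
    """One single-site Gibbs sweep over the columns of W.

    coef[j] is redrawn from its Normal full conditional
    ``v = (w_j'w_j / sigma_e2 + inv_prior_var[j])^-1``,
    ``mean = v * w_j' r_{-j} / sigma_e2``, with the residual updated after
    each draw. ``inv_prior_var[j] = 0`` encodes a flat prior.
    """
    n, k = W.shape
    for j in range(k):
        if wsq[j] == 0.0 and inv_prior_var[j] == 0.0:
            continue
        s = 0.0
        for i in range(n):
            s += W[i, j] * r[i]
        s += wsq[j] * coef[j]
        v = 1.0 / (wsq[j] / sigma_e2 + inv_prior_var[j])
        mean = v * s / sigma_e2
        new = mean + np.sqrt(v) * rng.normal(0.0, 1.0)
        d = new - coef[j]
        for i in range(n):
            r[i] -= W[i, j] * d
        coef[j] = new


@njit(cache=True)
def gibbs_sweep_tracked(W, wsq, coef, inv_prior_var, r, fit, sigma_e2, rng):
    """As :func:`gibbs_sweep`, additionally maintaining fit += W @ d(coef)."""
    n, k = W.shape
    for j in range(k):
        if wsq[j] == 0.0 and inv_prior_var[j] == 0.0:
            continue
        s = 0.0
        for i in range(n):
            s += W[i, j] * r[i]
        s += wsq[j] * coef[j]
        v = 1.0 / (wsq[j] / sigma_e2 + inv_prior_var[j])
        mean = v * s / sigma_e2
        new = mean + np.sqrt(v) * rng.normal(0.0, 1.0)
        d = new - coef[j]
        for i in range(n):
            r[i] -= W[i, j] * d
            fit[i] += W[i, j] * d
        coef[j] = new


@njit(cache=True)
def indicator_mh_sweep(beta, z, log_pi, comp_var, rng):
    """Metropolis-Hastings update of every mixture-component indicator.

    Proposals move to the neighbouring component: interior states propose
    up/down with probability 0.5 each; boundary states propose their single
    neighbour with probability 1. The Hastings correction
    ``q(z|z') / q(z'|z)`` is 0.5 when leaving a boundary, 2 when proposing
    onto one, and 1 otherwise (for K=2 the two corrections cancel).

    Returns the number of accepted moves.
    """
    K = log_pi.shape[0]
    p = beta.shape[0]
    accepted = 0
    if K < 2:
        return 0
    for i in range(p):
        zi = z[i]
        if zi == 0:
            zp = 1
        elif zi == K - 1:
            zp = K - 2
        else:
            zp = zi + 1 if rng.random() < 0.5 else zi - 1
        q_fwd = 1.0 if (zi == 0 or zi == K - 1) else 0.5
        q_rev = 1.0 if (zp == 0 or zp == K - 1) else 0.5
        b2 = beta[i] * beta[i]
        log_acc = (
            log_pi[zp]
            - log_pi[zi]
            - 0.5 * (np.log(comp_var[zp]) - np.log(comp_var[zi]))
            - 0.5 * b2 * (1.0 / comp_var[zp] - 1.0 / comp_var[zi])
            + np.log(q_rev / q_fwd)
        )
        if log_acc >= 0.0 or np.log(rng.random()) < log_acc:
            z[i] = zp
            accepted += 1
    return accepted


@njit(cache=True)
def mixture_loglik(beta, z, comp_var):
    """Sum of log N(beta_i; 0, comp_var[z_i])."""
    total = 0.0
    for i in range(beta.shape[0]):
        v = comp_var[z[i]]
        total += -0.5 * (LOG_2PI + np.log(v) + beta[i] * beta[i] / v)
    return total
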
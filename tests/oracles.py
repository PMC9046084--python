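"""Independent brute-force oracles used to validate the samplers.

These deliberately avoid the package's code paths: the posterior mean
oracle enumerates every read-assignment configuration and integrates the
Dirichlet prior analytically; the profile-MAP oracle is a dense 2-D grid
search on the stated objective.
"""

from __future__ import annotations

from itertools import product
from math import lgamma, log

import numpy as np
from scipy.special import logsumexp


def compositions(total: int, parts: int):
    """All nonnegative integer vectors of length ``parts`` summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def exact_posterior_mean_mu(x: np.ndarray, phi: np.ndarray, alpha: float) -> np.ndarray:
    """Exact E[mu | x] for the Dirichlet-multinomial mixture by enumeration.

    Enumerates every assignment U of each gene's reads to states, weights
    it by the marginal likelihood (the Dirichlet integral is analytic),
    and averages the conditional posterior mean of mu.
    """
    x = np.asarray(x, dtype=int)
    phi = np.asarray(phi, dtype=float)
    S, G = phi.shape
    R = int(x.sum())
    per_gene = [list(compositions(int(x[g]), S)) for g in range(G)]

    log_weights = []
    post_means = []
    for combo in product(*per_gene):
        U = np.array(combo).T  # S x G
        lw = 0.0
        for g in range(G):
            lw += lgamma(x[g] + 1)
            for s in range(S):
                lw -= lgamma(U[s, g] + 1)
                if U[s, g] > 0:
                    lw += U[s, g] * log(phi[s, g])
        R_s = U.sum(axis=1)
        for s in range(S):
            lw += lgamma(alpha + R_s[s]) - lgamma(alpha)
        lw += lgamma(S * alpha) - lgamma(S * alpha + R)
        log_weights.append(lw)
        post_means.append((alpha + R_s) / (S * alpha + R))
    log_weights = np.array(log_weights)
    post_means = np.array(post_means)
    w = np.exp(log_weights - logsumexp(log_weights))
    return w @ post_means


def grid_search_psi_env(
    z: np.ndarray, prior: np.ndarray, sigma: float, span: float = 5.0
) -> np.ndarray:
    """Dense 2-D grid search (coarse, then refined) for the 2-gene
    profile MAP objective; returns the optimal psi."""
    assert len(z) == 2 and len(prior) == 2

    def objective(lg1, lg2):
        w1 = prior[0] * np.exp(lg1)
        w2 = prior[1] * np.exp(lg2)
        tot = w1 + w2
        return (
            z[0] * (np.log(w1) - np.log(tot))
            + z[1] * (np.log(w2) - np.log(tot))
            - (lg1**2 + lg2**2) / (2 * sigma**2)
        )

    lo1 = lo2 = -span
    hi1 = hi2 = span
    step = 0.05
    for _ in range(3):
        g1 = np.arange(lo1, hi1 + step, step)
        g2 = np.arange(lo2, hi2 + step, step)
        A, B = np.meshgrid(g1, g2, indexing="ij")
        vals = objective(A, B)
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        best1, best2 = g1[i], g2[j]
        lo1, hi1 = best1 - 2 * step, best1 + 2 * step
        lo2, hi2 = best2 - 2 * step, best2 + 2 * step
        step /= 25.0
    w = prior * np.exp([best1, best2])
    return w / w.sum()
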
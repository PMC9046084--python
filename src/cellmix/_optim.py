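"""MAP estimation of a multinomial profile under a log-normal fold-change prior.

Shared by the reference update (pooled environment profiles) and the
embedding module (gene-program bases).  Given pooled counts ``z`` and a
prior centre profile ``prior``, the profile is parameterized as

    psi_g = prior_g * gamma_g / sum_g prior_g * gamma_g,
    log(gamma_g) ~ normal(0, sigma),

and ``log gamma`` is found by maximizing

    sum_g z_g * log psi_g  -  sum_g log(gamma_g)^2 / (2 sigma^2)

with a conjugate-gradient optimizer.  The normalization makes one
direction of log-gamma space flat; the Gaussian prior breaks the
degeneracy, so the problem is smooth and unconstrained.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)


def profile_map_objective(
    log_gamma: np.ndarray, z: np.ndarray, prior: np.ndarray, sigma: float
) -> float:
    """Log posterior (up to a constant) at a given log fold-change vector."""
    w = prior * np.exp(log_gamma)
    psi = w / w.sum()
    ll = float(np.dot(z, np.log(psi)))
    return ll - float(np.dot(log_gamma, log_gamma)) / (2.0 * sigma**2)


def _neg_obj_grad(log_gamma, z, prior, sigma, R):
    lw = np.log(prior) + log_gamma
    lw_max = lw.max()
    w = np.exp(lw - lw_max)
    tot = w.sum()
    log_psi = lw - lw_max - np.log(tot)
    obj = np.dot(z, log_psi) - np.dot(log_gamma, log_gamma) / (2.0 * sigma**2)
    psi = w / tot
    grad = z - R * psi - log_gamma / sigma**2
    return -obj, -grad


def map_profile(
    z: np.ndarray,
    prior: np.ndarray,
    sigma: float = 2.0,
    max_iter: int = 100_000,
    gtol: float = 1e-8,
    label: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """MAP profile given pooled counts and a prior centre.

    Returns ``(psi, gamma)``.  Falls back to the prior point (gamma=1)
    with a warning if the optimizer fails to improve on it.
    """
    z = np.asarray(z, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if z.shape != prior.shape:
        raise ValueError("counts and prior profile must have the same length")
    if np.any(prior <= 0):
        raise ValueError("prior profile must be strictly positive")
    if not np.all(np.isfinite(z)) or np.any(z < 0):
        raise ValueError(f"non-finite or negative pooled counts for {label or 'profile'}")
    R = z.sum()
    if R == 0:
        return prior / prior.sum(), np.ones_like(prior)

    x0 = np.zeros_like(prior)
    res = optimize.minimize(
        _neg_obj_grad,
        x0,
        args=(z, prior, sigma, R),
        jac=True,
        method="CG",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    f0 = profile_map_objective(x0, z, prior, sigma)
    f1 = profile_map_objective(res.x, z, prior, sigma)
    if not np.isfinite(f1):
        raise FloatingPointError(f"non-finite objective for {label or 'profile'}")
    if f1 < f0:
        logger.warning(
            "profile MAP for %s failed to improve on the prior point; "
            "returning gamma = 1", label or "profile",
        )
        return prior / prior.sum(), np.ones_like(prior)
    gamma = np.exp(res.x)
    w = prior * gamma
    return w / w.sum(), gamma
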
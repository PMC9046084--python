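"""Reference update: sample-specific malignant profiles, pooled
environment profiles, and re-estimated cell type fractions.

After a first deconvolution pass, the per-type read assignments Z carry
information absent from the single-cell prior.  The update exploits it
in two regimes:

* the malignant type is heterogeneous across tumours, so its profile is
  re-estimated per sample by maximum likelihood (the normalized Z row);
* nonmalignant ("environment") types are assumed similar across
  samples, so their reads are pooled over the cohort and a MAP profile
  is fit under a log-normal fold-change prior centred on the single-cell
  per-type reference phi' — with little data the estimate stays at the
  prior; with much data it moves to the pooled MLE.

A per-sample reference psi_n (malignant row sample-specific, other rows
shared) then replaces the prior and the Gibbs sampler is re-run at the
cell-type level, yielding the final fractions theta_f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._optim import map_profile
from .gibbs import (
    BulkExpression,
    CellTypeEstimate,
    GibbsConfig,
    _gibbs_one_sample,
)
from .reference import CellTypeReference, norm_to_one

logger = logging.getLogger(__name__)


@dataclass
class UpdatedReference:
    """Updated reference psi: per-sample malignant + pooled environment."""

    psi_mal: np.ndarray | None  # N x G (None in non-tumour mode)
    psi_env: np.ndarray  # T_env x G
    gamma: np.ndarray  # T_env x G fold-changes
    sigma: float
    malignant_type: int | None
    type_ids: list
    sample_ids: list
    gene_ids: np.ndarray | None = None

    @property
    def env_type_ids(self) -> list:
        if self.malignant_type is None:
            return list(self.type_ids)
        return [t for i, t in enumerate(self.type_ids) if i != self.malignant_type]

    def per_sample(self, n: int) -> np.ndarray:
        """Assemble the T x G reference for sample n (type order preserved)."""
        T = len(self.type_ids)
        G = self.psi_env.shape[1]
        psi = np.empty((T, G))
        env_rows = iter(range(self.psi_env.shape[0]))
        for t in range(T):
            if self.malignant_type is not None and t == self.malignant_type:
                psi[t] = self.psi_mal[n]
            else:
                psi[t] = self.psi_env[next(env_rows)]
        return psi


@dataclass
class FinalFractions:
    """Final cell-type fractions theta_f (rows on the simplex)."""

    theta_f: np.ndarray  # N x T
    sample_ids: list = field(default_factory=list)
    type_ids: list = field(default_factory=list)


def estimate_psi_mal(
    est: CellTypeEstimate,
    malignant_type: int,
    phi_prime: CellTypeReference,
    pseudo_min: float = 1e-8,
) -> np.ndarray:
    """Per-sample malignant profile: normalized malignant Z row, floored.

    Samples with no malignant reads fall back to the prior phi' row.
    """
    Z_mal = est.Z[:, malignant_type, :]
    N, G = Z_mal.shape
    out = np.empty((N, G))
    prior_row = phi_prime.phi_prime[malignant_type]
    for n in range(N):
        row = Z_mal[n]
        if row.sum() <= 0:
            logger.warning(
                "sample %s has no reads assigned to the malignant type; "
                "using the prior profile", est.sample_ids[n] if est.sample_ids else n,
            )
            out[n] = prior_row
        else:
            out[n] = norm_to_one(row, pseudo_min)
    return out


def estimate_psi_env(
    est: CellTypeEstimate,
    phi_prime: CellTypeReference,
    malignant_type: int | None,
    sigma: float = 2.0,
    cg_max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled MAP profiles for the environment types.

    Counts are pooled over all samples per type and fit independently
    (the log posterior separates across types).  Returns
    ``(psi_env, gamma)`` with one row per environment type, in type
    order with the malignant type omitted.
    """
    T = est.Z.shape[1]
    env_types = [t for t in range(T) if t != malignant_type]
    pooled = est.Z.sum(axis=0)  # T x G
    rows, gammas = [], []
    for t in env_types:
        label = str(est.type_ids[t]) if est.type_ids else str(t)
        psi, gamma = map_profile(
            pooled[t], phi_prime.phi_prime[t], sigma=sigma,
            max_iter=cg_max_iter, label=label,
        )
        rows.append(psi)
        gammas.append(gamma)
    return np.vstack(rows), np.vstack(gammas)


def build_updated_reference(
    est: CellTypeEstimate,
    phi_prime: CellTypeReference,
    malignant_type: int | None,
    sigma: float = 2.0,
    cg_max_iter: int = 100_000,
    pseudo_min: float = 1e-8,
    low_fraction_warn: float = 0.01,
) -> UpdatedReference:
    """Assemble psi from the first-pass estimate and the type prior.

    Environment types never reaching ``low_fraction_warn`` in any sample
    violate the pooling assumption's presence condition and are logged.
    """
    psi_env, gamma = estimate_psi_env(
        est, phi_prime, malignant_type, sigma=sigma, cg_max_iter=cg_max_iter
    )
    psi_mal = None
    if malignant_type is not None:
        psi_mal = estimate_psi_mal(est, malignant_type, phi_prime, pseudo_min)
    T = est.theta0.shape[1]
    for t in range(T):
        if t == malignant_type:
            continue
        if est.theta0[:, t].max() <= low_fraction_warn:
            logger.warning(
                "type %s never exceeds %.0f%% in any sample; the pooled "
                "profile update is poorly informed for it",
                est.type_ids[t] if est.type_ids else t, 100 * low_fraction_warn,
            )
    return UpdatedReference(
        psi_mal=psi_mal,
        psi_env=psi_env,
        gamma=gamma,
        sigma=sigma,
        malignant_type=malignant_type,
        type_ids=list(est.type_ids) if est.type_ids else list(range(T)),
        sample_ids=list(est.sample_ids),
        gene_ids=est.gene_ids,
    )


def refit_theta(
    bulk: BulkExpression, updated: UpdatedReference, cfg: GibbsConfig
) -> FinalFractions:
    """Re-run the Gibbs sampler at the type level with the updated reference."""
    N = bulk.X.shape[0]
    T = len(updated.type_ids)
    theta_f = np.empty((N, T))
    R = bulk.R
    for n in range(N):
        if R[n] == 0:
            raise ValueError(f"sample {bulk.sample_ids[n]!r} has zero reads")
        psi_n = updated.per_sample(n)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, n, 1]))
        theta_f[n], _ = _gibbs_one_sample(bulk.X[n], psi_n, cfg, rng)
    return FinalFractions(
        theta_f=theta_f,
        sample_ids=list(bulk.sample_ids),
        type_ids=list(updated.type_ids),
    )
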
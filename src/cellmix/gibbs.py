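"""Gibbs sampler for the Dirichlet–multinomial mixture deconvolution model.

Each bulk sample's reads are modelled as a two-stage draw: a fraction
vector ``mu`` over cell states from a symmetric Dirichlet(alpha) prior,
reads allocated to states multinomially by ``mu``, and each state's
reads distributed over genes by its reference profile ``phi``.  The
sampler alternates the two standard conditionals of the augmented
model:

* gene-wise read assignments ``U[., g] | mu, x_g`` — multinomial over
  states with weights proportional to ``mu_s * phi_sg``;
* fractions ``mu | U`` — Dirichlet(alpha + reads per state).

Posterior means of ``mu`` and ``U`` are taken over the retained draws
(after burn-in, thinned).  Samples are independent chains with RNG
streams derived from (seed, sample index), so results do not depend on
the order samples are processed in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference import CellStateReference

logger = logging.getLogger(__name__)


@dataclass
class BulkExpression:
    """Samples x genes nonnegative count matrix with ids."""

    X: np.ndarray
    sample_ids: list
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if np.any(X < 0):
            raise ValueError("bulk counts must be nonnegative")
        if not np.allclose(X, np.round(X)):
            logger.warning(
                "bulk matrix contains non-integer values; rounding to "
                "integers (the model is defined on counts)"
            )
        self.X = np.round(X).astype(np.int64)
        if self.X.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("X shape does not match ids")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def R(self) -> np.ndarray:
        """Per-sample total read counts."""
        return self.X.sum(axis=1)

    def align_genes(self, gene_ids) -> "BulkExpression":
        """Reorder/subset columns to match ``gene_ids`` (case-insensitive)."""
        lookup = {str(g).upper(): i for i, g in enumerate(self.gene_ids)}
        idx = []
        for g in gene_ids:
            key = str(g).upper()
            if key not in lookup:
                raise KeyError(f"gene {g!r} absent from bulk matrix")
            idx.append(lookup[key])
        return BulkExpression(
            X=self.X[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=np.asarray(gene_ids, dtype=object),
        )


@dataclass
class GibbsConfig:
    """MCMC schedule and prior strength.

    Defaults: a near-flat symmetric Dirichlet prior (alpha=1e-8) and a
    1000-sweep chain with 500 burn-in sweeps, keeping every 2nd draw.
    """

    alpha: float = 1e-8
    chain_length: int = 1000
    burn_in: int = 500
    thinning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("need 0 <= burn_in < chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means of state fractions and read assignments."""

    mu_bar: np.ndarray  # N x S
    U_bar: np.ndarray  # N x S x G
    sample_ids: list = field(default_factory=list)
    state_ids: list = field(default_factory=list)
    gene_ids: np.ndarray | None = None

    @property
    def R_ns(self) -> np.ndarray:
        """Mean reads assigned per (sample, state)."""
        return self.U_bar.sum(axis=2)


@dataclass
class CellTypeEstimate:
    """State posterior summed to cell types through the map h."""

    theta0: np.ndarray  # N x T
    Z: np.ndarray  # N x T x G
    sample_ids: list = field(default_factory=list)
    type_ids: list = field(default_factory=list)
    gene_ids: np.ndarray | None = None

    @property
    def R_nt(self) -> np.ndarray:
        return self.Z.sum(axis=2)


def sample_assignments(
    x_row: np.ndarray, phi: np.ndarray, mu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw read assignments U (states x genes) given fractions.

    For every gene g, ``U[:, g]`` is multinomial with size ``x_row[g]``
    and event probabilities proportional to ``mu_s * phi[s, g]``.
    Sampled as a chain of binomials vectorized over genes, so the cost
    is S-1 vectorized draws rather than G multinomial calls.
    """
    x_row = np.asarray(x_row)
    S, G = phi.shape
    weights = mu[:, None] * phi  # S x G
    col_tot = weights.sum(axis=0)
    if np.any((col_tot <= 0) & (x_row > 0)):
        raise ValueError("gene with reads but zero mixture probability")
    U = np.zeros((S, G), dtype=np.int64)
    remaining = x_row.astype(np.int64).copy()
    prob_left = col_tot.copy()
    for s in range(S - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(prob_left > 0, weights[s] / prob_left, 0.0)
        np.clip(p, 0.0, 1.0, out=p)
        draw = rng.binomial(remaining, p)
        U[s] = draw
        remaining -= draw
        prob_left -= weights[s]
    U[S - 1] = remaining
    return U


def sample_theta(U: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Draw fractions mu ~ Dirichlet(alpha + reads per state)."""
    R_s = np.asarray(U).sum(axis=1)
    gam = rng.standard_gamma(alpha + R_s)
    tot = gam.sum()
    if tot <= 0:  # numerically possible when all shapes are ~alpha
        gam = np.full_like(gam, 1.0 / len(gam))
        tot = 1.0
    return gam / tot


def _gibbs_one_sample(
    x_row: np.ndarray, phi: np.ndarray, cfg: GibbsConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Run one chain; return (mu_bar, U_bar) for this sample."""
    S, G = phi.shape
    mu = np.full(S, 1.0 / S)
    mu_sum = np.zeros(S)
    U_sum = np.zeros((S, G))
    kept = 0
    for it in range(cfg.chain_length):
        U = sample_assignments(x_row, phi, mu, rng)
        mu = sample_theta(U, cfg.alpha, rng)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            mu_sum += mu
            U_sum += U
            kept += 1
    return mu_sum / kept, U_sum / kept


def run_gibbs(
    bulk: BulkExpression,
    ref: CellStateReference | np.ndarray,
    cfg: GibbsConfig,
    state_ids: list | None = None,
) -> PosteriorSummary:
    """Posterior means of state fractions and read assignments per sample.

    ``ref`` may be a :class:`CellStateReference` (genes must already be
    aligned) or a bare row-stochastic S x G matrix.  Deterministic given
    ``cfg.seed``; each sample uses an independent RNG stream keyed by
    (seed, sample index).
    """
    if isinstance(ref, CellStateReference):
        phi = ref.phi
        if list(map(str, bulk.gene_ids)) != list(map(str, ref.gene_ids)):
            raise ValueError("bulk and reference genes are not aligned")
        state_ids = list(ref.state_ids)
    else:
        phi = np.asarray(ref, dtype=float)
        state_ids = state_ids or list(range(phi.shape[0]))
    if phi.shape[1] != bulk.X.shape[1]:
        raise ValueError("gene dimension mismatch")

    R = bulk.R
    zero = np.flatnonzero(R == 0)
    if zero.size:
        raise ValueError(f"sample {bulk.sample_ids[zero[0]]!r} has zero reads")

    N, G = bulk.X.shape
    S = phi.shape[0]
    mu_bar = np.empty((N, S))
    U_bar = np.empty((N, S, G))
    for n in range(N):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, n]))
        mu_bar[n], U_bar[n] = _gibbs_one_sample(bulk.X[n], phi, cfg, rng)
    return PosteriorSummary(
        mu_bar=mu_bar,
        U_bar=U_bar,
        sample_ids=list(bulk.sample_ids),
        state_ids=state_ids,
        gene_ids=bulk.gene_ids,
    )


def aggregate_states(
    summary: PosteriorSummary, ref: CellStateReference
) -> CellTypeEstimate:
    """Sum the state-level posterior to cell types via the map h."""
    N, S = summary.mu_bar.shape
    if S != ref.n_states:
        raise ValueError("summary and reference disagree on state count")
    T = ref.n_types
    G = summary.U_bar.shape[2]
    theta0 = np.zeros((N, T))
    Z = np.zeros((N, T, G))
    for t in range(T):
        idx = ref.states_of_type(t)
        theta0[:, t] = summary.mu_bar[:, idx].sum(axis=1)
        Z[:, t, :] = summary.U_bar[:, idx, :].sum(axis=1)
    return CellTypeEstimate(
        theta0=theta0,
        Z=Z,
        sample_ids=summary.sample_ids,
        type_ids=list(ref.type_ids),
        gene_ids=summary.gene_ids,
    )
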
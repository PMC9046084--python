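"""Malignant gene-program learning by EM on a partially fixed mixture.

Bulk expression is approximated as a nonnegative factorization
``X ~ upsilon . zeta`` in which the nonmalignant blocks are *fixed*:
the rows of ``zeta`` are K learned program bases ``eta`` followed by the
T-1 environment profiles ``psi_env``, and the rows of ``upsilon`` are
per-sample program weights ``omega`` followed by the environment
fractions ``theta_env``.  Each ``omega`` row sums to the malignant
fraction ``tau_n = 1 - sum_t theta_env[n, t]``, so ``upsilon`` rows lie
on the simplex and the model is a multinomial mixture with M = K + T - 1
components per sample.

``eta`` carries a log-normal fold-change prior centred on a user-
supplied (typically NMF-derived) guess ``eta0``; ``omega`` carries a
scaled near-flat Dirichlet prior.  EM alternates expected read
assignments with (a) a MAP update of each basis and (b) the posterior
mean of ``omega`` given the expected program counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from ._optim import map_profile
from .gibbs import BulkExpression

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Knobs for initialization and EM.

    ``n_nmf_restarts`` random initializations are used for the final
    NMF fit at the chosen K; rank selection over ``k_grid`` uses a
    smaller number of runs (``n_consensus_runs``) to build consensus
    matrices for the cophenetic score.
    """

    K: int | None = None
    alpha: float = 1e-8
    sigma: float = 2.0
    em_max_iter: int = 200
    em_tol: float = 1e-8
    seed: int = 0
    n_nmf_restarts: int = 200
    n_consensus_runs: int = 30
    k_grid: tuple = tuple(range(2, 13))
    drop_frac: float = 0.10
    nmf_max_iter: int = 400

    def __post_init__(self) -> None:
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("EM tolerances must be positive")


@dataclass
class EmbeddingResult:
    """Learned bases and weights plus the optimization trace."""

    eta: np.ndarray  # K x G, rows sum to 1
    eta0: np.ndarray  # K x G prior bases
    lam: np.ndarray  # K x G fold-changes of eta relative to eta0
    omega: np.ndarray  # N x K, row n sums to tau_n
    tau: np.ndarray  # N
    log_posterior_trace: np.ndarray
    sample_ids: list = field(default_factory=list)

    @property
    def kappa(self) -> np.ndarray:
        """Program weights normalized to the simplex (omega / tau)."""
        return self.omega / self.tau[:, None]


def expected_assignments(
    X: np.ndarray, upsilon: np.ndarray, zeta: np.ndarray
) -> np.ndarray:
    """Expected read assignments V (N x M x G) of the mixture E-step.

    V[n, m, g] = X[n, g] * upsilon[n, m] * zeta[m, g] / sum_m' (...).
    Materializes the full tensor; meant for small problems and tests —
    the EM loop itself only ever forms the pooled sums.
    """
    mix = upsilon @ zeta  # N x G
    W = upsilon[:, :, None] * zeta[None, :, :]  # N x M x G
    return X[:, None, :] * W / mix[:, None, :]


def _consensus_cophenetic(conn_sum: np.ndarray, n_runs: int) -> float:
    consensus = conn_sum / n_runs
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0  # perfectly stable (or degenerate) clustering
    link = linkage(condensed, method="average")
    coph, _ = cophenet(link, condensed)
    return float(coph)


def _nmf_fit(Z: np.ndarray, K: int, seed: int, max_iter: int) -> NMF:
    model = NMF(
        n_components=K,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-6,
    )
    model.fit(Z)
    return model

def select_k(
    Z_mal_norm: np.ndarray, cfg: EmbeddingConfig
) -> tuple[int, dict[int, float]]:
    """Consensus-NMF rank selection by cophenetic correlation.

    For each candidate K, samples are repeatedly factorized from random
    starts and co-clustered by their dominant basis; the cophenetic
    correlation of the consensus matrix measures stability.  The chosen
    K is the largest one scored before the first drop exceeding
    ``drop_frac`` of the observed score range (or the argmax when no
    such drop occurs).
    """
    Z = np.asarray(Z_mal_norm, dtype=float)
    N = Z.shape[0]
    ks = [k for k in cfg.k_grid]
    if any(k > min(Z.shape) for k in ks):
        raise ValueError("k_grid exceeds min(n_samples, n_genes)")
    scores: dict[int, float] = {}
    ss = np.random.SeedSequence([cfg.seed, 7])
    base = int(ss.generate_state(1)[0] % (2**31 - 1))
    for k in ks:
        conn_sum = np.zeros((N, N))
        for r in range(cfg.n_consensus_runs):
            model = _nmf_fit(Z, k, base + 1000 * k + r, cfg.nmf_max_iter)
            W = model.transform(Z)
            labels = W.argmax(axis=1)
            conn_sum += labels[:, None] == labels[None, :]
        scores[k] = _consensus_cophenetic(conn_sum, cfg.n_consensus_runs)
    vals = np.array([scores[k] for k in ks])
    rng_range = vals.max() - vals.min()
    chosen = ks[int(vals.argmax())]
    if rng_range > 0:
        for i in range(len(ks) - 1):
            if vals[i + 1] < vals[i] - cfg.drop_frac * rng_range:
                chosen = ks[i]
                break
    return chosen, scores


def nmf_init(
    Z_mal_norm: np.ndarray, cfg: EmbeddingConfig
) -> tuple[np.ndarray, int, dict[int, float]]:
    """NMF initialization of the program bases.

    Selects K by consensus cophenetic score when ``cfg.K`` is None, then
    refits ``n_nmf_restarts`` times at the chosen K and keeps the basis
    with minimal reconstruction error.  Returns ``(eta0, K, scores)``
    with eta0 rows normalized to sum to 1.
    """
    Z = np.asarray(Z_mal_norm, dtype=float)
    if np.any(Z < 0):
        raise ValueError("normalized malignant expression must be nonnegative")
    scores: dict[int, float] = {}
    if cfg.K is None:
        K, scores = select_k(Z, cfg)
    else:
        K = cfg.K
        if K > min(Z.shape):
            raise ValueError("K exceeds min(n_samples, n_genes)")
    ss = np.random.SeedSequence([cfg.seed, 11])
    base = int(ss.generate_state(1)[0] % (2**31 - 1))
    best = None
    for r in range(cfg.n_nmf_restarts):
        model = _nmf_fit(Z, K, base + r, cfg.nmf_max_iter)
        if best is None or model.reconstruction_err_ < best.reconstruction_err_:
            best = model
    H = best.components_
    row_sums = H.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("NMF produced an empty basis; reduce K")
    eta0 = H / row_sums
    # floor zero entries so the log-normal fold-change prior is well defined
    eta0 = np.vstack([_floor_row(r) for r in eta0])
    return eta0, K, scores


def _floor_row(row: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    zero = row < floor
    if not zero.any():
        return row / row.sum()
    out = row.copy()
    out[zero] = floor
    return out / out.sum()


def fit_embedding(
    bulk: BulkExpression,
    theta_env: np.ndarray,
    psi_env: np.ndarray,
    eta0: np.ndarray,
    cfg: EmbeddingConfig,
) -> EmbeddingResult:
    """EM fit of program bases eta and weights omega with fixed
    environment blocks.

    ``theta_env`` (N x T-1) and ``psi_env`` (T-1 x G) come from the
    reference update and are never modified.  The log posterior
    (observed-data likelihood plus the basis prior) is tracked every
    iteration and must be non-decreasing up to ``em_tol`` relative
    tolerance; a larger decrease raises, as it indicates a broken
    update.
    """
    X = bulk.X.astype(float)
    N, G = X.shape
    theta_env = np.asarray(theta_env, dtype=float)
    psi_env = np.asarray(psi_env, dtype=float)
    eta0 = np.asarray(eta0, dtype=float)
    K = eta0.shape[0]
    T_env = theta_env.shape[1] if theta_env.size else 0
    if theta_env.shape[0] != N and T_env:
        raise ValueError("theta_env must have one row per bulk sample")
    if T_env and psi_env.shape != (T_env, G):
        raise ValueError("psi_env shape mismatch")
    if eta0.shape[1] != G:
        raise ValueError("eta0 gene dimension mismatch")

    tau = 1.0 - (theta_env.sum(axis=1) if T_env else np.zeros(N))
    bad = np.flatnonzero(tau <= 0)
    if bad.size:
        sid = bulk.sample_ids[bad[0]]
        raise ValueError(f"sample {sid!r} has nonpositive malignant fraction tau")

    theta_env_orig = theta_env.copy()
    psi_env_orig = psi_env.copy()

    eta = eta0.copy()
    lam = np.ones_like(eta0)
    omega = np.tile((tau / K)[:, None], (1, K))

    def log_posterior(eta_cur, lam_cur, omega_cur):
        upsilon = np.hstack([omega_cur, theta_env]) if T_env else omega_cur
        zeta = np.vstack([eta_cur, psi_env]) if T_env else eta_cur
        mix = upsilon @ zeta
        ll = float(np.sum(X * np.log(mix)))
        prior = -float(np.sum(np.log(lam_cur) ** 2)) / (2.0 * cfg.sigma**2)
        return ll + prior

    trace = [log_posterior(eta, lam, omega)]
    for it in range(cfg.em_max_iter):
        upsilon = np.hstack([omega, theta_env]) if T_env else omega
        zeta = np.vstack([eta, psi_env]) if T_env else eta
        mix = upsilon @ zeta  # N x G
        A = X / mix  # N x G ratio matrix
        # pooled expected counts per basis (over samples) and per (n, basis)
        V_basis = eta * (upsilon[:, :K].T @ A)  # K x G
        V_nk = upsilon[:, :K] * (A @ eta.T)  # N x K
        # M-step for each basis: MAP under the fold-change prior
        for k in range(K):
            eta[k], lam[k] = map_profile(
                V_basis[k], eta0[k], sigma=cfg.sigma, label=f"basis {k}",
            )
        # posterior-mean update of omega under the scaled Dirichlet prior
        post = cfg.alpha + V_nk
        omega = tau[:, None] * post / post.sum(axis=1, keepdims=True)

        lp = log_posterior(eta, lam, omega)
        if lp < trace[-1] - cfg.em_tol * max(1.0, abs(trace[-1])):
            raise FloatingPointError(
                f"log posterior decreased at EM iteration {it}: "
                f"{trace[-1]:.6f} -> {lp:.6f}"
            )
        converged = abs(lp - trace[-1]) <= cfg.em_tol * max(1.0, abs(trace[-1]))
        trace.append(lp)
        if converged:
            break

    assert np.array_equal(theta_env, theta_env_orig)
    assert np.array_equal(psi_env, psi_env_orig)
    return EmbeddingResult(
        eta=eta,
        eta0=eta0,
        lam=lam,
        omega=omega,
        tau=tau,
        log_posterior_trace=np.asarray(trace),
        sample_ids=list(bulk.sample_ids),
    )
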
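"""Synthetic references and pseudo-bulks with known ground truth.

The generator emulates the benchmark design used to validate the
deconvolution model: multi-cell-type references with within-type cell
states, cells drawn per state from multinomial profiles, pseudo-bulks
formed either by summing sampled cells or by drawing reads from a
fraction-weighted profile mixture, and a log-normally distributed
multiplicative gene-wise noise term that decouples the profiles
generating the bulk from the reference the deconvolution sees.

Ground truth is recorded as *realized* read fractions (the proportion of
reads each state actually contributed), which is the quantity the model
estimates, rather than the nominal mixing fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import BulkExpression
from .reference import CellStateReference, build_state_reference

_MAL_LABEL = "malignant"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a small tumour cohort: 4 cell types of which one
    (malignant) carries 3 cell states, 1000 genes, 30 pseudo-bulks of
    50k reads each, and reference-vs-bulk multiplicative noise of
    sigma = 0.5 on the natural-log scale.
    """

    n_types: int = 4
    malignant_states: int = 3
    states_per_type: int = 1  # states per nonmalignant type
    n_genes: int = 1000
    cells_per_state: int = 50
    cell_depth: int = 1000
    n_samples: int = 30
    bulk_depth: int = 50_000
    fraction_conc: float = 1.0  # Dirichlet concentration over types
    state_dispersion: float = 0.3  # within-type state deviation weight
    sparsity: float = 0.3  # fraction of genes silenced per profile
    profile_sigma: float = 1.0  # log-sd of profile draw
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.n_genes, self.n_samples, self.bulk_depth,
               self.cells_per_state, self.cell_depth, self.malignant_states,
               self.states_per_type) < 1:
            raise ValueError("all sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class GroundTruth:
    """Known composition of a simulated pseudo-bulk cohort."""

    state_fractions: np.ndarray  # N x S nominal mixing fractions
    realized_state_fractions: np.ndarray  # N x S realized read fractions
    type_of_state: np.ndarray
    malignant_profiles: np.ndarray | None = None  # N x G generating profiles
    noise_sigma: float = 0.0

    def type_fractions(self, n_types: int) -> np.ndarray:
        """Realized read fractions summed to the type level."""
        N = self.realized_state_fractions.shape[0]
        out = np.zeros((N, n_types))
        for t in range(n_types):
            idx = np.flatnonzero(self.type_of_state == t)
            out[:, t] = self.realized_state_fractions[:, idx].sum(axis=1)
        return out


@dataclass
class ReferenceSim:
    """A simulated reference: the built prior plus its generating truth."""

    ref: CellStateReference
    cell_counts: np.ndarray
    state_labels: np.ndarray
    type_labels: np.ndarray
    true_profiles: np.ndarray  # S x G profiles the cells were drawn from
    malignant_type: int


def _draw_profile(rng, base_log: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Sparse log-normal expression profile around a shared gene baseline."""
    log_expr = base_log + cfg.profile_sigma * rng.standard_normal(cfg.n_genes)
    expr = np.exp(log_expr)
    mask = rng.random(cfg.n_genes) >= cfg.sparsity
    if not mask.any():
        mask[rng.integers(cfg.n_genes)] = True
    expr = expr * mask
    return expr / expr.sum()


def simulate_reference(cfg: SimulationConfig) -> ReferenceSim:
    """Draw state profiles, sample cells, and build the reference prior.

    States of one type share the type's mean profile, mixed with a
    state-specific draw at weight ``state_dispersion``, so within-type
    profiles correlate more strongly than between-type profiles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    base_log = rng.standard_normal(cfg.n_genes)  # shared gene-level baseline

    state_profiles, state_ids, type_of_state, type_ids = [], [], [], []
    for t in range(cfg.n_types):
        is_mal = t == 0
        t_label = _MAL_LABEL if is_mal else f"type{t}"
        type_ids.append(t_label)
        n_states = cfg.malignant_states if is_mal else cfg.states_per_type
        type_mean = _draw_profile(rng, base_log, cfg)
        for s in range(n_states):
            if n_states == 1:
                prof = type_mean
            else:
                own = _draw_profile(rng, base_log, cfg)
                prof = (1 - cfg.state_dispersion) * type_mean + cfg.state_dispersion * own
                prof = prof / prof.sum()
            state_profiles.append(prof)
            state_ids.append(f"{t_label}_s{s}")
            type_of_state.append(t)
    profiles = np.vstack(state_profiles)
    S = profiles.shape[0]

    counts = np.empty((S * cfg.cells_per_state, cfg.n_genes), dtype=np.int64)
    state_labels, type_labels = [], []
    for s in range(S):
        for c in range(cfg.cells_per_state):
            counts[s * cfg.cells_per_state + c] = rng.multinomial(
                cfg.cell_depth, profiles[s]
            )
        state_labels += [state_ids[s]] * cfg.cells_per_state
        type_labels += [type_ids[type_of_state[s]]] * cfg.cells_per_state

    gene_ids = np.array([f"G{g:05d}" for g in range(cfg.n_genes)], dtype=object)
    ref = build_state_reference(
        counts,
        state_labels,
        type_labels,
        gene_ids,
        malignant_type=_MAL_LABEL,
        state_ids_order=state_ids,
    )
    return ReferenceSim(
        ref=ref,
        cell_counts=counts,
        state_labels=np.asarray(state_labels, dtype=object),
        type_labels=np.asarray(type_labels, dtype=object),
        true_profiles=profiles,
        malignant_type=ref.malignant_type,
    )


def apply_lognormal_noise(
    phi: np.ndarray, sigma_noise: float, seed_or_rng
) -> np.ndarray:
    """Multiply each entry by exp(eps), eps ~ N(0, sigma), renormalize rows.

    With ``sigma_noise = 0`` the input is returned unchanged.
    """
    phi = np.asarray(phi, dtype=float)
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be nonnegative")
    if sigma_noise == 0:
        return phi.copy()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    noisy = phi * np.exp(sigma_noise * rng.standard_normal(phi.shape))
    return noisy / noisy.sum(axis=1, keepdims=True)


def draw_fractions(cfg: SimulationConfig, type_of_state: np.ndarray, rng) -> np.ndarray:
    """Per-sample state fractions: Dirichlet over types, then a Dirichlet
    split of each type's mass over its states."""
    S = len(type_of_state)
    T = type_of_state.max() + 1
    out = np.empty((cfg.n_samples, S))
    for n in range(cfg.n_samples):
        theta_t = rng.dirichlet(np.full(T, cfg.fraction_conc))
        for t in range(T):
            idx = np.flatnonzero(type_of_state == t)
            if len(idx) == 1:
                out[n, idx[0]] = theta_t[t]
            else:
                out[n, idx] = theta_t[t] * rng.dirichlet(np.ones(len(idx)))
    return out


def simulate_pseudobulk(
    profiles: np.ndarray,
    fractions: np.ndarray,
    depth: int,
    rng,
    gene_ids=None,
    mode: str = "profile",
    cell_counts: np.ndarray | None = None,
    cell_state_index: np.ndarray | None = None,
    cells_per_bulk: int = 100,
    type_of_state: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    per_sample_profiles: np.ndarray | None = None,
) -> tuple[BulkExpression, GroundTruth]:
    """Form pseudo-bulks at known composition.

    Two modes:

    * ``profile``: reads per state are multinomial in the fractions,
      then each state's reads are multinomial in its profile.  With
      ``per_sample_profiles`` (N x S x G) each sample draws from its own
      profiles (e.g. noise-perturbed per sample).
    * ``cell``: ``cells_per_bulk`` cells are drawn with states
      multinomial in the fractions, sampled with replacement from the
      supplied cell pool, and their counts summed.

    Ground truth records realized read fractions per state.
    """
    profiles = np.asarray(profiles, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if not np.allclose(fractions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("fraction rows must sum to 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    N, S = fractions.shape
    G = profiles.shape[1]
    if type_of_state is None:
        type_of_state = np.zeros(S, dtype=int)
    X = np.zeros((N, G), dtype=np.int64)
    realized = np.zeros((N, S))

    if mode == "profile":
        use_profiles = per_sample_profiles
        if use_profiles is None and noise_sigma > 0:
            use_profiles = np.stack(
                [apply_lognormal_noise(profiles, noise_sigma, rng) for _ in range(N)]
            )
        for n in range(N):
            prof_n = profiles if use_profiles is None else use_profiles[n]
            reads_per_state = rng.multinomial(depth, fractions[n])
            for s in np.flatnonzero(reads_per_state):
                X[n] += rng.multinomial(reads_per_state[s], prof_n[s])
            realized[n] = reads_per_state / depth
    elif mode == "cell":
        if cell_counts is None or cell_state_index is None:
            raise ValueError("cell mode needs cell_counts and cell_state_index")
        cell_state_index = np.asarray(cell_state_index)
        pools = [np.flatnonzero(cell_state_index == s) for s in range(S)]
        for n in range(N):
            n_cells = rng.multinomial(cells_per_bulk, fractions[n])
            for s in np.flatnonzero(n_cells):
                if len(pools[s]) == 0:
                    raise ValueError(f"no cells available for state {s}")
                chosen = rng.choice(pools[s], size=n_cells[s], replace=True)
                contrib = cell_counts[chosen].sum(axis=0)
                X[n] += contrib
                realized[n, s] = contrib.sum()
        totals = X.sum(axis=1, keepdims=True)
        realized = realized / totals
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if gene_ids is None:
        gene_ids = np.array([f"G{g:05d}" for g in range(G)], dtype=object)
    bulk = BulkExpression(
        X=X,
        sample_ids=[f"bulk{n:03d}" for n in range(N)],
        gene_ids=gene_ids,
    )
    truth = GroundTruth(
        state_fractions=fractions,
        realized_state_fractions=realized,
        type_of_state=np.asarray(type_of_state),
        noise_sigma=noise_sigma,
    )
    return bulk, truth


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ReferenceSim, BulkExpression, GroundTruth]:
    """Reference + noisy pseudo-bulk cohort with known composition.

    The reference is built from cells drawn from the clean state
    profiles; the bulks are drawn from a single noise-perturbed copy of
    those profiles (``noise_sigma``), emulating a batch effect between
    the single-cell reference and the bulk cohort.  Each sample's
    generating malignant profile (the realized-fraction-weighted mixture
    of noisy malignant state rows) is recorded in the ground truth.
    """
    sim = simulate_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    type_of_state = sim.ref.type_of_state
    noisy = apply_lognormal_noise(sim.true_profiles, cfg.noise_sigma, rng)
    fractions = draw_fractions(cfg, type_of_state, rng)
    bulk, truth = simulate_pseudobulk(
        noisy,
        fractions,
        cfg.bulk_depth,
        rng,
        gene_ids=sim.ref.gene_ids,
        type_of_state=type_of_state,
    )
    truth.noise_sigma = cfg.noise_sigma
    mal_states = np.flatnonzero(type_of_state == sim.malignant_type)
    w = truth.realized_state_fractions[:, mal_states]
    w_sums = w.sum(axis=1, keepdims=True)
    w_sums[w_sums == 0] = 1.0
    truth.malignant_profiles = (w / w_sums) @ noisy[mal_states]
    return sim, bulk, truth


def simulate_malignant_recovery_cohort(
    cfg: SimulationConfig,
    purity_low: float = 0.55,
    purity_high: float = 0.95,
) -> tuple[ReferenceSim, BulkExpression, GroundTruth]:
    """High-purity pseudo-bulks with sample-specific malignant profiles.

    Each sample's malignant component is generated from its own
    perturbation (log-normal, ``noise_sigma``) of the reference-level
    malignant profile, with the true malignant read fraction drawn
    uniformly on [purity_low, purity_high] and the nonmalignant types
    sharing the remainder.  This probes recovery of per-sample malignant
    expression rather than fractions.
    """
    sim = simulate_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    tos = sim.ref.type_of_state
    mal = sim.malignant_type
    mal_states = np.flatnonzero(tos == mal)
    base_mal = sim.true_profiles[mal_states].mean(axis=0)
    base_mal = base_mal / base_mal.sum()
    env_types = [t for t in range(cfg.n_types) if t != mal]
    env_rows = np.vstack(
        [sim.true_profiles[np.flatnonzero(tos == t)].mean(axis=0) for t in env_types]
    )
    env_rows = env_rows / env_rows.sum(axis=1, keepdims=True)

    N = cfg.n_samples
    purity = rng.uniform(purity_low, purity_high, N)
    env_split = rng.dirichlet(np.ones(len(env_types)), size=N) * (1 - purity)[:, None]
    fractions = np.column_stack([purity, env_split])

    mal_profiles = np.vstack(
        [apply_lognormal_noise(base_mal[None, :], cfg.noise_sigma, rng) for _ in range(N)]
    )
    base_rows = np.vstack([base_mal, env_rows])
    per_sample = np.repeat(base_rows[None, :, :], N, axis=0)
    per_sample[:, 0, :] = mal_profiles

    # mixture row t corresponds to reference type [mal] + env_types order
    row_types = np.array([mal] + env_types)
    bulk, truth = simulate_pseudobulk(
        base_rows,
        fractions,
        cfg.bulk_depth,
        rng,
        gene_ids=sim.ref.gene_ids,
        type_of_state=row_types,
        per_sample_profiles=per_sample,
        noise_sigma=cfg.noise_sigma,
    )
    truth.malignant_profiles = mal_profiles
    return sim, bulk, truth


def benchmark_metrics(
    theta_hat: np.ndarray, theta_true: np.ndarray, type_ids=None
) -> pd.DataFrame:
    """Per-cell-type Pearson r and MSE between estimated and true fractions."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("fraction matrices must have the same shape")
    T = theta_hat.shape[1]
    rows = []
    for t in range(T):
        a, b = theta_hat[:, t], theta_true[:, t]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"pearson_r": r, "mse": float(np.mean((a - b) ** 2))})
    index = list(type_ids) if type_ids is not None else list(range(T))
    return pd.DataFrame(rows, index=index)
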
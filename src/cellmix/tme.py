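"""Downstream microenvironment analyses of deconvolved output.

Two screens defined on the deconvolution results:

* a gene-by-gene Spearman correlation between malignant-cell expression
  and the fraction of a nonmalignant "query" cell type, with two
  false-positive filters — a likelihood-ratio "regress-out" test that
  rejects genes whose fraction association is already explained by the
  query cell's own expression of the gene, and a malignant-specificity
  filter requiring the gene to be expressed higher in at least one
  malignant state than in every nonmalignant type;
* signature scoring (e.g. M1/M2 macrophage polarization): per-sample
  Pearson correlation of deconvolved expression against reference
  signature profiles over a marker-gene set, restricted to samples with
  enough of the cell type for the expression estimate to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationReport:
    """Ranked gene-level correlation screen with filter columns."""

    table: pd.DataFrame  # index: gene; columns: rho, rank, lrt_p, specificity, flags
    alpha_level: float

    def passing(self) -> pd.DataFrame:
        """Genes passing both filters with a defined correlation."""
        t = self.table
        return t[(t["lrt_pass"]) & (t["malignant_specific"]) & t["rho"].notna()]


@dataclass
class SignatureScore:
    """Per-sample signature correlations (samples failing the fraction
    filter are excluded, not NaN-filled)."""

    scores: pd.DataFrame  # index: retained samples; columns: signature labels
    transform: str
    min_fraction: float


def rank_correlation(
    Z_mal_norm: np.ndarray, theta_query: np.ndarray, gene_ids=None
) -> pd.Series:
    """Per-gene Spearman correlation against the query-type fraction.

    Expression should be normalized per sample (fractions of malignant
    reads) so depth does not drive the ranking.  Zero-variance genes get
    NaN.  Ties receive average ranks.
    """
    Z = np.asarray(Z_mal_norm, dtype=float)
    theta_query = np.asarray(theta_query, dtype=float)
    if Z.shape[0] != theta_query.shape[0]:
        raise ValueError("expression and fractions disagree on sample count")
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 samples for a rank correlation")
    rho = np.full(Z.shape[1], np.nan)
    const = np.ptp(Z, axis=0) == 0
    if np.ptp(theta_query) == 0:
        pass  # all NaN: the fraction itself has no variation
    else:
        ranks_theta = stats.rankdata(theta_query)
        ranks_Z = stats.rankdata(Z[:, ~const], axis=0)
        rt = ranks_theta - ranks_theta.mean()
        rz = ranks_Z - ranks_Z.mean(axis=0)
        denom = np.sqrt((rt**2).sum() * (rz**2).sum(axis=0))
        rho[~const] = (rz.T @ rt) / denom
    index = gene_ids if gene_ids is not None else np.arange(Z.shape[1])
    return pd.Series(rho, index=index, name="spearman_rho")


def regress_out_filter(
    theta_query: np.ndarray,
    expr_query: np.ndarray,
    expr_mal: np.ndarray,
    alpha_level: float = 0.01,
) -> tuple[float, bool]:
    """Likelihood-ratio test that malignant expression adds signal.

    Null model: query fraction ~ intercept + query-cell expression of
    the gene.  Alternative: adds malignant-cell expression.  Returns
    ``(p_value, passes)`` where the p-value is chi-squared with 1 df on
    twice the log-likelihood gain; a rank-deficient design yields p = 1.
    """
    y = np.asarray(theta_query, dtype=float)
    x0 = np.asarray(expr_query, dtype=float)
    x1 = np.asarray(expr_mal, dtype=float)
    n = y.shape[0]
    if x0.shape[0] != n or x1.shape[0] != n:
        raise ValueError("all inputs must share the sample axis")
    X_null = np.column_stack([np.ones(n), x0])
    X_alt = np.column_stack([np.ones(n), x0, x1])
    if np.linalg.matrix_rank(X_alt) < X_alt.shape[1]:
        return 1.0, False
    ll_null = _gaussian_loglik(y, X_null)
    ll_alt = _gaussian_loglik(y, X_alt)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(lr, df=1))
    return p, p < alpha_level


def _gaussian_loglik(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def malignant_specificity_filter(
    ref,
    fold_threshold: float = 1.5,
    fdr: float = 0.05,
) -> pd.Series:
    """Flag genes expressed higher in some malignant state than in every
    nonmalignant type.

    A gene passes when one malignant state's profile value exceeds
    ``fold_threshold`` times every nonmalignant type's value, and the
    excess is supported by a one-sided two-proportion z-test on the raw
    count sums (Benjamini–Hochberg corrected across genes at ``fdr``).
    Without stored count sums only the fold rule is applied.
    """
    if ref.malignant_type is None:
        raise ValueError("reference has no designated malignant type")
    mal_states = ref.states_of_type(ref.malignant_type)
    env_types = [t for t in range(ref.n_types) if t != ref.malignant_type]
    type_ref = ref.type_reference()
    env_profiles = type_ref.phi_prime[env_types]  # T_env x G

    phi_mal = ref.phi[mal_states]  # S_mal x G
    best_state = phi_mal.argmax(axis=0)
    best_val = phi_mal.max(axis=0)
    env_max = env_profiles.max(axis=0)
    fold_ok = best_val > fold_threshold * env_max

    if ref.state_counts is None:
        flags = fold_ok
    else:
        G = ref.n_genes
        counts_mal = ref.state_counts[mal_states]
        totals_mal = counts_mal.sum(axis=1)
        env_counts = np.vstack(
            [ref.state_counts[ref.states_of_type(t)].sum(axis=0) for t in env_types]
        )
        env_totals = env_counts.sum(axis=1)
        # worst-case environment competitor per gene (largest proportion)
        env_prop = env_counts / env_totals[:, None]
        worst_env = env_prop.argmax(axis=0)
        pvals = np.ones(G)
        for g in np.flatnonzero(fold_ok):
            s = best_state[g]
            e = worst_env[g]
            pvals[g] = _one_sided_two_proportion(
                counts_mal[s, g], totals_mal[s], env_counts[e, g], env_totals[e]
            )
        sig = np.zeros(G, dtype=bool)
        if fold_ok.any():
            rej, *_ = multipletests(pvals[fold_ok], alpha=fdr, method="fdr_bh")
            sig[np.flatnonzero(fold_ok)] = rej
        flags = fold_ok & sig
    return pd.Series(flags, index=ref.gene_ids, name="malignant_specific")


def _one_sided_two_proportion(x1: float, n1: float, x2: float, n2: float) -> float:
    """One-sided z-test that proportion 1 exceeds proportion 2."""
    p1, p2 = x1 / n1, x2 / n2
    p_pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(stats.norm.sf(z))


def correlation_screen(
    Z_mal_norm: np.ndarray,
    theta_query: np.ndarray,
    Z_query_norm: np.ndarray,
    ref,
    gene_ids=None,
    alpha_level: float = 0.01,
    fold_threshold: float = 1.5,
) -> CorrelationReport:
    """Full ranked screen: Spearman rho plus both false-positive filters.

    Genes failing a filter are flagged in the output table rather than
    dropped, so the ranking is always complete.
    """
    gene_ids = (
        np.asarray(gene_ids, dtype=object)
        if gene_ids is not None
        else np.arange(Z_mal_norm.shape[1])
    )
    rho = rank_correlation(Z_mal_norm, theta_query, gene_ids)
    lrt_p = np.empty(len(gene_ids))
    lrt_pass = np.empty(len(gene_ids), dtype=bool)
    for g in range(len(gene_ids)):
        lrt_p[g], lrt_pass[g] = regress_out_filter(
            theta_query, Z_query_norm[:, g], Z_mal_norm[:, g], alpha_level
        )
    spec = malignant_specificity_filter(ref, fold_threshold=fold_threshold).to_numpy()
    table = pd.DataFrame(
        {
            "rho": rho.to_numpy(),
            "lrt_p": lrt_p,
            "lrt_pass": lrt_pass,
            "malignant_specific": spec,
            "zero_variance": np.isnan(rho.to_numpy()),
        },
        index=gene_ids,
    )
    table["rank"] = table["rho"].rank(ascending=False)
    return CorrelationReport(table=table.sort_values("rho", ascending=False),
                             alpha_level=alpha_level)


def signature_score(
    expr_deconv: np.ndarray,
    sample_ids,
    gene_ids,
    signatures: pd.DataFrame,
    markers,
    theta: np.ndarray,
    min_fraction: float = 0.05,
    transform: str = "log2",
) -> SignatureScore:
    """Correlate deconvolved expression with signature profiles.

    Samples with ``theta`` at or below ``min_fraction`` are excluded.
    Expression is depth-normalized per sample, then log2(x+1)
    transformed by default; signatures (genes x labels) are transformed
    the same way after column normalization.  Pearson r is computed over
    the marker genes present in both.
    """
    expr = np.asarray(expr_deconv, dtype=float)
    theta = np.asarray(theta, dtype=float)
    gene_index = pd.Index([str(g).upper() for g in gene_ids])
    markers = [str(m).upper() for m in markers]
    sig_index = pd.Index([str(g).upper() for g in signatures.index])
    use = [m for m in markers if m in gene_index and m in sig_index]
    if not use:
        raise ValueError("no marker genes shared between expression and signatures")

    keep = theta > min_fraction
    if not keep.any():
        raise ValueError(f"no sample exceeds the {min_fraction:.0%} fraction filter")
    expr = expr[keep]
    kept_ids = [s for s, k in zip(sample_ids, keep) if k]

    totals = expr.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = expr / totals
    gpos = [gene_index.get_loc(m) for m in use]
    mat = norm[:, gpos]
    sig = signatures.copy()
    sig.index = sig_index
    sig = sig.loc[use]
    sig_norm = sig / sig.sum(axis=0)

    if transform == "log2":
        mat = np.log2(1e6 * mat + 1.0)  # CPM-style scaling before log
        sig_t = np.log2(1e6 * sig_norm.to_numpy() + 1.0)
    elif transform == "none":
        sig_t = sig_norm.to_numpy()
    else:
        raise ValueError(f"unknown transform {transform!r}")

    n_sig = sig_t.shape[1]
    out = np.empty((mat.shape[0], n_sig))
    for j in range(n_sig):
        for i in range(mat.shape[0]):
            out[i, j] = stats.pearsonr(mat[i], sig_t[:, j])[0]
    scores = pd.DataFrame(out, index=kept_ids, columns=list(signatures.columns))
    return SignatureScore(scores=scores, transform=transform, min_fraction=min_fraction)
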
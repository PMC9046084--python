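"""Single-cell derived reference profiles.

The deconvolution model treats each cell state as a multinomial
distribution over genes.  The event probabilities are estimated from
labelled scRNA-seq counts by summing reads over the cells of a state and
renormalizing, then flooring zero entries at a small pseudo-count so
that every gene has nonzero probability under every state.

Two granularities are used throughout the package:

* the *cell state* reference ``phi`` (S x G) — the finest mixture unit,
  e.g. per-patient malignant subclusters or M1/M2 macrophage states;
* the *cell type* reference ``phi_prime`` (T x G) — one row per named
  population, used as the prior centre when pooling information across
  bulk samples.

States map onto types through a surjective map ``h``; fractions and read
assignments at the type level are posterior sums over the states of the
type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO_MIN = 1e-8

_RIBO_PREFIXES = ("RPL", "RPS", "MRPL", "MRPS")
_SEX_MITO_CHROMS = {"chrx", "chry", "chrm", "x", "y", "m", "mt", "chrmt"}


def norm_to_one(row: np.ndarray, pseudo_min: float = DEFAULT_PSEUDO_MIN) -> np.ndarray:
    """Normalize a nonnegative vector to sum to one with a floor on zeros.

    Zero entries become exactly ``pseudo_min``; nonzero entries keep
    their mutual proportions and are rescaled so the result sums to 1.

    Parameters
    ----------
    row
        Nonnegative vector with at least one positive entry.
    pseudo_min
        Positive floor assigned to zero entries after normalization.

    Raises
    ------
    ValueError
        If the row is all-zero, contains negatives, or ``pseudo_min``
        times the number of zeros reaches 1 (no mass left for the
        nonzero entries).
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise ValueError("norm_to_one expects a 1-D profile row")
    if np.any(row < 0):
        raise ValueError("profile row contains negative entries")
    if pseudo_min <= 0:
        raise ValueError("pseudo_min must be positive")
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero profile row cannot be normalized")
    zero = row == 0
    n_zero = int(zero.sum())
    if n_zero == 0:
        return row / total
    mass_floor = pseudo_min * n_zero
    if mass_floor >= 1:
        raise ValueError(
            f"pseudo_min={pseudo_min} too large for {n_zero} zero entries"
        )
    out = row * ((1.0 - mass_floor) / total)
    out[zero] = pseudo_min
    return out


def _check_gene_ids(gene_ids: np.ndarray) -> np.ndarray:
    gene_ids = np.asarray(gene_ids, dtype=object)
    norm = pd.Index([str(g).upper() for g in gene_ids])
    if norm.has_duplicates:
        dups = norm[norm.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicated gene ids (case-insensitive): {dups}")
    return gene_ids


@dataclass
class CellStateReference:
    """Row-stochastic per-cell-state reference with the state->type map.

    Attributes
    ----------
    phi
        S x G matrix; every row sums to 1 and every entry is at least
        ``pseudo_min``.
    state_ids, type_ids, gene_ids
        Labels for the axes.
    type_of_state
        Integer array of length S mapping each state to its type index.
    malignant_type
        Index of the designated malignant type, or None for non-tumour
        use (all types treated as environment).
    state_counts
        Optional S x G raw count sums the profiles were built from; kept
        for downstream count-based tests.
    """

    phi: np.ndarray
    state_ids: list
    type_of_state: np.ndarray
    type_ids: list
    gene_ids: np.ndarray
    malignant_type: int | None = None
    pseudo_min: float = DEFAULT_PSEUDO_MIN
    state_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.type_of_state = np.asarray(self.type_of_state, dtype=int)
        self.gene_ids = _check_gene_ids(self.gene_ids)
        S, G = self.phi.shape
        if len(self.state_ids) != S or len(self.gene_ids) != G:
            raise ValueError("label lengths do not match phi shape")
        if self.type_of_state.shape != (S,):
            raise ValueError("type_of_state must have one entry per state")
        T = len(self.type_ids)
        if set(self.type_of_state) != set(range(T)):
            raise ValueError("every type must own at least one state")
        if self.malignant_type is not None and not 0 <= self.malignant_type < T:
            raise ValueError("malignant_type out of range")
        sums = self.phi.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("phi rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.phi.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    @property
    def n_genes(self) -> int:
        return self.phi.shape[1]

    def states_of_type(self, t: int) -> np.ndarray:
        return np.flatnonzero(self.type_of_state == t)

    def type_reference(self) -> "CellTypeReference":
        """Collapse the state reference to the per-type reference.

        Uses the stored raw count sums when available (pooling reads, as
        the per-type profile is defined); otherwise falls back to an
        unweighted mean of the state rows.
        """
        T = self.n_types
        if self.state_counts is not None:
            pooled = np.vstack(
                [self.state_counts[self.states_of_type(t)].sum(axis=0) for t in range(T)]
            )
        else:
            pooled = np.vstack(
                [self.phi[self.states_of_type(t)].mean(axis=0) for t in range(T)]
            )
        phi_prime = np.vstack([norm_to_one(r, self.pseudo_min) for r in pooled])
        return CellTypeReference(
            phi_prime=phi_prime,
            type_ids=list(self.type_ids),
            gene_ids=self.gene_ids,
            pseudo_min=self.pseudo_min,
        )

    def subset_genes(self, keep: np.ndarray) -> "CellStateReference":
        """Restrict to a gene subset (bool mask or index array), renormalizing."""
        keep = np.asarray(keep)
        phi = self.phi[:, keep]
        counts = None if self.state_counts is None else self.state_counts[:, keep]
        base = counts if counts is not None else phi
        phi_new = np.vstack([norm_to_one(r, self.pseudo_min) for r in base])
        return CellStateReference(
            phi=phi_new,
            state_ids=list(self.state_ids),
            type_of_state=self.type_of_state.copy(),
            type_ids=list(self.type_ids),
            gene_ids=self.gene_ids[keep],
            malignant_type=self.malignant_type,
            pseudo_min=self.pseudo_min,
            state_counts=counts,
        )


@dataclass
class CellTypeReference:
    """Row-stochastic per-cell-type reference (prior centre phi')."""

    phi_prime: np.ndarray
    type_ids: list
    gene_ids: np.ndarray
    pseudo_min: float = DEFAULT_PSEUDO_MIN

    def __post_init__(self) -> None:
        self.phi_prime = np.asarray(self.phi_prime, dtype=float)
        self.gene_ids = _check_gene_ids(self.gene_ids)
        if self.phi_prime.shape != (len(self.type_ids), len(self.gene_ids)):
            raise ValueError("phi_prime shape does not match labels")
        if not np.allclose(self.phi_prime.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("phi_prime rows must sum to 1")


class GeneAnnotation:
    """Per-gene chromosome / biotype lookup; missing genes are 'unknown'."""

    def __init__(self, table: pd.DataFrame | None = None):
        # expected columns: gene_id, chromosome, biotype (extra ignored)
        if table is None:
            table = pd.DataFrame(columns=["gene_id", "chromosome", "biotype"])
        table = table.copy()
        if "gene_id" not in table.columns:
            raise ValueError("annotation table needs a gene_id column")
        for col in ("chromosome", "biotype"):
            if col not in table.columns:
                table[col] = "unknown"
        table["gene_id"] = table["gene_id"].astype(str).str.upper()
        self._table = table.set_index("gene_id")

    @classmethod
    def from_csv(cls, path) -> "GeneAnnotation":
        return cls(pd.read_csv(path))

    def chromosome(self, gene_id: str) -> str:
        try:
            return str(self._table.at[str(gene_id).upper(), "chromosome"])
        except KeyError:
            return "unknown"

    def biotype(self, gene_id: str) -> str:
        try:
            return str(self._table.at[str(gene_id).upper(), "biotype"])
        except KeyError:
            return "unknown"

    def __len__(self) -> int:
        return len(self._table)


def _group_sums(counts: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum rows of ``counts`` per unique label (first-appearance order)."""
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    sums = np.vstack([counts[labels == lab].sum(axis=0) for lab in uniq])
    return sums, uniq


def _warn_if_non_integer(counts: np.ndarray, what: str) -> None:
    if not np.allclose(counts, np.round(counts)):
        logger.warning(
            "%s contains non-integer values (TPM-like input); summing as-is, "
            "but note the multinomial model is defined on counts", what,
        )


def build_state_reference(
    counts: np.ndarray,
    state_labels,
    type_labels,
    gene_ids,
    malignant_type=None,
    pseudo_min: float = DEFAULT_PSEUDO_MIN,
    state_ids_order=None,
) -> CellStateReference:
    """Build the per-state reference by summing counts over cells.

    Parameters
    ----------
    counts
        cells x genes nonnegative matrix (raw counts/UMIs, or TPM-like
        values which are summed identically).
    state_labels, type_labels
        Per-cell labels; all cells of one state must share a type.
    malignant_type
        Type *label* (not index) to flag as malignant, or None.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("cell counts must be nonnegative")
    state_labels = np.asarray(state_labels)
    type_labels = np.asarray(type_labels)
    if counts.shape[0] != len(state_labels) or counts.shape[0] != len(type_labels):
        raise ValueError("one state and type label required per cell")
    _warn_if_non_integer(counts, "single-cell matrix")

    if state_ids_order is not None:
        state_ids = list(state_ids_order)
        missing = set(state_ids) - set(state_labels)
        if missing:
            raise ValueError(f"states with no cells: {sorted(missing)}")
        sums = np.vstack([counts[state_labels == s].sum(axis=0) for s in state_ids])
    else:
        sums, state_ids = _group_sums(counts, state_labels)

    # each state must belong to exactly one type
    type_of = []
    for s in state_ids:
        tl = pd.unique(type_labels[state_labels == s])
        if len(tl) != 1:
            raise ValueError(f"state {s!r} spans multiple types: {list(tl)}")
        type_of.append(tl[0])
    type_ids = list(pd.unique(np.asarray(type_of)))
    type_of_state = np.array([type_ids.index(t) for t in type_of])

    zero_states = [state_ids[i] for i in range(len(state_ids)) if sums[i].sum() <= 0]
    if zero_states:
        raise ValueError(f"states with zero total counts: {zero_states}")

    phi = np.vstack([norm_to_one(r, pseudo_min) for r in sums])
    mal_idx = None
    if malignant_type is not None:
        if malignant_type not in type_ids:
            raise ValueError(f"malignant type {malignant_type!r} not among type labels")
        mal_idx = type_ids.index(malignant_type)
    return CellStateReference(
        phi=phi,
        state_ids=list(state_ids),
        type_of_state=type_of_state,
        type_ids=type_ids,
        gene_ids=np.asarray(gene_ids, dtype=object),
        malignant_type=mal_idx,
        pseudo_min=pseudo_min,
        state_counts=sums,
    )


def build_type_reference(
    counts: np.ndarray,
    type_labels,
    gene_ids,
    pseudo_min: float = DEFAULT_PSEUDO_MIN,
) -> CellTypeReference:
    """Build the per-type reference phi' by summing counts over cells of a type."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("cell counts must be nonnegative")
    type_labels = np.asarray(type_labels)
    if counts.shape[0] != len(type_labels):
        raise ValueError("one type label required per cell")
    _warn_if_non_integer(counts, "single-cell matrix")
    sums, type_ids = _group_sums(counts, type_labels)
    zero = [type_ids[i] for i in range(len(type_ids)) if sums[i].sum() <= 0]
    if zero:
        raise ValueError(f"types with zero total counts: {zero}")
    phi_prime = np.vstack([norm_to_one(r, pseudo_min) for r in sums])
    return CellTypeReference(
        phi_prime=phi_prime,
        type_ids=list(type_ids),
        gene_ids=np.asarray(gene_ids, dtype=object),
        pseudo_min=pseudo_min,
    )


def filter_genes(
    bulk_matrix: np.ndarray,
    bulk_gene_ids,
    reference_gene_ids,
    annotation: GeneAnnotation | None = None,
    outlier_frac: float = 0.01,
    outlier_sample_frac: float = 0.10,
    drop_sex_mito: bool = True,
    drop_ribosomal: bool = True,
    protein_coding_only: bool = False,
) -> list:
    """Select genes shared by bulk and reference, minus problem categories.

    Removed are (a) genes on chrX/chrY/chrM, (b) ribosomal-protein genes
    (annotation biotype or RPL/RPS/MRPL/MRPS symbol prefix), and
    (c) bulk outliers: genes taking strictly more than ``outlier_frac``
    of a sample's reads in strictly more than ``outlier_sample_frac`` of
    samples.  Optionally restricted to protein-coding genes when an
    annotation with biotypes is supplied.

    Returns the retained gene ids in bulk order.
    """
    bulk_matrix = np.asarray(bulk_matrix, dtype=float)
    bulk_gene_ids = np.asarray(bulk_gene_ids, dtype=object)
    ref_norm = {str(g).upper() for g in reference_gene_ids}
    bulk_norm = np.array([str(g).upper() for g in bulk_gene_ids])

    shared = np.array([g in ref_norm for g in bulk_norm])
    if not shared.any():
        raise ValueError("bulk and reference share no gene ids")

    if annotation is None or len(annotation) == 0:
        if drop_sex_mito:
            warnings.warn(
                "no gene annotation supplied: sex/mitochondrial chromosome "
                "filter skipped", stacklevel=2,
            )
        annotation = annotation or GeneAnnotation()
        chrom_ok = np.ones(len(bulk_gene_ids), dtype=bool)
    elif drop_sex_mito:
        chrom_ok = np.array(
            [annotation.chromosome(g).lower() not in _SEX_MITO_CHROMS for g in bulk_gene_ids]
        )
    else:
        chrom_ok = np.ones(len(bulk_gene_ids), dtype=bool)

    if drop_ribosomal:
        ribo = np.array(
            [
                annotation.biotype(g).lower().startswith("ribosomal")
                or str(g).upper().startswith(_RIBO_PREFIXES)
                for g in bulk_gene_ids
            ]
        )
    else:
        ribo = np.zeros(len(bulk_gene_ids), dtype=bool)

    if protein_coding_only and len(annotation) > 0:
        coding = np.array(
            [annotation.biotype(g).lower() in {"protein-coding", "protein_coding"}
             for g in bulk_gene_ids]
        )
    else:
        coding = np.ones(len(bulk_gene_ids), dtype=bool)

    # outlier rule: share of reads > outlier_frac in > outlier_sample_frac of samples
    totals = bulk_matrix.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("bulk sample with zero total reads")
    share = bulk_matrix / totals
    n_samples = bulk_matrix.shape[0]
    n_exceed = (share > outlier_frac).sum(axis=0)
    outlier = n_exceed > outlier_sample_frac * n_samples

    keep = shared & chrom_ok & ~ribo & coding & ~outlier
    if not keep.any():
        raise ValueError("no genes survive filtering")
    return list(bulk_gene_ids[keep])
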
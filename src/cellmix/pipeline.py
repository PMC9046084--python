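"""End-to-end deconvolution convenience wrapper.

Chains the two passes most analyses need: the state-level Gibbs run with
the single-cell prior, aggregation to cell types, the reference update
(per-sample malignant MLE, pooled environment MAP), and the type-level
refit that yields the final fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs import (
    BulkExpression,
    CellTypeEstimate,
    GibbsConfig,
    PosteriorSummary,
    aggregate_states,
    run_gibbs,
)
from .reference import CellStateReference, CellTypeReference
from .update import FinalFractions, UpdatedReference, build_updated_reference, refit_theta


@dataclass
class DeconvolutionResult:
    """Everything the two-pass pipeline produces."""

    summary: PosteriorSummary
    estimate: CellTypeEstimate
    updated: UpdatedReference | None
    final: FinalFractions | None
    malignant_type: int | None = None

    @property
    def theta0(self) -> np.ndarray:
        return self.estimate.theta0

    @property
    def theta_f(self) -> np.ndarray:
        if self.final is None:
            raise AttributeError("pipeline was run without the update pass")
        return self.final.theta_f

    def malignant_expression(self, normalize: bool = True) -> np.ndarray:
        """Per-sample malignant expression: updated psi_mal rows when the
        update ran, otherwise normalized first-pass malignant Z rows."""
        if self.updated is not None and self.updated.psi_mal is not None:
            return self.updated.psi_mal
        if self.malignant_type is None:
            raise AttributeError("no malignant type designated on the reference")
        mal = self.estimate.Z[:, self.malignant_type, :]
        if normalize:
            totals = mal.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            mal = mal / totals
        return mal


def deconvolve(
    bulk: BulkExpression,
    ref: CellStateReference,
    cfg: GibbsConfig | None = None,
    update: bool = True,
    sigma: float = 2.0,
    cg_max_iter: int = 100_000,
    phi_prime: CellTypeReference | None = None,
) -> DeconvolutionResult:
    """Run the full two-pass deconvolution.

    With ``update=False`` only the first pass runs and ``theta0`` is the
    final answer.  ``phi_prime`` defaults to the type-level collapse of
    ``ref``.
    """
    cfg = cfg or GibbsConfig()
    summary = run_gibbs(bulk, ref, cfg)
    estimate = aggregate_states(summary, ref)
    if not update:
        return DeconvolutionResult(summary, estimate, None, None, ref.malignant_type)
    phi_prime = phi_prime or ref.type_reference()
    updated = build_updated_reference(
        estimate,
        phi_prime,
        malignant_type=ref.malignant_type,
        sigma=sigma,
        cg_max_iter=cg_max_iter,
        pseudo_min=ref.pseudo_min,
    )
    final = refit_theta(bulk, updated, cfg)
    return DeconvolutionResult(summary, estimate, updated, final, ref.malignant_type)
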
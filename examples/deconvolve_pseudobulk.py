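"""Deconvolve a simulated pseudo-bulk cohort and benchmark the estimates.

Builds a small synthetic tumour cohort (4 cell types, the malignant one
with 3 cell states) where the bulk samples differ from the single-cell
reference by multiplicative log-normal noise, runs the two-pass
deconvolution, and prints per-cell-type recovery metrics.
"""

import numpy as np

from cellmix import GibbsConfig, SimulationConfig, benchmark_metrics, deconvolve, simulate_cohort

cfg = SimulationConfig(
    n_genes=400,
    n_samples=12,
    bulk_depth=30_000,
    cells_per_state=25,
    noise_sigma=0.5,
    seed=1,
)
sim, bulk, truth = simulate_cohort(cfg)
print(f"reference: {sim.ref.n_states} states / {sim.ref.n_types} types, "
      f"{sim.ref.n_genes} genes; cohort: {bulk.X.shape[0]} samples")

result = deconvolve(bulk, sim.ref, GibbsConfig(chain_length=400, burn_in=200, seed=1))

true_frac = truth.type_fractions(sim.ref.n_types)
metrics = benchmark_metrics(result.theta0, true_frac, sim.ref.type_ids)
print("\nfirst-pass (theta0) per-type recovery vs ground truth:")
print(metrics.round(4))

r = np.corrcoef(result.theta0.ravel(), result.theta_f.ravel())[0, 1]
print(f"\ntheta0 vs theta_f Pearson r = {r:.4f}")
print("Pearson r near 1 per type means estimated fractions track the true "
      "read fractions across samples; MSE is their mean squared gap. The "
      "updated fractions (theta_f) should barely move on a well-specified "
      "cohort — the update mainly sharpens expression estimates.")
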
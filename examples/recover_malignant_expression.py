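"""Recover sample-specific malignant expression from high-purity bulks.

Each simulated bulk carries its own malignant expression profile (a
log-normal perturbation of the reference profile), emulating
patient-to-patient heterogeneity the single-cell prior has never seen.
The reference update estimates a per-sample malignant profile (psi_mal)
by maximum likelihood from the reads the sampler assigned to the
malignant type.
"""

import numpy as np

from cellmix import (
    GibbsConfig,
    SimulationConfig,
    deconvolve,
    simulate_malignant_recovery_cohort,
)

cfg = SimulationConfig(n_genes=400, n_samples=10, bulk_depth=30_000,
                       cells_per_state=25, noise_sigma=0.5, seed=2)
sim, bulk, truth = simulate_malignant_recovery_cohort(cfg)

result = deconvolve(bulk, sim.ref, GibbsConfig(chain_length=400, burn_in=200, seed=2))

purity = truth.realized_state_fractions[:, 0]
rs = np.array([
    np.corrcoef(result.updated.psi_mal[n], truth.malignant_profiles[n])[0, 1]
    for n in range(cfg.n_samples)
])
for n in range(cfg.n_samples):
    print(f"sample {n:2d}: true malignant fraction {purity[n]:.2f}, "
          f"profile recovery r = {rs[n]:.4f}")
print(f"\nmin r = {rs.min():.4f}, median r = {np.median(rs):.4f}")
print("Each r correlates the inferred per-sample malignant profile with the "
      "profile that actually generated that sample's malignant reads; values "
      "near 1 mean per-sample heterogeneity was recovered, not just the prior.")
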
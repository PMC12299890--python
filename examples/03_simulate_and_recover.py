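"""Validate the pipeline on synthetic data with known ground truth.

A one-compartment oral-absorption model (first-order absorption, optional
zero-order endogenous input) generates study-like profiles with lognormal
noise and LOQ censoring; the NCA estimators are then compared with the
analytic truth: a dense grid recovers the elimination rate almost exactly,
while the sparse censored study grid shows the estimator bias such designs
carry.
"""

import math

import numpy as np

from sparsepk import SimulationParams, default_study_design, recovery_experiment

params = SimulationParams(noise_cv=0.0, loq_mg_per_L=0.1)
dense = np.linspace(0.0, 10 * math.log(2) / params.ke_per_h, 30)
sparse = default_study_design().groups["subgroup2"]

print(f"true ke = {params.ke_per_h} 1/h, LOQ = {params.loq_mg_per_L} mg/L, noise-free\n")
for label, grid in [("dense 30-point grid", dense), ("sparse study grid (2-48 h)", sparse)]:
    report = recovery_experiment(params, grid, n_replicates=1, seed=0)
    k = report.loc["k_per_h"]
    print(f"{label}: ke_hat = {k['mean_estimate']:.4f} "
          f"(bias {100 * k['bias'] / k['truth']:+.1f}%)")

print("\nwith multiplicative noise (CV 20%), 200 replicates on the dense grid:")
noisy = recovery_experiment(SimulationParams(noise_cv=0.2, loq_mg_per_L=0.0),
                            dense, n_replicates=200, seed=1)
print(noisy.round(4).to_string())
print("\nbias is the mean estimate minus truth; rmse includes replicate scatter. "
      "AUC inherits the +cv^2/2 mean shift of lognormal noise by construction.")
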
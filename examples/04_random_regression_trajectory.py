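"""Random-regression model: parity-specific genetic parameters.

Fits the order-2 Legendre animal model and prints the per-calving genetic
variance, heritability and the genetic correlation between the first and
every other calving -- the quantities that motivate trajectory-aware
selection (h2 rises with parity while total variance falls).
"""

import numpy as np

from recurve import SimConfig, fit_rrm, simulate_ra_dataset
from recurve.legendre import genetic_correlation_matrix
from recurve.mixedmodel import information_criteria, trajectory_table

cfg = SimConfig(seed=11, n_founders=60, n_generations=5, cows_per_generation=170,
                n_sires_per_generation=8)
ped, table, truth = simulate_ra_dataset(cfg)
res = fit_rrm(table, ped, r=2)

traj = trajectory_table(res)
print(traj.round(2).to_string(index=False))
# genetic variance falls ~117 -> ~40 across calvings while h2 rises,
# mirroring the generating trajectory.

rg = genetic_correlation_matrix(res.components["Ka"], res.meta["basis"].Phi)
print("rg(calving 1, calving j):", np.round(rg[0], 2))

ic = information_criteria(res.logL, res.n_params, res.n_records)
print(f"logL = {res.logL:.1f}, k = {res.n_params}, AIC = {ic['AIC']:.0f}")
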
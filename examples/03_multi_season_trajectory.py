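"""Dynamic occupancy: colonization/extinction MLE and a bootstrap trajectory.

Fits the four dynamic-model variants over four seasons, compares them by AIC,
and projects occupancy forward from the best constant-rate fit through
psi_{t+1} = psi_t (1 - eps) + (1 - psi_t) gamma, with 95% intervals from a
1000-draw parametric bootstrap of the MLE.
"""

import occuwatch as ow

data, sites, _ = ow.simulate_dataset(ow.SimulationConfig(seed=13))

fits = [ow.fit_multi_season(data, sites, m) for m in ow.MultiSeasonModel]
print(ow.comparison_table(fits, criterion="AIC").round(3).to_string(index=False))

best = min((f for f in fits if f.converged), key=lambda f: f.AIC)
pars = best.params()
print(f"\nBest model: {best.model.value}")
print(f"psi1 = {pars.psi1_bb:.3f}, gamma = {pars.gamma[0]:.3f}, "
      f"eps = {pars.eps[0]:.3f}, p = {pars.p:.3f}")
print(f"Long-run equilibrium occupancy gamma/(gamma+eps) = "
      f"{pars.gamma[0] / (pars.gamma[0] + pars.eps[0]):.3f}\n")

trajectory = ow.bootstrap_trajectory(best, n_boot=1000, seed=1)
print(trajectory.for_area("BB").round(3).to_string(index=False))
print("\nEach row is the derived occupancy for that season with a 95% "
      "percentile interval from the parametric bootstrap.")
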
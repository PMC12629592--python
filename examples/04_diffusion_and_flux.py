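"""Lattice diffusion and the two routes to the growing end.

Estimates the 1D diffusion coefficient from synthetic trajectories via
the ensemble MSD, then asks how many molecules per second lattice
diffusion delivers to the end (Fick's-law model) compared with direct
binding from solution.
"""

import numpy as np

from tiptrack.diffusion import (
    FluxModel,
    compute_msd,
    diffusion_contribution,
    direct_arrival_rate,
    fit_diffusion_coefficient,
    flux_to_end,
    scanned_length,
    simulate_flux_walkers,
)
from tiptrack.simulate import simulate_trajectories

D_TRUE = 0.023  # um^2/s
trajectories = simulate_trajectories(D_TRUE, 203, (4, 60), dt=0.1, seed=9)
msd = compute_msd(trajectories, max_lag=4)
D = fit_diffusion_coefficient(msd, n_lags=4)
print(f"D = {D:.3f} um^2/s from {len(trajectories)} trajectories "
      f"(truth {D_TRUE})")
print(f"length scanned during a 0.6 s lattice dwell: "
      f"{scanned_length(D, 0.6):.0f} nm (about one GTP-cap length)")

kon_lat = 2.8e-6
koff_lat = kon_lat * 1057e3  # per-dimer lattice Kd 1057 uM
model = FluxModel(
    D=D_TRUE, kon_lattice=kon_lat, koff_lattice=koff_lat,
    concentration=10.0, site_density=1625.0,
)
j0 = flux_to_end(model)
walkers = simulate_flux_walkers(model, n_molecules=40_000, dt=0.004, seed=10)
np_direct = direct_arrival_rate(22.6e-6, 10.0, 260)
print(f"diffusive flux to the end: J0 = {j0:.4f} /s "
      f"(brute-force walkers: {walkers:.4f} /s)")
print(f"direct arrival rate: {np_direct:.3f} /s (260-site end); "
      f"0.067 /s with the wider ~296-site region")
print(f"lattice diffusion supplies ~{diffusion_contribution(j0, 0.067):.0f}% "
      f"of end arrivals - direct binding dominates.")
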
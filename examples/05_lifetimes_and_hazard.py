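"""Microtubule lifetimes, gamma fits and the catastrophe hazard.

Simulates growing microtubules whose lifetimes follow a gamma
distribution (catastrophe requires aging), refits the distribution by
maximum likelihood, and computes the probability-based catastrophe
frequency per lifetime bin.
"""

import numpy as np

from tiptrack.dynamics import fit_gamma, hazard_curve
from tiptrack.simulate import SimulationConfig, simulate_dynamics

config = SimulationConfig(n_frames=12_000, frame_interval=0.1)  # 20 min movie
mts = simulate_dynamics(
    config, growth_rate=0.8, lifetime_shape=3.0, lifetime_scale=107.8,
    n_microtubules=443, rng=np.random.default_rng(13),
)
lifetimes = np.array([m.lifetime for m in mts])
censored = np.array([m.censored for m in mts])

fit = fit_gamma(lifetimes, censored)
print(f"gamma fit: shape {fit.shape:.2f}, scale {fit.scale:.0f} s, "
      f"mean lifetime {fit.mean:.0f} s "
      f"({fit.n} catastrophes, {fit.n_censored} censored)")
print("A shape well above 1 means catastrophe risk grows with age;")
print("an exponential (shape 1) would mean age-independent catastrophe.")

hz = hazard_curve(lifetimes, bin_width=60.0, censored=censored)
print("\nlifetime bin   at risk   catastrophes   frequency")
for b, n, c, f in zip(
    hz.bin_starts[:8], hz.at_risk[:8], hz.catastrophes[:8], hz.frequency[:8]
):
    print(f"{b:6.0f} s       {n:5d}       {c:5d}        {f:.3f}")
print("The rising frequency column is the aging signature the gamma")
print("shape parameter summarizes.")
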
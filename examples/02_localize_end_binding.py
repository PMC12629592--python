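"""Sub-pixel localization of end-binding events in a rendered movie.

Renders a growing microtubule decorated with end-bound single
molecules, extracts per-frame line profiles from a kymograph, fits the
end edge (erfc) and molecule peak (Gaussian) in every frame, and pools
the per-event mean end-relative positions into a binding-region
distribution.
"""

import numpy as np

from tiptrack.io import LineROI, build_kymograph
from tiptrack.localization import (
    LineProfile,
    fit_end_profile,
    fit_molecule_peak,
    fit_position_distribution,
    localize_event,
)
from tiptrack.simulate import (
    MicrotubuleTruth,
    SimulationConfig,
    TruthBundle,
    render_movie,
    simulate_binding,
)

config = SimulationConfig(n_frames=2000, rng_seed=11)
rng = np.random.default_rng(config.rng_seed)

mt = MicrotubuleTruth(
    id=0, anchor_row=16 * config.pixel_size, anchor_col=0.0, orientation=1,
    growth_rate=0.8, lifetime=1e6, censored=True, seed_length=6000.0,
)
bindings = simulate_binding(
    config, [mt], kon_end=300e-6, kon_lattice=0.0, tau_end=0.75,
    concentration=10.0, rng=rng,
)
movie = render_movie(
    config, TruthBundle(config, [mt], bindings), microtubule_amplitude=800.0
)
kymo = build_kymograph(
    movie, LineROI(vertices=[(16.0, 0.0), (16.0, 127.0)], width=5)
)

events = []
for b in bindings:
    trace = b.axial_position_trace
    if trace.shape[0] < 2:
        continue
    end_fits, peak_fits = [], []
    for t, _ in trace:
        f = int(round(t / config.frame_interval))
        mt_prof = LineProfile(kymo.axial_positions, kymo.channel("microtubule")[f])
        mol_prof = LineProfile(kymo.axial_positions, kymo.channel("molecule")[f])
        end_fits.append(fit_end_profile(mt_prof, psf_guess=120.0))
        peak_fits.append(fit_molecule_peak(mol_prof))
    ev = localize_event(b.molecule_id, end_fits, peak_fits)
    if ev is not None:
        events.append(ev)

positions = np.array([e.position for e in events])
truth = np.array(
    [b.axial_position_trace[:, 1].mean() for b in bindings
     if b.axial_position_trace.shape[0] >= 2]
)
dist = fit_position_distribution(positions, model="gaussian", bin_width=20.0)

print(f"localized {len(events)} end-binding events (>= 2 frames each)")
print(f"mean end-relative position: {positions.mean():+.0f} nm "
      f"(truth {truth.mean():+.0f} nm; distal positive)")
print(f"binding-region FWHM: {dist.fwhm:.0f} nm "
      f"(region bounds {dist.region_bounds[0]:.0f} to {dist.region_bounds[1]:.0f} nm)")
print("Events inside the FWHM region count as end binding; more proximal")
print("positions count as lattice binding.")
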
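"""Projection-intensity comparisons on stabilized microtubules.

Sums many sparse single-molecule frames into a decoration-density
image, then compares (i) binding on two lattice types in the same flow
cell and (ii) end versus lattice binding on one microtubule.
"""

import numpy as np
from scipy.special import erfc

from tiptrack.intensity import (
    end_lattice_ratio,
    microtubule_mean_intensity,
    paired_condition_ratio,
    sum_projection,
)
from tiptrack.io import LineROI, MovieStack

rng = np.random.default_rng(17)

# --- sparse binding on two lattices, 1000 frames at 0.3 s ---------------
# GTPgammaS-like lattice at row 5 binds 3x more than the GDP lattice at
# row 11; each frame carries Poisson-distributed bound molecules
frames = rng.poisson(2.0, size=(1000, 16, 40)).astype(float)  # background
frames[:, 5, 5:35] += rng.poisson(0.9, size=(1000, 30))  # GTPgS lattice
frames[:, 11, 5:35] += rng.poisson(0.3, size=(1000, 30))  # GDP lattice
movie = MovieStack(frames[None], ("molecule",), 160.0, 0.3)
proj = sum_projection(movie, 1000)

bg_roi = LineROI([(2.0, 5.0), (2.0, 34.0)], width=1)
gtpgs = microtubule_mean_intensity(
    proj, LineROI([(5.0, 5.0), (5.0, 34.0)], width=1), bg_roi,
    lattice_class="GTPgS",
)
gdp = microtubule_mean_intensity(
    proj, LineROI([(11.0, 5.0), (11.0, 34.0)], width=1), bg_roi,
    lattice_class="GDP",
)
print(f"decoration density: GTPgS {gtpgs.intensity_per_um:.0f} A.U./um, "
      f"GDP {gdp.intensity_per_um:.0f} A.U./um")

cells = []
for _ in range(5):  # five flow cells with the same 3x preference
    cells.append(
        {
            "GTPgS": list(rng.normal(gtpgs.intensity_per_um, 80.0, 20)),
            "GDP": list(rng.normal(gdp.intensity_per_um, 80.0, 8)),
        }
    )
res = paired_condition_ratio(cells, "GTPgS", "GDP")
print(f"GTPgS/GDP ratio = {res['mean']:.2f} +/- {res['sem']:.2f} "
      f"(n={res['n_cells']} cells, p={res['p_value']:.1e} vs 1)")
print("A ratio above 1 means preferential binding to the GDP-Pi-like")
print("(GTPgammaS) lattice that mimics the EB cap.")

# --- end vs lattice on a GMPCPP microtubule ----------------------------
x = 160.0 * np.arange(40)
edge_px = 30.0
mt_profile = 100.0 * 0.5 * erfc((x / 160.0 - edge_px) / (np.sqrt(2) * 0.75))
mol_profile = np.where(x / 160.0 <= edge_px, 10.0, 0.0)
end_window = (x / 160.0 >= edge_px - 3) & (x / 160.0 <= edge_px)
mol_profile[end_window] *= 4.0  # 4x end enrichment

res_el = end_lattice_ratio(
    x, mol_profile, mt_profile, pixel_size=160.0, tipward=False
)
print(f"\nGMPCPP end/lattice intensity ratio = {res_el.ratio:.1f} "
      f"(edge at {res_el.edge_position/1e3:.1f} um)")
print("Ratios above 1 report end enrichment on stabilized microtubules,")
print("whose curled protofilament ends mimic growing tips.")
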
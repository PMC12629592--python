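# tiptrack

Single-molecule TIRF analysis of protein binding at growing microtubule
ends, built for experiments of the kind used to characterize the
kinesin-13 depolymerase MCAK: a fluorescent protein is imaged at
nanomolar concentration on dynamic microtubules, individual binding
events are localized with sub-pixel precision relative to the growing
plus end, and the event statistics are turned into binding kinetics,
diffusion and delivery models, and catastrophe statistics.

The package is a library: you use it from Python (see `examples/` for
one narrative script per capability). It contains no microscope data;
a ground-truthed synthetic TIRF generator (`tiptrack.simulate`) makes
every estimator testable end to end.

## What it computes

**Sub-pixel localization** (`tiptrack.localization`). A microtubule end
in a line profile is modeled as a PSF-convolved step ("Gaussian wall"
ending in a half-Gaussian), fitted as
`I(x) = bg + (A/2)·erfc((x − x_e)/(√2 σ))`; a single molecule is a
Gaussian peak over background. Per-frame molecule positions relative to
the fitted end (distal positive) are averaged over the dwell to one
position per event; the pooled positions are binned and fitted
(Gaussian, or exponentially modified Gaussian for comet-shaped binders
like EB1) and the FWHM defines the end-binding region. Localization
precision uses the quadrature identity `σ_I² = σ_O² + σ_PSF²`, with
σ_PSF calibrated from bead stacks.

**Binding kinetics** (`tiptrack.kinetics`). Events are screened by a
Gaussian intensity gate (μ ± 2σ) and a 200 ms dwell floor. Per-dimer
on-rates are `k_on = N_events / (N_sites · T · C)`; the end/lattice
preference `R_E/L` is the mean of per-microtubule on-rate ratios;
off-rates come from single-exponential fits to the dwell distribution
(with a floor-corrected MLE cross-check); dissociation constants are
`K_d = k_off/k_on` per site, and the multivalent end of `N` sites has
an effective `K_d/N`.

**Diffusion and delivery** (`tiptrack.diffusion`). The lattice
diffusion coefficient comes from linear regression of the ensemble MSD,
`⟨x²⟩ = 2Dt`, over the first four lags. A steady-state Fick's-law model
gives the diffusive flux into the growing end,
`J₀ = c_∞ √(D·k_off)` with `c_∞ = (k_on C / k_off) · ρ` and decay length
`x₀ = √(D/k_off)`, which is compared with the direct arrival rate
`N_p = k_on C N_sites` to partition the two binding pathways. A
brute-force Brownian-walker simulation cross-checks the closed form.

**Dynamic instability** (`tiptrack.dynamics`). Growth events are
segmented from end traces; lifetimes are fitted with a maximum-
likelihood gamma density, and the probability-based catastrophe
frequency (discrete hazard: catastrophes in a lifetime bin over
microtubules that reached it) quantifies microtubule aging.

**Projection intensities** (`tiptrack.intensity`). Frame sums over long
sparse movies give decoration densities on stabilized lattices
(GTPγS vs GDP ratios per flow cell; end vs lattice windows on GMPCPP
microtubules).

## Worked example

`python examples/04_diffusion_and_flux.py` prints:

```
D = 0.023 um^2/s from 203 trajectories (truth 0.023)
length scanned during a 0.6 s lattice dwell: 166 nm (about one GTP-cap length)
diffusive flux to the end: J0 = 0.0040 /s (brute-force walkers: 0.0041 /s)
direct arrival rate: 0.059 /s (260-site end); 0.067 /s with the wider ~296-site region
lattice diffusion supplies ~6% of end arrivals - direct binding dominates.
```

Reading: the MSD estimator recovers the generating diffusion
coefficient from 203 short synthetic tracks; at that mobility a
lattice-bound molecule scans roughly one GTP-cap length before
detaching; and solving the reaction–diffusion model shows that 1D
lattice diffusion delivers only a few percent of the molecules arriving
at the growing end — direct binding from solution dominates.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline numbers from scratch: the effective
multivalent dissociation constant of the end region, the Fick's-law
flux evaluated at the measured kinetic parameters, and four
parameter-recovery runs on synthetic data at the study's sample sizes
(mean end dwell from 966 events, diffusion coefficient from 203
trajectories, binding-region FWHM from 152 positions, two-color modal
offset from 62 events). Results are written as JSON keyed by target id.
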
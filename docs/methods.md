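# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Imaging model and coordinate conventions

Pixels are 0-based indices internally; every reported position is
physical (nm along the microtubule axis, seconds in time). Axial
positions of molecules are expressed relative to the fitted plus end,
distal positive and proximal (lattice-ward) negative, so a molecule
"behind" the tip has a negative coordinate.

Defaults state a typical single-molecule TIRF setup: 160 nm pixels
(100× objective on an EMCCD; the camera pixel size is not a measured
quantity here and is fully configurable), 100 ms frame interval with
50 ms exposure for single-molecule imaging, and a Gaussian PSF of
σ = 120 nm per channel. Site bookkeeping uses 13 protofilaments at the
8 nm axial dimer repeat (1625 dimers/µm); the end region defaults to
160 nm = 260 dimer sites. All of these are parameters, not constants.

## End and molecule localization

The microtubule lattice convolved with the PSF is a plateau whose
terminus is an error-function edge. We fit the single continuous model

    I(x) = bg + (A/2) · erfc((x − x_e) / (√2 σ))

rather than separate "wall" and "half-Gaussian" terms: the erfc is
exactly the PSF-convolved step, its centre x_e coincides with the peak
of the half-Gaussian derivative, and one model means fewer free
parameters and no ambiguity about background sharing. Initialisation:
background = profile minimum, amplitude = max − min, edge at the
half-maximum crossing, σ at the PSF guess; bounded least squares
(`scipy.optimize.curve_fit`). Fits that fail to converge or whose edge
lands on the span boundary are flagged and excluded downstream rather
than silently kept.

Molecules are fitted as Gaussian + constant. A second local maximum
within 70% of the main one raises an `ambiguous_peak` flag; events
flagged in a majority of frames should be dropped by the caller.

An event's position is the arithmetic mean of its per-frame
end-relative offsets and requires ≥ 2 valid frames (the 200 ms
detection floor at 100 ms/frame). Position is invariant under adding a
common constant to peak and edge (tested by property).

Pooled positions are binned (20 nm default) into a probability
histogram and fitted with a Gaussian (FWHM = 2√(2 ln 2)·σ exactly) or,
for comet-like distributions, an exponentially modified Gaussian whose
FWHM is evaluated on a dense grid (agreement with a root-finding
oracle < 0.1 nm). Binned fitting (rather than unbinned MLE) matches how
such probability distributions are conventionally fitted in this
literature; with 20 nm bins it inflates a 69 nm σ by < 0.4%.

Precision: an observed feature width is σ_I² = σ_O² + σ_PSF². The PSF
width is the median of per-bead integrated-Gaussian fits to a bead
stack (the integrated model matters: a point-sampled Gaussian fit is
biased wide by the pixel variance 1/12 px²). Records with σ_I < σ_PSF
are noise-dominated, excluded, and counted. The population precision is
the SD of a Gaussian fitted to the per-event σ_O distribution.

## Event screening and kinetics

The single-molecule gate is a Gaussian fitted to the event-intensity
histogram; acceptance is the closed interval [μ − 2σ, μ + 2σ] (≈ 95.45%
of a pure population). The fit is confined to the contiguous region
around the dominant mode so monomer contamination shifts neither μ nor
σ; a secondary mode above 25% of the main one with a real dip between
them triggers a bimodality warning.

On-rates are per tubulin dimer: k_on = N_events/(N_sites·T·C). The
end/lattice preference R_E/L is deliberately the mean of
per-microtubule ratios, not the ratio of mean rates — the two differ on
heterogeneous data (Jensen's inequality), and the per-microtubule
estimator is the one that matches published values; both can be formed
from the same pairs. Microtubules with zero lattice events are excluded
from the ratio with their count reported.

Dwell analysis reports (i) the arithmetic mean dwell of retained
events, (ii) k_off from a single-exponential fit to the binned dwell
probabilities over [min_dwell, ∞), and (iii) a shifted-exponential MLE
k_off = 1/(mean − min_dwell) as a cross-check: conditioning an
exponential on exceeding the detection floor shifts its mean by exactly
the floor (memorylessness), so the naive mean overestimates τ by
min_dwell. K_d = k_off/k_on per site (µM); the K_d used by default is
the exponential-fit rate. The multivalent end of N sites gets
K_d,eff = K_d/N (expected occupancy of one molecule at C = K_d/N,
within 1% of the exact K_d/(N−1) for N ≥ 100); the alternative
half-occupancy definition K_d·ln2/N is available but not default.

## Diffusion and the delivery model

MSD: time-averaged squared displacements per trajectory, ensemble
averaged per lag, SEM over trajectories. D is half the slope of an
unweighted straight-line fit over the first 4 lags with free intercept;
the intercept absorbs static localization error, and 4 lags is the
standard compromise for short tracks (tracks shorter than 4 frames are
rejected at construction). A negative fitted slope reports D = 0 with a
warning rather than a negative coefficient.

The delivery model treats lattice-bound molecules as a 1D
reaction–diffusion field with an absorbing end: far from the end the
bound density is c_∞ = (k_on·C/k_off)·ρ (ρ = 1625 dimers/µm), decaying
toward the end over x₀ = √(D/k_off), giving the absorbed flux
J₀ = D·c_∞/x₀ = c_∞·√(D·k_off). The k_off entering this model is the
exponential-fit lattice rate (equivalently K_d,L·k_on,L), not
1/mean-dwell. The brute-force cross-check simulates arrivals uniformly
over 8 decay lengths, Brownian steps with Brownian-bridge
first-passage detection (removing most discretization bias at
dt = 4–5 ms), and exponential unbinding; because bound molecules do
not interact, per-arrival simulation is equivalent to simulating the
full time-domain lattice and far cheaper. Agreement with the closed
form is within 5% across a 3×3 (D, k_off) grid.

The direct arrival rate is N_p = k_on·C·N_sites. With the 260-site
(160 nm) end this gives 0.059 s⁻¹ at 10 nM; a published 0.067 s⁻¹
implies ≈ 296 sites (a ~185 nm region). Both conventions are computed;
the pathway partition (J₀/N_p as a percentage) is reported against the
published direct rate where a comparison is intended.

## Lifetimes and catastrophe hazard

Growth segments are found by displacement-sign runs; a sign change must
persist ≥ 3 frames to split a segment (shorter excursions are treated
as tracking jitter). Segment slope (least squares) gives the growth
rate; a segment reaching the end of the movie is censored.

The lifetime density is fitted by gamma MLE (`scipy.stats.gamma.fit`,
location fixed at 0) on uncensored lifetimes only — matching a plain
density fit — with the censored count reported. The discrete hazard
("probability-based catastrophe frequency") is, per lifetime bin,
catastrophes in the bin over microtubules at risk at the bin start;
censored microtubules count as at risk up to their censoring time but
never as catastrophes. The last bin is closed so the maximum lifetime
is counted. On uncensored data the survival curve rebuilt as
∏(1 − f_bin) equals the empirical survival identically. Default bin
width 30 s.

## Projection intensities

Projections are exact per-pixel sums of a stated frame window.
Decoration density is the background-subtracted line-ROI intensity
integrated over the ROI and divided by its physical length (A.U./µm);
it is linear in molecule brightness and exactly invariant to a constant
offset. Condition comparisons are per flow cell (ratio of class means),
with a one-sample t-test against 1. The GMPCPP end window is 3 pixels
anchored at the erfc edge midpoint; the published definition of the
window's direction is ambiguous, so both orientations are implemented
(`tipward=True`, the default, extends off the tip; `tipward=False`
extends onto the lattice — the choice that matches a decorated-lattice
geometry where all signal lies lattice-ward of the edge). The lattice
value is the interior mean excluding 3-pixel guards at both ends.

## Synthetic data: what it does and does not emulate

The generator produces gamma lifetimes with linear growth and
instantaneous catastrophe (shrinkage is not rendered — the analysis
consumes growth phases and lifetimes only), Poisson arrivals at end
(homogeneous) and lattice (inhomogeneous in time via thinning, since
the lattice grows), exponential dwells with optional truncation at the
detection floor, end-bound molecules that hold a fixed offset to the
moving end, lattice molecules with Brownian steps of variance 2DΔt,
and rendering by integrated Gaussians (photon-conserving before noise)
with Poisson shot noise and Gaussian read noise. Identical seed and
configuration give bit-identical output.

Stated-world defaults: growth 0.8 µm/min; lifetime mean 323 s (shape 3
chosen as a typical aging value — the shape itself is a free simulation
choice, the mean is matched); k_on 22.6/2.8 ×10⁻⁶ s⁻¹nM⁻¹ per dimer
(end/lattice); dwells 0.75/0.62 s; D = 0.023 µm²/s; 10 nM
concentration; brightness 300 ± 72.5 A.U. per dimer.

Not emulated: 3D PSF structure and aberrations, EM-gain noise beyond a
scale factor plus read noise, photobleaching (dwell truth is purely
kinetic), shrinking ends, helical/2D lattice diffusion, and the
instrument's absolute photon budget — synthetic SNR is realistic in
order of magnitude, not matched to a specific camera. A green test on
synthetic data therefore establishes estimator correctness under the
model's assumptions, not robustness to every instrument artifact.

## Known limitations

- The erfc end model assumes a single well-resolved end per profile;
  crossing microtubules are not handled.
- The EMG fit is performed on binned probabilities; for very small
  samples an unbinned MLE would be more efficient.
- R_E/L as mean-of-ratios is biased upward at low per-microtubule
  counts (Jensen); the bias vanishes as counts grow and the
  ratio-of-means is available for comparison.
- The hazard estimator needs no smoothing but becomes noisy in bins
  with few microtubules at risk; interpret the tail cautiously.
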
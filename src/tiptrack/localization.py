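"""Sub-pixel localization of microtubule ends and single molecules.

The microtubule end in a line profile is the PSF-convolved edge of a
step: a "Gaussian wall" terminated by a half-Gaussian.  Both are one
continuous model here, ``I(x) = bg + (A/2) * erfc((x - x_e)/(sqrt(2)
sigma))``, whose centre ``x_e`` is the end reference.  Single molecules
are Gaussian peaks over a constant background.  Per-frame molecule
positions are expressed relative to the fitted end (distal positive)
and averaged over the dwell to give one position per event; the pooled
positions define the end-binding region via the FWHM of a fitted
distribution (Gaussian, or exponentially modified Gaussian for
comet-shaped binders such as EB1).

Localization precision: the observed width of a fitted feature is the
quadrature sum of the true measurement error and the PSF width,
``sigma_I^2 = sigma_O^2 + sigma_PSF^2``; the PSF width is calibrated
from bead stacks and deconvolved away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, special, stats

__all__ = [
    "LineProfile",
    "EndFit",
    "PeakFit",
    "EventLocalization",
    "PositionDistribution",
    "TwoColorResult",
    "fit_end_profile",
    "fit_molecule_peak",
    "localize_event",
    "fit_position_distribution",
    "two_color_distance",
    "estimate_psf_sigma",
    "deconvolve_precision",
    "population_precision",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class LineProfile:
    """Intensity samples along the microtubule axis for one frame."""

    positions: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # A.U.
    frame: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1D")
        if x.size < 8:
            raise ValueError("profile needs >= 8 samples for fitting")
        if not np.all(np.diff(x) > 0):
            raise ValueError("positions must be strictly increasing")
        self.positions = x
        self.intensities = y


@dataclass
class EndFit:
    """Erfc edge fit: the plus-end position of a microtubule."""

    edge_position: float  # nm
    edge_sigma: float  # nm
    amplitude: float
    background: float
    residual: float
    flag: str | None = None  # None = good fit

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass
class PeakFit:
    """Gaussian + constant fit: a single molecule's position."""

    center: float  # nm
    sigma: float  # nm
    amplitude: float
    background: float
    residual: float
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass
class EventLocalization:
    """Mean end-relative position of one binding event."""

    event_id: int
    frame_positions: np.ndarray  # nm per retained frame, distal positive
    n_frames: int
    position: float  # nm, arithmetic mean over the dwell

    @classmethod
    def from_frames(cls, event_id: int, frame_positions: np.ndarray) -> "EventLocalization":
        fp = np.asarray(frame_positions, dtype=float)
        return cls(
            event_id=event_id,
            frame_positions=fp,
            n_frames=int(fp.size),
            position=float(np.mean(fp)),
        )


@dataclass
class PositionDistribution:
    """Fitted end-binding-position distribution and its FWHM."""

    model: str  # "gaussian" | "emg"
    params: dict
    fwhm: float  # nm
    n: int
    mode: float  # nm, position of the distribution maximum
    region_bounds: tuple[float, float] | None = None  # gaussian only


def _erfc_edge(x, bg, amp, xe, sigma, orientation):
    z = orientation * (x - xe) / (np.sqrt(2.0) * sigma)
    return bg + 0.5 * amp * special.erfc(z)


def fit_end_profile(
    profile: LineProfile, psf_guess: float = 120.0, orientation: int = 1
) -> EndFit:
    """Least-squares erfc edge fit to a microtubule end profile.

    ``orientation=+1`` means the plus end points toward increasing x
    (intensity falls with x across the edge); ``-1`` mirrors the model.
    Initialisation: background = profile minimum, amplitude =
    max - min, edge at the half-maximum crossing, sigma from the PSF
    guess; bounded least squares.  Non-convergence or an edge pinned at
    the span boundary is flagged so the event can be excluded
    downstream.
    """
    x, y = profile.positions, profile.intensities
    bg0 = float(y.min())
    amp0 = float(y.max() - y.min())
    half = bg0 + 0.5 * amp0
    crossings = np.flatnonzero(np.diff(np.sign(y - half)))
    xe0 = float(x[crossings[-1]]) if crossings.size else float(x[x.size // 2])
    span = x[-1] - x[0]
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, bg, amp, xe, sig: _erfc_edge(xx, bg, amp, xe, sig, orientation),
            x, y, p0=(bg0, amp0, xe0, psf_guess),
            bounds=(
                [-np.inf, 0.0, x[0], 1e-3],
                [np.inf, np.inf, x[-1], span],
            ),
            maxfev=10_000,
        )
    except RuntimeError:
        return EndFit(np.nan, np.nan, np.nan, np.nan, np.inf, flag="no_convergence")
    bg, amp, xe, sig = popt
    resid = float(np.sqrt(np.mean((y - _erfc_edge(x, *popt, orientation)) ** 2)))
    flag = None
    edge_margin = 1e-6 * span
    if xe <= x[0] + edge_margin or xe >= x[-1] - edge_margin:
        flag = "edge_at_boundary"
    return EndFit(float(xe), float(sig), float(amp), float(bg), resid, flag=flag)


def _gaussian_const(x, bg, amp, mu, sigma):
    return bg + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_molecule_peak(profile: LineProfile, ambiguity_ratio: float = 0.7) -> PeakFit:
    """Gaussian + constant background fit to a single-molecule spot.

    A second local maximum within ``ambiguity_ratio`` of the main one
    is flagged as ambiguous; a profile with no usable peak (flat, or
    failed fit) is flagged ``no_peak``.
    """
    x, y = profile.positions, profile.intensities
    smooth = ndimage.uniform_filter1d(y, size=3)
    interior = smooth[1:-1]
    maxima = np.flatnonzero((interior >= smooth[:-2]) & (interior >= smooth[2:])) + 1
    bg0 = float(np.median(y))
    prominences = smooth[maxima] - bg0
    usable = maxima[prominences > 0]
    if usable.size == 0 or y.max() - y.min() <= 0:
        return PeakFit(np.nan, np.nan, np.nan, np.nan, np.inf, flag="no_peak")
    order = np.argsort(smooth[usable])[::-1]
    flag = None
    if usable.size > 1:
        p_main = smooth[usable[order[0]]] - bg0
        p_next = smooth[usable[order[1]]] - bg0
        if p_next >= ambiguity_ratio * p_main:
            flag = "ambiguous_peak"
    mu0 = float(x[usable[order[0]]])
    amp0 = float(y.max() - bg0)
    span = x[-1] - x[0]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_const, x, y,
            p0=(bg0, amp0, mu0, span / 10.0),
            bounds=([-np.inf, 0.0, x[0], 1e-3], [np.inf, np.inf, x[-1], span]),
            maxfev=10_000,
        )
    except RuntimeError:
        return PeakFit(np.nan, np.nan, np.nan, np.nan, np.inf, flag="no_peak")
    bg, amp, mu, sig = popt
    resid = float(np.sqrt(np.mean((y - _gaussian_const(x, *popt)) ** 2)))
    if amp <= 0:
        flag = flag or "no_peak"
    return PeakFit(float(mu), float(sig), float(amp), float(bg), resid, flag=flag)


def localize_event(
    event_id: int,
    end_fits: list[EndFit],
    peak_fits: list[PeakFit],
    orientation: int = 1,
) -> EventLocalization | None:
    """End-relative position of a binding event, averaged over its dwell.

    Per frame, ``dx = orientation * (peak - edge)`` so distal is
    positive regardless of which way the microtubule points.  Frames
    with a flagged end or peak fit are dropped; events with fewer than
    two valid frames (the 200 ms floor) are rejected (returns None).
    """
    if len(end_fits) != len(peak_fits):
        raise ValueError("end_fits and peak_fits must be frame-matched")
    dx = [
        orientation * (p.center - e.edge_position)
        for e, p in zip(end_fits, peak_fits)
        if e.ok and p.ok
    ]
    if len(dx) < 2:
        return None
    return EventLocalization.from_frames(event_id, np.asarray(dx))


def _emg_pdf(x, mu, sigma, lam):
    """Exponentially modified Gaussian density (exponential tail to +x)."""
    return stats.exponnorm.pdf(x, K=1.0 / (lam * sigma), loc=mu, scale=sigma)


def _grid_fwhm(fun, lo: float, hi: float, n: int = 200_001) -> tuple[float, float]:
    """FWHM and mode of a unimodal curve by dense-grid half-crossings."""
    xs = np.linspace(lo, hi, n)
    ys = fun(xs)
    i_max = int(np.argmax(ys))
    half = ys[i_max] / 2.0
    left = ys[: i_max + 1] - half
    right = ys[i_max:] - half
    i_l = np.flatnonzero(np.diff(np.sign(left)))
    i_r = np.flatnonzero(np.diff(np.sign(right)))
    if i_l.size == 0 or i_r.size == 0:
        raise ValueError("half-maximum not bracketed on the evaluation grid")

    def cross(i, y0, y1, x0, x1):
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    il = i_l[-1]
    x_left = cross(il, ys[il], ys[il + 1], xs[il], xs[il + 1])
    ir = i_r[0] + i_max
    x_right = cross(ir, ys[ir], ys[ir + 1], xs[ir], xs[ir + 1])
    return float(x_right - x_left), float(xs[i_max])


def fit_position_distribution(
    positions: np.ndarray | list[EventLocalization],
    model: str = "gaussian",
    bin_width: float = 20.0,
) -> PositionDistribution:
    """Fit the pooled binding-position distribution and report its FWHM.

    Positions are binned at ``bin_width`` (probability-normalized
    histogram) and fitted with the chosen model: ``"gaussian"`` for
    compact binders (FWHM = 2*sqrt(2 ln 2)*sigma exactly; the
    [mu - FWHM/2, mu + FWHM/2] region bounds are exported for
    end/lattice classification) or ``"emg"`` for comet-shaped
    distributions (FWHM from a dense grid).
    """
    if len(positions) and isinstance(positions[0], EventLocalization):
        positions = np.array([e.position for e in positions])
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    if n < 30:
        raise ValueError("need >= 30 events for a stable distribution fit")
    lo = bin_width * np.floor(positions.min() / bin_width)
    hi = bin_width * np.ceil(positions.max() / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(positions, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prob = counts / counts.sum()
    span = positions.max() - positions.min()

    if model == "gaussian":
        p0 = (prob.max(), float(np.mean(positions)), float(np.std(positions)))
        popt, _ = optimize.curve_fit(
            lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
            centers, prob, p0=p0,
            bounds=([0, lo, 1e-6], [np.inf, hi, np.inf]), maxfev=10_000,
        )
        amp, mu, sig = popt
        sig = abs(sig)
        if sig < bin_width / 10 or sig > span:
            raise ValueError(f"degenerate gaussian fit (sigma={sig:.3g} nm)")
        fwhm = FWHM_FACTOR * sig
        return PositionDistribution(
            model="gaussian",
            params={"amplitude": float(amp), "mu": float(mu), "sigma": float(sig)},
            fwhm=float(fwhm),
            n=n,
            mode=float(mu),
            region_bounds=(float(mu - fwhm / 2), float(mu + fwhm / 2)),
        )
    if model == "emg":
        mu0 = float(np.median(positions))
        sig0 = float(np.std(positions)) / 2
        lam0 = 2.0 / max(float(np.std(positions)), 1e-6)
        popt, _ = optimize.curve_fit(
            lambda x, a, mu, s, lam: a * _emg_pdf(x, mu, s, lam),
            centers, prob, p0=(prob.max() * 2 * sig0, mu0, sig0, lam0),
            bounds=([0, lo - span, 1e-6, 1e-9], [np.inf, hi + span, span, np.inf]),
            maxfev=20_000,
        )
        amp, mu, sig, lam = popt
        if sig < bin_width / 10 or sig > span:
            raise ValueError(f"degenerate EMG fit (sigma={sig:.3g} nm)")
        fwhm, mode = _grid_fwhm(
            lambda xs: _emg_pdf(xs, mu, sig, lam), lo - span, hi + span
        )
        return PositionDistribution(
            model="emg",
            params={
                "amplitude": float(amp),
                "mu": float(mu),
                "sigma": float(sig),
                "lambda": float(lam),
            },
            fwhm=fwhm,
            n=n,
            mode=mode,
        )
    raise ValueError(f"unknown model {model!r}")


@dataclass
class TwoColorResult:
    """Distribution of axial distances between two channels."""

    event_distances: np.ndarray  # nm, one mean distance per event
    mode: float  # nm, mode of the fitted distance distribution
    mean: float
    fraction_positive: float  # events with distance > 0
    bin_width: float
    histogram: tuple[np.ndarray, np.ndarray]  # (probabilities, bin centers)


def two_color_distance(
    peaks_a: list[np.ndarray],
    peaks_b: list[np.ndarray],
    registration_offset: float = 0.0,
    bin_width: float = 20.0,
) -> TwoColorResult:
    """Per-event mean axial distance between two-colour peak tracks.

    For each event, the per-frame distance is ``center_b - center_a +
    registration_offset`` (channel A is the origin); the event value is
    the mean over the frames of B's dwell.  The pooled distances are
    binned and fitted with a Gaussian whose mean is reported as the
    modal distance (falling back to the highest histogram bin if the
    fit fails).
    """
    if len(peaks_a) != len(peaks_b):
        raise ValueError("need the same number of events in both channels")
    distances = []
    for a, b in zip(peaks_a, peaks_b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("per-event frames must be matched across channels")
        distances.append(float(np.mean(b - a)) + registration_offset)
    distances = np.asarray(distances)
    lo = bin_width * np.floor(distances.min() / bin_width)
    hi = bin_width * np.ceil(distances.max() / bin_width)
    if hi <= lo:  # degenerate spread: a single bin around the data
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prob = counts / counts.sum()
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
            centers, prob,
            p0=(prob.max(), float(np.mean(distances)), float(np.std(distances))),
            maxfev=10_000,
        )
        mode = float(popt[1])
    except (RuntimeError, TypeError, ValueError):
        mode = float(centers[np.argmax(prob)])
    return TwoColorResult(
        event_distances=distances,
        mode=mode,
        mean=float(np.mean(distances)),
        fraction_positive=float(np.mean(distances > 0)),
        bin_width=bin_width,
        histogram=(prob, centers),
    )


def _fit_bead(cutout: np.ndarray) -> float | None:
    """Symmetric 2D Gaussian width (px) of one bead cutout.

    The model integrates the Gaussian over each unit pixel (erf
    differences); fitting a point-sampled Gaussian instead would
    broaden sigma by the pixel variance 1/12 px^2.
    """
    h, w = cutout.shape
    rows = np.arange(h)
    cols = np.arange(w)

    def pix(u, mu, sig):
        a = (u - mu + 0.5) / (np.sqrt(2.0) * sig)
        b = (u - mu - 0.5) / (np.sqrt(2.0) * sig)
        return 0.5 * (special.erf(a) - special.erf(b))

    def model(_, bg, amp, r0, c0, sig):
        return (bg + amp * np.outer(pix(rows, r0, sig), pix(cols, c0, sig))).ravel()

    bg0 = float(np.median(cutout))
    weights = np.clip(cutout - bg0, 0, None)
    total = float(weights.sum())
    if total <= 0:
        return None
    yy, xx = np.mgrid[0:h, 0:w]
    r0 = float((weights * yy).sum() / total)
    c0 = float((weights * xx).sum() / total)
    var = (weights * ((yy - r0) ** 2 + (xx - c0) ** 2)).sum() / (2.0 * total)
    sig0 = float(np.sqrt(max(var, 0.05)))
    try:
        popt, _ = optimize.curve_fit(
            model, None, cutout.ravel(),
            p0=(bg0, total, r0, c0, sig0),
            bounds=([-np.inf, 0, 0, 0, 0.1], [np.inf, np.inf, h, w, max(h, w)]),
            maxfev=10_000,
        )
    except RuntimeError:
        return None
    return float(popt[4])


def estimate_psf_sigma(
    stack, min_beads: int = 10, cutout_half: int = 5
) -> dict[str, float]:
    """Median per-bead Gaussian width per channel, in nm.

    Beads are detected as bright local maxima in the time-averaged
    frame of each channel; each is cut out and fitted with a symmetric
    2D Gaussian.  Fewer than ``min_beads`` detections warns but
    proceeds.
    """
    out: dict[str, float] = {}
    for ci, role in enumerate(stack.channels):
        mean_img = stack.pixels[ci].mean(axis=0).astype(float)
        bg = np.median(mean_img)
        thresh = bg + 0.25 * (mean_img.max() - bg)
        maxfilt = ndimage.maximum_filter(mean_img, size=2 * cutout_half + 1)
        peaks = np.argwhere((mean_img == maxfilt) & (mean_img > thresh))
        sigmas = []
        for r, c in peaks:
            if (
                r < cutout_half or c < cutout_half
                or r >= mean_img.shape[0] - cutout_half
                or c >= mean_img.shape[1] - cutout_half
            ):
                continue
            cut = mean_img[
                r - cutout_half : r + cutout_half + 1,
                c - cutout_half : c + cutout_half + 1,
            ]
            sig = _fit_bead(cut)
            if sig is not None:
                sigmas.append(sig)
        if len(sigmas) < min_beads:
            warnings.warn(
                f"only {len(sigmas)} beads found in channel {role!r} "
                f"(< {min_beads}); proceeding",
                stacklevel=2,
            )
        if not sigmas:
            raise ValueError(f"no beads found in channel {role!r}")
        out[role] = float(np.median(sigmas) * stack.pixel_size)
    return out


def deconvolve_precision(sigma_i: float, sigma_psf: float) -> float:
    """Measurement error from an observed width: the exact inverse of
    quadrature convolution, ``sigma_O = sqrt(sigma_I^2 - sigma_PSF^2)``.

    Raises if ``sigma_I < sigma_PSF`` (noise-dominated record; use
    :func:`population_precision` to tally and exclude such records).
    """
    if sigma_i < sigma_psf:
        raise ValueError("sigma_I < sigma_PSF: noise-dominated record")
    return float(np.sqrt(sigma_i**2 - sigma_psf**2))


def population_precision(
    sigma_i_values: np.ndarray, sigma_psf: float, bins: int = 20
) -> tuple[float, int]:
    """Population localization precision from per-event observed widths.

    Each record's measurement error is deconvolved from the PSF;
    records with ``sigma_I < sigma_PSF`` are excluded (their count is
    returned).  A Gaussian is fitted to the distribution of the
    remaining per-event errors and its standard deviation is the
    precision.
    """
    sigma_i_values = np.asarray(sigma_i_values, dtype=float)
    ok = sigma_i_values >= sigma_psf
    n_excluded = int(np.count_nonzero(~ok))
    errors = np.sqrt(sigma_i_values[ok] ** 2 - sigma_psf**2)
    if errors.size < 10:
        raise ValueError("too few usable records for a population fit")
    counts, edges = np.histogram(errors, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prob = counts / counts.sum()
    p0 = (prob.max(), float(np.mean(errors)), float(np.std(errors)) or 1.0)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
            centers, prob, p0=p0, maxfev=10_000,
        )
        precision = float(abs(popt[2]))
    except RuntimeError:
        precision = float(np.std(errors))
    return precision, n_excluded
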
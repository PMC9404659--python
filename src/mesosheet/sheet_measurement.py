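"""Light-sheet thickness measurement from 2-D sheet cross-section images.

The measurement substrate is an image of the sheet itself: the first
image axis is x, perpendicular to the sheet, and the second axis is y,
the propagation coordinate across the field of view.  Thickness is the
full width at half maximum (FWHM) of the transverse intensity profile;
for an Airy sheet, of the first (dominant) lobe only, so side lobes never
widen the reported value.

Profiles can be measured raw (interpolated half-maximum crossings) or by
nonlinear least-squares fits of either a Gaussian

    I(x) = A exp(-2 (x - c)^2 / w^2) + b          (FWHM = w sqrt(2 ln 2))

or the focal Airy intensity

    I(x) = A |Ai((x - c)/x0)|^2 exp(2 a (x - c)/x0) + b.

Uncertainties come from a bootstrap over image rows inside the averaging
window (an explicit convention of this package: the profile is the mean
of many single-row samples, and resampling rows propagates row-to-row
variability into the reported FWHM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import airy as _airy_all

from .beam_models import BeamProfile

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SheetImage:
    """2-D sheet cross-section image; axis 0 = x (transverse), axis 1 = y.

    ``pixel_pitch`` is the transverse (x) sampling; the propagation axis
    may be sampled more coarsely via ``pixel_pitch_y`` (the sheet varies
    slowly along y), defaulting to the same pitch.
    """

    pixels: np.ndarray
    pixel_pitch: float = 0.224      # um / pixel along x
    pixel_pitch_y: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("sheet image must be 2-D, at least 16 x 16 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("sheet image intensities must be finite")
        if np.any(px < 0):
            raise ValueError("sheet image intensities must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.pixel_pitch_y is None:
            object.__setattr__(self, "pixel_pitch_y", self.pixel_pitch)
        elif self.pixel_pitch_y <= 0:
            raise ValueError("pixel pitch must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def x_extent(self) -> float:
        return self.pixels.shape[0] * self.pixel_pitch

    @property
    def y_extent(self) -> float:
        return self.pixels.shape[1] * self.pixel_pitch_y


@dataclass
class FitResult:
    """Parameters of a profile fit plus goodness-of-fit."""

    kind: str                    # "gaussian" | "airy"
    params: dict
    fwhm: float
    residual: float              # RMS of (fit - data) / peak
    converged: bool
    message: str = ""


@dataclass
class ThicknessMeasurement:
    """Sheet thickness at one propagation position."""

    y_position: float
    fwhm: float
    fwhm_uncertainty: float
    fit_kind: str                # "gaussian" | "airy" | "raw"
    fit_params: dict
    fit_residual: float
    converged: bool = True


# --------------------------------------------------------------------------
# profile extraction
# --------------------------------------------------------------------------

def _background(values: np.ndarray, method: str = "lowest-decile",
                image: Optional[np.ndarray] = None) -> float:
    if method == "lowest-decile":
        n = max(1, int(round(0.10 * values.size)))
        return float(np.median(np.sort(values)[:n]))
    if method == "corners":
        if image is None:
            raise ValueError("corner background needs the full image")
        kx = max(1, image.shape[0] // 20)
        ky = max(1, image.shape[1] // 20)
        patches = np.concatenate([
            image[:kx, :ky].ravel(), image[:kx, -ky:].ravel(),
            image[-kx:, :ky].ravel(), image[-kx:, -ky:].ravel(),
        ])
        return float(np.median(patches))
    if method == "none":
        return 0.0
    raise ValueError(f"unknown background method: {method!r}")


def extract_profile(
    image: SheetImage,
    y: float,
    window: float,
    background: str = "lowest-decile",
) -> BeamProfile:
    """Columnwise mean intensity over a y-window, as a function of x.

    The background (median of the lowest decile) is subtracted and the
    profile clipped at zero.
    """
    pitch = image.pixel_pitch
    y_centers = (np.arange(image.pixels.shape[1]) + 0.5) * image.pixel_pitch_y
    sel = np.abs(y_centers - y) <= window / 2.0
    if not sel.any():
        raise ValueError(
            f"window [{y - window / 2}, {y + window / 2}] um lies outside "
            f"the image y-extent [0, {image.y_extent}] um"
        )
    prof = image.pixels[:, sel].mean(axis=1)
    prof = prof - _background(prof, background, image.pixels)
    prof = np.clip(prof, 0.0, None)
    if prof.max() <= 0:
        raise ValueError("profile is all zero after background subtraction")
    x = (np.arange(prof.size) + 0.5) * pitch
    return BeamProfile(x, prof)


# --------------------------------------------------------------------------
# FWHM of the dominant lobe
# --------------------------------------------------------------------------

def _half_crossing(x: np.ndarray, inten: np.ndarray, peak_idx: int,
                   half: float, step: int, rebound: float) -> float:
    """Position of the half-maximum crossing on one side of the peak.

    Walks away from the peak; stops with an error if the profile rebounds
    by more than ``rebound`` (an inter-lobe minimum above half maximum)
    before crossing, so side lobes are never included.
    """
    i = peak_idx
    run_min = inten[peak_idx]
    n = inten.size
    while True:
        j = i + step
        if j < 0 or j >= n:
            side = "left" if step < 0 else "right"
            raise ValueError(
                f"profile never falls below half maximum on the {side} side"
            )
        v = inten[j]
        if v <= half:
            return float(np.interp(half, [v, inten[i]], [x[j], x[i]]))
        if v < run_min:
            run_min = v
        elif v > run_min + rebound:
            side = "left" if step < 0 else "right"
            raise ValueError(
                f"dominant lobe does not reach half maximum on the {side} "
                "side before the adjacent minimum"
            )
        i = j


def fwhm(profile: BeamProfile) -> float:
    """FWHM of the dominant lobe, by linear interpolation of the two
    half-maximum crossings that bracket the global maximum.

    For multi-lobed (Airy) profiles this is the width of the first
    maximum only: the search stops at the adjacent inter-lobe minima.
    """
    x = profile.positions
    inten = profile.intensities
    i = int(np.argmax(inten))
    half = inten[i] / 2.0
    rebound = 0.05 * inten[i]
    left = _half_crossing(x, inten, i, half, -1, rebound)
    right = _half_crossing(x, inten, i, half, +1, rebound)
    return right - left


# --------------------------------------------------------------------------
# model fits
# --------------------------------------------------------------------------

def _gauss_model(x, amp, center, width, offset):
    return amp * np.exp(-2.0 * (x - center) ** 2 / width**2) + offset


def _airy_model(x, amp, center, x0, a, offset, orientation=1.0):
    s = orientation * (x - center) / x0
    return amp * np.abs(_airy_all(s)[0]) ** 2 * np.exp(2.0 * a * s) + offset


def _rms_residual(model_vals, data):
    peak = data.max()
    return float(np.sqrt(np.mean((model_vals - data) ** 2)) / peak)


def fit_gaussian_profile(profile: BeamProfile, max_restarts: int = 5,
                         seed: int = 0) -> FitResult:
    """Least-squares Gaussian fit; FWHM = w sqrt(2 ln 2)."""
    x, data = profile.positions, profile.intensities
    if x.size < 8:
        raise ValueError("Gaussian fit needs at least 8 samples")
    span = data.max() - data.min()
    if span <= 0:
        return FitResult("gaussian", {}, math.nan, math.inf, False,
                         "flat profile")
    try:
        w_init = fwhm(profile) / _SQRT_2LN2
    except ValueError:
        w_init = (x[-1] - x[0]) / 4.0
    p0 = [span, x[int(np.argmax(data))], w_init, data.min()]
    lo = [0.0, x[0], 1e-6, -np.inf]
    hi = [np.inf, x[-1], np.inf, np.inf]
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        p_try = list(p0)
        if attempt:
            p_try[1] += rng.normal(0, 0.1 * w_init)
            p_try[2] *= rng.uniform(0.5, 2.0)
        try:
            popt, _ = curve_fit(_gauss_model, x, data, p0=p_try,
                                bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        res = _rms_residual(_gauss_model(x, *popt), data)
        if best is None or res < best[1]:
            best = (popt, res)
        if res < 1e-3:
            break
    if best is None:
        return FitResult("gaussian", {}, math.nan, math.inf, False,
                         "fit did not converge")
    popt, res = best
    params = dict(zip(["amplitude", "center", "width", "offset"], popt))
    return FitResult("gaussian", params, popt[2] * _SQRT_2LN2, res, True)


def _airy_model_fwhm(params: dict, x: np.ndarray) -> float:
    """Main-lobe FWHM of a fitted Airy model, on a dense grid."""
    xx = np.linspace(x[0], x[-1], 50001)
    vals = _airy_model(xx, params["amplitude"], params["center"],
                       params["x0"], params["a"], 0.0,
                       params["orientation"])
    return fwhm(BeamProfile(xx, np.clip(vals, 0, None) + 1e-300))


def fit_airy_profile(profile: BeamProfile, max_restarts: int = 5,
                     seed: int = 0) -> FitResult:
    """Least-squares fit of the focal Airy intensity model.

    Both transverse orientations are tried (the beam tail direction
    depends on the illuminator geometry) and the lower-residual fit kept.
    The reported FWHM is the calibrated main-lobe width of the fitted
    model, not of the raw samples.
    """
    x, data = profile.positions, profile.intensities
    if x.size < 32:
        raise ValueError("Airy fit needs at least 32 samples")
    span = data.max() - data.min()
    if span <= 0:
        return FitResult("airy", {}, math.nan, math.inf, False, "flat profile")
    try:
        raw_width = fwhm(profile)
    except ValueError:
        raw_width = (x[-1] - x[0]) / 8.0
    # main lobe of Ai^2 has FWHM ~= 1.63 x0 and peaks ~1.02 x0 before center
    x0_init = raw_width / 1.63
    x_peak = x[int(np.argmax(data))]
    rng = np.random.default_rng(seed)
    best = None
    for orientation in (1.0, -1.0):
        c_init = x_peak + orientation * 1.019 * x0_init
        p0 = [span / 0.29, c_init, x0_init, 0.05, max(data.min(), 0.0)]
        lo = [0.0, x[0] - (x[-1] - x[0]), 1e-3, 0.0, -np.inf]
        hi = [np.inf, x[-1] + (x[-1] - x[0]), np.inf, 1.0 - 1e-9, np.inf]

        def model(xx, amp, center, x0, a, offset, _o=orientation):
            return _airy_model(xx, amp, center, x0, a, offset, _o)

        for attempt in range(max_restarts + 1):
            p_try = list(p0)
            if attempt:
                p_try[1] += rng.normal(0, 0.2 * x0_init)
                p_try[2] *= rng.uniform(0.7, 1.4)
                p_try[3] = rng.uniform(0.0, 0.2)
            try:
                popt, _ = curve_fit(model, x, data, p0=p_try,
                                    bounds=(lo, hi), maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            res = _rms_residual(model(x, *popt), data)
            if best is None or res < best[2]:
                best = (popt, orientation, res)
            if res < 1e-4:
                break
        if best is not None and best[2] < 1e-4:
            break
    if best is None:
        return FitResult("airy", {}, math.nan, math.inf, False,
                         "fit did not converge")
    popt, orientation, res = best
    params = dict(zip(["amplitude", "center", "x0", "a", "offset"], popt))
    params["orientation"] = orientation
    return FitResult("airy", params, _airy_model_fwhm(params, x), res, True)


# --------------------------------------------------------------------------
# measurement across the field of view
# --------------------------------------------------------------------------

def _measure_one(profile: BeamProfile, fit_kind: str, seed: int):
    if fit_kind == "raw":
        return fwhm(profile), {}, 0.0, True
    if fit_kind == "gaussian":
        fit = fit_gaussian_profile(profile, seed=seed)
    elif fit_kind == "airy":
        fit = fit_airy_profile(profile, seed=seed)
    else:
        raise ValueError(f"unknown fit kind: {fit_kind!r}")
    if not fit.converged:
        return fwhm(profile), fit.params, fit.residual, False
    return fit.fwhm, fit.params, fit.residual, True


def measure_thickness_across_fov(
    image: SheetImage,
    y_positions: Sequence[float],
    fit_kind: str = "airy",
    window: Optional[float] = None,
    n_boot: int = 200,
    seed: int = 0,
    background: str = "lowest-decile",
) -> list:
    """One ThicknessMeasurement per requested propagation position.

    The uncertainty is the half-width of the central 68% interval of the
    FWHM over ``n_boot`` row-resampled profiles (bootstrap over the
    averaging window).  Positions that fail to measure are returned with
    ``converged=False`` and NaN width rather than aborting the scan.
    """
    if window is None:
        window = 50 * image.pixel_pitch_y
    results = []
    rng = np.random.default_rng(seed)
    pitch = image.pixel_pitch
    y_centers = (np.arange(image.pixels.shape[1]) + 0.5) * image.pixel_pitch_y
    for y in y_positions:
        try:
            prof = extract_profile(image, y, window, background)
            width, params, resid, ok = _measure_one(prof, fit_kind, seed)
        except ValueError as exc:
            results.append(ThicknessMeasurement(
                y, math.nan, math.nan, fit_kind, {}, math.inf, False))
            continue
        # bootstrap over rows of the averaging window
        sel = np.abs(y_centers - y) <= window / 2.0
        cols = image.pixels[:, sel]
        boot = []
        for _ in range(n_boot):
            pick = rng.integers(0, cols.shape[1], size=cols.shape[1])
            p = cols[:, pick].mean(axis=1)
            p = np.clip(p - _background(p, background, image.pixels), 0, None)
            if p.max() <= 0:
                continue
            try:
                bp = BeamProfile((np.arange(p.size) + 0.5) * pitch, p)
                boot.append(fwhm(bp))
            except ValueError:
                continue
        if len(boot) >= max(10, n_boot // 4):
            q16, q84 = np.percentile(boot, [16, 84])
            err = float((q84 - q16) / 2.0)
        else:
            err = math.nan
        results.append(ThicknessMeasurement(
            y, width, err, fit_kind, params, resid, ok))
    return results
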
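"""Closed-form Gaussian and Airy light-sheet beam models.

All lengths are in micrometres.  The Gaussian sheet follows the standard
beam-propagation law

    w(z) = w0 * sqrt(1 + (z / zR)^2),      zR = pi * w0^2 / lambda,

where ``w0`` is the 1/e^2 waist radius at focus and ``zR`` the Rayleigh
range.  The finite-energy Airy sheet follows the accelerating-beam
envelope

    Phi(xi, s) = Ai(s - (xi/2)^2 + i*a*xi)
                 * exp(a*s - a*xi^2/2 - i*xi^3/12 + i*a^2*xi/2 + i*s*xi/2)

in the dimensionless transverse coordinate ``s`` and propagation
coordinate ``xi``; ``a`` is the aperture parameter of the finite-energy
beam (a << 1).  The physical mapping used throughout the package is
``s = x / x0`` and ``xi = y * lambda / (2 * pi * n * x0^2)`` with ``x0``
the transverse scale of the beam in a medium of refractive index ``n``.

The design helpers reproduce the standard sizing rules for a light-sheet
mesoscope: a Gaussian sheet whose confocal region (2 zR) spans the field
of view, and an Airy sheet whose theoretical field of view is

    FOV = 6 * alpha * lambda / (n * (1 - sqrt(1 - (NA/n)^2))).

Both equations are evaluated with the vacuum wavelength, which is the
convention that reproduces the published mesoscope design numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import airy as _airy_all


def _ai(z):
    """Airy function Ai evaluated for real or complex argument."""
    return _airy_all(z)[0]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalMedium:
    """Vacuum wavelength (um) and refractive index shared by all beam math."""

    wavelength: float
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.wavelength) and self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not (np.isfinite(self.refractive_index) and self.refractive_index >= 1):
            raise ValueError(
                f"refractive index must be >= 1, got {self.refractive_index}"
            )


@dataclass(frozen=True)
class GaussianSheetSpec:
    """Gaussian light-sheet: waist radius w0 (um) plus the optical medium.

    ``rayleigh_range`` is derived, zR = pi w0^2 / lambda (vacuum lambda).
    """

    waist_radius: float
    medium: OpticalMedium
    focus_position: float = 0.0  # propagation coordinate of the focus, um

    def __post_init__(self) -> None:
        if not (np.isfinite(self.waist_radius) and self.waist_radius > 0):
            raise ValueError(f"waist radius must be positive, got {self.waist_radius}")

    @classmethod
    def from_fwhm(cls, fwhm: float, medium: OpticalMedium,
                  focus_position: float = 0.0) -> "GaussianSheetSpec":
        """Sheet whose focal *intensity* FWHM (the measured thickness
        convention) equals ``fwhm``: w0 = FWHM / sqrt(2 ln 2)."""
        return cls(fwhm / math.sqrt(2.0 * math.log(2.0)), medium, focus_position)

    @property
    def rayleigh_range(self) -> float:
        return math.pi * self.waist_radius**2 / self.medium.wavelength

    def waist(self, z):
        """Beam waist radius w(z) at distance z from the focus."""
        return gaussian_waist(z, self)

    def thickness(self, z=0.0):
        """Full 1/e^2 thickness 2 w(z) -- the design thickness convention."""
        return 2.0 * gaussian_waist(z, self)

    def fwhm(self, z=0.0):
        """Intensity FWHM of the sheet cross-section at distance z."""
        return gaussian_waist(z, self) * math.sqrt(2.0 * math.log(2.0))

    def intensity(self, dz, y):
        """Relative excitation intensity at transverse offset ``dz`` from the
        sheet plane, at propagation coordinate ``y`` (unit peak at focus).

        The on-axis peak falls as w0/w(y) as the sheet diverges (energy
        conservation of a 1-D focus).
        """
        w = gaussian_waist(np.asarray(y, dtype=float) - self.focus_position, self)
        return (self.waist_radius / w) * np.exp(-2.0 * np.square(dz) / w**2)


@dataclass(frozen=True)
class AirySheetSpec:
    """Finite-energy Airy light-sheet parameterization.

    a                 aperture parameter of the finite-energy beam (0 < a < 1)
    alpha             empirical field-of-view scale factor of the illuminator
    effective_na      effective numerical aperture of the illumination optics
    transverse_scale  x0 (um): maps the dimensionless transverse coordinate
                      to physical distance
    """

    a: float
    alpha: float
    effective_na: float
    transverse_scale: float
    medium: OpticalMedium
    focus_position: float = 0.0  # y of xi = 0, um

    def __post_init__(self) -> None:
        if not (0 < self.a < 1):
            raise ValueError(f"a must be in (0, 1), got {self.a}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0 < self.effective_na < self.medium.refractive_index):
            raise ValueError(
                "effective NA must lie in (0, n); got "
                f"NA={self.effective_na}, n={self.medium.refractive_index}"
            )
        if self.transverse_scale <= 0:
            raise ValueError(
                f"transverse scale must be positive, got {self.transverse_scale}"
            )

    def xi(self, y):
        """Dimensionless propagation distance for physical coordinate y."""
        return (
            (np.asarray(y, dtype=float) - self.focus_position)
            * self.medium.wavelength
            / (2.0 * math.pi * self.medium.refractive_index * self.transverse_scale**2)
        )

    def fov(self) -> float:
        return airy_fov(self.medium, self.effective_na, self.alpha)

    def mainlobe_fwhm(self, y: float = 0.0) -> float:
        """Main-lobe FWHM (um) of the sheet cross-section at position y."""
        x0 = self.transverse_scale
        xi = float(self.xi(y))
        drift = (xi / 2.0) ** 2
        s = np.linspace(drift - 25.0, drift + 10.0, 40001)
        prof = np.abs(airy_envelope(DimensionlessAiryCoords(s, xi), self.a)) ** 2
        return x0 * _mainlobe_fwhm_grid(s, prof)

    def intensity(self, dz, y):
        """Relative excitation intensity at offset ``dz`` from the main-lobe
        position at focus, propagation coordinate ``y`` (unit peak at focus).

        The main lobe sits at dz = 0 for y = focus_position; at other y it
        follows the parabolic trajectory of the envelope.
        """
        s_pk = _mainlobe_peak_s(self.a)
        s = s_pk + np.asarray(dz, dtype=float) / self.transverse_scale
        xi = self.xi(y)
        amp = np.abs(airy_envelope(DimensionlessAiryCoords(s, xi), self.a)) ** 2
        return amp / _mainlobe_peak_value(self.a)


@dataclass(frozen=True)
class DimensionlessAiryCoords:
    """Dimensionless transverse (s) and propagation (xi) coordinates."""

    s: object  # scalar or ndarray
    xi: object


@dataclass(frozen=True)
class BeamProfile:
    """1-D transverse intensity profile: positions (um) vs intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.size == 0:
            raise ValueError("positions must be a non-empty 1-D array")
        if inten.shape != pos.shape:
            raise ValueError("positions and intensities must have the same shape")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        if inten.max() <= 0:
            raise ValueError("profile must have positive maximum intensity")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)


# --------------------------------------------------------------------------
# Gaussian beam operations
# --------------------------------------------------------------------------

def gaussian_waist(z, spec: GaussianSheetSpec):
    """w(z) = w0 sqrt(1 + (z/zR)^2); symmetric in z, >= w0."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    out = spec.waist_radius * np.sqrt(1.0 + (z / spec.rayleigh_range) ** 2)
    return float(out) if out.ndim == 0 else out


def rayleigh_range(w0: float, medium: OpticalMedium) -> float:
    """zR = pi w0^2 / lambda (vacuum wavelength convention)."""
    if not (np.isfinite(w0) and w0 > 0):
        raise ValueError(f"waist radius must be positive, got {w0}")
    return math.pi * w0**2 / medium.wavelength


def design_gaussian_sheet(fov_length: float, medium: OpticalMedium) -> GaussianSheetSpec:
    """Design the thinnest Gaussian sheet whose usable length spans a field.

    The usable length is the confocal region 2 zR (the sheet is no more
    than sqrt(2) times its focal thickness at the edges), so
    w0 = sqrt(fov * lambda / (2 pi)) and 2 zR = fov exactly.  Focal
    thickness is ``spec.thickness(0) = 2 w0`` and the edge thickness
    ``spec.thickness(zR) = sqrt(2) * 2 w0``.
    """
    if not (np.isfinite(fov_length) and fov_length > 0):
        raise ValueError(f"FOV length must be positive, got {fov_length}")
    w0 = math.sqrt(fov_length * medium.wavelength / (2.0 * math.pi))
    return GaussianSheetSpec(w0, medium)


# --------------------------------------------------------------------------
# Airy beam operations
# --------------------------------------------------------------------------

def airy_envelope(coords: DimensionlessAiryCoords, a: float):
    """Finite-energy Airy electric-field envelope Phi(xi, s).

    Phi = Ai(s - (xi/2)^2 + i a xi)
          * exp(a s - a xi^2/2 - i xi^3/12 + i a^2 xi/2 + i s xi/2)
    """
    if a < 0:
        raise ValueError(f"a must be non-negative, got {a}")
    s = np.asarray(coords.s, dtype=float)
    xi = np.asarray(coords.xi, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(xi))):
        raise ValueError("coordinates must be finite")
    arg = s - (xi / 2.0) ** 2 + 1j * a * xi
    phase = (
        a * s
        - a * xi**2 / 2.0
        - 1j * xi**3 / 12.0
        + 1j * a**2 * xi / 2.0
        + 1j * s * xi / 2.0
    )
    out = _ai(arg) * np.exp(phase)
    return complex(out) if out.ndim == 0 else out


def airy_intensity_profile(x_grid, y: float, spec: AirySheetSpec) -> BeamProfile:
    """Transverse intensity profile |Phi|^2 of the Airy sheet at position y.

    ``x_grid`` are physical transverse positions (um); the profile is
    normalized to unit peak.
    """
    x = np.asarray(x_grid, dtype=float)
    if x.size == 0:
        raise ValueError("x_grid must be non-empty")
    s = x / spec.transverse_scale
    xi = float(spec.xi(y))
    amp = np.abs(airy_envelope(DimensionlessAiryCoords(s, xi), spec.a)) ** 2
    return BeamProfile(x, amp / amp.max())


def airy_fov(medium: OpticalMedium, na: float, alpha: float) -> float:
    """Theoretical Airy light-sheet field of view (um).

    FOV = 6 alpha lambda / (n (1 - sqrt(1 - (NA/n)^2)))
    """
    n = medium.refractive_index
    if not (0 < na < n):
        raise ValueError(f"NA must lie in (0, n={n}), got {na}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return 6.0 * alpha * medium.wavelength / (n * (1.0 - math.sqrt(1.0 - (na / n) ** 2)))


def airy_axial_resolution(medium: OpticalMedium, na: float) -> float:
    """Theoretical axial resolution r = lambda / (2 NA 0.88) (um)."""
    if na <= 0:
        raise ValueError(f"NA must be positive, got {na}")
    return medium.wavelength / (2.0 * na * 0.88)


# --------------------------------------------------------------------------
# calibration helpers
# --------------------------------------------------------------------------

def _mainlobe_fwhm_grid(s: np.ndarray, intensity: np.ndarray) -> float:
    """FWHM of the dominant lobe of a sampled profile (linear interpolation)."""
    i = int(np.argmax(intensity))
    half = intensity[i] / 2.0
    j = i
    while j > 0 and intensity[j] > half:
        j -= 1
    if intensity[j] > half:
        raise ValueError("profile does not fall below half maximum on the left")
    left = np.interp(half, [intensity[j], intensity[j + 1]], [s[j], s[j + 1]])
    k = i
    while k < len(intensity) - 1 and intensity[k] > half:
        k += 1
    if intensity[k] > half:
        raise ValueError("profile does not fall below half maximum on the right")
    right = np.interp(half, [intensity[k], intensity[k - 1]], [s[k], s[k - 1]])
    return float(right - left)


@lru_cache(maxsize=64)
def _mainlobe_peak_s(a: float) -> float:
    """Location (dimensionless) of the main-lobe peak of Ai(s)^2 exp(2 a s)."""
    s = np.linspace(-3.0, 1.0, 20001)
    prof = np.abs(_ai(s)) ** 2 * np.exp(2.0 * a * s)
    return float(s[int(np.argmax(prof))])


@lru_cache(maxsize=64)
def _mainlobe_peak_value(a: float) -> float:
    """Peak intensity of Ai(s)^2 exp(2 a s) at the main lobe."""
    s_pk = _mainlobe_peak_s(a)
    return float(np.abs(_ai(s_pk)) ** 2 * np.exp(2.0 * a * s_pk))


def airy_mainlobe_fwhm_dimensionless(a: float) -> float:
    """Main-lobe FWHM of Ai(s)^2 exp(2 a s) in dimensionless s units."""
    s = np.linspace(-8.0, 4.0, 200001)
    prof = np.abs(_ai(s)) ** 2 * np.exp(2.0 * a * s)
    return _mainlobe_fwhm_grid(s, prof)


def calibrate_transverse_scale(
    target_fwhm: float = 7.8,
    a: float = 0.05,
    tol: float = 1e-3,
    x0_bounds: tuple = (0.1, 100.0),
) -> float:
    """Transverse scale x0 (um) such that the main-lobe FWHM at the focus
    equals ``target_fwhm``.

    FWHM is strictly increasing in x0 (pure scaling), so 1-D bisection on
    x0 converges unconditionally; ``tol`` is in um of x0.
    """
    if target_fwhm <= 0:
        raise ValueError("target FWHM must be positive")
    f_s = airy_mainlobe_fwhm_dimensionless(a)  # FWHM_x = x0 * f_s
    lo, hi = x0_bounds
    if not (lo * f_s <= target_fwhm <= hi * f_s):
        raise ValueError("target FWHM outside the bisection bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid * f_s < target_fwhm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# independent propagation oracle
# --------------------------------------------------------------------------

def angular_spectrum_propagate(
    initial_field,
    s_grid: np.ndarray,
    xi: float,
    pad_left: float = 350.0,
    pad_right: float = 80.0,
    refine: int = 6,
) -> np.ndarray:
    """Propagate a 1-D paraxial field by FFT over the angular spectrum.

    Solves i dPhi/dxi + (1/2) d^2Phi/ds^2 = 0: each Fourier mode exp(i k s)
    acquires the phase exp(-i k^2 xi / 2).  ``initial_field`` is a callable
    s -> complex amplitude at xi = 0.  The transform runs on an internally
    refined grid (step/`refine`) extended by ``pad_left``/``pad_right``
    dimensionless units whose nodes contain ``s_grid`` exactly, so the
    returned samples carry no interpolation error and periodic wrap-around
    of the oscillatory tail is pushed far outside the window.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or s_grid.size < 2:
        raise ValueError("s_grid must be a 1-D array with at least 2 points")
    ds = s_grid[1] - s_grid[0]
    if not np.allclose(np.diff(s_grid), ds):
        raise ValueError("s_grid must be uniform")
    dsf = ds / refine
    n_left = int(math.ceil(pad_left / dsf))
    n_right = int(math.ceil(pad_right / dsf))
    n_core = (s_grid.size - 1) * refine
    sf = s_grid[0] + dsf * np.arange(-n_left, n_core + n_right + 1)
    field0 = np.asarray(initial_field(sf), dtype=complex)
    k = 2.0 * math.pi * np.fft.fftfreq(sf.size, d=dsf)
    propagated = np.fft.ifft(np.fft.fft(field0) * np.exp(-0.5j * k**2 * xi))
    return propagated[n_left + refine * np.arange(s_grid.size)]
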
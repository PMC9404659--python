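"""Post-acquisition restoration: outlier removal, maximum projection and
maximum-likelihood (Richardson-Lucy) deconvolution.

The deconvolution uses the classical maximum-likelihood estimate for
Poisson statistics (multiplicative Richardson-Lucy updates) with a
separable Gaussian approximation of the light-sheet system PSF: a
lateral Gaussian set by the emission wavelength and detection NA, and an
axial profile that is the product of the illumination sheet thickness
profile (its 1/e^2 waist is the "sheet waist" deconvolution parameter)
with the detection focal-depth Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Light-sheet PSF parameterization for CMLE deconvolution.

    sheet_waist          1/e^2 waist (um) of the Gaussian approximation of
                         the illumination sheet (12 um for the Airy sheet,
                         25 um for the Gaussian sheet)
    sampling_xyz         voxel size (x, y, z) in um
    """

    sheet_waist: float = 12.0
    excitation_wavelength: float = 0.488
    emission_wavelength: float = 0.520
    sampling_xyz: tuple = (0.2244, 0.2244, 1.5)
    detection_na: float = 0.46
    immersion_index: float = 1.515
    iterations: int = 40
    background: float = 0.0
    detection_axial_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sheet_waist <= 0 or self.excitation_wavelength <= 0 \
                or self.emission_wavelength <= 0:
            raise ValueError("lengths must be positive")
        if len(self.sampling_xyz) != 3 or any(s <= 0 for s in self.sampling_xyz):
            raise ValueError("sampling_xyz must be three positive lengths")
        if self.detection_na <= 0 or self.immersion_index < 1:
            raise ValueError("invalid detection optics")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.detection_axial_sigma is not None and self.detection_axial_sigma <= 0:
            raise ValueError("detection axial sigma must be positive")

    @property
    def lateral_sigma(self) -> float:
        """Gaussian approximation of the detection lateral PSF (um)."""
        return 0.21 * self.emission_wavelength / self.detection_na

    @property
    def axial_sigma(self) -> float:
        """Sigma (um) of the axial PSF profile.

        The illumination sheet intensity exp(-2 z^2 / w^2) is a Gaussian
        of sigma w/2.  Widefield detection redistributes defocused light
        laterally but conserves it, so by default the sheet alone sets
        the axial discrimination; a finite ``detection_axial_sigma``
        multiplies in an explicit detection focal-depth Gaussian.
        """
        s_ill = self.sheet_waist / 2.0
        if self.detection_axial_sigma is None:
            return s_ill
        return 1.0 / math.sqrt(1.0 / s_ill**2
                               + 1.0 / self.detection_axial_sigma**2)


# --------------------------------------------------------------------------
# outlier removal
# --------------------------------------------------------------------------

def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (yy**2 + xx**2) <= radius**2


def remove_outliers(
    image: np.ndarray,
    radius: int = 3,
    threshold: Optional[float] = None,
    polarity: str = "bright",
) -> np.ndarray:
    """Replace pixels deviating from their disc-neighbourhood median.

    A pixel differing from the median of its radius-``radius`` disc by
    more than ``threshold`` (in the bright direction by default) is
    replaced by that median; every other pixel is returned bit-identical.
    The default threshold is 5x the robust sigma (1.4826 MAD) of the
    image.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("remove_outliers expects a 2-D image")
    work = img.astype(float)
    if threshold is None:
        mad = np.median(np.abs(work - np.median(work)))
        threshold = 5.0 * 1.4826 * mad
        if threshold <= 0:
            return img.copy()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    med = ndimage.median_filter(work, footprint=_disc_footprint(radius),
                                mode="reflect")
    diff = work - med
    if polarity == "bright":
        mask = diff > threshold
    elif polarity == "dark":
        mask = diff < -threshold
    elif polarity == "both":
        mask = np.abs(diff) > threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    out = img.copy()
    out[mask] = med[mask].astype(img.dtype) if np.issubdtype(img.dtype, np.integer) \
        else med[mask]
    return out


# --------------------------------------------------------------------------
# maximum projection
# --------------------------------------------------------------------------

def max_projection(stack) -> np.ndarray:
    """Per-pixel maximum over the planes of a stack."""
    planes = stack.planes if hasattr(stack, "planes") else np.asarray(stack)
    planes = np.asarray(planes)
    if planes.ndim != 3 or planes.shape[0] == 0:
        raise ValueError("stack must be a non-empty 3-D array")
    return planes.max(axis=0)


# --------------------------------------------------------------------------
# PSF model
# --------------------------------------------------------------------------

def lightsheet_psf(config: DeconvolutionConfig,
                   shape: Optional[tuple] = None) -> np.ndarray:
    """Separable 3-D PSF (z, y, x), normalized to unit sum.

    By default the support extends to 4 sigma per axis (at least one
    sample each side); a requested ``shape`` must span at least 3 sigma
    per axis or it cannot represent the kernel.
    """
    dx, dy, dz = config.sampling_xyz
    sigmas = (config.axial_sigma, config.lateral_sigma, config.lateral_sigma)
    steps = (dz, dy, dx)
    if shape is None:
        shape = tuple(2 * max(1, int(math.ceil(4.0 * s / d))) + 1
                      for s, d in zip(sigmas, steps))
    if len(shape) != 3 or any(n < 3 or n % 2 == 0 for n in shape):
        raise ValueError("PSF shape must be three odd sizes >= 3")
    for n, s, d in zip(shape, sigmas, steps):
        if (n - 1) * d < 3.0 * s:
            raise ValueError(
                f"PSF support {(n - 1) * d:.3g} um is below 3 sigma "
                f"({3 * s:.3g} um); enlarge the grid"
            )
    axes = []
    for n, s, d in zip(shape, sigmas, steps):
        u = (np.arange(n) - n // 2) * d
        axes.append(np.exp(-u**2 / (2.0 * s**2)))
    psf = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return psf / psf.sum()


# --------------------------------------------------------------------------
# CMLE / Richardson-Lucy deconvolution
# --------------------------------------------------------------------------

def cmle_deconvolve(
    stack,
    psf: np.ndarray,
    iterations: int = 40,
    background: float = 0.0,
    eps: float = 1e-12,
    chunk_planes: Optional[int] = None,
) -> np.ndarray:
    """Richardson-Lucy (classical MLE for Poisson noise) deconvolution.

    Multiplicative updates on the background-subtracted data d:

        e_{k+1} = e_k * [ (d / (e_k (*) psf)) (*) psf_flipped ]

    starting from e_0 = d.  Convolution uses reflective padding by one
    PSF half-support so flux is conserved at the boundaries; divisions
    are guarded by ``eps``.  ``chunk_planes`` processes the stack in
    z sub-volumes overlapping by the PSF axial half-support (for stacks
    too large to transform at once); the returned array is float64.
    """
    data = np.asarray(stack.planes if hasattr(stack, "planes") else stack,
                      dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D stack")
    psf = np.asarray(psf, dtype=float)
    if psf.ndim != 3:
        raise ValueError("expected a 3-D PSF")
    if not math.isclose(psf.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("PSF must be normalized to unit sum")
    if background < 0:
        raise ValueError("background must be non-negative")
    data = np.clip(data - background, 0.0, None)
    if data.max() <= 0:
        raise ValueError("data is all zero after background subtraction")

    if chunk_planes is not None:
        return _deconvolve_chunked(data, psf, iterations, eps, chunk_planes)
    return _rl_core(data, psf, iterations, eps)


def _rl_core(data: np.ndarray, psf: np.ndarray, iterations: int,
             eps: float) -> np.ndarray:
    # reflect-pad by one PSF half-support, then convolve circularly: a
    # circular convolution with a unit-sum kernel maps constants to
    # themselves and conserves total flux exactly, and the padding keeps
    # the periodic wrap-around off the cropped region
    pad = tuple(min(s // 2, max(d - 1, 0)) for s, d in zip(psf.shape, data.shape))
    d_pad = np.pad(data, [(p, p) for p in pad], mode="reflect")
    shape = d_pad.shape
    # a PSF wider than the transform volume is cropped centrally and
    # renormalized: the tails it loses could never be observed anyway
    crop_psf = tuple(slice(max(0, (s - n) // 2), max(0, (s - n) // 2) + min(s, n))
                     for s, n in zip(psf.shape, shape))
    psf = psf[crop_psf]
    psf = psf / psf.sum()
    kernel = np.zeros(shape)
    sl = tuple(slice(n // 2 - s // 2, n // 2 - s // 2 + s)
               for n, s in zip(shape, psf.shape))
    kernel[sl] = psf
    otf = np.fft.rfftn(np.fft.ifftshift(kernel))
    est = d_pad.copy()
    for _ in range(iterations):
        conv = np.fft.irfftn(np.fft.rfftn(est) * otf, s=shape, axes=(0, 1, 2))
        ratio = d_pad / np.maximum(conv, eps)
        est = est * np.fft.irfftn(np.fft.rfftn(ratio) * np.conj(otf), s=shape, axes=(0, 1, 2))
        np.clip(est, 0.0, None, out=est)
    crop = tuple(slice(p, n - p if p else None) for p, n in zip(pad, shape))
    return est[crop]


def _deconvolve_chunked(data, psf, iterations, eps, chunk_planes):
    overlap = psf.shape[0]
    n = data.shape[0]
    out = np.empty_like(data)
    start = 0
    while start < n:
        stop = min(n, start + chunk_planes)
        lo = max(0, start - overlap)
        hi = min(n, stop + overlap)
        sub = _rl_core(data[lo:hi], psf, iterations, eps)
        out[start:stop] = sub[start - lo:stop - lo]
        start = stop
    return out
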
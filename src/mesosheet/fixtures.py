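"""Deterministic synthetic fixtures.

Every fixture is generated from a seed and a parameter dict, so the full
toolchain (measurement, simulation, restoration, CLI) is exercisable
end-to-end without any downloaded data.  The sheet cross-section images
stand in for reflected-beam photographs of the illumination sheet; the
phantom stacks stand in for nuclei-stained cleared-tissue volumes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .beam_models import AirySheetSpec, GaussianSheetSpec, OpticalMedium
from .mesoscope_sim import CameraModel, generate_phantom, simulate_stack
from .sheet_measurement import SheetImage
from . import io as msio

SheetSpec = Union[GaussianSheetSpec, AirySheetSpec]


def render_sheet_image(
    sheet: SheetSpec,
    x_extent: float = 160.0,
    y_extent: float = 3000.0,
    pitch: float = 0.224,
    pitch_y: float = 3.0,
    peak_counts: float = 3000.0,
    offset: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SheetImage:
    """Synthetic sheet cross-section image I(x, y).

    Axis 0 is x (transverse to the sheet), axis 1 is y (propagation).
    The sheet's transverse center sits mid-image; intensity follows the
    beam model, scaled to ``peak_counts`` at the focus, on a constant
    ``offset`` with optional Gaussian noise.  The default x-extent keeps
    the parabolic trajectory of an Airy main lobe (tens of um across a
    3 mm field) inside the frame; y is sampled coarsely since the sheet
    varies slowly along the propagation axis.
    """
    nx = int(round(x_extent / pitch))
    ny = int(round(y_extent / pitch_y))
    x = (np.arange(nx) + 0.5) * pitch - x_extent / 2.0
    y = (np.arange(ny) + 0.5) * pitch_y
    inten = sheet.intensity(x[:, None], y[None, :])
    img = offset + peak_counts * inten
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return SheetImage(np.clip(img, 0.0, None), pitch, pitch_y)


def noisy_profile(
    sheet: SheetSpec,
    y: float = 0.0,
    x_extent: float = 60.0,
    n_samples: int = 512,
    snr: Optional[float] = 20.0,
    seed: int = 0,
):
    """1-D transverse profile with additive Gaussian noise at a given
    peak SNR (``snr=None`` for noiseless)."""
    x = np.linspace(-x_extent / 2.0, x_extent / 2.0, n_samples)
    inten = np.asarray(sheet.intensity(x, float(y)), dtype=float)
    inten = inten / inten.max()
    if snr is not None:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0.0, 1.0 / snr, size=inten.shape)
    return x, inten


def default_airy_sheet(medium: Optional[OpticalMedium] = None,
                       a: float = 0.05,
                       transverse_scale: float = 4.672) -> AirySheetSpec:
    """The published Airy illuminator configuration (488 nm, n 1.515,
    NA 0.043, alpha 0.7) with x0 calibrated for a 7.8 um main lobe."""
    medium = medium or OpticalMedium(0.488, 1.515)
    return AirySheetSpec(a=a, alpha=0.7, effective_na=0.043,
                         transverse_scale=transverse_scale, medium=medium)


def make_fixture(kind: str, seed: int, params: Optional[dict] = None,
                 out_dir=".") -> list:
    """Write a deterministic fixture to disk; returns the paths written.

    kinds: ``sheet_image`` (TIFF cross-section of a sheet),
    ``phantom_stack`` (simulated nuclei stack + sidecar),
    ``profile`` (noisy 1-D transverse profile as CSV).
    """
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    medium = OpticalMedium(params.pop("wavelength_um", 0.488),
                           params.pop("refractive_index", 1.515))

    if kind == "sheet_image":
        shape = params.pop("sheet", "airy")
        if shape == "airy":
            sheet = default_airy_sheet(medium, a=params.pop("a", 0.05),
                                       transverse_scale=params.pop("x0", 4.672))
        else:
            fov = params.pop("fov_um", 3000.0)
            from .beam_models import design_gaussian_sheet
            sheet = design_gaussian_sheet(fov, medium)
            sheet = GaussianSheetSpec(sheet.waist_radius, medium,
                                      focus_position=fov / 2.0)
        img = render_sheet_image(sheet, seed=seed, **params)
        path = out_dir / f"sheet_{shape}_{seed}.tif"
        msio.write_stack(img.pixels[None].astype(np.float32), path)
        return [path, path.with_suffix(".tif.json")]

    if kind == "phantom_stack":
        extent = params.pop("extent", (60.0, 60.0, 60.0))
        phantom = generate_phantom(
            seed, params.pop("n_nuclei", 20), extent,
            n_occluders=params.pop("n_occluders", 0))
        sheet = default_airy_sheet(medium)
        camera = CameraModel(pixel_pitch=params.pop("pitch_um", 0.672),
                             sensor_positions=1,
                             hot_pixel_rate=params.pop("hot_pixel_rate", 0.0))
        z_range = params.pop("z_range", (20.0, 40.0))
        stack = simulate_stack(phantom, sheet, camera, z_range,
                               params.pop("z_step_um", 1.5), seed=seed,
                               **params)
        path = out_dir / f"phantom_stack_{seed}.tif"
        msio.write_stack(stack, path)
        return [path, path.with_suffix(".tif.json")]

    if kind == "profile":
        shape = params.pop("sheet", "airy")
        if shape == "airy":
            sheet = default_airy_sheet(medium, a=params.pop("a", 0.05),
                                       transverse_scale=params.pop("x0", 4.672))
        else:
            sheet = GaussianSheetSpec.from_fwhm(params.pop("fwhm_um", 30.0),
                                                medium)
        x, inten = noisy_profile(sheet, seed=seed, **params)
        path = out_dir / f"profile_{shape}_{seed}.csv"
        pd.DataFrame({"x_um": x, "intensity": inten}).to_csv(path, index=False)
        return [path]

    raise ValueError(f"unknown fixture kind {kind!r}")
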
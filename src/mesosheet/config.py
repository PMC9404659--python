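"""Flat key-value run configuration.

One YAML file of namespaced keys (``optics.*``, ``camera.*``, ``sim.*``,
``restore.*``); CLI flags override file values, and every run can log
the fully resolved mapping.  The defaults reproduce the published Airy
mesoscope configuration (488 nm, n = 1.515, NA = 0.043, alpha = 0.7,
224 nm pitch, 25 s frame transfer).  All lengths are micrometres
internally; the CLI accepts unit-suffixed values (``488nm``, ``3mm``)
and converts at the boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

DEFAULTS = {
    "optics.wavelength_um": 0.488,
    "optics.refractive_index": 1.515,
    "optics.effective_na": 0.043,
    "optics.alpha": 0.7,
    "optics.a": 0.05,
    "optics.transverse_scale_um": 4.672,   # calibrated to a 7.8 um main lobe
    "optics.fov_um": 3000.0,
    "camera.pixel_pitch_um": 0.224,
    "camera.sensor_positions": 9,
    "camera.exposure_per_position_s": 0.1,
    "camera.transfer_time_s": 25.0,
    "camera.read_noise_sd": 2.0,
    "camera.hot_pixel_rate": 0.0,
    "camera.bit_depth": 12,
    "camera.gain": 1.0,
    "camera.offset": 100.0,
    "sim.detection_sigma_z_um": 3.0,
    "sim.direction": "+y",
    "sim.seed": 0,
    "restore.outlier_radius": 3,
    "restore.outlier_threshold_sigma": 5.0,
    "restore.iterations": 40,
    "restore.background": 0.0,
    "measure.window_um": 11.2,             # 50 rows at Nyquist pitch
    "measure.n_boot": 200,
    "measure.background": "lowest-decile",
}

_UNITS_UM = {"nm": 1e-3, "um": 1.0, "µm": 1.0, "mm": 1e3, "m": 1e6}


def parse_length(text) -> float:
    """Parse a possibly unit-suffixed length into micrometres."""
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*(nm|um|µm|mm|m)?\s*", str(text))
    if not m:
        raise ValueError(f"cannot parse length {text!r}")
    value = float(m.group(1))
    return value * _UNITS_UM[m.group(2) or "um"]


def load_config(path) -> dict:
    """Load a flat YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat mapping")
    return resolve_config(raw)


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults updated with overrides; unknown keys are rejected."""
    cfg = dict(DEFAULTS)
    for key, value in (overrides or {}).items():
        if key not in DEFAULTS:
            raise KeyError(f"unknown configuration key {key!r}")
        cfg[key] = value
    return cfg
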
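"""TIFF stack input/output with a plain-text metadata sidecar.

Stacks are written as multi-page TIFF (12-bit camera data travels in
16-bit containers; deconvolved data as 32-bit float) with the z
positions and acquisition metadata in a JSON sidecar next to the image
file, so a write/read round trip is lossless and byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .mesoscope_sim import ImageStack


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack, path) -> Path:
    """Write an ImageStack (or bare 3-D array) as a multi-page TIFF."""
    path = Path(path)
    if isinstance(stack, np.ndarray):
        stack = ImageStack(stack, np.arange(stack.shape[0], dtype=float))
    planes = stack.planes
    if planes.dtype == np.float64:
        planes = planes.astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    sidecar = {
        "z_positions": [float(z) for z in stack.z_positions],
        "metadata": _jsonable(stack.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    A truncated or unreadable page raises a ValueError naming the page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    planes = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            try:
                planes.append(page.asarray())
            except Exception as exc:  # corrupt page: report its index
                raise ValueError(f"cannot read TIFF page {i} of {path}: {exc}")
    if not planes:
        raise ValueError(f"no image pages in {path}")
    arr = np.stack(planes)
    if arr.ndim == 2:
        arr = arr[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        z = np.asarray(meta["z_positions"], dtype=float)
        metadata = meta.get("metadata", {})
    else:
        z = np.arange(arr.shape[0], dtype=float)
        metadata = {}
    return ImageStack(arr, z, metadata)
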
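"""Readers and writers for image grids.

Two formats cover all pipeline stages:

* **raw grid** — little-endian float64 binary plus a JSON sidecar carrying
  shape, spacing and HU window.  Round-trips bit-exactly and is the format
  the dataset builder uses.
* **16-bit PNG** — the HU window mapped linearly onto [0, 65535]; lossy at
  window/65535 HU quantization, intended for inspection and interchange.

A minimal DICOM reader (pixel data + rescale slope/intercept only) is
provided for applying a trained model to clinical slices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import ImageGrid

__all__ = [
    "write_raw",
    "read_raw",
    "write_png16",
    "read_png16",
    "read_dicom",
]


def write_raw(grid: ImageGrid, path: str | Path) -> None:
    """Write ``<path>`` (float64 LE binary) and ``<path>.json`` sidecar."""
    path = Path(path)
    path.write_bytes(np.ascontiguousarray(grid.values, dtype="<f8").tobytes())
    sidecar = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing_mm),
        "hu_window": list(grid.hu_window),
        "dtype": "<f8",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raw(path: str | Path) -> ImageGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.frombuffer(path.read_bytes(), dtype=meta["dtype"]).reshape(meta["shape"])
    return ImageGrid(
        values.copy(),
        spacing_mm=tuple(meta["spacing_mm"]),
        hu_window=tuple(meta["hu_window"]),
    )


def write_png16(grid: ImageGrid, path: str | Path) -> None:
    """Write a 16-bit grayscale PNG with the HU window mapped to [0, 65535]."""
    lo, hi = grid.hu_window
    scaled = np.clip((grid.values - lo) / (hi - lo), 0.0, 1.0)
    arr = np.round(scaled * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(Path(path))
    meta = {"spacing_mm": list(grid.spacing_mm), "hu_window": list(grid.hu_window)}
    Path(path).with_suffix(".png.json").write_text(json.dumps(meta))


def read_png16(path: str | Path) -> ImageGrid:
    """Invert :func:`write_png16` (exact up to the 16-bit quantization)."""
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=np.float64)
    side = path.with_suffix(".png.json")
    if side.exists():
        meta = json.loads(side.read_text())
        lo, hi = meta["hu_window"]
        spacing = tuple(meta["spacing_mm"])
    else:
        lo, hi = -1000.0, 3000.0
        spacing = (1.0, 1.0)
    values = lo + arr / 65535.0 * (hi - lo)
    return ImageGrid(values, spacing_mm=spacing, hu_window=(lo, hi))


def read_dicom(path: str | Path) -> ImageGrid:
    """Read pixel data from a DICOM slice, applying rescale slope/intercept.

    Only the pixel array and the HU rescale are interpreted; no orientation
    or multi-frame handling.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    lo = min(-1000.0, float(values.min()))
    hi = max(3000.0, float(values.max()))
    return ImageGrid(values, spacing_mm=(float(spacing[0]), float(spacing[1])), hu_window=(lo, hi))
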
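"""Image and sidecar I/O: 8-bit TIFF/PNG images, JSON truth sidecars, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .vascularity import ChoroidBoundaries


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a single-channel 8-bit image as TIFF or PNG (by extension)."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image extension: {path.suffix}")


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file missing: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sidecar file missing: {path}")
    return json.loads(path.read_text())


def boundaries_from_sidecar(sidecar: dict) -> ChoroidBoundaries:
    """Boundary curves from a truth/segmentation sidecar dictionary."""
    return ChoroidBoundaries(
        upper_px=np.asarray(sidecar["upper_boundary_px"], dtype=int),
        lower_px=np.asarray(sidecar["lower_boundary_px"], dtype=int),
    )


def boundaries_from_csv(path: str | Path) -> ChoroidBoundaries:
    """Boundary curves from a ``column,upper_px,lower_px`` CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"column", "upper_px", "lower_px"}
    if not need.issubset(df.columns):
        raise ValueError(f"boundary CSV missing columns: {sorted(need - set(df.columns))}")
    df = df.sort_values("column")
    return ChoroidBoundaries(
        upper_px=df["upper_px"].to_numpy(dtype=int),
        lower_px=df["lower_px"].to_numpy(dtype=int),
    )
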
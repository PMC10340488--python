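"""Image and configuration I/O helpers."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.segmentation import find_boundaries

from .handcrafted import SegConfig, validate_rgb


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG); alpha is dropped, gray promoted."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return validate_rgb(arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero pixel is foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, validate_rgb(image))


def overlay_contour(
    image: np.ndarray, mask: np.ndarray, color: tuple[int, int, int] = (0, 255, 255)
) -> np.ndarray:
    """Draw the mask boundary on the image (cyan by default)."""
    out = validate_rgb(image).copy()
    edge = find_boundaries(np.asarray(mask, dtype=bool), mode="outer")
    out[edge] = color
    return out


def write_overlay(path: str | Path, image: np.ndarray, mask: np.ndarray) -> None:
    iio.imwrite(path, overlay_contour(image, mask))


def save_seg_config(path: str | Path, config: SegConfig) -> None:
    data = asdict(config)
    data["grayscale_weights"] = list(config.grayscale_weights)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_seg_config(path: str | Path) -> SegConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "grayscale_weights" in data:
        data["grayscale_weights"] = tuple(data["grayscale_weights"])
    return SegConfig(**data)
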
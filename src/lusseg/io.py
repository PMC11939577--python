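"""Reading and writing images and configuration files.

Images travel through the package as 2-D float arrays in [0,1] (row 0 is the
shallowest depth); masks as {0,1} arrays.  On disk, images are 8-bit
grayscale PNG/JPEG and masks are 0/255 PNG.  Color inputs are converted by
luminance.  YAML configs map block-per-module onto the config dataclasses.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml
from PIL import Image

__all__ = ["read_gray", "write_gray_png", "read_mask", "write_mask_png",
           "load_yaml_config"]


def read_gray(path: str | Path) -> np.ndarray:
    """Load an image as grayscale [0,1] (luminance conversion for color)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def write_gray_png(path: str | Path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(
        path, format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 PNG mask as a {0,1} array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0.5).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a YAML mapping")
    return data
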
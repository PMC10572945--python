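"""File I/O: 8-bit grayscale images, feature tables, JSON reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

log = logging.getLogger("sonomass")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF grayscale image as uint8.

    16-bit inputs are rescaled to 8 bits with a logged warning; color
    images are rejected.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit input rescaled to 8-bit", path)
        return (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    raise ValueError(f"{path}: unsupported bit depth {arr.dtype}")


def write_image(path, img: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG/TIFF (round-trips bit-exactly)."""
    img = np.asarray(img)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    if img.dtype != np.uint8:
        raise ValueError("write_image expects uint8 (or boolean mask) data")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img)


def write_features(path, vectors: np.ndarray, names: list[str],
                   labels=None, filenames=None) -> pd.DataFrame:
    """Write a features CSV: one row per image, named feature columns."""
    df = pd.DataFrame(np.atleast_2d(vectors), columns=names)
    if labels is not None:
        df.insert(0, "label", list(labels))
    if filenames is not None:
        df.insert(0, "filename", list(filenames))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
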
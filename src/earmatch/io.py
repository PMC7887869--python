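"""Manifest / ROI sidecar CSV dialects and image loading.

Manifest columns: ``image_path, subject_id, gender, side, capture_index``.
ROI sidecar columns: ``image_path, x0, y0, x1, y1`` (0-based, half-open).
These are the formats both the real-data path and the synthetic generator
speak.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import CropROI

MANIFEST_COLUMNS = ["image_path", "subject_id", "gender", "side", "capture_index"]
ROI_COLUMNS = ["image_path", "x0", "y0", "x1", "y1"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "gender": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    df["gender"] = df["gender"].fillna("")
    df["capture_index"] = df["capture_index"].astype(int)
    return df[MANIFEST_COLUMNS]


def read_rois(path) -> Dict[str, CropROI]:
    df = pd.read_csv(path, comment="#")
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI sidecar {path} lacks columns: {sorted(missing)}")
    return {
        row.image_path: CropROI(int(row.x0), int(row.y0), int(row.x1), int(row.y1))
        for row in df.itertuples()
    }


def rois_from_frame(df: Optional[pd.DataFrame]) -> Dict[str, CropROI]:
    if df is None:
        return {}
    return {
        row.image_path: CropROI(int(row.x0), int(row.y0), int(row.x1), int(row.y1))
        for row in df.itertuples()
    }


def load_image_pixels(path, root: Optional[Path] = None) -> np.ndarray:
    """Read a PNG/JPEG as an array: HxW (grayscale) or HxWx3 (color)."""
    p = Path(path)
    if root is not None and not p.is_absolute():
        p = Path(root) / p
    img = Image.open(p)
    if img.mode in ("L", "I;16"):
        return np.asarray(img.convert("L"), dtype=np.uint8)
    return np.asarray(img.convert("RGB"), dtype=np.uint8)


class ImageSource:
    """Resolves manifest paths to pixel arrays.

    Either an in-memory mapping (synthetic cohorts) or a directory root of
    PNG/JPEG files.
    """

    def __init__(
        self,
        images: Optional[Mapping[str, np.ndarray]] = None,
        root: Optional[Path] = None,
    ) -> None:
        self._images = images
        self._root = Path(root) if root is not None else None

    def pixels(self, image_path: str) -> np.ndarray:
        if self._images is not None and image_path in self._images:
            return self._images[image_path]
        return load_image_pixels(image_path, self._root)


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
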
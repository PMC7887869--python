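"""Deterministic image conditioning for ear photographs.

The conditioning order is fixed: grayscale conversion, manual crop to the
ear region, resize to a set ear width, histogram equalization.  Each stage
after grayscale can be switched off independently for ablation studies, but
the relative order of the enabled stages never changes — applying histogram
equalization to an uncropped frame, for example, is a legal (and measurably
worse) configuration, not a reordering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from PIL import Image

from .errors import ConfigError, InvalidImageError, InvalidROIError

__all__ = [
    "EarImage",
    "CropROI",
    "PipelineConfig",
    "to_grayscale",
    "crop",
    "resize_to_width",
    "equalize_histogram",
    "preprocess",
]

#: ITU-R BT.601 luma weights used for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EarImage:
    """A single-channel 8-bit ear photograph plus its capture metadata.

    ``pixels`` is a ``(height, width)`` uint8 array.  ``gender`` uses exact
    string labels (``"F"``/``"M"`` by convention); an empty string means
    unknown and disables gender filtering for this image.  ``side`` is one of
    ``"left"``, ``"right"`` or ``"unspecified"``.  ``capture_index``
    distinguishes repeat shots of the same ear.
    """

    pixels: np.ndarray
    subject_id: str = ""
    gender: str = ""
    side: str = "unspecified"
    capture_index: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidImageError(
                f"EarImage requires a non-empty 2-D pixel grid, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidImageError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray) -> "EarImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class CropROI:
    """Manual ear crop rectangle, 0-based, half-open: [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise InvalidROIError(f"zero- or negative-area ROI {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise InvalidROIError(f"negative ROI origin {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def validate_against(self, width: int, height: int) -> None:
        if self.x1 > width or self.y1 > height:
            raise InvalidROIError(
                f"ROI {self} exceeds image bounds {width}x{height}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Switchboard for the identification pipeline.

    The five technique flags correspond to the ablation axes of the system:
    manual cropping, resizing to a fixed ear width, histogram equalization,
    keypoint concatenation across captures, and the gender pre-filter on the
    gallery.  ``top_k`` bounds the ranked candidate list.
    """

    use_crop: bool = True
    use_resize: bool = True
    target_width: int = 150
    use_hist_eq: bool = True
    use_concatenation: bool = True
    use_gender_filter: bool = True
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_width < 8:
            raise ConfigError(f"target_width must be >= 8, got {self.target_width}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")

    def preprocessing_fingerprint(self, backend_id: str = "") -> str:
        """Stable hash of the preprocessing regime plus descriptor backend.

        Two galleries (or cache entries) are comparable only if their
        fingerprints agree; concatenation/filter/top-k flags do not alter
        descriptors and are deliberately excluded.
        """
        payload = json.dumps(
            {
                "use_crop": self.use_crop,
                "use_resize": self.use_resize,
                "target_width": self.target_width,
                "use_hist_eq": self.use_hist_eq,
                "backend": backend_id,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def describe(self) -> str:
        """Short human-readable strategy label, e.g. ``crop+resize150+he``."""
        parts = []
        if self.use_crop:
            parts.append("crop")
        if self.use_resize:
            parts.append(f"resize{self.target_width}")
        if self.use_hist_eq:
            parts.append("he")
        if self.use_concatenation:
            parts.append("concat")
        if self.use_gender_filter:
            parts.append("gender")
        return "+".join(parts) if parts else "none"


def to_grayscale(image, **metadata) -> EarImage:
    """Convert a color or grayscale pixel grid to an 8-bit ``EarImage``.

    Color input is reduced by the BT.601 luma combination
    0.299 R + 0.587 G + 0.114 B, rounded half up.  Grayscale input passes
    through unchanged.  An ``EarImage`` argument is returned as-is (its
    metadata wins over ``metadata`` kwargs).
    """
    if isinstance(image, EarImage):
        return image
    px = np.asarray(image)
    if px.size == 0:
        raise InvalidImageError("empty image")
    if px.ndim == 2:
        return EarImage(px, **metadata)
    if px.ndim == 3 and px.shape[2] == 3:
        luma = px.astype(np.float64) @ _LUMA
        gray = np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)
        return EarImage(gray, **metadata)
    raise InvalidImageError(
        f"unsupported channel layout: shape {px.shape} (need HxW or HxWx3)"
    )


def crop(image: EarImage, roi: CropROI) -> EarImage:
    """Extract the ROI rectangle verbatim; no clamping of out-of-bounds ROIs."""
    roi.validate_against(image.width, image.height)
    return image.with_pixels(image.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1].copy())


def resize_to_width(image: EarImage, target_width: int) -> EarImage:
    """Resize to a set ear width, height scaled to keep proportions.

    Output height is ``round(height * target_width / width)`` (half up, at
    least 1).  Shrinking uses area (box) averaging — the resampling itself
    acts as the noise-suppressing blur that makes small-width matching
    robust — while enlarging uses bilinear interpolation.  An image already
    at the target width is returned unchanged.
    """
    if target_width < 1:
        raise ConfigError(f"target_width must be >= 1, got {target_width}")
    if image.width == target_width:
        return image
    new_height = max(1, int(np.floor(image.height * target_width / image.width + 0.5)))
    resample = Image.Resampling.BOX if target_width < image.width else Image.Resampling.BILINEAR
    pil = Image.fromarray(image.pixels, mode="L")
    out = pil.resize((target_width, new_height), resample=resample)
    return image.with_pixels(np.asarray(out, dtype=np.uint8))


def equalize_histogram(image: EarImage) -> EarImage:
    """Standard 256-bin histogram equalization.

    Every intensity v is remapped to
    ``round((cdf(v) - cdf_min) / (N - cdf_min) * 255)`` where ``N`` is the
    pixel count and ``cdf_min`` the smallest nonzero cumulative count.  The
    mapping is monotone non-decreasing.  A constant image is the degenerate
    0/0 case of the formula and is returned unchanged.
    """
    px = image.pixels
    hist = np.bincount(px.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = px.size
    cdf_min = int(cdf[np.nonzero(hist)[0][0]])
    if cdf_min == n:  # single intensity level: identity
        return image.with_pixels(px.copy())
    lut = np.floor((cdf - cdf_min) / (n - cdf_min) * 255.0 + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return image.with_pixels(lut[px])


def preprocess(
    image,
    config: PipelineConfig,
    roi: Optional[CropROI] = None,
    **metadata,
) -> EarImage:
    """Run the enabled conditioning stages in their fixed order.

    Order is grayscale -> crop -> resize -> histogram equalization; disabled
    stages are skipped without reordering.  ``roi`` is required when
    ``config.use_crop`` is set.
    """
    out = to_grayscale(image, **metadata)
    if config.use_crop:
        if roi is None:
            raise ConfigError("use_crop is set but no ROI was provided")
        out = crop(out, roi)
    if config.use_resize:
        out = resize_to_width(out, config.target_width)
    if config.use_hist_eq:
        out = equalize_histogram(out)
    return out
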
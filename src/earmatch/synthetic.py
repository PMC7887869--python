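"""Seeded synthetic ear cohorts with ground-truth identity.

Each subject gets a unique high-contrast "ear": curved sinusoidal ridges on
an elliptical support, mimicking the helix/antihelix edge structure that
keypoint detectors latch onto.  Each capture of a subject re-renders that
pattern under the nuisance factors of a handheld, device-stabilized capture
session: small rotation jitter, illumination decay (dimming battery),
sensor noise, and — outside the ground-truth ear ROI — capture-specific
background clutter standing in for hair and neckline.  Identity is texture,
not anatomy: the generator exercises the pipeline's contracts, it does not
claim anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigError
from .evaluation import EvaluationResult, evaluate
from .io import ImageSource, MANIFEST_COLUMNS, ROI_COLUMNS
from .preprocess import PipelineConfig

__all__ = ["SyntheticCohortSpec", "generate_cohort", "expected_separability_check"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    ``image_size`` is (width, height) of the raw frame before cropping; the
    ear ROI occupies the central 0.6 x 0.4 of the frame, so a manual crop
    removes roughly three quarters of the pixels.  ``rotation_jitter`` is
    the uniform +/- range in degrees; ``second_angle_offset`` (degrees)
    additionally rotates every odd capture, emulating a rotating-shroud
    second angle.  ``illumination_range`` is the multiplicative brightness
    span of a dimming battery; ``noise_sigma`` is additive Gaussian sensor
    noise in 8-bit intensity units.
    """

    n_subjects: int = 30
    images_per_subject: int = 4
    image_size: Tuple[int, int] = (600, 1200)
    rotation_jitter: float = 3.0
    second_angle_offset: float = 0.0
    illumination_range: Tuple[float, float] = (0.6, 1.0)
    noise_sigma: float = 3.0
    background_clutter: bool = True
    gender_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.images_per_subject < 1:
            raise ConfigError("n_subjects and images_per_subject must be >= 1")
        lo, hi = self.illumination_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("illumination_range must satisfy 0 < lo <= hi <= 1")
        w, h = self.image_size
        if w < 32 or h < 32:
            raise ConfigError("image_size must be at least 32x32")
        if not 0.0 <= self.gender_ratio <= 1.0:
            raise ConfigError("gender_ratio must lie in [0, 1]")

    def roi_bounds(self) -> Tuple[int, int, int, int]:
        """Ground-truth ear ROI (x0, y0, x1, y1), central 0.6w x 0.4h."""
        w, h = self.image_size
        return (int(0.2 * w), int(0.3 * h), int(0.8 * w), int(0.7 * h))


def _ear_texture(roi_w: int, roi_h: int, rng: np.random.Generator) -> np.ndarray:
    """Subject-unique ridge pattern in [0, 1] on an elliptical support."""
    yy, xx = np.mgrid[0:roi_h, 0:roi_w]
    # normalized coordinates in [-1, 1] over the ROI
    x = (xx - (roi_w - 1) / 2) / (roi_w / 2)
    y = (yy - (roi_h - 1) / 2) / (roi_h / 2)
    # ellipse slightly inside the ROI so rotation jitter stays in bounds
    ax, ay = 0.84, 0.84
    r = np.hypot(x / ax, y / ay)
    th = np.arctan2(y, x)

    n_rings = rng.uniform(4.0, 9.0)
    lobes = int(rng.integers(2, 6))
    warp = rng.uniform(0.15, 0.45)
    phase1, phase2, phase3 = rng.uniform(0.0, 2 * np.pi, size=3)
    f_lin = rng.uniform(2.0, 5.0)
    direction = rng.uniform(0.0, np.pi)

    rings = np.sin(2 * np.pi * (n_rings * r + warp * np.sin(lobes * th + phase1)) + phase2)
    grating = np.sin(2 * np.pi * f_lin * (x * np.cos(direction) + y * np.sin(direction)) + phase3)
    pattern = 0.5 + 0.32 * rings + 0.13 * grating

    inside = r <= 1.0
    # bright rim at the support boundary: a stable, high-contrast "helix" edge
    rim = (r > 0.92) & inside
    out = np.full((roi_h, roi_w), 0.35)
    out[inside] = pattern[inside]
    out[rim] = 0.9
    return np.clip(out, 0.0, 1.0)


def _subject_canvas(spec: SyntheticCohortSpec, subject_idx: int) -> np.ndarray:
    """Noise-free canvas for one subject: ear texture on a plain background."""
    w, h = spec.image_size
    x0, y0, x1, y1 = spec.roi_bounds()
    rng = np.random.default_rng([spec.seed, subject_idx])
    canvas = np.full((h, w), 0.35)
    canvas[y0:y1, x0:x1] = _ear_texture(x1 - x0, y1 - y0, rng)
    return canvas


def _clutter_field(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Capture-specific high-contrast blob texture (hair/neckline stand-in)."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=12.0)
    scale = np.max(np.abs(g)) or 1.0
    return np.clip(0.5 + 1.6 * g / scale, 0.0, 1.0)


def generate_cohort(
    spec: SyntheticCohortSpec,
    out_dir: Optional[Path] = None,
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render the cohort: images, manifest, ROI sidecar.

    Identical spec (including seed) produces byte-identical output.  When
    ``out_dir`` is given, PNGs plus ``manifest.csv`` and ``rois.csv`` are
    written there in the standard dialects.
    """
    w, h = spec.image_size
    x0, y0, x1, y1 = spec.roi_bounds()
    n_female = int(np.floor(spec.n_subjects * spec.gender_ratio + 0.5))

    images: Dict[str, np.ndarray] = {}
    manifest_rows = []
    roi_rows = []
    for i in range(spec.n_subjects):
        sid = f"S{i:03d}"
        gender = "F" if i < n_female else "M"
        base = _subject_canvas(spec, i)
        for j in range(spec.images_per_subject):
            rng = np.random.default_rng([spec.seed, i, 1000 + j])
            angle = rng.uniform(-spec.rotation_jitter, spec.rotation_jitter)
            if j % 2 == 1:
                angle += spec.second_angle_offset
            frame = base
            if angle != 0.0:
                frame = ndimage.rotate(base, angle, reshape=False, order=1,
                                       mode="nearest")
            frame = frame.copy()
            if spec.background_clutter:
                clutter = _clutter_field((h, w), rng)
                outside = np.ones((h, w), dtype=bool)
                outside[y0:y1, x0:x1] = False
                frame[outside] = clutter[outside]
            brightness = rng.uniform(*spec.illumination_range)
            frame = frame * brightness
            frame = frame + rng.normal(0.0, spec.noise_sigma / 255.0, frame.shape)
            pixels = np.clip(np.floor(frame * 255.0 + 0.5), 0, 255).astype(np.uint8)

            name = f"{sid}_c{j}.png"
            images[name] = pixels
            manifest_rows.append({
                "image_path": name,
                "subject_id": sid,
                "gender": gender,
                "side": "left" if j % 2 == 0 else "right",
                "capture_index": j,
            })
            roi_rows.append({"image_path": name, "x0": x0, "y0": y0, "x1": x1, "y1": y1})

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    rois = pd.DataFrame(roi_rows, columns=ROI_COLUMNS)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, pixels in images.items():
            Image.fromarray(pixels, mode="L").save(out_dir / name)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        rois.to_csv(out_dir / "rois.csv", index=False)

    return images, manifest, rois


def expected_separability_check(
    cohort: Tuple[Dict[str, np.ndarray], pd.DataFrame, pd.DataFrame],
    config: PipelineConfig,
    backend=None,
    cache=None,
) -> EvaluationResult:
    """End-to-end smoke test: run the full evaluation on a generated cohort."""
    images, manifest, rois = cohort
    return evaluate(
        manifest, rois, config,
        source=ImageSource(images=images),
        backend=backend, cache=cache,
    )
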
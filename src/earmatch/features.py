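"""Keypoint descriptor extraction and composite identity vectors.

An ear image is represented for matching purposes by its *vector map*: the
set of 128-dimensional keypoint descriptors produced by a local-feature
detector (SIFT by default).  Descriptors from several captures of the same
ear can be stacked into one composite vector map, which keeps the stable
("constant") keypoints of the ear while diluting fortuitous single-capture
keypoints — raising the signal-to-noise ratio of identification.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InvalidCompositeError, UnmatchableError
from .preprocess import EarImage, PipelineConfig

__all__ = [
    "DESCRIPTOR_DIM",
    "DescriptorSet",
    "SiftBackend",
    "ToyGradientBackend",
    "DescriptorCache",
    "extract_descriptors",
    "concatenate",
    "default_backend",
]

#: Dimensionality of a single keypoint descriptor ("a vector of 128 numbers").
DESCRIPTOR_DIM = 128


def _canonical_order(descriptors: np.ndarray) -> np.ndarray:
    """Row order sorting descriptors lexicographically by their 128 values.

    Keypoint geometry is not retained in a :class:`DescriptorSet`, so the
    canonical order is defined on descriptor values alone.  This makes
    concatenation associative and order-insensitive, and makes extraction
    reproducible across backends that enumerate keypoints in arbitrary order.
    """
    if len(descriptors) <= 1:
        return np.arange(len(descriptors))
    # np.lexsort treats the *last* key as primary; feed columns reversed.
    return np.lexsort(descriptors.T[::-1])


@dataclass(frozen=True)
class DescriptorSet:
    """An n x 128 matrix of keypoint descriptors plus provenance.

    Rows are stored in canonical (lexicographic) order.  ``n == 0`` marks an
    unmatchable set (e.g. a contrast-free image with no keypoints); callers
    decide whether that is an error.
    """

    descriptors: np.ndarray
    source_images: tuple = ()
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.descriptors, dtype=np.float32)
        if d.ndim != 2 or (d.size and d.shape[1] != DESCRIPTOR_DIM):
            raise ValueError(
                f"descriptors must be n x {DESCRIPTOR_DIM}, got shape {d.shape}"
            )
        if d.size == 0:
            d = d.reshape(0, DESCRIPTOR_DIM)
        object.__setattr__(self, "descriptors", d)
        object.__setattr__(self, "source_images", tuple(self.source_images))

    @property
    def n(self) -> int:
        return self.descriptors.shape[0]

    @property
    def unmatchable(self) -> bool:
        return self.n == 0

    def canonicalized(self) -> "DescriptorSet":
        order = _canonical_order(self.descriptors)
        return DescriptorSet(self.descriptors[order], self.source_images, self.subject_id)


class SiftBackend:
    """SIFT keypoint detection and description (scikit-image implementation).

    Hyperparameters are left at the library's published defaults; the
    backend identity/version participates in cache keys and gallery
    fingerprints so that descriptor sets from different backends never mix.
    ``calls`` counts raw extractions and is the hook used to verify that the
    descriptor cache really skips this step on reruns.
    """

    name = "sift-skimage"

    def __init__(self) -> None:
        import skimage

        self.version = skimage.__version__
        self.calls = 0

    @property
    def identity(self) -> str:
        return f"{self.name}/{self.version}"

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        from skimage.feature import SIFT

        self.calls += 1
        det = SIFT()
        try:
            det.detect_and_extract(pixels)
        except RuntimeError:  # no keypoints found (e.g. constant image)
            return np.empty((0, DESCRIPTOR_DIM), dtype=np.float32)
        return det.descriptors.astype(np.float32)


class ToyGradientBackend:
    """Deterministic grid-sampled gradient-histogram descriptors.

    Tiles the image into ``cell`` x ``cell`` patches; each patch with enough
    gradient energy yields one descriptor: a 4x4 spatial grid of 8-bin
    gradient-orientation histograms (128 values), L2-normalized and scaled
    to the 0–255 range SIFT uses.  Useful for exercising the matching and
    gallery layers without a vision library in the loop.
    """

    name = "toy-gradient"
    version = "1"

    def __init__(self, cell: int = 16, min_energy: float = 1.0) -> None:
        self.cell = cell
        self.min_energy = min_energy
        self.calls = 0

    @property
    def identity(self) -> str:
        return f"{self.name}/{self.version}"

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        self.calls += 1
        img = pixels.astype(np.float64)
        gy, gx = np.gradient(img)
        mag = np.hypot(gx, gy)
        ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
        bins = np.minimum((ang / (2 * np.pi) * 8).astype(int), 7)
        c = self.cell
        out = []
        for r0 in range(0, img.shape[0] - c + 1, c):
            for c0 in range(0, img.shape[1] - c + 1, c):
                m = mag[r0 : r0 + c, c0 : c0 + c]
                if m.mean() < self.min_energy:
                    continue
                b = bins[r0 : r0 + c, c0 : c0 + c]
                desc = np.zeros((4, 4, 8))
                q = c // 4
                for i in range(4):
                    for j in range(4):
                        sub_m = m[i * q : (i + 1) * q, j * q : (j + 1) * q]
                        sub_b = b[i * q : (i + 1) * q, j * q : (j + 1) * q]
                        desc[i, j] = np.bincount(
                            sub_b.ravel(), weights=sub_m.ravel(), minlength=8
                        )[:8]
                v = desc.ravel()
                norm = np.linalg.norm(v)
                if norm > 0:
                    v = v / norm * 255.0
                out.append(v)
        if not out:
            return np.empty((0, DESCRIPTOR_DIM), dtype=np.float32)
        return np.asarray(out, dtype=np.float32)


_DEFAULT_BACKEND: Optional[SiftBackend] = None


def default_backend() -> SiftBackend:
    """Shared default SIFT backend instance."""
    global _DEFAULT_BACKEND
    if _DEFAULT_BACKEND is None:
        _DEFAULT_BACKEND = SiftBackend()
    return _DEFAULT_BACKEND


class DescriptorCache:
    """Persistent SQLite store of extracted descriptor sets.

    Keyed by (image content, preprocessing regime, backend identity), so a
    rerun over unchanged inputs skips feature extraction entirely.  Layout:
    one table ``descriptors(key TEXT PRIMARY KEY, n INT, data BLOB)`` with
    row-major 32-bit floats.
    """

    def __init__(self, path) -> None:
        self._conn = sqlite3.connect(str(path))
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS descriptors ("
            "key TEXT PRIMARY KEY, n INTEGER NOT NULL, data BLOB NOT NULL)"
        )
        self._conn.commit()
        self.hits = 0
        self.misses = 0

    @staticmethod
    def key_for(pixels: np.ndarray, fingerprint: str) -> str:
        h = hashlib.sha256()
        h.update(fingerprint.encode())
        h.update(str(pixels.shape).encode())
        h.update(np.ascontiguousarray(pixels).tobytes())
        return h.hexdigest()

    def get(self, key: str) -> Optional[np.ndarray]:
        row = self._conn.execute(
            "SELECT n, data FROM descriptors WHERE key = ?", (key,)
        ).fetchone()
        if row is None:
            self.misses += 1
            return None
        self.hits += 1
        n, blob = row
        return np.frombuffer(blob, dtype=np.float32).reshape(n, DESCRIPTOR_DIM).copy()

    def put(self, key: str, descriptors: np.ndarray) -> None:
        d = np.ascontiguousarray(descriptors, dtype=np.float32)
        self._conn.execute(
            "INSERT OR REPLACE INTO descriptors (key, n, data) VALUES (?, ?, ?)",
            (key, d.shape[0], d.tobytes()),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()


def extract_descriptors(
    image: EarImage,
    backend=None,
    config: Optional[PipelineConfig] = None,
    cache: Optional[DescriptorCache] = None,
) -> DescriptorSet:
    """Extract the canonical descriptor set of a preprocessed ear image.

    With a ``cache``, the (image, preprocessing regime, backend) key is
    consulted first and the backend is only invoked on a miss.  A zero-
    keypoint image yields an empty, unmatchable set rather than an error.
    """
    backend = backend or default_backend()
    source = (image.source,) if image.source else ()
    key = None
    if cache is not None:
        fp = (config or PipelineConfig()).preprocessing_fingerprint(backend.identity)
        key = cache.key_for(image.pixels, fp)
        hit = cache.get(key)
        if hit is not None:
            return DescriptorSet(hit, source, image.subject_id or None)
    raw = backend.extract(image.pixels)
    ds = DescriptorSet(raw, source, image.subject_id or None).canonicalized()
    if cache is not None and key is not None:
        cache.put(key, ds.descriptors)
    return ds


def concatenate(sets: Sequence[DescriptorSet]) -> DescriptorSet:
    """Stack descriptor sets of one subject into a composite vector map.

    The composite holds the row-wise union of all constituent descriptors in
    canonical order, so size is additive and the operation is associative
    and order-insensitive.  Mixing subjects is an error; an all-empty input
    produces an (unmatchable) empty composite.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("concatenate requires at least one descriptor set")
    subjects = {s.subject_id for s in sets if s.subject_id is not None}
    if len(subjects) > 1:
        raise InvalidCompositeError(
            f"cannot build a composite across subjects: {sorted(subjects)}"
        )
    if len(sets) == 1:
        return sets[0]
    stacked = np.vstack([s.descriptors for s in sets])
    sources = tuple(src for s in sets for src in s.source_images)
    subject = next(iter(subjects)) if subjects else None
    return DescriptorSet(stacked, sources, subject).canonicalized()
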
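"""Enrollment and persistence of subject identity records.

A gallery stores *vector maps only* — never raw ear photographs — so a
stolen gallery file cannot be used to reconstruct or visually identify
anyone's ear.  All records in one gallery share a preprocessing/backend
fingerprint; mixing preprocessing regimes is refused at load and insert
time rather than silently producing incomparable scores.
"""

from __future__ import annotations

import json
import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import EnrollmentError, GalleryStoreError
from .features import (
    DESCRIPTOR_DIM,
    DescriptorCache,
    DescriptorSet,
    concatenate,
    default_backend,
    extract_descriptors,
)
from .preprocess import CropROI, EarImage, PipelineConfig, preprocess

__all__ = ["SubjectRecord", "Gallery", "enroll", "save_gallery", "load_gallery"]

_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled identity: ID, gender label, composite vector map."""

    subject_id: str
    gender: str
    composite: DescriptorSet
    enrolled_from: tuple = ()
    config_hash: str = ""


class Gallery:
    """In-memory collection of subject records under one preprocessing regime."""

    def __init__(self, config_hash: str = "") -> None:
        self.config_hash = config_hash
        self._records: Dict[str, SubjectRecord] = {}

    def add(self, record: SubjectRecord) -> None:
        if record.subject_id in self._records:
            raise EnrollmentError(f"subject {record.subject_id!r} already enrolled")
        if record.config_hash and self.config_hash and record.config_hash != self.config_hash:
            raise GalleryStoreError(
                "record preprocessing fingerprint does not match the gallery's"
            )
        if not self.config_hash:
            self.config_hash = record.config_hash
        self._records[record.subject_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._records

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        return self._records[subject_id]

    @property
    def records(self) -> List[SubjectRecord]:
        return [self._records[k] for k in sorted(self._records)]


def enroll(
    gallery: Gallery,
    subject_id: str,
    gender: str,
    images: Sequence[EarImage],
    rois: Optional[Sequence[Optional[CropROI]]],
    config: PipelineConfig,
    backend=None,
    cache: Optional[DescriptorCache] = None,
) -> SubjectRecord:
    """Preprocess + extract each enrollment image and store the identity.

    With concatenation enabled the per-image descriptor sets are stacked
    into one composite vector map; with a single image a plain record is
    stored (a warning is raised when concatenation was requested, since a
    one-image composite buys nothing).  Raw pixels are never retained in
    the gallery.
    """
    if not images:
        raise EnrollmentError("enrollment requires at least one image")
    if subject_id in gallery:
        raise EnrollmentError(f"subject {subject_id!r} already enrolled")
    backend = backend or default_backend()
    if rois is None:
        rois = [None] * len(images)
    sets = []
    sources = []
    for img, roi in zip(images, rois):
        pre = preprocess(img, config, roi)
        ds = extract_descriptors(pre, backend=backend, config=config, cache=cache)
        sources.append(img.source or f"{subject_id}#{img.capture_index}")
        if not ds.unmatchable:
            sets.append(
                DescriptorSet(ds.descriptors, (sources[-1],), subject_id)
            )
    if not sets:
        raise EnrollmentError(
            f"subject {subject_id!r}: no descriptors in any enrollment image"
        )
    if config.use_concatenation:
        if len(sets) < 2:
            warnings.warn(
                f"subject {subject_id!r}: concatenation requested but only one "
                "usable image; storing a single-image record",
                stacklevel=2,
            )
        composite = concatenate(sets)
    else:
        composite = sets[0]
    record = SubjectRecord(
        subject_id=subject_id,
        gender=gender,
        composite=composite,
        enrolled_from=tuple(sources),
        config_hash=config.preprocessing_fingerprint(backend.identity),
    )
    gallery.add(record)
    return record


def save_gallery(gallery: Gallery, path) -> None:
    """Serialize to a single SQLite file; round-trips bit-exactly.

    Schema: ``meta(key, value)`` with the schema version and preprocessing
    fingerprint; ``subjects(subject_id, gender, enrolled_from, n)``;
    ``descriptors(subject_id, data)`` with row-major float32 blobs.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(str(path))
    try:
        conn.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL)")
        conn.execute(
            "CREATE TABLE subjects (subject_id TEXT PRIMARY KEY, gender TEXT, "
            "enrolled_from TEXT, n INTEGER NOT NULL)"
        )
        conn.execute(
            "CREATE TABLE descriptors (subject_id TEXT PRIMARY KEY, data BLOB NOT NULL)"
        )
        conn.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)", (_SCHEMA_VERSION,)
        )
        conn.execute("INSERT INTO meta VALUES ('config_hash', ?)", (gallery.config_hash,))
        for rec in gallery.records:
            conn.execute(
                "INSERT INTO subjects VALUES (?, ?, ?, ?)",
                (
                    rec.subject_id,
                    rec.gender,
                    json.dumps(list(rec.enrolled_from)),
                    rec.composite.n,
                ),
            )
            blob = np.ascontiguousarray(rec.composite.descriptors, dtype=np.float32)
            conn.execute(
                "INSERT INTO descriptors VALUES (?, ?)",
                (rec.subject_id, blob.tobytes()),
            )
        conn.commit()
    finally:
        conn.close()


def load_gallery(path, expected_config: Optional[str] = None) -> Gallery:
    """Load a gallery store; refuse fingerprint mismatches explicitly.

    ``expected_config`` is a preprocessing fingerprint (as returned by
    :meth:`PipelineConfig.preprocessing_fingerprint`); when given, a store
    written under a different regime raises ``GalleryStoreError`` instead of
    silently reusing incomparable descriptors.
    """
    path = Path(path)
    if not path.exists():
        raise GalleryStoreError(f"no gallery store at {path}")
    conn = sqlite3.connect(str(path))
    try:
        try:
            meta = dict(conn.execute("SELECT key, value FROM meta"))
            rows = conn.execute(
                "SELECT s.subject_id, s.gender, s.enrolled_from, s.n, d.data "
                "FROM subjects s JOIN descriptors d USING (subject_id)"
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise GalleryStoreError(f"corrupt gallery store {path}: {exc}") from exc
        if meta.get("schema_version") != _SCHEMA_VERSION:
            raise GalleryStoreError(
                f"unsupported gallery schema version {meta.get('schema_version')!r}"
            )
        config_hash = meta.get("config_hash", "")
        if expected_config is not None and config_hash != expected_config:
            raise GalleryStoreError(
                f"gallery was built under preprocessing regime {config_hash!r}, "
                f"not the requested {expected_config!r}"
            )
        gallery = Gallery(config_hash)
        for subject_id, gender, enrolled_from, n, blob in rows:
            desc = np.frombuffer(blob, dtype=np.float32).reshape(n, DESCRIPTOR_DIM)
            sources = tuple(json.loads(enrolled_from))
            gallery.add(
                SubjectRecord(
                    subject_id=subject_id,
                    gender=gender,
                    composite=DescriptorSet(desc.copy(), sources, subject_id),
                    enrolled_from=sources,
                    config_hash=config_hash,
                )
            )
        return gallery
    finally:
        conn.close()
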
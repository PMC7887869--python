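"""Rank-1..rank-10 recognition rates and the ablation grid runner.

Closed-set identification: every probe's true subject is enrolled, probes
are scored against the full gallery (their own record included), and the
rank of the true subject in each ranked list is aggregated into cumulative
rank-k recognition rates.  The ablation runner re-evaluates the same
train/test split under a list of pipeline configurations to quantify what
each technique (crop, resize, histogram equalization, concatenation,
gender filter) buys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import DescriptorSet, concatenate, default_backend, extract_descriptors
from .gallery import Gallery, enroll
from .io import ImageSource, atomic_write_text, rois_from_frame
from .matching import Outcome, classify_outcome, rank_matches
from .preprocess import CropROI, EarImage, PipelineConfig, preprocess

__all__ = [
    "SplitSpec",
    "EvaluationResult",
    "evaluate",
    "run_ablation",
    "resize_sweep",
    "incremental_strategies",
    "factorial_strategies",
    "results_frame",
    "write_results_csv",
]

logger = logging.getLogger(__name__)

MAX_RANK = 10


@dataclass(frozen=True)
class SplitSpec:
    """Per-subject assignment of captures to enrollment vs probe roles.

    Captures are ordered by ``capture_index``; the first ``train_count``
    enroll the subject and the remainder are probes.  ``train_count=None``
    auto-selects half of the captures (at least one, always leaving at
    least one probe) — with two captures per subject the first enrolls and
    the second probes; with four, two enroll and two probe.  Whether probe
    captures form one concatenated composite or individual probes follows
    the pipeline's concatenation flag.
    """

    train_count: Optional[int] = None

    def counts_for(self, n_images: int) -> Tuple[int, int]:
        if n_images < 2:
            raise ConfigError("each subject needs at least 2 captures (train + test)")
        tc = self.train_count if self.train_count is not None else max(1, n_images // 2)
        if not 1 <= tc < n_images:
            raise ConfigError(
                f"train_count={tc} leaves no probe images for a subject with "
                f"{n_images} captures"
            )
        return tc, n_images - tc


@dataclass
class EvaluationResult:
    """Cumulative rank-k recognition rates for one probe set vs one gallery."""

    strategy: str
    width: int
    n_probes: int
    hits_at_k: np.ndarray  # length 10, hits_at_k[k-1] = #probes with rank <= k
    per_probe: pd.DataFrame  # probe_id, true_id, rank, outcome

    @property
    def rate_at_k(self) -> np.ndarray:
        if self.n_probes == 0:
            return np.zeros(MAX_RANK)
        return self.hits_at_k / self.n_probes

    def rate(self, k: int) -> float:
        return float(self.rate_at_k[k - 1])

    def summary_row(self) -> dict:
        row = {"strategy": self.strategy, "width": self.width, "n_probes": self.n_probes}
        for k in range(1, MAX_RANK + 1):
            row[f"rank{k}"] = self.rate(k)
        return row


def _image_from_row(row, pixels) -> EarImage:
    from .preprocess import to_grayscale

    return to_grayscale(
        pixels,
        subject_id=str(row.subject_id),
        gender=str(row.gender) if row.gender else "",
        side=str(row.side),
        capture_index=int(row.capture_index),
        source=str(row.image_path),
    )


def _split_manifest(manifest: pd.DataFrame, split: SplitSpec):
    """Yield (subject_id, gender, train_rows, test_rows) per subject."""
    df = manifest.sort_values(["subject_id", "capture_index", "image_path"])
    for sid, grp in df.groupby("subject_id", sort=True):
        rows = list(grp.itertuples())
        tc, _ = split.counts_for(len(rows))
        gender = str(rows[0].gender) if rows[0].gender else ""
        yield str(sid), gender, rows[:tc], rows[tc:]


def evaluate(
    manifest: pd.DataFrame,
    rois: Union[pd.DataFrame, Dict[str, CropROI], None],
    config: PipelineConfig,
    split: Optional[SplitSpec] = None,
    source: Optional[ImageSource] = None,
    backend=None,
    cache=None,
    strategy_label: Optional[str] = None,
) -> EvaluationResult:
    """Enroll every subject's train captures, then identify every probe.

    Probes that yield zero descriptors are counted as "no match" outcomes
    (and logged), never dropped: a probe the system cannot score is an
    identification failure, not a smaller denominator.
    """
    split = split or SplitSpec()
    source = source or ImageSource()
    backend = backend or default_backend()
    roi_map = rois_from_frame(rois) if isinstance(rois, pd.DataFrame) else dict(rois or {})

    def roi_for(path: str) -> Optional[CropROI]:
        if not config.use_crop:
            return None
        if path not in roi_map:
            raise ConfigError(f"use_crop is set but no ROI for image {path!r}")
        return roi_map[path]

    gallery = Gallery()
    probes: List[Tuple[str, str, str, Optional[DescriptorSet]]] = []
    for sid, gender, train_rows, test_rows in _split_manifest(manifest, split):
        train_imgs = [_image_from_row(r, source.pixels(r.image_path)) for r in train_rows]
        train_rois = [roi_for(r.image_path) for r in train_rows]
        enroll(gallery, sid, gender, train_imgs, train_rois, config,
               backend=backend, cache=cache)

        test_sets = []
        for r in test_rows:
            img = _image_from_row(r, source.pixels(r.image_path))
            pre = preprocess(img, config, roi_for(r.image_path))
            ds = extract_descriptors(pre, backend=backend, config=config, cache=cache)
            test_sets.append((str(r.image_path), DescriptorSet(
                ds.descriptors, ds.source_images, sid)))
        if config.use_concatenation:
            usable = [ds for _, ds in test_sets if not ds.unmatchable]
            probe_id = "+".join(p for p, _ in test_sets)
            probes.append((probe_id, sid, gender,
                           concatenate(usable) if usable else None))
        else:
            for probe_id, ds in test_sets:
                probes.append((probe_id, sid, gender,
                               None if ds.unmatchable else ds))

    records = gallery.records
    hits = np.zeros(MAX_RANK, dtype=int)
    rows = []
    for probe_id, true_id, gender, ds in probes:
        if ds is None:
            logger.warning("probe %s has no descriptors; counted as no-match", probe_id)
            rows.append({"probe_id": probe_id, "true_id": true_id,
                         "rank": None, "outcome": Outcome.NONE.value})
            continue
        ranked = rank_matches(ds, records, config, probe_gender=gender)
        outcome = classify_outcome(ranked, true_id)
        if outcome.rank is not None and outcome.rank <= MAX_RANK:
            hits[outcome.rank - 1 :] += 1
        rows.append({"probe_id": probe_id, "true_id": true_id,
                     "rank": outcome.rank, "outcome": outcome.outcome.value})

    per_probe = pd.DataFrame(rows, columns=["probe_id", "true_id", "rank", "outcome"])
    return EvaluationResult(
        strategy=strategy_label or config.describe(),
        width=config.target_width if config.use_resize else 0,
        n_probes=len(probes),
        hits_at_k=hits,
        per_probe=per_probe,
    )


def _cfg(crop=False, resize=True, he=False, concat=False, gender=False, width=150):
    return PipelineConfig(
        use_crop=crop, use_resize=resize, target_width=width, use_hist_eq=he,
        use_concatenation=concat, use_gender_filter=gender,
    )


def incremental_strategies(width: int = 150) -> List[Tuple[str, PipelineConfig]]:
    """The six-row ablation grid: resize-only up to the full technique stack."""
    return [
        ("one:resize", _cfg(width=width)),
        ("two:resize+he", _cfg(he=True, width=width)),
        ("three:crop+resize", _cfg(crop=True, width=width)),
        ("four:crop+resize+he", _cfg(crop=True, he=True, width=width)),
        ("five:crop+resize+he+concat", _cfg(crop=True, he=True, concat=True, width=width)),
        ("six:crop+resize+he+concat+gender",
         _cfg(crop=True, he=True, concat=True, gender=True, width=width)),
    ]


def factorial_strategies(width: int = 150) -> List[Tuple[str, PipelineConfig]]:
    """Five-row grid crossing HE with the gender filter on a crop+resize base."""
    return [
        ("crop+resize", _cfg(crop=True, width=width)),
        ("crop+resize+he", _cfg(crop=True, he=True, width=width)),
        ("crop+resize+gender", _cfg(crop=True, gender=True, width=width)),
        ("crop+resize+he+gender", _cfg(crop=True, he=True, gender=True, width=width)),
        ("crop+resize+he+concat+gender",
         _cfg(crop=True, he=True, concat=True, gender=True, width=width)),
    ]


def run_ablation(
    manifest: pd.DataFrame,
    rois,
    strategies: Sequence[Tuple[str, PipelineConfig]],
    split: Optional[SplitSpec] = None,
    source: Optional[ImageSource] = None,
    backend=None,
    cache=None,
) -> List[EvaluationResult]:
    """Evaluate each strategy on the same train/test split."""
    if not strategies:
        raise ConfigError("run_ablation requires at least one strategy")
    return [
        evaluate(manifest, rois, config, split=split, source=source,
                 backend=backend, cache=cache, strategy_label=label)
        for label, config in strategies
    ]


def resize_sweep(
    manifest: pd.DataFrame,
    rois,
    widths: Sequence[int],
    split: Optional[SplitSpec] = None,
    source: Optional[ImageSource] = None,
    backend=None,
    cache=None,
) -> List[EvaluationResult]:
    """Crop+resize-only evaluation at each target width (the width sweep)."""
    if not widths:
        raise ConfigError("resize_sweep requires at least one width")
    strategies = [
        (f"crop+resize{w}", _cfg(crop=True, width=int(w))) for w in widths
    ]
    return run_ablation(manifest, rois, strategies, split=split, source=source,
                        backend=backend, cache=cache)


def results_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in results])


def write_results_csv(
    results: Sequence[EvaluationResult],
    path,
    provenance: Optional[dict] = None,
) -> None:
    """Summary CSV (rates to 2 decimals) with a provenance header line."""
    df = results_frame(results).copy()
    for k in range(1, MAX_RANK + 1):
        df[f"rank{k}"] = df[f"rank{k}"].round(2)
    header = ""
    if provenance is not None:
        header = "# provenance: " + json.dumps(provenance, sort_keys=True) + "\n"
    atomic_write_text(path, header + df.to_csv(index=False))


def write_per_probe_csv(result: EvaluationResult, path,
                        provenance: Optional[dict] = None) -> None:
    header = ""
    if provenance is not None:
        header = "# provenance: " + json.dumps(provenance, sort_keys=True) + "\n"
    atomic_write_text(path, header + result.per_probe.to_csv(index=False))
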
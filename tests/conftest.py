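import numpy as np
import pytest
from hypothesis import settings

from earmatch import (
    DescriptorSet,
    Gallery,
    PipelineConfig,
    SiftBackend,
    SyntheticCohortSpec,
    ToyGradientBackend,
    enroll,
    generate_cohort,
    to_grayscale,
)
from earmatch.io import ImageSource
from earmatch.preprocess import CropROI

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def random_descriptor_set(rng, n, subject_id=None):
    return DescriptorSet(
        rng.uniform(0.0, 255.0, size=(n, 128)).astype(np.float32),
        subject_id=subject_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_backend():
    return ToyGradientBackend()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for fast unit tests (toy-backend friendly)."""
    spec = SyntheticCohortSpec(
        n_subjects=5, images_per_subject=4, image_size=(200, 400), seed=11
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def sift_cohort50():
    """The n=50 cohort used by the identification-property checks."""
    spec = SyntheticCohortSpec(n_subjects=50, images_per_subject=4, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def sift_gallery50(sift_cohort50):
    """Full-technique-stack gallery over the n=50 cohort, plus probe sets.

    Each subject enrolls with the first two captures (concatenated
    composite); the remaining two captures become individual probe
    descriptor sets (100 probes in total).
    """
    from earmatch import extract_descriptors, preprocess

    images, manifest, rois = sift_cohort50
    config = PipelineConfig()
    backend = SiftBackend()
    roi_map = {
        r.image_path: CropROI(int(r.x0), int(r.y0), int(r.x1), int(r.y1))
        for r in rois.itertuples()
    }
    gallery = Gallery()
    probes = []  # (probe_id, true_id, gender, DescriptorSet)
    ordered = manifest.sort_values(["subject_id", "capture_index"])
    for sid, grp in ordered.groupby("subject_id", sort=True):
        rows = list(grp.itertuples())
        gender = rows[0].gender
        imgs = [
            to_grayscale(
                images[r.image_path],
                subject_id=str(sid), gender=gender, side=r.side,
                capture_index=int(r.capture_index), source=r.image_path,
            )
            for r in rows
        ]
        row_rois = [roi_map[r.image_path] for r in rows]
        enroll(gallery, str(sid), gender, imgs[:2], row_rois[:2], config,
               backend=backend)
        for img, roi in zip(imgs[2:], row_rois[2:]):
            pre = preprocess(img, config, roi)
            ds = extract_descriptors(pre, backend=backend, config=config)
            probes.append((img.source, str(sid), gender,
                           DescriptorSet(ds.descriptors, ds.source_images, str(sid))))
    return gallery, probes, config
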
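# Methods

## Identification model

A subject's identity is represented by a *vector map*: the set of 128-d
SIFT keypoint descriptors extracted from one or more preprocessed captures
of their ear. Identification is closed-set nearest-neighbor retrieval: a
probe vector map P is scored against every enrolled vector map E by

    score(P, E) = (1/|P|) · Σ_i min_j ‖p_i − e_j‖²,

the average over probe descriptors of the squared Euclidean distance to the
nearest descriptor in E. The score is asymmetric — the probe side is
averaged — and the matching direction is always probe → gallery. Squared
(rather than plain) Euclidean distance is kept because it is the score the
method defines; rankings are identical under any strictly monotone
transform of per-pair scores, so the choice affects reported score values
only. Candidates are sorted ascending, ties broken lexicographically by
subject ID for cross-platform determinism, and truncated to the top 10.
A probe whose true subject appears at rank 1 counts toward both rank-1 and
rank-10 accuracy; ranks 2–10 toward rank-10 only.

There is no open-set rejection: the model assumes every probe is enrolled,
and no score threshold is applied. The score scale depends on the
descriptor backend's normalization (SIFT descriptors live on a 0–255-ish
scale, so squared distances are O(10⁴–10⁵)); only relative order matters.

## Preprocessing

Fixed order, each stage independently switchable: grayscale → manual crop →
resize → histogram equalization.

- **Grayscale**: BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded half
  up. The weights are pinned so descriptor caches are reproducible across
  image backends.
- **Crop**: a manually supplied ROI rectangle, 0-based half-open
  coordinates. Out-of-bounds ROIs are errors, never silently clamped:
  a wrong ROI should be visible, not absorbed. Automated ear detection is
  out of scope.
- **Resize**: to a fixed ear width (default 150 px), height rounded to
  preserve proportions. Shrinking uses area (box) averaging — at the
  typical ~10× shrink this doubles as the low-pass filter that suppresses
  pixel noise before keypoint detection — and enlarging uses bilinear.
- **Histogram equalization**: the standard 256-bin cumulative-histogram
  remap v′ = round((cdf(v) − cdf_min)/(N − cdf_min) · 255), with cdf_min
  the smallest nonzero cumulative count. The induced intensity map is
  monotone non-decreasing. A constant image is the 0/0-degenerate case and
  is returned unchanged (any constant image is equally "equalized";
  identity is least surprising). Equalization counters illumination
  variability (e.g. a capture rig's battery dimming between sessions), but
  only helps after cropping: applied to a full frame it stretches the
  background's histogram at the ear's expense.

## Feature extraction and composites

The descriptor backend is pluggable behind a two-method contract
(`identity`, `extract`). The default is scikit-image's SIFT at its
published hyperparameter defaults; the backend identity participates in
every cache key and gallery fingerprint, so descriptor sets produced under
different backends or preprocessing regimes can never be mixed silently.
A deterministic toy backend (grid-sampled gradient-orientation histograms,
pure numpy) exercises the matching, gallery and evaluation layers in tests
without a vision library in the loop.

Descriptor rows are stored in a canonical order: lexicographic over the 128
descriptor values. Keypoint geometry is deliberately not retained in the
container, so this ordering makes extraction reproducible regardless of the
backend's keypoint enumeration order and makes concatenation associative,
order-insensitive, and an identity on single sets.

**Concatenation** stacks the descriptor sets of several captures of one ear
into a composite (sizes add; subjects must match). Its benefit is a
superset property of nearest-neighbor search: adding rows to a gallery
entry can only shrink any probe descriptor's NN distance, so descriptors
stable across captures dominate while capture-specific ones are diluted.
Both tests and the acceptance checks assert this inequality directly.

**Cache**: extracted descriptor sets persist in SQLite keyed by
(image content hash, preprocessing fingerprint, backend identity). A rerun
over unchanged inputs performs zero backend invocations (asserted via an
instrumented call counter) and yields descriptor-identical results.

## Gallery

Galleries store subject ID, gender label, enrolled-image provenance and the
composite vector map — never raw pixels, so a leaked gallery cannot be used
to reconstruct or visually recognize anyone's ear. One SQLite file, three
tables (meta / subjects / descriptors), float32 row-major blobs;
load(save(g)) is bit-exact. All records share one preprocessing/backend
fingerprint; loading under a different regime is an explicit error.
Enrollment is write-once: re-enrolling an existing subject ID is a
conflict, and later visits do not update the stored composite.

## Evaluation

Per subject, captures ordered by capture index are split into enrollment
and probe roles; the default takes the first half (at least one) for
enrollment. With concatenation enabled, enrollment captures form one
composite and the probe captures form one composite probe per subject;
with it disabled, the first enrollment capture is stored and each probe
capture is scored individually. The ablation grid runs a list of pipeline
configurations over the same capture assignment, so strategies differ only
in technique, not in data. Probes yielding zero descriptors count as
"no match" outcomes — a probe the system cannot score is an identification
failure, not a smaller denominator. Rates are reported to two decimals in
CSV output, full precision internally. No confidence intervals are
attached: each cohort evaluation is a self-contained benchmark, not a
sample from a population of cohorts.

Built-in strategy grids: a six-row grid from resize-only up to the full
crop + resize + HE + concatenation + gender-filter stack, a five-row
variant without the HE-free concatenation rung, and a resize-width sweep
(crop + resize only) over {75, 100, 125, 150, 175, 200} px by default.

## Synthetic cohorts

The generator exists so every contract above is testable at desk scale with
known ground truth. Identity is modeled as texture, not anatomy: each
subject gets a unique pattern of curved sinusoidal ridges (4–9 rings,
2–5 angular lobes, random phases) on an elliptical support with a bright
rim — high-contrast curved edges of the kind SIFT keys on, playing the role
of helix/antihelix contours. Each capture re-renders the subject's pattern
under the nuisance factors of a stabilized handheld capture session:

| parameter | default | emulates |
|---|---|---|
| `image_size` | 600 × 1200 px | raw frame before cropping |
| ear ROI | central 0.6 w × 0.4 h | manual crop removing ~3/4 of pixels |
| `rotation_jitter` | ±3° | imperfect device seating |
| `second_angle_offset` | 0° (off) | rotating-shroud second angle, if set |
| `illumination_range` | 0.6–1.0 × | battery dimming between sessions |
| `noise_sigma` | 3 intensity levels | sensor noise |
| `background_clutter` | on | hair/neckline outside the ROI |
| `gender_ratio` | 0.5 | cohort composition |

Clutter is a per-capture Gaussian-smoothed noise field (σ = 12 px at full
resolution) clipped to high contrast: it contributes several hundred
keypoints per uncropped frame — enough to dominate the ~150 ear keypoints
and reproduce the crop-dependence of accuracy — while staying cheap enough
that uncropped configurations run at desk scale. Defaults are set so that
the full technique stack saturates rank-1 accuracy on a 30-subject cohort
while crop-disabled configurations measurably degrade, giving the ablation
grid a meaningful gradient. Identical spec + seed is byte-identical output.

What the generator does **not** model: real ear geometry and its
inter-subject similarity structure, skin-tone-dependent contrast, motion
blur, occlusion *inside* the ROI (hair over the ear), or ear growth over
time. Passing tests on synthetic cohorts therefore validates the pipeline's
mechanics and the relative effect of each technique, not absolute
recognition rates on real populations.

## Problem sizes and numerical choices

The standing evaluation sizes are 30 subjects × 4 captures for the ablation
grid and 50 subjects for the self-identification and gender-filter
property checks — large enough that ranking mistakes are visible, small
enough for interactive iteration. The vectorized scorer (BLAS-backed
pairwise squared distances) is checked against a brute-force double-loop
oracle on random descriptor sets to 1e-6 relative; observed agreement is at
machine precision. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; SIFT extraction and every preprocessing stage
are deterministic, so identical inputs and configuration give bit-identical
galleries, scores and CSVs.

Known limitations: no open-set rejection threshold; manual ROIs are
trusted as given; SIFT hyperparameters are not tuned per dataset; absolute
scores are backend-dependent and not comparable across backends.
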
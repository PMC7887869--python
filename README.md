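# earmatch

Ear-biometric subject identification from photographs, built for settings
where conventional patient identifiers (names, birth records, ID cards) are
unreliable — e.g. linking infants to their records across clinic visits. The
ear is a good biometric for this: anatomically distinctive, accessible
across the lifespan, and photographable with a phone camera, with none of
the acceptability or hardware barriers of fingerprints or iris scans.

`earmatch` implements the full identification pipeline as a library plus a
command-line tool:

1. **Preprocessing** — grayscale → manual crop to the ear region (ROI) →
   resize to a fixed ear width (default 150 px, height keeps proportions) →
   histogram equalization. Each stage after grayscale can be switched off
   for ablation; the order is fixed.
2. **Feature extraction** — SIFT keypoint descriptors: each ear image
   becomes a *vector map*, an n × 128 matrix of local descriptors.
   Descriptors from multiple captures of the same ear can be stacked into
   one **composite** identity vector ("keypoint concatenation"), which
   keeps the ear's stable keypoints while diluting capture-specific ones.
3. **Matching** — a probe vector map *P* is scored against each enrolled
   subject's vector map *E* by the average nearest-neighbor squared
   Euclidean distance

   score(P, E) = (1/|P|) · Σᵢ minⱼ ‖pᵢ − eⱼ‖²,

   optionally after narrowing the gallery to the probe's gender group.
   The 10 smallest scores form the ranked candidate list.
4. **Evaluation** — closed-set rank-1…rank-10 recognition rates over a
   cohort, an ablation grid over technique combinations, and a resize-width
   sweep. Galleries persist to SQLite (vector maps only — no photographs
   are ever stored), and a descriptor cache makes reruns skip extraction
   entirely.

A seeded synthetic-cohort generator renders unique high-contrast "ear"
textures under realistic capture nuisances (rotation jitter, illumination
decay, sensor noise, background clutter standing in for hair/neckline), so
the whole pipeline is testable without any image download.

## Worked example

Generate a 10-subject synthetic cohort (4 captures each) and run the
six-strategy ablation grid — strategies add one technique at a time, from
resize-only to crop + resize + histogram equalization + concatenation +
gender filter:

```
$ earmatch synth --subjects 10 --seed 7 --out demo
wrote 40 images for 10 subjects to demo

$ earmatch ablate --manifest demo/manifest.csv --rois demo/rois.csv \
      --images-root demo --strategy incremental --out demo/ablation.csv
one:resize: rank1=0.90 rank10=1.00
two:resize+he: rank1=0.85 rank10=1.00
three:crop+resize: rank1=1.00 rank10=1.00
four:crop+resize+he: rank1=1.00 rank10=1.00
five:crop+resize+he+concat: rank1=1.00 rank10=1.00
six:crop+resize+he+concat+gender: rank1=1.00 rank10=1.00
```

Each line is the fraction of probes whose true subject came back at rank 1
(rank1) or within the top ten (rank10). The gradient shows the techniques
doing their jobs: without the manual crop, background clutter contributes
keypoints and costs rank-1 accuracy (0.90), and equalizing an uncropped
frame makes things worse (0.85) because the clutter dominates the
histogram; once the ear is cropped out, the stack saturates. The CSV
carries all ten ranks plus a provenance header (backend, seed, config).

Enroll the cohort into a persistent gallery and identify a probe image:

```
$ earmatch enroll --manifest demo/manifest.csv --rois demo/rois.csv \
      --images-root demo --gallery demo/gallery.sqlite
...
gallery demo/gallery.sqlite: 10 subjects (0 failures)

$ earmatch identify demo/S003_c2.png --roi 120 360 480 840 \
      --gallery demo/gallery.sqlite --gender F
1	S003	0.0000
2	S001	43696.7521
3	S000	51093.6795
...
```

The probe is one of S003's enrolled captures, so its descriptors are a
subset of the stored composite and the score is exactly 0; the gap to the
runner-up is the identification margin.

The same operations are available as library calls
(`earmatch.generate_cohort`, `earmatch.evaluate`, `earmatch.run_ablation`,
`earmatch.rank_matches`, …) for use on real image directories with a
`manifest.csv` / `rois.csv` pair in the same format.

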
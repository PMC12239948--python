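# sarcotrace

Quantitative image analysis of sarcomere addition in developing
*Drosophila* muscle.

During pupal development a fly flight muscle roughly doubles in length
within hours, adding on the order of one sarcomere per myofibril every two
minutes — yet myofibrils are under tension throughout and cannot simply be
opened up.  Growth proceeds by **sarcomere division**: the myosin filament
stack (A-band) of a mother sarcomere segregates into two rigid daughter
blocks that slide apart along the tension axis while a new Z-disc forms
between them.  `sarcotrace` implements the analysis machinery needed to
quantify this process from fluorescence microscopy, for researchers
studying myofibrillogenesis and muscle growth:

- **Z-disc detection** in multichannel 3D confocal stacks (Sallimus
  channel): per-slice global ∧ local-adaptive thresholding,
  intensity-weighted component centroids, cubic-spline subvoxel *z*
  refinement, and 0.4 μm single-linkage merging of multi-slice detections.
- **Chromatic-shift correction** of the 405 nm channel by
  cross-correlating the Sls image against a false image of Gaussians at
  detected actin peaks.
- **Myofibril tracing**: candidate sarcomeres from Z-disc pairs within
  3.5 μm and an angular cone around the fiber axis, scored by mean actin +
  Obscurin intensity along the segment, selected greedily with branch
  resolution (each Z-disc keeps at most one sarcomere per side), then
  file-driven curation and the 1.8 μm quantitative-length filter.
- **Sarcomere profiles**: per-channel intensity profiles over the
  sarcomere coordinate *s* ∈ [0, 1], normalized by the smoothed-profile
  maximum, oriented by left-half Obscurin mass, pooled into half-open
  length bins; the six division landmarks Z1, S1, M1, M2, S2, Z2 and the
  slopes of their pairwise distances against sarcomere length.  Rigid
  daughter blocks show d(M1–S2)/dL = 1 while Z1–M1 stays constant.
- **Dynamics**: movie stabilization, line scans with transverse averaging,
  myosin-peak tracking with interpeak-distance series, and the FRAP
  recovery fit I(t) = I_max·(1 − exp(−ln 2 · t / t₅₀%)) over the first
  70 min (Nelder–Mead from the initial guess I_max = 0.55, t₅₀% = 30 min).
- **Larval M-band rings**: diameter as the projection of the
  lateral–lateral segment perpendicular to the junction axis; Sls/Obscurin
  band intensities from 2 μm multi-line scans normalized to reference
  bands; small/medium/large diameter bins at 4 and 6 μm.
- **Pair statistics**: sarcomeres from Sls peaks on parallel line scans,
  "pronounced" Mhc-GFP flags from joint max/total intensity quantiles,
  isolated adjacent-pair counts, and a permutation p-value against a
  random-redistribution null.
- **Synthetic data with ground truth** for every one of these inputs, so
  the whole pipeline is testable end to end without any raw images.

## Worked example

```python
from sarcotrace import RunConfig, io, synthdata

stack, truth = synthdata.make_flight_stack(
    n_myofibrils=3, n_sarcomeres=30, noise_sd=0.02,
    planted_shift=(2, -3), seed=11)
bundle = io.run_pipeline(RunConfig(output_dir="demo_out", seed=11), stack=stack)
log = bundle["log"]["stages"]
print("chromatic shift :", (log["chromshift"]["dy"], log["chromshift"]["dx"]))
print("Z-discs         :", log["zdisc"]["n_zdiscs"])
print("myofibrils      :", log["trace"]["n_myofibrils"])
print("sarcomeres kept :", log["curation"]["n_curated"])
```

prints

```
chromatic shift : (2, -3)
Z-discs         : 93
myofibrils      : 3
sarcomeres kept : 90
```

The planted 405 nm channel shift of (2, −3) pixels is recovered exactly
and undone; all 93 rendered Z-discs (3 myofibrils × 31) are found with no
false positives; tracing links them into 3 chains of 30 sarcomeres whose
lengths match the 2 μm ground truth (90 survive the >1.8 μm quantitative
filter).  `demo_out/` then holds the Z-disc and sarcomere tables, per-bin
mean profiles, and a JSON run log; every table header carries the
configuration hash.

The same pipeline is available from the shell:

```sh
sarcotrace simulate --out stack.tif --n-myofibrils 3 --n-sarcomeres 30 --seed 11
sarcotrace run-all --input stack.tif --out demo_out
```

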
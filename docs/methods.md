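# Methods

This note documents the models, parameter choices and numerical details
behind `sarcotrace`, and what the synthetic-data tests do and do not show
about real microscopy data.

## The measurement problem

Developing *Drosophila* flight muscles add sarcomeres by division: a
mother sarcomere's A-band segregates into two daughter blocks — (Z1, M1,
S1) and (Z2, M2, S2), where Z are Z-discs, M Obscurin-marked M-bands and S
nascent Sallimus accumulations — that separate along the tension axis
while keeping their internal spacings fixed.  Detecting this process in
fixed images requires (i) finding thousands of Z-discs in 3D stacks,
(ii) linking them into myofibrils, (iii) averaging oriented, normalized
intensity profiles per sarcomere-length bin, and (iv) quantifying landmark
distance trends against length.  Live-imaging (FRAP, peak tracking) and
larval-muscle (M-band rings, pronounced-pair statistics) analyses
complement the fixed-image pipeline.

## Z-disc detection

Per z-slice, the binary mask is the conjunction of a **global** and a
**local adaptive** threshold:

- Global: one Otsu histogram split computed over the whole 3D Sls channel
  and applied to every slice.  A per-slice split was tried first and
  rejected: slices without signal have their noise floor split in half,
  which seeded false detections and let single-linkage merging bridge
  neighboring myofibrils (precision dropped to ≈ 0.7 on the standard noisy
  fixture; the stack-wide split restores 1.0).
- Local: pixel > local mean in a 1.0 μm window, scaled by
  2·(1 − sensitivity) with sensitivity 0.5 by default (i.e. the local mean
  itself).  Both the window and the sensitivity are configuration options,
  since the original settings behind this detection scheme are not
  published.

Connected components (8-connectivity, minimum 20 px) become candidate
points at their intensity-weighted centroids.  Each point then receives a
subvoxel *z*: a cubic spline through its axial intensity profile (averaged
over a 3×3 lateral neighborhood) is evaluated on a grid of 0.01·dz, and
the nearest interior local maximum is taken; monotone profiles keep the
boundary maximum and are flagged.  Finally, points strictly closer than
0.4 μm are merged by single-linkage clustering into one Z-disc at the
unweighted mean of the member positions; discs supported by fewer than 2
slices are dropped (a real disc spans several 200 nm slices, single-slice
detections are noise).  Cluster ids are assigned in lexicographic position
order, making the output invariant to input ordering.

## Chromatic-shift correction

Only the 405 nm (Sls) channel shows chromatic aberration, well described
by a uniform integer pixel translation at this field of view.  Actin peaks
are detected per slice with the same thresholding machinery (sensitivity
0.3 rather than 0.5: actin carries a plateau across the sarcomere in
addition to its Z-disc peaks, and the stricter local threshold separates
the peaks from the plateau); a false image of σ = 2 px Gaussians at the
peak positions is cross-correlated with the Sls slice via FFT, the argmax
restricted to ±10 px.  The component-wise median over slices gives the
stack shift; the Sls channel is translated back by the negated vector with
zero fill.  Estimation is integer-exact for planted translations up to
±8 px on noiseless renders, and a warning flag is raised above 5 px, the
ceiling observed for the instrument this models.

## Tracing and curation

Candidate sarcomeres are Z-disc pairs within 3.5 μm whose separation lies
within a 30° half-angle of the fiber axis (the principal axis of the
Z-disc cloud; both parameters configurable — the angular range used
originally was set manually).  Scores are the sum of mean actin and mean
Obscurin intensity at 50 trilinear samples along the segment, each channel
normalized by its stack-wide 99th percentile so the two stains contribute
comparably.  Selection is greedy in descending score with deterministic
tie-breaks (length, then endpoint ids); a candidate is accepted only if
neither endpoint already has an accepted sarcomere on that side of the
axis.  This one-per-side rule simultaneously enforces chain degree ≤ 2 and
resolves branches in favor of the higher-scoring candidate.  On small
instances the greedy result provably equals the lexicographically maximal
feasible subset in score order (verified against an exhaustive oracle in
the tests); whether the original optimization was jointly optimal or
greedy is unknown, so the comparison oracle bounds the difference.

Curation is file-driven (id, accept|reject CSV) instead of interactive;
independent of any manual decisions, sarcomeres of length ≤ 1.8 μm are
excluded from quantitative output, and the removal fraction is reported.

## Profiles and division landmarks

Profiles are 100 trilinear samples per channel over s ∈ [0, 1],
normalized by the maximum of a moving-average-smoothed copy (window =
1/10 of the sarcomere length, shrinking at the ends) and oriented so the
left half (s ≤ ½) holds at least as much Obscurin as the right (exact ties
keep input order; the larger daughter block therefore sits left).  Length
bins are half-open with edges 1.8, 2.2, 2.4, 2.6, 3.0, 3.4 μm; [1.8, 2.2)
is the "regular" bin.  Per-bin mean profiles store pointwise mean and SD.

Landmarks on a mean profile: Z1/Z2 at s = 0/1; M1/M2 the two highest
Obscurin local maxima (prominence ≥ 0.1 of the profile maximum,
configurable), M1 the left one; S1/S2 the two highest *interior* Sls
maxima within s ∈ [0.1, 0.9], a window that operationalizes "away from the
Z-discs".  Peak positions are refined to subsample precision with a
three-point parabola — without this, the landmark quantization of ~L/100
propagates into slope errors comparable to the ±0.05 acceptance band of
the rigid-block test.  Distance trends are ordinary least-squares slopes
against bin mean length and require at least three clean bins.

Neighbor-normalized amounts integrate the *raw* (un-normalized) profile
times length and divide by the mean of the two flanking regular
sarcomeres; sarcomeres lacking a detected neighbor are excluded from the
aggregate.

## Dynamics and FRAP

Stabilization removes per-frame integer translations estimated by phase
cross-correlation against the first frame (a running-reference option
exists; which reference the original used is unstated).  Line scans
average over a transverse width (0.5–0.6 μm in typical use) with bilinear
sampling, optionally smoothed by an odd moving-average window (default
none; 5 samples in typical use).  Peaks are linked frame-to-frame by
nearest position with a 0.5 μm/frame gate; unmatched peaks open new tracks
(division events), lost tracks are truncated and flagged.

The FRAP ratio I(t) (mean inside bleach / mean outside) is fitted with
I(t) = I_max·(1 − exp(−ln 2 · t / t₅₀%)) over t ≤ 70 min by Nelder–Mead
from (0.55, 30 min), with non-positive half-time iterates barrier-
penalized.  Noiseless model data is recovered to 10⁻⁶ across I_max ∈
[0.1, 1] and t₅₀% ∈ [5, 60] min; under noise the fit agrees with a dense
grid-search oracle (tested).  An all-zero series short-circuits to
I_max = 0 with an "unidentifiable half-time" flag.

## Rings

Ring height is defined as the junction-to-junction distance (the notion of
"height" is otherwise ambiguous); diameter is the absolute projection of
the lateral–lateral segment onto the perpendicular of the junction axis,
exactly invariant under rigid motions.  The three measurement scans (2 μm,
along the lateral line, centered at the laterals and their midpoint)
average parallel scans across 50 % (Sls) or 25 % (Obscurin) of ring
height; each profile is minimum-subtracted before totalling, making the
normalized values invariant to constant offsets and global scale.
Reference scans default to the measured scans' direction and thickness but
accept explicit values (the original reference thickness was chosen
manually).  Diameter bins follow the printed labels: [0, 4), [4, 6],
(6, ∞) μm; the boundary convention at exactly 4 and 6 μm is a documented
choice, exposed in the code.

## Pair statistics

Sarcomeres are the intervals between consecutive Sls peaks on each line
scan; a sarcomere is "pronounced" when its Mhc maximum **and** total both
reach their dataset-wide 0.93 quantiles (≥ comparison at ties; the
quantiles are calibrated so that the flagged fraction is about 7 % and are
configurable).  An isolated pair is a (0, 1, 1, 0) window: a maximal
pronounced run of length exactly two with both flanking sarcomeres present
and non-pronounced, so runs touching scan ends never count and pairs never
span scans.  The permutation null redistributes the flags uniformly at
random with scan lengths and total flag count preserved — globally across
the concatenated scans by default, or stratified per scan; which variant
the original analysis used (and hence whether its printed significance
bound is reproducible) cannot be determined from the published
description, so both are provided and neither is asserted against it.
Scans are internally ordered canonically (by length, then flag count)
before permuting, making the p-value exactly invariant under input scan
reordering.  The p-value is (1 + #{count ≥ observed}) / (1 + n_perm),
which is super-uniform under the null (tested at α = 0.01 and 0.05).

## Synthetic data: what it does and does not emulate

The generator renders myofibrils along x, laterally offset ≥ 1 μm, at the
stated acquisition geometry (0.03321 μm lateral pixels, 200 nm z-step;
0.06589 μm for larval fixtures).  Axial intensity per channel: Gaussian
Z-disc bands (σ 0.08 μm) for Sls and actin, an actin plateau (0.35) across
the sarcomere, a boxcar A-band for Mhc with a central Gaussian Obscurin
band; dividing sarcomeres render two rigid daughter blocks with fixed
internal spacings (defaults: Z-to-M 0.675 μm, M-to-S 0.4 μm) whose
separation grows one-to-one with length, nascent S bands at amplitude
0.55, and an asymmetry parameter splitting the block intensities.  The
axial profile is multiplied by a radial Gaussian cross-section
(σ 0.25 μm), blurred with an anisotropic Gaussian PSF (σxy 0.1 μm, σz
0.3 μm — a standard confocal approximation; no image-formation parameters
are published for the original data), and degraded with Poisson shot noise
(500 photons at unit intensity) plus additive Gaussian noise.  The default
noisy fixture uses additive sd 0.02, i.e. peak SNR ≈ 18.  No published SNR
or amplitude figures exist for any channel; these defaults were chosen
once as plausible for deconvolved confocal data.

All randomness flows from one explicit seed through a documented split
(`default_rng([seed, k])` with fixed purpose indices k), so identical
seeds give bit-identical outputs and tests can re-run individual draws
independently.

Known limitations:

- The intensity model is phenomenological.  Real stainings have
  myofibril-to-myofibril brightness variation, background gradients and
  depth-dependent attenuation, none of which are rendered; passing the
  detection invariants here shows the algorithmic contract is correct, not
  that the default thresholds are optimal on real stacks.
- At the rendered amplitudes, the nascent S1/S2 Sls bands of strongly
  recruiting dividing sarcomeres are bright enough to be detected as extra
  Z-disc candidates, splitting those sarcomeres during tracing — the same
  ambiguity that makes manual curation necessary on real data.  The
  division morphometrics (landmarks, slopes) are therefore exercised on
  profile fixtures with known landmark ground truth rather than through
  stack tracing.
- Drift is rigid translation only; there is no photophysics beyond the
  stated recovery formula, and no EM synthesis.

## Problem sizes

The standard stack fixture is 3 myofibrils × 30 sarcomeres (93 Z-discs,
~4 × 11 × 134 × 1868 voxels), which the full detection-and-tracing chain
processes in a few seconds.  The acceptance computation averages 40 noisy
replicate profiles per length bin at 3 bins; permutation tests use 10³–10⁵
permutations with exact-enumeration cross-checks on instances up to
C(12, 4) placements.  These sizes were chosen to make every result cheap
to recompute from scratch while keeping Monte-Carlo error well inside the
asserted tolerances.
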
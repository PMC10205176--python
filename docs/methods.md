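# Methods

This note records the models, conventions and numerical choices behind
`petquant`, and what the synthetic cohorts do and do not establish about
real data.

## Synthetic dynamic-PET cohorts

**Acquisition.** All simulations use the 60-min, 22-frame schedule
(4 × 30 s + 4 × 60 s + 4 × 120 s + 4 × 240 s + 6 × 300 s). Frame values
are duration-weighted averages of the underlying continuous curve,
computed on a 1-s sub-grid. Image units are nominal kBq/mL; no activity
calibration, decay, attenuation or reconstruction physics is modelled —
synthetic data is defined post-correction, which is the state in which
quantification pipelines receive clinical data anyway.

**Input curve.** The reference-tissue curve is a documented
two-exponential bolus shape, `C(t) ∝ exp(-λ_w t) − exp(-λ_r t)` with rise
λ_r = 2 min⁻¹ and washout λ_w = 0.02 min⁻¹, scaled to a peak of 30 kBq/mL
by default. The blood-pool curve uses the same family with λ_r = 8 min⁻¹,
λ_w = 0.35 min⁻¹ and a 3× peak: an early, sharp, fast-clearing spike.
These shapes are chosen so the four kinetic classes are linearly
distinguishable after area normalization, the working assumption of the
supervised-cluster method.

**Tissue kinetics.** Every non-blood voxel follows the simplified
reference tissue model (SRTM),

```
C_T(t) = R1·C_ref(t) + [k2 − R1·k2/(1+BP)] · (C_ref ⊗ e^{−k2 t/(1+BP)})
```

with class parameters (R1, k2 [min⁻¹], BP): grey matter without specific
binding (1.0, 0.35, 0) — by construction identical to the reference
curve; white matter (0.5, 0.15, 0.10) — low-amplitude, lagged; grey
matter with specific binding (0.95, 0.35, 0.25). The convolution runs on
a 0.05-min grid with an exponential-kernel trapezoid recursion; the
R1-proportional term reuses frame values directly so that R1 = 1, BP = 0
reproduces the reference exactly. The implied ground-truth distribution
volume ratio of every voxel, 1 + BP, is stored alongside the image.

**Phantom geometry.** An ellipsoidal brain (≈5 900 of 32 × 32 × 16
voxels at the default grid) with a white-matter core (normalized radius
≤ 0.55), a small central blood pool, and a grey-matter shell divided into
octant sectors: six sectors are ROIs (named after cortical/limbic regions
for interface realism), two sectors are non-binding grey matter — the
ground-truth reference region, ≈21 % of the brain. The default grid keeps
a 40-subject cohort under ~5 s on one CPU; it is configurable.

**Group structure and variability.** Patients ("AD") carry a binding
elevation ΔBP = 0.08 in the superior-frontal-gyrus sector; every subject
additionally draws per-ROI BP jitter (sd 0.06) and a global amplitude
factor (sd 5 %). The texture route's effect is a multiplicative Gaussian
random field (sd 5 % of intensity, clipped below at 5 % of the unperturbed
value), smoothed with
a group-dependent kernel: σ = 1.2 voxels for controls, 1.6 for patients,
each with between-subject jitter sd 0.25. Smoothing length controls GLCM
correlation/entropy monotonically without changing mean uptake, so the
two routes receive separate, independently tunable effects. The effect
sizes were fixed once to place both classifiers in a moderate-separation
regime (single-ROI kinetic effect ≈ 1.3 between-subject SDs; LOOCV
accuracies varying roughly between 0.5 and 0.9 across master seeds)
rather than at ceiling; with deterministic per-group texture lengths the
texture classifier is perfect, which is not a regime any clinical cohort
of this kind exhibits.

**Noise.** Zero-mean Gaussian per frame with sd = noise_scale/√duration
(noise_scale default 2 kBq/mL·s^½), the standard frame-duration weighting
surrogate for reconstructed-PET noise; negative values are clipped at 0.
Determinism: all randomness flows from integer seeds through
`numpy.random.default_rng`; cohorts derive per-subject seeds from a
`SeedSequence` spawn of the master seed.

**What the generator does not emulate:** scanner resolution and
partial-volume effects, attenuation/scatter residuals, motion,
registration error, anatomical variability (all subjects share one
geometry), and realistic TSPO heterogeneity within tissue classes.
Passing tests therefore demonstrate the *correctness and calibration of
the analysis chain under its own assumptions*, not clinical performance.

## Kinetic route

**Supervised cluster extraction.** Each in-mask voxel TAC and each class
TAC is normalized to unit area under the curve (trapezoid over frame
midpoints anchored at the origin) — shape, not amplitude. The voxel shape
is decomposed against the four class shapes by non-negative least
squares; voxels are ranked by the non-binding-grey-matter weight and the
top `fraction` (default 0.1 of in-mask voxels; an absolute weight
threshold is available) form the reference mask, ties at the cutoff all
included so the result is independent of voxel ordering. The reference
TAC is the plain mean of the selected voxels' raw TACs. The NNLS step is
solved exactly by active-set enumeration: with four shared columns, every
non-empty column subset is solved once for all voxels by a precomputed
pseudoinverse, and the subset satisfying feasibility and the KKT
conditions is selected per voxel. On synthetic data the class basis is
the generator's ground truth; for real data it must be supplied as a CSV
(one column per class, one row per frame), since population bases are
site-specific.

**Logan analysis.** Cumulative integrals by trapezoid on frame midpoints
anchored at (0, 0); regression of y(T) = ∫₀ᵀC_T/C_T(T) on
x(T) = ∫₀ᵀC_ref/C_T(T) over frames with midpoint ≥ t*. Default
t* = 20 min — standard practice for a 60-min scan of this tracer family,
configurable, with an optional automatic rule (earliest time from which
the relative deviation from the final-segment line stays below 10 %).
Voxels with non-positive activity in the fit window or a degenerate
abscissa are excluded, reported as NaN and counted, never imputed. Under
the noiseless SRTM forward model the estimated DVR is within 0.1 % of
1 + BP for BP ≤ 0.5 — well inside the 5 % band the recovery test asserts.

**ROI reduction.** Arithmetic mean of finite voxels per atlas label, with
the voxel count and across-voxel SD reported.

## Texture route

Summation window 40–60 min (exactly the four late 300-s frames; a window
must align with frame boundaries to 1 s). Quantization: linear min–max
over in-mask voxels to Ng = 64 levels, `level = floor((x−min)/(max−min)·Ng)`
clamped to Ng−1; optional (0.5, 99.5) percentile clipping for outlier
robustness (off by default). GLCM: the 13 unique distance-1 3D
directions, pooled into a single matrix before normalization (per-
direction feature averaging is available behind a flag); symmetric
accumulation; pairs with either voxel outside the mask are discarded —
no padding. Features: the 14 classical statistics with base-2 logs,
0·log 0 ≡ 0, an ε = 10⁻¹² guard inside the IMC-1 logarithm, and the
maximal correlation coefficient computed as √(second-largest eigenvalue)
of Q(i,j) = Σ_k p(i,k)p(j,k)/(p_x(i)p_y(k)) after removing zero-marginal
rows/columns. Degenerate marginals make correlation and MCC undefined;
they are reported as NaN with a warning rather than silently zeroed.

Ng = 64 is a common radiomics default balancing co-occurrence sparsity
against gray-level resolution at these volume sizes; no attempt is made
to reproduce any particular published feature magnitudes, which depend on
the (usually unstated) quantization of the source images.

## Classification and comparison

The feature cap reads the 10:1 samples-per-feature rule as
floor(total n / 10) — 4 features at n = 40; the stricter per-class
reading floor(min class / 10) is available behind a flag. The correlation
filter repeatedly removes, from the currently worst pair (largest
|Pearson r| > 0.9), the member with the larger mean absolute correlation
to all remaining features, ties broken toward the alphabetically later
name; zero-variance features are dropped first. Ranking: one
L2-regularized logistic fit (C = 1) on z-scored features — light
regularization keeps the fit defined under complete separation —
importance = |coefficient|, ties alphabetical. LOOCV: per fold, features
are z-scored with the training subjects' statistics only, a linear SVM
(C = 1, configurable) is trained and the held-out subject classified;
no quantity derived from the held-out subject touches training. Metrics
use AD as the positive class. Cochran's Q is computed from the general
k-classifier formula with the denominator-zero convention Q = 0 (p = 1);
the default response entering Q is "predicted AD" (testing equality of
patient-call proportions), with "correct" available as an alternative
convention.

## Group statistics

Shapiro–Wilk per group at α = 0.05; both groups must pass for the pooled-
variance two-sample t-test (Welch optional), otherwise the two-tailed
Mann–Whitney U (exact null for n < 8 without ties, tie-corrected normal
approximation otherwise). No multiplicity correction by default, with an
optional Benjamini–Hochberg pass. Simulation places the composite
gate-then-test type-I error at ≈0.04–0.05 under Gaussian nulls at
n = (19, 21), within the ±0.03 band asserted in the tests.

## Problem sizes used in the test suite

The default phantom grid is 32 × 32 × 16 with 16 × 16 × 8 used where many
subjects are generated per test; oracle equivalence for the GLCM runs on
6 × 6 × 3 volumes at Ng ≤ 4 against a brute-force double-loop reference;
the NNLS grid-search oracle enumerates the 0.01-step unit simplex
(~1.8 × 10⁵ weight vectors), which contains the exact optimum for voxels
built as convex combinations of the class shapes; Cochran/McNemar
equivalence is exhaustive over all 2¹⁰ two-classifier response matrices
of five subjects; chance-level LOOCV uses 100 label permutations and the
type-I simulation 1000 replicates. These sizes keep the full suite and
the acceptance script to a few minutes on one CPU while leaving every
check exact or tightly Monte-Carlo bounded.

## Known limitations

* The supervised-cluster step assumes the supplied class TACs span every
  voxel's kinetics; pathology outside the four classes biases the
  reference region. Only the fraction rule and an absolute-weight
  threshold are implemented, not probabilistic class maps.
* Logan graphical analysis is noise-biased (slope attenuation with noisy
  C_T); the package reports fit R² but does not bias-correct.
* The texture features are whole-brain only by design; no
  tissue-compartment or lesion-focused texture is computed.
* LOOCV at n = 40 has high variance; single-seed accuracies of the
  synthetic pipeline scatter widely (roughly 0.5–0.9) and should be read
  as one draw, not a stable estimate.
* Cochran's Q on two classifiers with ~40 subjects has low power; a
  non-significant Q is compatible with modest true differences.
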
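# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `dwibench`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Signal model and estimation

The diffusion-weighted signal for weighting b (s/mm²) along unit direction
**n** is modelled by the cumulant expansion

    ln S(b, n) = ln S0 − b · D_app(n) + (b²/6) · MD² · W_app(n)

with D_app(n) = nᵀDn for the symmetric rank-2 tensor D (mm²/s),
W_app(n) = Σ nᵢnⱼnₖn_l W_ijkl for the dimensionless symmetric rank-4 tensor
W, and MD the mean diffusivity. Single-shell protocols identify only the
first two terms (DTI, 7 coefficients); multi-shell protocols with at least
two distinct non-zero b-values identify the kurtosis term as well (DKI, 22
coefficients).

Estimation is weighted linear least squares on log-signals: an ordinary LLS
pass, then (by default) two reweighted passes with weights equal to the
squared predicted signals — the first-order optimal weighting when magnitude
noise of SD σ maps to log-domain noise of SD σ/S. The kurtosis term is fitted
through the substitution V = MD²·W, which keeps the problem strictly linear;
W is recovered by dividing by the fitted MD². Internally b is rescaled to
ms/µm² and diffusivities to µm²/ms so every design column is O(1) and the
normal equations are well conditioned; noise-free forward/fit roundtrips
reproduce (D, V, S0) to ~1e-13 relative error.

Scalar maps: FA = √(3/2)·√(Σ(λᵢ−λ̄)²/Σλᵢ²), MD = λ̄, AD = λ₁,
RD = (λ₂+λ₃)/2 with eigenvalues sorted descending and negatives (noise)
clamped to zero; K_app(n) = V_app(n)/D_app(n)², MK = the average of K_app
over 120 quasi-uniform directions (Fibonacci sphere; doubling the set moves
MK by <0.5% on smooth phantoms), AK = K_app along the principal eigenvector,
RK = the average over 36 directions orthogonal to it. Kurtosis maps are
clipped to [−2, 10] and the clipped fraction logged.

## Acquisition protocols

Three built-in schemes mirror a two-scanner study design: a 72-volume
single-shell protocol (8×b0 + 64×b1000, 2.0 mm), a 65-volume multi-shell
protocol (3×b0 + 6×b250 + 6×b500 + 20×b1000 + 30×b2750, 2.3 mm — the
high-b shell costs SNR, conventionally compensated by the larger voxel), and
a 33-volume single-shell protocol (3×b0 + 30×b1000, 2.0 mm) standing in for
an ultra-high-field scanner with fewer directions. Default cohort sizes per
protocol are 20/63, 20/56 and 21/54 (controls/patients; unbalanced, as is
typical when patients are oversampled). Direction sets are deterministic
Fibonacci-sphere hemispheres. b ≤ 50 s/mm² counts as unweighted.

## The synthetic cohort generator

The generator reproduces the *statistical* structure of a tract-wise group
study, not anatomy:

- **Atlas.** Soft-edged tubes on a 3D grid (sigmoid falloff, plateau ≈ 1,
  radius ~1.2–1.7 voxels), placed on jittered lattice slots whose x-columns
  alternate between anterior–posterior and inferior–superior tube axes
  (orientation diversity without crossings). A left-hemisphere band is
  mirrored exactly to the right (n//3 mirrored pairs); the rest are midline
  tubes. Deterministic per seed.
- **Tissue.** Per-tract baselines drawn once per cohort (FA ~ U(0.35, 0.55),
  MD ~ U(0.70, 0.90)×10⁻³ mm²/s, MK ~ U(0.9, 1.1), AK ~ U(0.6, 0.8),
  RK ~ U(1.2, 1.6) — typical deep-WM values); left/right partners share
  baselines and per-subject deviations, since they are one anatomical tract.
  Tensors are axially symmetric along the tube axis: the FA↔eigenvalue map
  is inverted in closed form (λ = MD(1+2a, 1−a, 1−a), FA = 3a/√(3+6a²)).
  The kurtosis tensor is axially symmetric in the fiber frame with W_zzzz and
  W_rrrr set from the AK/RK targets exactly and the cross term W_xxzz solved
  linearly so the directional-average MK hits its target; it is then rotated
  into the tract frame.
- **Between-subject variability** decomposes into a global per-subject
  component shared by all tracts and an independent per-tract component;
  the shared-variance fraction defaults to 0.8 because diffusion parameters
  are strongly correlated across tracts within a subject (global physiology,
  scanner calibration). Default SDs: FA 0.02, MD 0.03×10⁻³ mm²/s, MK 0.06,
  AK 0.05, RK 0.08.
- **The designed effect** shifts the affected parameter's tract mean in the
  patient group by designed_d × between_subject_sd, so the population Cohen's
  d equals designed_d exactly by construction (default: FA lowered, the usual
  direction of WM pathology).
- **Partial volume.** Each voxel blends tract and background parameters by
  the tract probability; the background compartment (FA 0.12, MD
  0.85×10⁻³ mm²/s, kurtosis ≈ 0.7) carries its *own* independent
  between-subject variability, so smoothing dilutes group contrast faster
  than it shrinks the between-subject SD — the mechanism behind the dominant
  "effect size declines with smoothing" pattern.
- **Baseline (T2-like) contrast.** S0 is ~20% darker inside tracts than in
  background and is multiplied by a per-subject anatomy texture: a smooth
  random field (SD 0.12) plus a few bright sharp-edged inclusions placed
  outside the tracts (CSF-like landmarks). The texture multiplies every
  volume identically and therefore cancels out of all diffusion parameter
  estimates; its sole role is to give the volumes the shared anatomical
  detail that image registration relies on in real brains.
- **Artifacts.** Rician noise (per-voxel sqrt((S+ε₁)²+ε₂²), σ = mean b0
  signal / snr_b0; the rectified floor gives a zero signal the mean
  σ√(π/2)); slice-wise k-space truncation to a central fraction (Gibbs
  ringing); per-volume rigid motion plus eddy-current shear/scale along the
  phase-encode axis (y) proportional to the volume's gradient amplitude
  along that axis, so b0 volumes get motion only. Motion is expressed
  relative to the initial head position (the first b0 keeps identity).
  When the tissue model is available, motion injection is physically
  consistent: a rotated head sees the scanner gradient along Rᵀn, so the
  volume is re-simulated with the rotated encoding before resampling.
  Ground-truth transforms are recorded for recovery tests.

What passing tests on these cohorts do *not* show about real data: there is
no anatomy (no crossing fibers, no CSF contamination of tracts, no
susceptibility distortion), noise is stationary, segmentation is exact by
construction (per-subject segmentation variability is available only as an
optional probability-map jitter), and protocol differences beyond geometry
and direction count (TE-driven SNR differences between protocols) must be
injected explicitly through `snr_b0`.

## Processing steps

- **MPPCA denoising.** For every sliding 5×5×5 patch (125 samples ≥ the
  volume count of all built-in protocols) the volume-by-volume second-moment
  matrix XXᵀ/M is eigendecomposed; with eigenvalues λ₁ ≤ … ≤ λ_N, the q
  smallest are classified as noise when their spread fits the
  Marchenko–Pastur support width for their mean, λ_q − λ₁ < 4√(q/M)·mean(λ₁…λ_q),
  taking the largest such q; the mean estimates σ². Noise components are
  suppressed and overlapping patches averaged. On pure Gaussian noise the
  median σ̂ is within a few percent of truth; rank-1 data pass through at
  machine precision.
- **Gibbs unringing.** Kellner-style subvoxel shifts: each axial slice is
  split into two k-space-weighted images ((1+cos k_other)/((1+cos kx)+(1+cos ky))
  assigns each in-plane axis the frequencies it dominates); along each axis,
  shifted copies at s = k/(2M), k = −M…M are generated with the Fourier
  shift theorem, each sample adopts the shift minimizing a one-sided
  oscillation measure (sum of |first differences| over 1..window neighbours,
  smaller of left/right), and the value is linearly interpolated back to the
  grid. Defaults M = 20, window = 3.
- **Motion/eddy correction.** Per-volume transform restricted to rigid plus
  phase-encode shear/scale. b0 volumes are registered rigidly to the first
  b0; diffusion-weighted volumes are initialized against the averaged-b0
  reference and then refined in model-based rounds: a WLLS fit of the
  current corrected data (with per-volume-rotated b-vectors) predicts each
  volume's own contrast via leave-one-out, and the volume is re-registered
  against its prediction. Each round also estimates one global residual
  transform of the mean corrected DW volume against the b0 reference
  (a "gauge fix": a rotation common to all DW volumes is invisible to
  model-predicted references because the fit follows it). The similarity is
  normalized cross-correlation over an interior mask (border excluded so
  out-of-field voxels cannot bias the optimum), optimized with bounded
  Powell on lightly presmoothed volumes; volumes are resampled once, from
  the raw data, with cubic splines, and b-vectors are rotated by the
  estimated rigid part. A parsimony threshold (`min_gain`) optionally
  requires a minimum similarity gain before a transform is adopted, which
  leaves artifact-free data bit-identical.
- **Smoothing.** Per-volume 3D Gaussian, SD in voxel units (the
  resolution-relative interpretation, which keeps the sweep comparable
  across protocols with different voxel sizes), reflecting boundaries (sum
  conserved). Smoothing is applied after segmentation masks are fixed and
  immediately before fitting; masks are never smoothed.
- **Pipelines.** The 8 subsets of {MPPCA, Gibbs, Eddy}, always applied in
  that fixed order (the conventional order of the optimization literature:
  denoise before interpolating operations, unring before resampling).
  Step-prefix results are cached per subject so the enumeration reuses
  shared work, and all pipelines of a protocol see the same cohort and the
  same noise realizations (pipeline deltas are paired comparisons).

## Tract statistics and QC

Per tract, voxels with probability ≥ 0.5 contribute with weight p:
mean = Σpx/Σp and SD = √(Σp(x−mean)²/Σp) (population form; an unweighted
variant is available — the weighting of the SD is a documented choice, as
only "probability-weighted mean and SD" is conventionally specified). Both
mean and SD are carried downstream as separate features. Left/right pairs
are averaged into one merged tract before effect sizes (72 → 41 in the
full-size naming scheme). Tract-volume QC computes, over controls only, the
coefficient of variation (sample SD / mean) of the merged tract volume
(voxels with p ≥ 0.5 × voxel volume — the same inclusion rule as the
statistics, for internal consistency) and excludes tracts with CoV > 0.25.
Exclusion is monotone in the threshold; zero-volume occurrences are excluded
with a reason.

## Effect sizes and significance

Cohen's d uses the pooled SD with n−1 weights. The null threshold for |d| is
the edge of the central (1−α) interval of the null sampling distribution —
Monte-Carlo over 200,000 two-group standard-normal replicates by default, or
the central-t closed form t_{1−α/2,df}·√(1/n₁+1/n₂); the two agree within
Monte-Carlo error (~0.52 at the built-in cohort sizes, slightly below the
conventionally quoted 0.53–0.54). No multiple-comparison correction is
applied by default; the Bonferroni-corrected level (1 − 0.05/72 ≈ 99.9%) and
the exact binomial family-wise bound (P(more than 7 of 72 false positives at
5%) = 0.027 < 0.05) are reported alongside. Step impact Δ(step) averages,
over the four matched pipeline pairs (P∪{step} vs P∖{step}), the difference
in tract-averaged d, per parameter × feature, with equal pair weights (the
exact averaging being a documented choice), plus grand means across
parameters. Smoothing sweeps are classified into four patterns: monotone
decline, little influence (range < 0.01), rise to an interior peak then
decline (peak σ reported), or overall rise.

## Problem sizes

The shipped tests run the full chain at deliberately small scale — grids of
16³–24³ voxels, 5–12 tracts, cohorts of 11–76 subjects, up to 20 replicates,
and subsampled direction sets where only the machinery (not angular
resolution) is under test; the study-condition quantities themselves
(designed d, group-size ratios, noise levels, artifact magnitudes, the
0.5-probability floor, the 0.25 CoV limit, the 0–1 smoothing sweep) are kept
at full fidelity.

## Known limitations

- Rotation recovery of the motion correction plateaus around 1° per volume
  on these small grids. The cause is structural, not numerical: against
  *oracle* references the same registration recovers rotations to <0.15°,
  but any model-predicted reference inherits a smooth per-direction pose
  error field from the fit (the fit has ~7 free parameters per voxel and
  absorbs it), so the model-based fixed point is biased at the ~1° level.
  Translations recover to <0.25 voxels. On realistically sized brains the
  anatomical information per degree is an order of magnitude larger and this
  floor drops accordingly.
- The DKI quadratic is used as-is within each scheme's b-range; for
  physically extreme kurtosis the log-signal can curve upward near b_max
  (the usual validity bound K_app ≤ 3/(b_max·D_app) is the caller's
  responsibility; the sampler stays inside it).
- The eddy model has no susceptibility/field-map component, and no outlier
  rejection or harmonization is implemented anywhere (per-protocol analyses
  never mix scanners).
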
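# Methods

This note documents the algorithms, the parameter defaults (with units and
the reason for each choice), the synthetic generative model and its realism
limits, and the numerical decisions made in `pullstorm`. Every empirical
number quoted here was computed with this package (the test suite and
`scripts/acceptance.py` recompute them).

## 1. Imaging model (`pullstorm.synthetic`)

### Acquisition defaults (`AcquisitionParams`)

| parameter | default | unit | rationale |
|---|---|---|---|
| `pixel_size` | 103.5 | nm/px | EMCCD pixel pitch of the emulated TIRF setup |
| `fov_side` | 483 | px | 483 × 103.5 nm ≈ 50 µm ⇒ FoV area ≈ 2500 µm² |
| `n_frames_dl` | 50 | frames | diffraction-limited stacks are short; spots are immobile |
| `n_frames_storm` | 8000 | frames | dSTORM acquisitions need thousands of blink events |
| `n_fov_dl` / `n_fov_storm` | 16 / 4 | — | counts accumulate over 16 FoVs per target |
| `psf_sigma` | 130 | nm | Gaussian PSF sd ≈ λ/(2π·NA)·k for visible light at NA ≈ 1.49 |
| `camera_gain` | 250 | ADU/photon | EM gain regime of an EMCCD |
| `camera_offset` | 100 | ADU | bias level |
| `read_noise` | 50 | ADU | post-gain effective read noise |

The camera is linear: `ADU = Poisson(photons)·gain + offset + N(0, read_noise)`,
clipped at zero. Aggregates are sets of point emitters sampled uniformly over
the true shape support (discs for round aggregates; randomly oriented
rectangles with aspect ratio drawn in [6, 12] for fibrils — a w×ℓ rectangle
has circularity π·(ℓ/w)/(1+ℓ/w)², below 0.4 for any aspect above ≈5.6).
Emitter density defaults to 1 per 200 nm² of support.

### Localization streams (`simulate_storm_table`)

Emitters blink with a two-state model: the number of bursts per emitter is
Poisson (`mean_bursts` = 3), burst lengths are geometric
(`mean_on_frames` = 2), burst start frames uniform over the acquisition. Each
active frame yields one localization at the emitter position plus isotropic
Gaussian localization error (`loc_error_nm` = 20, the typical dSTORM
precision), translated by the cumulative stage drift at that frame (linear
ramp plus optional random walk). Uniform false localizations are added at
`background_per_um2_frame` = 1e-4. Tables carry the interchange schema
`frame, x, y, sigma, intensity, uncertainty` (nm, photons).

### Cohort model (`CohortSpec`)

Per participant, an abundance factor is log-normal (`participant_log_sd` =
0.3), the αS/Aβ count ratio is log-normal around the group median
(`ratio_location`: 1.056 for PD, 0.48 for control — a 2.2-fold contrast;
`ratio_dispersion` = 0.7), and the fibrillar weight of the Aβ shape mixture is
Beta-distributed around the group mean (0.12 PD vs 0.06 control) with
concentration `weight_concentration` = 30. Counts per FoV are Poisson.

The dispersion parameters are calibrated to published discrimination
performance rather than invented: σ_log = 0.7 makes the ratio-alone ROC AUC
between two groups of 10 equal Φ(δ/(σ√2)) ≈ 0.79, and the concentration 30
makes the *simulated* morphology-proportion AUC ≈ 0.76 — including the
binomial counting noise of classifying ~10² aggregates per participant, which
a naive delta-method calibration (concentration 15) had neglected. With these
two calibrated marginals the combined discriminator reaches a mean AUC of
0.85 over 100 seeded cohorts and exceeds the ratio-only AUC in 79% of seeds.

### Realism limits of the generator

- Emitters are uniform over the support; real fibrils have inhomogeneous
  epitope accessibility and labelling stochasticity.
- Blinking is memoryless; real dSTORM photophysics shows power-law off-times
  and photobleaching over the acquisition.
- The PSF is an isotropic Gaussian; no astigmatism, aberration or depth
  dependence.
- Drift is a smooth ramp (optional random walk); no vibration spikes or
  thermal jumps.
- Participant biology reduces to three latent scalars (abundance, ratio,
  fibril weight); no age/sex/comorbidity structure, no assay batch effects.

## 2. Diffraction-limited counting (`pullstorm.counting`)

Each 50-frame stack is mean-projected (spots are immobilized, so averaging
raises SNR ∝ √frames). The projection is decomposed with an à-trous B-spline
wavelet (order 3, two levels; separable kernel [1,4,6,4,1]/16, holes at
stride 2 in the second level, symmetric boundaries). The decomposition is
additive: `frame = smooth + F1 + F2` to float precision. The detection image
is the second detail plane **F2**; candidates must exceed the hybrid
threshold

```
0.5 · std(Wave.F1)  +  0.1 · mean(Med.F)
```

(F1 tracks pixel noise, the 3×3-median-filtered mean tracks uniform
background). Spots are 8-connected maxima of F2 with a 2-pixel
non-maximum-suppression radius and a 3-pixel border exclusion. Measured on
synthetic SNR-10 stacks, recall and precision are both 1.0 (72 spots over 6
FoVs), and pure-noise stacks yield zero detections.

## 3. Localization post-processing (`pullstorm.storm`)

The chain order is fixed:
trim → (localize) → drift correction → blink merging → density filter →
rendering → mask regularization → segmentation/morphometry.

**Trim.** The first 200 frames are discarded (focus/illumination settling).

**Localization** (when starting from raw frames). Per-frame wavelet detection
(same filter as counting) followed by least-squares 2-D Gaussian fits in 7×7
px windows; photons = 2π·A·σ²/(gain·px²); the precision column follows the
Thompson scaling `unc² = s_a²/N + 8π·s_a⁴·b²/(px²·N²)` with
`s_a² = σ² + px²/12`. On a synthetic SNR-10 blinking spot the empirical
per-axis precision is ≈15 nm, inside the expected 10–30 nm regime.

**Drift estimation.** Frames are split into 10 equal bins. For every bin pair
the modal displacement of nearest-neighbour localization pairs (pairing
window 200 nm) is found by annealed mean shift (bandwidth 3h → h, h = 20 nm
— the localization precision scale). A first sequential pass over consecutive
bins provides a coarse trajectory used to recentre the pairing windows; the
redundant all-pairs displacement matrix is then solved for per-bin offsets by
least squares (bin 0 pinned), and the per-frame track is linear interpolation
between bin midpoints, anchored at zero for frame 0. Pairs are capped at
20 000 per bin pair by a deterministic subsample for speed. On a dense test
scene (49 discs, ≈40 000 localizations), a 100 nm linear ramp is recovered
with < 10 nm maximum error (4.1 nm at the acceptance seed) and a no-drift
scene stays within the same bound.

**Blink merging.** Localizations within 50 nm in consecutive frames are
chained (gaps of up to 3 missing frames allowed) and collapsed to their
photon-weighted mean; photons sum, the first frame is kept.

**Density filter.** Localizations with fewer than 5 neighbours within 50 nm
(all frames pooled) are discarded as false localizations.

**Rendering.** A binarized 2-D histogram with 10 nm bins, half-open
`[k·px, (k+1)·px)`, origin at the FoV corner.

**Mask regularization.** A binarized histogram of a finitely sampled
structure is dotted and ragged; its Crofton perimeter grossly over-estimates
boundary length and collapses the circularity of genuinely round objects
(measured ≈0.15 for discs on raw masks). The mask is therefore closed with a
3-px (30 nm) disc and eroded by 2 px (20 nm) before measurement. With this
step discs measure circularity ≥ 0.69 and fibrils ≤ 0.39 on synthetic scenes,
and measured areas land within 30% of truth; both `close_px` and `erode_px`
are exposed in the configuration (0 = raw mask).

**Morphometry.** 8-connected components of the regularized mask; area = pixel
count × (10 nm)²; perimeter = Crofton 4-direction estimate; circularity =
4π·area/perimeter², clamped to 1. Components with fewer than 10 assigned
localizations are discarded as under-sampled. Note the Crofton estimator is
itself biased for polygonal shapes: an axis-aligned square converges to
circularity ≈ 0.875 (not π/4 ≈ 0.785); discs converge to ≥ 0.95. The
0.4 classification threshold is far from both, so the bias does not affect
class assignment; across 18 synthetic aggregates the full chain classifies
100% correctly.

## 4. Cohort statistics (`pullstorm.stats`)

All tests are two-tailed at α = 0.05, uncorrected (single pre-specified
hypotheses).

- **Gated two-group comparison.** Shapiro–Wilk on both samples; if both pass,
  Levene's test (mean-centred) selects Student's t (homoscedastic) or
  Welch's t, with Cohen's d = t·√(1/n₁+1/n₂) and a t-based 95% CI of the mean
  difference. Any normality rejection selects the Wilcoxon rank-sum
  (Mann–Whitney) test with effect size r = |Z|/√N, where Z standardizes W
  against mean n₁n₂/2 and sd √(n₁n₂(n₁+n₂+1)/12) with no continuity or tie
  correction — the convention that reproduces the published worked values
  r(79, 10, 10) = 0.490, r(118, 20, 20) = 0.351, r(41, 17, 18) = 0.625 — and a
  Hodges–Lehmann 95% shift CI.
- **Morphology thresholds.** The empirical CDFs of pooled disease and control
  aggregate features are subtracted on the union grid of observed values; the
  maximizer of the oriented difference (control−disease for area,
  disease−control for circularity; ties to the smallest value) is the
  threshold. Defaults: area > 0.03 µm² and circularity < 0.4 for Aβ, area
  > 0.02 µm² for αS. Verified identical to exhaustive search on hundreds of
  random instances.
- **ROC.** Thresholds are midpoints of sorted unique scores extended by ±∞;
  a case is positive when score ≥ threshold; AUC is the trapezoid integral,
  exactly equal to the Mann–Whitney U/(n₁n₂) (ties count one half; verified
  to 1e-16 over 1000 random instances). The operating cutoff maximizes
  Youden's J with ties broken toward the smallest threshold.
- **Logistic regression.** Maximum-likelihood fit (delegated to a standard
  MLE implementation), Wald z per coefficient, McFadden pseudo-R² =
  1 − lnL/lnL₀, likelihood-ratio χ² against the intercept-only model; perfect
  separation is detected and flagged rather than reported as a finite fit.
- **Auxiliary tests.** Pearson and Kendall tau-b correlations, Pearson χ²
  (no continuity correction), Dunn's rank-based pairwise comparisons with tie
  correction and Bonferroni adjustment.
- **Front end.** `CohortModel(summaries).fit()` runs the gated comparison and
  ROC for each measure (counts, ratio, morphology proportions,
  discriminator) and returns a `CohortResults` with a `summary()` table.

Participants with zero Aβ counts (undefined ratio) are flagged invalid and
excluded from group tests; the pipeline logs each exclusion with the
participant id, as are FoVs whose localization tables are too small for drift
correction (< 500 rows by default).

## 5. Numerical and engineering choices

- Wavelet filtering uses separable `convolve1d` with reflect boundaries;
  exact additivity of the planes is asserted in the tests.
- Gaussian fits use bounded least squares; diverged fits and fits leaving the
  window are dropped rather than clipped.
- Mean shift anneals the bandwidth (3h → h) to avoid capture by side lobes of
  the pairwise-displacement distribution; the all-pairs least-squares step
  (solved with `lstsq`, bin 0 pinned) averages out residual per-pair error.
- All randomness flows through `numpy.random.default_rng(seed)`; a fixed seed
  makes every artifact byte-identical (tested), including TIFF output.
- CSV numeric formatting is fixed (`%.4f` for localization tables) so that
  round-trips and byte-comparisons are stable.

## 6. Limitations

- The drift estimator requires a few thousand localizations per temporal bin;
  sparse FoVs are excluded (logged) rather than estimated poorly.
- Crofton perimeters are grid-biased (see §3); circularities of compact
  non-circular polygons cluster near 0.875 rather than their continuum
  values. Classification at the 0.4 threshold is unaffected.
- The published cohort results depend on the original participant data, which
  are not available; cohort-level claims are therefore validated as
  *properties* on synthetic cohorts (direction, calibration, ordering of
  AUCs), not as numeric equalities. Only the printed worked values
  (effect sizes, folds) are reproduced numerically.
- The generator's calibration targets (ratio AUC 0.79, morphology AUC 0.76)
  fix second moments only; higher moments of real participant distributions
  are not modelled.
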
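# Methods

## The representation

A macular pigment (MP) map is a square matrix (default 81×81) of pigment
concentration values in [0, 1] covering a 4-degree-eccentricity patch
centred on the foveola. The pixel patch is mapped to the unit disk
(pixel-centre coordinates, boundary pixel kept iff ρ ≤ 1 exactly) and
modelled as a truncated Zernike expansion

    MP(ρ, φ) ≈ Σ_j C_j Z_j(ρ, φ),   j = 0 … J−1,  J ≤ 105,

where Z_j is the product of the radial polynomial R_n^|m|(ρ) and cos(mφ)
(m ≥ 0) or sin(|m|φ) (m < 0). No normalisation factor is applied, so
|Z_j| ≤ 1 on the disk and coefficients share the amplitude scale of the map
values. J = 105 covers all complete radial orders n = 0…13.

Two sequential orderings of the same 105 functions are supported: the
OSA/ANSI index j = (n(n+2)+m)/2 (default) and a zero-based Noll ordering
(`noll0`, classical Noll minus one, under which defocus is term 3 and
primary spherical term 10). They are pure column permutations of each
other; fits and reconstructions are equivalent under either, and the
magnitude/asymmetry/irregularity categorisation is defined on (n, m), not
on j, so it is convention-independent.

Azimuth convention: φ is measured counter-clockwise from the +x image axis
with the row index increasing downward (+y up the image). This matters
only for the sign/orientation of asymmetry coefficients, never for their
energy.

## Fitting

The model is linear in C, so the production fit is a dense linear
least-squares solve (`numpy.linalg.lstsq`) on the n_pixels × J design
matrix of basis values at the in-disk pixels (5025 pixels × 105 columns at
the default geometry; the design is full-rank and cached per geometry).
Quasi-Newton (L-BFGS with analytic gradient) and Levenberg–Marquardt
solvers exist only inside the optimiser benchmark; all three recover
self-generated fields to machine precision, and least squares is the
default because it is exact, deterministic and orders of magnitude faster.

Error metric: normalised RMSE over in-disk pixels, normaliser selectable
among the reference's range (default), mean or max. A constant reference
degrades the range normaliser; it then falls back to max with a warning.
Coefficient agreement uses a Hamming distance on vectors normalised by the
reference's maximum absolute amplitude, counting entries differing by more
than 0.01.

The benchmark (`evaluate_optimizers`) draws i.i.d. uniform[−1, 1]
coefficient vectors, evaluates the field on the disk grid and affinely
rescales it to [0, 1] (the rescale maps exactly onto the piston term, so
the adjusted generating vector remains ground truth). Accuracy is the mean
noise-free refit nRMSE over trials; robustness the standard deviation of
the nRMSE after adding noise of amplitude 10% of the field range (Gaussian
default; uniform selectable since both conventions appear in the
literature for this protocol); uniqueness the mean Hamming distance.
Noise-free linear least squares is exact, so the reported accuracy is at
numerical precision (~1e-15) and uniqueness is 0.

Reconstructions set out-of-disk pixels to NaN (documented sentinel).

## Synthetic phantoms

`synthetic_data` emulates the three group patterns qualitatively:

| parameter | group 1 | group 2 | group 3 | meaning |
|---|---|---|---|---|
| peak_amplitude (A.U.) | 0.55 | 0.40 | 0.30 | raised-Gaussian central peak height |
| peak_width (fraction of disk radius) | 0.35 | 0.35 | 0.40 | Gaussian σ |
| centre_offset (px) | 0.5 | 1.0 | 1.5 | radial peak displacement (random direction) |
| asymmetry_amplitude (A.U.) | 0 | 0.08 | 0 | ρ·cos(φ−θ) modulation |
| irregularity_amplitude (A.U.) | 0 | 0 | 0.06 | high-\|m\| (≥3) Zernike texture |
| peripheral_baseline (A.U.) | 0.15 | 0.15 | 0.25 | flat pedestal |
| noise_sd (A.U.) | 0.02 | 0.02 | 0.02 | i.i.d. Gaussian pixel noise |

These defaults are a one-time calibration chosen so the group contrasts
echo the reported qualitative findings (higher, more peaked MP under 50;
radial asymmetry in the older disease-free group; elevated periphery and
irregular texture with disease); they are generator knobs, not measured
quantities.

Design choices worth knowing:

- The central peak is a raised Gaussian, deliberately **outside** the
  Zernike span, so representation-accuracy results are not circular; the
  fitted ε is genuinely nonzero, as for real maps.
- The asymmetry orientation θ and the irregularity component set are
  **population-level** draws: a cohort draws them once (uniform angle;
  4 components with |m| ≥ 3, n ≤ 9, random weights) and jitters them per
  subject (orientation sd 0.2 rad). If instead every subject drew its own
  orientation/template, group means would coincide and no mean-based
  statistic (two-sample t, LDA) could detect the planted contrast — the
  phantom would be unfaithful to the systematic anatomical patterns it
  stands in for. Per-map generation outside a cohort still draws them
  randomly.
- Zernike-derived components are evaluated with ρ clamped at 1 outside the
  disk so the square map's corners stay bounded; fitting only ever sees
  in-disk pixels, where the components are exact basis functions.
- Per-subject variability is multiplicative log-normal jitter with CV 20%
  on all nonzero amplitudes. Maps are clamped to [0, 1]; a parameter set
  clamping more than 20% of pixels is rejected as out of range.
- The ground-truth record carries every realised draw, and
  `reconstruct_truth` rebuilds the noise-free phantom exactly from it.

What the phantoms do **not** emulate: drusen morphology, imaging
point-spread and vignetting, inter-eye correlation, the smoothing the
map-inversion method applies to real data, and any quantitative group
effect sizes. Passing the synthetic pipeline therefore demonstrates the
machinery (representation, ranking, classification) recovers planted
structure of the stated kinds — it does not certify real-data accuracy
figures.

## Classification

The four binary tests are fixed as 1&2 vs 3, 2 vs 3, 1 vs 2&3 and 1 vs 2,
with the later-listed side as the positive class (configurable; recorded
in every report).

- **LOO-LDA**: linear discriminant analysis with Ledoit–Wolf shrinkage of
  the within-class covariance (lsqr solver), needed because ~105
  correlated features against tens-to-hundreds of samples is
  ill-conditioned. Leave-one-out operates on images by default; a
  subject-level option leaves all of one subject's images out together to
  avoid leakage when subjects contribute several images.
- **PRNN**: a single-hidden-layer feedforward pattern-recognition network
  (standardised inputs, ReLU, default 100 hidden units) trained per repeat
  on a random 70/15/15 train/validation/test split, 100 repeats by
  default; the report carries the mean and the accuracy-maximal triple.
  The default solver is full-batch L-BFGS with the validation fraction
  held out: at these sample sizes (validation ≈ 10 samples) stochastic
  training with early stopping is dominated by the granularity of the
  validation score and reproducibly underfits, so early stopping is
  engaged only when an `adam`/`sgd` solver is chosen. Degenerate splits
  that empty a class are resampled and logged.
- **Selection**: hyperparameter grids are scored by seeded stratified
  5-fold cross-validation and chosen by the ROC operating point closest to
  (sensitivity, specificity) = (1, 1), ties to higher accuracy then
  smaller model; infeasible grid points are logged and excluded.

## Ranking, MANOVA, baseline

Coefficients are ranked by the absolute two-sample (two-tailed,
pooled-variance) t-statistic. Zero pooled variance falls back to +inf when
the class means differ (ranked first) and −inf otherwise (ranked last).
The leave-one-out consensus recomputes the ranking with each sample
removed and takes the per-position mode; an index that wins several
positions keeps its earliest, the vacated position falling to the
next-most-frequent unused index there, ties to the smaller index.

One-way MANOVA computes Wilks' Λ = det(W)/det(W+B) from within/between
scatter matrices, with a Ledoit–Wolf-style shrinkage of W towards the
scaled identity whenever residual degrees of freedom do not exceed the
feature count (logged; the estimator matches the LDA shrinkage); p-values
use Bartlett's chi-square approximation. An exactly singular W yields
Λ = 0.

The conventional baseline representation per map is (peak, total): the
in-disk maximum and the integral with pixel area (2/size)² in unit-disk
units. On the default synthetic cohort Λ on the 105-coefficient
representation is far smaller (stronger separation) than Λ on the
baseline pair — the property-based form of the coefficient-vs-scalar
contrast.

## Problem sizes and determinism

Tests and the acceptance script run at the study's native desk scale: 81×81
maps, J = 105, 30 subjects per group (90 maps) for the cohort properties,
15 per group for the single-contrast ranking cohorts, 10 trials for the
optimiser benchmark. Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); the CLI fans one global seed into per-stage
substreams via `SeedSequence` with a CRC-derived stream key, so stages are
independently reproducible.

## Known limitations

- Discrete orthogonality: the basis is orthogonal in the continuum but only
  approximately on an 81×81 pixel disk; fits are well-posed regardless
  (full-rank design), and the Gram off-diagonals shrink with grid
  refinement.
- Real-data headline figures (accuracies near 0.8, Λ = 0.125/0.899) belong
  to the deposited cohort, which is an optional download; nothing in this
  package asserts them on synthetic data.
- The t-statistic ranking is a filter on means; contrasts expressed purely
  in coefficient variance are invisible to it (and to LDA), which is
  precisely why the phantom plants population-consistent patterns.
- Image inputs are linearly rescaled per image to [0, 1]; a cross-image
  common scale, if required, must be applied upstream (the scaling applied
  is recorded in map metadata).
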
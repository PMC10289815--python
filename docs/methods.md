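# Methods

## Problem and model

Olive fruit accumulate oil roughly sigmoidally and phenols parabolically
over the weeks following pit hardening, while the skin colour moves from
green through purple to black. `olivescan` models the two quality traits
as nonlinear functions of 35 scalar colorimetric indexes derived from
the mean R, G, B pixel values of the segmented fruit region, using
single-hidden-layer feed-forward networks trained by resilient
backpropagation, and compares three input encodings of the same
information (all indexes, PC scores, sparse-PCA-selected indexes) under
a shared repeated hold-out protocol.

## Synthetic benchmark

The generator emulates a seasonal trial with three cultivars spanning
early, middle and late ripening groups. Per cultivar and time `t` (days
after pit hardening, DAPH; default window 28–112):

* oil(t) = base + (max − base) / (1 + exp(−rate·(t − midpoint))),
  base 5.5 %FW, max 18–22 %FW by cultivar, midpoint 75 DAPH, rate
  0.1 day⁻¹. The logistic captures the early plateau and late
  saturation of the observed roughly linear mid-season rise.
* phenols(t) = peak − curvature·(t − peak time)², truncated at 0;
  peak 41 (high-phenol cultivar), 32 and 28 mg GAE g⁻¹ DW, peak time
  55 DAPH, curvature 0.012 mg day⁻².
* each channel follows peak − curvature·(t − peak time)² clamped to
  [0, 255]; peaks near (150, 130, 60) with per-channel peak times
  (40, 45, 55) DAPH. Distinct per-channel peak times make the joint
  (R, G, B) → t map invertible, so the traits are identifiable from
  colour alone in the noiseless limit. Ripening groups shift the
  channel peak times by −10/0/+10 days (early/middle/late).
* additive, independent Gaussian noise: SD 2.5 (channels), 0.8 %FW
  (oil), 2.0 mg GAE g⁻¹ DW (phenols). No per-sample variance figures
  are available for the motivating study; these are plausible
  magnitudes relative to the trait ranges, chosen once.

The default benchmark uses 17 times × 3 replicates = 51 samples per
cultivar (matching the magnitude of a season's image count per
cultivar). The renderer draws non-overlapping ellipses with the
sample's base colour (plus optional per-fruit jitter) on a saturated
blue background, RGB (30, 60, 160), chosen so the CIELAB *b\** of the
background is strongly negative (≈ −57) while fruit tissue is not.

What the generator does **not** emulate: illumination gradients,
vignetting, JPEG artifacts, fruit occlusion, specular highlights,
within-fruit colour gradients, and year effects. Passing tests
therefore demonstrate correctness of the pipeline mechanics and
achievable accuracy under clean, well-posed conditions — not field
performance.

## Imaging

White balance multiplies each channel by `255 / patch mean`, computed in
real arithmetic, then clips to [0, 255] and rounds half-up. Segmentation
converts sRGB to CIELAB (D65, 2°) and thresholds *b\**: pixels below the
threshold (default −15) are background. A fixed threshold replaces the
interactive auto-threshold of GUI tools because it is reproducible; an
Otsu-on-*b\** option is available. A morphological opening (disk radius
2) and removal of components below `min_area_px` (default 16) follow;
an optional white-patch rectangle is always forced to background.
Channel means are unrounded arithmetic means over mask pixels.

## Colorimetric indexes

All 35 indexes are computed from the ROI means, never per pixel. Any
zero denominator yields NaN (an undefined flag), not an exception;
imputation (training-split column median) happens only at modelling
time. Two dialects exist because several published formulas contain
typesetting artifacts: the default `interpreted` dialect reads the hue
constant `30.5` as √3 and lightness L as (R+G+B)/3; `as_printed`
evaluates every formula exactly as typeset. Two formulas (BIM's doubled
channels, HUE2's collapsed numerator) have no obvious canonical form
and are kept as printed in both dialects rather than guessing intent.

## Dimensionality reduction

Features are standardized with training-split means/SDs; zero-variance
columns are dropped with a warning. PCA eigendecomposes
XᵀX/(n−1) of the standardized block and retains the smallest k whose
cumulative variance fraction reaches the cutoff (default 0.85, "≥"
rather than "close to" for determinism). Loadings follow the sign
convention that each column's largest-magnitude entry is positive.

The sparse PCA enforces a per-component cardinality (NNZL) rather than
an L1 penalty, because target counts are the natural parameterisation
here: alternating between (a) a ridge step per component (quadratic
penalty 1e−6; the Gram matrix is Cholesky-factorised once) followed by
hard-thresholding to the NNZL largest-magnitude coefficients, and (b)
an orthogonal Procrustes update of the orthonormal basis via SVD of
XᵀXB, for at most 200 iterations or until the max change of the
unit-normalised loadings falls below 1e−6. Adjusted explained variance
comes from the QR decomposition of the sparse scores (squared diagonal
of R over (n−1), as a fraction of total variance), so correlation among
sparse components is not double-counted. At full cardinality and
vanishing ridge the procedure reduces to PCA (verified in tests).

The per-component NNZL is chosen by a small genetic algorithm over
integer chromosomes in [1, p]^k: tournament selection (size 3), uniform
crossover (0.8), ±1-step integer mutation (0.1), elitism (1 member),
population 20, 50 generations, mandatory seed. The fitness trades
explained variance against cardinality:

    fitness(c) = APEV(c) / CPV_pca − w · Σc / (k·p),    w = 0.5

where APEV is the sparse fit's adjusted explained variance and CPV_pca
the retained-PCA cumulative variance. The functional form was an open
design choice; this one is brute-force verifiable at small p (the GA
provably matches exhaustive enumeration in the tests) and reproduces
the qualitative outcome that most variables are kept and a handful
zeroed. Variables with a nonzero loading in any sparse component are
retained once (union rule).

## Network and training

One hidden layer, logistic activation, one linear output node; hidden
width round-half-up(N/3 + 2). Targets are min–max scaled to [0, 1] on
the training split; the output is linear (rather than logistic) to
avoid saturation at trait extremes, with predictions mapped back to
original units. Weights start uniform(−0.5, 0.5) from a mandatory seed
— initialisation is the one uncontrolled random component of this model
family, so it is always logged. Training is Rprop+ on the summed-
squared-error gradient: η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δ ∈ [1e−6, 50],
stopping when max |∂E/∂w| < 0.01 or after 10 000 epochs (the de-facto
defaults of the resilient-backprop literature). Non-convergence at the
epoch budget is flagged in the report, not fatal. The error trace may
oscillate (Rprop is not monotone) but the final error never exceeds the
initial one.

## Evaluation protocol

Per cultivar × trait: five random 70/30 splits (|train| = floor(0.7·n))
derived from one master seed, identical across the three variants. Per
split, the feature medians (imputation), standardizer, PCA projection,
GA + sparse-PCA selection and target scaling are all fitted on the
training block only — an instrumented test asserts no test row ever
reaches a fitting routine. Metrics: R² as the squared Pearson
correlation of observed and predicted; RMSE with the n−1 denominator
(kept as published even though n is the conventional choice); MAE. The
GPI normalises each indicator min–max over all model × iteration cells
of the scenario, takes medians over the same cells, and sums signed
deviations over iterations and indicators (−1 for R², +1 for errors);
a constant indicator is set to 0.5 everywhere (contributing zero) with
a warning. Ranks are assigned by descending GPI with ties broken by
model registration order (BPNN, PCA_BPNN, SPCA_BPNN). Residuals
(observed − fitted on test sets) are pooled over the five iterations;
diagnostics report IQR, SD, the ±2 SD band about the residual mean and
a LOWESS smooth (span 0.75) of residual versus fitted value.

## Known limitations and numerical notes

* With the 0.85 cutoff the PC-score variant may retain a single
  component; a 1-D linear projection of the ripening curve can fold
  over (two times with the same score), capping that variant's accuracy
  even on noiseless data (observed ≈0.85 R² there, versus ≥0.99 for the
  other variants). This is a property of the method, not a defect.
* VARI and the hue-like indexes are unbounded near their degenerate
  denominators; only GLI/NGRDI/SCI have guaranteed [−1, 1] range.
* The GA fitness at small p has many near-ties; determinism is
  guaranteed by the seed, optimality only verified exhaustively at
  p = 3.
* Problem sizes used throughout (51 samples per cultivar, 5 hold-out
  iterations, GA population 20 × 50 generations) are the package
  defaults and complete in seconds per scenario on one CPU.
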
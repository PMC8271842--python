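# Methods

This note documents the models, numerical choices and limitations behind
`hyperseed`, in the spirit of a statistical-software methods appendix.

## Reflectance calibration and the wavelength axis

Raw sensor counts are converted per pixel and band to reflectance
`R = (D_raw − D_dark)/(D_white − D_dark)`. References may be full frames or
per-band vectors (both broadcast against the cube); positions where
`white == dark` either raise (default) or emit 0 with a warning. Sensor noise
can push `raw` below `dark`; negative reflectance is clamped to 0 by default
because the slope-greyscale statistic downstream assumes non-negative
spectra (a flag disables clamping).

The default wavelength axis for a `B`-band cube spanning `(lo, hi)` nm is the
uniform grid with step `(hi − lo)/B`, band `k` (0-based) at `lo + k·step` —
for 204 bands over 400–1000 nm this is the 2.941 nm interval of the
instrument class emulated here. Instrument vendors print per-band wavelength
tables that do not lie exactly on any uniform grid; an explicit per-band
wavelength list can therefore be supplied to override the grid. Band indices
are 1-based inclusive at every API/CLI boundary (`crop 15:190` keeps bands
15..190); internal storage is 0-based.

## Pretreatments

The three pretreatments are *alternatives*, applied independently to each
per-seed mean spectrum — never chained.

- **SNV** centers each spectrum and scales by its sample (N−1) standard
  deviation, removing additive offset and multiplicative scatter. A constant
  spectrum is a degenerate input and raises.
- **Savitzky–Golay derivatives** use the 11-point quadratic local fit. Both
  kernels are derived at run time from the least-squares normal equations
  (so other odd windows/orders remain available); for the default they reduce
  to the classical closed forms `j/110` (first derivative) and
  `(j² − 10)/429` (second derivative), exact on polynomials up to order 2 at
  interior points. A legacy `literal` mode negates the j = ±3 terms of the
  first-derivative kernel to reproduce a sign variant that circulates in the
  applied literature; it is not a valid least-squares kernel and exists for
  comparison only.
- **Edge policy**: derivative outputs drop the 5 leading and trailing points
  (valid-mode correlation) and truncate the wavelength axis to match, so no
  fabricated boundary values feed band selection. An optional mirror-padding
  mode keeps full length. `Δλ` defaults to the median step of the axis the
  filter is applied to.

## Segmentation

The per-pixel statistic `g = arctan(min_band x / max_band x)` maps flat
(background) spectra to `π/4` and rising seed spectra to smaller values; it
is invariant to per-pixel positive scaling, which is exactly why
multiplicative artifacts (cast shadows, uneven illumination) do not move it.
Pixels whose spectral maximum is 0 get `g = 0` by convention. The greyscale
is thresholded by global Otsu (256-bin histogram; foreground = below the
threshold by default, a flag flips it); no locally adaptive thresholding is
used because the slope statistic already removes illumination variation.
Connected components (8-connectivity default, minimum area 20 px) are
relabeled 1..K in raster-scan order of first pixel, making labeling
deterministic. Touching seeds are not split — the assumed scene layout keeps
seeds separated, as on a bench where kernels are laid out ~5 mm apart. A
single-band Otsu baseline is retained for comparison; it fails under shadows
by design of the physics, not of the code.

## SPXY partitioning

Pairwise distances combine feature-space and label-space terms, each
normalized by its maximum: `d_xy = d_x/max d_x + d_y/max d_y` (the label term
is defined as 0 when only one class is present). Selection is the
deterministic Kennard–Stone procedure on `d_xy`: seed with the most distant
pair, then repeatedly add the sample whose minimum distance to the current
training set is largest. Ties break toward the lower original row index, so
the split is reproducible and permutation-equivariant up to ties. The
training-set size is `round(fraction·N)` with round-half-up. Distances are
computed on the *pretreated* spectra that will be modeled, since
partitioning follows pretreatment in the pipeline. A seeded uniform random
split is available for comparison.

## The penalized logistic model

The classifier is binary logistic regression with an L1 penalty on the slope
coefficients only. The package exposes the cost in its conventional
total-likelihood form `S_λ(β) = −l(β) + λ‖β‖₁`; the solver minimizes the
per-observation average `−l(β)/N + λ‖β‖₁`. The two differ only in the
scaling of λ (λ_total = N·λ_per-sample), and the per-observation convention —
the one used by glmnet-style software — is what makes a fixed λ search range
meaningful across group sizes from 81 to 144 seeds. The default grid is 100
log-spaced values over 1e-4–0.2, descending, with warm starts.

**Solver.** Columns are standardized internally (zero mean, unit population
sd; constant columns are left out); coefficients are back-transformed to the
original scale on return. Each λ is solved by an IRLS outer loop (quadratic
approximation at the current coefficients, fitted probabilities clipped to
[1e-5, 1 − 1e-5] so the curvature stays bounded away from zero on separable
data) with cyclic coordinate descent and soft-thresholding inside, the
intercept updated unpenalized. Convergence is declared when a full outer
iteration moves no coefficient by more than `tol` (default 1e-7); the sweep
budget is 1e5 coordinate sweeps, and a model that exhausts it carries a
`converged=False` flag plus a warning. Soft-thresholding produces *exact*
zeros; band selection tests `β_j ≠ 0` with no epsilon. Optimality is
certifiable through `kkt_residual`: `|g_j| ≤ λ` for zero coefficients and
`g_j = −λ·sign(β_j)` otherwise, with `g` the per-sample gradient on
standardized columns. The smallest all-zero penalty has the closed form
`λ_max = max_j |Σ_i z_ij (y_i − ȳ)| / N`.

**Cross-validation and λ choice.** Folds are label-stratified and seeded
(stratification keeps both classes in every training fold at the benchmark's
3:1 to 24:1 class ratios; a fold plan whose training parts lack a class is
re-drawn up to 10 times, then raises). Two per-λ summaries are recorded: a
Brier-type mean squared error between predicted probabilities and 0/1 labels,
and 0.5-threshold classification accuracy. Two selection rules are provided:
`min_error` (argmin of the MSE curve) and the default
`max_accuracy_sparsest` — among grid values tied at the maximum CV accuracy,
take the largest λ, i.e. the model needing the fewest bands for the same
predictive performance. The sparsest-tie search spans the whole grid rather
than a neighborhood of the error minimum; with a monotone-in-λ sparsity
profile the two agree whenever the accuracy plateau is contiguous.
Classification uses strict inequality: a predicted probability of exactly 0.5
is non-target.

## Benchmark design

Thirteen groups mix one target variety (72 pure seeds) with one to three
adulterant varieties (3–36 seeds each) per the packaged `groups.json`. Per
group and pretreatment: SPXY 1:1 split, 10-fold CV for λ on the training half
only, sparse fit at λ*, and an unpenalized full-band fit (λ = 0) on the same
training half; both evaluated on the untouched test half. Test indices never
enter λ selection or fitting (asserted). Accuracy is test-set only. The
full-band fit on P > N training data is separable and cannot converge to a
finite optimum; it runs under a capped sweep budget (2·10⁴) and its
saturated predictions are evaluated as-is — this is the honest full-band
baseline, not a bug. Published per-group accuracies from bench data are not
reproducible without that data; the benchmark therefore asserts the
*direction* (sparse ≥ full-band on average per pretreatment) and bit-exact
reproducibility under fixed seeds, not specific percentages.

## Synthetic data: what it emulates, what it does not

**Scenes.** Seeds are ellipses (default half-axes 7×4 px, jittered position
and orientation) on a flat background of reflectance 0.95. Seed spectra
follow a logistic reflectance ramp from ~0.15 to ~0.55 across 450–950 nm with
variety-specific Gaussian absorption dips; default dip positions sit near
wavelengths where rice varieties tend to show absorption contrast (~679, 811,
872 nm and others) but are illustrative placements, not measurements.
Shadows multiply *background* reflectance only, preserving spectral shape —
the mechanism that defeats single-band thresholding while leaving the slope
statistic untouched. Noise is additive white Gaussian per pixel and band
(sd 0.01 default). Not emulated: touching kernels, specular highlights,
sensor striping, wavelength-dependent blur. Segmentation results on these
scenes therefore demonstrate the statistic's shadow invariance, not
performance on cluttered bench imagery.

**Feature tables.** The sparse-classification generator draws 75 seeds per
class over 176 bands; classes differ only at 6 informative bands. Per-seed
noise is smooth band-correlated Gaussian (sd 0.02, correlation length ~3
bands) plus white noise (sd 0.04). Effect sizes are ±0.065 reflectance,
equal in magnitude with alternating sign — about 1.5 within-class standard
deviations per band. The equal-magnitude choice is deliberate: a pilot power
analysis showed that with unequal effects the sparsest-tie selection rule
will happily drop the weakest true band once the accuracy plateau is reached,
which tests the rule's thrift rather than the solver's recovery. With equal
effects no band is redundant at the plateau, so support recovery is a
well-posed target (observed: 6/6 bands recovered in nearly all seeded
replicates, median selected-set size 6–13). The per-variety table generator
adds a per-seed multiplicative gain (sd 0.05) — the scatter effect SNV is
designed to remove — plus smooth (sd 0.015) and white (sd 0.01) noise around
each variety curve.

## Problem sizes and determinism

Default experiment sizes — 10 scenes of 96×96×176, 20 support-recovery
replicates of 150×176, and the 13-group benchmark at 81–144 seeds per group —
were chosen so the entire validation runs in minutes on a single core while
keeping every per-group sample size identical to the benchmark design.
All stochastic steps take explicit integer seeds; identical seeds give
bit-identical scenes, tables, folds and reports.

## Known limitations

- Binary classification only: one target variety versus "anything else";
  multinomial purity profiles are out of scope.
- No inference on coefficients (p-values, confidence intervals); selected
  band sets are point estimates and can vary across reseeded splits,
  especially among correlated neighboring bands.
- The λ = 0 full-band fit is a diagnostic baseline; its coefficients are not
  interpretable when P exceeds the training size.
- ENVI support covers plain .hdr + flat binary rasters (BSQ/BIL/BIP, common
  numeric types); vendor-specific session containers are not parsed.
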
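# hyperseed

Hyperspectral seed-purity identification with simultaneous wavelength-band
selection, built around an L1-penalized (LASSO) logistic regression solved by
coordinate descent.

## The problem

Checking the varietal purity of a seed lot — how many kernels in a bag of a
declared rice variety actually belong to it — is traditionally done by eye or
by destructive chemistry. Hyperspectral imaging offers a fast, non-destructive
alternative: each seed yields a reflectance spectrum over 400–1000 nm in ~200
narrow bands, and adulterant varieties differ subtly in a handful of
absorption features. Two practical obstacles stand in the way: seeds must
first be separated from the imaging background under uneven illumination, and
the ~200 bands are massively redundant, so a full-band classifier overfits
while a camera that scans all bands is needlessly expensive.

`hyperseed` implements a complete pipeline addressing both:

1. **Calibration & cropping** — raw counts to reflectance via
   `R = (D_raw − D_dark)/(D_white − D_dark)`, then cropping to the usable
   bands (default 15–190 of 204, ≈450–950 nm).
2. **Pretreatment** — SNV (per-spectrum standardization) or Savitzky–Golay
   first/second derivatives (window 11, quadratic fit; FD kernel `j/110`,
   SD kernel `(j²−10)/429`).
3. **Segmentation** — a per-pixel *spectral-slope greyscale*
   `g = arctan(min(x)/max(x))`: the flat whiteboard background gives
   `g ≈ π/4` regardless of illumination (so cast shadows vanish), while
   rising seed spectra give low `g`. Otsu thresholding plus connected-component
   labeling then yields one mean spectrum per seed.
4. **Partitioning** — SPXY (sample-set partitioning based on joint x–y
   distance): a deterministic Kennard–Stone-style 1:1 train/test split on
   `d_xy = d_x/max d_x + d_y/max d_y`.
5. **Model** — binary logistic regression on the log-odds
   `log[p/(1−p)] = β₀ + Σ_j β_j x_j` with an L1 penalty `λΣ_j |β_j|`
   (intercept unpenalized), minimized by cyclic soft-threshold coordinate
   descent inside an IRLS loop, warm-started along a descending λ grid
   (default 100 log-spaced points over 1e-4–0.2, per-observation scaling).
   λ is chosen by stratified 10-fold CV; among λ tied at the best CV accuracy
   the largest (sparsest) wins. Bands with exactly nonzero coefficients are
   the selected feature wavelengths; a seed is called *target variety* iff
   the predicted probability exceeds 0.5.

A full synthetic-data module generates seed scenes (elliptical seeds on a
bright whiteboard, optional multiplicative shadows) and spectra tables with
known sparse class structure, so every stage is testable against ground truth.

## Worked example

```python
import hyperseed as hs

# scene -> segmentation -> per-seed spectra
cube, truth = hs.generate_scene(hs.SceneSpec(seed=7, shadows=((0.28, 0.78, 0.05, 0.60, 0.45),)))
mask = hs.binarize_otsu(hs.slope_greyscale(cube))
labels = hs.label_components(mask)
print(labels.n_regions)                       # 16  (exact seed count)

# sparse band selection on spectra with 6 known informative bands
ds, truth = hs.generate_feature_data(seed=2)  # 150 seeds x 176 bands
cv = hs.cross_validate(ds.X, ds.y, folds=10, seed=2)
lam = hs.select_lambda(cv)
model = hs.fit_lasso_logistic(ds.X, ds.y, lam)
sel = hs.selected_bands(model, ds.wavelengths_nm)
print(truth.informative.tolist())             # [25, 55, 85, 115, 145, 166]
print(sel.indices.tolist())                   # [25, 55, 85, 115, 145, 166]
print(f"{100 * cv.cv_accuracy.max():.1f}%")   # 93.3%
```

The selected bands coincide with the generator's informative set: the L1
geometry zeroes every uninformative coefficient exactly, so band selection and
classification happen in a single fit.

The 13-group benchmark (one target variety adulterated with 1–3 others at
varying rates, per the packaged group design) compares the sparse model
(LLRM) with the full-band unpenalized logistic model (LRM):

```bash
hyperseed evaluate --groups all --preproc snv,fd,sd --seed 1 --out report.csv
```

On the default synthetic varieties this prints mean test accuracies of about
99.6/99.6/97.8 % (LLRM under SNV/FD/SD) against 89.7/92.8/83.1 % (LRM),
with a typical selected-band count of ~10 of 176 — the sparse model is more
accurate with ~6 % of the bands, because dropping noise bands raises the
effective signal-to-noise ratio while the full-band fit overfits the
training half.

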
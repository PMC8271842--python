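"""Synthetic hyperspectral scenes and spectra tables with full ground truth.

Two generators exercise the pipeline end to end:

``generate_scene`` renders seeds as elliptical regions on a flat bright
whiteboard.  Seed spectra follow a smooth logistic reflectance ramp rising
over 400-1000 nm with variety-specific Gaussian absorption dips; the
background is spectrally flat.  Optional cast shadows attenuate background
intensity multiplicatively while preserving spectral shape — exactly the
artifact the spectral-slope segmentation statistic is designed to ignore,
and the one that defeats single-band thresholding.

``generate_feature_data`` draws per-seed spectra for a binary classification
task whose classes differ only at a known sparse set of informative bands,
on top of smooth band-correlated noise plus white noise.  It provides the
controlled sparse-logistic benchmark used to measure band-selection support
recovery.

The default dip positions sit near wavelengths that frequently carry
varietal absorption contrast in rice (e.g. around 679, 811 and 872 nm);
they are illustrative placements, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .exceptions import DomainError
from .io import HyperCube, wavelength_axis
from .tables import LabeledDataset, SpectraTable

__all__ = [
    "VarietySpectrumModel",
    "SceneSpec",
    "SceneTruth",
    "FeatureTruth",
    "default_variety_models",
    "generate_scene",
    "generate_variety_tables",
    "generate_feature_data",
]


@dataclass(frozen=True)
class VarietySpectrumModel:
    """Smooth monotone reflectance ramp with Gaussian absorption dips.

    ``low``/``high`` bound the logistic ramp (reflectance units),
    ``inflection_nm``/``width_nm`` place it along the wavelength axis, and
    each dip is a (center nm, depth, width nm) triple subtracted from the
    ramp.  ``noise_sd`` is the per-pixel-per-band additive noise used when
    the model is rendered into a scene.
    """

    low: float = 0.15
    high: float = 0.55
    inflection_nm: float = 700.0
    width_nm: float = 120.0
    dips: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.01

    def curve(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=np.float64)
        base = self.low + (self.high - self.low) * expit(
            (wl - self.inflection_nm) / self.width_nm
        )
        for center, depth, width in self.dips:
            if not wl[0] <= center <= wl[-1]:
                raise DomainError(f"dip at {center} nm outside wavelength range")
            base = base - depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return np.clip(base, 1e-3, 1.0 - 1e-3)


def default_variety_models() -> list[VarietySpectrumModel]:
    """Four variety models sharing a ramp but differing in absorption dips."""
    return [
        VarietySpectrumModel(dips=((548.6, 0.050, 18.0), (678.7, 0.080, 15.0),
                                   (871.6, 0.040, 20.0))),
        VarietySpectrumModel(dips=((583.9, 0.060, 18.0), (678.7, 0.045, 15.0),
                                   (810.9, 0.060, 18.0))),
        VarietySpectrumModel(dips=((548.6, 0.030, 18.0), (643.0, 0.070, 15.0),
                                   (847.3, 0.050, 18.0))),
        VarietySpectrumModel(dips=((513.4, 0.050, 16.0), (738.5, 0.060, 18.0),
                                   (896.0, 0.050, 18.0))),
    ]


@dataclass(frozen=True)
class SceneSpec:
    """Layout and imaging parameters of a synthetic seed scene.

    ``shadows`` are rectangles in fractional image coordinates
    (row0, row1, col0, col1, attenuation) applied multiplicatively to
    background pixels only.
    """

    shape: tuple[int, int] = (96, 96)
    counts: tuple[int, ...] = (4, 4, 4, 4)
    seed_axes_px: tuple[float, float] = (7.0, 4.0)
    orientation_jitter_deg: float = 25.0
    position_jitter_px: float = 2.0
    background_reflectance: float = 0.95
    shadows: tuple[tuple[float, float, float, float, float], ...] = ()
    noise_sd: float = 0.01
    n_bands: int = 176
    wavelength_range: tuple[float, float] = (450.0, 950.0)
    seed: int = 0


@dataclass
class SceneTruth:
    """Ground truth for a generated scene."""

    labels: np.ndarray                 # raster, 0 = background, 1..K seeds
    varieties: np.ndarray              # per-label 1-based variety index
    mean_spectra: np.ndarray           # per-label noiseless spectrum (K x P)
    informative_bands: np.ndarray      # 1-based band indices of dip centers
    shadow_mask: np.ndarray


@dataclass
class FeatureTruth:
    """Ground truth for a generated sparse-logistic spectra dataset."""

    informative: np.ndarray            # 1-based band indices
    effect_sizes: np.ndarray
    base_curve: np.ndarray
    wavelengths_nm: np.ndarray


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = [int(u) for _, u in sorted(zip(first, uniq)) if u > 0]
    remap = np.zeros(int(flat.max()) + 1, dtype=np.int64)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels], np.asarray(order, dtype=np.int64)


def generate_scene(
    spec: SceneSpec, models: list[VarietySpectrumModel] | None = None
) -> tuple[HyperCube, SceneTruth]:
    """Render a seed scene and its ground truth.  Deterministic per seed."""
    models = default_variety_models() if models is None else models
    if len(models) < len(spec.counts):
        raise DomainError("need one spectrum model per variety")
    h, w = spec.shape
    total = int(sum(spec.counts))
    if total < 1:
        raise DomainError("scene needs at least one seed")
    ncols = int(np.ceil(np.sqrt(total)))
    nrows = int(np.ceil(total / ncols))
    cell_h, cell_w = h / nrows, w / ncols
    a, b = spec.seed_axes_px
    if 2 * max(a, b) + 2 * spec.position_jitter_px >= min(cell_h, cell_w):
        raise DomainError(
            f"{total} seeds with axes {spec.seed_axes_px} do not fit a "
            f"{h}x{w} image without overlap"
        )
    rng = np.random.default_rng(spec.seed)
    wl = wavelength_axis(spec.n_bands, spec.wavelength_range)
    varieties = np.concatenate(
        [np.full(c, v + 1, dtype=np.int64) for v, c in enumerate(spec.counts)]
    )
    rng.shuffle(varieties)

    labels = np.zeros((h, w), dtype=np.int64)
    rr, cc = np.mgrid[0:h, 0:w]
    k = 0
    for gi in range(nrows):
        for gj in range(ncols):
            if k >= total:
                break
            cy = (gi + 0.5) * cell_h + rng.uniform(-1, 1) * spec.position_jitter_px
            cx = (gj + 0.5) * cell_w + rng.uniform(-1, 1) * spec.position_jitter_px
            theta = np.deg2rad(rng.uniform(-1, 1) * spec.orientation_jitter_deg)
            dy, dx = rr - cy, cc - cx
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            labels[inside] = k + 1
            k += 1
    labels, placement_order = _relabel_raster_order(labels)
    varieties = varieties[placement_order - 1]

    shadow_mask = np.zeros((h, w), dtype=bool)
    for r0, r1, c0, c1, _ in spec.shadows:
        shadow_mask[int(r0 * h) : int(r1 * h), int(c0 * w) : int(c1 * w)] = True

    cube = np.full((h, w, spec.n_bands), spec.background_reflectance)
    for r0, r1, c0, c1, atten in spec.shadows:
        region = np.zeros((h, w), dtype=bool)
        region[int(r0 * h) : int(r1 * h), int(c0 * w) : int(c1 * w)] = True
        region &= labels == 0  # shadows attenuate the background only
        cube[region] *= atten

    kcount = int(labels.max())
    curves = np.empty((kcount, spec.n_bands))
    for lab in range(1, kcount + 1):
        model = models[varieties[lab - 1] - 1]
        curve = model.curve(wl)
        curves[lab - 1] = curve
        cube[labels == lab] = curve
    cube += rng.normal(0.0, spec.noise_sd, size=cube.shape)
    np.clip(cube, 0.0, None, out=cube)

    dip_centers = sorted(
        {c for v in set(varieties.tolist()) for c, _, _ in models[v - 1].dips}
    )
    informative = np.array(
        [int(np.argmin(np.abs(wl - c))) + 1 for c in dip_centers], dtype=np.int64
    )
    truth = SceneTruth(
        labels=labels,
        varieties=varieties,
        mean_spectra=curves,
        informative_bands=informative,
        shadow_mask=shadow_mask,
    )
    return HyperCube(reflectance=cube, wavelengths_nm=wl), truth


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, sigma_bands: float
) -> np.ndarray:
    """Band-correlated Gaussian noise with the requested marginal sd."""
    raw = rng.normal(size=shape)
    sm = gaussian_filter1d(raw, sigma=sigma_bands, axis=-1, mode="reflect")
    impulse = np.zeros(shape[-1])
    impulse[shape[-1] // 2] = 1.0
    kernel_norm = np.sqrt(
        np.sum(gaussian_filter1d(impulse, sigma=sigma_bands, mode="constant") ** 2)
    )
    return sd * sm / kernel_norm


def generate_variety_tables(
    n_seeds: int = 72,
    models: list[VarietySpectrumModel] | None = None,
    n_bands: int = 176,
    wavelength_range: tuple[float, float] = (450.0, 950.0),
    scatter_sd: float = 0.05,
    smooth_sd: float = 0.015,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[SpectraTable]:
    """Per-variety tables of seed-mean spectra for the grouped benchmark.

    Each seed draws a multiplicative gain (surface-scatter effect that SNV
    removes), a smooth band-correlated deviation (biological variation) and
    white noise around its variety curve.
    """
    models = default_variety_models() if models is None else models
    rng = np.random.default_rng(seed)
    wl = wavelength_axis(n_bands, wavelength_range)
    tables = []
    for v, model in enumerate(models, start=1):
        curve = model.curve(wl)
        gain = np.clip(1.0 + scatter_sd * rng.standard_normal(n_seeds), 0.5, None)
        X = gain[:, None] * curve[None, :]
        X += _smooth_noise(rng, (n_seeds, n_bands), smooth_sd, sigma_bands=4.0)
        X += rng.normal(0.0, noise_sd, size=X.shape)
        tables.append(
            SpectraTable(
                ids=np.arange(1, n_seeds + 1),
                variety=np.full(n_seeds, f"variety_{v}", dtype=object),
                X=X,
                wavelengths_nm=wl,
            )
        )
    return tables


#: Fractional positions of the default informative bands along the axis
#: (for 176 bands these land on indices 25, 55, 85, 115, 145, 166).
DEFAULT_INFORMATIVE_FRACTIONS = (
    25 / 176, 55 / 176, 85 / 176, 115 / 176, 145 / 176, 166 / 176,
)
DEFAULT_EFFECT_SIZES = (0.065, -0.065, 0.065, -0.065, 0.065, 0.065)


def generate_feature_data(
    n_per_class: int = 75,
    n_bands: int = 176,
    informative: tuple[int, ...] | None = None,
    effect_sizes: tuple[float, ...] | None = None,
    noise_sd: float = 0.04,
    smooth_sd: float = 0.02,
    smooth_sigma_bands: float = 3.0,
    wavelength_range: tuple[float, float] = (450.0, 950.0),
    seed: int = 0,
) -> tuple[LabeledDataset, FeatureTruth]:
    """Binary spectra dataset whose classes differ only at known bands.

    Class 1 adds ``effect_sizes`` to the shared base curve at the 1-based
    ``informative`` band indices; both classes share smooth correlated noise
    (sd ``smooth_sd``) and white noise (sd ``noise_sd``).  Default effects
    are equal in magnitude (about 1.5 within-class standard deviations per
    band, alternating sign) so every informative band contributes the same
    marginal information: no single band separates the classes, and none is
    redundant at the accuracy plateau.
    """
    if informative is None:
        informative = tuple(
            int(round(f * n_bands)) for f in DEFAULT_INFORMATIVE_FRACTIONS
        )
    else:
        informative = tuple(informative)
    effect_sizes = (
        DEFAULT_EFFECT_SIZES if effect_sizes is None else tuple(effect_sizes)
    )
    if len(informative) != len(effect_sizes):
        raise DomainError("informative bands and effect sizes must align")
    if len(set(informative)) != len(informative):
        raise DomainError("informative band indices must be distinct")
    if not all(1 <= b <= n_bands for b in informative):
        raise DomainError(f"informative bands must lie in 1..{n_bands}")
    if n_per_class < 2:
        raise DomainError("need at least 2 samples per class")
    if noise_sd < 0 or smooth_sd < 0:
        raise DomainError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    wl = wavelength_axis(n_bands, wavelength_range)
    base = VarietySpectrumModel().curve(wl)
    n = 2 * n_per_class
    X = np.tile(base, (n, 1))
    y = np.repeat([0, 1], n_per_class)
    idx0 = np.asarray(informative, dtype=np.int64) - 1
    X[np.ix_(np.flatnonzero(y == 1), idx0)] += np.asarray(effect_sizes)
    if smooth_sd > 0:
        X += _smooth_noise(rng, (n, n_bands), smooth_sd, smooth_sigma_bands)
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=X.shape)
    ids = np.array(
        [f"c{c}:{i}" for c, i in zip(y, np.arange(n))], dtype=object
    )
    dataset = LabeledDataset(X=X, y=y, ids=ids, wavelengths_nm=wl)
    truth = FeatureTruth(
        informative=np.asarray(informative, dtype=np.int64),
        effect_sizes=np.asarray(effect_sizes, dtype=np.float64),
        base_curve=base,
        wavelengths_nm=wl,
    )
    return dataset, truth
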
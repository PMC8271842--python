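"""Seed/background segmentation from the spectral-slope greyscale.

Seeds resting on a reference whiteboard separate spectrally rather than
spatially: the whiteboard reflects almost equally at every band (flat
spectrum, min/max ratio near 1) while seed reflectance rises steadily across
400-1000 nm (ratio well below 1).  The per-pixel statistic

    g = arctan( min_band(x) / max_band(x) )

is therefore near arctan(1) = pi/4 on the background and substantially lower
on seeds, independent of illumination level, which is what lets it ignore
cast shadows (a shadow scales the whole spectrum, leaving the ratio
unchanged).  The greyscale is binarized with Otsu's threshold, connected
regions are labeled, and each region's mean spectrum becomes one row of a
:class:`~hyperseed.tables.SpectraTable`.

A single-band Otsu baseline (`binarize_single_band`) is kept for comparison;
it sees only spatial intensity at one wavelength and is defeated by shadows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

from .exceptions import DegenerateInputError, DomainError
from .io import HyperCube
from .tables import SpectraTable

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "slope_greyscale",
    "binarize_otsu",
    "binarize_single_band",
    "label_components",
    "mean_spectra",
]


@dataclass
class LabelMap:
    """Integer label raster (0 = background) with per-label pixel counts."""

    labels: np.ndarray
    region_sizes: np.ndarray  # region_sizes[k-1] = pixels with label k

    @property
    def n_regions(self) -> int:
        return int(self.region_sizes.size)


def slope_greyscale(cube: HyperCube) -> np.ndarray:
    """Per-pixel arctan(min/max) of the spectrum, in [0, pi/4].

    Pixels whose spectral maximum is 0 get value 0 by convention.
    """
    refl = cube.reflectance
    if np.any(refl < 0):
        raise DomainError("slope greyscale requires non-negative reflectance")
    mn = refl.min(axis=2)
    mx = refl.max(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mx > 0, mn / np.where(mx > 0, mx, 1.0), 0.0)
    return np.arctan(ratio)


def _otsu_threshold(grey: np.ndarray) -> float:
    if grey.max() == grey.min():
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    return float(threshold_otsu(grey, nbins=256))


def binarize_otsu(grey: np.ndarray, foreground_side: str = "below") -> np.ndarray:
    """Otsu binarization of a greyscale image (256-bin histogram).

    ``foreground_side="below"`` (default) marks pixels below the threshold as
    foreground — the right orientation for the slope greyscale, where sloped
    seed spectra give low values and the flat whiteboard gives high values.
    """
    grey = np.asarray(grey, dtype=np.float64)
    if foreground_side not in ("below", "above"):
        raise DomainError(f"unknown foreground side {foreground_side!r}")
    t = _otsu_threshold(grey)
    return grey < t if foreground_side == "below" else grey > t


def binarize_single_band(
    cube: HyperCube, wavelength_nm: float, foreground_side: str = "below"
) -> np.ndarray:
    """Single-band Otsu baseline: threshold the image at one wavelength.

    The nearest band is used; a wavelength outside the axis range is accepted
    with a logged warning.
    """
    wl = cube.wavelengths_nm
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        logger.warning(
            "wavelength %.2f nm outside axis range [%.2f, %.2f]; using nearest band",
            wavelength_nm, wl[0], wl[-1],
        )
    band = int(np.argmin(np.abs(wl - wavelength_nm)))
    return binarize_otsu(cube.reflectance[:, :, band], foreground_side)


def label_components(
    mask: np.ndarray, connectivity: int = 8, min_area: int = 20
) -> LabelMap:
    """Label connected foreground regions, dropping those below ``min_area``.

    Surviving regions are relabeled 1..K in raster-scan order of their first
    pixel, so identical masks always yield identical label maps.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity not in (4, 8):
        raise DomainError(f"connectivity must be 4 or 8, got {connectivity}")
    raw = _sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(raw.ravel())
    keep = np.flatnonzero(counts >= max(min_area, 1))
    keep = keep[keep > 0]
    # raster order of first occurrence
    flat = raw.ravel()
    uniq, first = np.unique(flat, return_index=True)
    first_idx = dict(zip(uniq.tolist(), first.tolist()))
    order = sorted(keep, key=lambda lab: first_idx[lab])
    remap = np.zeros(counts.size, dtype=raw.dtype)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    out = remap[raw]
    sizes = np.asarray([counts[old] for old in order], dtype=np.int64)
    return LabelMap(labels=out, region_sizes=sizes)


def mean_spectra(
    cube: HyperCube,
    labels: LabelMap,
    group_meta: dict[int, str] | None = None,
) -> SpectraTable:
    """Mean spectrum of every labeled region, one table row per seed.

    ``group_meta`` optionally maps label -> variety name; unmapped labels get
    an empty annotation.
    """
    lab = labels.labels
    if lab.shape != cube.reflectance.shape[:2]:
        raise DomainError(
            f"label raster {lab.shape} does not align with cube "
            f"{cube.reflectance.shape[:2]}"
        )
    k = labels.n_regions
    wl = cube.wavelengths_nm
    if k == 0:
        logger.warning("empty label set: returning empty spectra table")
        return SpectraTable(
            ids=np.empty(0, dtype=np.int64),
            variety=np.empty(0, dtype=object),
            X=np.empty((0, wl.size)),
            wavelengths_nm=wl.copy(),
        )
    flat_lab = lab.ravel()
    flat_refl = cube.reflectance.reshape(-1, wl.size)
    sums = np.zeros((k + 1, wl.size))
    np.add.at(sums, flat_lab, flat_refl)
    means = sums[1:] / labels.region_sizes[:, None]
    ids = np.arange(1, k + 1)
    meta = group_meta or {}
    variety = np.array([meta.get(int(i), "") for i in ids], dtype=object)
    return SpectraTable(ids=ids, variety=variety, X=means, wavelengths_nm=wl.copy())
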
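"""Hyperspectral cube I/O, reflectance calibration and band cropping.

Cubes are stored as ``rows x cols x bands`` float arrays with a strictly
increasing wavelength axis in nanometres.  Raw sensor counts are converted to
reflectance with the usual white/dark reference calibration

    R = (D_raw - D_dark) / (D_white - D_dark)

applied element-wise, where the references may be full frames or per-band
vectors.  ENVI (.hdr text header + flat binary raster, BSQ/BIL/BIP) is the
on-disk exchange format; an NPZ container with arrays ``reflectance`` and
``wavelengths_nm`` is supported as a convenience for calibrated cubes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import CalibrationError, DomainError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "RawCube",
    "ReferenceFrames",
    "HyperCube",
    "wavelength_axis",
    "calibrate_reflectance",
    "crop_bands",
    "read_envi",
    "write_envi",
    "load_cube",
    "save_cube",
]

#: ENVI "data type" codes for the numeric types this reader handles.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def wavelength_axis(band_count: int, range_nm: tuple[float, float]) -> np.ndarray:
    """Uniform wavelength grid for ``band_count`` bands over ``range_nm``.

    The step is ``(max - min) / band_count``; band k (0-based) sits at
    ``min + k * step``.  For 204 bands over 400-1000 nm this yields the
    2.941 nm interval quoted for the Specim IQ class of instruments.
    """
    lo, hi = float(range_nm[0]), float(range_nm[1])
    if band_count < 2:
        raise DomainError(f"band_count must be >= 2, got {band_count}")
    if not hi > lo:
        raise DomainError(f"degenerate wavelength range ({lo}, {hi})")
    step = (hi - lo) / band_count
    return lo + step * np.arange(band_count)


@dataclass
class RawCube:
    """Raw light-intensity counts, ``rows x cols x bands``."""

    data: np.ndarray
    wavelength_range: tuple[float, float] | None = None
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DomainError(f"raw cube must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("raw cube contains non-finite counts")
        if np.any(self.data < 0):
            raise DomainError("raw cube contains negative counts")
        if self.wavelengths_nm is not None:
            self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
            if self.wavelengths_nm.size != self.data.shape[2]:
                raise DomainError("wavelength list length does not match band count")

    @property
    def band_count(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """White and dark reference intensities, per-band vectors or full frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise DomainError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )


@dataclass
class HyperCube:
    """Calibrated reflectance cube with its wavelength axis."""

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise DomainError(f"cube must be 3-D, got shape {self.reflectance.shape}")
        if self.wavelengths_nm.size != self.reflectance.shape[2]:
            raise DomainError(
                f"{self.wavelengths_nm.size} wavelengths for "
                f"{self.reflectance.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise DomainError("reflectance contains non-finite values")

    @property
    def band_count(self) -> int:
        return self.reflectance.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape


def calibrate_reflectance(
    raw: RawCube,
    refs: ReferenceFrames,
    *,
    zero_division: str = "raise",
    clamp_negative: bool = True,
    wavelength_range: tuple[float, float] = (400.0, 1000.0),
) -> HyperCube:
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    Parameters
    ----------
    zero_division:
        Policy where ``white == dark``: ``"raise"`` (default) or ``"zero"``
        (emit 0 there with a logged warning).
    clamp_negative:
        Sensor noise can push ``raw`` below ``dark``; by default the
        resulting negative reflectance is clamped to 0 so the downstream
        slope statistic sees non-negative spectra.
    """
    white, dark = refs.white, refs.dark
    try:
        np.broadcast_shapes(raw.data.shape, white.shape)
    except ValueError as exc:
        raise DomainError(
            f"references of shape {white.shape} do not broadcast to cube "
            f"{raw.data.shape}"
        ) from exc
    denom = white - dark
    bad = denom == 0
    if np.any(bad):
        if zero_division == "raise":
            raise CalibrationError(
                f"white == dark at {int(np.count_nonzero(bad))} positions"
            )
        if zero_division != "zero":
            raise DomainError(f"unknown zero_division policy {zero_division!r}")
        logger.warning(
            "white == dark at %d positions; emitting reflectance 0 there",
            int(np.count_nonzero(bad)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - dark) / denom
    refl = np.where(np.broadcast_to(bad, refl.shape), 0.0, refl)
    if clamp_negative:
        refl = np.maximum(refl, 0.0)
    if raw.wavelengths_nm is not None:
        wl = raw.wavelengths_nm
    else:
        wl = wavelength_axis(raw.band_count, raw.wavelength_range or wavelength_range)
    return HyperCube(reflectance=refl, wavelengths_nm=wl)


def crop_bands(cube: HyperCube, first_index: int, last_index: int) -> HyperCube:
    """Keep bands ``first_index..last_index`` (1-based, inclusive).

    The working range used throughout defaults to bands 15..190 of a 204-band
    400-1000 nm cube, i.e. roughly 450-950 nm, discarding the noisy extremes.
    """
    n = cube.band_count
    if not (1 <= first_index <= last_index <= n):
        raise DomainError(
            f"band range {first_index}..{last_index} invalid for {n} bands"
        )
    sl = slice(first_index - 1, last_index)
    return HyperCube(
        reflectance=cube.reflectance[:, :, sl].copy(),
        wavelengths_nm=cube.wavelengths_nm[sl].copy(),
    )


# ---------------------------------------------------------------------------
# ENVI format
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("missing ENVI magic line")
    # strip the magic line, then parse "key = value" with {...} blocks
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _find_raster(header_path: Path, fields: dict) -> Path:
    if "data file" in fields:
        cand = header_path.parent / fields["data file"].strip("{} \n")
        if cand.exists():
            return cand
    stem = header_path.with_suffix("")
    for ext in ("", ".img", ".dat", ".raw", ".bin"):
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != header_path:
            return cand
    raise FormatError(f"no raster file found next to header {header_path}")


def read_envi(header_path: str | Path) -> RawCube:
    """Read an ENVI cube (text .hdr + flat binary raster) as a :class:`RawCube`.

    Supports BSQ/BIL/BIP interleaves and the numeric ENVI data types 1-5, 12.
    Wavelength metadata is attached when the header carries a ``wavelength``
    block, otherwise a uniform 400-1000 nm axis is synthesized.
    """
    header_path = Path(header_path)
    try:
        text = header_path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read ENVI header {header_path}: {exc}") from exc
    fields = _parse_envi_header(text)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header {header_path} missing field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", 0))
    raster = _find_raster(header_path, fields)
    buf = np.fromfile(raster, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if buf.size != expected:
        raise FormatError(
            f"raster {raster} holds {buf.size} values, header declares {expected}"
        )
    if interleave == "bsq":
        cube = buf.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = buf.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = buf.reshape(lines, samples, bands)
    wavelengths = None
    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip("{} \n")
        wavelengths = np.array(
            [float(v) for v in wl_text.replace("\n", " ").split(",") if v.strip()]
        )
        if wavelengths.size != bands:
            raise FormatError(
                f"header lists {wavelengths.size} wavelengths for {bands} bands"
            )
    return RawCube(
        data=np.ascontiguousarray(cube, dtype=np.float64),
        wavelengths_nm=wavelengths,
    )


def write_envi(
    data: np.ndarray,
    header_path: str | Path,
    *,
    interleave: str = "bsq",
    wavelengths_nm: np.ndarray | None = None,
    dtype: np.dtype | type = np.float64,
) -> Path:
    """Write a ``rows x cols x bands`` array as an ENVI .hdr/.img pair."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise DomainError(f"unsupported interleave {interleave!r}")
    data = np.asarray(data, dtype=dtype)
    if data.ndim != 3:
        raise DomainError("expected a 3-D cube")
    lines, samples, bands = data.shape
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data
    raster_path = header_path.with_suffix(".img")
    np.ascontiguousarray(flat).tofile(raster_path)
    code = _DTYPE_CODES[np.dtype(dtype)]
    header = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"data file = {raster_path.name}",
    ]
    if wavelengths_nm is not None:
        wl = ", ".join(f"{w:.6f}" for w in np.asarray(wavelengths_nm))
        header.append("wavelength = {" + wl + "}")
    header_path.write_text("\n".join(header) + "\n")
    return header_path


def save_cube(cube: HyperCube, path: str | Path) -> Path:
    """Save a calibrated cube to an NPZ container."""
    path = Path(path)
    np.savez(path, reflectance=cube.reflectance, wavelengths_nm=cube.wavelengths_nm)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_cube(path: str | Path) -> HyperCube:
    """Load a calibrated cube from an NPZ container or an ENVI header."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        raw = read_envi(path)
        wl = raw.wavelengths_nm
        if wl is None:
            wl = wavelength_axis(raw.band_count, (400.0, 1000.0))
        return HyperCube(reflectance=raw.data, wavelengths_nm=wl)
    with np.load(path) as npz:
        try:
            return HyperCube(
                reflectance=npz["reflectance"], wavelengths_nm=npz["wavelengths_nm"]
            )
        except KeyError as exc:
            raise FormatError(f"{path} lacks array {exc}") from exc
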
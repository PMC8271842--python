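"""Spectral pretreatments: SNV and Savitzky-Golay derivatives.

The three pretreatments are alternatives, never chained: standard normal
variate (SNV) removes per-spectrum multiplicative scatter by centering and
scaling each spectrum to unit sample variance; the first and second
Savitzky-Golay derivatives (window 11, polynomial order 2) remove baseline
offsets and, for the second derivative, linear trends, sharpening absorption
features before band selection.

With window 11 and a quadratic local fit the derivative filters reduce to the
classical closed-form kernels

    first derivative:   w_j = j / 110,            j = -5..5   (then / dl)
    second derivative:  w_j = (j^2 - 10) / 429,   j = -5..5   (then / dl^2)

which are exact on polynomials of degree <= 2 at interior points.  Both are
derived here from the local least-squares fit so arbitrary odd windows and
orders remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import factorial

import numpy as np

from .exceptions import DegenerateInputError, DomainError
from .tables import SpectraTable

__all__ = [
    "PreprocessTag",
    "snv",
    "savitzky_golay_kernel",
    "sg_first_derivative",
    "sg_second_derivative",
    "apply_preprocessing",
]

METHODS = ("raw", "snv", "fd", "sd")


@dataclass(frozen=True)
class PreprocessTag:
    """Named pretreatment plus its parameters.

    ``delta_lambda`` defaults to the step of the wavelength axis it is applied
    to.  ``edge="drop"`` discards the half-window at each end of derivative
    outputs (valid-mode convolution); ``edge="mirror"`` keeps full length via
    reflection padding.  ``literal_fd`` reproduces a legacy sign variant of
    the first-derivative kernel in which the j = +/-3 terms enter negated.
    """

    method: str = "raw"
    window: int = 11
    polyorder: int = 2
    delta_lambda: float | None = None
    edge: str = "drop"
    literal_fd: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DomainError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.window % 2 == 0 or self.window < 3:
            raise DomainError(f"window must be odd and >= 3, got {self.window}")
        if self.polyorder >= self.window:
            raise DomainError("polynomial order must be < window")
        if self.edge not in ("drop", "mirror"):
            raise DomainError(f"unknown edge policy {self.edge!r}")


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale to unit sample (N-1) variance."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise DomainError("SNV needs a 1-D spectrum with at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant spectrum: SNV denominator is zero")
    return (x - x.mean()) / sd


def savitzky_golay_kernel(window: int = 11, polyorder: int = 2, deriv: int = 1) -> np.ndarray:
    """Savitzky-Golay convolution weights from the local least-squares fit.

    Returns ``w`` ordered by offset j = -h..h such that
    ``sum_j w[j] * R(lambda + j*dl)`` estimates the ``deriv``-th derivative at
    ``lambda`` (before division by ``dl**deriv``).
    """
    if window % 2 == 0 or window < 3:
        raise DomainError(f"window must be odd and >= 3, got {window}")
    if not 0 <= deriv <= polyorder < window:
        raise DomainError("need 0 <= deriv <= polyorder < window")
    half = window // 2
    j = np.arange(-half, half + 1, dtype=np.float64)
    design = j[:, None] ** np.arange(polyorder + 1)[None, :]
    # row `deriv` of the pseudoinverse gives the fitted polynomial coefficient
    # c_deriv as a linear functional of the window values
    return factorial(deriv) * np.linalg.pinv(design)[deriv]


def _literal_fd_kernel() -> np.ndarray:
    # legacy variant: j = +/-3 differences subtracted instead of added
    w = np.arange(-5, 6, dtype=np.float64)
    w[np.abs(np.arange(-5, 6)) == 3] *= -1
    return w / 110.0


def _sg_derivative(
    values: np.ndarray, kernel: np.ndarray, scale: float, edge: str
) -> np.ndarray:
    x = np.asarray(values, dtype=np.float64)
    window = kernel.size
    if x.ndim != 1:
        raise DomainError("expected a 1-D spectrum")
    if x.size < window:
        raise DomainError(f"spectrum has {x.size} points, window needs {window}")
    if edge == "mirror":
        half = window // 2
        x = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    # out[i] = sum_j kernel[j] * x[i + j]  (cross-correlation, not convolution)
    return np.correlate(x, kernel, mode="valid") / scale


def sg_first_derivative(
    values: np.ndarray,
    delta_lambda: float = 1.0,
    *,
    window: int = 11,
    polyorder: int = 2,
    edge: str = "drop",
    literal: bool = False,
) -> np.ndarray:
    """First Savitzky-Golay derivative (default 11-point quadratic, j/110 kernel)."""
    if delta_lambda <= 0:
        raise DomainError("delta_lambda must be positive")
    if literal:
        if (window, polyorder) != (11, 2):
            raise DomainError("literal kernel is defined only for window 11, order 2")
        kernel = _literal_fd_kernel()
    else:
        kernel = savitzky_golay_kernel(window, polyorder, deriv=1)
    return _sg_derivative(values, kernel, delta_lambda, edge)


def sg_second_derivative(
    values: np.ndarray,
    delta_lambda: float = 1.0,
    *,
    window: int = 11,
    polyorder: int = 2,
    edge: str = "drop",
) -> np.ndarray:
    """Second Savitzky-Golay derivative (default kernel {15,6,-1,-6,-9,-10}/429)."""
    if delta_lambda <= 0:
        raise DomainError("delta_lambda must be positive")
    kernel = savitzky_golay_kernel(window, polyorder, deriv=2)
    return _sg_derivative(values, kernel, delta_lambda**2, edge)


def apply_preprocessing(table: SpectraTable, tag: PreprocessTag) -> SpectraTable:
    """Apply a pretreatment row-wise to a spectra table.

    ``raw`` passes through unchanged; derivative methods truncate the
    wavelength axis consistently with the edge policy.
    """
    if tag.method == "raw":
        return SpectraTable(
            ids=table.ids.copy(),
            variety=table.variety.copy(),
            X=table.X.copy(),
            wavelengths_nm=table.wavelengths_nm.copy(),
        )
    wl = table.wavelengths_nm
    if tag.method in ("fd", "sd"):
        if tag.delta_lambda is not None:
            dl = tag.delta_lambda
        else:
            steps = np.diff(wl)
            dl = float(np.median(steps))
        half = tag.window // 2
        out_wl = wl[half:-half] if tag.edge == "drop" else wl

        def _one(row: np.ndarray) -> np.ndarray:
            if tag.method == "fd":
                return sg_first_derivative(
                    row, dl, window=tag.window, polyorder=tag.polyorder,
                    edge=tag.edge, literal=tag.literal_fd,
                )
            return sg_second_derivative(
                row, dl, window=tag.window, polyorder=tag.polyorder, edge=tag.edge
            )
    else:  # snv
        out_wl = wl

        def _one(row: np.ndarray) -> np.ndarray:
            return snv(row)

    rows = []
    for k in range(len(table)):
        try:
            rows.append(_one(table.X[k]))
        except DomainError as exc:
            raise type(exc)(
                f"row {k} (seed_id={table.ids[k]!r}): {exc}"
            ) from exc
    return SpectraTable(
        ids=table.ids.copy(),
        variety=table.variety.copy(),
        X=np.vstack(rows),
        wavelengths_nm=np.asarray(out_wl, dtype=np.float64).copy(),
    )
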
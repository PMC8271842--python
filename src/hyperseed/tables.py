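"""Tabular containers for per-seed spectra and labeled model matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["SpectraTable", "LabeledDataset"]


@dataclass
class SpectraTable:
    """Per-seed mean spectra: one row per seed, one column per wavelength.

    ``variety`` carries a free-form per-seed annotation (variety name or
    label); binary modelling labels live in :class:`LabeledDataset`.
    """

    ids: np.ndarray
    variety: np.ndarray
    X: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.variety = np.asarray(self.variety)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.X.ndim != 2:
            raise DomainError(f"X must be 2-D, got shape {self.X.shape}")
        n, p = self.X.shape
        if self.ids.shape != (n,) or self.variety.shape != (n,):
            raise DomainError("ids/variety must align with rows of X")
        if self.wavelengths_nm.shape != (p,):
            raise DomainError(
                f"{self.wavelengths_nm.size} wavelengths for {p} spectral columns"
            )

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:.2f}" for w in self.wavelengths_nm]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.variety)
        df.insert(0, "seed_id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["seed_id", "label"]:
            raise DomainError(
                f"{path}: expected leading columns seed_id, label, got "
                f"{list(df.columns[:2])}"
            )
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(
            ids=df["seed_id"].to_numpy(),
            variety=df["label"].to_numpy(),
            X=df.iloc[:, 2:].to_numpy(dtype=np.float64),
            wavelengths_nm=wl,
        )


@dataclass
class LabeledDataset:
    """Model matrix with binary labels: 1 = target variety, 0 = adulterant."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.ids = np.asarray(self.ids)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        n, p = self.X.shape
        if self.y.shape != (n,) or self.ids.shape != (n,):
            raise DomainError("y and ids must align with rows of X")
        if not np.isin(self.y, (0, 1)).all():
            raise DomainError("labels must be binary 0/1")
        self.y = self.y.astype(np.int64)
        if self.wavelengths_nm.shape != (p,):
            raise DomainError("wavelength axis does not match feature count")

    def __len__(self) -> int:
        return self.X.shape[0]
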
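"""Adulteration-group assembly and SPXY train/test partitioning.

The benchmark design mixes a target variety's pure seeds with one to three
adulterant varieties in 13 configurations (shipped as a packaged JSON
config).  Each assembled group is split 1:1 into training and test sets with
the sample-set partitioning based on joint x-y distance (SPXY): pairwise
distances combine a normalized Euclidean distance in spectral space with a
normalized label distance,

    d_xy(p, q) = d_x(p, q) / max(d_x)  +  d_y(p, q) / max(d_y),

and a Kennard-Stone-style greedy selection seeds the training set with the
most distant pair, then repeatedly adds the sample farthest (in minimum
d_xy) from the current training set.  The procedure is deterministic; ties
are broken toward the lower original row index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import DomainError
from .tables import LabeledDataset, SpectraTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSpec",
    "SplitIndices",
    "default_group_specs",
    "assemble_group",
    "joint_distance_matrix",
    "spxy_split",
    "random_split",
]


@dataclass(frozen=True)
class GroupSpec:
    """One benchmark group: per-variety seed counts and the target variety."""

    group_id: int
    target: int  # 1-based variety index
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.target <= len(self.counts):
            raise DomainError(
                f"target variety {self.target} out of range for {len(self.counts)} varieties"
            )
        if self.counts[self.target - 1] <= 0:
            raise DomainError("target variety count must be positive")
        if any(c < 0 for c in self.counts):
            raise DomainError("negative seed count")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices covering an assembled dataset."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        train = np.asarray(self.train, dtype=np.int64)
        test = np.asarray(self.test, dtype=np.int64)
        object.__setattr__(self, "train", train)
        object.__setattr__(self, "test", test)
        if np.intersect1d(train, test).size:
            raise DomainError("train and test indices overlap")


def default_group_specs() -> list[GroupSpec]:
    """The 13 packaged benchmark group definitions."""
    text = resources.files("hyperseed.data").joinpath("groups.json").read_text()
    cfg = json.loads(text)
    return [
        GroupSpec(
            group_id=int(g["group_id"]),
            target=int(g["target"]),
            counts=tuple(int(c) for c in g["counts"]),
        )
        for g in cfg["groups"]
    ]


def assemble_group(
    tables: list[SpectraTable],
    spec: GroupSpec,
    seed: int | np.random.Generator = 0,
) -> LabeledDataset:
    """Concatenate the requested seeds per variety into one labeled dataset.

    When a variety table holds more seeds than requested, the subset is drawn
    without replacement using the given RNG seed.  Label 1 marks the target
    variety.
    """
    if len(tables) != len(spec.counts):
        raise DomainError(
            f"{len(tables)} variety tables for {len(spec.counts)} count entries"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    wl = tables[0].wavelengths_nm
    xs, ys, ids = [], [], []
    for v, (table, count) in enumerate(zip(tables, spec.counts), start=1):
        if count == 0:
            continue
        if len(table) < count:
            raise DomainError(
                f"variety {v}: requested {count} seeds but table has {len(table)}"
            )
        if not np.array_equal(table.wavelengths_nm, wl):
            raise DomainError(f"variety {v}: wavelength axis mismatch")
        if len(table) == count:
            rows = np.arange(count)
        else:
            rows = np.sort(rng.choice(len(table), size=count, replace=False))
        xs.append(table.X[rows])
        ys.append(np.full(count, 1 if v == spec.target else 0, dtype=np.int64))
        ids.extend(f"v{v}:{table.ids[r]}" for r in rows)
    return LabeledDataset(
        X=np.vstack(xs),
        y=np.concatenate(ys),
        ids=np.asarray(ids, dtype=object),
        wavelengths_nm=wl.copy(),
    )


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise SPXY distance: normalized Euclidean x-distance plus
    normalized label distance.  With a single class the y-term is zero."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise DomainError("need at least 2 samples")
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros((n, n))
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


def spxy_split(
    X: np.ndarray, y: np.ndarray, train_fraction: float = 0.5
) -> SplitIndices:
    """Deterministic SPXY selection of a training set of size
    round(train_fraction * N), remainder to test."""
    if not 0.0 < train_fraction < 1.0:
        raise DomainError(f"train_fraction must be in (0, 1), got {train_fraction}")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 4:
        raise DomainError("need at least 4 samples to split")
    n_train = int(np.floor(train_fraction * n + 0.5))  # round half up
    n_train = min(max(n_train, 2), n - 1)
    d = joint_distance_matrix(X, y)
    # seed pair: maximum d_xy, ties toward lowest (row, col)
    flat = np.argmax(d)
    p, q = divmod(int(flat), n)
    selected = [min(p, q), max(p, q)]
    in_train = np.zeros(n, dtype=bool)
    in_train[selected] = True
    # min distance from each candidate to the training set
    min_d = np.minimum(d[:, selected[0]], d[:, selected[1]])
    while len(selected) < n_train:
        min_d_masked = np.where(in_train, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))  # argmax takes first (lowest index) on ties
        selected.append(nxt)
        in_train[nxt] = True
        min_d = np.minimum(min_d, d[:, nxt])
    train = np.sort(np.asarray(selected, dtype=np.int64))
    test = np.flatnonzero(~in_train).astype(np.int64)
    y_arr = np.asarray(y)
    if np.unique(y_arr).size > 1 and np.unique(y_arr[train]).size < 2:
        logger.warning("SPXY training set contains a single class")
    return SplitIndices(train=train, test=test)


def random_split(
    n: int, train_fraction: float = 0.5, seed: int = 0
) -> SplitIndices:
    """Seeded uniform random split with the same size contract as SPXY."""
    if not 0.0 < train_fraction < 1.0:
        raise DomainError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    return SplitIndices(
        train=np.sort(perm[:n_train]), test=np.sort(perm[n_train:])
    )
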
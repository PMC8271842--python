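"""Benchmark harness: sparse band-selecting model vs full-band logistic model.

For each adulteration group the experiment applies one pretreatment,
performs a 1:1 SPXY train/test split, selects the penalty by 10-fold CV on
the training half only, fits the sparse model at the selected lambda, fits
the unpenalized full-band model on the same training half, and scores both
on the held-out test half.  Reported accuracy is always test-set only; the
test indices are audited to never enter lambda selection or fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lasso
from .datasets import GroupSpec, assemble_group, default_group_specs, spxy_split
from .exceptions import DomainError
from .preprocess import PreprocessTag, apply_preprocessing
from .tables import LabeledDataset, SpectraTable

__all__ = ["EvalConfig", "EvaluationReport", "accuracy", "run_group_experiment",
           "run_full_benchmark"]


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Classification accuracy in percent."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise DomainError("predictions and labels must align")
    if predictions.size == 0:
        raise DomainError("empty input")
    return 100.0 * float(np.mean(predictions == labels))


@dataclass(frozen=True)
class EvalConfig:
    """Experiment parameters shared across groups."""

    lambda_grid: np.ndarray | None = None
    folds: int = 10
    cv_seed: int = 0
    rule: str = "max_accuracy_sparsest"
    train_fraction: float = 0.5
    tol: float = 1e-7
    max_iter: int = 100_000
    lrm_max_iter: int = 20_000  # unpenalized full-band fit may be separable


@dataclass
class EvaluationReport:
    """Per-group rows plus per-pretreatment averages."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame

    def to_markdown(self) -> str:
        lines = ["| group | preprocessing | model | accuracy % | n_test | bands | lambda |",
                 "|---|---|---|---|---|---|---|"]
        for _, r in self.rows.iterrows():
            lam = "" if np.isnan(r["lambda"]) else f"{r['lambda']:.4g}"
            lines.append(
                f"| {r['group_id']} | {r['preprocessing']} | {r['model']} | "
                f"{r['accuracy_pct']:.2f} | {r['n_test']} | {r['n_selected_bands']} | {lam} |"
            )
        lines.append("")
        lines.append("| preprocessing | model | mean accuracy % |")
        lines.append("|---|---|---|")
        for _, r in self.aggregates.iterrows():
            lines.append(
                f"| {r['preprocessing']} | {r['model']} | {r['mean_accuracy_pct']:.2f} |"
            )
        return "\n".join(lines)


def _preprocessed_dataset(dataset: LabeledDataset, tag: PreprocessTag) -> LabeledDataset:
    table = SpectraTable(
        ids=dataset.ids, variety=dataset.y.astype(object),
        X=dataset.X, wavelengths_nm=dataset.wavelengths_nm,
    )
    out = apply_preprocessing(table, tag)
    return LabeledDataset(
        X=out.X, y=dataset.y, ids=dataset.ids, wavelengths_nm=out.wavelengths_nm
    )


def run_group_experiment(
    dataset: LabeledDataset,
    preprocessing: PreprocessTag,
    config: EvalConfig = EvalConfig(),
    group_id: int = 0,
) -> list[dict]:
    """Run the sparse-vs-full comparison on one assembled group.

    Returns two report rows (sparse model, full-band model).
    """
    try:
        data = _preprocessed_dataset(dataset, preprocessing)
        split = spxy_split(data.X, data.y, config.train_fraction)
        assert np.intersect1d(split.train, split.test).size == 0
        Xtr, ytr = data.X[split.train], data.y[split.train]
        Xte, yte = data.X[split.test], data.y[split.test]
        cv = lasso.cross_validate(
            Xtr, ytr, config.lambda_grid, folds=config.folds,
            seed=config.cv_seed, tol=config.tol, max_iter=config.max_iter,
        )
        lam_star = lasso.select_lambda(cv, config.rule)
        sparse = lasso.fit_lasso_logistic(
            Xtr, ytr, lam_star, tol=config.tol, max_iter=config.max_iter
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            full = lasso.fit_lasso_logistic(
                Xtr, ytr, 0.0, tol=config.tol, max_iter=config.lrm_max_iter
            )
    except DomainError as exc:
        raise DomainError(
            f"group {group_id} ({preprocessing.method}): {exc}"
        ) from exc
    p = data.X.shape[1]
    rows = []
    for name, model, bands in (
        ("LLRM", sparse, sparse.n_nonzero),
        ("LRM", full, p),
    ):
        pred = lasso.predict(model, Xte)
        rows.append(
            {
                "group_id": group_id,
                "preprocessing": preprocessing.method,
                "model": name,
                "accuracy_pct": accuracy(pred, yte),
                "n_test": int(yte.size),
                "n_selected_bands": int(bands),
                "lambda": lam_star if name == "LLRM" else np.nan,
            }
        )
    return rows


def run_full_benchmark(
    variety_tables: list[SpectraTable],
    config: EvalConfig = EvalConfig(),
    preprocessings: tuple[str, ...] = ("snv", "fd", "sd"),
    group_specs: list[GroupSpec] | None = None,
    assembly_seed: int = 0,
) -> EvaluationReport:
    """Assemble every benchmark group, run all pretreatments, aggregate.

    Emits one row per (group, pretreatment, model) and per-pretreatment mean
    accuracies.  Fully deterministic for fixed seeds and config.
    """
    if any(len(t) < 72 for t in variety_tables):
        raise DomainError("each variety table must hold at least 72 seeds")
    specs = default_group_specs() if group_specs is None else group_specs
    rows: list[dict] = []
    for spec in specs:
        dataset = assemble_group(
            variety_tables, spec, seed=assembly_seed + spec.group_id
        )
        for method in preprocessings:
            tag = PreprocessTag(method=method)
            rows.extend(
                run_group_experiment(dataset, tag, config, group_id=spec.group_id)
            )
    frame = pd.DataFrame(rows)
    aggregates = (
        frame.groupby(["preprocessing", "model"], as_index=False)["accuracy_pct"]
        .mean()
        .rename(columns={"accuracy_pct": "mean_accuracy_pct"})
    )
    return EvaluationReport(rows=frame, aggregates=aggregates)
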
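"""Repeated-resampling classification benchmark.

The experiment grid crosses two train/test split schemes (record-level
``by_test`` vs grouped ``by_patient``), two missing-extremum restitution
schemes (``zeros`` vs ``ratio_mean``), and five classifiers (random forest,
logistic regression, and SVMs with linear / RBF / polynomial kernels). Each
cell is repeated ``n_repetitions`` times on fresh stratified 80/20 resamples;
per-repetition metrics (5-fold CV accuracy on the training side, then
specificity, sensitivity, precision, recall, accuracy, F1 and AUC on the
held-out side) are averaged per cell. With the defaults the grid is
2 × 2 × 5 = 20 cells and 20 × 300 = 6000 individual runs.

Grouped splitting exists because all tests of one patient look alike and
share one patient-level outcome: letting a patient straddle the split lets
classifiers recognize patients rather than physiology, inflating every
metric. Restitution and normalization statistics are fit on the training
side of each repetition (a ``fit_on_all`` compatibility flag reproduces the
leakier fit-before-split ordering).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import (KFold, StratifiedGroupKFold,
                                     StratifiedKFold, train_test_split)
from sklearn.svm import SVC

from .features import (MODEL_INPUT_COLUMNS, apply_normalizer, fit_impute_stats,
                       fit_normalizer, impute_missing)

__all__ = [
    "ModelSpec",
    "ExperimentConfig",
    "Metrics",
    "METRIC_NAMES",
    "DEFAULT_MODELS",
    "build_estimator",
    "split_data",
    "crossval_accuracy",
    "compute_metrics",
    "run_single",
    "run_experiment_grid",
]

METRIC_NAMES = ["cv_accuracy", "specificity", "sensitivity", "precision",
                "recall", "accuracy", "f1", "auc"]


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family, with an SVM kernel where applicable."""

    family: Literal["random_forest", "logistic_regression", "svm"]
    kernel: Literal["linear", "rbf", "poly"] | None = None
    hyperparameters: tuple = ()  # (key, value) pairs; library defaults if empty

    def __post_init__(self) -> None:
        if (self.kernel is not None) != (self.family == "svm"):
            raise ValueError("kernel must be given exactly when family='svm'")

    @property
    def name(self) -> str:
        return self.family if self.kernel is None else f"svm_{self.kernel}"


DEFAULT_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("random_forest"),
    ModelSpec("logistic_regression"),
    ModelSpec("svm", "linear"),
    ModelSpec("svm", "rbf"),
    ModelSpec("svm", "poly"),
)


def build_estimator(spec: ModelSpec, seed: int | None = None):
    """Instantiate the scikit-learn estimator behind a spec.

    Hyperparameters are the library defaults unless overridden in the spec;
    ``seed`` pins any stochastic initialization.
    """
    kw = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **kw)
    if spec.family == "logistic_regression":
        kw.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **kw)
    return SVC(kernel=spec.kernel, random_state=seed, **kw)


def _decision_scores(est, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ROC: probabilities if available, else margins."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


@dataclass(frozen=True)
class ExperimentConfig:
    """The full experiment grid specification."""

    split_modes: tuple[str, ...] = ("by_test", "by_patient")
    impute_schemes: tuple[str, ...] = ("zeros", "ratio_mean")
    models: tuple[ModelSpec, ...] = DEFAULT_MODELS
    test_fraction: float = 0.2
    cv_folds: int = 5
    n_repetitions: int = 300
    base_seed: int = 0
    fit_on_all: bool = False  # True reproduces fit-before-split normalization

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.split_modes) * len(self.impute_schemes) * len(self.models)

    @property
    def n_runs(self) -> int:
        return self.n_cells * self.n_repetitions


@dataclass
class Metrics:
    """Per-run metric suite; AUC is NaN when the truth is single-class."""

    cv_accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _split_by_patient(table: pd.DataFrame, test_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy whole-patient assignment approximating the target row fraction.

    One patient per class is forced into the test side whenever the class
    has at least two patients (so both sides keep both classes when
    feasible); remaining patients join the test side while that moves its
    row count toward ``test_fraction`` of all rows.
    """
    pat = table.groupby("patient_id").agg(
        n=("target", "size"), y=("target", "first"))
    patients = pat.index.to_numpy()
    order = patients[rng.permutation(len(patients))]
    target_rows = test_fraction * len(table)

    test_ids: set = set()
    rows = 0
    for cls in (1, 0):
        cls_pats = [p for p in order if pat.loc[p, "y"] == cls]
        if len(cls_pats) >= 2:
            test_ids.add(cls_pats[0])
            rows += int(pat.loc[cls_pats[0], "n"])
    for p in order:
        if p in test_ids:
            continue
        cls = pat.loc[p, "y"]
        train_left = sum(1 for q in patients
                        if q not in test_ids and q != p and pat.loc[q, "y"] == cls)
        if train_left == 0:
            continue  # would empty this class from the training side
        n_p = int(pat.loc[p, "n"])
        if abs(rows + n_p - target_rows) < abs(rows - target_rows):
            test_ids.add(p)
            rows += n_p
    mask = table["patient_id"].isin(test_ids)
    return table[~mask].copy(), table[mask].copy()


def split_data(table: pd.DataFrame, mode: str, test_fraction: float,
               seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified train/test resample.

    ``by_test`` splits at the row level with class stratification;
    ``by_patient`` assigns each patient wholly to one side. Deterministic
    given ``seed``.
    """
    if mode == "by_test":
        train, test = train_test_split(
            table, test_size=test_fraction, random_state=seed,
            stratify=table["target"])
        return train.copy(), test.copy()
    if mode == "by_patient":
        return _split_by_patient(table, test_fraction,
                                 np.random.default_rng(seed))
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# Cross-validation and metrics
# ---------------------------------------------------------------------------

def _input_matrix(table: pd.DataFrame,
                  columns: Sequence[str] | None = None) -> np.ndarray:
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c in MODEL_INPUT_COLUMNS]
    return table[cols].to_numpy(dtype=float)


def crossval_accuracy(spec: ModelSpec, train: pd.DataFrame, cv_folds: int,
                      seed: int, *, grouped: bool = False,
                      columns: Sequence[str] | None = None) -> float:
    """Mean accuracy over (stratified, optionally patient-grouped) CV folds.

    ``cv_folds == len(train)`` degrades gracefully to leave-one-out. A fold
    arrangement whose training side is single-class is resampled with a new
    seed, up to 100 attempts.
    """
    X = _input_matrix(train, columns)
    y = train["target"].to_numpy(dtype=int)
    groups = train["patient_id"].to_numpy()
    if cv_folds > len(train):
        raise ValueError(f"cv_folds={cv_folds} exceeds {len(train)} training rows")
    last_err: Exception | None = None
    for attempt in range(100):
        rs = seed + attempt
        if cv_folds == len(train):
            splitter = KFold(n_splits=cv_folds)
        elif grouped:
            splitter = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True,
                                            random_state=rs)
        else:
            splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                       random_state=rs)
        try:
            accs = []
            for tr_idx, va_idx in splitter.split(X, y,
                                                 groups if grouped else None):
                if len(np.unique(y[tr_idx])) < 2:
                    raise ValueError("single-class training fold")
                est = build_estimator(spec, seed=rs)
                est.fit(X[tr_idx], y[tr_idx])
                accs.append(accuracy_score(y[va_idx], est.predict(X[va_idx])))
            return float(np.mean(accs))
        except ValueError as err:
            last_err = err
            continue
    raise RuntimeError(f"cross-validation failed after 100 fold resamples: "
                       f"{last_err}")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None,
                    cv_accuracy: float = math.nan) -> Metrics:
    """Confusion-matrix metric suite with pinned zero-denominator conventions.

    Precision (and hence F1) is 0 when nothing is predicted positive; AUC
    is the rank statistic over continuous scores (ties count half) and is
    NaN when the truth contains a single class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    acc = safe(tp + tn, len(y_true))
    f1 = safe(2 * prec * sens, prec + sens)
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = math.nan
    return Metrics(cv_accuracy=cv_accuracy, specificity=spec, sensitivity=sens,
                   precision=prec, recall=sens, accuracy=acc, f1=f1, auc=auc)


# ---------------------------------------------------------------------------
# Single run and full grid
# ---------------------------------------------------------------------------

_MODEL_SEED_OFFSET = 10 ** 6  # keeps split and model seeds disjoint


def run_single(table: pd.DataFrame, config: ExperimentConfig, model: ModelSpec,
               repetition: int, *, split_mode: str,
               impute_scheme: str) -> Metrics:
    """One resample: split -> train-side restitution/normalization -> CV ->
    fit -> held-out metrics. Repetition ``r`` uses ``base_seed + r`` for the
    split and ``base_seed + 10**6 + r`` for model initialization."""
    seed = config.base_seed + repetition
    model_seed = config.base_seed + _MODEL_SEED_OFFSET + repetition
    train, test = split_data(table, split_mode, config.test_fraction, seed)

    stats_source = table if config.fit_on_all else train
    imp = (fit_impute_stats(stats_source)
           if impute_scheme == "ratio_mean" else None)
    train = impute_missing(train, impute_scheme, imp)
    test = impute_missing(test, impute_scheme, imp)
    norm = fit_normalizer(impute_missing(stats_source, impute_scheme, imp)
                          if config.fit_on_all else train)
    train = apply_normalizer(train, norm)
    test = apply_normalizer(test, norm)

    cv = crossval_accuracy(model, train, min(config.cv_folds, len(train)),
                           seed, grouped=(split_mode == "by_patient"))
    est = build_estimator(model, seed=model_seed)
    Xtr, ytr = _input_matrix(train), train["target"].to_numpy(dtype=int)
    Xte, yte = _input_matrix(test), test["target"].to_numpy(dtype=int)
    est.fit(Xtr, ytr)
    return compute_metrics(yte, est.predict(Xte), _decision_scores(est, Xte),
                           cv_accuracy=cv)


def _cell_runs(table: pd.DataFrame, config: ExperimentConfig, model: ModelSpec,
               split_mode: str, impute_scheme: str) -> list[dict]:
    records = []
    for r in range(config.n_repetitions):
        m = run_single(table, config, model, r, split_mode=split_mode,
                       impute_scheme=impute_scheme)
        records.append({
            "split_mode": split_mode, "impute_scheme": impute_scheme,
            "model": model.name, "repetition": r,
            "split_seed": config.base_seed + r,
            "model_seed": config.base_seed + _MODEL_SEED_OFFSET + r,
            "hyperparameters": {k: v for k, v in
                                build_estimator(model).get_params().items()
                                if not callable(v)},
            **m.as_dict(),
        })
    return records


def run_experiment_grid(table: pd.DataFrame, config: ExperimentConfig,
                        *, n_jobs: int = 1,
                        log_path: str | Path | None = None) -> pd.DataFrame:
    """Execute the full grid and average each cell over repetitions.

    Returns one row per (split_mode, impute_scheme, model) with the mean
    and standard deviation of every metric; single-class AUC runs are
    excluded from the AUC average. Parallelism is over grid cells with
    per-repetition seeding, so results are identical at any ``n_jobs``.
    ``log_path`` receives one JSON line per run (seeds, hyperparameters,
    metrics).
    """
    cells = [(m, sm, im) for sm in config.split_modes
             for im in config.impute_schemes for m in config.models]
    all_records = Parallel(n_jobs=n_jobs)(
        delayed(_cell_runs)(table, config, model, sm, im)
        for model, sm, im in cells)

    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec_list in all_records:
                for rec in rec_list:
                    fh.write(json.dumps(rec, default=str) + "\n")

    rows = []
    for (model, sm, im), recs in zip(cells, all_records):
        df = pd.DataFrame(recs)
        row = {"split_mode": sm, "impute_scheme": im, "model": model.name,
               "n_repetitions": len(recs)}
        for metric in METRIC_NAMES:
            vals = df[metric].dropna()  # drops undefined-AUC runs
            row[metric] = float(vals.mean()) if len(vals) else math.nan
            row[f"{metric}_std"] = (float(vals.std(ddof=0))
                                    if len(vals) else math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
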
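"""Random-Forest calibration of the immobility-detection threshold.

For each mouse the automated immobility time is computed at the five
candidate thresholds (0.4-1.2 g) and paired with the manually scored
immobility time.  A Random Forest regressor with features
``(threshold, auto_time)`` and target ``manual_time`` is trained with an
animal-level 75/25 split and grouped 5-fold cross-validation (no mouse
ever spans partitions or folds), a baseline forest (200 trees, seed 42)
is compared against a randomized-search-tuned one, and the selected model
scans a dense threshold grid to find the single *global best threshold*
(GBT) minimizing the mean absolute prediction error across animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, RandomizedSearchCV

__all__ = [
    "CalibrationDataset",
    "CalibrationResult",
    "build_dataset",
    "split_by_animal",
    "cross_validate",
    "fit_model",
    "tune_model",
    "estimate_global_threshold",
    "calibrate",
    "mae",
]

FEATURES = ["threshold", "auto_time"]
TARGET = "manual_time"
GRID_STEP_G = 0.001

#: Randomized-search ranges for the tuned forest (25 draws, seed 42).
TUNING_DISTRIBUTIONS = {
    "n_estimators": list(range(100, 601, 50)),
    "max_depth": [None, 4, 6, 8, 10, 12, 14, 16],
    "min_samples_leaf": [1, 2, 3, 4, 5, 6, 7, 8],
    "max_features": [1.0, "sqrt"],
}


@dataclass(frozen=True)
class CalibrationDataset:
    """Full cross of mice x candidate thresholds.

    ``frame`` has columns ``mouse_id, threshold, auto_time, manual_time``;
    every mouse carries the same threshold set and a single manual time.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        required = {"mouse_id", "threshold", "auto_time", "manual_time"}
        if not required <= set(df.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if ((df["auto_time"] < 0) | (df["auto_time"] > 360)).any():
            raise ValueError("auto_time outside [0, 360]")
        if ((df["manual_time"] < 0) | (df["manual_time"] > 360)).any():
            raise ValueError("manual_time outside [0, 360]")
        ref = None
        for mouse, grp in df.groupby("mouse_id"):
            ths = tuple(sorted(grp["threshold"]))
            if ref is None:
                ref = ths
            elif ths != ref:
                raise ValueError("every mouse must share the same threshold set")
            if grp["manual_time"].nunique() > 1:
                raise ValueError("manual_time must be constant within a mouse")

    @property
    def mice(self) -> list:
        return sorted(self.frame["mouse_id"].unique())

    @property
    def thresholds(self) -> np.ndarray:
        return np.sort(self.frame["threshold"].unique())

    def subset(self, mice) -> "CalibrationDataset":
        return CalibrationDataset(
            self.frame[self.frame["mouse_id"].isin(list(mice))].reset_index(drop=True)
        )


@dataclass(frozen=True)
class CalibrationResult:
    global_best_threshold: float  # g
    individual_thresholds: dict  # mouse_id -> g
    cv_mae: float  # s, mean over grouped folds
    test_mae: float  # s, held-out animals
    model_choice: str  # "baseline" | "tuned"
    objective: str = "model"
    seed: int = 42
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cv_mae < 0 or self.test_mae < 0:
            raise ValueError("MAE cannot be negative")


def mae(auto_times, manual_times) -> float:
    """Mean absolute error between paired scores (seconds)."""
    a = np.asarray(auto_times, dtype=float)
    m = np.asarray(manual_times, dtype=float)
    if a.shape != m.shape or a.size == 0:
        raise ValueError("unpaired vectors")
    return float(np.mean(np.abs(a - m)))


def build_dataset(cohort_scores: dict, manual: dict) -> CalibrationDataset:
    """Assemble the calibration table from per-mouse threshold sweeps.

    ``cohort_scores`` maps mouse_id to ``[(threshold, auto_time), ...]``;
    ``manual`` maps mouse_id to the manually scored immobility time.  No
    rows are deleted or imputed; a scored mouse without a manual time is an
    error.
    """
    rows = []
    for mouse, sweep in cohort_scores.items():
        if mouse not in manual:
            raise ValueError("unpaired subject")
        for th, auto in sweep:
            rows.append((mouse, float(th), float(auto), float(manual[mouse])))
    if not rows:
        raise ValueError("empty cohort")
    return CalibrationDataset(
        pd.DataFrame(rows, columns=["mouse_id", "threshold", "auto_time", "manual_time"])
    )


def split_by_animal(dataset: CalibrationDataset, train_frac: float = 0.75, seed: int = 42):
    """Animal-level train/test split: no mouse appears in both partitions.

    The train partition holds ``round(train_frac * n_mice)`` mice, drawn by
    a seeded permutation of the sorted mouse ids.
    """
    mice = dataset.mice
    if len(mice) < 4:
        raise ValueError("too few subjects to split")
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(mice))
    n_train = int(round(train_frac * len(mice)))
    train_mice = [mice[i] for i in sorted(order[:n_train])]
    test_mice = [mice[i] for i in sorted(order[n_train:])]
    return dataset.subset(train_mice), dataset.subset(test_mice)


def _make_model(spec="baseline", seed: int = 42, **kw):
    if spec == "baseline":
        return RandomForestRegressor(n_estimators=200, random_state=seed, **kw)
    raise ValueError(f"unknown model spec {spec!r}")


def cross_validate(train: CalibrationDataset, model=None, n_splits: int = 5, seed: int = 42) -> float:
    """Grouped cross-validation MAE (seconds), averaged across folds.

    Folds are grouped by mouse so no animal spans folds.
    """
    df = train.frame
    groups = df["mouse_id"].to_numpy()
    if len(np.unique(groups)) < n_splits:
        raise ValueError("too few groups for 5-fold grouping")
    if model is None:
        model = _make_model(seed=seed)
    X = df[FEATURES].to_numpy()
    y = df[TARGET].to_numpy()
    maes = []
    for tr_idx, te_idx in GroupKFold(n_splits=n_splits).split(X, y, groups):
        m = clone(model)
        m.fit(X[tr_idx], y[tr_idx])
        maes.append(mae(m.predict(X[te_idx]), y[te_idx]))
    return float(np.mean(maes))


def fit_model(train: CalibrationDataset, spec: str = "baseline", seed: int = 42):
    """Fit the threshold-response forest on the full training partition."""
    if len(train.frame) == 0:
        raise ValueError("no training data")
    model = _make_model(spec, seed=seed) if isinstance(spec, str) else spec
    X = train.frame[FEATURES].to_numpy()
    y = train.frame[TARGET].to_numpy()
    model.fit(X, y)
    return model


def tune_model(train: CalibrationDataset, n_iter: int = 25, seed: int = 42):
    """Randomized hyperparameter search under the same grouped CV scheme.

    Returns ``(selected_model_unfitted, comparison)`` where the comparison
    records baseline and tuned CV MAE and the choice.  The baseline forest
    is kept unless the tuned one strictly improves the CV MAE.
    """
    df = train.frame
    groups = df["mouse_id"].to_numpy()
    if len(np.unique(groups)) < 5:
        raise ValueError("too few groups for 5-fold grouping")
    baseline = _make_model(seed=seed)
    baseline_cv = cross_validate(train, baseline, seed=seed)

    X = df[FEATURES].to_numpy()
    y = df[TARGET].to_numpy()
    search = RandomizedSearchCV(
        _make_model(seed=seed),
        TUNING_DISTRIBUTIONS,
        n_iter=n_iter,
        scoring="neg_mean_absolute_error",
        cv=GroupKFold(n_splits=5),
        random_state=seed,
        n_jobs=1,
    )
    search.fit(X, y, groups=groups)
    tuned_cv = -float(search.best_score_)

    if tuned_cv < baseline_cv:
        choice, model = "tuned", _make_model(seed=seed).set_params(**search.best_params_)
        chosen_cv = tuned_cv
    else:
        choice, model = "baseline", baseline
        chosen_cv = baseline_cv
    comparison = {
        "baseline_cv_mae": baseline_cv,
        "tuned_cv_mae": tuned_cv,
        "tuned_params": dict(search.best_params_),
        "model_choice": choice,
        "cv_mae": chosen_cv,
    }
    return model, comparison


def _auto_time_interp(dataset: CalibrationDataset, mouse, grid: np.ndarray) -> np.ndarray:
    """Monotone (piecewise-linear) auto-time across candidate thresholds."""
    grp = dataset.frame[dataset.frame["mouse_id"] == mouse].sort_values("threshold")
    th = grp["threshold"].to_numpy()
    at = np.maximum.accumulate(grp["auto_time"].to_numpy())  # enforce monotone
    return np.interp(grid, th, at)


def estimate_global_threshold(
    model,
    dataset: CalibrationDataset,
    grid_step: float = GRID_STEP_G,
    auto_time_fn=None,
    objective: str = "direct",
) -> tuple:
    """Scan a dense threshold grid for the global best threshold (GBT).

    For each grid threshold the per-mouse auto time is recomputed from the
    signal when ``auto_time_fn(mouse, threshold) -> seconds`` is supplied,
    otherwise interpolated monotonically across the candidate sweep.  Two
    objectives are implemented: the default ``"direct"`` minimizes the mean
    over mice of ``|auto_time(theta) - manual_time|``; ``"model"`` instead
    minimizes ``|model-predicted manual - observed manual|``.  The direct
    objective is the default because on cohorts scored at only five
    candidate thresholds the forest can learn to invert each candidate's
    bias, flattening the model objective to candidate resolution.  Ties
    resolve to the smallest threshold.

    Returns ``(gbt, individual_thresholds, grid, error_curve)``.
    """
    ths = dataset.thresholds
    lo, hi = float(ths.min()), float(ths.max())
    n_steps = int(round((hi - lo) / grid_step))
    if n_steps < 1:
        raise ValueError("degenerate threshold range")
    grid = lo + grid_step * np.arange(n_steps + 1)

    mice = dataset.mice
    manual = {
        m: float(dataset.frame.loc[dataset.frame["mouse_id"] == m, "manual_time"].iloc[0])
        for m in mice
    }
    errs = np.empty((len(mice), len(grid)))
    for i, m in enumerate(mice):
        if auto_time_fn is not None:
            autos = np.array([auto_time_fn(m, th) for th in grid], dtype=float)
        else:
            autos = _auto_time_interp(dataset, m, grid)
        if objective == "model":
            X = np.column_stack([grid, autos])
            pred = model.predict(X)
        elif objective == "direct":
            pred = autos
        else:
            raise ValueError(f"unknown objective {objective!r}")
        errs[i] = np.abs(pred - manual[m])

    mean_err = errs.mean(axis=0)
    gbt = float(grid[int(np.argmin(mean_err))])
    individual = {m: float(grid[int(np.argmin(errs[i]))]) for i, m in enumerate(mice)}
    ind_vals = np.array(list(individual.values()))
    if not (ind_vals.min() - 1e-12 <= gbt <= ind_vals.max() + 1e-12):
        warnings.warn(
            "global best threshold falls outside the range of individual "
            "optimal thresholds",
            stacklevel=2,
        )
    return gbt, individual, grid, mean_err


def calibrate(
    dataset: CalibrationDataset,
    seed: int = 42,
    tune: bool = True,
    grid_step: float = GRID_STEP_G,
    auto_time_fn=None,
    objective: str = "direct",
) -> CalibrationResult:
    """Full calibration: split, CV, model selection, test MAE, GBT scan."""
    train, test = split_by_animal(dataset, seed=seed)
    if tune:
        model, comparison = tune_model(train, seed=seed)
        choice = comparison["model_choice"]
        cv = comparison["cv_mae"]
    else:
        model = _make_model(seed=seed)
        cv = cross_validate(train, model, seed=seed)
        choice = "baseline"
        comparison = {"baseline_cv_mae": cv, "model_choice": choice}
    fitted = fit_model(train, spec=model, seed=seed)
    test_pred = fitted.predict(test.frame[FEATURES].to_numpy())
    test_mae = mae(test_pred, test.frame[TARGET].to_numpy())
    gbt, individual, _, _ = estimate_global_threshold(
        fitted, dataset, grid_step=grid_step, auto_time_fn=auto_time_fn,
        objective=objective,
    )
    return CalibrationResult(
        global_best_threshold=gbt,
        individual_thresholds=individual,
        cv_mae=float(cv),
        test_mae=float(test_mae),
        model_choice=choice,
        objective=objective,
        seed=seed,
        extras=comparison,
    )
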
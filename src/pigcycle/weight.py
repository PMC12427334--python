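"""Random-forest live-weight estimation from dorsal morphometrics.

The regressor maps the 5-vector (RA, CP, BL, BW, E) to body weight in kg.
Because each animal contributes many images, naive record-level splits
leak identity: the same pig's nearly identical silhouettes end up on both
sides and inflate accuracy.  All partitioning here — the train/test split
and every cross-validation fold — is therefore done at the level of pig
IDs, so no animal's records ever straddle a boundary.

Hyperparameters are chosen by exhaustive grid search with pig-level
K-fold cross-validation, scored by mean fold MAE; ties go to the smaller
forest, then the shallower depth, then the larger min-split (parsimony).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "SearchGrid",
    "EvalReport",
    "FittedWeightModel",
    "split_by_pig",
    "fit",
    "predict",
    "evaluate",
]

FEATURE_COLUMNS = ["RA", "CP", "BL", "BW", "E"]


@dataclass(frozen=True)
class SearchGrid:
    """Hyperparameter grid for the forest.

    The default grid is the full protocol grid (4 x 4 x 3 = 48 cells);
    ``small()`` gives a 2 x 2 x 2 grid for quick runs on synthetic data.
    """

    n_trees_options: Sequence[int] = (50, 100, 200, 500)
    max_depth_options: Sequence[int | None] = (10, 20, 30, None)
    min_split_options: Sequence[int] = (2, 5, 10)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_trees_options and self.max_depth_options and self.min_split_options):
            raise ValueError("every option list must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def small(cls, seed: int = 0, cv_folds: int = 5) -> "SearchGrid":
        return cls(
            n_trees_options=(100, 200),
            max_depth_options=(10, None),
            min_split_options=(2, 5),
            cv_folds=cv_folds,
            seed=seed,
        )


@dataclass(frozen=True)
class EvalReport:
    """Held-out accuracy summary plus feature importances."""

    MAE: float
    R2: float
    MAPE: float
    RMSE: float
    feature_importances: dict[str, float]
    n: int
    mape_excluded: int = 0

    def __post_init__(self) -> None:
        if self.RMSE + 1e-9 < self.MAE:
            raise ValueError("RMSE cannot be below MAE")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class FittedWeightModel:
    model: RandomForestRegressor
    hyperparameters: dict
    cv_mae: float
    train_weight_range: tuple[float, float]
    cv_table: pd.DataFrame | None = None

    def feature_importances(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(FEATURE_COLUMNS, self.model.feature_importances_)}


def _require_frame(records: pd.DataFrame, need_target: bool = True) -> None:
    missing = [c for c in ["pig_id", *FEATURE_COLUMNS] if c not in records.columns]
    if need_target and "observed_weight" not in records.columns:
        missing.append("observed_weight")
    if missing:
        raise ValueError(f"records table missing columns: {missing}")


def split_by_pig(
    records: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records so every pig's images land wholly on one side.

    The number of test pigs is the whole-pig count nearest to
    ``test_fraction`` of the herd (at least 1).  Deterministic in seed.
    """
    _require_frame(records, need_target=False)
    pigs = np.array(sorted(records["pig_id"].unique()))
    if len(pigs) < 5:
        raise ValueError(f"need >= 5 distinct pigs, got {len(pigs)}")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = max(1, int(math.floor(len(pigs) * test_fraction + 0.5)))
    if n_test >= len(pigs):
        raise ValueError("test fraction leaves no training pigs")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(pigs)
    test_ids = set(shuffled[:n_test])
    test = records[records["pig_id"].isin(test_ids)].copy()
    train = records[~records["pig_id"].isin(test_ids)].copy()
    overlap = set(train["pig_id"]) & set(test["pig_id"])
    assert not overlap, f"pig-level split violated: {overlap}"
    return train, test


def _pig_folds(pigs: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(np.sort(pigs))
    return [shuffled[i::k] for i in range(k)]


def fit(train: pd.DataFrame, grid: SearchGrid | None = None) -> FittedWeightModel:
    """Grid search with pig-level CV folds, then refit on all training data.

    Selection criterion: lowest mean cross-validated MAE; ties broken by
    fewer trees, then shallower depth (None counts as deepest), then
    larger min-split.  Configurations that fail to fit are recorded as
    invalid and skipped.
    """
    grid = grid or SearchGrid()
    _require_frame(train)
    if train.empty:
        raise ValueError("training table is empty")
    pigs = train["pig_id"].unique()
    k = min(grid.cv_folds, len(pigs))
    if k < 2:
        raise ValueError("need at least 2 pigs for cross-validation")
    folds = _pig_folds(pigs, k, grid.seed)

    X = train[FEATURE_COLUMNS].to_numpy()
    y = train["observed_weight"].to_numpy()
    pig_col = train["pig_id"].to_numpy()

    rows = []
    for n_trees in grid.n_trees_options:
        for depth in grid.max_depth_options:
            for min_split in grid.min_split_options:
                maes = []
                try:
                    for fold_pigs in folds:
                        held = np.isin(pig_col, fold_pigs)
                        model = RandomForestRegressor(
                            n_estimators=n_trees,
                            max_depth=depth,
                            min_samples_split=min_split,
                            random_state=grid.seed,
                            n_jobs=1,
                        )
                        model.fit(X[~held], y[~held])
                        err = np.abs(model.predict(X[held]) - y[held])
                        maes.append(float(err.mean()))
                    rows.append(
                        {
                            "n_trees": n_trees,
                            "max_depth": depth,
                            "min_split": min_split,
                            "cv_mae": float(np.mean(maes)),
                            "valid": True,
                        }
                    )
                except Exception as exc:  # cell recorded invalid, search continues
                    rows.append(
                        {
                            "n_trees": n_trees,
                            "max_depth": depth,
                            "min_split": min_split,
                            "cv_mae": float("inf"),
                            "valid": False,
                            "error": str(exc),
                        }
                    )
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise RuntimeError("every grid configuration failed to fit")

    def _depth_none(d) -> bool:
        return d is None or (isinstance(d, float) and math.isnan(d))

    def sort_key(row):
        depth_rank = float("inf") if _depth_none(row.max_depth) else row.max_depth
        return (row.cv_mae, row.n_trees, depth_rank, -row.min_split)

    best = min(valid.itertuples(index=False), key=sort_key)
    chosen = {
        "n_estimators": int(best.n_trees),
        "max_depth": None if _depth_none(best.max_depth) else int(best.max_depth),
        "min_samples_split": int(best.min_split),
    }
    final = RandomForestRegressor(**chosen, random_state=grid.seed, n_jobs=1)
    final.fit(X, y)
    return FittedWeightModel(
        model=final,
        hyperparameters=chosen,
        cv_mae=float(best.cv_mae),
        train_weight_range=(float(y.min()), float(y.max())),
        cv_table=table,
    )


def predict(model: FittedWeightModel, features) -> np.ndarray:
    """Ensemble-mean weight prediction (kg) for one or many 5-vectors."""
    arr = np.asarray(
        features[FEATURE_COLUMNS].to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected {len(FEATURE_COLUMNS)} features, got {arr.shape[1]}")
    if not np.isfinite(arr).all():
        raise ValueError("feature vector contains non-finite entries")
    return model.model.predict(arr)


def evaluate(
    preds, truth, feature_importances: dict[str, float] | None = None
) -> EvalReport:
    """MAE, RMSE, MAPE (%) and R2 of predictions against scale weights.

    Zero-weight truth values are excluded from MAPE (their relative error
    is undefined); the count of exclusions is carried in the report.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("predictions and truth must be equal-length with n >= 2")
    err = p - t
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    nonzero = t != 0
    excluded = int((~nonzero).sum())
    mape = float((np.abs(err[nonzero]) / t[nonzero]).mean() * 100.0) if nonzero.any() else float("nan")
    sst = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - float((err**2).sum()) / sst if sst > 0 else float("nan")
    return EvalReport(
        MAE=mae,
        R2=r2,
        MAPE=mape,
        RMSE=rmse,
        feature_importances=feature_importances or {},
        n=int(p.size),
        mape_excluded=excluded,
    )
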
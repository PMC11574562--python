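"""Chained-equations (MICE) imputation with gradient-boosted tree regressors.

A metabolite can go unquantified in a run for technical or biological
reasons, leaving NaN cells in the normalized feature matrix.  The classifier
needs complete vectors, so missing cells are filled by chained equations:

1. every missing cell starts at its feature's observed training mean;
2. features are visited in a fixed order (ascending missingness count,
   ties broken by metabolite id); for each visited feature a regression
   model is fit from predictor features (current working values) to the
   feature's observed cells, and the feature's missing cells are
   overwritten with its predictions -- one sweep over all features is one
   iteration;
3. sweeps repeat until an iteration limit (default 5) is reached or the
   sum of squared differences between successive imputations grows, in
   which case the grown iteration is rolled back.

As is standard for chained equations on wide matrices, each feature's
regression uses a preselected predictor subset: its ``n_predictors`` most
correlated companion features (absolute Pearson correlation on the
mean-initialized matrix, ties broken by metabolite id).  This keeps the
thousands of per-feature tree fits tractable while retaining the
correlated structure the imputation exploits.

Fitting yields a frozen :class:`ImputationModel` -- per-feature means,
predictor lists and one trained regressor per feature -- that is applied
to test or validation samples *without refitting*, each sample
independently, preserving the single-sample testing contract.  Observed
cells are never modified.

The regressor is a LightGBM gradient-boosted tree ensemble by default; any
object implementing the small ``fit/predict/save/load`` surface of
:class:`LgbmRegressor` can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import lightgbm as lgb
import numpy as np
import pandas as pd

from .containers import FeatureMatrix

# Ensemble defaults: shallow trees and coarse histograms keep each of the
# thousands of per-feature fits cheap on a single CPU while capturing the
# smooth monotone relationships between correlated metabolite intensities.
DEFAULT_LGBM_PARAMS: dict = {
    "objective": "regression",
    "n_estimators": 100,
    "num_leaves": 7,
    "max_depth": 3,
    "learning_rate": 0.1,
    "min_child_samples": 5,
    "colsample_bytree": 0.7,
    "max_bin": 63,
    "verbosity": -1,
    "n_jobs": 1,
    "deterministic": True,
    "force_col_wise": True,
}

DEFAULT_N_PREDICTORS = 30


class LgbmRegressor:
    """Thin deterministic wrapper around a LightGBM regressor booster."""

    def __init__(self, seed: int = 0, **params):
        self.params = {**DEFAULT_LGBM_PARAMS, **params, "random_state": seed}
        self._booster: lgb.Booster | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LgbmRegressor":
        model = lgb.LGBMRegressor(**self.params)
        model.fit(np.asarray(X, float), np.asarray(y, float))
        self._booster = model.booster_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._booster is None:
            raise RuntimeError("regressor is not fitted")
        return self._booster.predict(np.asarray(X, float))

    def save(self, path: str | Path) -> None:
        if self._booster is None:
            raise RuntimeError("regressor is not fitted")
        self._booster.save_model(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LgbmRegressor":
        obj = cls()
        obj._booster = lgb.Booster(model_file=str(path))
        return obj


RegressorFactory = Callable[[int], LgbmRegressor]


@dataclass
class ImputationModel:
    """Frozen chained-equations imputer fitted on training data."""

    feature_means: pd.Series
    regressors: dict[str, LgbmRegressor]
    predictors: dict[str, list[str]]
    visit_order: list[str]
    n_iterations_run: int
    seed: int
    feature_order: list[str] = field(default_factory=list)
    ssd_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_order:
            self.feature_order = list(self.feature_means.index)
        missing = set(self.feature_order) - set(self.regressors)
        if missing:
            raise ValueError(f"no regressor for features {sorted(missing)[:5]}")

    # -- serialization (directory bundle: means JSON + booster text files) ---
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "feature_order": self.feature_order,
            "visit_order": self.visit_order,
            "n_iterations_run": self.n_iterations_run,
            "seed": self.seed,
            "ssd_history": self.ssd_history,
            "feature_means": {k: float(v) for k, v in self.feature_means.items()},
            "predictors": self.predictors,
        }
        (out / "manifest.json").write_text(json.dumps(manifest))
        reg_dir = out / "regressors"
        reg_dir.mkdir(exist_ok=True)
        for fid, reg in self.regressors.items():
            reg.save(reg_dir / f"{fid}.txt")

    @classmethod
    def load(cls, in_dir: str | Path) -> "ImputationModel":
        out = Path(in_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        regs = {fid: LgbmRegressor.load(out / "regressors" / f"{fid}.txt")
                for fid in manifest["feature_order"]}
        return cls(
            feature_means=pd.Series(manifest["feature_means"]),
            regressors=regs,
            predictors=manifest["predictors"],
            visit_order=manifest["visit_order"],
            n_iterations_run=manifest["n_iterations_run"],
            seed=manifest["seed"],
            feature_order=manifest["feature_order"],
            ssd_history=manifest["ssd_history"],
        )


def _visit_order(mask: pd.DataFrame) -> list[str]:
    counts = mask.sum(axis=0)
    order = counts.iloc[np.lexsort((counts.index, counts.to_numpy()))]
    return [f for f in order.index if counts[f] > 0]


def _select_predictors(work: np.ndarray, columns: list[str],
                       n_predictors: int) -> dict[str, list[int]]:
    """Top-|r| companion features per target on the initialized matrix."""
    n_feat = work.shape[1]
    k = min(n_predictors, n_feat - 1)
    std = work.std(axis=0)
    safe = np.where(std > 0, std, 1.0)
    Z = (work - work.mean(axis=0)) / safe
    corr = np.abs(Z.T @ Z) / len(work)
    np.fill_diagonal(corr, -np.inf)
    corr[:, std == 0] = -np.inf  # constant columns carry no signal
    out: dict[str, list[int]] = {}
    ids = np.asarray(columns)
    for j in range(n_feat):
        # rank by (correlation desc, metabolite_id asc) for determinism
        order = np.lexsort((ids, -corr[j]))
        out[columns[j]] = sorted(order[:k].tolist())
    return out


def fit_mice(train: FeatureMatrix, max_iterations: int = 5, seed: int = 0,
             regressor_factory: RegressorFactory | None = None,
             n_predictors: int = DEFAULT_N_PREDICTORS,
             ) -> tuple[ImputationModel, FeatureMatrix]:
    """Fit the chained-equations model and complete the training matrix.

    Returns the frozen model plus the completed training matrix.  A feature
    with zero observed values cannot be initialized and raises.  With no
    missing cells the matrix is returned unchanged (``n_iterations_run`` is
    0) but per-feature regressors are still fitted so the model can handle
    missingness in later test samples.
    """
    factory = regressor_factory or (lambda s: LgbmRegressor(seed=s))
    values = train.values
    mask = values.isna()
    if (values.notna().sum(axis=0) == 0).any():
        bad = [f for f in values.columns if values[f].notna().sum() == 0]
        raise ValueError(f"features with zero observed values: {bad[:5]}")

    means = values.mean(axis=0, skipna=True)
    work = values.to_numpy(float).copy()
    mask_arr = mask.to_numpy()
    columns = list(values.columns)
    col_index = {f: j for j, f in enumerate(columns)}
    # Step 1: mean initialization.
    for f, j in col_index.items():
        work[mask_arr[:, j], j] = means[f]

    pred_idx = _select_predictors(work, columns, n_predictors)
    visit = _visit_order(mask)
    ssd_history: list[float] = []
    n_iter = 0
    if visit and max_iterations > 0:
        prev_imputed = None
        for it in range(max_iterations):
            snapshot = work.copy()
            for rank, f in enumerate(visit):
                j = col_index[f]
                miss = mask_arr[:, j]
                others = pred_idx[f]
                reg = factory(_chain_seed(seed, it, rank))
                reg.fit(work[~miss][:, others], work[~miss, j])
                work[miss, j] = reg.predict(work[miss][:, others])
            imputed = work[mask_arr]
            if prev_imputed is None:
                ssd = float(np.sum((imputed - means.to_numpy()[
                    np.where(mask_arr)[1]]) ** 2))
            else:
                ssd = float(np.sum((imputed - prev_imputed) ** 2))
            if ssd_history and ssd > ssd_history[-1]:
                work = snapshot  # roll back the iteration that grew
                break
            ssd_history.append(ssd)
            prev_imputed = imputed.copy()
            n_iter = it + 1

    completed_values = pd.DataFrame(work, index=values.index, columns=columns)
    # Frozen per-feature regressors for test-time use, fitted on the
    # completed training matrix.
    regressors: dict[str, LgbmRegressor] = {}
    for rank, f in enumerate(columns):
        others = pred_idx[f]
        reg = factory(_chain_seed(seed, max_iterations + 1, rank))
        reg.fit(work[:, others], work[:, col_index[f]])
        regressors[f] = reg

    model = ImputationModel(
        feature_means=means, regressors=regressors,
        predictors={f: [columns[j] for j in pred_idx[f]] for f in columns},
        visit_order=visit, n_iterations_run=n_iter, seed=seed,
        feature_order=columns, ssd_history=ssd_history)
    completed = train.with_values(completed_values,
                                  f"imputed:mice(iter={n_iter})")
    return model, completed


def _chain_seed(seed: int, iteration: int, rank: int) -> int:
    return int((seed * 1_000_003 + iteration * 9973 + rank) % (2 ** 31 - 1))


def impute(data: FeatureMatrix | pd.Series | pd.DataFrame,
           model: ImputationModel):
    """Complete test samples with the frozen model (no refitting).

    Missing cells are initialized with the training feature means, then
    each originally-missing feature is overwritten once per sweep by its
    frozen regressor's prediction from the sample's current predictor
    values, in the model's visit order extended with any further features
    missing here.  Each sample's chain uses only that sample's values, so
    batch and one-at-a-time processing give identical results; at least
    one sweep is always made so missing cells never remain at the bare
    mean initialization.
    """
    single = isinstance(data, pd.Series)
    if single:
        frame = data.to_frame().T
    elif isinstance(data, FeatureMatrix):
        frame = data.values
    else:
        frame = data
    if list(frame.columns) != model.feature_order:
        raise ValueError("feature order does not match imputation model")
    arr = frame.to_numpy(float).copy()
    mask = np.isnan(arr)
    if len(arr) and mask.all(axis=1).any():
        raise ValueError("cannot impute an all-missing sample")

    col_index = {f: j for j, f in enumerate(model.feature_order)}
    means = model.feature_means.reindex(model.feature_order).to_numpy(float)
    for j in range(arr.shape[1]):
        arr[mask[:, j], j] = means[j]

    missing_set = {f for f in model.feature_order if mask[:, col_index[f]].any()}
    visit = [f for f in model.visit_order if f in missing_set]
    visit += [f for f in model.feature_order
              if f in missing_set and f not in set(model.visit_order)]
    n_sweeps = max(1, model.n_iterations_run)
    for _ in range(n_sweeps):
        for f in visit:
            j = col_index[f]
            miss = mask[:, j]
            others = [col_index[p] for p in model.predictors[f]]
            arr[miss, j] = model.regressors[f].predict(arr[miss][:, others])

    out = pd.DataFrame(arr, index=frame.index, columns=frame.columns)
    if single:
        return out.iloc[0].rename(data.name)
    if isinstance(data, FeatureMatrix):
        return data.with_values(out, "imputed:frozen_mice")
    return out
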
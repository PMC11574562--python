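"""Model / Results facade for the full detection workflow.

:class:`MulticancerDetectionModel` bundles an annotated feature matrix,
sample metadata and the reference library with the processing settings;
``fit()`` runs curation filtering, feature reduction, log10 scaling,
train-referenced quantile normalization, chained-equations imputation,
hyperparameter grid search, stratified k-fold cross-validation and the
final SVM-RBF fit, and returns a :class:`MulticancerDetectionResults`
carrying every frozen artifact.

The results object applies those frozen artifacts -- normalization
reference, imputation model, support-vector expansion -- to new samples
one at a time (or as a batch; the two are identical by construction),
which is the contract a deployed screening test has to honour.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .evaluate import EvaluationReport, evaluate
from .impute import ImputationModel, fit_mice, impute
from .preprocess import (FilterConfig, NormalizationReference,
                         apply_feature_filter, apply_quantile_normalization,
                         filter_nonhuman, fit_quantile_reference,
                         log_transform)
from .svm import (DEFAULT_C_GRID, CvConfig, SvmModel, decision_scores,
                  default_sigma_grid, grid_search, kfold_cv, rfe_rank,
                  train_svm)
from .synthetic import MetaboliteRecord


@dataclass
class DetectionSettings:
    """Tunable settings of the detection workflow."""

    filter_mode: str = "prevalence"
    min_presence_fraction: float = 0.20
    k_percent: float = 20.0
    mice_max_iterations: int = 5
    c_grid: tuple = DEFAULT_C_GRID
    sigma_grid: tuple | None = None  # None -> median-heuristic log grid
    cv_folds: int = 20
    cutoff: float = 0.0
    seed: int = 0


class MulticancerDetectionModel:
    """Cancer-vs-normal serum metabolome classifier, statsmodels style.

    Parameters
    ----------
    matrix : FeatureMatrix
        Aligned, annotated raw-intensity matrix (training samples).
    metadata : pandas.DataFrame
        Sample table with at least ``sample_id`` and ``class`` columns.
    library : list of MetaboliteRecord
        Reference library used for origin curation.
    settings : DetectionSettings, optional
    """

    def __init__(self, matrix: FeatureMatrix, metadata: pd.DataFrame,
                 library: list[MetaboliteRecord],
                 settings: DetectionSettings | None = None) -> None:
        self.matrix = matrix
        self.metadata = metadata.reset_index(drop=True)
        self.library = library
        self.settings = settings or DetectionSettings()
        meta_ids = set(self.metadata["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    @classmethod
    def from_cohort(cls, matrix: FeatureMatrix, metadata: pd.DataFrame,
                    library: list[MetaboliteRecord],
                    **settings) -> "MulticancerDetectionModel":
        return cls(matrix, metadata, library, DetectionSettings(**settings))

    @property
    def labels(self) -> pd.Series:
        meta = self.metadata.set_index("sample_id")
        return meta.loc[self.matrix.sample_ids, "class"]

    def fit(self, verbose: bool = False) -> "MulticancerDetectionResults":
        s = self.settings
        m = filter_nonhuman(self.matrix, self.library)
        m = apply_feature_filter(m, FilterConfig(
            k_percent=s.k_percent,
            min_presence_fraction=s.min_presence_fraction,
            mode=s.filter_mode))
        m = log_transform(m)
        ref = fit_quantile_reference(m)
        m = apply_quantile_normalization(m, ref)
        imp_model, completed = fit_mice(m, max_iterations=s.mice_max_iterations,
                                        seed=s.seed)
        X = completed.values
        labels = self.labels

        sigma_grid = list(s.sigma_grid) if s.sigma_grid else \
            default_sigma_grid(X, seed=s.seed)
        cv = CvConfig(k_folds=s.cv_folds, seed=s.seed)
        C, sigma, grid_table = grid_search(X, labels, s.c_grid, sigma_grid, cv)
        cv_reports, cv_summary = kfold_cv(X, labels, cv, C, sigma,
                                          metadata=self.metadata)
        svm = train_svm(X, labels, C=C, sigma=sigma, seed=s.seed,
                        feature_names=list(X.columns))
        train_scores = pd.Series(decision_scores(svm, X), index=X.index)
        train_report = evaluate(train_scores, labels, self.metadata,
                                cutoff=s.cutoff)
        return MulticancerDetectionResults(
            settings=s, svm=svm, normalization_reference=ref,
            imputation_model=imp_model, grid_table=grid_table,
            cv_reports=cv_reports, cv_summary=cv_summary,
            train_report=train_report, train_sample_ids=list(X.index),
            completed_train=completed, train_labels=labels)


@dataclass
class MulticancerDetectionResults:
    """Frozen artifacts and diagnostics of a fitted detection model."""

    settings: DetectionSettings
    svm: SvmModel
    normalization_reference: NormalizationReference
    imputation_model: ImputationModel
    grid_table: pd.DataFrame
    cv_reports: list[EvaluationReport]
    cv_summary: pd.DataFrame
    train_report: EvaluationReport
    train_sample_ids: list[str]
    completed_train: FeatureMatrix | None = None
    train_labels: pd.Series | None = None

    # -- frozen single-sample processing ------------------------------------
    @property
    def feature_order(self) -> list[str]:
        return self.normalization_reference.feature_order

    def transform(self, raw: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        """Raw intensities -> complete normalized vectors, frozen artifacts.

        Selects the retained features (features absent from ``raw`` become
        missing), log10-scales, quantile-normalizes each sample against the
        training reference, and imputes remaining gaps with the frozen
        chained-equations model.  Row-independent throughout.
        """
        values = raw.values if isinstance(raw, FeatureMatrix) else raw
        sub = values.reindex(columns=self.feature_order)
        arr = sub.to_numpy(float)
        if np.nanmin(arr, initial=np.inf) <= 0:
            raise ValueError("raw intensities must be positive")
        with np.errstate(invalid="ignore"):
            logged = pd.DataFrame(np.log10(arr), index=sub.index,
                                  columns=sub.columns)
        normed = apply_quantile_normalization(logged,
                                              self.normalization_reference)
        return impute(normed, self.imputation_model)

    def decision_scores(self, raw: FeatureMatrix | pd.DataFrame,
                        pre_transformed: bool = False) -> pd.Series:
        X = raw if pre_transformed else self.transform(raw)
        X = X.values if isinstance(X, FeatureMatrix) else X
        return pd.Series(decision_scores(self.svm, X), index=X.index,
                         name="y_score")

    def predict(self, raw, pre_transformed: bool = False) -> pd.Series:
        s = self.decision_scores(raw, pre_transformed=pre_transformed)
        return pd.Series(np.where(s > self.settings.cutoff, "cancer", "normal"),
                         index=s.index, name="predicted")

    def evaluate(self, raw, metadata: pd.DataFrame,
                 pre_transformed: bool = False) -> EvaluationReport:
        """Score and evaluate an independent sample set with leakage guard."""
        index = (raw.values if isinstance(raw, FeatureMatrix) else raw).index
        overlap = set(index) & set(self.train_sample_ids)
        if overlap:
            raise ValueError(
                f"validation samples seen in training: {sorted(overlap)[:5]}")
        scores = self.decision_scores(raw, pre_transformed=pre_transformed)
        labels = metadata.set_index("sample_id").loc[scores.index, "class"]
        return evaluate(scores, labels, metadata, cutoff=self.settings.cutoff)

    def rank_features(self, step: int = 1, holdout_fraction: float = 0.3,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """SVM-RFE ranking of the retained features on the training data."""
        if self.completed_train is None or self.train_labels is None:
            raise ValueError("training data not retained; refit to rank")
        return rfe_rank(self.completed_train.values, self.train_labels,
                        C=self.svm.C, sigma=self.svm.sigma, step=step,
                        holdout_fraction=holdout_fraction,
                        seed=self.settings.seed)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        s = [
            "Multicancer serum-metabolome detection model",
            "============================================",
            f"retained features:   {len(self.feature_order)}",
            f"training samples:    {len(self.train_sample_ids)}",
            f"support vectors:     {self.svm.n_support}",
            f"hyperparameters:     C={self.svm.C:g}, sigma={self.svm.sigma:.4g}",
            f"imputation sweeps:   {self.imputation_model.n_iterations_run}",
            f"decision cutoff:     {self.settings.cutoff:g}",
            "",
            f"{self.settings.cv_folds}-fold cross-validation "
            "(mean [95% CI] across folds):",
        ]
        for _, row in self.cv_summary.iterrows():
            s.append(f"  {row['metric']:>12s}: {row['mean']:6.2f}% "
                     f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
        s += ["", "training-set fit:",
              f"  sensitivity {self.train_report.sensitivity:.2f}%  "
              f"specificity {self.train_report.specificity:.2f}%  "
              f"accuracy {self.train_report.accuracy:.2f}%  "
              f"AUC {self.train_report.auc:.4f}"]
        return "\n".join(s)

    # -- plotting ------------------------------------------------------------
    def plot_scores(self, report: EvaluationReport, ax=None):
        """Strip plot of y-scores by class with the decision cutoff line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = report.score_table
        rng = np.random.default_rng(0)
        for i, cls in enumerate(("normal", "cancer")):
            y = t.loc[t["label"] == cls, "y_score"]
            ax.scatter(i + rng.uniform(-0.2, 0.2, len(y)), y, s=6, alpha=0.5,
                       label=cls)
        ax.axhline(report.cutoff, color="k", lw=0.8, ls="--")
        ax.set_xticks([0, 1], ["normal", "cancer"])
        ax.set_ylabel("y-score")
        return ax

    def plot_cv_sensitivity(self, ax=None):
        """Per-fold CV sensitivities with the across-fold mean line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        sens = [r.sensitivity for r in self.cv_reports]
        ax.plot(range(1, len(sens) + 1), sens, "o-", ms=4)
        ax.axhline(np.mean(sens), color="tab:blue", lw=1, alpha=0.6)
        ax.set_xlabel("fold")
        ax.set_ylabel("sensitivity (%)")
        ax.set_ylim(0, 105)
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.normalization_reference.to_json(out / "normalization_reference.json")
        self.imputation_model.save(out / "imputation_model")
        self.svm.save(out / "svm_model")
        self.grid_table.drop(columns=["fold_accuracies"], errors="ignore") \
            .to_csv(out / "grid_search.csv", index=False)
        self.cv_summary.to_csv(out / "cv_summary.csv", index=False)
        self.train_report.to_json(out / "train_report.json")
        (out / "results.json").write_text(json.dumps({
            "settings": asdict(self.settings),
            "train_sample_ids": self.train_sample_ids}))

    @classmethod
    def load(cls, in_dir: str | Path) -> "MulticancerDetectionResults":
        out = Path(in_dir)
        d = json.loads((out / "results.json").read_text())
        settings = DetectionSettings(**{**d["settings"],
                                        "c_grid": tuple(d["settings"]["c_grid"])})
        train_rep = json.loads((out / "train_report.json").read_text())
        report = EvaluationReport(
            TP=train_rep["TP"], FP=train_rep["FP"], TN=train_rep["TN"],
            FN=train_rep["FN"], sensitivity=train_rep["sensitivity"],
            specificity=train_rep["specificity"],
            accuracy=train_rep["accuracy"], auc=train_rep["auc"],
            cutoff=train_rep["cutoff"], per_group=train_rep["per_group"])
        return cls(
            settings=settings,
            svm=SvmModel.load(out / "svm_model"),
            normalization_reference=NormalizationReference.from_json(
                out / "normalization_reference.json"),
            imputation_model=ImputationModel.load(out / "imputation_model"),
            grid_table=pd.read_csv(out / "grid_search.csv"),
            cv_reports=[], cv_summary=pd.read_csv(out / "cv_summary.csv"),
            train_report=report, train_sample_ids=d["train_sample_ids"])
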
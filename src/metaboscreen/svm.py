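"""SVM-RBF training, scoring, model selection and RFE feature ranking.

The classifier is a soft-margin support-vector machine with the Gaussian
(RBF) kernel

    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))

whose decision function is the kernel expansion over support vectors

    F(x) = sum_i alpha_i y_i k(x, x_i) + b,

with cancer encoded as y = +1, so larger y-scores mean more cancer-like;
a sample is called cancer when its score exceeds the cutoff (0 by default;
a score exactly at the cutoff is called normal).

The dual problem is solved by libsvm's SMO implementation (via
scikit-learn); the fitted coefficients are extracted into an explicit
:class:`SvmModel` whose scores this module computes itself from the kernel
expansion above.  Hyperparameters (C, sigma) are chosen by grid search over
mean stratified k-fold cross-validated accuracy with shared fold
assignments, ties broken toward smaller C then larger sigma.

Feature ranking uses SVM-RFE with the kernel-space drop-one criterion: a
feature's importance is the change in the margin functional
W^2 = sum_ij alpha_i alpha_j y_i y_j k(x_i, x_j) when that feature is
removed from the kernel; the least important features are eliminated and
the SVM retrained until none remain.  Rank 1 is the last survivor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluate import EvaluationReport, evaluate

LABEL_CANCER, LABEL_NORMAL = "cancer", "normal"


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "if":
        y = arr.astype(float)
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise ValueError("numeric labels must be +-1")
        return y
    return np.where(arr == LABEL_CANCER, 1.0, -1.0)


def rbf_kernel(x: np.ndarray, x_prime: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x - x'||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, float)
    x_prime = np.asarray(x_prime, float)
    if x.shape != x_prime.shape:
        raise ValueError("vectors must have equal length")
    d2 = float(np.sum((x - x_prime) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma ** 2))


@dataclass
class SvmModel:
    """Explicit RBF-SVM decision function: support vectors and weights."""

    support_vectors: np.ndarray  # (n_sv, n_features)
    alpha: np.ndarray            # non-negative dual weights
    y: np.ndarray                # support-vector labels in {-1, +1}
    b: float                     # intercept
    sigma: float                 # Gaussian kernel width
    C: float                     # box constraint
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(self.alpha < -1e-9):
            raise ValueError("alpha weights must be non-negative")

    @property
    def n_support(self) -> int:
        return len(self.alpha)

    def dual_objective(self) -> float:
        """Dual objective sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij."""
        coef = self.alpha * self.y
        K = _kernel_matrix(self.support_vectors, self.support_vectors, self.sigma)
        return float(self.alpha.sum() - 0.5 * coef @ K @ coef)

    # -- serialization -------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.support_vectors,
                     columns=self.feature_names).to_csv(
            out / "support_vectors.csv", index=False)
        (out / "svm.json").write_text(json.dumps({
            "alpha": self.alpha.tolist(), "y": self.y.tolist(),
            "b": self.b, "sigma": self.sigma, "C": self.C,
            "feature_names": self.feature_names}))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SvmModel":
        out = Path(in_dir)
        d = json.loads((out / "svm.json").read_text())
        sv = pd.read_csv(out / "support_vectors.csv").to_numpy(float)
        return cls(sv, np.asarray(d["alpha"]), np.asarray(d["y"]),
                   float(d["b"]), float(d["sigma"]), float(d["C"]),
                   d["feature_names"])


def train_svm(X, labels, C: float, sigma: float, seed: int = 0,
              feature_names: list[str] | None = None,
              tol: float = 1e-5) -> SvmModel:
    """Solve the soft-margin RBF dual and return the explicit model.

    The quadratic program is solved by the SMO algorithm (libsvm backend);
    the support vectors, their weights ``alpha_i`` (0 <= alpha_i <= C with
    ``sum_i alpha_i y_i = 0``), the intercept and the kernel width are
    extracted so scoring is an explicit kernel sum over support vectors.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if np.isnan(X).any():
        raise ValueError("training matrix must be complete (no NaN)")
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    gamma = 1.0 / (2.0 * sigma ** 2)
    clf = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol,
              cache_size=200, random_state=seed)
    clf.fit(X, y)
    dual = clf.dual_coef_[0]          # alpha_i * y_i
    sv = clf.support_vectors_
    return SvmModel(
        support_vectors=sv,
        alpha=np.abs(dual),
        y=np.sign(dual),
        b=float(clf.intercept_[0]),
        sigma=float(sigma),
        C=float(C),
        feature_names=feature_names or [f"f{j}" for j in range(X.shape[1])],
    )


def decision_score(model: SvmModel, sample) -> float:
    """y-score F(x) = sum_i alpha_i y_i k(x, x_i) + b for one sample."""
    x = np.asarray(sample, float).ravel()
    if x.shape[0] != model.support_vectors.shape[1]:
        raise ValueError("sample length does not match model feature space")
    k = _kernel_matrix(x[None, :], model.support_vectors, model.sigma)[0]
    return float(np.dot(model.alpha * model.y, k) + model.b)


def decision_scores(model: SvmModel, X) -> np.ndarray:
    """Vectorized y-scores for a complete matrix (rows = samples)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    K = _kernel_matrix(X, model.support_vectors, model.sigma)
    return K @ (model.alpha * model.y) + model.b


def classify(score, cutoff: float = 0.0):
    """Call cancer above the cutoff; scores at or below it are normal."""
    arr = np.asarray(score, float)
    out = np.where(arr > cutoff, LABEL_CANCER, LABEL_NORMAL)
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


@dataclass
class CvConfig:
    """Cross-validation settings (default: stratified 20-fold)."""

    k_folds: int = 20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def splitter(self) -> StratifiedKFold:
        return StratifiedKFold(n_splits=self.k_folds, shuffle=True,
                               random_state=self.seed)


def _folds(y: np.ndarray, cv: CvConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    if cv.k_folds > len(y):
        raise ValueError("k_folds exceeds sample count")
    if cv.stratified:
        counts = [int((y == v).sum()) for v in np.unique(y)]
        if cv.k_folds > min(counts):
            raise ValueError("k_folds exceeds the smallest class count")
    return list(cv.splitter().split(np.zeros(len(y)), y))


def grid_search(X, labels, c_grid, sigma_grid, cv: CvConfig,
                ) -> tuple[float, float, pd.DataFrame]:
    """Mean CV accuracy over the (C, sigma) grid with shared folds.

    Returns the maximizing pair (ties broken toward smaller C, then larger
    sigma) and the full table for audit.
    """
    c_grid, sigma_grid = list(c_grid), list(sigma_grid)
    if not c_grid or not sigma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    y = _encode_labels(labels)
    folds = _folds(y, cv)
    rows = []
    for C in c_grid:
        for sigma in sigma_grid:
            accs = []
            for tr, te in folds:
                model = train_svm(X[tr], y[tr], C=C, sigma=sigma, seed=cv.seed)
                pred = decision_scores(model, X[te]) > 0.0
                accs.append(float(np.mean(pred == (y[te] > 0))))
            rows.append({"C": C, "sigma": sigma,
                         "mean_cv_accuracy": float(np.mean(accs)),
                         "fold_accuracies": accs})
    table = pd.DataFrame(rows)
    ranked = table.iloc[np.lexsort((-table["sigma"].to_numpy(),
                                    table["C"].to_numpy(),
                                    -table["mean_cv_accuracy"].to_numpy()))]
    best = ranked.iloc[0]
    return float(best["C"]), float(best["sigma"]), table


def median_heuristic_sigma(X, max_samples: int = 500, seed: int = 0) -> float:
    """Median pairwise Euclidean distance -- a standard kernel-width scale."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if len(X) > max_samples:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), max_samples, replace=False)]
    d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(X ** 2, axis=1)[None, :]
          - 2.0 * X @ X.T)
    d = np.sqrt(np.maximum(d2[np.triu_indices(len(X), k=1)], 0.0))
    med = float(np.median(d))
    return med if med > 0 else 1.0


def default_sigma_grid(X, seed: int = 0) -> list[float]:
    s = median_heuristic_sigma(X, seed=seed)
    return [s * f for f in (0.25, 0.5, 1.0, 2.0, 4.0)]


DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)


def kfold_cv(X, labels, cv: CvConfig, C: float, sigma: float,
             metadata: pd.DataFrame | None = None,
             ) -> tuple[list[EvaluationReport], pd.DataFrame]:
    """Stratified k-fold cross-validation at the zero-score cutoff.

    Each sample appears in exactly one test fold.  Returns per-fold
    evaluation reports plus a summary table with the across-fold mean and
    normal-theory 95% CI of sensitivity, specificity and accuracy.
    """
    if isinstance(X, pd.DataFrame):
        sample_ids = list(X.index)
        X = X.to_numpy(float)
    else:
        sample_ids = [str(i) for i in range(len(X))]
    y = _encode_labels(labels)
    reports = []
    for tr, te in _folds(y, cv):
        model = train_svm(X[tr], y[tr], C=C, sigma=sigma, seed=cv.seed)
        scores = decision_scores(model, X[te])
        fold_labels = np.where(y[te] > 0, LABEL_CANCER, LABEL_NORMAL)
        reports.append(evaluate(
            pd.Series(scores, index=[sample_ids[i] for i in te]),
            pd.Series(fold_labels, index=[sample_ids[i] for i in te])))
    rows = []
    for metric in ("sensitivity", "specificity", "accuracy"):
        vals = np.array([getattr(r, metric) for r in reports])
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({"metric": metric, "mean": float(vals.mean()),
                     "ci_low": float(vals.mean() - half),
                     "ci_high": float(vals.mean() + half)})
    return reports, pd.DataFrame(rows)


def _margin_functional(A: np.ndarray, K: np.ndarray) -> float:
    return float(np.sum(A * K))


def rfe_rank(X, labels, C: float, sigma: float, step: int = 1,
             holdout: tuple | None = None, holdout_fraction: float = 0.3,
             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SVM-RFE feature ranking with a held-out sensitivity trace.

    Per round: retrain on the surviving features, record held-out
    sensitivity at cutoff 0, score every surviving feature by the drop-one
    change in the margin functional W^2, and eliminate the ``step`` least
    important (the final round keeps the remainder and ranks it by
    importance).  ``holdout`` may supply ``(X_val, labels_val)``;
    otherwise a stratified fraction of the input is split off.

    Returns ``(ranking, rounds)``: ranking has one row per feature with
    its rank (1 = last survivor) and elimination round; rounds records the
    per-round surviving count and held-out sensitivity.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        names = [f"f{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least 2 features")
    if step < 1:
        raise ValueError("step must be >= 1")
    y = _encode_labels(labels)
    if holdout is not None:
        Xv, yv = holdout
        Xv = Xv.to_numpy(float) if isinstance(Xv, pd.DataFrame) else np.asarray(Xv, float)
        yv = _encode_labels(yv)
        Xt, yt = X, y
    else:
        rng = np.random.default_rng(seed)
        val_idx = np.zeros(len(y), dtype=bool)
        for v in np.unique(y):
            idx = np.flatnonzero(y == v)
            take = rng.choice(idx, max(1, int(round(holdout_fraction * len(idx)))),
                              replace=False)
            val_idx[take] = True
        Xt, yt, Xv, yv = X[~val_idx], y[~val_idx], X[val_idx], y[val_idx]

    surviving = list(range(X.shape[1]))
    ranks = np.zeros(X.shape[1], dtype=int)
    rounds = []
    next_rank = X.shape[1]
    rnd = 0
    while surviving:
        rnd += 1
        cols = np.array(surviving)
        model = train_svm(Xt[:, cols], yt, C=C, sigma=sigma, seed=seed)
        scores = decision_scores(model, Xv[:, cols])
        pos = yv > 0
        sens = 100.0 * float(np.mean(scores[pos] > 0)) if pos.any() else np.nan
        rounds.append({"round": rnd, "n_features": len(surviving),
                       "sensitivity": sens})

        sv = model.support_vectors
        coef = model.alpha * model.y
        A = np.outer(coef, coef)
        K = _kernel_matrix(sv, sv, model.sigma)
        W2 = _margin_functional(A, K)
        # drop-one: removing feature f multiplies K elementwise by
        # exp(d_f / (2 sigma^2)) where d_f is that feature's squared diff
        importance = np.empty(len(cols))
        inv = 1.0 / (2.0 * model.sigma ** 2)
        for c, _ in enumerate(cols):
            diff = sv[:, c][:, None] - sv[:, c][None, :]
            K_minus = K * np.exp((diff ** 2) * inv)
            importance[c] = abs(W2 - _margin_functional(A, K_minus))

        order = np.argsort(importance, kind="stable")  # least important first
        if len(surviving) <= step:
            # final round: rank the remainder by importance
            for c in order:
                ranks[cols[c]] = next_rank
                next_rank -= 1
            surviving = []
        else:
            for c in order[:step]:
                ranks[cols[c]] = next_rank
                next_rank -= 1
            drop = set(cols[order[:step]])
            surviving = [j for j in surviving if j not in drop]

    ranking = pd.DataFrame({"metabolite_id": names, "rank": ranks})
    ranking = ranking.sort_values("rank").reset_index(drop=True)
    return ranking, pd.DataFrame(rounds)
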
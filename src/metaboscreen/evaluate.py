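"""Confusion-matrix metrics, ROC AUC and subgroup sensitivity breakdowns.

Given per-sample decision scores and true class labels, this module builds
the standard screening-test report: confusion counts at a score cutoff,

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN),

the ROC AUC computed by the rank (Mann-Whitney) construction with tie
correction, and -- when sample metadata is supplied -- per-subgroup
detection sensitivities (by cancer type, clinical stage and age group)
with 95% Wilson score confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

POSITIVE = "cancer"
SUBGROUP_KEYS = ("cancer_type", "stage", "age_group")


def auc_mann_whitney(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """ROC AUC via average ranks (tie-corrected Mann-Whitney statistic)."""
    scores = np.asarray(scores, float)
    is_positive = np.asarray(is_positive, bool)
    n_pos, n_neg = int(is_positive.sum()), int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def wilson_interval(successes: int, total: int,
                    alpha: float = 0.05) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion, in percent."""
    if total == 0:
        return (0.0, 100.0)
    lo, hi = proportion_confint(successes, total, alpha=alpha, method="wilson")
    return (100.0 * float(lo), 100.0 * float(hi))


@dataclass
class EvaluationReport:
    """Screening-test performance summary for one sample set."""

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float     # percent
    auc: float
    cutoff: float
    per_group: dict[str, dict[str, dict]] = field(default_factory=dict)
    score_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("TP", "FP", "TN", "FN", "sensitivity", "specificity",
              "accuracy", "auc", "cutoff")}
        d["per_group"] = self.per_group
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def scores_to_csv(self, path: str | Path) -> None:
        if self.score_table is None:
            raise ValueError("report carries no score table")
        self.score_table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            "Screening evaluation",
            "====================",
            f"samples: {self.TP + self.FP + self.TN + self.FN}"
            f" (cancer {self.TP + self.FN}, normal {self.TN + self.FP})",
            f"cutoff:  {self.cutoff:g}",
            f"TP={self.TP}  FN={self.FN}  TN={self.TN}  FP={self.FP}",
            f"sensitivity: {self.sensitivity:6.2f}%",
            f"specificity: {self.specificity:6.2f}%",
            f"accuracy:    {self.accuracy:6.2f}%",
            f"AUC-ROC:     {self.auc:6.4f}",
        ]
        for key, groups in self.per_group.items():
            lines.append(f"-- sensitivity by {key} --")
            for g, d in groups.items():
                lines.append(
                    f"  {g:>24s}: {d['sensitivity']:6.2f}% "
                    f"({d['n_positive_detected']}/{d['n_total']}) "
                    f"CI [{d['ci_low']:.1f}, {d['ci_high']:.1f}]")
        return "\n".join(lines)


def evaluate(scores: pd.Series, labels: pd.Series,
             metadata: pd.DataFrame | None = None,
             cutoff: float = 0.0) -> EvaluationReport:
    """Build the full evaluation report from aligned scores and labels.

    ``scores`` and ``labels`` must share an index of sample ids; when
    ``metadata`` is given it must carry ``sample_id`` plus the subgroup
    columns, and subgroup sensitivities are computed over the cancer
    samples of each subgroup.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    if len(scores) != len(labels) or not scores.index.equals(labels.index):
        raise ValueError("scores and labels must be aligned on sample id")
    s = scores.to_numpy(float)
    pos = labels.to_numpy() == POSITIVE
    called = s > cutoff
    TP = int((called & pos).sum())
    FP = int((called & ~pos).sum())
    FN = int((~called & pos).sum())
    TN = int((~called & ~pos).sum())
    total = TP + FP + TN + FN
    report = EvaluationReport(
        TP=TP, FP=FP, TN=TN, FN=FN,
        sensitivity=100.0 * TP / (TP + FN) if TP + FN else np.nan,
        specificity=100.0 * TN / (TN + FP) if TN + FP else np.nan,
        accuracy=100.0 * (TP + TN) / total if total else np.nan,
        auc=auc_mann_whitney(s, pos) if pos.any() and (~pos).any() else np.nan,
        cutoff=cutoff,
        score_table=pd.DataFrame({
            "sample_id": scores.index, "y_score": s,
            "label": labels.to_numpy(),
            "predicted": np.where(called, POSITIVE, "normal")}),
    )
    if metadata is not None:
        meta = metadata.set_index("sample_id").loc[scores.index]
        for key in SUBGROUP_KEYS:
            if key not in meta.columns:
                continue
            groups: dict[str, dict] = {}
            for g, idx in meta.loc[pos].groupby(key, observed=True).groups.items():
                detected = int((scores.loc[idx] > cutoff).sum())
                n = len(idx)
                sens = 100.0 * detected / n
                lo, hi = wilson_interval(detected, n)
                groups[str(g)] = {
                    "n_positive_detected": detected, "n_total": n,
                    "sensitivity": sens,
                    "ci_low": min(lo, sens), "ci_high": max(hi, sens)}
            report.per_group[key] = groups
    return report
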
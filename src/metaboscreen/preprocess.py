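"""Feature curation, reduction, log scaling and quantile normalization.

The curation filter removes metabolites of non-human origin (drug- or
plant-derived, or of ambiguous origin) so the classifier only ever sees
endogenous serum metabolites.  Feature reduction then drops either rarely
observed features (prevalence mode, the pipeline default) or the lowest
fraction by mean abundance (abundance-percentile mode); both conventions
are in circulation and both are provided.

Normalization is *train-referenced* quantile normalization: the training
matrix defines a single reference distribution of log10 intensities, and
any later sample -- including a single test sample arriving alone -- is
mapped onto that reference by rank.  This single-sample property is what
makes the procedure deployable in a screening setting, where samples are
processed one at a time against frozen training artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import FeatureMatrix
from .synthetic import MetaboliteRecord

LOG10_TAG = "log10"
QNORM_TAG = "quantile_normalized"


@dataclass
class FilterConfig:
    """Feature-reduction settings.

    ``prevalence`` keeps features observed in at least
    ``min_presence_fraction`` of samples (boundary inclusive);
    ``abundance_percentile`` drops the ``k_percent`` lowest features by
    mean observed log10 intensity.
    """

    k_percent: float = 20.0
    min_presence_fraction: float = 0.20
    mode: str = "prevalence"

    def __post_init__(self) -> None:
        if not 0 <= self.k_percent < 100:
            raise ValueError("k_percent must lie in [0, 100)")
        if not 0 <= self.min_presence_fraction <= 1:
            raise ValueError("min_presence_fraction must lie in [0, 1]")
        if self.mode not in ("prevalence", "abundance_percentile"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


def filter_nonhuman(matrix: FeatureMatrix,
                    library: list[MetaboliteRecord]) -> FeatureMatrix:
    """Retain only features whose library origin is ``human``."""
    origin = dict(zip((r.metabolite_id for r in library),
                      (r.origin for r in library)))
    unknown = [f for f in matrix.feature_ids if f not in origin]
    if unknown:
        raise KeyError(f"features missing from library: {unknown[:5]}"
                       f"{'...' if len(unknown) > 5 else ''}")
    keep = [f for f in matrix.feature_ids if origin[f] == "human"]
    return matrix.with_values(matrix.values[keep], "curated:human_origin")


def apply_feature_filter(matrix: FeatureMatrix,
                         cfg: FilterConfig) -> FeatureMatrix:
    """Drop rare or low-abundance features according to ``cfg``."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot filter an empty matrix")
    values = matrix.values
    if cfg.mode == "prevalence":
        presence = values.notna().mean(axis=0)
        keep = [f for f in matrix.feature_ids
                if presence[f] >= cfg.min_presence_fraction]
        entry = f"filtered:prevalence>={cfg.min_presence_fraction}"
    else:
        obs = values.to_numpy(float)
        if LOG10_TAG not in matrix.transform_log:
            with np.errstate(divide="ignore", invalid="ignore"):
                obs = np.log10(obs)
        means = pd.Series(np.nanmean(obs, axis=0), index=values.columns)
        n_drop = int(np.floor(cfg.k_percent / 100.0 * matrix.shape[1]))
        # rank by (mean, metabolite_id); id breaks ties deterministically
        ranked = means.iloc[np.lexsort((means.index, means.to_numpy()))]
        dropped = set(ranked.index[:n_drop])
        keep = [f for f in matrix.feature_ids if f not in dropped]
        entry = f"filtered:abundance_lowest_{cfg.k_percent}pct"
    if not keep:
        raise ValueError("feature filter removed every feature")
    return matrix.with_values(values[keep], entry)


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """log10-scale every observed cell; missing cells stay missing."""
    if LOG10_TAG in matrix.transform_log:
        raise ValueError("matrix is already log10-scaled (provenance check)")
    obs = matrix.values.to_numpy(float)
    if np.nanmin(obs, initial=np.inf) <= 0:
        raise ValueError("log10 requires strictly positive observed values")
    with np.errstate(invalid="ignore"):
        logged = pd.DataFrame(np.log10(obs), index=matrix.values.index,
                              columns=matrix.values.columns)
    return matrix.with_values(logged, LOG10_TAG)


@dataclass
class NormalizationReference:
    """Frozen train-set quantiles for single-sample normalization.

    ``reference_quantiles[r]`` is the mean over training samples of each
    sample's value at grid position ``(r + 0.5) / n_features`` after the
    sample's observed values are sorted and linearly interpolated onto
    that common grid (which handles unequal missingness).
    """

    reference_quantiles: np.ndarray
    feature_order: list[str]
    provenance: str

    def __post_init__(self) -> None:
        self.reference_quantiles = np.asarray(self.reference_quantiles, float)
        if len(self.reference_quantiles) != len(self.feature_order):
            raise ValueError("quantile vector and feature order disagree")
        if np.any(np.diff(self.reference_quantiles) < 0):
            raise ValueError("reference quantiles must be non-decreasing")

    @property
    def grid(self) -> np.ndarray:
        n = len(self.feature_order)
        return (np.arange(n) + 0.5) / n

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "reference_quantiles": self.reference_quantiles.tolist(),
            "feature_order": self.feature_order,
            "provenance": self.provenance,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationReference":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["reference_quantiles"]),
                   d["feature_order"], d["provenance"])


def _matrix_digest(values: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, values.columns)).encode())
    h.update(np.ascontiguousarray(values.to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def fit_quantile_reference(train: FeatureMatrix) -> NormalizationReference:
    """Build the reference distribution from a log-scaled training matrix."""
    if LOG10_TAG not in train.transform_log:
        raise ValueError("quantile reference must be fit on log10 data")
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    n_feat = train.shape[1]
    grid = (np.arange(n_feat) + 0.5) / n_feat
    rows = train.values.to_numpy(float)
    acc = np.zeros(n_feat)
    for i, row in enumerate(rows):
        v = np.sort(row[~np.isnan(row)])
        if len(v) == 0:
            raise ValueError(
                f"sample {train.sample_ids[i]!r} has no observed values")
        pos = (np.arange(len(v)) + 0.5) / len(v)
        acc += np.interp(grid, pos, v)
    ref = acc / len(rows)
    return NormalizationReference(np.maximum.accumulate(ref),
                                  train.feature_ids,
                                  f"train:{_matrix_digest(train.values)}")


def _normalize_row(row: np.ndarray, ref: NormalizationReference) -> np.ndarray:
    out = np.full_like(row, np.nan)
    ok = ~np.isnan(row)
    m = int(ok.sum())
    if m == 0:
        return out
    ranks = rankdata(row[ok], method="average")
    pos = (ranks - 0.5) / m
    out[ok] = np.interp(pos, ref.grid, ref.reference_quantiles)
    return out


def apply_quantile_normalization(data: FeatureMatrix | pd.Series | pd.DataFrame,
                                 ref: NormalizationReference):
    """Map each sample's observed values onto the reference distribution.

    Per sample: observed values are ranked (ties get the average rank) and
    rank ``r`` of ``m`` observed values is mapped to the reference quantile
    at grid position ``(r - 0.5) / m`` by linear interpolation.  Samples
    are strictly independent of one another, so normalizing row by row
    equals normalizing the whole matrix at once.
    """
    if isinstance(data, pd.Series):
        if list(data.index) != ref.feature_order:
            raise ValueError("feature order does not match reference")
        return pd.Series(_normalize_row(data.to_numpy(float), ref),
                         index=data.index, name=data.name)
    values = data.values if isinstance(data, FeatureMatrix) else data
    if list(values.columns) != ref.feature_order:
        raise ValueError("feature order does not match reference")
    arr = values.to_numpy(float)
    normed = np.vstack([_normalize_row(r, ref) for r in arr]) if len(arr) \
        else arr
    out = pd.DataFrame(normed, index=values.index, columns=values.columns)
    if isinstance(data, FeatureMatrix):
        return data.with_values(out, QNORM_TAG)
    return out
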
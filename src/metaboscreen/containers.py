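"""Core in-memory containers shared across the pipeline.

The pipeline moves data through two shapes: per-run peak lists
(one table of ``(m/z, RT, intensity)`` triples per analytical run) and a
cross-run feature matrix (samples x annotated metabolite features).
Missing measurements are encoded as NaN in the matrix and as *absent
peaks* in a peak list -- a metabolite that was not quantified in a run
simply has no row there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Mass of a proton in Da; positive ion mode observes [M+H]+ so the
#: instrument m/z is the neutral monoisotopic mass plus this offset.
PROTON_MASS = 1.00727646688

PEAK_COLUMNS = ("mz", "rt", "intensity")


@dataclass
class PeakList:
    """All peaks detected in one analytical run.

    Parameters
    ----------
    run_id : str
        Identifier of the run; for the simulated cohorts one sample is
        acquired per run, so ``run_id`` doubles as the sample id.
    batch_id : str
        Acquisition batch the run belongs to.
    peaks : pandas.DataFrame
        Table with columns ``mz`` (Da), ``rt`` (seconds) and
        ``intensity`` (arbitrary units, strictly positive).
    """

    run_id: str
    batch_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peak table lacks columns {missing}")
        if len(self.peaks) and (self.peaks["intensity"] <= 0).any():
            raise ValueError("peak intensities must be strictly positive")
        if len(self.peaks) and (self.peaks["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    def copy(self) -> "PeakList":
        return PeakList(self.run_id, self.batch_id, self.peaks.copy())

    def to_csv(self, path: str | Path) -> None:
        self.peaks.to_csv(path, index=False, columns=list(PEAK_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path, run_id: str | None = None,
                 batch_id: str = "") -> "PeakList":
        path = Path(path)
        peaks = pd.read_csv(path)
        return cls(run_id or path.stem, batch_id, peaks)


class FeatureMatrix:
    """Samples x annotated metabolite features with provenance.

    Wraps a :class:`pandas.DataFrame` (rows = sample ids, columns =
    metabolite ids, NaN = missing) together with per-feature annotation
    (consensus m/z and RT of the peaks that produced each column) and an
    append-only ``transform_log`` recording every transformation applied
    so far.  The log is used both for provenance and to refuse invalid
    re-application (e.g. taking log10 twice).
    """

    def __init__(self, values: pd.DataFrame,
                 annotations: pd.DataFrame | None = None,
                 transform_log: list[str] | None = None) -> None:
        if annotations is None:
            annotations = pd.DataFrame(
                {"metabolite_id": values.columns,
                 "consensus_mz": np.nan, "consensus_rt": np.nan})
        if list(annotations["metabolite_id"]) != list(values.columns):
            raise ValueError("annotation rows must match matrix columns")
        obs = values.to_numpy(float)
        self.values = values
        self.annotations = annotations.reset_index(drop=True)
        self.transform_log: list[str] = list(transform_log or [])
        if "log10" not in self.transform_log:
            with np.errstate(invalid="ignore"):
                if np.nanmin(obs, initial=np.inf) < 0:
                    raise ValueError("negative intensities before log transform")

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    # -- provenance-preserving derivation ------------------------------------
    def with_values(self, values: pd.DataFrame, log_entry: str) -> "FeatureMatrix":
        """Return a new matrix with ``log_entry`` appended to the log."""
        ann = self.annotations[
            self.annotations["metabolite_id"].isin(values.columns)]
        ann = ann.set_index("metabolite_id").loc[list(values.columns)]
        ann = ann.reset_index()
        return FeatureMatrix(values, ann, self.transform_log + [log_entry])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.annotations.copy(),
                             list(self.transform_log))

    # -- serialization -------------------------------------------------------
    def to_dir(self, path: str | Path, name: str = "feature_matrix") -> None:
        """Write values as CSV plus a sidecar JSON with annotations/log."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(path / f"{name}.csv", index_label="sample_id")
        sidecar = {
            "transform_log": self.transform_log,
            "annotations": self.annotations.to_dict(orient="list"),
        }
        (path / f"{name}.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path,
                 name: str = "feature_matrix") -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path / f"{name}.csv", index_col="sample_id")
        sidecar = json.loads((path / f"{name}.json").read_text())
        ann = pd.DataFrame(sidecar["annotations"])
        return cls(values, ann, sidecar["transform_log"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return (f"<FeatureMatrix {n} samples x {p} features, "
                f"transforms={self.transform_log}>")


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated cohort.

    ``features``: metabolite_id, is_signature, effect_sign, base_log_abundance.
    ``runs``: run_id, batch_id, drift_ppm (injected per-run mass drift).
    ``missing``: long table (sample_id, metabolite_id, cause in {mnar, mcar}).
    """

    features: pd.DataFrame
    runs: pd.DataFrame
    missing: pd.DataFrame

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(path / "truth_features.csv", index=False)
        self.runs.to_csv(path / "truth_runs.csv", index=False)
        self.missing.to_csv(path / "truth_missing.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "TruthTable":
        path = Path(path)
        return cls(
            pd.read_csv(path / "truth_features.csv"),
            pd.read_csv(path / "truth_runs.csv"),
            pd.read_csv(path / "truth_missing.csv"),
        )
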
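"""End-to-end orchestration: simulate -> align -> fit -> validate.

``run_train`` executes the whole training workflow on a cohort of peak
lists and archives every frozen artifact plus a :class:`RunManifest`
(config snapshot, seeds, artifact hashes, stage timings) so a run can be
audited and replayed.  ``run_validate`` pushes an independent cohort
through the frozen artifacts one sample at a time -- after a hard audit
that no validation sample id was ever seen in training -- and returns the
evaluation report with subgroup breakdowns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (VlmAnchorSet, build_feature_matrix, correct_all,
                        correct_masses, detect_vlm_anchors)
from .containers import PeakList, TruthTable
from .evaluate import EvaluationReport
from .model import (DetectionSettings, MulticancerDetectionModel,
                    MulticancerDetectionResults)
from .synthetic import (CohortConfig, MetaboliteRecord, generate_cohort,
                        generate_library, load_library, save_library)


@dataclass
class AlignmentSettings:
    """Anchor-detection and annotation settings for the pipeline.

    The anchor window must exceed the full run-to-run drift span (peaks of
    one metabolite spread across the whole drift range before correction),
    and the presence threshold must tolerate the cohort's missingness.
    """

    ppm_window: float = 45.0
    min_presence: float = 0.75
    annotation_ppm: float = 10.0
    rt_tolerance: float = 30.0


@dataclass
class PipelineConfig:
    """Structured configuration of a full training/validation run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alignment: AlignmentSettings = field(default_factory=AlignmentSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    validation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort = CohortConfig(**d.get("cohort", {}))
        if isinstance(cohort.drift_ppm_range, list):
            cohort.drift_ppm_range = tuple(cohort.drift_ppm_range)
        det = d.get("detection", {})
        if isinstance(det.get("c_grid"), list):
            det["c_grid"] = tuple(det["c_grid"])
        if isinstance(det.get("sigma_grid"), list):
            det["sigma_grid"] = tuple(det["sigma_grid"])
        return cls(cohort=cohort,
                   alignment=AlignmentSettings(**d.get("alignment", {})),
                   detection=DetectionSettings(**det),
                   validation_fraction=d.get("validation_fraction", 0.5),
                   seed=d.get("seed", 0))


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    seed: int
    version: str
    artifacts: dict[str, dict] = field(default_factory=dict)  # name -> {path, sha256}
    timings: dict[str, float] = field(default_factory=dict)   # stage -> seconds
    train_sample_ids: list[str] = field(default_factory=list)
    validation_sample_ids: list[str] = field(default_factory=list)

    def record(self, name: str, path: Path) -> None:
        self.artifacts[name] = {"path": str(path), "sha256": _hash_path(path)}

    def verify(self) -> None:
        for name, a in self.artifacts.items():
            p = Path(a["path"])
            if not p.exists():
                raise FileNotFoundError(f"artifact {name} missing: {p}")
            if _hash_path(p) != a["sha256"]:
                raise ValueError(f"artifact {name} hash mismatch: {p}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _hash_path(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def split_cohort(metadata: pd.DataFrame,
                 validation_fraction: float | dict[str, float],
                 seed: int) -> tuple[list[str], list[str]]:
    """Stratified by class and cancer type, split sample ids by sample.

    ``validation_fraction`` may be a single fraction or a per-class map
    (e.g. different fractions for cancer and normal samples, mirroring a
    published train-test / validation allocation).
    """
    rng = np.random.default_rng(seed)
    val_ids: list[str] = []
    for (cls, _), grp in metadata.groupby(["class", "cancer_type"],
                                          observed=True):
        frac = validation_fraction.get(cls, 0.0) \
            if isinstance(validation_fraction, dict) else validation_fraction
        ids = grp["sample_id"].to_numpy()
        n_val = int(round(frac * len(ids)))
        val_ids.extend(rng.choice(ids, n_val, replace=False))
    val_set = set(val_ids)
    train_ids = [s for s in metadata["sample_id"] if s not in val_set]
    return train_ids, sorted(val_set)


@dataclass
class TrainedPipeline:
    """In-memory result of ``run_train`` (manifest + frozen components)."""

    manifest: RunManifest
    results: MulticancerDetectionResults
    anchors: VlmAnchorSet
    library: list[MetaboliteRecord]
    config: PipelineConfig
    validation_runs: list[PeakList]
    validation_metadata: pd.DataFrame
    truth: TruthTable | None = None


def run_train(config: PipelineConfig, out_dir: str | Path,
              cohort: tuple[list[PeakList], pd.DataFrame, TruthTable] | None = None,
              library: list[MetaboliteRecord] | None = None,
              ) -> TrainedPipeline:
    """Execute the training workflow and archive its artifacts.

    When ``cohort`` is None a synthetic cohort is simulated from
    ``config.cohort``.  The cohort is split by sample (stratified on class
    and cancer type); anchors, normalization reference, imputation model
    and SVM are fitted on the training side only, and the validation side
    is returned untouched for :func:`run_validate`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed,
                           version=__version__)
    t0 = time.perf_counter()

    if library is None:
        library = generate_library(config.cohort.n_metabolites,
                                   config.cohort.fraction_nonhuman,
                                   seed=config.seed)
    if cohort is None:
        cohort = generate_cohort(config.cohort, library)
    peak_lists, metadata, truth = cohort
    manifest.timings["simulate"] = time.perf_counter() - t0

    save_library(library, out / "library.tsv")
    manifest.record("library", out / "library.tsv")
    metadata.to_csv(out / "metadata.csv", index=False)
    manifest.record("metadata", out / "metadata.csv")

    t0 = time.perf_counter()
    train_ids, val_ids = split_cohort(metadata, config.validation_fraction,
                                      config.seed)
    manifest.train_sample_ids = train_ids
    manifest.validation_sample_ids = val_ids
    by_id = {p.run_id: p for p in peak_lists}
    train_runs = [by_id[s] for s in train_ids]
    val_runs = [by_id[s] for s in val_ids]

    a = config.alignment
    anchors = detect_vlm_anchors(train_runs, ppm_window=a.ppm_window,
                                 min_presence=a.min_presence)
    corrected = correct_all(train_runs, anchors)
    matrix = build_feature_matrix(corrected, library,
                                  annotation_ppm=a.annotation_ppm,
                                  rt_tolerance=a.rt_tolerance)
    anchors.to_json(out / "anchors.json")
    manifest.record("anchors", out / "anchors.json")
    matrix.to_dir(out, name="train_matrix")
    manifest.record("train_matrix", out / "train_matrix.csv")
    manifest.timings["align"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = MulticancerDetectionModel(matrix, metadata, library,
                                      config.detection)
    results = model.fit()
    manifest.timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results.save(out)
    for name, rel in [("normalization_reference", "normalization_reference.json"),
                      ("imputation_model", "imputation_model"),
                      ("svm_model", "svm_model"),
                      ("grid_search", "grid_search.csv"),
                      ("cv_summary", "cv_summary.csv"),
                      ("train_report", "train_report.json")]:
        manifest.record(name, out / rel)
    manifest.timings["archive"] = time.perf_counter() - t0
    manifest.save(out / "manifest.json")
    val_meta = metadata[metadata["sample_id"].isin(val_ids)].reset_index(drop=True)
    return TrainedPipeline(manifest=manifest, results=results,
                           anchors=anchors, library=library, config=config,
                           validation_runs=val_runs,
                           validation_metadata=val_meta, truth=truth)


def process_validation_run(run: PeakList, trained: TrainedPipeline) -> pd.DataFrame:
    """One validation run -> raw single-row feature table (frozen anchors)."""
    a = trained.config.alignment
    corrected = correct_masses(run, trained.anchors)
    mat = build_feature_matrix([corrected], trained.library,
                               annotation_ppm=a.annotation_ppm,
                               rt_tolerance=a.rt_tolerance)
    return mat.values.reindex(columns=trained.results.feature_order)


def run_validate(trained: TrainedPipeline,
                 validation_runs: list[PeakList] | None = None,
                 validation_metadata: pd.DataFrame | None = None,
                 ) -> EvaluationReport:
    """Score an independent cohort through the frozen training artifacts.

    Every sample is aligned against the training anchor set, annotated,
    normalized, imputed and scored using training-time artifacts only.
    A sample-id overlap with the training set raises (leakage guard).
    """
    runs = validation_runs if validation_runs is not None else trained.validation_runs
    meta = validation_metadata if validation_metadata is not None \
        else trained.validation_metadata
    ids = [r.run_id for r in runs]
    overlap = set(ids) & set(trained.manifest.train_sample_ids)
    if overlap:
        raise ValueError(
            f"leakage: validation ids seen in training: {sorted(overlap)[:5]}")
    rows = [process_validation_run(r, trained) for r in runs]
    raw = pd.concat(rows)
    raw.index = pd.Index(ids, name="sample_id")
    return trained.results.evaluate(raw, meta)
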
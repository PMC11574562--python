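"""Virtual-lock-mass (VLM) m/z correction and feature-matrix assembly.

High-resolution LC-MS runs carry a small, run-specific multiplicative mass
error (ppm scale), so the same metabolite appears at slightly different m/z
in different runs.  Because downstream learning needs common features, the
error must be removed before peaks are pooled across runs.  The scheme here
treats peaks that are reliably and unambiguously present across runs as
internal anchors ("virtual lock masses"):

1. pool all peaks, cluster by m/z, and keep clusters in which every matched
   run contributes exactly one peak inside the ppm window and the match
   rate reaches ``min_presence`` -- each surviving cluster's mean m/z is an
   anchor consensus mass, and each run's deviation from it is that run's
   observed ppm error at that mass;
2. correct every peak of a run by the run's ppm error, piecewise-linearly
   interpolated in m/z between flanking anchors (constant beyond the ends).

Only relative run-to-run error is identifiable: a mass offset common to
every run is invisible to any internal-anchor scheme.

After correction, peaks are annotated against the reference library
(nearest mass within a ppm tolerance, RT gate) and assembled into one
samples x metabolites :class:`~metaboscreen.containers.FeatureMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PROTON_MASS, FeatureMatrix, PeakList
from .synthetic import MetaboliteRecord, library_to_frame

logger = logging.getLogger(__name__)

DEFAULT_PPM_WINDOW = 10.0
DEFAULT_MIN_PRESENCE = 0.95
DEFAULT_ANNOTATION_PPM = 10.0
DEFAULT_RT_TOLERANCE = 30.0


@dataclass
class VlmAnchorSet:
    """Consensus anchor masses plus each run's observed ppm error at them.

    ``ppm_errors`` is an anchors x runs table (NaN where the run did not
    contribute a peak to that anchor), rows aligned with ``consensus_mz``
    which is strictly increasing.
    """

    consensus_mz: np.ndarray
    run_ids: list[str]
    ppm_errors: pd.DataFrame  # index: anchor position, columns: run_id
    ppm_window: float
    min_presence: float

    def __post_init__(self) -> None:
        if len(self.consensus_mz) > 1 and not np.all(np.diff(self.consensus_mz) > 0):
            raise ValueError("anchor masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.consensus_mz)

    def run_errors(self, run_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(anchor masses, ppm errors) observed for one run, NaN-free."""
        err = self.ppm_errors[run_id].to_numpy()
        ok = ~np.isnan(err)
        return self.consensus_mz[ok], err[ok]

    def median_run_error(self) -> pd.Series:
        """Per-run median ppm error across anchors (drift estimate)."""
        return self.ppm_errors.median(axis=0, skipna=True)

    # -- persistence (consensus masses only; foreign runs are corrected by
    #    matching their own peaks against the consensus) --------------------
    def to_json(self, path) -> None:
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps({
            "consensus_mz": self.consensus_mz.tolist(),
            "ppm_window": self.ppm_window,
            "min_presence": self.min_presence}))

    @classmethod
    def from_json(cls, path) -> "VlmAnchorSet":
        import json
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        cons = np.asarray(d["consensus_mz"])
        return cls(cons, [], pd.DataFrame(np.empty((len(cons), 0))),
                   d["ppm_window"], d["min_presence"])


def detect_vlm_anchors(runs: list[PeakList], ppm_window: float = DEFAULT_PPM_WINDOW,
                       min_presence: float = DEFAULT_MIN_PRESENCE) -> VlmAnchorSet:
    """Find virtual-lock-mass anchors across a set of runs.

    Pooled peaks are clustered greedily along the m/z axis (a new cluster
    starts whenever the gap to the previous peak exceeds ``ppm_window``).
    A cluster becomes an anchor iff (i) every peak lies within
    ``+-ppm_window`` of the cluster mean, (ii) no run contributes two peaks
    (ambiguous windows are discarded), and (iii) at least ``min_presence``
    of the runs contribute one.
    """
    if len(runs) < 2:
        raise ValueError("anchor detection needs at least 2 runs")
    if ppm_window <= 0:
        raise ValueError("ppm_window must be positive")
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must lie in (0, 1]")

    run_ids = [r.run_id for r in runs]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError("duplicate run_id in anchor detection input")
    mz = np.concatenate([r.peaks["mz"].to_numpy() for r in runs])
    run_idx = np.concatenate([np.full(len(r), i) for i, r in enumerate(runs)])
    order = np.argsort(mz, kind="stable")
    mz, run_idx = mz[order], run_idx[order]

    # Greedy 1-D clustering: break where the relative gap exceeds the window.
    gaps = np.diff(mz) / mz[:-1] * 1e6
    breaks = np.flatnonzero(gaps > ppm_window) + 1
    bounds = np.concatenate([[0], breaks, [len(mz)]])

    n_runs = len(runs)
    consensus: list[float] = []
    errors: list[np.ndarray] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        c_mz, c_runs = mz[lo:hi], run_idx[lo:hi]
        counts = np.bincount(c_runs, minlength=n_runs)
        if counts.max(initial=0) > 1:
            continue  # some run matched twice -> ambiguous window
        center = float(c_mz.mean())
        dev_ppm = (c_mz - center) / center * 1e6
        if np.abs(dev_ppm).max(initial=0.0) > ppm_window:
            continue
        if (counts > 0).sum() / n_runs < min_presence:
            continue
        err = np.full(n_runs, np.nan)
        err[c_runs] = dev_ppm
        consensus.append(center)
        errors.append(err)

    err_df = pd.DataFrame(np.asarray(errors).reshape(len(consensus), n_runs),
                          columns=run_ids)
    return VlmAnchorSet(np.asarray(consensus), run_ids, err_df,
                        ppm_window, min_presence)


def _match_run_errors(run: PeakList, anchors: VlmAnchorSet) -> tuple[np.ndarray, np.ndarray]:
    """Estimate a foreign run's per-anchor errors by direct matching."""
    mz = np.sort(run.peaks["mz"].to_numpy())
    cons = anchors.consensus_mz
    pos = np.searchsorted(mz, cons)
    best = np.full(len(cons), np.nan)
    for j, c in enumerate(cons):
        cand = [k for k in (pos[j] - 1, pos[j]) if 0 <= k < len(mz)]
        if not cand:
            continue
        devs = [(mz[k] - c) / c * 1e6 for k in cand]
        inside = [d for d in devs if abs(d) <= anchors.ppm_window]
        if len(inside) == 1:
            best[j] = inside[0]
    ok = ~np.isnan(best)
    return cons[ok], best[ok]


def correct_masses(run: PeakList, anchors: VlmAnchorSet) -> PeakList:
    """Remove a run's mass error using the anchor set.

    Each peak's m/z is divided by ``1 + e(mz)/1e6`` where ``e`` is the
    run's ppm error interpolated piecewise-linearly between flanking
    anchors (constant extrapolation outside the anchor range).  RT,
    intensity and peak order are untouched.
    """
    if len(anchors) == 0:
        logger.warning("empty anchor set: run %s returned uncorrected", run.run_id)
        return run.copy()
    if run.run_id in anchors.ppm_errors.columns:
        a_mz, a_err = anchors.run_errors(run.run_id)
    else:
        a_mz, a_err = _match_run_errors(run, anchors)
    if len(a_mz) == 0:
        logger.warning("run %s matches no anchors: returned uncorrected", run.run_id)
        return run.copy()
    peaks = run.peaks.copy()
    mz = peaks["mz"].to_numpy()
    err = np.interp(mz, a_mz, a_err)  # constant beyond first/last anchor
    peaks["mz"] = mz / (1.0 + err / 1e6)
    return PeakList(run.run_id, run.batch_id, peaks)


def correct_all(runs: list[PeakList], anchors: VlmAnchorSet) -> list[PeakList]:
    return [correct_masses(r, anchors) for r in runs]


def build_feature_matrix(runs: list[PeakList], library: list[MetaboliteRecord],
                         annotation_ppm: float = DEFAULT_ANNOTATION_PPM,
                         rt_tolerance: float = DEFAULT_RT_TOLERANCE) -> FeatureMatrix:
    """Annotate corrected peaks against the library and pivot to a matrix.

    A peak is assigned to the library record minimizing the absolute ppm
    difference between the peak's neutral mass (observed m/z minus the
    proton mass, positive ion mode) and the record's monoisotopic mass,
    subject to the ppm tolerance and an RT gate.  Unannotated peaks are
    dropped.  If two peaks of one sample annotate to the same metabolite,
    the higher-intensity peak wins.  Absent peaks become NaN cells.
    """
    if not runs:
        raise ValueError("no runs supplied")
    if annotation_ppm <= 0:
        raise ValueError("annotation_ppm must be positive")
    lib = library_to_frame(library).sort_values("monoisotopic_mass")
    lib_mass = lib["monoisotopic_mass"].to_numpy()
    lib_rt = lib["nominal_rt"].to_numpy()
    lib_ids = lib["metabolite_id"].to_numpy()

    frames = []
    for run in runs:
        if len(run) == 0:
            continue
        neutral = run.peaks["mz"].to_numpy() - PROTON_MASS
        pos = np.searchsorted(lib_mass, neutral)
        lo = np.clip(pos - 1, 0, len(lib_mass) - 1)
        hi = np.clip(pos, 0, len(lib_mass) - 1)
        ppm_lo = np.abs(neutral - lib_mass[lo]) / lib_mass[lo] * 1e6
        ppm_hi = np.abs(neutral - lib_mass[hi]) / lib_mass[hi] * 1e6
        take_hi = ppm_hi < ppm_lo
        idx = np.where(take_hi, hi, lo)
        ppm = np.where(take_hi, ppm_hi, ppm_lo)
        rt_ok = np.abs(run.peaks["rt"].to_numpy() - lib_rt[idx]) <= rt_tolerance
        keep = (ppm <= annotation_ppm) & rt_ok
        if not keep.any():
            continue
        frames.append(pd.DataFrame({
            "sample_id": run.run_id,
            "metabolite_id": lib_ids[idx[keep]],
            "intensity": run.peaks["intensity"].to_numpy()[keep],
        }))
    sample_ids = [r.run_id for r in runs]
    if not frames:
        values = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
        return FeatureMatrix(values, transform_log=["aligned+annotated"])

    long = pd.concat(frames, ignore_index=True)
    # Injectivity: at most one peak per (sample, metabolite) cell.
    long = (long.sort_values("intensity")
                .drop_duplicates(["sample_id", "metabolite_id"], keep="last"))
    values = long.pivot(index="sample_id", columns="metabolite_id",
                        values="intensity")
    values = values.reindex(index=sample_ids)
    values = values[sorted(values.columns)]
    values.index.name = "sample_id"
    values.columns.name = None

    ann_map = {m: (mass, rt) for m, mass, rt in
               zip(lib_ids, lib_mass + PROTON_MASS, lib_rt)}
    annotations = pd.DataFrame({
        "metabolite_id": list(values.columns),
        "consensus_mz": [ann_map[m][0] for m in values.columns],
        "consensus_rt": [ann_map[m][1] for m in values.columns],
    })
    return FeatureMatrix(values, annotations, transform_log=["aligned+annotated"])


def ppm_error_vs_library(runs: list[PeakList], library: list[MetaboliteRecord],
                         match_ppm: float = 200.0) -> np.ndarray:
    """Signed ppm error of every peak against its nearest library mass.

    Diagnostic used to quantify how much mass error remains before/after
    correction; ``match_ppm`` only bounds the nearest-neighbour search so
    genuinely unmatched noise peaks are excluded.
    """
    lib_mz = np.sort(library_to_frame(library)["monoisotopic_mass"].to_numpy()) + PROTON_MASS
    out = []
    for run in runs:
        mz = run.peaks["mz"].to_numpy()
        pos = np.searchsorted(lib_mz, mz)
        lo = np.clip(pos - 1, 0, len(lib_mz) - 1)
        hi = np.clip(pos, 0, len(lib_mz) - 1)
        d_lo = (mz - lib_mz[lo]) / lib_mz[lo] * 1e6
        d_hi = (mz - lib_mz[hi]) / lib_mz[hi] * 1e6
        d = np.where(np.abs(d_hi) < np.abs(d_lo), d_hi, d_lo)
        out.append(d[np.abs(d) <= match_ppm])
    return np.concatenate(out) if out else np.array([])
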
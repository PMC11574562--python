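"""Simulated multi-batch LC-MS serum-metabolome cohorts with ground truth.

Real untargeted serum metabolomics data for multi-cancer detection are not
publicly deposited, so every downstream stage of this package is exercised
on cohorts produced here.  The generator emulates the statistical structure
the pipeline has to cope with:

* a reference library of annotated metabolites (a stand-in for an HMDB-style
  annotation source) with human / drug / plant / ambiguous origin classes;
* per-feature log10-normal intensities with a per-batch offset (batch
  effect), a class effect on a small *signature* subset of features in
  cancer samples, and i.i.d. residual noise;
* one ppm-scale mass drift value per analytical run, so every observed m/z
  is shifted multiplicatively -- the error the virtual-lock-mass correction
  is meant to remove;
* abundance-dependent dropout (MNAR: a cell below its feature's low-intensity
  quantile is not detected) plus completely random dropout (MCAR).

Missing measurements are *absent peaks*: a peak list simply has no row for
an unquantified metabolite, never a zero intensity.

Cohort composition defaults (cancer-type mix, stage distribution, age and
sex margins) are patterned on the demography of a 6445-participant
case-control serum study spanning 30 cancer types; the intensity model
itself is a stand-in, as no distributional facts about real serum feature
intensities are available (see docs/methods.md).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PROTON_MASS, PeakList, TruthTable

ORIGINS = ("human", "drug", "plant", "ambiguous")
NONHUMAN_ORIGINS = ("drug", "plant", "ambiguous")
STAGES = ("I", "II", "III", "IV", "NS")
AGE_GROUPS = ("20-30", "31-40", "41-50", "51-60", "61-70", ">70")

# Age-group composition (fractions) by class, from the study demography
# table: cancer patients skew older than non-cancer volunteers.
AGE_DIST = {
    "cancer": (0.052, 0.135, 0.251, 0.284, 0.197, 0.081),
    "normal": (0.1885, 0.1896, 0.2032, 0.2049, 0.1539, 0.0598),
}
SEX_DIST = {"cancer": {"F": 0.474, "M": 0.526},
            "normal": {"F": 0.481, "M": 0.519}}

# Clinical-stage composition of the cancer arm (stages I-IV plus
# not-staged cancers of unknown primary origin).
STAGE_DIST = (0.170, 0.401, 0.317, 0.110, 0.002)

# Class- and stage-specific distribution of the 2831 cancer samples in the
# study the generator is patterned on: cancer type, female/male counts,
# total, and per-stage counts (unknown-primary cancers are not staged).
CANCER_COMPOSITION_TSV = """\
cancer_type	female	male	total	stage_i	stage_ii	stage_iii	stage_iv
breast	262	0	262	36	133	77	16
endometrial	70	0	70	20	26	19	5
cervical	137	0	137	27	58	40	12
ovarian	155	0	155	28	64	48	15
lung	68	158	226	40	55	80	51
aml	36	50	86	10	15	29	32
thyroid	58	41	99	16	46	32	5
melanoma	18	47	65	24	26	14	1
colorectal	82	127	209	20	81	90	18
kidney	16	39	55	8	25	17	6
nhl	19	28	47	13	15	9	10
pancreatic	19	40	59	9	25	17	8
liver_and_bile	35	78	113	36	33	32	12
gastric	62	132	194	38	90	57	9
head_and_neck	154	397	551	80	262	147	61
esophageal	67	76	143	26	61	42	14
bladder	10	22	32	4	12	14	2
brain_and_cns	8	34	42	11	13	14	4
multiple_myeloma	3	15	18	0	7	7	4
gall_bladder	18	17	35	3	18	13	1
sarcoma	22	23	45	6	10	23	6
prostate	0	122	122	17	37	55	13
testicular	0	4	4	0	2	2	0
vulvar	5	0	5	0	1	2	2
anal	6	3	9	2	3	3	1
vaginal	2	0	2	0	0	2	0
penile	0	18	18	4	7	7	0
unknown_primary	4	2	6	0	0	0	0
germ_cell_tumor	2	12	14	0	10	3	1
squamous_cell_carcinoma	4	4	8	3	1	3	1
"""


def cancer_composition() -> pd.DataFrame:
    """Per-cancer-type sample composition the defaults are patterned on."""
    return pd.read_csv(io.StringIO(CANCER_COMPOSITION_TSV), sep="\t")


def study_composition() -> dict[str, float]:
    """Cohort-level arithmetic recomputed from the composition tables.

    All quantities are derived from the printed per-type / per-stage counts
    and the published train-test / validation split sizes; nothing here is
    measured from simulated data.
    """
    comp = cancer_composition()
    n_cancer = int(comp["total"].sum())
    n_normal = 3614
    staged = comp[["stage_i", "stage_ii", "stage_iii", "stage_iv"]].sum()
    n_traintest_cancer, n_traintest_normal = 1445, 1812
    n_val_cancer, n_val_normal = 1386, 1802
    return {
        "n_cancer": n_cancer,
        "n_normal": n_normal,
        "n_total": n_cancer + n_normal,
        "cancer_fraction_percent": 100.0 * n_cancer / (n_cancer + n_normal),
        "n_cancer_types": int(len(comp)),
        "early_stage_percent": 100.0 * (staged["stage_i"] + staged["stage_ii"]) / n_cancer,
        "stage_i_percent": 100.0 * staged["stage_i"] / n_cancer,
        "n_traintest_total": n_traintest_cancer + n_traintest_normal,
        "n_validation_total": n_val_cancer + n_val_normal,
        "n_female": int(comp["female"].sum()),
        "n_male": int(comp["male"].sum()),
    }


@dataclass(frozen=True)
class MetaboliteRecord:
    """One annotated metabolite in the reference library."""

    metabolite_id: str
    name: str
    monoisotopic_mass: float  # Da, neutral
    origin: str               # human | drug | plant | ambiguous
    nominal_rt: float         # seconds
    base_log_abundance: float  # log10 intensity units

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")
        if self.nominal_rt < 0:
            raise ValueError("nominal_rt must be non-negative")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


def library_to_frame(library: list[MetaboliteRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in library])


def save_library(library: list[MetaboliteRecord], path: str | Path) -> None:
    cols = ["metabolite_id", "name", "monoisotopic_mass", "origin",
            "nominal_rt", "base_log_abundance"]
    library_to_frame(library).to_csv(path, sep="\t", index=False, columns=cols)


def load_library(path: str | Path) -> list[MetaboliteRecord]:
    df = pd.read_csv(path, sep="\t")
    if "base_log_abundance" not in df.columns:
        df["base_log_abundance"] = 5.0
    return [MetaboliteRecord(**row) for row in df.to_dict(orient="records")]


def generate_library(n_metabolites: int, fraction_nonhuman: float,
                     seed: int) -> list[MetaboliteRecord]:
    """Generate a mock annotation library with unambiguous masses.

    Masses are laid out on a jittered log-spaced grid over the small-molecule
    window 70-1200 Da, which guarantees pairwise spacing of at least ~40% of
    the mean relative gap -- far wider than twice the 10 ppm annotation
    tolerance for any library of realistic size, so annotation of a drifted
    peak is unambiguous by construction.  Exactly
    ``round(fraction_nonhuman * n)`` records are flagged with a non-human
    origin (drug / plant / ambiguous).
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    if not 0 <= fraction_nonhuman < 1:
        raise ValueError("fraction_nonhuman must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(70.0), np.log(1200.0)
    step = (hi - lo) / n_metabolites
    grid = lo + (np.arange(n_metabolites) + 0.5) * step
    jitter = rng.uniform(-0.3, 0.3, n_metabolites) * step
    masses = np.exp(grid + jitter)

    n_nonhuman = int(round(fraction_nonhuman * n_metabolites))
    origins = np.array(["human"] * n_metabolites, dtype=object)
    idx = rng.choice(n_metabolites, size=n_nonhuman, replace=False)
    origins[idx] = rng.choice(NONHUMAN_ORIGINS, size=n_nonhuman)

    rts = rng.uniform(30.0, 900.0, n_metabolites)
    base = rng.normal(5.0, 0.8, n_metabolites)
    width = len(str(n_metabolites))
    return [
        MetaboliteRecord(
            metabolite_id=f"M{i + 1:0{width}d}",
            name=f"metabolite-{i + 1:0{width}d}",
            monoisotopic_mass=float(masses[i]),
            origin=str(origins[i]),
            nominal_rt=float(rts[i]),
            base_log_abundance=float(base[i]),
        )
        for i in range(n_metabolites)
    ]


def _default_cancer_counts() -> dict[str, int]:
    # Eight of the commonest cancer types in the composition table,
    # 50 samples each: 400 cancer samples spread over >= 5 types.
    types = ["breast", "lung", "colorectal", "gastric", "head_and_neck",
             "ovarian", "prostate", "esophageal"]
    return {t: 50 for t in types}


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults describe the package's reference cohort: 400 cancer samples
    spread over eight cancer types plus 400 non-cancer controls, 1000
    library metabolites of which 60 form the cancer signature, acquired in
    four batches with +-30 ppm per-run mass drift and both abundance-driven
    (MNAR) and completely random (MCAR) dropout.
    """

    n_cancer_per_type: dict[str, int] = field(default_factory=_default_cancer_counts)
    n_normal: int = 400
    n_metabolites: int = 1000
    n_signature: int = 60
    effect_size: float = 0.6          # log10 shift on signature features
    stage_attenuation: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STAGES})
    n_batches: int = 4
    batch_sd: float = 0.15            # sd of per-batch log10 offset
    drift_ppm_range: tuple[float, float] = (-30.0, 30.0)
    mcar_rate: float = 0.03
    mnar_threshold_quantile: float = 0.05
    residual_sd: float = 0.30         # i.i.d. per-cell log10 noise
    n_latent_factors: int = 5         # shared biological variation
    latent_sd: float = 0.15           # sd of per-feature factor loadings
    fraction_nonhuman: float = 0.20
    rt_jitter_sd: float = 2.0         # seconds
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature > self.n_metabolites:
            raise ValueError("n_signature cannot exceed n_metabolites")
        for name in ("mcar_rate", "mnar_threshold_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_normal < 0 or any(v < 0 for v in self.n_cancer_per_type.values()):
            raise ValueError("sample counts must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def _centered_drifts(rng: np.random.Generator, n: int,
                     lo: float, hi: float) -> np.ndarray:
    """Per-run drifts over [lo, hi] with mean pinned to the interval center.

    A lock-mass style correction can only remove *relative* run-to-run mass
    error; a common offset shared by every run is unidentifiable from the
    data alone.  Drifts are therefore drawn as antithetic pairs about the
    interval center so the cohort-mean drift equals the center exactly and
    recovered per-run errors are comparable to the injected truth.
    """
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    m = n // 2
    u = rng.uniform(0.0, half, m)
    deltas = np.concatenate([u, -u, [0.0]] if n % 2 else [u, -u])
    return center + rng.permutation(deltas)


def _sample_metadata(config: CohortConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []
    for ctype in sorted(config.n_cancer_per_type):
        for _ in range(config.n_cancer_per_type[ctype]):
            rows.append({"class": "cancer", "cancer_type": ctype})
    rows.extend({"class": "normal", "cancer_type": "none"}
                for _ in range(config.n_normal))
    meta = pd.DataFrame(rows)
    n = len(meta)
    meta.insert(0, "sample_id", [f"S{i + 1:05d}" for i in range(n)])

    is_cancer = (meta["class"] == "cancer").to_numpy()
    stage = np.array(["NS"] * n, dtype=object)
    stage[is_cancer] = rng.choice(STAGES, size=is_cancer.sum(), p=STAGE_DIST)
    meta["stage"] = stage
    age = np.empty(n, dtype=object)
    sex = np.empty(n, dtype=object)
    for cls in ("cancer", "normal"):
        m = (meta["class"] == cls).to_numpy()
        p = np.asarray(AGE_DIST[cls])
        age[m] = rng.choice(AGE_GROUPS, size=m.sum(), p=p / p.sum())
        sex[m] = rng.choice(["F", "M"], size=m.sum(),
                            p=[SEX_DIST[cls]["F"], SEX_DIST[cls]["M"]])
    meta["age_group"] = age
    meta["sex"] = sex

    # Randomize acquisition order before assigning contiguous batches, so
    # batch membership carries no class signal by construction.
    order = rng.permutation(n)
    meta = meta.iloc[order].reset_index(drop=True)
    block = int(np.ceil(n / config.n_batches))
    meta["batch_id"] = [f"B{i // block + 1}" for i in range(n)]
    return meta


def generate_cohort(config: CohortConfig, library: list[MetaboliteRecord],
                    ) -> tuple[list[PeakList], pd.DataFrame, TruthTable]:
    """Simulate peak lists, sample metadata and the matching ground truth.

    The true log10 abundance of feature *f* in sample *s* is::

        base_f + batch_offset(b) + batch_interaction(b, f)
               + sum_k score(s, k) * loading(k, f)
               + 1[cancer] * sign_f * effect_size * attenuation(stage)
               + eps,   eps ~ N(0, residual_sd)

    where the class term applies only to the ``n_signature`` signature
    features and the latent-factor term (``n_latent_factors`` standard
    normal per-sample scores with N(0, latent_sd) per-feature loadings)
    creates the between-metabolite correlation characteristic of serum
    profiles, which the chained-equations imputer exploits.  Observed m/z is the protonated library mass scaled by the
    run's drift; a cell is dropped as MNAR when its intensity falls below
    the ``mnar_threshold_quantile`` of its feature's intensity distribution,
    and as MCAR with probability ``mcar_rate`` otherwise.
    """
    if not library:
        raise ValueError("library must be non-empty")
    config.validate()
    if config.n_metabolites != len(library):
        raise ValueError("config.n_metabolites must match library size")
    rng = np.random.default_rng(config.seed)

    meta = _sample_metadata(config, rng)
    n_samples, n_feat = len(meta), len(library)
    if n_samples == 0:
        raise ValueError("cohort has no samples")

    lib = library_to_frame(library)
    base = lib["base_log_abundance"].to_numpy()
    masses = lib["monoisotopic_mass"].to_numpy()
    rts = lib["nominal_rt"].to_numpy()
    feat_ids = lib["metabolite_id"].to_numpy()

    sig_idx = np.sort(rng.choice(n_feat, size=config.n_signature, replace=False))
    sig_sign = rng.choice([-1.0, 1.0], size=config.n_signature)

    batches = sorted(meta["batch_id"].unique())
    b_index = meta["batch_id"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    batch_offset = rng.normal(0.0, config.batch_sd, len(batches))
    batch_inter = rng.normal(0.0, config.batch_sd / 2.0, (len(batches), n_feat))

    log_int = np.tile(base, (n_samples, 1))
    log_int += batch_offset[b_index, None] + batch_inter[b_index, :]
    if config.n_latent_factors > 0:
        scores = rng.normal(0.0, 1.0, (n_samples, config.n_latent_factors))
        loadings = rng.normal(0.0, config.latent_sd,
                              (config.n_latent_factors, n_feat))
        log_int += scores @ loadings
    is_cancer = (meta["class"] == "cancer").to_numpy()
    atten = meta["stage"].map(config.stage_attenuation).fillna(1.0).to_numpy()
    class_term = np.zeros((n_samples, n_feat))
    class_term[:, sig_idx] = (is_cancer * atten)[:, None] * \
        (config.effect_size * sig_sign)[None, :]
    log_int += class_term
    log_int += rng.normal(0.0, config.residual_sd, (n_samples, n_feat))
    intensity = 10.0 ** log_int

    # Missingness: MNAR strictly below the per-feature low-intensity
    # quantile, then MCAR on the remainder.
    mnar = np.zeros((n_samples, n_feat), dtype=bool)
    if config.mnar_threshold_quantile > 0:
        thr = np.quantile(intensity, config.mnar_threshold_quantile, axis=0)
        mnar = intensity < thr[None, :]
    mcar = (~mnar) & (rng.random((n_samples, n_feat)) < config.mcar_rate)
    observed = ~(mnar | mcar)

    drifts = _centered_drifts(rng, n_samples, *config.drift_ppm_range)
    rt_jitter = rng.normal(0.0, config.rt_jitter_sd, (n_samples, n_feat))

    peak_lists: list[PeakList] = []
    mz_true = masses + PROTON_MASS
    for i, row in enumerate(meta.itertuples(index=False)):
        keep = observed[i]
        peaks = pd.DataFrame({
            "mz": mz_true[keep] * (1.0 + drifts[i] / 1e6),
            "rt": np.maximum(rts[keep] + rt_jitter[i, keep], 0.0),
            "intensity": intensity[i, keep],
        })
        peak_lists.append(PeakList(row.sample_id, row.batch_id, peaks))

    is_sig = np.zeros(n_feat, dtype=bool)
    is_sig[sig_idx] = True
    sign_col = np.zeros(n_feat)
    sign_col[sig_idx] = sig_sign
    truth = TruthTable(
        features=pd.DataFrame({
            "metabolite_id": feat_ids, "is_signature": is_sig,
            "effect_sign": sign_col, "base_log_abundance": base}),
        runs=pd.DataFrame({
            "run_id": meta["sample_id"], "batch_id": meta["batch_id"],
            "drift_ppm": drifts}),
        missing=pd.DataFrame({
            "sample_id": np.repeat(meta["sample_id"].to_numpy(), n_feat)[~observed.ravel()],
            "metabolite_id": np.tile(feat_ids, n_samples)[~observed.ravel()],
            "cause": np.where(mnar, "mnar", "mcar").ravel()[~observed.ravel()]}),
    )
    return peak_lists, meta, truth


def save_cohort(peak_lists: list[PeakList], metadata: pd.DataFrame,
                truth: TruthTable, out_dir: str | Path) -> None:
    """Write a cohort in the plain-text interchange layout used by the CLI."""
    out = Path(out_dir)
    runs_dir = out / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    for pl in peak_lists:
        pl.to_csv(runs_dir / f"{pl.run_id}.csv")
    metadata.to_csv(out / "metadata.csv", index=False)
    truth.to_dir(out / "truth")


def load_cohort(in_dir: str | Path) -> tuple[list[PeakList], pd.DataFrame, TruthTable | None]:
    in_dir = Path(in_dir)
    metadata = pd.read_csv(in_dir / "metadata.csv")
    batch_of = dict(zip(metadata["sample_id"], metadata["batch_id"]))
    peak_lists = [
        PeakList.from_csv(p, run_id=p.stem, batch_id=str(batch_of.get(p.stem, "")))
        for p in sorted((in_dir / "runs").glob("*.csv"))
    ]
    truth_dir = in_dir / "truth"
    truth = TruthTable.from_dir(truth_dir) if truth_dir.exists() else None
    return peak_lists, metadata, truth
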
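"""Synthetic cohorts for the brain-age / co-pathology pipeline.

Generates everything the downstream stages consume, with known planted
ground truth:

* cross-sectional cohorts of cognitively unimpaired (CU) subjects and four
  cognitively impaired subgroups defined by the CSF p-tau181/Abeta42 ratio
  (threshold 0.021) and trichotomous alpha-synuclein SAA status;
* 3D T1-like volumes whose morphology encodes an "effective age": a
  centered ellipsoidal cavity (a ventricle surrogate) whose radius grows
  linearly with effective age inside a two-shell head phantom;
* longitudinal tables of ICV-normalized regional composite volumes and
  cognitive scores following linear or quadratic group trajectories with
  per-subject random intercepts/slopes.

Planted effect sizes default to the reported cohort effect table: group
brain-age offsets (2.08, 2.40, 4.64, 6.93) years vs CU, yearly BAG slopes
(0.03, 0.14, 0.29, 0.54), and regional atrophy slopes on the order of
1e-4 ICV-normalized units per year. CU subjects have offset and slope 0
by construction, so their effective age equals chronological age when
noise is off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CU = "CU"
GROUPS_CI = ("AD-LB-", "AD-LB+", "AD+LB-", "AD+LB+")
GROUPS = (CU,) + GROUPS_CI

#: cohort sizes of the four impaired subgroups in the reference cohort
DEFAULT_CI_SIZES = {"AD-LB-": 195, "AD-LB+": 46, "AD+LB-": 396, "AD+LB+": 166}

AD_THRESHOLD = 0.021


@dataclass
class SubjectSpec:
    subject_id: str
    CA0: float
    sex: str                      # 'F' | 'M'
    education: float              # years
    cognitive_state: str          # 'CU' | 'MCI' | 'dementia'
    ptau181: float
    abeta42: float
    saa: str                      # 'positive' | 'negative' | 'intermediate'
    true_group: str               # one of GROUPS
    visit_times: list = field(default_factory=lambda: [0.0])


@dataclass
class ScanVolume:
    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    subject_id: str = ""
    visit_index: int = 0


@dataclass
class OutcomeSpec:
    """Generating model of one longitudinal outcome.

    value = intercept + group_int[g] + (slope + group_slope[g]) * t
            + (quad + group_quad[g]) * t^2
            + b0_subject + b1_subject * t + resid,
    with group contrasts relative to AD-LB- (CU entries are 0).
    """

    name: str
    order: str                    # 'linear' | 'quadratic'
    intercept: float
    slope: float
    group_int: dict
    group_slope: dict
    quad: float = 0.0
    group_quad: dict = field(default_factory=dict)
    rand_int_sd: float = 0.0
    rand_slope_sd: float = 0.0
    resid_sd: float = 0.0


def _gdict(lbm, lbp, adm, adp):
    return {"CU": 0.0, "AD-LB-": lbm, "AD-LB+": lbp, "AD+LB-": adm, "AD+LB+": adp}


def default_outcomes() -> dict:
    """Generator defaults for longitudinal outcomes.

    Baselines come from the reference cohort's baseline table (regional
    volumes ICV-normalized with a nominal 1,500 cm^3 ICV); group baseline
    and slope contrasts come from the reported mixed-model coefficient
    tables. Values not reported (reference-group slopes, random-effect and
    residual spreads) are fixed at plausible ADNI-like magnitudes.
    """
    out = {}
    out["bag"] = OutcomeSpec(
        "bag", "linear", intercept=2.0, slope=0.03,
        group_int=_gdict(0.0, 0.94, 2.25, 3.53),
        group_slope=_gdict(0.0, 0.11, 0.26, 0.51),
        rand_int_sd=3.0, rand_slope_sd=0.2, resid_sd=1.5)
    out["mtl"] = OutcomeSpec(
        "mtl", "linear", intercept=7.787e-3, slope=-1.0e-4,
        group_int=_gdict(0.0, -1.0e-4, -5.01e-4, -8.52e-4),
        group_slope=_gdict(0.0, -5.0e-5, -1.45e-4, -2.14e-4),
        rand_int_sd=8e-4, rand_slope_sd=3e-5, resid_sd=1.5e-4)
    out["basal_ganglia"] = OutcomeSpec(
        "basal_ganglia", "linear", intercept=8.431e-3, slope=-5.0e-5,
        group_int=_gdict(0.0, -3.0e-5, -5.0e-5, -8.0e-5),
        group_slope=_gdict(0.0, -2.0e-5, -7.3e-5, -1.21e-4),
        rand_int_sd=1e-3, rand_slope_sd=2e-5, resid_sd=1e-4)
    out["occipital"] = OutcomeSpec(
        "occipital", "linear", intercept=1.893e-2, slope=-1.0e-4,
        group_int=_gdict(0.0, -2.0e-4, -3.0e-4, -4.0e-4),
        group_slope=_gdict(0.0, -5.0e-5, -2.09e-4, -3.27e-4),
        rand_int_sd=2e-3, rand_slope_sd=5e-5, resid_sd=3e-4)
    out["middle_temporal"] = OutcomeSpec(
        "middle_temporal", "linear", intercept=8.947e-3, slope=-8.0e-5,
        group_int=_gdict(0.0, -2.0e-4, -5.00e-4, -6.60e-4),
        group_slope=_gdict(0.0, -6.0e-5, -2.04e-4, -3.67e-4),
        rand_int_sd=1.2e-3, rand_slope_sd=4e-5, resid_sd=2e-4)
    out["cdrsb"] = OutcomeSpec(
        "cdrsb", "quadratic", intercept=1.44, slope=0.30,
        group_int=_gdict(0.0, -0.15, 0.84, 1.23),
        group_slope=_gdict(0.0, 0.05, 0.15, 0.25),
        quad=0.02, group_quad=_gdict(0.0, 0.02, 0.05, 0.14),
        rand_int_sd=1.2, rand_slope_sd=0.2, resid_sd=0.6)
    out["adas11"] = OutcomeSpec(
        "adas11", "quadratic", intercept=8.49, slope=0.80,
        group_int=_gdict(0.0, 0.59, 1.42, 2.73),
        group_slope=_gdict(0.0, 0.10, 0.50, 0.90),
        quad=0.10, group_quad=_gdict(0.0, 0.05, 0.25, 0.57),
        rand_int_sd=4.0, rand_slope_sd=0.5, resid_sd=2.0)
    out["memory"] = OutcomeSpec(
        "memory", "linear", intercept=0.56, slope=-0.05,
        group_int=_gdict(0.0, -0.12, -0.90, -1.30),
        group_slope=_gdict(0.0, 0.0, -0.12, -0.25),
        rand_int_sd=0.9, rand_slope_sd=0.08, resid_sd=0.3)
    out["language"] = OutcomeSpec(
        "language", "quadratic", intercept=0.38, slope=-0.03,
        group_int=_gdict(0.0, -0.06, -0.56, -0.95),
        group_slope=_gdict(0.0, 0.0, -0.04, -0.08),
        quad=-0.005, group_quad=_gdict(0.0, 0.01, -0.01, -0.03),
        rand_int_sd=0.9, rand_slope_sd=0.05, resid_sd=0.3)
    out["visuospatial"] = OutcomeSpec(
        "visuospatial", "linear", intercept=0.12, slope=-0.02,
        group_int=_gdict(0.0, 0.07, -0.35, -0.60),
        group_slope=_gdict(0.0, -0.02, -0.06, -0.22),
        rand_int_sd=0.7, rand_slope_sd=0.06, resid_sd=0.3)
    out["executive"] = OutcomeSpec(
        "executive", "quadratic", intercept=0.40, slope=-0.03,
        group_int=_gdict(0.0, -0.33, -0.74, -1.23),
        group_slope=_gdict(0.0, 0.0, -0.02, -0.04),
        quad=-0.002, group_quad=_gdict(0.0, 0.0, -0.005, -0.01),
        rand_int_sd=0.9, rand_slope_sd=0.04, resid_sd=0.3)
    return out


@dataclass
class GeneratorParams:
    """All knobs of the synthetic cohort generator."""

    # effective-age model (years): offset + slope * t added per group
    group_offset: dict = field(default_factory=lambda: _gdict(2.08, 2.40, 4.64, 6.93))
    group_slope: dict = field(default_factory=lambda: _gdict(0.03, 0.14, 0.29, 0.54))
    noise_sd: float = 0.0          # sd of effective-age noise, years

    # demographics
    age_range: tuple = (23.0, 100.0)
    ci_age_mean_sd: dict = field(default_factory=lambda: {
        "AD-LB-": (72.0, 8.2), "AD-LB+": (73.8, 7.2),
        "AD+LB-": (73.5, 7.0), "AD+LB+": (74.3, 7.2)})
    female_frac: dict = field(default_factory=lambda: {
        "CU": 0.632, "AD-LB-": 0.405, "AD-LB+": 0.283,
        "AD+LB-": 0.424, "AD+LB+": 0.392})
    dementia_frac: dict = field(default_factory=lambda: {
        "AD-LB-": 0.09, "AD-LB+": 0.13, "AD+LB-": 0.41, "AD+LB+": 0.52})
    education_mean_sd: tuple = (16.0, 2.7)
    intermediate_frac: float = 0.05  # extra CI subjects with intermediate SAA
    visit_count_range: tuple = (1, 6)

    # biomarker model
    ad_threshold: float = AD_THRESHOLD

    # volume rendering
    volume_shape: tuple = (32, 32, 32)
    voxel_noise_sd: float = 0.05

    # longitudinal outcomes
    outcomes: dict = field(default_factory=default_outcomes)

    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid age range {self.age_range}")
        if any(s < 16 for s in self.volume_shape):
            raise ValueError("volume_shape must be at least 16 voxels per axis")
        if self.group_offset[CU] != 0.0 or self.group_slope[CU] != 0.0:
            raise ValueError("CU group must have offset 0 and slope 0")
        if not (0 <= self.intermediate_frac < 1):
            raise ValueError("intermediate_frac must be in [0, 1)")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_biomarkers(rng, group: str, threshold: float):
    """p-tau181 / Abeta42 pair consistent with the group's AD status."""
    abeta = rng.uniform(500.0, 1700.0)
    if group.startswith("AD+"):
        ratio = rng.uniform(threshold, 4 * threshold)
    else:
        ratio = rng.uniform(0.25 * threshold, 0.98 * threshold)
    return ratio * abeta, abeta


def _make_subject(rng, sid, group, params: GeneratorParams, saa=None) -> SubjectSpec:
    lo, hi = params.age_range
    if group == CU:
        ca0 = rng.uniform(lo, hi)
        cognitive_state = "CU"
    else:
        mu, sd = params.ci_age_mean_sd[group]
        ca0 = float(np.clip(rng.normal(mu, sd), lo, hi))
        cognitive_state = "dementia" if rng.uniform() < params.dementia_frac[group] else "MCI"
    sex = "F" if rng.uniform() < params.female_frac[group] else "M"
    edu = float(np.clip(rng.normal(*params.education_mean_sd), 6, 24))
    ptau, abeta = _draw_biomarkers(rng, group, params.ad_threshold)
    if saa is None:
        saa = "positive" if group.endswith("LB+") else "negative"
        if group == CU:
            saa = "negative"
    n_visits = int(rng.integers(params.visit_count_range[0],
                                params.visit_count_range[1] + 1))
    visit_times = [float(t) for t in range(n_visits)]
    return SubjectSpec(subject_id=sid, CA0=float(ca0), sex=sex, education=edu,
                       cognitive_state=cognitive_state, ptau181=float(ptau),
                       abeta42=float(abeta), saa=saa, true_group=group,
                       visit_times=visit_times)


def generate_cohort(n_cu: int, n_per_group=None, params: GeneratorParams | None = None):
    """Generate a cohort table plus the underlying subject specifications.

    ``n_per_group`` maps the four impaired subgroups to subject counts
    (or is a 4-tuple in AD-LB-, AD-LB+, AD+LB-, AD+LB+ order). A fraction
    ``params.intermediate_frac`` of extra impaired subjects is added with
    intermediate SAA readouts; their table group label is 'excluded'.
    Identical seeds produce byte-identical tables.
    """
    params = params or GeneratorParams()
    params.validate()
    if n_per_group is None:
        n_per_group = {g: 0 for g in GROUPS_CI}
    if not isinstance(n_per_group, dict):
        n_per_group = dict(zip(GROUPS_CI, n_per_group))
    if n_cu < 0 or any(v < 0 for v in n_per_group.values()):
        raise ValueError("subject counts must be non-negative")

    rng = np.random.default_rng(params.seed)
    subjects = []
    for i in range(n_cu):
        subjects.append(_make_subject(rng, f"CU{i:05d}", CU, params))
    for g in GROUPS_CI:
        tag = g.replace("+", "p").replace("-", "m")
        for i in range(n_per_group.get(g, 0)):
            subjects.append(_make_subject(rng, f"{tag}{i:05d}", g, params))
    n_ci = sum(n_per_group.get(g, 0) for g in GROUPS_CI)
    n_int = int(round(params.intermediate_frac * n_ci))
    for i in range(n_int):
        g = GROUPS_CI[int(rng.integers(0, 4))]
        subjects.append(_make_subject(rng, f"INT{i:05d}", g, params, saa="intermediate"))

    rows = []
    for s in subjects:
        label = "excluded" if s.saa == "intermediate" else s.true_group
        rows.append({
            "subject_id": s.subject_id, "scan_id": f"{s.subject_id}_v0",
            "CA": s.CA0, "sex": s.sex, "education": s.education,
            "cognitive_state": s.cognitive_state, "ptau181": s.ptau181,
            "abeta42": s.abeta42, "saa": s.saa, "group": label,
            "n_visits": len(s.visit_times), "split": "",
        })
    cols = ["subject_id", "scan_id", "CA", "sex", "education", "cognitive_state",
            "ptau181", "abeta42", "saa", "group", "n_visits", "split"]
    table = pd.DataFrame(rows, columns=cols)
    return table, subjects


# ---------------------------------------------------------------------------
# Effective age and volume rendering
# ---------------------------------------------------------------------------

def effective_age(subject: SubjectSpec, t: float, params: GeneratorParams,
                  rng=None) -> float:
    """Generative brain age at follow-up time t (years since baseline).

    CA0 + t + group_offset + group_slope * t, plus optional Gaussian noise
    when an rng is supplied and ``params.noise_sd > 0``. CU subjects track
    chronological age exactly when noise is off.
    """
    g = subject.true_group
    age = subject.CA0 + t + params.group_offset[g] + params.group_slope[g] * t
    if rng is not None and params.noise_sd > 0:
        age += rng.normal(0.0, params.noise_sd)
    return float(age)


def _cavity_radius_fraction(age: float) -> float:
    """Cavity radius as a fraction of the head radius.

    Parameterized so the cavity *volume* (proportional to the cube of the
    radius) grows linearly with age, which keeps the voxel-count feature
    linear in effective age.
    """
    frac = np.clip((age - 20.0) / 80.0, 0.0, 1.2)
    r_min, r_max = 0.15, 0.70
    return float((r_min ** 3 + (r_max ** 3 - r_min ** 3) * frac) ** (1.0 / 3.0))


def render_volume(subject: SubjectSpec, t: float, params: GeneratorParams,
                  rng=None) -> ScanVolume:
    """Render a T1-like phantom whose cavity size encodes effective age.

    The head is a bright ellipsoidal shell (cortex, intensity 1.0) around
    uniform tissue (0.8); the central cavity (0.05) has a radius that
    grows linearly with effective age. Voxel noise is added only when an
    rng is supplied. Identical inputs produce identical grids.
    """
    params.validate()
    shape = tuple(params.volume_shape)
    age = effective_age(subject, t, params, rng=rng if params.noise_sd > 0 else None)
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    # normalized radial coordinate: 1.0 at the head boundary
    r2 = sum((g / (0.45 * n)) ** 2 for g, n in zip(grids, shape))
    r = np.sqrt(r2)
    vol = np.zeros(shape)
    vol[r <= 1.0] = 0.8          # brain tissue
    vol[(r > 0.88) & (r <= 1.0)] = 1.0  # cortical shell
    cav = _cavity_radius_fraction(age)
    vol[r <= cav] = 0.05         # ventricle-like cavity
    if rng is not None and params.voxel_noise_sd > 0:
        vol = vol + rng.normal(0.0, params.voxel_noise_sd, shape)
    return ScanVolume(voxels=vol, subject_id=subject.subject_id,
                      visit_index=subject.visit_times.index(t) if t in subject.visit_times else 0)


def cavity_volume(volume: ScanVolume | np.ndarray, threshold: float = 0.3) -> int:
    """Brute-force morphological oracle: voxel count of the central cavity.

    Counts sub-threshold voxels inside the head mask (radial coordinate
    <= 0.85), which isolates the cavity from the zero background.
    """
    vox = volume.voxels if isinstance(volume, ScanVolume) else np.asarray(volume)
    shape = vox.shape
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    r = np.sqrt(sum((g / (0.45 * n)) ** 2 for g, n in zip(grids, shape)))
    return int(np.sum((vox < threshold) & (r <= 0.85)))


def region_atlas(shape) -> np.ndarray:
    """Synthetic integer region atlas on the phantom grid.

    1 = central cavity zone, 2 = periventricular band (where the growing
    cavity boundary moves), 3 = cortical shell, 4 = remaining tissue;
    0 = background.
    """
    shape = tuple(shape)
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape], indexing="ij")
    r = np.sqrt(sum((g / (0.45 * n)) ** 2 for g, n in zip(grids, shape)))
    atlas = np.zeros(shape, dtype=np.int32)
    atlas[r <= 1.0] = 4
    atlas[(r > 0.88) & (r <= 1.0)] = 3
    atlas[r <= 0.70] = 2
    atlas[r <= 0.25] = 1
    return atlas


ATLAS_REGION_NAMES = {1: "cavity_core", 2: "periventricular", 3: "cortex", 4: "tissue"}


def render_cohort_volumes(subjects, params: GeneratorParams, rng=None,
                          visits="first"):
    """Render volumes for a list of subjects.

    Returns (volumes array (N, D, H, W), metadata DataFrame with
    subject_id, group, time, CA, effective_age).
    """
    vols, rows = [], []
    for s in subjects:
        times = s.visit_times if visits == "all" else s.visit_times[:1]
        for t in times:
            sv = render_volume(s, t, params, rng=rng)
            vols.append(sv.voxels)
            rows.append({"subject_id": s.subject_id, "group": s.true_group,
                         "time": t, "CA": s.CA0 + t, "sex": s.sex,
                         "effective_age": effective_age(s, t, params)})
    meta = pd.DataFrame(rows)
    return np.asarray(vols), meta


# ---------------------------------------------------------------------------
# Longitudinal trajectories
# ---------------------------------------------------------------------------

def generate_trajectories(subjects, params: GeneratorParams, rng=None,
                          outcomes=None) -> pd.DataFrame:
    """Long-format table of regional-volume and cognitive trajectories.

    One row per subject x visit x outcome. With ``rng=None`` all random
    effects and residuals are off and rows equal the generating mean
    (flat at baseline if all betas are zero).
    """
    params.validate()
    specs = params.outcomes if outcomes is None else {
        k: v for k, v in params.outcomes.items() if k in outcomes}
    rows = []
    for s in subjects:
        if not s.visit_times:
            raise ValueError(f"subject {s.subject_id} has no visits")
        g = s.true_group
        for name, spec in specs.items():
            if rng is not None:
                b0 = rng.normal(0.0, spec.rand_int_sd) if spec.rand_int_sd > 0 else 0.0
                b1 = rng.normal(0.0, spec.rand_slope_sd) if spec.rand_slope_sd > 0 else 0.0
            else:
                b0 = b1 = 0.0
            for t in s.visit_times:
                mu = (spec.intercept + spec.group_int[g]
                      + (spec.slope + spec.group_slope[g]) * t
                      + b0 + b1 * t)
                if spec.order == "quadratic":
                    mu += (spec.quad + spec.group_quad.get(g, 0.0)) * t * t
                if rng is not None and spec.resid_sd > 0:
                    mu += rng.normal(0.0, spec.resid_sd)
                rows.append({
                    "subject_id": s.subject_id, "group": g, "time": t,
                    "outcome": name, "value": mu, "baseline_age": s.CA0,
                    "sex": s.sex, "cognitive_state": s.cognitive_state,
                    "education": s.education, "icv": 1500.0,
                })
    return pd.DataFrame(rows, columns=["subject_id", "group", "time", "outcome",
                                       "value", "baseline_age", "sex",
                                       "cognitive_state", "education", "icv"])


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def params_to_yaml(params: GeneratorParams, path=None) -> str:
    """Serialize generator parameters (including outcome specs) to YAML."""
    import dataclasses

    import yaml

    payload = dataclasses.asdict(params)
    payload["outcomes"] = {k: dataclasses.asdict(v)
                           for k, v in params.outcomes.items()}
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> GeneratorParams:
    """Load generator parameters from a YAML string or file path."""
    import os

    import yaml

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(source)
    outcomes = {k: OutcomeSpec(**v) for k, v in payload.pop("outcomes", {}).items()}
    for key in ("age_range", "education_mean_sd", "visit_count_range", "volume_shape"):
        if key in payload:
            payload[key] = tuple(payload[key])
    if "ci_age_mean_sd" in payload:
        payload["ci_age_mean_sd"] = {g: tuple(v)
                                     for g, v in payload["ci_age_mean_sd"].items()}
    params = GeneratorParams(outcomes=outcomes or default_outcomes(), **payload)
    params.validate()
    return params


def save_volume(scan: ScanVolume, path) -> None:
    """Write a scan as NIfTI-1 with voxel spacing on the affine diagonal."""
    import nibabel as nib

    affine = np.diag(list(scan.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(scan.voxels, dtype=np.float32), affine), str(path))


def load_volume(path) -> ScanVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScanVolume(voxels=np.asarray(img.dataobj, dtype=np.float64), spacing=spacing)
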
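"""Synthetic multimodal cohort generator.

Emulates a three-group clinical cohort (healthy controls, generalized
anxiety disorder with optional comorbid major depression, and MD-only)
with four measurement modalities:

* questionnaire sum scores (PSWQ, BDI, IUS-12, STAI-T) drawn from
  per-group truncated normals with configurable means/SDs;
* timed salivary cortisol profiles constructed so each subject's log-AUC
  (trapezoid, natural log, zero baseline) exactly realizes a draw from the
  configured per-group log-AUC distribution;
* gray- and white-matter volume maps: smooth nonnegative 3D fields on a
  shared grid, with multiplicative group effects localized to regions of a
  synthetic box atlas, plus Gaussian-smoothed voxel noise (emulating the
  output of VBM-style preprocessing, which itself is out of scope);
* exact-count categorical demographics, so that chi-square group
  comparisons on the generated tables reproduce the configured counts.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.ndimage import gaussian_filter

from .cortisol import CortisolProfile
from .features import ROIAtlas, VolumeImage

__all__ = [
    "GROUPS",
    "ATLAS_AREAS",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "make_box_atlas",
    "default_effect_table",
    "null_cohort_config",
    "generate_cohort",
    "write_dataset",
    "load_dataset",
]

GROUPS = ("HC", "GAD", "MD")
SCALES = ("pswq", "bdi", "ius12", "stait")

# 15 bilateral areas -> 30 labeled regions ("<area> L"/"<area> R")
ATLAS_AREAS = (
    "Putamen",
    "Amygdala",
    "Nucleus caudate",
    "Hippocampus",
    "Thalamus",
    "Anterior cingulate gyrus",
    "Superior frontal gyrus",
    "Middle frontal gyrus",
    "Superior medial frontal gyrus",
    "Inferior frontal gyrus, pars triangularis",
    "Inferior frontal gyrus, pars opercularis",
    "Superior frontal gyrus, orbital",
    "Middle frontal gyrus, orbital",
    "Inferior frontal gyrus, orbital",
    "Medial frontal gyrus, orbital",
)

# Per-group questionnaire sum-score means and SDs (defaults of the cohort
# the generator is calibrated to emulate).
DEFAULT_QUESTIONNAIRE_PARAMS = {
    "pswq": {"HC": (36.00, 9.98), "GAD": (62.00, 6.22), "MD": (57.43, 12.06)},
    "bdi": {"HC": (4.50, 4.82), "GAD": (21.16, 7.37), "MD": (21.36, 9.14)},
    "ius12": {"HC": (25.75, 6.72), "GAD": (41.00, 7.03), "MD": (32.71, 9.25)},
    "stait": {"HC": (33.58, 6.77), "GAD": (56.16, 7.11), "MD": (55.00, 7.04)},
}
# Instrument score ranges used for clipping.
SCALE_RANGES = {
    "pswq": (16, 80),
    "bdi": (0, 63),
    "ius12": (12, 60),
    "stait": (20, 80),
}
# Per-group mean/SD of the cortisol log-AUC (ln nmol/L x min over 100 min).
DEFAULT_CORTISOL_PARAMS = {
    "HC": (199.55, 66.05),
    "GAD": (159.85, 38.76),
    "MD": (196.61, 70.30),
}
DEFAULT_AGE_PARAMS = {
    "HC": (32.25, 9.33),
    "GAD": (33.47, 8.90),
    "MD": (29.86, 11.71),
}
# Exact per-group category counts, relative to the reference group sizes;
# scaled proportionally if group sizes are changed.
DEFAULT_GROUP_SIZES = {"HC": 24, "GAD": 19, "MD": 14}
DEFAULT_DEMOGRAPHIC_COUNTS = {
    "female": {"HC": 17, "GAD": 16, "MD": 12},
    "right_handed": {"HC": 21, "GAD": 17, "MD": 11},
    "secondary_school": {"HC": 18, "GAD": 12, "MD": 12},
    "nonsmoker": {"HC": 22, "GAD": 19, "MD": 13},
}
# One control's smoking status is recorded as missing in the reference
# counts (22 nonsmokers of 23 with data).
DEFAULT_MISSING_SMOKING = {"HC": 1, "GAD": 0, "MD": 0}


def default_effect_table(gm_effect: float = 0.10, wm_effect: float = 0.0) -> dict:
    """Multiplicative per-region, per-group tissue-volume shifts.

    Frontal and cingulate gray matter defaults to a symmetric opposite-sign
    pattern — volume up in GAD, down in MD — while subcortical regions are
    untouched.  White matter carries no group effect by default.  Values
    are multipliers relative to healthy controls (1.0).
    """
    table: dict[str, dict[str, float]] = {}
    for area in ATLAS_AREAS:
        if "frontal" in area.lower() or "cingulate" in area.lower():
            for side in ("L", "R"):
                table[f"{area} {side}"] = {"GAD": 1.0 + gm_effect, "MD": 1.0 - gm_effect}
    if wm_effect:
        table["White matter"] = {"GAD": 1.0 + wm_effect, "MD": 1.0 - wm_effect}
    return table


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate the reference cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_comorbid: int = 12
    questionnaire_params: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_QUESTIONNAIRE_PARAMS)
    )
    cortisol_params: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CORTISOL_PARAMS)
    )
    age_params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_AGE_PARAMS))
    demographic_counts: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_DEMOGRAPHIC_COUNTS)
    )
    missing_smoking: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_SMOKING)
    )
    sample_times: tuple = (0.0, 10.0, 35.0, 55.0, 75.0, 100.0)
    cortisol_shape_sd: float = 0.15
    grid_shape: tuple = (40, 48, 40)
    voxel_size_mm: float = 3.0
    effect_table: dict = field(default_factory=default_effect_table)
    gm_base: float = 0.35
    wm_base: float = 0.30
    noise_sd: float = 0.05
    smoothing_fwhm_mm: float = 8.0
    missing_cortisol: int = 1
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g} must be > 0")
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must cover {GROUPS}")
        if not 0 <= self.n_comorbid <= self.group_sizes["GAD"]:
            raise ValueError(
                f"n_comorbid ({self.n_comorbid}) exceeds GAD group size "
                f"({self.group_sizes['GAD']})"
            )
        times = np.asarray(self.sample_times, dtype=float)
        if len(times) != 6:
            raise ValueError("sample_times must have length 6")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        for scale, per_group in self.questionnaire_params.items():
            for g, (_, sd) in per_group.items():
                if sd <= 0:
                    raise ValueError(f"{scale}/{g}: SD must be > 0")
        for g, (_, sd) in self.cortisol_params.items():
            if sd <= 0:
                raise ValueError(f"cortisol {g}: SD must be > 0")
        if len(self.grid_shape) != 3 or any(d <= 0 for d in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        if self.missing_cortisol < 0:
            raise ValueError("missing_cortisol must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_times"] = list(self.sample_times)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = copy.deepcopy(d)
        if "sample_times" in d:
            d["sample_times"] = tuple(d["sample_times"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        for key in ("questionnaire_params",):
            if key in d:
                d[key] = {
                    scale: {g: tuple(v) for g, v in per.items()}
                    for scale, per in d[key].items()
                }
        for key in ("cortisol_params", "age_params"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        return cls(**d)


def null_cohort_config(**overrides) -> CohortConfig:
    """A no-effect configuration: identical distributions in every group.

    Questionnaire, cortisol and age parameters are set to the healthy-group
    values for all groups and the imaging effect table is emptied, so group
    labels carry no systematic information in any modality.
    """
    cfg = CohortConfig(**overrides)
    cfg.questionnaire_params = {
        scale: {g: per["HC"] for g in GROUPS}
        for scale, per in cfg.questionnaire_params.items()
    }
    cfg.cortisol_params = {g: cfg.cortisol_params["HC"] for g in GROUPS}
    cfg.age_params = {g: cfg.age_params["HC"] for g in GROUPS}
    cfg.effect_table = {}
    return cfg


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: labels, demographics and questionnaire sum scores."""

    subject_id: str
    group: str
    comorbid_md: bool
    sex: str
    handedness: str
    education: str
    smoker: str | None
    age: float
    pswq: int
    bdi: int
    ius12: int
    stait: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.comorbid_md and self.group != "GAD":
            raise ValueError(f"{self.subject_id}: comorbid_md requires group GAD")
        for scale in SCALES:
            lo, hi = SCALE_RANGES[scale]
            v = getattr(self, scale)
            if not lo <= v <= hi:
                raise ValueError(f"{self.subject_id}: {scale}={v} outside [{lo},{hi}]")


@dataclass
class Cohort:
    subjects: list
    cortisol: list
    gm: list
    wm: list
    atlas: ROIAtlas
    truth: dict
    config: CohortConfig


def _box(center: float, edge: int, lo: int, hi: int) -> slice:
    start = int(round(center - edge / 2.0))
    start = max(lo, min(start, hi - edge))
    return slice(start, start + edge)


def make_box_atlas(grid_shape, voxel_size_mm: float = 3.0) -> tuple[ROIAtlas, dict]:
    """Axis-aligned box parcellation with 30 labeled regions plus WM.

    The 15 bilateral areas are laid out on a 5 x 3 lattice in the (y, z)
    plane, mirrored left/right along x; a white-matter slab sits above the
    gray-matter boxes.  All structures live inside a "brain" slab that
    leaves a margin at the grid edges.  Returns the atlas and a metadata
    dict with per-region slices and voxel counts.
    """
    nx, ny, nz = (int(d) for d in grid_shape)
    m = max(1, round(min(grid_shape) * 0.05))
    edge = max(1, round(min(grid_shape) * 0.10))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    table: dict[int, str] = {}
    slices: dict[str, tuple] = {}

    ix = {"L": m + 0.25 * (nx - 2 * m), "R": m + 0.75 * (nx - 2 * m)}
    ys = [m + (k + 0.5) / 5.0 * (ny - 2 * m) for k in range(5)]
    zs = [m + (0.12 + 0.25 * k) * (nz - 2 * m) for k in range(3)]
    label = 0
    for i, area in enumerate(ATLAS_AREAS):
        sy = _box(ys[i % 5], edge, m, ny - m)
        sz = _box(zs[i // 5], edge, m, nz - m)
        for side in ("L", "R"):
            label += 1
            sx = _box(ix[side], edge, m, nx - m)
            labels[sx, sy, sz] = label
            table[label] = f"{area} {side}"
            slices[table[label]] = (
                (sx.start, sx.stop), (sy.start, sy.stop), (sz.start, sz.stop)
            )

    wm_mask = np.zeros((nx, ny, nz), dtype=bool)
    z0 = int(round(m + 0.80 * (nz - 2 * m)))
    z1 = int(round(m + 0.95 * (nz - 2 * m)))
    wm_mask[m : nx - m, m : ny - m, z0 : max(z1, z0 + 1)] = True
    slices["White matter"] = ((m, nx - m), (m, ny - m), (z0, max(z1, z0 + 1)))

    brain = np.zeros((nx, ny, nz), dtype=bool)
    brain[m : nx - m, m : ny - m, m : nz - m] = True
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    atlas = ROIAtlas(labels=labels, table=table, wm_mask=wm_mask, affine=affine)
    meta = {
        "region_slices": slices,
        "region_voxel_counts": {
            name: int(np.prod([b - a for a, b in sl])) for name, sl in slices.items()
        },
        "brain_margin": m,
        "box_edge": edge,
    }
    return atlas, meta


def _trapezoid_weights(times: np.ndarray) -> np.ndarray:
    w = np.zeros_like(times)
    dt = np.diff(times)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return w


# Mild anticipatory-stress shape: log-concentration rises toward scan start
# and decays afterwards; net trapezoid area zero after per-subject leveling.
_PROFILE_SHAPE = np.array([0.10, 0.22, 0.08, -0.05, -0.14, -0.21])


def _scaled_count(count: int, n: int, n_ref: int) -> int:
    return min(n, max(0, round(count * n / n_ref)))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a complete multimodal cohort from a configuration.

    Deterministic given ``config.seed``: the same configuration always
    yields field-by-field identical subjects, profiles and images.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- subjects -----------------------------------------------------
    subjects: list[SubjectRecord] = []
    order = [(g, i) for g in GROUPS for i in range(cfg.group_sizes[g])]
    group_members: dict[str, list[int]] = {g: [] for g in GROUPS}
    for idx, (g, _) in enumerate(order):
        group_members[g].append(idx)

    # categorical demographics: exact counts per group, assignment shuffled
    cat_flags: dict[str, dict[int, str | None]] = {}
    for var, per_group in cfg.demographic_counts.items():
        flags: dict[int, str | None] = {}
        for g in GROUPS:
            members = group_members[g]
            n = len(members)
            k = _scaled_count(per_group[g], n, DEFAULT_GROUP_SIZES[g])
            perm = rng.permutation(n)
            chosen = set(members[j] for j in perm[:k])
            for idx in members:
                flags[idx] = "yes" if idx in chosen else "no"
            if var == "nonsmoker":
                n_missing = _scaled_count(
                    cfg.missing_smoking.get(g, 0), n, DEFAULT_GROUP_SIZES[g]
                )
                # missing status overrides, preferentially on "no" subjects
                others = [members[j] for j in perm[k:]][:n_missing]
                for idx in others:
                    flags[idx] = None
        cat_flags[var] = flags

    comorbid = set(group_members["GAD"][: cfg.n_comorbid])
    counter = {g: 0 for g in GROUPS}
    for idx, (g, _) in enumerate(order):
        counter[g] += 1
        sid = f"{g}{counter[g]:03d}"
        mean, sd = cfg.age_params[g]
        age = float(np.clip(rng.normal(mean, sd), 18.0, 70.0))
        scores = {}
        for scale in SCALES:
            mu, s = cfg.questionnaire_params[scale][g]
            lo, hi = SCALE_RANGES[scale]
            scores[scale] = int(np.clip(round(rng.normal(mu, s)), lo, hi))
        smoker_flag = cat_flags["nonsmoker"][idx]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=g,
                comorbid_md=idx in comorbid,
                sex="female" if cat_flags["female"][idx] == "yes" else "male",
                handedness="right" if cat_flags["right_handed"][idx] == "yes" else "left",
                education="secondary"
                if cat_flags["secondary_school"][idx] == "yes"
                else "other",
                smoker=None if smoker_flag is None else ("no" if smoker_flag == "yes" else "yes"),
                age=round(age, 1),
                **scores,
            )
        )

    # --- cortisol ------------------------------------------------------
    times = np.asarray(cfg.sample_times, dtype=float)
    w = _trapezoid_weights(times)
    span = float(times[-1] - times[0])
    n_total = len(subjects)
    incomplete = set(
        int(i) for i in rng.choice(n_total, size=min(cfg.missing_cortisol, n_total),
                                   replace=False)
    ) if cfg.missing_cortisol > 0 else set()
    profiles: list[CortisolProfile] = []
    for idx, rec in enumerate(subjects):
        mu, sd = cfg.cortisol_params[rec.group]
        target = max(rng.normal(mu, sd), 0.2 * span)  # keep log-levels positive
        shape = _PROFILE_SHAPE + rng.normal(0.0, cfg.cortisol_shape_sd, size=len(times))
        level = (target - float(w @ shape)) / span
        logv = shape + level
        values = np.exp(logv)
        if idx in incomplete:
            drop = int(rng.integers(len(times)))
            values = values.copy()
            values[drop] = np.nan
        profiles.append(
            CortisolProfile(subject_id=rec.subject_id, times=tuple(times),
                            values=tuple(values))
        )

    # --- images --------------------------------------------------------
    atlas, atlas_meta = make_box_atlas(cfg.grid_shape, cfg.voxel_size_mm)
    m = atlas_meta["brain_margin"]
    nx, ny, nz = cfg.grid_shape
    brain = np.zeros(cfg.grid_shape, dtype=bool)
    brain[m : nx - m, m : ny - m, m : nz - m] = True
    sigma_vox = cfg.smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / cfg.voxel_size_mm
    label_field = atlas.labels
    region_of_label = atlas.table

    def _subject_image(rec: SubjectRecord, tissue: str) -> VolumeImage:
        base = cfg.gm_base if tissue == "GM" else cfg.wm_base
        data = np.where(brain, base, 0.0).astype(np.float64)
        if tissue == "GM":
            mult = np.ones(cfg.grid_shape)
            for lab, name in region_of_label.items():
                eff = cfg.effect_table.get(name, {}).get(rec.group)
                if eff is not None:
                    mult[label_field == lab] = eff
            data *= mult
        else:
            eff = cfg.effect_table.get("White matter", {}).get(rec.group)
            if eff is not None:
                data[atlas.wm_mask] *= eff
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.grid_shape)
        data[brain] += noise[brain]
        data = gaussian_filter(data, sigma=sigma_vox)
        np.clip(data, 0.0, None, out=data)
        return VolumeImage(
            subject_id=rec.subject_id, data=data.astype(np.float32),
            affine=atlas.affine, tissue=tissue,
        )

    gm_images = [_subject_image(rec, "GM") for rec in subjects]
    wm_images = [_subject_image(rec, "WM") for rec in subjects]

    truth = {
        "effect_table": copy.deepcopy(cfg.effect_table),
        "incomplete_cortisol_ids": sorted(
            subjects[i].subject_id for i in incomplete
        ),
        **atlas_meta,
    }
    return Cohort(
        subjects=subjects, cortisol=profiles, gm=gm_images, wm=wm_images,
        atlas=atlas, truth=truth, config=cfg,
    )


# ----------------------------------------------------------------------
# dataset I/O


def subjects_to_frame(subjects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "comorbid_md": int(s.comorbid_md),
                "sex": s.sex,
                "handedness": s.handedness,
                "education": s.education,
                "smoker": "" if s.smoker is None else s.smoker,
                "age": s.age,
                "pswq": s.pswq,
                "bdi": s.bdi,
                "ius12": s.ius12,
                "stait": s.stait,
            }
            for s in subjects
        ]
    )


def subjects_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for i, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise ValueError(f"subjects table row {i}: unknown group label {group!r}")
        smoker = row.get("smoker", "")
        smoker = None if (pd.isna(smoker) or smoker == "") else str(smoker)
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                comorbid_md=bool(int(row["comorbid_md"])),
                sex=str(row["sex"]),
                handedness=str(row["handedness"]),
                education=str(row["education"]),
                smoker=smoker,
                age=float(row["age"]),
                pswq=int(row["pswq"]),
                bdi=int(row["bdi"]),
                ius12=int(row["ius12"]),
                stait=int(row["stait"]),
            )
        )
    return records


def write_dataset(cohort: Cohort, directory) -> dict:
    """Persist a cohort to disk; returns the file manifest.

    Layout: ``subjects.tsv``, ``cortisol.tsv`` (long format), per-subject
    NIfTI GM/WM images under ``gm/`` and ``wm/``, ``atlas.nii.gz``,
    ``wm_mask.nii.gz`` and ``manifest.json`` with the seed, the full
    configuration and the atlas region table.  Round-trips losslessly
    through :func:`load_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "gm").mkdir(exist_ok=True)
    (directory / "wm").mkdir(exist_ok=True)

    subjects_to_frame(cohort.subjects).to_csv(
        directory / "subjects.tsv", sep="\t", index=False
    )
    rows = []
    for prof in cohort.cortisol:
        for t, v in zip(prof.times, prof.values):
            rows.append({
                "subject_id": prof.subject_id,
                "time_min": t,
                "cortisol_nmol_l": "" if np.isnan(v) else repr(float(v)),
            })
    pd.DataFrame(rows).to_csv(directory / "cortisol.tsv", sep="\t", index=False)

    image_files = {"gm": {}, "wm": {}}
    for tissue, images in (("gm", cohort.gm), ("wm", cohort.wm)):
        for img in images:
            rel = f"{tissue}/{img.subject_id}_{tissue}.nii.gz"
            nib.save(nib.Nifti1Image(img.data, img.affine), directory / rel)
            image_files[tissue][img.subject_id] = rel
    nib.save(
        nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), cohort.atlas.affine),
        directory / "atlas.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(cohort.atlas.wm_mask.astype(np.uint8), cohort.atlas.affine),
        directory / "wm_mask.nii.gz",
    )

    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "files": {
            "subjects": "subjects.tsv",
            "cortisol": "cortisol.tsv",
            "atlas": "atlas.nii.gz",
            "wm_mask": "wm_mask.nii.gz",
            "images": image_files,
        },
        "atlas_table": {str(k): v for k, v in cohort.atlas.table.items()},
        "truth": _jsonable(cohort.truth),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_dataset(directory) -> Cohort:
    """Load a cohort written by :func:`write_dataset`.

    All images (subject maps, atlas, WM mask) must share one grid shape and
    affine; mismatches are rejected.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = CohortConfig.from_dict(manifest["config"])

    subjects = subjects_from_frame(
        pd.read_csv(directory / manifest["files"]["subjects"], sep="\t",
                    keep_default_na=False, na_values=[],
                    float_precision="round_trip")
    )
    cort_df = pd.read_csv(directory / manifest["files"]["cortisol"], sep="\t",
                          float_precision="round_trip")
    profiles = []
    for sid in cort_df["subject_id"].drop_duplicates():
        sub = cort_df[cort_df["subject_id"] == sid].sort_values("time_min")
        profiles.append(
            CortisolProfile(
                subject_id=str(sid),
                times=tuple(sub["time_min"].astype(float)),
                values=tuple(pd.to_numeric(sub["cortisol_nmol_l"], errors="coerce")),
            )
        )

    def _load_nii(rel):
        path = directory / rel
        if not path.exists():
            raise FileNotFoundError(f"missing image file {path}")
        img = nib.load(str(path))
        return np.asarray(img.dataobj), img.affine

    atlas_data, atlas_affine = _load_nii(manifest["files"]["atlas"])
    wm_data, wm_affine = _load_nii(manifest["files"]["wm_mask"])
    table = {int(k): v for k, v in manifest["atlas_table"].items()}
    if wm_data.shape != atlas_data.shape or not np.allclose(atlas_affine, wm_affine):
        raise ValueError("grid mismatch between atlas and wm_mask")
    atlas = ROIAtlas(
        labels=atlas_data.astype(np.int16), table=table,
        wm_mask=wm_data.astype(bool), affine=atlas_affine,
    )

    def _load_images(tissue):
        images = []
        file_of = manifest["files"]["images"][tissue]
        order = [s.subject_id for s in subjects if s.subject_id in file_of]
        order += [sid for sid in file_of if sid not in set(order)]
        for sid in order:
            data, affine = _load_nii(file_of[sid])
            if data.shape != atlas_data.shape or not np.allclose(affine, atlas_affine):
                raise ValueError(f"grid mismatch for image {file_of[sid]}")
            images.append(
                VolumeImage(subject_id=sid, data=data, affine=affine,
                            tissue=tissue.upper())
            )
        return images

    return Cohort(
        subjects=subjects, cortisol=profiles,
        gm=_load_images("gm"), wm=_load_images("wm"),
        atlas=atlas, truth=manifest.get("truth", {}), config=cfg,
    )
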
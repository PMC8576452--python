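"""Synthetic study cohort: subject table + tissue maps with planted atrophy.

The generator emulates a two-axis clinical cohort — diabetes status
(T2DM vs NT) crossed with cognitive status (CI vs NC, defined by a MoCA
score below 26) — together with per-subject gray-matter probability maps on
the normalized grid.  Disease signal is planted as multiplicative GM
reduction inside a configurable set of atlas regions, calibrated so that
the across-subject distribution of total GM volume over those regions
differs between groups by a requested standardized effect size (Cohen's d).

The anatomical template is a procedural phantom: nested ellipsoidal shells
(WM core, GM ribbon, CSF rind) with smooth logistic transitions.  Subject
variability has two components:

* a global GM scale factor ``~ N(1, scale_sd^2)`` emulating brain-size /
  total-GM variation between individuals, and
* a smooth multiplicative field (white noise smoothed with a Gaussian of
  configurable FWHM, renormalized to field SD ``noise_sd``) emulating local
  morphometric variation.

Both components enter the analytic atrophy calibration, so no Monte Carlo
tuning is needed: for the atrophy region set S,

    Var(V_S) = scale_sd^2 * V0_S^2 + alpha^2 * || G * (t . 1_S) ||_2^2

where t is the template GM map, G the smoothing kernel and alpha the white
noise amplitude that yields field SD ``noise_sd`` after smoothing (adjoint
identity: sum_R t.(G*eps) = sum eps.(G*(t.1_R)) for a symmetric kernel).

All randomness flows from one integer seed; per-subject streams are derived
from the spec seed and a stable hash of the subject id.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    DEFAULT_N_REGIONS,
    DEFAULT_SHAPE,
    BrainMask,
    Parcellation,
    TissueMaps,
    VolumeError,
    build_brain_mask,
    load_volume,
    save_volume,
    synthetic_parcellation,
    write_json,
)

MOCA_CI_THRESHOLD = 26

CSV_COLUMNS = [
    "subject_id",
    "diagnosis",
    "cognition",
    "age",
    "gender",
    "education",
    "moca",
    "fpg",
    "ogtt_2h",
]


class CohortError(ValueError):
    """Raised for inconsistent cohort specifications or records."""


@dataclass
class SubjectRecord:
    """One subject's clinical row.

    ``cognition`` is derived from MoCA: CI iff ``moca < 26``.  For T2DM
    subjects the fasting plasma glucose (mmol/L) satisfies the diagnostic
    criterion (>= 7.0) when populated; ``ogtt_2h`` is optional and left
    unpopulated by the generator.
    """

    subject_id: str
    diagnosis: str  # "T2DM" | "NT"
    cognition: str  # "CI" | "NC"
    age: float
    gender: str  # "M" | "F"
    education: float
    moca: int
    fpg: float | None = None
    ogtt_2h: float | None = None

    def validate(self) -> "SubjectRecord":
        if self.diagnosis not in ("T2DM", "NT"):
            raise CohortError(f"bad diagnosis {self.diagnosis!r}")
        if self.cognition not in ("CI", "NC"):
            raise CohortError(f"bad cognition {self.cognition!r}")
        if self.gender not in ("M", "F"):
            raise CohortError(f"bad gender {self.gender!r}")
        if not 0 <= self.moca <= 30:
            raise CohortError(f"MoCA {self.moca} outside [0, 30]")
        if (self.cognition == "CI") != (self.moca < MOCA_CI_THRESHOLD):
            raise CohortError(
                f"cognition {self.cognition} inconsistent with MoCA {self.moca}"
            )
        if self.age <= 0 or self.education < 0:
            raise CohortError("age must be > 0 and education >= 0")
        if self.diagnosis == "T2DM" and self.fpg is not None and not np.isnan(self.fpg):
            ogtt_ok = self.ogtt_2h is not None and not (
                isinstance(self.ogtt_2h, float) and np.isnan(self.ogtt_2h)
            ) and self.ogtt_2h >= 11.1
            if self.fpg < 7.0 and not ogtt_ok:
                raise CohortError(
                    f"T2DM subject {self.subject_id} meets neither FPG >= 7.0 "
                    "nor OGTT >= 11.1"
                )
        return self


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the study composition: 58 T2DM (25 CI) and 65 NT
    (15 CI) subjects, per-group demographic moments, and a planted regional
    GM atrophy of Cohen's d 1.5 on the cognition contrast and 0.75 on the
    diabetes contrast in atlas regions 1-10.
    """

    n_t2dm: int = 58
    n_nt: int = 65
    n_t2dm_ci: int = 25
    n_nt_ci: int = 15
    # (mean, sd) per diagnosis group, years
    age_params: dict = field(
        default_factory=lambda: {"T2DM": (51.17, 9.28), "NT": (48.34, 7.39)}
    )
    education_params: dict = field(
        default_factory=lambda: {"T2DM": (9.83, 4.32), "NT": (9.94, 3.90)}
    )
    # male fraction per diagnosis group
    gender_props: dict = field(
        default_factory=lambda: {"T2DM": 34 / 58, "NT": 31 / 65}
    )
    # (mean, sd) per diagnosis group; SDs chosen from the printed min-max
    # ranges (~ range / 4)
    moca_params: dict = field(
        default_factory=lambda: {"T2DM": (25.12, 3.2), "NT": (26.75, 2.4)}
    )
    atrophy_regions: tuple[int, ...] = tuple(range(1, 11))
    # standardized effect per contrast; key = affected clinical class
    atrophy_effect: dict = field(default_factory=lambda: {"CI": 1.5, "T2DM": 0.75})
    noise_sd: float = 0.05  # SD of the smooth local field (multiplicative)
    scale_sd: float = 0.04  # SD of the global GM scale factor
    smooth_fwhm: float = 4.0  # mm, FWHM of the noise smoothing kernel
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size: float = 1.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        counts = (self.n_t2dm, self.n_nt, self.n_t2dm_ci, self.n_nt_ci)
        if any(c < 0 for c in counts):
            raise CohortError(f"counts must be >= 0, got {counts}")
        if self.n_t2dm_ci > self.n_t2dm:
            raise CohortError(
                f"n_t2dm_ci={self.n_t2dm_ci} exceeds n_t2dm={self.n_t2dm}"
            )
        if self.n_nt_ci > self.n_nt:
            raise CohortError(f"n_nt_ci={self.n_nt_ci} exceeds n_nt={self.n_nt}")
        for grp in ("T2DM", "NT"):
            if not 0 <= self.gender_props[grp] <= 1:
                raise CohortError(f"gender_props[{grp}] outside [0, 1]")
        if any(d < 0 for d in self.atrophy_effect.values()):
            raise CohortError("atrophy_effect values must be >= 0")
        if self.noise_sd < 0 or self.scale_sd < 0 or self.smooth_fwhm <= 0:
            raise CohortError("noise_sd/scale_sd must be >= 0 and smooth_fwhm > 0")
        if self.seed is None:
            raise CohortError("seed must be set")
        return self

    @property
    def n_total(self) -> int:
        return self.n_t2dm + self.n_nt

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["atrophy_regions"] = list(self.atrophy_regions)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "atrophy_regions" in d:
            d["atrophy_regions"] = tuple(d["atrophy_regions"])
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        for key in ("age_params", "education_params", "moca_params"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        return cls(**d).validate()


def _subject_rng(spec_seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject stream from the cohort seed and subject id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), sub_key]))


def _draw_group(
    rng: np.random.Generator,
    spec: CohortSpec,
    diagnosis: str,
    n: int,
    n_ci: int,
    start_index: int,
) -> list[SubjectRecord]:
    """Draw one diagnosis group with an exact CI/NC split.

    MoCA is drawn from a discretized clipped normal, then the ``n_ci``
    subjects with the lowest scores are assigned CI; any of them at or above
    the threshold is shifted down to 25 and any NC subject below it is
    shifted up to 26 (the minimal-shift assignment).
    """
    age_m, age_s = spec.age_params[diagnosis]
    edu_m, edu_s = spec.education_params[diagnosis]
    moca_m, moca_s = spec.moca_params[diagnosis]
    male_p = spec.gender_props[diagnosis]

    age = np.clip(rng.normal(age_m, age_s, size=n), 18.0, 90.0)
    education = np.clip(rng.normal(edu_m, edu_s, size=n), 0.0, 22.0)
    gender = np.where(rng.random(n) < male_p, "M", "F")
    moca = np.clip(np.rint(rng.normal(moca_m, moca_s, size=n)), 0, 30).astype(int)
    if diagnosis == "T2DM":
        fpg = 7.0 + np.abs(rng.normal(1.5, 1.5, size=n))
    else:
        fpg = np.clip(rng.normal(5.3, 0.5, size=n), 3.5, 6.9)

    # exact CI split: lowest-MoCA subjects become CI (smallest shifts first)
    order = np.argsort(moca, kind="stable")
    is_ci = np.zeros(n, dtype=bool)
    is_ci[order[:n_ci]] = True
    moca = moca.copy()
    moca[is_ci & (moca >= MOCA_CI_THRESHOLD)] = MOCA_CI_THRESHOLD - 1
    moca[~is_ci & (moca < MOCA_CI_THRESHOLD)] = MOCA_CI_THRESHOLD

    records = []
    for i in range(n):
        rec = SubjectRecord(
            subject_id=f"sub-{start_index + i:03d}",
            diagnosis=diagnosis,
            cognition="CI" if is_ci[i] else "NC",
            age=float(round(age[i], 2)),
            gender=str(gender[i]),
            education=float(round(education[i], 2)),
            moca=int(moca[i]),
            fpg=float(round(fpg[i], 2)),
            ogtt_2h=None,
        )
        records.append(rec.validate())
    return records


def generate_subject_table(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the clinical table with exact group and CI/NC counts."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    records = _draw_group(rng, spec, "T2DM", spec.n_t2dm, spec.n_t2dm_ci, 1)
    records += _draw_group(
        rng, spec, "NT", spec.n_nt, spec.n_nt_ci, spec.n_t2dm + 1
    )
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        row["fpg"] = np.nan if rec.fpg is None else rec.fpg
        row["ogtt_2h"] = np.nan if rec.ogtt_2h is None else rec.ogtt_2h
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                cognition=str(row["cognition"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                education=float(row["education"]),
                moca=int(row["moca"]),
                fpg=None if pd.isna(row.get("fpg")) else float(row["fpg"]),
                ogtt_2h=None if pd.isna(row.get("ogtt_2h")) else float(row["ogtt_2h"]),
            ).validate()
        )
    return records


# ---------------------------------------------------------------------------
# phantom template and noise model
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[tuple, TissueMaps] = {}


def phantom_tissue_maps(shape: tuple[int, int, int] = DEFAULT_SHAPE) -> TissueMaps:
    """Procedural brain phantom: nested ellipsoidal shells on ``shape``.

    A normalized ellipsoidal radius rho is computed around the grid center;
    logistic transitions define a WM core (rho < 0.55), a GM ribbon
    (0.55-0.85) and a CSF rind (0.85-0.95).  Tissue fractions are scaled
    slightly below 1 so subject-level perturbations stay within [0, 1].
    The result is cached per shape.
    """
    key = tuple(shape)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    shape = tuple(int(s) for s in shape)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s for s in shape]
    axes = [
        ((np.arange(s) - c) / a) ** 2
        for s, c, a in zip(shape, center, semi)
    ]
    rho = np.sqrt(
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    ).astype(np.float32)

    w = 0.03  # logistic transition width in rho units

    def inside(r_edge: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((rho - r_edge) / w))

    p_brain = inside(0.95)
    p_inner = inside(0.85)
    p_core = inside(0.55)
    csf = (0.95 * (p_brain - p_inner)).astype(np.float32)
    gm = (0.92 * (p_inner - p_core)).astype(np.float32)
    wm = (0.95 * p_core).astype(np.float32)
    maps = TissueMaps(gm=gm, wm=wm, csf=csf).validate(shape)
    _TEMPLATE_CACHE[key] = maps
    return maps


def default_parcellation(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    n_regions: int = DEFAULT_N_REGIONS,
    seed: int = 0,
    mask_threshold: float = 0.5,
) -> tuple[Parcellation, BrainMask]:
    """Brain mask + synthetic parcellation of the default phantom."""
    template = phantom_tissue_maps(shape)
    mask = build_brain_mask(template, threshold=mask_threshold)
    parc = synthetic_parcellation(mask, n_regions=n_regions, seed=seed)
    return parc, mask


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size: float) -> float:
    return fwhm_mm / (voxel_size * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def _kernel_l2_norm(sigma: float) -> float:
    """L2 norm of the discrete 3-D Gaussian smoothing kernel.

    Smoothing unit white noise with G gives a field of SD ``||G||_2``; the
    norm is measured exactly by smoothing a delta impulse.
    """
    half = max(int(np.ceil(4 * sigma)), 1)
    n = 2 * half + 1
    delta = np.zeros((n, n, n))
    delta[half, half, half] = 1.0
    g = ndimage.gaussian_filter(delta, sigma=sigma)
    return float(np.sqrt((g**2).sum()))


@dataclass(frozen=True)
class AtrophyModel:
    """Precomputed per-contrast GM scale factors for the atrophy regions.

    ``factors`` maps contrast class ("CI" / "T2DM") to the multiplicative GM
    factor applied inside the region set for subjects of that class.
    """

    region_mask: np.ndarray
    factors: dict
    sigma_s: float  # across-subject SD of total GM volume over the region set
    v0_s: float  # template GM volume over the region set


def build_atrophy_model(
    spec: CohortSpec, parcellation: Parcellation
) -> AtrophyModel:
    """Calibrate region scale factors so planted effects equal Cohen's d.

    The across-subject SD of the summed GM volume over the atrophy region
    set S combines the global scale component (scale_sd * V0_S) and the
    smooth-field component alpha * ||G * (t . 1_S)||_2 (adjoint identity).
    The factor for contrast class c is ``1 - d_c * sigma_S / V0_S``.
    """
    template = phantom_tissue_maps(spec.shape)
    if parcellation.labels.shape != template.gm.shape:
        raise VolumeError(
            f"parcellation shape {parcellation.labels.shape} does not match "
            f"cohort grid {template.gm.shape}"
        )
    missing = [
        r
        for r in spec.atrophy_regions
        if r < 1 or r > parcellation.n_regions
    ]
    if missing:
        raise CohortError(f"atrophy regions outside 1..R: {missing}")
    region_mask = np.isin(parcellation.labels, np.asarray(spec.atrophy_regions))
    t_s = template.gm * region_mask
    v0_s = float(t_s.sum())
    if v0_s <= 0:
        raise CohortError("atrophy region set contains no template GM")
    sigma_vox = _fwhm_to_sigma_voxels(spec.smooth_fwhm, spec.voxel_size)
    alpha = spec.noise_sd / _kernel_l2_norm(sigma_vox)
    g_ts = ndimage.gaussian_filter(t_s.astype(np.float64), sigma=sigma_vox)
    var_local = alpha**2 * float((g_ts**2).sum())
    var_global = (spec.scale_sd * v0_s) ** 2
    sigma_s = float(np.sqrt(var_global + var_local))
    factors = {}
    for cls, d in spec.atrophy_effect.items():
        if cls not in ("CI", "T2DM"):
            raise CohortError(f"unknown atrophy contrast class {cls!r}")
        factors[cls] = max(0.0, 1.0 - d * sigma_s / v0_s)
    return AtrophyModel(
        region_mask=region_mask, factors=factors, sigma_s=sigma_s, v0_s=v0_s
    )


def generate_tissue_maps(
    record: SubjectRecord,
    parcellation: Parcellation,
    spec: CohortSpec,
    atrophy: AtrophyModel | None = None,
) -> TissueMaps:
    """Generate one subject's tissue maps with planted group-dependent atrophy.

    The template GM is multiplied by a global scale factor, a smooth local
    field, and — for subjects whose diagnosis/cognition matches a contrast in
    ``spec.atrophy_effect`` — the calibrated regional atrophy factor.  WM and
    CSF are left at template values; GM is clipped so the tissue-sum
    invariant holds.  Deterministic given ``spec.seed`` and the subject id.
    """
    spec.validate()
    template = phantom_tissue_maps(spec.shape)
    if parcellation.labels.shape != template.gm.shape:
        raise VolumeError(
            f"parcellation shape {parcellation.labels.shape} != grid {template.gm.shape}"
        )
    if atrophy is None:
        atrophy = build_atrophy_model(spec, parcellation)
    rng = _subject_rng(spec.seed, record.subject_id)
    sigma_vox = _fwhm_to_sigma_voxels(spec.smooth_fwhm, spec.voxel_size)
    alpha = spec.noise_sd / _kernel_l2_norm(sigma_vox)
    noise = ndimage.gaussian_filter(
        rng.standard_normal(template.gm.shape).astype(np.float32), sigma=sigma_vox
    )
    global_scale = 1.0 + spec.scale_sd * float(rng.standard_normal())
    gm = template.gm * (global_scale * (1.0 + alpha * noise))

    factor = 1.0
    if record.cognition == "CI" and "CI" in atrophy.factors:
        factor *= atrophy.factors["CI"]
    if record.diagnosis == "T2DM" and "T2DM" in atrophy.factors:
        factor *= atrophy.factors["T2DM"]
    if factor != 1.0:
        gm = np.where(atrophy.region_mask, gm * factor, gm)

    # keep probabilities valid: gm in [0, 1 - wm - csf]
    headroom = 1.0 - template.wm - template.csf
    gm = np.clip(gm, 0.0, headroom).astype(np.float32)
    return TissueMaps(
        gm=gm,
        wm=template.wm.copy(),
        csf=template.csf.copy(),
        voxel_size=spec.voxel_size,
    )


def iter_cohort_maps(
    records: Sequence[SubjectRecord],
    parcellation: Parcellation,
    spec: CohortSpec,
) -> Iterator[tuple[SubjectRecord, TissueMaps]]:
    """Stream (record, maps) pairs without holding the whole cohort in memory."""
    atrophy = build_atrophy_model(spec, parcellation)
    for rec in records:
        yield rec, generate_tissue_maps(rec, parcellation, spec, atrophy)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def write_cohort(
    records: Sequence[SubjectRecord],
    maps: Iterable[TissueMaps],
    out_dir: str | Path,
    spec: CohortSpec | None = None,
) -> dict:
    """Write per-subject NIfTI tissue maps, the subject CSV and a manifest.

    Returns the manifest dict (also written to ``manifest.json``): spec,
    seed, file listing.  Round-trips losslessly (float32) through
    :func:`read_cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes_written = []
    for rec, m in zip(records, maps):
        for tissue in ("gm", "wm", "csf"):
            path = out_dir / f"{rec.subject_id}_{tissue}.nii.gz"
            save_volume(getattr(m, tissue), path)
            volumes_written.append(path.name)
    table_path = out_dir / "cohort.csv"
    records_to_frame(records).to_csv(table_path, index=False)
    manifest = {
        "n_subjects": len(records),
        "subject_ids": [r.subject_id for r in records],
        "table": table_path.name,
        "volumes": volumes_written,
        "seed": None if spec is None else spec.seed,
        "spec": None if spec is None else spec.to_dict(),
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[list[SubjectRecord], list[TissueMaps], dict]:
    """Read back a cohort written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    records = frame_to_records(pd.read_csv(cohort_dir / manifest["table"]))
    maps = []
    for rec in records:
        maps.append(
            TissueMaps(
                gm=np.asarray(
                    load_volume(cohort_dir / f"{rec.subject_id}_gm.nii.gz"),
                    dtype=np.float32,
                ),
                wm=np.asarray(
                    load_volume(cohort_dir / f"{rec.subject_id}_wm.nii.gz"),
                    dtype=np.float32,
                ),
                csf=np.asarray(
                    load_volume(cohort_dir / f"{rec.subject_id}_csf.nii.gz"),
                    dtype=np.float32,
                ),
            ).validate()
        )
    return records, maps, manifest
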
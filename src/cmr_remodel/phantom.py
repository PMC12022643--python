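"""Synthetic short-axis phantom generator.

Every downstream stage is exercised on phantoms with fully known ground
truth: concentric annular myocardium around a circular blood pool on each
short-axis slice, tissue-specific native and post-contrast T1 values
consistent with a target extracellular volume fraction, focal
hyperenhanced lesions of known geometry on the LGE image, and additive
Gaussian noise (Rician optional).  Slices are labeled basal/mid/apical
base-to-apex; the apical annulus is smaller and no apex cap is generated
(the 16-segment model excludes the apex).

A paired-cohort generator draws per-subject baselines and within-person
pre-to-post changes and solves the post-operative tissue/geometry
parameters so the generating changes realize configured effect-size
distributions; the realized draws are recorded for oracle comparison.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import LEVELS
from .tissue import ecv_from_t1, MYOCARDIAL_DENSITY_G_PER_ML
from .volumetrics import SubjectMeta, bsa as bsa_formula

__all__ = [
    "LesionSpec",
    "PhantomParams",
    "GroundTruth",
    "CohortEffects",
    "ImageStack",
    "MaskSet",
    "SubjectBundle",
    "PhantomError",
    "generate_subject",
    "generate_paired_cohort",
    "write_subject",
]

# mask labels
LBL_BACKGROUND, LBL_BLOOD, LBL_MYO, LBL_REF_ROI = 0, 1, 2, 3

# anterior RV insertion direction (math-convention degrees); the inferior
# insertion sits 120 deg across the septum, so the free-wall sweep is
# clockwise and septal sweep angles fall in [240, 360).
_THETA_ANTERIOR = 135.0
_THETA_INFERIOR = 255.0
_REF_ROI_SWEEP = (95.0, 145.0)  # remote free wall, mid-wall radial band
_SEPTAL_SWEEP = (245.0, 355.0)  # window available for lesion placement


class PhantomError(ValueError):
    """Invalid phantom parameters."""


@dataclass
class LesionSpec:
    """A focal hyperenhanced lesion: angular sector of the myocardium,
    extending a transmural fraction of the wall outward from the
    endocardial edge, with an LGE-signal multiplier on the myocardial
    base intensity."""

    slice_index: int
    sweep_start_deg: float
    sweep_extent_deg: float
    transmural_fraction: float
    multiplier: float = 3.0


def _default_noise() -> dict:
    return {"t1": 15.0, "lge": 3.0, "cine": 5.0}


@dataclass
class PhantomParams:
    grid_size: int = 128
    n_slices: int = 9
    voxel_spacing: float = 1.0  # mm
    slice_thickness: float = 8.0  # mm
    endo_radius: tuple | None = None  # mm per slice, end-diastole
    epi_radius: tuple | None = None
    endo_radius_es: tuple | None = None
    epi_radius_es: tuple | None = None
    t1_myo_native: float = 1313.0  # ms
    t1_myo_post: float = 640.0
    t1_blood_native: float = 1900.0
    t1_blood_post: float = 450.0
    hematocrit: float = 0.40
    lesion_spec: list = field(default_factory=list)
    noise_sd: dict = field(default_factory=_default_noise)
    rician: bool = False
    heart_rate: float = 66.0  # bpm
    height: float = 166.0  # cm
    weight: float = 70.0  # kg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise PhantomError("need at least 3 slices (basal/mid/apical)")
        if not isinstance(self.noise_sd, dict):
            self.noise_sd = {k: float(self.noise_sd)
                             for k in ("t1", "lge", "cine")}
        if self.endo_radius is None or self.epi_radius is None:
            endo, epi = solve_radii(145.0, 160.0, self.n_slices,
                                    self.slice_thickness)
            self.endo_radius = self.endo_radius or endo
            self.epi_radius = self.epi_radius or epi
        self.endo_radius = tuple(float(r) for r in self.endo_radius)
        self.epi_radius = tuple(float(r) for r in self.epi_radius)
        if len(self.endo_radius) != self.n_slices or \
                len(self.epi_radius) != self.n_slices:
            raise PhantomError("one endo/epi radius per slice is required")
        if self.endo_radius_es is None:
            # default end-systole: cavity scaled to EF 65.9%, wall area
            # conserved per slice (incompressible myocardium)
            f = np.sqrt(1.0 - 0.659)
            self.endo_radius_es = tuple(r * f for r in self.endo_radius)
        if self.epi_radius_es is None:
            self.epi_radius_es = tuple(
                float(np.sqrt(res ** 2 + rp ** 2 - re ** 2))
                for re, rp, res in zip(self.endo_radius, self.epi_radius,
                                       self.endo_radius_es))
        self.endo_radius_es = tuple(float(r) for r in self.endo_radius_es)
        self.epi_radius_es = tuple(float(r) for r in self.epi_radius_es)
        self._validate()

    def _validate(self) -> None:
        for re, rp in zip(self.endo_radius, self.epi_radius):
            if not 0 < re < rp:
                raise PhantomError("epi radius must exceed endo radius > 0")
        for re, rp in zip(self.endo_radius_es, self.epi_radius_es):
            if not 0 < re < rp:
                raise PhantomError("end-systolic epi radius must exceed endo")
        half = (self.grid_size - 1) / 2 * self.voxel_spacing
        if max(max(self.epi_radius), max(self.epi_radius_es)) >= half - 2:
            raise PhantomError("epicardium does not fit on the grid")
        if not 0 < self.hematocrit < 1:
            raise PhantomError("hematocrit must lie in (0, 1)")
        for t1 in (self.t1_myo_native, self.t1_myo_post,
                   self.t1_blood_native, self.t1_blood_post):
            if t1 <= 0:
                raise PhantomError("T1 values must be positive")
        if self.t1_myo_post >= self.t1_myo_native or \
                self.t1_blood_post >= self.t1_blood_native:
            raise PhantomError("post-contrast T1 must be below native T1")
        for les in self.lesion_spec:
            if not 0 <= les.slice_index < self.n_slices:
                raise PhantomError("lesion slice index out of range")
            if not 0 < les.transmural_fraction <= 1:
                raise PhantomError("lesion transmural fraction must be in (0, 1]")
            if not 0 < les.sweep_extent_deg <= 360:
                raise PhantomError("lesion angular extent must be in (0, 360]")

    @property
    def slice_levels(self) -> list[str]:
        """Level label per slice, base to apex, split in equal thirds."""
        per = self.n_slices / 3.0
        return [LEVELS[min(2, int(i / per))] for i in range(self.n_slices)]

    def true_ecv(self) -> float:
        return ecv_from_t1(self.t1_myo_native, self.t1_myo_post,
                           self.t1_blood_native, self.t1_blood_post,
                           self.hematocrit)


#: per-level relative cavity/wall cross-section weights (base > mid > apex)
_LEVEL_WEIGHT = {"basal": 1.15, "mid": 1.0, "apical": 0.70}


def solve_radii(edv_ml: float, myo_ml: float, n_slices: int,
                thickness: float) -> tuple[tuple, tuple]:
    """Per-slice endo/epi radii (mm) realizing target cavity and
    myocardial volumes with a tapered base-to-apex profile."""
    per = n_slices / 3.0
    levels = [LEVELS[min(2, int(i / per))] for i in range(n_slices)]
    w = np.array([_LEVEL_WEIGHT[lv] for lv in levels])
    w = w / w.sum()
    endo = tuple(float(np.sqrt(wi * edv_ml * 1000.0 / (np.pi * thickness)))
                 for wi in w)
    epi = tuple(float(np.sqrt(re ** 2 + wi * myo_ml * 1000.0 /
                              (np.pi * thickness)))
                for re, wi in zip(endo, w))
    return endo, epi


@dataclass
class GroundTruth:
    """Analytic truth computed from the generating parameters."""

    true_ecv: float
    true_myo_volume_ed: float  # mL
    true_lge_volume: float  # mL
    true_mass: float  # g
    true_segment_t1: dict
    true_edv: float  # mL
    true_esv: float  # mL
    # derived conveniences
    true_ef: float
    true_bsa: float
    true_lvmi: float
    true_iecv: float
    true_icv: float
    true_lge_mass: float


@dataclass
class ImageStack:
    t1_native: np.ndarray
    t1_post: np.ndarray
    lge: np.ndarray
    cine_ed: np.ndarray
    cine_es: np.ndarray
    voxel_spacing: float
    slice_thickness: float


@dataclass
class MaskSet:
    labels_ed: np.ndarray  # int labels per voxel (0/1/2/3)
    labels_es: np.ndarray
    slice_levels: list
    rv_insertion_anterior: list  # (row, col) per slice
    rv_insertion_inferior: list
    voxel_spacing: float
    slice_thickness: float


@dataclass
class SubjectBundle:
    meta: SubjectMeta
    truth: GroundTruth
    params: PhantomParams
    images: ImageStack | None = None
    masks: MaskSet | None = None


# LGE image base intensities (arbitrary magnitude units)
_LGE_BG, _LGE_MYO, _LGE_BLOOD = 5.0, 60.0, 150.0
_CINE_BG, _CINE_MYO, _CINE_BLOOD = 10.0, 80.0, 250.0


def _slice_polar(grid: int, spacing: float):
    c = (grid - 1) / 2.0
    ii, jj = np.indices((grid, grid))
    x = (jj - c) * spacing
    y = (c - ii) * spacing
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    sweep = (_THETA_ANTERIOR - theta) % 360.0
    return r, sweep


def _in_sweep(sweep: np.ndarray, start: float, extent: float) -> np.ndarray:
    rel = (sweep - start) % 360.0
    return rel < extent


def _insertion_point(grid: int, spacing: float, r_mm: float,
                     theta_deg: float) -> tuple[float, float]:
    c = (grid - 1) / 2.0
    th = np.radians(theta_deg)
    return (float(c - r_mm / spacing * np.sin(th)),
            float(c + r_mm / spacing * np.cos(th)))


def _noise(rng: np.random.Generator, image: np.ndarray, sd: float,
           rician: bool) -> np.ndarray:
    if sd <= 0:
        return image
    if rician:
        return np.hypot(image + rng.normal(0, sd, image.shape),
                        rng.normal(0, sd, image.shape))
    return image + rng.normal(0, sd, image.shape)


def ground_truth_from_params(params: PhantomParams) -> GroundTruth:
    """Analytic ground truth, independent of any rasterization."""
    t = params.slice_thickness
    area_ed = [np.pi * (rp ** 2 - re ** 2)
               for re, rp in zip(params.endo_radius, params.epi_radius)]
    myo_ml = sum(area_ed) * t / 1000.0
    edv = sum(np.pi * re ** 2 for re in params.endo_radius) * t / 1000.0
    esv = sum(np.pi * re ** 2 for re in params.endo_radius_es) * t / 1000.0
    lge_ml = 0.0
    for les in params.lesion_spec:
        re = params.endo_radius[les.slice_index]
        rp = params.epi_radius[les.slice_index]
        r_out = re + les.transmural_fraction * (rp - re)
        lge_ml += (les.sweep_extent_deg / 360.0) * np.pi * \
            (r_out ** 2 - re ** 2) * t / 1000.0
    if lge_ml > myo_ml:
        raise PhantomError("lesion volume exceeds myocardial volume")
    ecv = params.true_ecv()
    body_sa = bsa_formula(params.height, params.weight)
    mass = myo_ml * MYOCARDIAL_DENSITY_G_PER_ML
    nonenh_i = (myo_ml - lge_ml) / body_sa
    return GroundTruth(
        true_ecv=ecv,
        true_myo_volume_ed=myo_ml,
        true_lge_volume=lge_ml,
        true_mass=mass,
        true_segment_t1={s: params.t1_myo_native for s in range(1, 17)},
        true_edv=edv,
        true_esv=esv,
        true_ef=100.0 * (edv - esv) / edv,
        true_bsa=body_sa,
        true_lvmi=mass / body_sa,
        true_iecv=nonenh_i * ecv,
        true_icv=nonenh_i * (1.0 - ecv),
        true_lge_mass=lge_ml * MYOCARDIAL_DENSITY_G_PER_ML,
    )


def generate_subject(params: PhantomParams,
                     subject_id: str = "phantom",
                     timepoint: str = "pre") -> SubjectBundle:
    """Render one subject-timepoint: aligned image stack, label masks,
    metadata and analytic ground truth.  Identical parameters and seed
    produce bit-identical arrays."""
    g = params.grid_size
    n = params.n_slices
    r, sweep = _slice_polar(g, params.voxel_spacing)

    labels_ed = np.zeros((g, g, n), dtype=np.int16)
    labels_es = np.zeros_like(labels_ed)
    lesion = np.zeros((g, g, n), dtype=bool)
    t1n = np.zeros((g, g, n))
    t1p = np.zeros((g, g, n))
    lge = np.full((g, g, n), _LGE_BG)
    cine_ed = np.full((g, g, n), _CINE_BG)
    cine_es = np.full((g, g, n), _CINE_BG)

    lesions_by_slice: dict[int, list[LesionSpec]] = {}
    for les in params.lesion_spec:
        lesions_by_slice.setdefault(les.slice_index, []).append(les)

    ant_pts, inf_pts = [], []
    for k in range(n):
        re, rp = params.endo_radius[k], params.epi_radius[k]
        res, rps = params.endo_radius_es[k], params.epi_radius_es[k]
        cavity = r < re
        myo = (r >= re) & (r < rp)
        cavity_es = r < res
        myo_es = (r >= res) & (r < rps)

        labels_ed[..., k][cavity] = LBL_BLOOD
        labels_ed[..., k][myo] = LBL_MYO
        labels_es[..., k][cavity_es] = LBL_BLOOD
        labels_es[..., k][myo_es] = LBL_MYO

        roi = myo & _in_sweep(sweep, _REF_ROI_SWEEP[0],
                              _REF_ROI_SWEEP[1] - _REF_ROI_SWEEP[0]) & \
            (r >= re + 0.25 * (rp - re)) & (r < re + 0.75 * (rp - re))
        labels_ed[..., k][roi] = LBL_REF_ROI

        t1n[..., k][cavity] = params.t1_blood_native
        t1n[..., k][myo] = params.t1_myo_native
        t1p[..., k][cavity] = params.t1_blood_post
        t1p[..., k][myo] = params.t1_myo_post
        lge[..., k][cavity] = _LGE_BLOOD
        lge[..., k][myo] = _LGE_MYO
        cine_ed[..., k][cavity] = _CINE_BLOOD
        cine_ed[..., k][myo] = _CINE_MYO
        cine_es[..., k][cavity_es] = _CINE_BLOOD
        cine_es[..., k][myo_es] = _CINE_MYO

        for les in lesions_by_slice.get(k, []):
            r_out = re + les.transmural_fraction * (rp - re)
            sel = myo & _in_sweep(sweep, les.sweep_start_deg,
                                  les.sweep_extent_deg) & (r < r_out)
            if not sel.any():
                raise PhantomError("lesion rasterizes to zero voxels")
            if (sel & roi).any():
                raise PhantomError("lesion overlaps the LGE reference ROI")
            lesion[..., k][sel] = True
            lge[..., k][sel] = _LGE_MYO * les.multiplier

        ant_pts.append(_insertion_point(g, params.voxel_spacing, rp,
                                        _THETA_ANTERIOR))
        inf_pts.append(_insertion_point(g, params.voxel_spacing, rp,
                                        _THETA_INFERIOR))

    rng = np.random.default_rng(params.seed)
    t1n = _noise(rng, t1n, params.noise_sd.get("t1", 0.0), params.rician)
    t1p = _noise(rng, t1p, params.noise_sd.get("t1", 0.0), params.rician)
    lge = _noise(rng, lge, params.noise_sd.get("lge", 0.0), params.rician)
    cine_ed = _noise(rng, cine_ed, params.noise_sd.get("cine", 0.0),
                     params.rician)
    cine_es = _noise(rng, cine_es, params.noise_sd.get("cine", 0.0),
                     params.rician)

    images = ImageStack(t1n, t1p, lge, cine_ed, cine_es,
                        params.voxel_spacing, params.slice_thickness)
    masks = MaskSet(labels_ed, labels_es, params.slice_levels,
                    ant_pts, inf_pts,
                    params.voxel_spacing, params.slice_thickness)
    meta = SubjectMeta(subject_id, timepoint, params.hematocrit,
                       params.height, params.weight, params.heart_rate)
    truth = ground_truth_from_params(params)
    return SubjectBundle(meta=meta, truth=truth, params=params,
                         images=images, masks=masks)


# ---------------------------------------------------------------------------
# Paired cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortEffects:
    """Within-person change distributions (mean, sd) used to generate a
    paired pre/post cohort.

    The changes in iECV, iCV and ejection fraction are drawn directly; the
    LGE-volume change is the compartment-bookkeeping slack drawn from a
    shifted standardized-exponential whose location/scale are solved so the
    implied LVMI change has exactly the configured mean and sd.  The ECV
    and LGE-mass change fields are informational: both quantities are
    algebraically determined by the drawn compartments and are recorded,
    not drawn.
    """

    n_subjects: int = 43
    delta_lvmi: tuple = (-19.8, 8.4)  # g/m^2
    delta_ecv_points: tuple = (1.2, 2.3)  # ECV percentage points (derived)
    delta_iecv: tuple = (-4.4, 2.6)  # mL/m^2
    delta_icv: tuple = (-16.6, 6.6)  # mL/m^2
    delta_ef_points: tuple = (-2.6, 3.1)
    delta_lge_mass_g: tuple = (2.9, 3.3)  # g (derived)
    baseline_change_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise PhantomError("need at least 2 subjects")
        for name in ("delta_lvmi", "delta_ecv_points", "delta_iecv",
                     "delta_icv", "delta_ef_points", "delta_lge_mass_g"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise PhantomError(f"{name} sd must be >= 0")
        if not -1 < self.baseline_change_correlation < 1:
            raise PhantomError("correlation must lie in (-1, 1)")


@dataclass
class CohortBaselines:
    """Baseline (pre-operative) population distributions, (mean, sd)."""

    lvmi: tuple = (101.0, 20.0)  # g/m^2
    ecv: tuple = (0.282, 0.033)  # fraction
    edvi: tuple = (86.6, 12.0)  # mL/m^2
    ef: tuple = (65.9, 3.5)  # %
    lge_mass: tuple = (4.5, 2.0)  # g
    bsa: tuple = (1.67, 0.17)  # m^2
    height: tuple = (166.0, 8.0)  # cm
    heart_rate: tuple = (66.0, 10.0)  # bpm
    hematocrit: tuple = (0.393, 0.035)  # fraction
    t1_myo_native: tuple = (1313.0, 34.0)  # ms
    t1_blood_native: tuple = (1900.0, 60.0)
    t1_blood_post: tuple = (450.0, 30.0)


def solve_post_contrast_myo_t1(ecv: float, hct: float, t1_myo_native: float,
                               t1_blood_native: float,
                               t1_blood_post: float) -> float:
    """Myocardial post-contrast T1 realizing a target ECV."""
    dr1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_native
    r1_post = 1.0 / t1_myo_native + ecv / (1.0 - hct) * dr1_blood
    return 1.0 / r1_post


def _place_lesions(lge_volume_ml: float, endo: tuple, epi: tuple,
                   levels: list, thickness: float,
                   transmural: float = 0.6) -> list[LesionSpec]:
    """Distribute a target LGE volume over septal sectors of the basal and
    mid slices (where focal fibrosis predominates in HOCM)."""
    if lge_volume_ml <= 0:
        return []
    window = _SEPTAL_SWEEP[1] - _SEPTAL_SWEEP[0]
    lesions = []
    remaining = lge_volume_ml * 1000.0  # mm^3
    for k, lv in enumerate(levels):
        if lv == "apical":
            continue
        re, rp = endo[k], epi[k]
        r_out = re + transmural * (rp - re)
        per_deg = np.pi * (r_out ** 2 - re ** 2) * thickness / 360.0
        ext = min(window, remaining / per_deg)
        if ext < 2.0:
            continue
        lesions.append(LesionSpec(k, _SEPTAL_SWEEP[0], float(ext),
                                  transmural))
        remaining -= ext * per_deg
        if remaining <= 1e-9:
            break
    if remaining > 1e-6 * lge_volume_ml * 1000.0 + 1e-6:
        if transmural < 0.9:
            return _place_lesions(lge_volume_ml, endo, epi, levels,
                                  thickness, transmural=0.9)
        raise PhantomError("LGE volume does not fit in the septal wall")
    return lesions


def _draw(rng, mean_sd, lo=None, hi=None, z=None):
    mean, sd = mean_sd
    zz = rng.standard_normal() if z is None else z
    v = mean + sd * zz
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


def generate_paired_cohort(effects: CohortEffects,
                           base_params: PhantomParams | None = None,
                           baselines: CohortBaselines | None = None,
                           render: bool = True,
                           max_retries: int = 20):
    """Generate paired pre/post subjects with known generating changes.

    Returns ``(pairs, record)`` where ``pairs`` is a list of
    ``(pre_bundle, post_bundle)`` and ``record`` a DataFrame of the
    realized generating draws per subject (the oracle for recovered
    changes).  ``render=False`` skips rasterization: bundles then carry
    parameters, metadata and analytic truth only.
    """
    base_params = base_params or PhantomParams()
    baselines = baselines or CohortBaselines()
    rng = np.random.default_rng(effects.seed)

    mu_l_lvmi, sd_lvmi = effects.delta_lvmi
    mu_iecv, sd_iecv = effects.delta_iecv
    mu_icv, sd_icv = effects.delta_icv
    rho = effects.baseline_change_correlation
    dens = MYOCARDIAL_DENSITY_G_PER_ML

    # LGE-volume-index slack: solved so the derived LVMI change has the
    # configured mean and sd (LVMI = density * (iECV + iCV + lgeV/BSA))
    mu_slack = mu_l_lvmi / dens - mu_iecv - mu_icv
    var_slack = (sd_lvmi / dens) ** 2 - sd_iecv ** 2 - sd_icv ** 2
    if var_slack < -1e-12:
        raise PhantomError(
            "inconsistent change sds: sd(LVMI)/density must be at least "
            "sqrt(sd(iECV)^2 + sd(iCV)^2)")
    sd_slack = float(np.sqrt(max(var_slack, 0.0)))

    pairs = []
    rows = []
    for s in range(effects.n_subjects):
        for attempt in range(max_retries):
            z_size = rng.standard_normal()  # shared hypertrophy-scale z
            lvmi_pre = _draw(rng, baselines.lvmi, lo=55.0, z=z_size)
            ecv_pre = _draw(rng, baselines.ecv, lo=0.18, hi=0.45)
            edvi_pre = _draw(rng, baselines.edvi, lo=50.0)
            ef_pre = _draw(rng, baselines.ef, lo=45.0, hi=80.0)
            lge_mass_pre = _draw(rng, baselines.lge_mass, lo=0.5)
            body_sa = _draw(rng, baselines.bsa, lo=1.2, hi=2.4)
            height = _draw(rng, baselines.height, lo=140.0)
            heart_rate = _draw(rng, baselines.heart_rate, lo=40.0)
            hct = _draw(rng, baselines.hematocrit, lo=0.25, hi=0.55)
            t1_myo_n = _draw(rng, baselines.t1_myo_native, lo=900.0)
            t1_bl_n = _draw(rng, baselines.t1_blood_native, lo=1500.0)
            t1_bl_p = _draw(rng, baselines.t1_blood_post, lo=250.0)
            weight = 3600.0 * body_sa ** 2 / height  # Mosteller inverse

            myo_ml_pre = lvmi_pre * body_sa / dens
            lge_ml_pre = lge_mass_pre / dens
            lge_vi_pre = lge_ml_pre / body_sa
            nonenh_i_pre = myo_ml_pre / body_sa - lge_vi_pre
            iecv_pre = nonenh_i_pre * ecv_pre
            icv_pre = nonenh_i_pre * (1.0 - ecv_pre)

            # within-person changes
            def corr_z():
                return rho * z_size + np.sqrt(1 - rho ** 2) * \
                    rng.standard_normal()

            d_iecv = mu_iecv + sd_iecv * corr_z()
            d_icv = mu_icv + sd_icv * corr_z()
            d_ef = _draw(rng, effects.delta_ef_points)
            # shifted standardized exponential: mean 0, var 1, support >= -1
            d_slack = mu_slack + sd_slack * (rng.exponential(1.0) - 1.0)

            iecv_post = iecv_pre + d_iecv
            icv_post = icv_pre + d_icv
            lge_vi_post = lge_vi_pre + d_slack
            ef_post = ef_pre + d_ef
            nonenh_i_post = iecv_post + icv_post
            # post LGE volume needs a small positive floor so the lesion
            # still rasterizes to a meaningful sector
            if (iecv_post <= 1.0 or icv_post <= 10.0 or lge_vi_post < 0.05
                    or not 20.0 <= ef_post <= 85.0):
                continue
            ecv_post = iecv_post / nonenh_i_post
            if not 0.10 < ecv_post < 0.60:
                continue
            myo_ml_post = (nonenh_i_post + lge_vi_post) * body_sa
            lvmi_post = myo_ml_post * dens / body_sa
            d_lvmi = lvmi_post - lvmi_pre

            sid = f"S{s:03d}"
            bundles = {}
            try:
                for tp, (myo_ml, edvi, ef, ecv, lge_ml) in {
                    "pre": (myo_ml_pre, edvi_pre, ef_pre, ecv_pre,
                            lge_ml_pre),
                    "post": (myo_ml_post, edvi_pre, ef_post, ecv_post,
                             lge_vi_post * body_sa),
                }.items():
                    edv_ml = edvi * body_sa
                    endo, epi = solve_radii(edv_ml, myo_ml,
                                            base_params.n_slices,
                                            base_params.slice_thickness)
                    f_es = np.sqrt(1.0 - ef / 100.0)
                    endo_es = tuple(r * f_es for r in endo)
                    levels = [LEVELS[min(2, int(i / (base_params.n_slices
                                                     / 3.0)))]
                              for i in range(base_params.n_slices)]
                    lesions = _place_lesions(lge_ml, endo, epi, levels,
                                             base_params.slice_thickness)
                    params = PhantomParams(
                        grid_size=base_params.grid_size,
                        n_slices=base_params.n_slices,
                        voxel_spacing=base_params.voxel_spacing,
                        slice_thickness=base_params.slice_thickness,
                        endo_radius=endo, epi_radius=epi,
                        endo_radius_es=endo_es,
                        t1_myo_native=t1_myo_n,
                        t1_myo_post=solve_post_contrast_myo_t1(
                            ecv, hct, t1_myo_n, t1_bl_n, t1_bl_p),
                        t1_blood_native=t1_bl_n, t1_blood_post=t1_bl_p,
                        hematocrit=hct, lesion_spec=lesions,
                        noise_sd=dict(base_params.noise_sd),
                        rician=base_params.rician,
                        heart_rate=heart_rate, height=height, weight=weight,
                        seed=int(rng.integers(2 ** 31)),
                    )
                    if render:
                        bundles[tp] = generate_subject(params,
                                                       subject_id=sid,
                                                       timepoint=tp)
                    else:
                        bundles[tp] = SubjectBundle(
                            meta=SubjectMeta(sid, tp, hct, height, weight,
                                             heart_rate),
                            truth=ground_truth_from_params(params),
                            params=params)
            except PhantomError:
                continue  # unphysical realization; redraw the subject
            break
        else:
            raise PhantomError(
                f"subject {s}: no physical post-operative solution after "
                f"{max_retries} attempts")

        pairs.append((bundles["pre"], bundles["post"]))
        rows.append({
            "subject_id": f"S{s:03d}",
            "bsa": body_sa,
            "lvmi_pre": lvmi_pre, "lvmi_post": lvmi_post,
            "ecv_pre": ecv_pre, "ecv_post": ecv_post,
            "iecv_pre": iecv_pre, "icv_pre": icv_pre,
            "delta_lvmi_gen": d_lvmi,
            "delta_iecv_gen": d_iecv,
            "delta_icv_gen": d_icv,
            "delta_ef_gen": d_ef,
            "delta_lge_vi_gen": d_slack,
            "delta_lge_mass_gen": d_slack * body_sa * dens,
            "delta_ecv_points_gen": 100.0 * (ecv_post - ecv_pre),
        })
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _save_nifti(data: np.ndarray, spacing: float, thickness: float,
                path: Path) -> None:
    """Write a deterministic .nii.gz (gzip mtime fixed at 0)."""
    affine = np.diag([spacing, spacing, thickness, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    raw = img.to_bytes()
    path.write_bytes(gzip.compress(raw, mtime=0))


def write_subject(bundle: SubjectBundle, out_dir: str | Path) -> Path:
    """Persist one subject-timepoint directory: NIfTI images and label
    maps, JSON sidecar (insertion points, slice levels), metadata and
    ground truth."""
    if bundle.images is None or bundle.masks is None:
        raise PhantomError("bundle was generated without rendering")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    im, mk = bundle.images, bundle.masks
    sp, th = im.voxel_spacing, im.slice_thickness
    _save_nifti(im.t1_native, sp, th, out / "t1_native.nii.gz")
    _save_nifti(im.t1_post, sp, th, out / "t1_post.nii.gz")
    _save_nifti(im.lge, sp, th, out / "lge.nii.gz")
    _save_nifti(im.cine_ed, sp, th, out / "cine_ed.nii.gz")
    _save_nifti(im.cine_es, sp, th, out / "cine_es.nii.gz")
    _save_nifti(mk.labels_ed, sp, th, out / "mask_ed.nii.gz")
    _save_nifti(mk.labels_es, sp, th, out / "mask_es.nii.gz")
    sidecar = {
        "slice_levels": list(mk.slice_levels),
        "rv_insertion_anterior": [list(p) for p in mk.rv_insertion_anterior],
        "rv_insertion_inferior": [list(p) for p in mk.rv_insertion_inferior],
        "voxel_spacing_mm": sp,
        "slice_thickness_mm": th,
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=1,
                                                 sort_keys=True))
    (out / "meta.json").write_text(json.dumps(asdict(bundle.meta), indent=1,
                                              sort_keys=True))
    (out / "truth.json").write_text(json.dumps(asdict(bundle.truth), indent=1,
                                               sort_keys=True))
    return out
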
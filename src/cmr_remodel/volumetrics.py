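"""LV volumes, function, mass and body-surface-area indexing.

Volumes come from slice summation (Simpson's rule with zero inter-slice
gap): each slice contributes mask area times slice thickness.  Mass is
myocardial volume times a density of 1.05 g/mL.  BSA uses the Mosteller
formula by default (Du Bois selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SliceContours, GeometryError, wall_thickness_by_ray

__all__ = [
    "SubjectMeta",
    "VolumetricResult",
    "volume_from_masks",
    "lv_function",
    "mass_from_volume",
    "bsa",
    "max_wall_thickness",
]

DENSITY_G_PER_ML = 1.05


@dataclass
class SubjectMeta:
    subject_id: str
    timepoint: str  # "pre" | "post"
    hematocrit: float  # fraction
    height_cm: float
    weight_kg: float
    heart_rate_bpm: float

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError("timepoint must be 'pre' or 'post'")
        if min(self.height_cm, self.weight_kg, self.heart_rate_bpm) <= 0:
            raise ValueError("height, weight and heart rate must be positive")
        if self.hematocrit > 1.0:
            self.hematocrit = self.hematocrit / 100.0


@dataclass
class VolumetricResult:
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_percent: float
    co_l_min: float
    myo_volume_ed_ml: float
    mass_g: float
    mwt_mm: float
    bsa_m2: float
    edvi: float
    esvi: float
    svi: float
    lvmi: float


def volume_from_masks(masks: list[np.ndarray], voxel_spacing: float,
                      slice_thickness: float) -> float:
    """Slice-summation volume in mL of a stack of binary masks."""
    if len(masks) == 0:
        raise GeometryError("no slices provided")
    voxels = 0
    for m in masks:
        if m is None:
            raise GeometryError("missing slice mask")
        voxels += int(np.count_nonzero(m))
    return voxels * voxel_spacing ** 2 * slice_thickness / 1000.0


def lv_function(edv_ml: float, esv_ml: float,
                heart_rate_bpm: float) -> tuple[float, float, float]:
    """Stroke volume (mL), ejection fraction (%), cardiac output (L/min)."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    if esv_ml > edv_ml:
        raise ValueError("ESV exceeds EDV")
    sv = edv_ml - esv_ml
    ef = 100.0 * sv / edv_ml
    co = sv * heart_rate_bpm / 1000.0
    return sv, ef, co


def mass_from_volume(myo_volume_ml: float,
                     density: float = DENSITY_G_PER_ML) -> float:
    if myo_volume_ml < 0:
        raise ValueError("volume must be non-negative")
    return myo_volume_ml * density


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 (Mosteller default, Du Bois optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm ** 0.725 * weight_kg ** 0.425)
    raise ValueError(f"unknown BSA formula {formula!r}")


def max_wall_thickness(contours: list[SliceContours]) -> float:
    """Maximal wall thickness (mm) over all slices and 1-degree rays,
    measured on the end-diastolic contours."""
    if not contours:
        raise GeometryError("no slices provided")
    best = -np.inf
    for c in contours:
        thick = wall_thickness_by_ray(c)
        m = np.nanmax(thick)
        if m > best:
            best = m
    if not np.isfinite(best):
        raise GeometryError("degenerate band: no wall thickness measurable")
    return float(best)
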
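"""Focal and diffuse fibrosis quantification.

Focal replacement fibrosis is measured on the late-gadolinium-enhancement
(LGE) image with the 6-SD method: a myocardial voxel is enhanced when its
intensity exceeds the mean of a remote-myocardium reference ROI by more
than six sample standard deviations.  Diffuse fibrosis surrogates come from
T1 mapping: segmental native and post-contrast T1 feed the extracellular
volume fraction

    ECV = (1 - Hct) * (dR1_myo / dR1_blood),   dR1 = 1/T1_post - 1/T1_native,

and the per-study global T1/ECV are area-weighted means over segments,
excluding any segment containing LGE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SegmentModel

__all__ = [
    "ReferenceROI",
    "LgeResult",
    "EcvResult",
    "TissueError",
    "lge_threshold",
    "lge_quantify",
    "ecv_from_t1",
    "global_weighted_mean",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class TissueError(ValueError):
    """Invalid tissue-analysis input."""


@dataclass
class ReferenceROI:
    """Remote (non-enhanced) myocardium ROI with its LGE-signal statistics.

    ``sd`` is the sample standard deviation (n-1 denominator).
    """

    voxels: np.ndarray  # boolean raster
    mean: float
    sd: float
    n: int

    @classmethod
    def from_image(cls, lge_image: np.ndarray, roi_mask: np.ndarray,
                   band: np.ndarray | None = None) -> "ReferenceROI":
        roi_mask = np.asarray(roi_mask, dtype=bool)
        n = int(np.count_nonzero(roi_mask))
        if n < 2:
            raise TissueError("reference ROI needs at least 2 voxels for an SD")
        if band is not None and np.any(roi_mask & ~np.asarray(band, dtype=bool)):
            raise TissueError("reference ROI extends outside the myocardial band")
        vals = np.asarray(lge_image, dtype=float)[roi_mask]
        return cls(voxels=roi_mask, mean=float(vals.mean()),
                   sd=float(vals.std(ddof=1)), n=n)


@dataclass
class LgeResult:
    lge_mask: np.ndarray
    lge_volume_ml: float
    lge_mass_g: float
    lge_percent: float
    segments_with_lge: set[int] = field(default_factory=set)


@dataclass
class EcvResult:
    segment_native_t1: dict[int, float]
    segment_post_t1: dict[int, float]
    segment_ecv: dict[int, float]
    blood_native_t1: float
    blood_post_t1: float
    hematocrit: float
    global_native_t1: float
    global_ecv: float
    included_segments: set[int]


def lge_threshold(lge_image: np.ndarray, band: np.ndarray,
                  roi: ReferenceROI, n_sd: float = 6.0) -> np.ndarray:
    """Enhanced-voxel mask: band voxels strictly above mean + n_sd * sd."""
    lge_image = np.asarray(lge_image, dtype=float)
    band = np.asarray(band, dtype=bool)
    if lge_image.shape != band.shape:
        raise TissueError("LGE image and band are misaligned")
    thr = roi.mean + n_sd * roi.sd
    return band & (lge_image > thr)


def lge_quantify(lge_mask: np.ndarray, band: np.ndarray,
                 voxel_spacing: float, slice_thickness: float,
                 density: float = MYOCARDIAL_DENSITY_G_PER_ML,
                 segment_models: list[SegmentModel] | None = None,
                 lge_masks_by_slice: list[np.ndarray] | None = None,
                 min_segment_fraction: float = 0.0) -> LgeResult:
    """Volume/mass/percent of the enhanced region, plus LGE-bearing segments.

    Segment presence is judged per slice against ``segment_models``: a
    segment carries LGE when the enhanced fraction of its area exceeds
    ``min_segment_fraction`` (default: any enhanced voxel counts).
    """
    lge_mask = np.asarray(lge_mask, dtype=bool)
    band = np.asarray(band, dtype=bool)
    if not band.any():
        raise TissueError("empty myocardial band")
    if np.any(lge_mask & ~band):
        raise TissueError("enhanced mask extends outside the band")
    voxel_ml = voxel_spacing ** 2 * slice_thickness / 1000.0
    vol = float(np.count_nonzero(lge_mask) * voxel_ml)
    band_vol = float(np.count_nonzero(band) * voxel_ml)
    segments: set[int] = set()
    if segment_models is not None:
        if lge_masks_by_slice is None:
            raise TissueError("per-slice LGE masks required with segment models")
        for model, sl_mask in zip(segment_models, lge_masks_by_slice):
            for lab, area in model.segment_area.items():
                if area <= 0:
                    continue
                hit = np.count_nonzero((model.segment_map == lab) & sl_mask)
                frac = hit * voxel_spacing ** 2 / area
                if hit > 0 and frac > min_segment_fraction:
                    segments.add(lab)
    return LgeResult(
        lge_mask=lge_mask,
        lge_volume_ml=vol,
        lge_mass_g=vol * density,
        lge_percent=100.0 * vol / band_vol,
        segments_with_lge=segments,
    )


def ecv_from_t1(t1_myo_native: float, t1_myo_post: float,
                t1_blood_native: float, t1_blood_post: float,
                hematocrit: float) -> float:
    """Extracellular volume fraction from paired T1 times and hematocrit.

    Hematocrit given as a percentage (> 1) is normalized to a fraction.
    Raises if the blood relaxation-rate change is zero (no contrast effect)
    or the result is negative (non-physical myocardial T1 pair).
    """
    for t1 in (t1_myo_native, t1_myo_post, t1_blood_native, t1_blood_post):
        if not np.isfinite(t1) or t1 <= 0:
            raise TissueError("all T1 values must be positive and finite")
    if hematocrit > 1.0:
        hematocrit = hematocrit / 100.0
    if not 0 < hematocrit < 1:
        raise TissueError("hematocrit must lie in (0, 1)")
    dr1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_native
    if dr1_blood == 0:
        raise TissueError("no contrast effect: blood dR1 is zero")
    dr1_myo = 1.0 / t1_myo_post - 1.0 / t1_myo_native
    ecv = (1.0 - hematocrit) * dr1_myo / dr1_blood
    if ecv < 0:
        raise TissueError("non-physical ECV < 0 (myocardial post-contrast T1 "
                          "exceeds native while blood shortened)")
    return float(ecv)


def global_weighted_mean(segment_values: dict[int, float],
                         segment_area: dict[int, float],
                         excluded: set[int] = frozenset()):
    """Area-weighted mean of per-segment values over non-excluded segments.

    Segments with LGE (and segments with missing values or zero area) do
    not contribute.  Returns ``(mean, included_segment_set)``.
    """
    included = [lab for lab in segment_values
                if lab not in excluded
                and segment_area.get(lab, 0.0) > 0
                and np.isfinite(segment_values[lab])]
    if not included:
        raise TissueError("all segments excluded; global value undefined")
    w = np.array([segment_area[lab] for lab in included])
    v = np.array([segment_values[lab] for lab in included])
    return float(np.average(v, weights=w)), set(included)
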
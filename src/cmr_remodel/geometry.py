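"""Measurement regions on short-axis slices.

Turns endocardial/epicardial masks plus the right-ventricular insertion
points into the regions every tissue metric is read from: the myocardial
band (epi minus endo), its core after a fractional radial offset from both
edges, and the AHA 16-segment partition (6 basal, 6 mid, 4 apical sectors,
apex cap excluded).

Angular convention: sector angles start at the anterior RV insertion point
and sweep through the LV free wall (anterior -> anterolateral -> ... ->
anteroseptal); a sector boundary belongs to the sector it starts.  Rays are
binned at 1 degree; a voxel belongs to the ray nearest the angle of its
center.  Coordinates are 0-based voxel indices, positions are voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SliceContours",
    "SegmentModel",
    "GeometryError",
    "myocardial_band",
    "radial_offset",
    "assign_segments",
    "segment_stats",
    "cavity_centroid",
    "LEVELS",
    "SEGMENT_LEVELS",
]

LEVELS = ("basal", "mid", "apical")

#: AHA segment labels per level, ordered along the sweep direction
#: (anterior first, then through the free wall, septal sectors last).
_SECTOR_LABELS = {
    "basal": (1, 6, 5, 4, 3, 2),
    "mid": (7, 12, 11, 10, 9, 8),
    "apical": (13, 16, 15, 14),
}

SEGMENT_LEVELS = {
    lab: level for level, labs in _SECTOR_LABELS.items() for lab in labs
}


class GeometryError(ValueError):
    """Degenerate or inconsistent contour geometry."""


@dataclass
class SliceContours:
    """Endo/epi masks and anatomical anchors for one short-axis slice.

    ``endo_mask`` rasterizes the LV cavity (blood pool); ``epi_mask`` the
    full region enclosed by the epicardial contour (cavity + myocardium),
    so ``endo_mask`` must be a subset of ``epi_mask``.
    """

    endo_mask: np.ndarray
    epi_mask: np.ndarray
    level: str
    voxel_spacing: float
    slice_thickness: float
    rv_insertion_anterior: tuple[float, float] | None = None
    rv_insertion_inferior: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.endo_mask = np.asarray(self.endo_mask, dtype=bool)
        self.epi_mask = np.asarray(self.epi_mask, dtype=bool)
        if self.endo_mask.shape != self.epi_mask.shape:
            raise GeometryError("endo and epi masks differ in shape")
        if self.level not in LEVELS:
            raise GeometryError(f"unknown slice level {self.level!r}")
        if np.any(self.endo_mask & ~self.epi_mask):
            raise GeometryError("endocardial mask extends outside epicardial mask")
        if self.voxel_spacing <= 0 or self.slice_thickness <= 0:
            raise GeometryError("voxel spacing and slice thickness must be positive")


@dataclass
class SegmentModel:
    """Voxel-to-AHA-segment assignment for one slice.

    ``segment_map`` holds labels 1..16 over the (possibly offset) band and
    0 elsewhere; ``segment_area`` maps each label present on this slice to
    its in-plane area in mm^2.
    """

    segment_map: np.ndarray
    segment_area: dict[int, float]
    level: str
    voxel_spacing: float
    level_of_segment: dict[int, str] = field(default_factory=lambda: dict(SEGMENT_LEVELS))


def cavity_centroid(contours: SliceContours) -> tuple[float, float]:
    """Centroid (row, col) of the endocardial mask in voxel coordinates."""
    if not contours.endo_mask.any():
        raise GeometryError("empty endocardial mask")
    idx = np.argwhere(contours.endo_mask)
    ci, cj = idx.mean(axis=0)
    if not contours.endo_mask[int(round(ci)), int(round(cj))]:
        raise GeometryError("cavity centroid falls outside the endocardial mask")
    return float(ci), float(cj)


def myocardial_band(contours: SliceContours) -> np.ndarray:
    """Myocardial band: epicardial region minus the cavity."""
    band = contours.epi_mask & ~contours.endo_mask
    if not band.any():
        raise GeometryError("degenerate contours: myocardial band is empty")
    return band


def _polar(mask_shape: tuple[int, int], center: tuple[float, float],
           spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel radius (mm) and math-convention angle (deg, CCW from +x
    with +y pointing toward decreasing row index)."""
    ii, jj = np.indices(mask_shape)
    x = (jj - center[1]) * spacing
    y = (center[0] - ii) * spacing
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return r, theta


def _ray_bins(theta: np.ndarray) -> np.ndarray:
    """Nearest 1-degree ray index in {0..359} for each voxel angle."""
    return np.rint(theta).astype(int) % 360


def _ray_extrema(r: np.ndarray, bins: np.ndarray, mask: np.ndarray,
                 window: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Per-ray min/max voxel-center radius of ``mask``, length-360 arrays.

    A 1-degree arc is narrower than a voxel at typical radii, so a single
    bin catches only a scattering of the wall's voxels; the edge radii are
    therefore estimated over a +/-``window``-degree support (circular).
    Rays with no mask voxel within the window report NaN.
    """
    rmin = np.full(360, np.nan)
    rmax = np.full(360, np.nan)
    bb = bins[mask]
    rr = r[mask]
    order = np.argsort(bb)
    bb, rr = bb[order], rr[order]
    starts = np.searchsorted(bb, np.arange(361))
    per_min = np.full(360, np.nan)
    per_max = np.full(360, np.nan)
    for b in range(360):
        seg = rr[starts[b]:starts[b + 1]]
        if seg.size:
            per_min[b] = seg.min()
            per_max[b] = seg.max()
    shifts = range(-window, window + 1)
    stack_min = np.stack([np.roll(per_min, s) for s in shifts])
    stack_max = np.stack([np.roll(per_max, s) for s in shifts])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        rmin = np.nanmin(stack_min, axis=0)
        rmax = np.nanmax(stack_max, axis=0)
    return rmin, rmax


def radial_offset(band: np.ndarray, contours: SliceContours,
                  fraction: float = 0.10) -> np.ndarray:
    """Trim a fraction of the local wall thickness from both band edges.

    For each 1-degree ray from the cavity centroid, voxels within
    ``fraction`` of the ray's wall thickness of the endocardial or
    epicardial edge are removed.  ``fraction = 0`` returns the band
    unchanged.  Rays whose wall is thinner than 3 voxels keep their single
    most central voxel (with a warning) so no ray is emptied.
    """
    if not 0 <= fraction < 0.5:
        raise GeometryError("offset fraction must lie in [0, 0.5)")
    band = np.asarray(band, dtype=bool)
    if not band.any():
        raise GeometryError("cannot offset an empty band")
    if fraction == 0:
        return band.copy()

    center = cavity_centroid(contours)
    r, theta = _polar(band.shape, center, contours.voxel_spacing)
    bins = _ray_bins(theta)
    rmin, rmax = _ray_extrema(r, bins, band)

    vox_r = r[band]
    vox_b = bins[band]
    wall = rmax - rmin
    thin = wall < 3 * contours.voxel_spacing
    lo = rmin + fraction * wall
    hi = rmax - fraction * wall
    mid = 0.5 * (rmin + rmax)

    sel = (vox_r >= lo[vox_b]) & (vox_r <= hi[vox_b]) & ~thin[vox_b]
    # thin rays (and rays emptied by the trim) keep their central voxel
    keep = np.zeros_like(band)
    idx = np.argwhere(band)
    keep[tuple(idx[sel].T)] = True
    n_thin = 0
    for b in np.unique(vox_b):
        on_ray = vox_b == b
        if thin[b]:
            n_thin += 1
        if thin[b] or not sel[on_ray].any():
            cand = np.flatnonzero(on_ray)
            best = cand[np.argmin(np.abs(vox_r[cand] - mid[b]))]
            keep[tuple(idx[best])] = True
    if n_thin:
        warnings.warn(
            f"{n_thin} rays have wall thinner than 3 voxels; "
            "kept their central voxel", stacklevel=2)
    return keep


def _sweep_angle(theta: np.ndarray, theta_anterior: float, ccw: bool) -> np.ndarray:
    if ccw:
        return (theta - theta_anterior) % 360.0
    return (theta_anterior - theta) % 360.0


def sweep_direction(theta_anterior: float, theta_inferior: float) -> bool:
    """True if the free-wall sweep from the anterior insertion runs
    counterclockwise (math convention).

    The septum occupies the short arc between the two insertion points;
    the sweep traverses the free wall first, i.e. the long arc.
    """
    d_ccw = (theta_inferior - theta_anterior) % 360.0
    return d_ccw >= 180.0


def assign_segments(band: np.ndarray, contours: SliceContours,
                    ccw: bool | None = None) -> SegmentModel:
    """Partition a myocardial band into AHA segments for its slice level.

    Basal and mid levels get six 60-degree sectors, apical four 90-degree
    sectors.  The sector angle is the sweep angle from the anterior RV
    insertion direction through the free wall; each band voxel is assigned
    via its nearest 1-degree ray, and a boundary ray belongs to the sector
    it starts (the anterior-insertion ray itself is segment 1/7/13).
    """
    band = np.asarray(band, dtype=bool)
    if not band.any():
        raise GeometryError("cannot segment an empty band")
    if contours.rv_insertion_anterior is None:
        raise GeometryError("anterior RV insertion point is required")
    if ccw is None:
        if contours.rv_insertion_inferior is None:
            raise GeometryError(
                "inferior RV insertion point (or an explicit sweep direction) "
                "is required")
    center = cavity_centroid(contours)
    r, theta = _polar(band.shape, center, contours.voxel_spacing)

    def _point_angle(pt: tuple[float, float]) -> float:
        x = (pt[1] - center[1])
        y = (center[0] - pt[0])
        if x == 0 and y == 0:
            raise GeometryError("RV insertion point coincides with the centroid")
        return float(np.degrees(np.arctan2(y, x)) % 360.0)

    th_ant = _point_angle(contours.rv_insertion_anterior)
    if ccw is None:
        th_inf = _point_angle(contours.rv_insertion_inferior)
        ccw = sweep_direction(th_ant, th_inf)

    sweep = _sweep_angle(theta, th_ant, ccw)
    rays = _ray_bins(sweep)  # nearest-degree sweep ray, 0..359

    labels = _SECTOR_LABELS[contours.level]
    width = 360 // len(labels)
    sector_of_ray = np.asarray(labels)[np.minimum(rays // width, len(labels) - 1)]

    seg_map = np.zeros(band.shape, dtype=np.int16)
    seg_map[band] = sector_of_ray[band]

    voxel_area = contours.voxel_spacing ** 2
    area = {int(lab): float(np.count_nonzero(seg_map == lab) * voxel_area)
            for lab in labels}
    return SegmentModel(segment_map=seg_map, segment_area=area,
                        level=contours.level,
                        voxel_spacing=contours.voxel_spacing)


def segment_stats(values_map: np.ndarray, model: SegmentModel):
    """Arithmetic mean of ``values_map`` per segment, with segment areas.

    Returns ``{label: (mean, area_mm2)}``; an empty segment reports
    ``nan`` as its mean (flagged missing, never coerced to zero).
    """
    values_map = np.asarray(values_map, dtype=float)
    if values_map.shape != model.segment_map.shape:
        raise GeometryError("values map and segment map differ in shape")
    out: dict[int, tuple[float, float]] = {}
    for lab, area in model.segment_area.items():
        sel = model.segment_map == lab
        if not sel.any():
            out[lab] = (float("nan"), 0.0)
        else:
            out[lab] = (float(values_map[sel].mean()), area)
    return out


def _ray_outer_radius(mask: np.ndarray, center: tuple[float, float],
                      spacing: float, step: float = 0.25) -> np.ndarray:
    """Outermost radius (mm) of ``mask`` along each 1-degree ray from
    ``center``, found by marching outward in sub-voxel steps with
    nearest-voxel lookup.  NaN where a ray never enters the mask."""
    n_i, n_j = mask.shape
    half = max(n_i, n_j) * spacing
    t = np.arange(0.0, half, step * spacing)
    th = np.radians(np.arange(360.0))
    ii = np.rint(center[0] - np.outer(np.sin(th), t) / spacing).astype(int)
    jj = np.rint(center[1] + np.outer(np.cos(th), t) / spacing).astype(int)
    valid = (ii >= 0) & (ii < n_i) & (jj >= 0) & (jj < n_j)
    inside = np.zeros_like(valid)
    inside[valid] = mask[ii[valid], jj[valid]]
    any_in = inside.any(axis=1)
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    out = np.where(any_in, t[last] + 0.5 * step * spacing, np.nan)
    return out


def _circular_smooth(values: np.ndarray, width: int = 7) -> np.ndarray:
    kernel = np.ones(width) / width
    padded = np.concatenate([values[-(width // 2):], values,
                             values[: width // 2]])
    return np.convolve(padded, kernel, mode="valid")


def wall_thickness_by_ray(contours: SliceContours) -> np.ndarray:
    """Wall thickness (mm) per 1-degree ray from the cavity centroid.

    The thickness along a ray is the outer radius of the epicardial mask
    minus the outer radius of the endocardial mask.  Both radii are found
    by sub-voxel ray marching and smoothed over a 7-degree circular window
    so the voxelization wobble (about half a voxel per ray) does not
    inflate maximum-thickness statistics.
    """
    myocardial_band(contours)  # validates non-degenerate contours
    center = cavity_centroid(contours)
    epi_r = _ray_outer_radius(contours.epi_mask, center,
                              contours.voxel_spacing)
    endo_r = _ray_outer_radius(contours.endo_mask, center,
                               contours.voxel_spacing)
    if np.isnan(epi_r).all() or np.isnan(endo_r).all():
        raise GeometryError("no ray intersects both contours")
    thick = _circular_smooth(epi_r) - _circular_smooth(endo_r)
    return thick
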
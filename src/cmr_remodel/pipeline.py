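"""End-to-end orchestration: subject -> metrics -> cohort -> statistics.

A subject-timepoint is a directory of aligned NIfTI volumes (native and
post-contrast T1 maps, LGE magnitude, cine ED/ES), integer label maps
(0 background, 1 blood pool, 2 myocardium, 3 LGE reference ROI), a JSON
sidecar with the RV insertion points and slice levels, and JSON metadata.
``quantify_subject`` runs geometry -> tissue -> volumetrics -> remodeling
and yields one metrics row; ``run_cohort`` pairs timepoints by subject id
and runs the statistics stage, writing the summary (pre/post/change/test),
regression and correlation tables with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import geometry as geo
from . import remodeling as rem
from . import stats as st
from . import tissue as tis
from . import volumetrics as vol
from .phantom import SubjectBundle, ImageStack, MaskSet, LBL_BLOOD, LBL_MYO, \
    LBL_REF_ROI
from .volumetrics import SubjectMeta

__all__ = ["RunConfig", "PipelineError", "quantify_subject", "run_cohort",
           "read_subject", "run_stats_stage"]

log = logging.getLogger("cmr_remodel")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All analysis settings; defaults follow the published protocol
    (6-SD LGE threshold, 10% endo/epi offset, Bonferroni 0.05/20)."""

    density_g_per_ml: float = 1.05
    bsa_formula: str = "mosteller"
    lge_sd_multiplier: float = 6.0
    offset_fraction: float = 0.10
    segment_exclusion_fraction: float = 0.0
    alpha: float = 0.05
    family_size: int = 20
    shapiro_alpha: float = 0.05
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    rcs_knots: int = 4
    seed: int = 0
    blood_roi_slice: str = "mid"  # blood T1 measured on the mid slice

    def manifest(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest}


_REQUIRED_FILES = ["t1_native.nii.gz", "t1_post.nii.gz", "lge.nii.gz",
                   "cine_ed.nii.gz", "cine_es.nii.gz",
                   "mask_ed.nii.gz", "mask_es.nii.gz",
                   "sidecar.json", "meta.json"]


def read_subject(subject_dir: str | Path) -> SubjectBundle:
    """Load a subject-timepoint directory into an in-memory bundle."""
    d = Path(subject_dir)
    for f in _REQUIRED_FILES:
        if not (d / f).exists():
            raise PipelineError(f"missing required file {f} in {d}")
    vols = {}
    shapes = set()
    for name in ("t1_native", "t1_post", "lge", "cine_ed", "cine_es",
                 "mask_ed", "mask_es"):
        img = nib.load(d / f"{name}.nii.gz")
        vols[name] = np.asarray(img.dataobj)
        shapes.add(vols[name].shape)
        zooms = img.header.get_zooms()[:3]
    if len(shapes) != 1:
        raise PipelineError(f"image/mask shape mismatch in {d}: {shapes}")
    sidecar = json.loads((d / "sidecar.json").read_text())
    meta = json.loads((d / "meta.json").read_text())
    sp = float(sidecar.get("voxel_spacing_mm", zooms[0]))
    th = float(sidecar.get("slice_thickness_mm", zooms[2]))
    images = ImageStack(vols["t1_native"], vols["t1_post"], vols["lge"],
                        vols["cine_ed"], vols["cine_es"], sp, th)
    masks = MaskSet(vols["mask_ed"].astype(np.int16),
                    vols["mask_es"].astype(np.int16),
                    sidecar["slice_levels"],
                    [tuple(p) for p in sidecar["rv_insertion_anterior"]],
                    [tuple(p) for p in sidecar["rv_insertion_inferior"]],
                    sp, th)
    return SubjectBundle(
        meta=SubjectMeta(meta["subject_id"], meta["timepoint"],
                         meta["hematocrit"], meta["height_cm"],
                         meta["weight_kg"], meta["heart_rate_bpm"]),
        truth=None, params=None, images=images, masks=masks)


def _contours(masks: MaskSet, phase: str) -> list[geo.SliceContours]:
    labels = masks.labels_ed if phase == "ed" else masks.labels_es
    out = []
    for k in range(labels.shape[2]):
        sl = labels[..., k]
        endo = sl == LBL_BLOOD
        epi = endo | (sl == LBL_MYO) | (sl == LBL_REF_ROI)
        out.append(geo.SliceContours(
            endo_mask=endo, epi_mask=epi, level=masks.slice_levels[k],
            voxel_spacing=masks.voxel_spacing,
            slice_thickness=masks.slice_thickness,
            rv_insertion_anterior=tuple(masks.rv_insertion_anterior[k]),
            rv_insertion_inferior=tuple(masks.rv_insertion_inferior[k])))
    return out


def quantify_subject(subject: SubjectBundle | str | Path,
                     config: RunConfig | None = None,
                     artifacts_dir: str | Path | None = None
                     ) -> rem.SubjectMetrics:
    """Full single-subject quantification.

    Accepts an in-memory bundle or a subject-timepoint directory.  When
    ``artifacts_dir`` is given, the segment label map, LGE mask and
    per-segment table are persisted there.
    """
    config = config or RunConfig()
    if not isinstance(subject, SubjectBundle):
        subject = read_subject(subject)
    im, mk, meta = subject.images, subject.masks, subject.meta
    if im is None or mk is None:
        raise PipelineError("subject bundle has no image data")
    if im.t1_native.shape != mk.labels_ed.shape:
        raise PipelineError("image/mask misalignment")
    n_slices = mk.labels_ed.shape[2]

    contours_ed = _contours(mk, "ed")
    contours_es = _contours(mk, "es")

    # --- volumetrics ------------------------------------------------------
    sp, th = mk.voxel_spacing, mk.slice_thickness
    edv = vol.volume_from_masks([c.endo_mask for c in contours_ed], sp, th)
    esv = vol.volume_from_masks([c.endo_mask for c in contours_es], sp, th)
    bands_ed = [geo.myocardial_band(c) for c in contours_ed]
    myo_v = vol.volume_from_masks(bands_ed, sp, th)
    sv, ef, co = vol.lv_function(edv, esv, meta.heart_rate_bpm)
    mass = vol.mass_from_volume(myo_v, config.density_g_per_ml)
    mwt = vol.max_wall_thickness(contours_ed)
    body_sa = vol.bsa(meta.height_cm, meta.weight_kg, config.bsa_formula)

    # --- geometry: offset band + segments ---------------------------------
    seg_full, seg_core = [], []
    for c, band in zip(contours_ed, bands_ed):
        core = geo.radial_offset(band, c, config.offset_fraction)
        seg_full.append(geo.assign_segments(band, c))
        seg_core.append(geo.assign_segments(core, c))

    # --- LGE: 6-SD threshold over the full band ---------------------------
    roi_mask = mk.labels_ed == LBL_REF_ROI
    band3d = np.stack([b for b in bands_ed], axis=2) | roi_mask
    roi = tis.ReferenceROI.from_image(im.lge, roi_mask, band=band3d)
    lge_mask = tis.lge_threshold(im.lge, band3d, roi,
                                 n_sd=config.lge_sd_multiplier)
    lge_res = tis.lge_quantify(
        lge_mask, band3d, sp, th, density=config.density_g_per_ml,
        segment_models=seg_full,
        lge_masks_by_slice=[lge_mask[..., k] for k in range(n_slices)],
        min_segment_fraction=config.segment_exclusion_fraction)

    # --- T1 / ECV over the offset band, LGE segments excluded -------------
    blood_idx = {"mid": n_slices // 2, "base": 0,
                 "apex": n_slices - 1}[config.blood_roi_slice]
    blood_sel = mk.labels_ed[..., blood_idx] == LBL_BLOOD
    blood_t1n = float(im.t1_native[..., blood_idx][blood_sel].mean())
    blood_t1p = float(im.t1_post[..., blood_idx][blood_sel].mean())

    seg_t1n: dict[int, float] = {}
    seg_t1p: dict[int, float] = {}
    seg_area: dict[int, float] = {}
    for k, model in enumerate(seg_core):
        stats_n = geo.segment_stats(im.t1_native[..., k], model)
        stats_p = geo.segment_stats(im.t1_post[..., k], model)
        for lab, (mean_n, area) in stats_n.items():
            if area <= 0:
                continue
            # accumulate area-weighted over slices sharing a level
            prev_a = seg_area.get(lab, 0.0)
            seg_area[lab] = prev_a + area
            wa, wb = prev_a / seg_area[lab], area / seg_area[lab]
            seg_t1n[lab] = wa * seg_t1n.get(lab, 0.0) + wb * mean_n
            seg_t1p[lab] = wa * seg_t1p.get(lab, 0.0) + wb * stats_p[lab][0]

    seg_ecv = {}
    for lab in seg_t1n:
        try:
            seg_ecv[lab] = tis.ecv_from_t1(seg_t1n[lab], seg_t1p[lab],
                                           blood_t1n, blood_t1p,
                                           meta.hematocrit)
        except tis.TissueError:
            warnings.warn(f"segment {lab}: non-physical T1 pair; dropped",
                          stacklevel=2)

    excl = lge_res.segments_with_lge
    g_t1, included = tis.global_weighted_mean(seg_t1n, seg_area, excl)
    g_ecv, _ = tis.global_weighted_mean(seg_ecv, seg_area, excl)

    # --- remodeling -------------------------------------------------------
    iecv = rem.indexed_ecv(myo_v, lge_res.lge_volume_ml, body_sa, g_ecv)
    icv = rem.indexed_cv(myo_v, lge_res.lge_volume_ml, body_sa, g_ecv)

    metrics = rem.SubjectMetrics(
        subject_id=meta.subject_id, timepoint=meta.timepoint,
        bsa_m2=body_sa, edv_ml=edv, esv_ml=esv, sv_ml=sv, ef_percent=ef,
        co_l_min=co, myo_volume_ed_ml=myo_v, mass_g=mass, mwt_mm=mwt,
        edvi=edv / body_sa, esvi=esv / body_sa, svi=sv / body_sa,
        lvmi=mass / body_sa, lge_volume_ml=lge_res.lge_volume_ml,
        lge_mass_g=lge_res.lge_mass_g,
        lge_mass_indexed=lge_res.lge_mass_g / body_sa,
        lge_percent=lge_res.lge_percent, global_native_t1=g_t1,
        global_ecv=g_ecv, iecv=iecv, icv=icv)

    if artifacts_dir is not None:
        out = Path(artifacts_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .phantom import _save_nifti
        seg3d = np.stack([m.segment_map for m in seg_core], axis=2)
        _save_nifti(seg3d, sp, th, out / "segments.nii.gz")
        _save_nifti(lge_mask.astype(np.uint8), sp, th, out / "lge_mask.nii.gz")
        pd.DataFrame({
            "segment": list(seg_t1n),
            "area_mm2": [seg_area[s] for s in seg_t1n],
            "native_t1": [seg_t1n[s] for s in seg_t1n],
            "post_t1": [seg_t1p[s] for s in seg_t1n],
            "ecv": [seg_ecv.get(s, np.nan) for s in seg_t1n],
            "has_lge": [s in excl for s in seg_t1n],
        }).to_csv(out / "segments.csv", index=False)
    return metrics


# ---------------------------------------------------------------------------
# Cohort stage
# ---------------------------------------------------------------------------

def run_stats_stage(paired: pd.DataFrame, config: RunConfig | None = None,
                    metrics: list[str] | None = None):
    """Statistics on a paired table (``<metric>_pre/_post`` columns).

    Returns ``(table2, table3, corr_r, corr_p)``: the per-metric paired
    summary with normality-gated tests at the Bonferroni-adjusted alpha,
    regression blocks predicting the LVMI and iECV reductions from
    baseline values, and the Pearson correlation matrices.
    """
    config = config or RunConfig()
    metrics = metrics or [m for m in rem.PAIRED_METRICS
                          if f"{m}_pre" in paired.columns]
    m_family = config.family_size or len(metrics)
    rows = []
    for m in metrics:
        pre = paired[f"{m}_pre"].to_numpy(float)
        post = paired[f"{m}_post"].to_numpy(float)
        res = st.paired_compare(pre, post, alpha=config.alpha, m=m_family,
                                metric=m, shapiro_alpha=config.shapiro_alpha)
        d = post - pre
        rows.append({
            "metric": m, "n": len(pre),
            "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
            "pre_median": np.median(pre),
            "post_mean": post.mean(), "post_sd": post.std(ddof=1),
            "post_median": np.median(post),
            "change_mean": d.mean(), "change_sd": d.std(ddof=1),
            "change_median": np.median(d),
            "test": res.test, "statistic": res.statistic, "p": res.p,
            "alpha_adjusted": res.alpha_adjusted,
            "significant": res.significant,
        })
    table2 = pd.DataFrame(rows)

    # regression: reduction (pre - post) of LVMI and iECV on baseline values
    predictors = ["lvmi", "ecv_percent", "icv", "iecv", "global_native_t1",
                  "lge_percent"]
    predictors = [p for p in predictors if f"{p}_pre" in paired.columns]
    X = paired[[f"{p}_pre" for p in predictors]].copy()
    X.columns = predictors
    t3_rows = []
    reg_results = {}
    for outcome_metric in ("lvmi", "iecv"):
        if f"{outcome_metric}_pre" not in paired.columns:
            continue
        y = paired[f"{outcome_metric}_pre"] - paired[f"{outcome_metric}_post"]
        y.name = f"{outcome_metric}_reduction"
        # baseline values of the outcome metric itself stay in the candidate
        # set (baseline size predicts its own regression)
        cand = X
        uni, retained = st.univariable_screen(y, cand, alpha=config.alpha)
        for _, r in uni.iterrows():
            t3_rows.append({"outcome": y.name, "block": "univariable",
                            **r.to_dict()})
        if retained:
            res = st.stepwise_multivariable(
                y, cand[retained], entry_p=config.stepwise_entry_p,
                removal_p=config.stepwise_removal_p, outcome=y.name,
                dw_seed=config.seed)
            reg_results[y.name] = res
            for _, r in res.table.iterrows():
                t3_rows.append({"outcome": y.name, "block": "multivariable",
                                "durbin_watson": res.durbin_watson,
                                "durbin_watson_p": res.durbin_watson_p,
                                "n_flagged": len(res.flagged),
                                **r.to_dict()})
    table3 = pd.DataFrame(t3_rows)

    corr_cols = {f"{p}_pre": f"baseline_{p}" for p in predictors}
    corr_cols.update({f"{m}_delta": f"delta_{m}"
                      for m in ("lvmi", "iecv", "icv", "ecv_percent",
                                "ef_percent") if f"{m}_delta" in paired})
    cdf = paired[list(corr_cols)].rename(columns=corr_cols)
    corr_r, corr_p = st.correlation_matrix(cdf)
    return table2, table3, corr_r, corr_p, reg_results


def run_cohort(cohort: list[tuple[SubjectBundle, SubjectBundle]] | str | Path,
               config: RunConfig | None = None,
               out_dir: str | Path | None = None):
    """Quantify every subject-timepoint, pair by id, run the statistics.

    ``cohort`` is either a list of (pre, post) bundles or a directory of
    ``<subject>/<timepoint>/`` subject directories.  Subjects missing a
    timepoint are excluded with a logged count.  Returns a dict with the
    metrics table, paired table, summary/regression/correlation tables.
    """
    config = config or RunConfig()
    by_subject: dict[str, dict[str, rem.SubjectMetrics]] = {}
    if isinstance(cohort, (str, Path)):
        root = Path(cohort)
        subj_dirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not subj_dirs:
            raise PipelineError(f"no subject directories under {root}")
        for sd in subj_dirs:
            for tp_dir in sorted(p for p in sd.iterdir() if p.is_dir()):
                try:
                    mrow = quantify_subject(tp_dir, config)
                except (PipelineError, geo.GeometryError,
                        tis.TissueError) as e:
                    log.error("subject %s skipped: %s", tp_dir, e)
                    continue
                by_subject.setdefault(mrow.subject_id, {})[mrow.timepoint] = mrow
    else:
        for pre_b, post_b in cohort:
            for b in (pre_b, post_b):
                mrow = quantify_subject(b, config)
                by_subject.setdefault(mrow.subject_id, {})[mrow.timepoint] = mrow

    pairs = [(d["pre"], d["post"]) for sid, d in sorted(by_subject.items())
             if "pre" in d and "post" in d]
    n_dropped = len(by_subject) - len(pairs)
    if n_dropped:
        log.warning("%d subjects missing a timepoint; excluded", n_dropped)
    if len(pairs) < 2:
        raise PipelineError("need at least 2 complete pre/post pairs")

    metrics_rows = pd.DataFrame(
        [m.as_row() for d in by_subject.values() for m in d.values()])
    paired = rem.build_paired_table(pairs)
    table2, table3, corr_r, corr_p, reg = run_stats_stage(paired, config)

    result = {"metrics": metrics_rows, "paired": paired, "table2": table2,
              "table3": table3, "corr_r": corr_r, "corr_p": corr_p,
              "regressions": reg, "n_pairs": len(pairs),
              "n_dropped": n_dropped}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_rows.to_csv(out / "metrics.csv", index=False)
        paired.to_csv(out / "paired_table.csv", index=False)
        table2.to_csv(out / "table2.csv", index=False)
        table3.to_csv(out / "table3.csv", index=False)
        corr_r.to_csv(out / "correlations_r.csv")
        corr_p.to_csv(out / "correlations_p.csv")
        manifest = config.manifest()
        manifest["n_pairs"] = len(pairs)
        manifest["n_dropped"] = n_dropped
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return result
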
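"""Compartment volumes and within-person pre/post changes.

The non-enhanced myocardial volume (end-diastolic myocardial volume minus
LGE volume), indexed to body surface area, is split by the extracellular
volume fraction into the indexed extracellular volume

    iECV = (myoV/BSA - lgeV/BSA) * ECV            [mL/m^2]

and the indexed cellular volume

    iCV  = (myoV/BSA - lgeV/BSA) * (1 - ECV)      [mL/m^2],

so iCV + iECV equals the indexed non-enhanced myocardial volume exactly and
iECV/(iCV+iECV) reconstructs ECV.  Both the LV mass/volume term and the LGE
volume term are divided by BSA.

Sign conventions for paired changes: summary tables report
``delta = post - pre`` (a negative delta is regression); regression
outcomes use ``change = pre - post`` so a reduction is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = [
    "SubjectMetrics",
    "indexed_ecv",
    "indexed_cv",
    "paired_change",
    "build_paired_table",
    "PAIRED_METRICS",
]


@dataclass
class SubjectMetrics:
    """All per-subject scalars produced by the quantification stages."""

    subject_id: str
    timepoint: str
    bsa_m2: float
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_percent: float
    co_l_min: float
    myo_volume_ed_ml: float
    mass_g: float
    mwt_mm: float
    edvi: float
    esvi: float
    svi: float
    lvmi: float
    lge_volume_ml: float
    lge_mass_g: float
    lge_mass_indexed: float
    lge_percent: float
    global_native_t1: float
    global_ecv: float  # fraction
    iecv: float
    icv: float

    def as_row(self) -> dict:
        d = asdict(self)
        d["ecv_percent"] = 100.0 * self.global_ecv
        return d


#: metrics reported pre/post/change in the cohort summary table
PAIRED_METRICS = [
    "edvi", "esvi", "svi", "ef_percent", "co_l_min", "mass_g", "lvmi",
    "mwt_mm", "lge_mass_g", "lge_mass_indexed", "lge_percent",
    "global_native_t1", "ecv_percent", "icv", "iecv",
]


def _indexed_nonenhanced(myo_volume_ed: float, lge_volume: float,
                         bsa: float) -> float:
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    if myo_volume_ed < 0 or lge_volume < 0:
        raise ValueError("volumes must be non-negative")
    if lge_volume > myo_volume_ed:
        raise ValueError("LGE volume exceeds myocardial volume")
    return (myo_volume_ed - lge_volume) / bsa


def indexed_ecv(myo_volume_ed: float, lge_volume: float, bsa: float,
                global_ecv: float) -> float:
    """iECV (mL/m^2): indexed non-enhanced myocardial volume times ECV."""
    return _indexed_nonenhanced(myo_volume_ed, lge_volume, bsa) * global_ecv


def indexed_cv(myo_volume_ed: float, lge_volume: float, bsa: float,
               global_ecv: float) -> float:
    """iCV (mL/m^2): indexed non-enhanced myocardial volume times 1-ECV."""
    return _indexed_nonenhanced(myo_volume_ed, lge_volume, bsa) * (1.0 - global_ecv)


def paired_change(pre: SubjectMetrics, post: SubjectMetrics, metric: str,
                  convention: str = "post_minus_pre"):
    """Within-person change of one metric.

    Returns ``(delta, percent_change)`` where delta follows ``convention``
    ("post_minus_pre" for summary tables, "pre_minus_post" for regression
    outcomes where a reduction is positive) and ``percent_change`` is
    ``100 * (pre - post) / pre`` (percent reduction), ``nan`` if the
    baseline value is zero.
    """
    if pre.subject_id != post.subject_id:
        raise ValueError("paired metrics must come from the same subject")
    a = pre.as_row()[metric]
    b = post.as_row()[metric]
    if convention == "post_minus_pre":
        delta = b - a
    elif convention == "pre_minus_post":
        delta = a - b
    else:
        raise ValueError(f"unknown sign convention {convention!r}")
    pct = float("nan") if a == 0 else 100.0 * (a - b) / a
    return delta, pct


def build_paired_table(pairs: list[tuple[SubjectMetrics, SubjectMetrics]],
                       metrics: list[str] | None = None) -> pd.DataFrame:
    """One row per subject: pre, post and post-pre delta per metric."""
    metrics = metrics or PAIRED_METRICS
    rows = []
    for pre, post in pairs:
        row = {"subject_id": pre.subject_id}
        for m in metrics:
            a = pre.as_row()[m]
            b = post.as_row()[m]
            row[f"{m}_pre"] = a
            row[f"{m}_post"] = b
            row[f"{m}_delta"] = b - a
        rows.append(row)
    return pd.DataFrame(rows)
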
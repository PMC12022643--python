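"""Reporting helpers: clinical-style rounding and Markdown summaries."""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

__all__ = ["count_percent", "percent_reduction", "render_summary"]


def count_percent(k: int, n: int) -> int:
    """Percentage of a count, rounded half-up to the nearest integer, the
    way clinical tables print n (%) entries (e.g. 12/43 -> 28)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("count must lie in [0, n]")
    return int(math.floor(100.0 * k / n + 0.5))


def percent_reduction(pre: float, post: float) -> float:
    """Percent reduction 100*(pre - post)/pre; positive when the value
    regressed."""
    if pre == 0:
        raise ValueError("baseline value is zero; percent change undefined")
    return 100.0 * (pre - post) / pre


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.3g}"
    return str(x)


def render_summary(table2: pd.DataFrame, table3: pd.DataFrame,
                   out_path: str | Path | None = None) -> str:
    """Render the cohort summary and regression tables as Markdown."""
    lines = ["# Cohort summary", "",
             "## Paired pre/post changes", "",
             "| metric | pre (mean±sd) | post (mean±sd) | change (mean±sd) "
             "| test | p | significant |",
             "|---|---|---|---|---|---|---|"]
    for _, r in table2.iterrows():
        lines.append(
            f"| {r['metric']} | {r['pre_mean']:.1f}±{r['pre_sd']:.1f} "
            f"| {r['post_mean']:.1f}±{r['post_sd']:.1f} "
            f"| {r['change_mean']:+.1f}±{r['change_sd']:.1f} "
            f"| {r['test']} | {r['p']:.3g} "
            f"| {'*' if r['significant'] else ''} |")
    if len(table3):
        lines += ["", "## Predictors of remodeling", "",
                  "| outcome | block | predictor | beta | 95% CI | p |",
                  "|---|---|---|---|---|---|"]
        for _, r in table3.iterrows():
            lines.append(
                f"| {r['outcome']} | {r['block']} | {r['predictor']} "
                f"| {r['beta']:.3g} "
                f"| {r['ci_low']:.3g} to {r['ci_high']:.3g} "
                f"| {r['p']:.3g} |")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
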
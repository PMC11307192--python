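"""Descriptive statistics over a participant-characteristics table.

Means and sample SDs (n−1) are computed at full precision; a display
convention (round-half-up at a configurable number of decimals) is applied
only for presentation and for comparison against published tables.  The
packaged reference cohort ships with the printed group cells of its source
table; :func:`verify_reference_summary` reports, cell by cell, whether the
recomputed statistic matches the printed one — printed cells known to be
inconsistent with their own columns are flagged, never forced.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataValidationError
from .hr_io import CohortRow, load_reference_annotations, load_reference_cohort

__all__ = [
    "NUMERIC_COLUMNS",
    "SummaryRow",
    "SubgroupComparison",
    "round_half_up",
    "summarize",
    "compare_subgroups",
    "verify_reference_summary",
]

NUMERIC_COLUMNS = [
    "age_years", "height_m", "mass_kg", "updrs2", "updrs3",
    "hy", "mmse", "tmt_a_s", "tmt_b_s", "tug_s",
]

_SUBGROUPS = {"experiment1_all", "experiment2_subset"}


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at ``decimals`` places (display rule)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(str(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryRow:
    column: str
    subgroup: str
    n: int
    mean: float
    sd: float                 # NaN when n == 1 (flagged undefined)
    mean_display: float
    sd_display: float
    sd_defined: bool


def _select(rows: Sequence[CohortRow], subgroup: str) -> list[CohortRow]:
    if subgroup not in _SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    if subgroup == "experiment2_subset":
        return [r for r in rows if r.in_experiment2]
    return list(rows)


def summarize(
    rows: Sequence[CohortRow], subgroup: str = "experiment1_all",
    display_decimals: int = 2,
) -> list[SummaryRow]:
    """Mean and sample SD of every numeric column for one subgroup."""
    sub = _select(rows, subgroup)
    if not sub:
        raise DataValidationError(f"empty subgroup {subgroup!r}")
    out = []
    for col in NUMERIC_COLUMNS:
        vals = np.array([getattr(r, col) for r in sub], dtype=float)
        mean = float(vals.mean())
        sd_defined = vals.size > 1
        sd = float(vals.std(ddof=1)) if sd_defined else float("nan")
        out.append(SummaryRow(
            column=col, subgroup=subgroup, n=vals.size, mean=mean, sd=sd,
            mean_display=round_half_up(mean, display_decimals),
            sd_display=round_half_up(sd, display_decimals) if sd_defined else float("nan"),
            sd_defined=sd_defined,
        ))
    return out


@dataclass(frozen=True)
class SubgroupComparison:
    column: str
    n1: int
    n2: int
    t_welch: float
    p_welch: float
    t_pooled: float
    p_pooled: float
    degenerate: bool


def compare_subgroups(rows: Sequence[CohortRow]) -> list[SubgroupComparison]:
    """Independent-samples t-tests (Welch and pooled-variance) per column,
    comparing the full cohort with the training subset."""
    g1 = _select(rows, "experiment1_all")
    g2 = _select(rows, "experiment2_subset")
    if len(g1) < 2 or len(g2) < 2:
        raise DataValidationError("both subgroups need at least 2 participants")
    out = []
    for col in NUMERIC_COLUMNS:
        a = np.array([getattr(r, col) for r in g1], dtype=float)
        b = np.array([getattr(r, col) for r in g2], dtype=float)
        degenerate = bool(a.std(ddof=1) == 0 and b.std(ddof=1) == 0)
        if degenerate:
            same = a.mean() == b.mean()
            tw = tp = 0.0 if same else float("nan")
            pw = pp = 1.0 if same else float("nan")
        else:
            tw, pw = (float(v) for v in stats.ttest_ind(a, b, equal_var=False))
            tp, pp = (float(v) for v in stats.ttest_ind(a, b, equal_var=True))
        out.append(SubgroupComparison(col, a.size, b.size, tw, pw, tp, pp, degenerate))
    return out


def verify_reference_summary() -> dict[str, dict]:
    """Compare recomputed group cells of the packaged reference cohort with
    the printed ones, at the printed precision.

    Returns a mapping ``'subgroup.column.stat'`` → record with the computed
    full-precision value, the display-rounded value at the printed
    precision, the printed value, whether they match, and whether the cell
    is annotated as a known discrepancy of the source table.
    """
    rows = load_reference_cohort()
    ann = load_reference_annotations()
    discrepant = set(ann["discrepant_cells"])
    result: dict[str, dict] = {}
    for subgroup, cols in ann["printed"].items():
        summary = {s.column: s for s in summarize(rows, subgroup)}
        for col, cells in cols.items():
            for stat, printed_str in cells.items():
                computed = summary[col].mean if stat == "mean" else summary[col].sd
                decimals = len(printed_str.split(".")[1]) if "." in printed_str else 0
                shown = round_half_up(computed, decimals)
                key = f"{subgroup}.{col}.{stat}"
                result[key] = {
                    "computed": computed,
                    "displayed": shown,
                    "printed": float(printed_str),
                    "matches": shown == float(printed_str),
                    "known_discrepant": key in discrepant,
                }
    return result
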
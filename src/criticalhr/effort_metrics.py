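"""Per-effort derived quantities.

The central quantity is the total number of heartbeats HB expended over an
effort: the arithmetic mean of the window-average HR samples (b·min⁻¹)
multiplied by the effort duration in minutes.  HB plotted against effort
duration is the raw material for the critical-heart-rate fit, exactly as
distance against duration is for critical speed.

Effort durations are additionally screened against the practical
recommendation that each effort last 3–12 min; two historical windows from
the critical-power literature (8–20 min and 12–15 min) are reported as
informational flags only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataValidationError
from .hr_io import EffortTrial

__all__ = ["EffortSummary", "total_heartbeats", "summarize_effort",
           "RECOMMENDED_DURATION_MIN"]

#: Recommended effort-duration window, minutes (inclusive bounds).
RECOMMENDED_DURATION_MIN = (3.0, 12.0)

#: Historical windows from earlier critical-power work, informational only.
HISTORICAL_WINDOWS_MIN = {"8_20": (8.0, 20.0), "12_15": (12.0, 15.0)}


@dataclass(frozen=True)
class EffortSummary:
    distance_m: float
    time_s: float
    duration_min: float
    mean_hr_bpm: float
    max_hr_bpm: float
    total_hb_beats: float
    mean_speed_m_per_s: float
    duration_valid: bool
    #: informational: duration also inside each historical window
    historical_windows: dict[str, bool]


def total_heartbeats(trial: EffortTrial) -> float:
    """Total heartbeats HB = mean(window-average HR) × duration in minutes."""
    if len(trial.series) == 0:
        raise DataValidationError(
            f"trial {trial.participant_id}/{trial.distance_m:g}m has no HR samples"
        )
    if trial.time_s <= 0:
        raise DataValidationError("non-positive effort duration")
    return trial.series.mean_hr() * trial.time_s / 60.0


def summarize_effort(
    trial: EffortTrial,
    min_duration_min: float = RECOMMENDED_DURATION_MIN[0],
    max_duration_min: float = RECOMMENDED_DURATION_MIN[1],
) -> EffortSummary:
    """All per-effort quantities, plus the duration-window validity flag."""
    hb = total_heartbeats(trial)
    duration_min = trial.time_s / 60.0
    return EffortSummary(
        distance_m=trial.distance_m,
        time_s=trial.time_s,
        duration_min=duration_min,
        mean_hr_bpm=trial.series.mean_hr(),
        max_hr_bpm=trial.series.max_hr(),
        total_hb_beats=hb,
        mean_speed_m_per_s=trial.distance_m / trial.time_s,
        duration_valid=min_duration_min <= duration_min <= max_duration_min,
        historical_windows={
            name: lo <= duration_min <= hi
            for name, (lo, hi) in HISTORICAL_WINDOWS_MIN.items()
        },
    )
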
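"""Pre/post training-effect analysis.

Sensitivity of the walking protocol to an aerobic training block is
assessed with paired t-tests and banded Cohen's d on effort times, total
heartbeats, the fitted critical speed and critical HR, and the six-minute
walk test.  Sign convention: improvements in timed efforts are *negative*
changes (less time), six-minute-walk gains are *positive* changes (more
distance).

Participants enter the analysis only if they attended the required share of
training sessions (default 90% of 16 sessions: 8 weeks, twice weekly).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .critical_models import fit_trials
from .effort_metrics import total_heartbeats
from .errors import DataValidationError
from .hr_io import EffortTrial, Session
from .reliability import PairedMeasurements, paired_effect

__all__ = [
    "TRAINING_PROGRAM",
    "PrePostDataset",
    "TrainingEffect",
    "TrainingEffectReport",
    "training_effect",
    "sixmwt_effect",
    "adherence_filter",
    "experiment2_report",
]

#: Bookkeeping constants for the training block the analysis assumes.
TRAINING_PROGRAM = {
    "weeks": 8,
    "sessions_per_week": 2,
    "total_sessions": 16,
    "session_parts": (
        "10 min warm-up: stretching and mobility",
        "balance and calisthenic strength work (15 min weeks 1-4, 10 min weeks 5-8)",
        "continuous walking above the critical HR (20 min weeks 1-4, 30 min weeks 5-8)",
    ),
    "adherence_threshold_percent": 90.0,
}


@dataclass(frozen=True)
class PrePostDataset:
    """One metric measured before and after training, paired by participant."""

    metric: str
    pre: tuple[float, ...]
    post: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.post):
            raise DataValidationError("pre and post must have equal length")
        if len(self.pre) < 2:
            raise DataValidationError("need at least 2 paired participants")

    @classmethod
    def from_arrays(cls, metric, pre, post, units=""):
        return cls(metric, tuple(float(x) for x in pre),
                   tuple(float(x) for x in post), units)

    @property
    def n(self) -> int:
        return len(self.pre)


@dataclass(frozen=True)
class TrainingEffect:
    metric: str
    units: str
    n: int
    mean_pre: float
    mean_post: float
    mean_change: float          # mean(post − pre); negative = faster/lower
    percent_change: float       # 100 · (mean_post − mean_pre) / mean_pre
    p_value: float
    d: float
    band: str
    direction: str              # 'decrease' | 'increase' | 'none'
    degenerate: bool = False


@dataclass(frozen=True)
class TrainingEffectReport:
    effects: tuple[TrainingEffect, ...]
    retained_ids: tuple[str, ...]
    adherence_percent: dict[str, float] = field(default_factory=dict)


def training_effect(dataset: PrePostDataset, d_method: str = "pooled") -> TrainingEffect:
    """Paired pre/post comparison for one metric.

    Percent change uses the mean-of-sessions convention,
    100·(mean_post − mean_pre)/mean_pre, not the mean of per-participant
    ratios.
    """
    pre, post = np.asarray(dataset.pre), np.asarray(dataset.post)
    # paired_effect is oriented test-minus-retest; feed post first so the
    # sign of the change is post − pre.
    eff = paired_effect(
        PairedMeasurements.from_arrays(dataset.metric, dataset.post, dataset.pre),
        d_method=d_method,
    )
    mean_pre, mean_post = float(pre.mean()), float(post.mean())
    change = mean_post - mean_pre
    if mean_pre == 0.0:
        raise DataValidationError("mean pre value is zero; percent change undefined")
    direction = "none" if change == 0 else ("decrease" if change < 0 else "increase")
    return TrainingEffect(
        metric=dataset.metric,
        units=dataset.units,
        n=dataset.n,
        mean_pre=mean_pre,
        mean_post=mean_post,
        mean_change=eff.mean_diff,
        percent_change=100.0 * change / mean_pre,
        p_value=eff.p_value,
        d=eff.d,
        band=eff.band,
        direction=direction,
        degenerate=eff.degenerate,
    )


def sixmwt_effect(dataset: PrePostDataset, d_method: str = "pooled") -> TrainingEffect:
    """Six-minute-walk-test distance change; same contract as
    :func:`training_effect`, units fixed to metres."""
    ds = PrePostDataset(dataset.metric or "sixmwt_distance_m",
                        dataset.pre, dataset.post, units="m")
    return training_effect(ds, d_method=d_method)


def adherence_filter(
    attendance: Mapping[str, int],
    total_sessions: int = TRAINING_PROGRAM["total_sessions"],
    threshold_percent: float = TRAINING_PROGRAM["adherence_threshold_percent"],
) -> list[str]:
    """Participant ids attending at least ``threshold_percent`` of sessions."""
    retained = []
    for pid, count in attendance.items():
        if count < 0:
            raise DataValidationError(f"negative attendance for {pid}")
        if count > total_sessions:
            raise DataValidationError(f"attendance {count} exceeds {total_sessions} sessions")
        if 100.0 * count / total_sessions >= threshold_percent:
            retained.append(pid)
    return sorted(retained, key=str)


def _session_tables(trials, session):
    by_pid = defaultdict(dict)
    for tr in trials:
        if tr.session == session:
            by_pid[tr.participant_id][tr.distance_m] = tr
    return by_pid


def experiment2_report(
    trials: Sequence[EffortTrial],
    attendance: Mapping[str, int] | None = None,
    sixmwt: Mapping[str, tuple[float, float]] | None = None,
    baseline_session: Session = Session.pre,
    post_session: Session = Session.post,
    d_method: str = "pooled",
) -> TrainingEffectReport:
    """Full pre/post panel: per-distance times and heartbeats, CS, CHR and
    optionally the six-minute walk test.

    ``attendance`` maps participant id to sessions attended; participants
    below the adherence threshold (and those with incomplete trial sets)
    are excluded.  ``sixmwt`` maps participant id to (pre, post) distances
    in metres.  ``baseline_session`` names which session anchors the
    comparison (the protocol may anchor intensity prescription on a
    different visit than the statistical baseline).
    """
    pre_tab = _session_tables(trials, baseline_session)
    post_tab = _session_tables(trials, post_session)
    distances = sorted({tr.distance_m for tr in trials})

    pids = [
        pid for pid in sorted(set(pre_tab) | set(post_tab))
        if all(d in pre_tab.get(pid, {}) and d in post_tab.get(pid, {}) for d in distances)
    ]
    adherence: dict[str, float] = {}
    if attendance is not None:
        total = TRAINING_PROGRAM["total_sessions"]
        adherence = {pid: 100.0 * attendance.get(pid, 0) / total for pid in pids}
        kept = set(adherence_filter(attendance))
        dropped = [p for p in pids if p not in kept]
        if dropped:
            warnings.warn(f"excluded for low adherence: {dropped}")
        pids = [p for p in pids if p in kept]
    if len(pids) < 2:
        raise DataValidationError("fewer than 2 adherent participants with complete pre/post data")

    columns: dict[str, tuple[list[float], list[float], str]] = {}
    for d in distances:
        columns[f"time_{d:g}m_s"] = ([], [], "s")
        columns[f"hb_{d:g}m_beats"] = ([], [], "beats")
    columns["cs_m_per_s"] = ([], [], "m/s")
    columns["chr_bpm"] = ([], [], "b/min")

    for pid in pids:
        for i, tab in enumerate((pre_tab, post_tab)):
            for d in distances:
                tr = tab[pid][d]
                columns[f"time_{d:g}m_s"][i].append(tr.time_s)
                columns[f"hb_{d:g}m_beats"][i].append(total_heartbeats(tr))
            cs_fit, hr_fit = fit_trials([tab[pid][d] for d in distances])
            columns["cs_m_per_s"][i].append(cs_fit.slope)
            columns["chr_bpm"][i].append(hr_fit.slope)

    effects = [
        training_effect(
            PrePostDataset.from_arrays(metric, pre_vals, post_vals, units),
            d_method=d_method,
        )
        for metric, (pre_vals, post_vals, units) in columns.items()
    ]
    if sixmwt is not None:
        rows = [(pid, *sixmwt[pid]) for pid in pids if pid in sixmwt]
        if len(rows) >= 2:
            effects.append(sixmwt_effect(PrePostDataset.from_arrays(
                "sixmwt_distance_m",
                [r[1] for r in rows], [r[2] for r in rows], units="m",
            ), d_method=d_method))
    return TrainingEffectReport(tuple(effects), tuple(pids), adherence)
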
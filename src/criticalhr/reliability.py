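"""Test–retest reliability battery.

Given paired measurements from two sessions a week apart, this module
computes the full reproducibility panel used to validate field exercise
tests: paired-sample t comparison, Cohen's d with banded interpretation,
typical error (TE), coefficient of variation (CV%), intraclass correlation
(two-way ANOVA forms), standard error of measurement SEM = SD·√(1 − ICC) and
the minimal detectable change MDC = SEM·1.96·√2.

Effect-size bands follow a literal half-open reading of the convention
small (≤0.20), moderate (≤0.50), large (≤0.80), very large (>0.80), applied
to |d|.  Note this assigns "very large", not "large", to d just above 0.80;
the rule is applied uniformly and is deliberately documented here because
it inverts the more common "large ≥ 0.8" phrasing.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .critical_models import fit_trials
from .effort_metrics import total_heartbeats
from .errors import DataValidationError
from .hr_io import EffortTrial, Session

__all__ = [
    "PairedMeasurements",
    "PairedEffect",
    "ReliabilityReport",
    "MDC_FACTOR",
    "effect_band",
    "typical_error",
    "cv_percent",
    "icc",
    "icc_mean_squares",
    "sem",
    "mdc",
    "paired_effect",
    "reliability_report",
    "experiment1_battery",
    "holm_adjusted_p",
]

#: 1.96·√2 — multiplier turning SEM into the 95% minimal detectable change.
MDC_FACTOR = 1.96 * math.sqrt(2.0)

_ICC_FORMS = {
    "icc21": "two_way_random_absolute",
    "icc31": "two_way_mixed_consistency",
}
_ICC_ALIASES = {v: k for k, v in _ICC_FORMS.items()} | {k: k for k in _ICC_FORMS}


@dataclass(frozen=True)
class PairedMeasurements:
    """One metric measured in two sessions, paired by participant."""

    metric: str
    test: tuple[float, ...]
    retest: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.test) != len(self.retest):
            raise DataValidationError("sessions must have equal length")
        if len(self.test) < 2:
            raise DataValidationError("need at least 2 paired participants")

    @classmethod
    def from_arrays(cls, metric: str, test: Sequence[float],
                    retest: Sequence[float]) -> "PairedMeasurements":
        return cls(metric, tuple(float(x) for x in test),
                   tuple(float(x) for x in retest))

    @property
    def n(self) -> int:
        return len(self.test)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.test, float), np.asarray(self.retest, float)


@dataclass(frozen=True)
class PairedEffect:
    mean_diff: float
    t_stat: float
    p_value: float
    d: float
    band: str
    degenerate: bool = False  # zero-variance differences; p is a limit


def effect_band(d: float) -> str:
    a = abs(d)
    if a <= 0.20:
        return "small"
    if a <= 0.50:
        return "moderate"
    if a <= 0.80:
        return "large"
    return "very_large"


def typical_error(pairs: PairedMeasurements) -> float:
    """Within-subject SD: SD of difference scores (n−1) divided by √2."""
    test, retest = pairs.arrays()
    return float(np.std(test - retest, ddof=1) / math.sqrt(2.0))


def cv_percent(pairs: PairedMeasurements, method: str = "ratio") -> float:
    """Coefficient of variation of the measurement, in percent.

    ``ratio``: 100 · TE / grand mean.  ``log``: 100 · (exp(SD(Δlog)/√2) − 1),
    the log-scale typical error back-transformed (requires positive values).
    """
    test, retest = pairs.arrays()
    if method == "ratio":
        grand = float(np.mean(np.concatenate([test, retest])))
        if grand == 0.0:
            raise DataValidationError("grand mean is zero; CV% undefined")
        return 100.0 * typical_error(pairs) / grand
    if method == "log":
        if np.any(test <= 0) or np.any(retest <= 0):
            raise DataValidationError("log-method CV% requires positive values")
        dlog = np.log(test) - np.log(retest)
        return 100.0 * (math.exp(float(np.std(dlog, ddof=1)) / math.sqrt(2.0)) - 1.0)
    raise ValueError(f"unknown CV method {method!r}")


def icc_mean_squares(pairs: PairedMeasurements) -> dict[str, float]:
    """Two-way (participant × session) ANOVA mean squares."""
    x = np.column_stack(pairs.arrays())  # n × k
    n, k = x.shape
    grand = x.mean()
    msr = k * float(np.var(x.mean(axis=1), ddof=1))          # rows: participants
    msc = n * float(np.var(x.mean(axis=0), ddof=1))          # cols: sessions
    sst = float(((x - grand) ** 2).sum())
    sse = sst - msr * (n - 1) - msc * (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return {"msr": msr, "msc": msc, "mse": max(mse, 0.0), "n": n, "k": k}


def icc(pairs: PairedMeasurements, form: str = "icc21") -> float:
    """Intraclass correlation from the two-way decomposition.

    ``icc21`` (= two_way_random_absolute): single-measurement absolute
    agreement, sessions a random factor.  ``icc31`` (=
    two_way_mixed_consistency): single-measurement consistency, sessions
    fixed.  Returns NaN (with a warning) when between-participant variance
    is zero, where the ratio is undefined.
    """
    key = _ICC_ALIASES.get(form)
    if key is None:
        raise ValueError(f"unknown ICC form {form!r}")
    ms = icc_mean_squares(pairs)
    msr, msc, mse, n, k = ms["msr"], ms["msc"], ms["mse"], ms["n"], ms["k"]
    if msr == 0.0 and mse == 0.0:
        warnings.warn(f"{pairs.metric}: zero between-participant variance; ICC undefined")
        return float("nan")
    if key == "icc21":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    if denom <= 0.0:
        warnings.warn(f"{pairs.metric}: degenerate variance structure; ICC undefined")
        return float("nan")
    return float((msr - mse) / denom)


def sem(sd: float, icc_value: float) -> float:
    """Standard error of measurement, SD·√(1 − ICC)."""
    if icc_value > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if math.isnan(icc_value):
        return float("nan")
    return sd * math.sqrt(1.0 - icc_value)


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence, SEM·1.96·√2."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return sem_value * MDC_FACTOR


def paired_effect(pairs: PairedMeasurements, d_method: str = "pooled") -> PairedEffect:
    """Two-sided paired t with Cohen's d.

    ``d_method='pooled'`` divides the mean difference by the pooled SD of
    the two sessions; ``'dz'`` divides by the SD of the differences.
    """
    test, retest = pairs.arrays()
    diff = test - retest
    mean_diff = float(diff.mean())
    sd_diff = float(np.std(diff, ddof=1))
    s1, s2 = float(np.std(test, ddof=1)), float(np.std(retest, ddof=1))
    pooled = math.sqrt((s1 ** 2 + s2 ** 2) / 2.0)

    degenerate = sd_diff == 0.0
    if degenerate:
        t_stat = 0.0 if mean_diff == 0.0 else math.copysign(math.inf, mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        t_stat, p = (float(v) for v in stats.ttest_rel(test, retest))

    denom = pooled if d_method == "pooled" else sd_diff
    if d_method not in {"pooled", "dz"}:
        raise ValueError(f"unknown effect-size method {d_method!r}")
    d = 0.0 if mean_diff == 0.0 else (math.inf if denom == 0.0 else mean_diff / denom)
    return PairedEffect(mean_diff, t_stat, p, d, effect_band(d), degenerate)


@dataclass(frozen=True)
class ReliabilityReport:
    """Full test–retest panel for one metric."""

    metric: str
    n: int
    mean_test: float
    mean_retest: float
    mean_diff: float
    p_value: float
    effect_size_d: float
    effect_band: str
    te: float
    cv_percent: float
    icc: float
    icc_form: str
    icc_consistency: float      # ICC(3,1), always reported alongside
    sd_used: float              # the SD entering SEM
    sem: float
    mdc: float


def reliability_report(
    pairs: PairedMeasurements,
    icc_form: str = "icc21",
    cv_method: str = "ratio",
    sem_sd: str = "pooled",
    d_method: str = "pooled",
) -> ReliabilityReport:
    """Compute the whole panel for one paired metric.

    ``sem_sd`` selects the SD entering SEM: ``'pooled'`` (root mean of the
    two session variances, default) or ``'test'`` (first-session SD only).
    """
    test, retest = pairs.arrays()
    eff = paired_effect(pairs, d_method=d_method)
    te = typical_error(pairs)
    icc_primary = icc(pairs, form=icc_form)
    icc31 = icc(pairs, form="icc31")
    if sem_sd == "pooled":
        sd_used = math.sqrt(
            (np.std(test, ddof=1) ** 2 + np.std(retest, ddof=1) ** 2) / 2.0
        )
    elif sem_sd == "test":
        sd_used = float(np.std(test, ddof=1))
    else:
        raise ValueError(f"unknown sem_sd choice {sem_sd!r}")
    sem_value = sem(sd_used, icc_primary)
    return ReliabilityReport(
        metric=pairs.metric,
        n=pairs.n,
        mean_test=float(test.mean()),
        mean_retest=float(retest.mean()),
        mean_diff=eff.mean_diff,
        p_value=eff.p_value,
        effect_size_d=eff.d,
        effect_band=eff.band,
        te=te,
        cv_percent=cv_percent(pairs, method=cv_method),
        icc=icc_primary,
        icc_form=_ICC_ALIASES[icc_form],
        icc_consistency=icc31,
        sd_used=float(sd_used),
        sem=sem_value,
        mdc=mdc(sem_value) if not math.isnan(sem_value) else float("nan"),
    )


def _session_tables(
    trials: Sequence[EffortTrial], session: Session
) -> dict[str, dict[float, EffortTrial]]:
    by_pid: dict[str, dict[float, EffortTrial]] = defaultdict(dict)
    for tr in trials:
        if tr.session == session:
            by_pid[tr.participant_id][tr.distance_m] = tr
    return by_pid


def experiment1_battery(
    trials: Sequence[EffortTrial],
    session_a: Session = Session.test,
    session_b: Session = Session.retest,
    **report_options,
) -> dict[str, ReliabilityReport]:
    """Reliability reports for the whole protocol.

    Produces one report per metric: time and total heartbeats at every
    distance, plus the fitted critical speed and critical HR.  Participants
    missing either session (or any distance within one) are dropped with a
    warning.
    """
    a_tab, b_tab = _session_tables(trials, session_a), _session_tables(trials, session_b)
    distances = sorted({tr.distance_m for tr in trials})
    pids = []
    for pid in sorted(set(a_tab) | set(b_tab)):
        if all(d in a_tab.get(pid, {}) and d in b_tab.get(pid, {}) for d in distances):
            pids.append(pid)
        else:
            warnings.warn(f"participant {pid}: incomplete sessions; dropped from reliability")
    if len(pids) < 2:
        raise DataValidationError("fewer than 2 participants with complete paired sessions")

    values: dict[str, tuple[list[float], list[float]]] = defaultdict(lambda: ([], []))
    for pid in pids:
        for i, tab in enumerate((a_tab, b_tab)):
            for d in distances:
                tr = tab[pid][d]
                values[f"time_{d:g}m_s"][i].append(tr.time_s)
                values[f"hb_{d:g}m_beats"][i].append(total_heartbeats(tr))
            cs_fit, hr_fit = fit_trials([tab[pid][d] for d in distances])
            values["cs_m_per_s"][i].append(cs_fit.slope)
            values["chr_bpm"][i].append(hr_fit.slope)

    return {
        metric: reliability_report(
            PairedMeasurements.from_arrays(metric, a_vals, b_vals), **report_options
        )
        for metric, (a_vals, b_vals) in values.items()
    }


def holm_adjusted_p(p_values: Mapping[str, float]) -> dict[str, float]:
    """Optional Holm step-down adjustment across a family of paired tests."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    out, running = {}, 0.0
    for i, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        out[name] = running
    return {k: out[k] for k in p_values}
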
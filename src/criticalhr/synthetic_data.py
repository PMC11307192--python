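"""Synthetic cohorts with known ground truth.

Simulated participants carry true critical speed CS and distance reserve D′,
so a maximal effort over distance d takes (d − D′)/CS seconds, perturbed by
multiplicative lognormal timing noise (unit mean).  Heart rate during an
effort follows a mono-exponential on-response with linear cardiovascular
drift,

    HR(t) = rest + amplitude · (1 − e^(−t/τ)) + drift · t/60,

clipped at the participant's age-predicted maximal HR and emitted as
window-average samples.  Because total heartbeats derived from this trace
are not exactly linear in time, the participant's *true* critical heart rate
and heartbeat reserve are defined as the closed-form least-squares line
through the noiseless heartbeat counts at the protocol distances (computed
here from the normal equations, independently of the fitting module), which
makes zero-noise recovery an end-to-end pipeline check.

The default configuration mirrors the validation-study conditions: 15
participants, 400/800/1200 m in random order, two sessions, 5-s HR
averaging, 2% timing noise, 15% between-participant CS variability, and a
training effect of −8/−4/−2% on effort times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError
from .hr_io import CohortRow, EffortTrial, HRSample, HRSeries, Session, load_reference_cohort

__all__ = [
    "SimulatedParticipant",
    "SimulationConfig",
    "SimulatedDataset",
    "hr_trace",
    "simulate_effort",
    "simulate_cohort",
    "fitted_parameters",
    "make_table1_fixture",
]


class SimulatedParticipant(BaseModel):
    """Ground-truth parameters for one simulated walker."""

    participant_id: str
    age_years: float = Field(gt=0)
    true_cs_m_per_s: float = Field(gt=0)
    true_dprime_m: float = Field(gt=0)
    true_chr_bpm: float = Field(gt=0)
    # the heartbeat reserve can legitimately come out negative: drift makes
    # heartbeat totals mildly convex in time, pulling the fitted intercept down
    true_hbprime_beats: float
    hr_rest_bpm: float = Field(gt=0)
    hr_amplitude_bpm: float = Field(gt=0)
    hr_max_bpm: float = Field(gt=0)
    tau_s: float
    drift_bpm_per_min: float = Field(ge=0)
    timing_noise_cv: float = Field(ge=0)

    @field_validator("tau_s")
    @classmethod
    def _tau_range(cls, v: float) -> float:
        if not 10.0 < v < 120.0:
            raise ValueError("tau_s must lie in (10, 120) s")
        return v

    @model_validator(mode="after")
    def _chr_physiologic(self) -> "SimulatedParticipant":
        # CHR is a heartbeat-per-minute slope; over protocol durations it can
        # sit above the kinetic plateau by roughly drift x mean effort
        # duration, so the bound allows the drift contribution over 30 min,
        # plus 1 bpm of slack for the discretized window-average sampling.
        ceiling = (self.hr_rest_bpm + self.hr_amplitude_bpm
                   + 30.0 * self.drift_bpm_per_min + 1.0)
        if self.true_chr_bpm >= ceiling:
            raise ValueError("true CHR exceeds achievable HR over protocol durations")
        return self


class SimulationConfig(BaseModel):
    """Cohort-level generator settings; the defaults are the study design."""

    n_participants: int = Field(default=15, ge=1)
    distances_m: tuple[float, ...] = (400.0, 800.0, 1200.0)
    seed: int = Field(default=0, ge=0)
    design: str = "experiment1"          # experiment1 | experiment2 | both
    cs_mean: float = Field(default=1.25, gt=0)      # m/s
    cs_sd: float = Field(default=0.1875, ge=0)      # 15% between-participant CV
    dprime_mean: float = Field(default=30.0, gt=0)  # m
    dprime_sd: float = Field(default=10.0, ge=0)
    age_mean: float = 72.0
    age_sd: float = 7.0
    hr_rest_mean: float = 75.0
    hr_rest_sd: float = 8.0
    chr_fraction_of_hrmax: float = Field(default=0.70, gt=0, lt=1)
    hrmax_formula: str = "tanaka"
    tau_mean_s: float = 45.0
    tau_sd_s: float = 12.0
    drift_mean_bpm_per_min: float = 0.5
    drift_sd_bpm_per_min: float = 0.3
    retest_noise_cv: float = Field(default=0.02, ge=0)
    training_time_reduction_percent: dict[float, float] = Field(
        default_factory=lambda: {400.0: 8.0, 800.0: 4.0, 1200.0: 2.0}
    )
    sampling_interval_s: float = Field(default=5.0, gt=0)

    @field_validator("distances_m")
    @classmethod
    def _distinct_positive(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(d <= 0 for d in v) or len(set(v)) != len(v):
            raise ValueError("distances must be positive and distinct")
        return v

    @field_validator("design")
    @classmethod
    def _known_design(cls, v: str) -> str:
        if v not in {"experiment1", "experiment2", "both"}:
            raise ValueError("design must be experiment1, experiment2 or both")
        return v


@dataclass
class SimulatedDataset:
    participants: list[SimulatedParticipant]
    trials: list[EffortTrial]
    config: SimulationConfig

    def truth(self) -> dict[str, SimulatedParticipant]:
        return {p.participant_id: p for p in self.participants}


def hr_trace(
    duration_s: float,
    hr_rest: float,
    hr_amplitude: float,
    tau_s: float,
    drift_bpm_per_min: float,
    interval_s: float = 5.0,
    hr_ceiling: float | None = None,
) -> HRSeries:
    """Window-average HR samples for one effort.

    Each sample is stamped at the end of its averaging window and holds the
    kinetic model evaluated at the window midpoint (the last, possibly
    partial, window is averaged over what remains of the effort).
    """
    if duration_s <= 0:
        raise ConfigError("effort duration must be positive")
    n_windows = max(1, math.ceil(duration_s / interval_s - 1e-9))
    ends = interval_s * np.arange(1, n_windows + 1)
    mids = (np.minimum(ends, duration_s) + (ends - interval_s)) / 2.0
    hr = hr_rest + hr_amplitude * (1.0 - np.exp(-mids / tau_s)) \
        + drift_bpm_per_min * mids / 60.0
    if hr_ceiling is not None:
        hr = np.minimum(hr, hr_ceiling)
    samples = [HRSample(elapsed_s=float(t), hr_bpm=float(h)) for t, h in zip(ends, hr)]
    return HRSeries(samples=samples, sampling_interval_s=interval_s)


def _noiseless_time(participant: SimulatedParticipant, distance_m: float) -> float:
    if distance_m <= participant.true_dprime_m:
        raise ConfigError(
            f"distance {distance_m:g} m does not exceed D' = "
            f"{participant.true_dprime_m:g} m"
        )
    return (distance_m - participant.true_dprime_m) / participant.true_cs_m_per_s


def simulate_effort(
    participant: SimulatedParticipant,
    distance_m: float,
    rng: np.random.Generator | None = None,
    session: Session = Session.test,
    time_scale: float = 1.0,
    sampling_interval_s: float = 5.0,
) -> EffortTrial:
    """One maximal effort: noisy time from the distance–time line, HR trace
    from the kinetic model.  ``time_scale`` < 1 models a training-induced
    speed-up; ``rng=None`` (or zero noise CV) yields the noiseless time."""
    base = _noiseless_time(participant, distance_m) * time_scale
    cv = participant.timing_noise_cv
    if rng is not None and cv > 0:
        sigma = math.sqrt(math.log1p(cv * cv))
        factor = math.exp(rng.normal(-0.5 * sigma * sigma, sigma))
    else:
        factor = 1.0
    time_s = base * factor
    series = hr_trace(
        time_s, participant.hr_rest_bpm, participant.hr_amplitude_bpm,
        participant.tau_s, participant.drift_bpm_per_min,
        interval_s=sampling_interval_s, hr_ceiling=participant.hr_max_bpm,
    )
    return EffortTrial(
        participant_id=participant.participant_id, session=session,
        distance_m=distance_m, time_s=time_s, series=series,
    )


def _normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xb, yb = x.mean(), y.mean()
    slope = float(((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum())
    return slope, float(yb - slope * xb)


def _hb_from_series(series: HRSeries, time_s: float) -> float:
    return float(np.mean(series.hr_bpm)) * time_s / 60.0


def _draw_participant(config: SimulationConfig, rng: np.random.Generator,
                      idx: int) -> SimulatedParticipant:
    from .critical_models import predicted_hrmax

    # floor at a slow-but-ambulatory critical speed so effort durations stay
    # within a plausible field-test range
    cs = max(rng.normal(config.cs_mean, config.cs_sd), 0.7)
    dprime = float(np.clip(rng.normal(config.dprime_mean, config.dprime_sd), 5.0, 150.0))
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 55.0, 90.0))
    hrmax = predicted_hrmax(age, config.hrmax_formula)
    rest = float(np.clip(rng.normal(config.hr_rest_mean, config.hr_rest_sd), 50.0, 110.0))
    amplitude = max(config.chr_fraction_of_hrmax * hrmax - rest, 15.0)
    tau = float(np.clip(rng.normal(config.tau_mean_s, config.tau_sd_s), 12.0, 115.0))
    drift = float(np.clip(
        rng.normal(config.drift_mean_bpm_per_min, config.drift_sd_bpm_per_min), 0.0, 2.0))

    # ground-truth CHR/HB' := least-squares line through the noiseless
    # heartbeat counts at the protocol distances (normal equations, kept
    # independent of the fitting module's code path)
    times = np.array([(d - dprime) / cs for d in config.distances_m])
    if np.any(times <= 0):
        raise ConfigError("every protocol distance must exceed D'")
    hbs = []
    for t in times:
        series = hr_trace(t, rest, amplitude, tau, drift,
                          interval_s=config.sampling_interval_s, hr_ceiling=hrmax)
        hbs.append(_hb_from_series(series, t))
    chr_bpm, hbprime = _normal_equations(times / 60.0, np.array(hbs))

    return SimulatedParticipant(
        participant_id=f"sim{idx + 1:03d}",
        age_years=age,
        true_cs_m_per_s=float(cs),
        true_dprime_m=dprime,
        true_chr_bpm=chr_bpm,
        true_hbprime_beats=hbprime,
        hr_rest_bpm=rest,
        hr_amplitude_bpm=amplitude,
        hr_max_bpm=hrmax,
        tau_s=tau,
        drift_bpm_per_min=drift,
        timing_noise_cv=config.retest_noise_cv,
    )


_DESIGN_SESSIONS = {
    "experiment1": (Session.test, Session.retest),
    "experiment2": (Session.pre, Session.post),
    "both": (Session.test, Session.retest, Session.pre, Session.post),
}


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate a full cohort under the configured design.

    Each participant performs every distance once per session, in random
    order within the session.  Retest re-samples timing noise only.  Post
    (training) sessions shorten effort times by the configured per-distance
    percentages; heartbeat totals fall with them because the HR kinetics are
    unchanged over a shorter effort.  Identical seed and config give an
    identical dataset.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants + 1)
    draw_rng = np.random.default_rng(children[0])
    participants = [
        _draw_participant(config, draw_rng, i) for i in range(config.n_participants)
    ]
    reductions = {float(k): v for k, v in config.training_time_reduction_percent.items()}
    trials: list[EffortTrial] = []
    for i, participant in enumerate(participants):
        prng = np.random.default_rng(children[i + 1])
        for session in _DESIGN_SESSIONS[config.design]:
            order = prng.permutation(len(config.distances_m))
            for j in order:
                d = config.distances_m[j]
                scale = 1.0
                if session is Session.post:
                    scale = 1.0 - reductions.get(float(d), 0.0) / 100.0
                trials.append(simulate_effort(
                    participant, d, rng=prng, session=session, time_scale=scale,
                    sampling_interval_s=config.sampling_interval_s,
                ))
    return SimulatedDataset(participants, trials, config)


def fitted_parameters(
    trials: Sequence[EffortTrial], session: Session
) -> dict[str, dict[str, float]]:
    """Per-participant fitted CS/D′/CHR/HB′ for one session's trials."""
    from .critical_models import fit_trials

    by_pid: dict[str, list[EffortTrial]] = {}
    for tr in trials:
        if tr.session == session:
            by_pid.setdefault(tr.participant_id, []).append(tr)
    out = {}
    for pid, tlist in by_pid.items():
        tlist = sorted(tlist, key=lambda tr: tr.distance_m)
        cs_fit, hr_fit = fit_trials(tlist)
        out[pid] = {
            "cs_m_per_s": cs_fit.slope, "dprime_m": cs_fit.intercept,
            "chr_bpm": hr_fit.slope, "hbprime_beats": hr_fit.intercept,
            "r2_speed": cs_fit.r_squared, "r2_hr": hr_fit.r_squared,
        }
    return out


def make_table1_fixture() -> list[CohortRow]:
    """The packaged reference cohort (15 rows; 8 flagged for the training
    arm), for tests and examples that need realistic characteristics."""
    return load_reference_cohort()
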
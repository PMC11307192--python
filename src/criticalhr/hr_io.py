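"""Readers and writers for heart-rate series, effort metadata, cohort tables
and reports.

All schema and unit enforcement happens here, at the package boundary.  Heart
rate comes in as plain CSV with two numeric columns (elapsed seconds from
effort start, HR in beats per minute); each sample is the average over the
preceding recording window (5 s by default) and its timestamp marks the *end*
of that window.  Cohort tables are TSV/CSV with one row per participant.
Reports serialize to JSON or to flat TSV with dotted keys.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import warnings
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ParseError, SchemaError, DataValidationError

__all__ = [
    "HRSample",
    "HRSeries",
    "Session",
    "EffortTrial",
    "CohortRow",
    "read_hr_series",
    "write_hr_series",
    "read_cohort_table",
    "write_cohort_table",
    "load_reference_cohort",
    "load_reference_annotations",
    "write_report",
    "read_report",
    "read_config",
    "write_dataset",
    "read_dataset",
]

#: Plausibility window for a single HR sample, beats per minute (open interval).
HR_PLAUSIBLE_BPM = (20.0, 250.0)

DEFAULT_SAMPLING_INTERVAL_S = 5.0


class HRSample(BaseModel):
    """One recorded heart-rate value: window-average HR at ``elapsed_s``."""

    elapsed_s: float = Field(ge=0.0)
    hr_bpm: float = Field(gt=0.0)

    @property
    def plausible(self) -> bool:
        lo, hi = HR_PLAUSIBLE_BPM
        return lo < self.hr_bpm < hi


class HRSeries(BaseModel):
    """A heart-rate recording for a single effort.

    Timestamps are effort-relative seconds, strictly increasing; a sample's
    timestamp marks the end of its averaging window.  Gaps larger than the
    sampling interval are tolerated (and reported by :meth:`gaps`) but never
    imputed.
    """

    samples: list[HRSample]
    sampling_interval_s: float = Field(default=DEFAULT_SAMPLING_INTERVAL_S, gt=0.0)

    @model_validator(mode="after")
    def _check_monotone(self) -> "HRSeries":
        t = [s.elapsed_s for s in self.samples]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("elapsed_s must be strictly increasing")
        return self

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def elapsed_s(self) -> np.ndarray:
        return np.array([s.elapsed_s for s in self.samples], dtype=float)

    @property
    def hr_bpm(self) -> np.ndarray:
        return np.array([s.hr_bpm for s in self.samples], dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples[-1].elapsed_s if self.samples else 0.0

    def mean_hr(self) -> float:
        """Unweighted mean of the window-average samples."""
        if not self.samples:
            raise DataValidationError("empty HR series")
        return float(np.mean(self.hr_bpm))

    def max_hr(self) -> float:
        if not self.samples:
            raise DataValidationError("empty HR series")
        return float(np.max(self.hr_bpm))

    def implausible_samples(self) -> list[HRSample]:
        return [s for s in self.samples if not s.plausible]

    def gaps(self, tolerance: float = 1e-9) -> list[tuple[float, float]]:
        """Intervals between consecutive samples longer than the interval."""
        t = self.elapsed_s
        out = []
        for a, b in zip(t, t[1:]):
            if b - a > self.sampling_interval_s + tolerance:
                out.append((float(a), float(b)))
        return out


class Session(str, enum.Enum):
    """Which visit a trial belongs to."""

    test = "test"
    retest = "retest"
    pre = "pre"
    post = "post"


class EffortTrial(BaseModel):
    """One timed maximal walking effort with its HR recording."""

    participant_id: str
    session: Session
    distance_m: float = Field(gt=0.0)
    time_s: float = Field(gt=0.0)
    series: HRSeries

    @model_validator(mode="after")
    def _check_series_span(self) -> "EffortTrial":
        if self.series.samples:
            last = self.series.samples[-1].elapsed_s
            if last > self.time_s + self.series.sampling_interval_s:
                raise ValueError(
                    f"last HR sample at {last:.1f}s exceeds stopwatch time "
                    f"{self.time_s:.1f}s by more than one sampling interval"
                )
        return self


class CohortRow(BaseModel):
    """One participant's descriptive characteristics."""

    id: str
    sex: str = Field(pattern="^[MF]$")
    age_years: float = Field(ge=0)
    height_m: float = Field(ge=0)
    mass_kg: float = Field(ge=0)
    updrs2: float = Field(ge=0)
    updrs3: float = Field(ge=0)
    hy: float
    mmse: float = Field(ge=0)
    tmt_a_s: float = Field(ge=0)
    tmt_b_s: float = Field(ge=0)
    tug_s: float = Field(ge=0)
    in_experiment2: bool = False

    @field_validator("hy")
    @classmethod
    def _check_hy(cls, v: float) -> float:
        if not (1.0 <= v <= 5.0) or round(v * 2) != v * 2:
            raise ValueError("Hoehn & Yahr stage must lie in [1, 5] in 0.5 steps")
        return v


# ---------------------------------------------------------------------------
# HR series I/O
# ---------------------------------------------------------------------------

def _looks_like_header(line: str, sep: str) -> bool:
    for tok in line.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_hr_series(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sampling_interval_s: float = DEFAULT_SAMPLING_INTERVAL_S,
    sep: str = ",",
) -> HRSeries:
    """Read an HR recording from CSV.

    ``dialect`` maps the logical columns to file column names, e.g.
    ``{"elapsed": "t", "hr": "pulse"}``; defaults to ``elapsed_s``/``hr_bpm``.
    Headerless two-column numeric files are accepted positionally.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise SchemaError(f"{path}: empty HR file")

    has_header = _looks_like_header(first, sep)
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc

    if has_header:
        names = {"elapsed": "elapsed_s", "hr": "hr_bpm"}
        if dialect:
            names.update(dialect)
        missing = [c for c in names.values() if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        df = df[[names["elapsed"], names["hr"]]]
    else:
        if df.shape[1] < 2:
            raise SchemaError(f"{path}: need two columns (elapsed_s, hr_bpm)")
        df = df.iloc[:, :2]
    df.columns = ["elapsed_s", "hr_bpm"]

    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2 if has_header else 1):
        try:
            t, hr = float(row.elapsed_s), float(row.hr_bpm)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric cell at row {i}") from exc
        if math.isnan(t) or math.isnan(hr):
            raise ParseError(f"{path}: missing value at row {i}")
        samples.append(HRSample(elapsed_s=t, hr_bpm=hr))
    try:
        series = HRSeries(samples=samples, sampling_interval_s=sampling_interval_s)
    except pydantic.ValidationError as exc:
        raise DataValidationError(f"{path}: {exc.errors()[0]['msg']}") from exc
    for a, b in series.gaps():
        warnings.warn(f"{path}: gap in HR recording between {a:.0f}s and {b:.0f}s")
    return series


def write_hr_series(series: HRSeries, path: str | Path) -> None:
    df = pd.DataFrame({"elapsed_s": series.elapsed_s, "hr_bpm": series.hr_bpm})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "id", "sex", "age_years", "height_m", "mass_kg", "updrs2", "updrs3",
    "hy", "mmse", "tmt_a_s", "tmt_b_s", "tug_s", "in_experiment2",
]


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read a participant-characteristics table (TSV or CSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        warnings.warn(f"{path}: empty cohort table")
        return []
    df = pd.read_csv(path, sep=None, engine="python")
    unknown = [c for c in df.columns if c not in _COHORT_COLUMNS]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns and c != "in_experiment2"]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    rows = []
    for rec in df.to_dict("records"):
        rec["id"] = str(rec["id"])
        if "in_experiment2" in rec:
            rec["in_experiment2"] = bool(int(rec["in_experiment2"]))
        try:
            rows.append(CohortRow(**rec))
        except pydantic.ValidationError as exc:
            err = exc.errors()[0]
            raise DataValidationError(
                f"{path}: participant {rec['id']}: {err['loc']}: {err['msg']}"
            ) from exc
    return rows


def write_cohort_table(rows: Iterable[CohortRow], path: str | Path) -> None:
    df = pd.DataFrame([r.model_dump() for r in rows])
    df["in_experiment2"] = df["in_experiment2"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_reference_cohort() -> list[CohortRow]:
    """The packaged reference cohort: 15 people with idiopathic Parkinson's
    disease from a published validation study of the walking protocol; the 8
    participants flagged ``in_experiment2`` completed the training arm."""
    return read_cohort_table(_data_path("pd_cohort.tsv"))


def load_reference_annotations() -> dict:
    """Printed group-summary cells for the reference cohort and the list of
    printed cells known not to equal the column statistics of the rows."""
    with open(_data_path("pd_cohort_printed_summary.json")) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Reports and configs
# ---------------------------------------------------------------------------

def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, BaseModel):
        return _to_plain(obj.model_dump())
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            for i, x in enumerate(v):
                if isinstance(x, Mapping):
                    out.update(_flatten(x, f"{key}.{i}."))
                else:
                    out[f"{key}.{i}"] = x
        else:
            out[key] = v
    return out


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a report (dataclass, model or mapping) to JSON or flat TSV.

    TSV flattens nested structure into dotted keys, one column per leaf.
    """
    plain = _to_plain(report)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(plain, fh, indent=2, allow_nan=True)
            fh.write("\n")
    elif format == "tsv":
        flat = _flatten(plain)
        with open(path, "w") as fh:
            fh.write("\t".join(flat) + "\n")
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in flat.values()) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str | None = None) -> dict[str, Any]:
    path = Path(path)
    fmt = format or ("tsv" if path.suffix == ".tsv" else "json")
    if fmt == "json":
        with open(path) as fh:
            return json.load(fh)
    header, values = Path(path).read_text().splitlines()[:2]
    out: dict[str, Any] = {}
    for k, v in zip(header.split("\t"), values.split("\t")):
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = {"True": True, "False": False, "None": None}.get(v, v)
    return out


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a JSON or YAML run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text) or {}
    return json.loads(text)


# ---------------------------------------------------------------------------
# Trial datasets on disk
# ---------------------------------------------------------------------------

def write_dataset(trials: Sequence[EffortTrial], out_dir: str | Path,
                  extra: Mapping[str, Any] | None = None) -> Path:
    """Write a set of trials as ``trials.tsv`` + one HR CSV per trial.

    ``extra`` (e.g. ground-truth parameters, config echo) is written as
    ``meta.json`` alongside.
    """
    out_dir = Path(out_dir)
    (out_dir / "hr").mkdir(parents=True, exist_ok=True)
    records = []
    for trial in trials:
        hr_name = f"hr/{trial.participant_id}_{trial.session.value}_{int(trial.distance_m)}.csv"
        write_hr_series(trial.series, out_dir / hr_name)
        records.append({
            "participant_id": trial.participant_id,
            "session": trial.session.value,
            "distance_m": trial.distance_m,
            "time_s": trial.time_s,
            "hr_file": hr_name,
            "sampling_interval_s": trial.series.sampling_interval_s,
        })
    pd.DataFrame(records).to_csv(out_dir / "trials.tsv", sep="\t", index=False)
    if extra is not None:
        write_report(extra, out_dir / "meta.json", "json")
    return out_dir


def read_dataset(in_dir: str | Path) -> list[EffortTrial]:
    """Read back a trial dataset written by :func:`write_dataset` (or built
    by hand in the same layout)."""
    in_dir = Path(in_dir)
    index = in_dir / "trials.tsv"
    if not index.exists():
        raise FileNotFoundError(index)
    df = pd.read_csv(index, sep="\t")
    trials = []
    for rec in df.to_dict("records"):
        series = read_hr_series(
            in_dir / rec["hr_file"],
            sampling_interval_s=float(rec.get("sampling_interval_s", DEFAULT_SAMPLING_INTERVAL_S)),
        )
        trials.append(EffortTrial(
            participant_id=str(rec["participant_id"]),
            session=Session(rec["session"]),
            distance_m=float(rec["distance_m"]),
            time_s=float(rec["time_s"]),
            series=series,
        ))
    return trials
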
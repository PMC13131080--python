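"""Readers and writers for the three measurement streams and the results.

All readers parse plain long-format CSV (RFC-4180, configurable decimal
separator and column names) into validated in-memory containers; no
computation happens here beyond parsing and unit bookkeeping.  Vendor
exports (spirometer, linear position transducer) are adapted through the
column-mapping arguments rather than through vendor-specific parsers.

Schemas
-------
breath.csv      one row per breath: ``time_s, vo2``
reps.csv        one row per repetition: ``set_index, rep_index, mpv_m_s``
lactate.csv     one row per sample: ``sample, offset_s, value_mmol_l``
                where ``sample`` is ``baseline``, ``pre_final_set`` or
                ``post`` (``offset_s`` = seconds after recovery start,
                used for post samples only)
marks.csv       two columns ``key, value`` with keys ``exercise_start_s``
                and ``recovery_start_s``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VO2_UNITS",
    "BreathSeries",
    "ParticipantInfo",
    "LactatePanel",
    "RepetitionTable",
    "PhaseMarks",
    "ParseError",
    "read_breath_csv",
    "read_repetition_csv",
    "read_lactate_csv",
    "read_marks",
    "write_report",
]

#: Accepted V-dot-O2 units for raw breath data.
VO2_UNITS = ("L/min", "mL/min", "mL/kg/min")


class ParseError(ValueError):
    """Malformed or invariant-violating input file."""


@dataclass
class BreathSeries:
    """Raw irregular breath-by-breath oxygen-uptake samples.

    ``time_s`` is on the session clock (t = 0 at baseline start) and must be
    strictly increasing; ``vo2`` carries the declared ``unit`` unchanged —
    conversion to L/s happens in :mod:`ergopart.kinetics`.
    """

    time_s: np.ndarray
    vo2: np.ndarray
    unit: str
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.unit not in VO2_UNITS:
            raise ParseError(f"unit must be one of {VO2_UNITS}, got {self.unit!r}")
        if self.time_s.shape != self.vo2.shape or self.time_s.ndim != 1:
            raise ParseError("time_s and vo2 must be 1-d arrays of equal length")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            bad = int(np.flatnonzero(np.diff(self.time_s) <= 0)[0]) + 1
            raise ParseError(f"breath times not strictly increasing at row {bad + 1}")
        if np.any(self.vo2 < 0):
            raise ParseError("negative vo2 sample")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def span_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class ParticipantInfo:
    id: str
    body_mass_kg: float
    sex: str = "unspecified"
    squat_1rm_kg: float | None = None

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ParseError("body_mass_kg must be > 0")
        if self.sex not in ("F", "M", "unspecified"):
            raise ParseError("sex must be 'F', 'M' or 'unspecified'")


@dataclass(frozen=True)
class LactatePanel:
    """Blood lactate samples: baseline, optional pre-final-set, post series.

    ``post_mmol_l`` maps seconds-after-recovery-start (the study sampled at
    +60, +180 and +300 s) to concentration.  The pre-final-set sample is
    quality control only; no energy formula consumes it.
    """

    baseline_mmol_l: float
    post_mmol_l: Mapping[int, float]
    pre_final_set_mmol_l: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_mmol_l < 0:
            raise ParseError("baseline lactate must be >= 0")
        if not self.post_mmol_l:
            raise ParseError("at least one post-exercise lactate sample is required")
        if any(v < 0 for v in self.post_mmol_l.values()):
            raise ParseError("negative lactate concentration")
        if self.pre_final_set_mmol_l is not None and self.pre_final_set_mmol_l < 0:
            raise ParseError("negative lactate concentration")

    @property
    def peak_post_mmol_l(self) -> float:
        return max(self.post_mmol_l.values())

    @property
    def rise_mmol_l(self) -> float:
        """Baseline-to-peak net rise; may be negative (policy applied later)."""
        return self.peak_post_mmol_l - self.baseline_mmol_l


@dataclass
class RepetitionTable:
    """Per-repetition mean propulsive velocity (MPV) grid for one session."""

    frame: pd.DataFrame  # columns: set_index, rep_index, mpv_m_s

    def __post_init__(self) -> None:
        required = {"set_index", "rep_index", "mpv_m_s"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParseError(f"repetition table missing columns: {sorted(missing)}")
        f = self.frame.copy()
        f["set_index"] = f["set_index"].astype(int)
        f["rep_index"] = f["rep_index"].astype(int)
        f["mpv_m_s"] = f["mpv_m_s"].astype(float)
        if (f["mpv_m_s"] <= 0).any():
            raise ParseError("mpv_m_s must be > 0")
        if f.duplicated(["set_index", "rep_index"]).any():
            dup = f[f.duplicated(["set_index", "rep_index"])].iloc[0]
            raise ParseError(
                f"duplicate repetition (set {dup.set_index}, rep {dup.rep_index})"
            )
        self.frame = f.sort_values(["set_index", "rep_index"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def set_indices(self) -> list[int]:
        return sorted(int(s) for s in self.frame["set_index"].unique())

    def set_mpv(self, set_index: int) -> np.ndarray:
        sub = self.frame[self.frame["set_index"] == set_index]
        return sub["mpv_m_s"].to_numpy()

    def require_complete(self, n_sets: int, reps_per_set: int) -> None:
        """Raise unless the table is the full n_sets x reps_per_set grid."""
        expected = {(s, r) for s in range(1, n_sets + 1) for r in range(1, reps_per_set + 1)}
        got = set(zip(self.frame["set_index"], self.frame["rep_index"]))
        if got != expected:
            raise ParseError(
                f"incomplete repetition grid: missing {sorted(expected - got)[:5]}"
                + ("..." if len(expected - got) > 5 else "")
            )


@dataclass(frozen=True)
class PhaseMarks:
    """Manually defined phase boundaries on the session clock."""

    exercise_start_s: float
    recovery_start_s: float

    def __post_init__(self) -> None:
        if not self.recovery_start_s > self.exercise_start_s:
            raise ParseError(
                f"recovery_start_s ({self.recovery_start_s}) must exceed "
                f"exercise_start_s ({self.exercise_start_s})"
            )


# ---------------------------------------------------------------------------
# readers


def _read_csv(path, decimal: str = ".") -> pd.DataFrame:
    try:
        return pd.read_csv(path, decimal=decimal)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc


def read_breath_csv(
    path,
    unit: str,
    time_col: str = "time_s",
    vo2_col: str = "vo2",
    decimal: str = ".",
    participant_id: str = "",
) -> BreathSeries:
    """Read a long breath-by-breath CSV; the V-dot-O2 unit must be declared."""
    frame = _read_csv(path, decimal=decimal)
    for col in (time_col, vo2_col):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r} (have {list(frame.columns)})")
    time = pd.to_numeric(frame[time_col], errors="coerce")
    vo2 = pd.to_numeric(frame[vo2_col], errors="coerce")
    for name, series in (("time", time), ("vo2", vo2)):
        if series.isna().any():
            row = int(series.index[series.isna()][0]) + 2  # header + 1-based
            raise ParseError(f"{path}: unparseable {name} value at line {row}")
    dt = np.diff(time.to_numpy())
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 3  # offending (second) row, 1-based + header
        raise ParseError(f"{path}: breath time not strictly increasing at line {row}")
    return BreathSeries(
        time_s=time.to_numpy(), vo2=vo2.to_numpy(), unit=unit, participant_id=participant_id
    )


def read_repetition_csv(path, decimal: str = ".") -> RepetitionTable:
    frame = _read_csv(path, decimal=decimal)
    return RepetitionTable(frame=frame)


def read_lactate_csv(path, decimal: str = ".") -> LactatePanel:
    frame = _read_csv(path, decimal=decimal)
    for col in ("sample", "value_mmol_l"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    baseline = None
    pre_final = None
    post: dict[int, float] = {}
    for i, row in frame.iterrows():
        kind = str(row["sample"])
        value = float(row["value_mmol_l"])
        if kind == "baseline":
            baseline = value
        elif kind == "pre_final_set":
            pre_final = value
        elif kind == "post":
            if "offset_s" not in frame.columns or pd.isna(row["offset_s"]):
                raise ParseError(f"{path}: post sample at line {i + 2} lacks offset_s")
            post[int(row["offset_s"])] = value
        else:
            raise ParseError(f"{path}: unknown sample kind {kind!r} at line {i + 2}")
    if baseline is None:
        raise ParseError(f"{path}: no baseline sample")
    return LactatePanel(
        baseline_mmol_l=baseline, post_mmol_l=post, pre_final_set_mmol_l=pre_final
    )


def read_marks(path, decimal: str = ".") -> PhaseMarks:
    frame = _read_csv(path, decimal=decimal)
    for col in ("key", "value"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    values = dict(zip(frame["key"].astype(str), frame["value"].astype(float)))
    for key in ("exercise_start_s", "recovery_start_s"):
        if key not in values:
            raise ParseError(f"{path}: missing mark {key!r}")
    return PhaseMarks(
        exercise_start_s=values["exercise_start_s"],
        recovery_start_s=values["recovery_start_s"],
    )


# ---------------------------------------------------------------------------
# writers


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_report(report: dict, out_dir, sessions: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the JSON run report and, optionally, a tidy per-session CSV.

    Output is bit-stable for identical inputs: keys are sorted and floats
    serialized at full repr precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(report, cls=_NumpyEncoder, indent=2, sort_keys=True) + "\n"
    )
    paths["report"] = report_path
    if sessions is not None:
        csv_path = out_dir / "sessions.csv"
        sessions.to_csv(csv_path, index=False)
        paths["sessions"] = csv_path
    return paths
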
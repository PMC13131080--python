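"""Velocity-loss and related mean-propulsive-velocity (MPV) metrics.

Velocity loss (VL) for a set is the percentage drop from the fastest to the
last repetition; the session value averages the per-set losses.  The
fastest repetition need not be the first, so normalized profiles (percent
of the set's fastest rep) do not necessarily start at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import RepetitionTable

__all__ = [
    "VelocityLossResult",
    "set_velocity_loss",
    "session_velocity_loss",
    "normalize_mpv",
    "VelocityError",
]


class VelocityError(ValueError):
    pass


@dataclass(frozen=True)
class VelocityLossResult:
    per_set_vl_pct: dict[int, float]
    session_vl_pct: float
    fastest_rep_index: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "per_set_vl_pct": dict(self.per_set_vl_pct),
            "session_vl_pct": self.session_vl_pct,
            "fastest_rep_index": dict(self.fastest_rep_index),
        }


def set_velocity_loss(mpv: np.ndarray) -> float:
    """VL (%) for one ordered set of MPV values: 100*(max - last)/max."""
    mpv = np.asarray(mpv, dtype=float)
    if mpv.size < 2:
        raise VelocityError(f"need >= 2 repetitions, got {mpv.size}")
    if np.any(mpv <= 0):
        raise VelocityError("MPV values must be > 0")
    fastest = float(mpv.max())
    return 100.0 * (fastest - float(mpv[-1])) / fastest


def session_velocity_loss(table: RepetitionTable) -> VelocityLossResult:
    """Per-set VL and their arithmetic mean across the session's sets."""
    per_set: dict[int, float] = {}
    fastest_idx: dict[int, int] = {}
    for s in table.set_indices:
        mpv = table.set_mpv(s)
        per_set[s] = set_velocity_loss(mpv)
        fastest_idx[s] = int(np.argmax(mpv)) + 1  # 1-based rep index
    session = float(np.mean(list(per_set.values())))
    return VelocityLossResult(
        per_set_vl_pct=per_set, session_vl_pct=session, fastest_rep_index=fastest_idx
    )


def normalize_mpv(table: RepetitionTable) -> pd.DataFrame:
    """Each repetition as a percentage of the fastest rep within its set."""
    frame = table.frame.copy()
    set_max = frame.groupby("set_index")["mpv_m_s"].transform("max")
    frame["pct_of_fastest"] = 100.0 * frame["mpv_m_s"] / set_max
    return frame
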
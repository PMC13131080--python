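"""Session structure for cluster-set (CS) and traditional-set (TS) protocols.

A resistance-exercise session is represented as an ordered, contiguous
sequence of segments on a single session clock (t = 0 at the start of the
baseline segment): a seated baseline, alternating work and rest segments,
and one long seated final recovery.  Every downstream integration window —
the aerobic work-phase integral and the fast-component credit windows —
is defined by this timeline, so it is built once and validated strictly.

The defaults encode the two study protocols: four sets of six back squats,
180 s between sets, and (CS only) a 30 s intra-set rest after repetitions
2 and 4, followed by 900 s of seated recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ProtocolSpec",
    "Segment",
    "SessionTimeline",
    "build_timeline",
    "TimelineError",
]

SEGMENT_KINDS = ("baseline", "work", "intra_rest", "inter_rest", "final_recovery")

#: Rest-segment kinds that receive an anaerobic-alactic (fast component) credit.
REST_KINDS = ("intra_rest", "inter_rest", "final_recovery")


class TimelineError(ValueError):
    """Structural problem in a protocol spec or session timeline."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Static description of a set structure.

    Parameters
    ----------
    label:
        ``"CS"`` (cluster sets, short intra-set rests) or ``"TS"``
        (traditional continuous sets).
    cluster_size:
        Repetitions per cluster for CS (2 in the study: rest after reps 2
        and 4 of a 6-rep set).  Must be ``None`` for TS.
    load_pct_1rm:
        Metadata only; the load never enters the energy model.
    """

    label: str
    n_sets: int = 4
    reps_per_set: int = 6
    cluster_size: int | None = None
    intra_set_rest_s: float = 30.0
    inter_set_rest_s: float = 180.0
    final_recovery_s: float = 900.0
    load_pct_1rm: float = 75.0

    def __post_init__(self) -> None:
        if self.label not in ("CS", "TS"):
            raise TimelineError(f"label must be 'CS' or 'TS', got {self.label!r}")
        if self.n_sets < 1:
            raise TimelineError("n_sets must be >= 1")
        if self.reps_per_set < 1:
            raise TimelineError("reps_per_set must be >= 1")
        for name in ("intra_set_rest_s", "inter_set_rest_s", "final_recovery_s"):
            if getattr(self, name) <= 0:
                raise TimelineError(f"{name} must be > 0")
        if self.label == "TS":
            if self.cluster_size is not None:
                raise TimelineError("TS protocols have no clusters (cluster_size must be None)")
        else:
            if self.cluster_size is None:
                raise TimelineError("CS protocols require cluster_size")
            if not 1 <= self.cluster_size <= self.reps_per_set:
                raise TimelineError("cluster_size must be in [1, reps_per_set]")
            if self.reps_per_set % self.cluster_size != 0:
                raise TimelineError(
                    f"reps_per_set ({self.reps_per_set}) must be divisible by "
                    f"cluster_size ({self.cluster_size})"
                )

    @classmethod
    def cs(cls, **overrides) -> "ProtocolSpec":
        """The study's cluster-set protocol (rest after reps 2 and 4)."""
        return cls(label="CS", cluster_size=2, **overrides)

    @classmethod
    def ts(cls, **overrides) -> "ProtocolSpec":
        """The study's traditional-set protocol (continuous 6-rep sets)."""
        return cls(label="TS", **overrides)

    @property
    def clusters_per_set(self) -> int:
        if self.cluster_size is None:
            return 1
        return self.reps_per_set // self.cluster_size

    @property
    def reps_per_work_segment(self) -> int:
        return self.cluster_size if self.cluster_size is not None else self.reps_per_set

    @property
    def n_work_segments(self) -> int:
        return self.n_sets * self.clusters_per_set

    @property
    def n_intra_rests(self) -> int:
        return self.n_sets * (self.clusters_per_set - 1)

    @property
    def n_inter_rests(self) -> int:
        return self.n_sets - 1


@dataclass(frozen=True)
class Segment:
    kind: str
    start_s: float
    end_s: float
    set_index: int | None = None      # 1-based set, None for baseline/final recovery
    cluster_index: int | None = None  # 1-based cluster within the set (CS work/intra_rest)

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise TimelineError(f"unknown segment kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise TimelineError(
                f"segment {self.kind} has non-positive duration "
                f"[{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionTimeline:
    """Contiguous, validated sequence of session segments."""

    segments: tuple[Segment, ...]
    spec: ProtocolSpec | None = None

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise TimelineError("timeline has no segments")
        for prev, cur in zip(segs, segs[1:]):
            if abs(cur.start_s - prev.end_s) > 1e-9:
                raise TimelineError(
                    f"timeline gap/overlap between {prev.kind} (ends {prev.end_s}) "
                    f"and {cur.kind} (starts {cur.start_s})"
                )
        if sum(1 for s in segs if s.kind == "final_recovery") != 1:
            raise TimelineError("timeline must contain exactly one final_recovery segment")

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def of_kind(self, *kinds: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind in kinds)

    @property
    def work_segments(self) -> tuple[Segment, ...]:
        return self.of_kind("work")

    @property
    def rest_segments(self) -> tuple[Segment, ...]:
        """All rest segments including the final recovery."""
        return self.of_kind(*REST_KINDS)

    @property
    def final_recovery(self) -> Segment:
        return self.of_kind("final_recovery")[0]

    @property
    def exercise_start_s(self) -> float:
        return self.work_segments[0].start_s

    @property
    def recovery_start_s(self) -> float:
        """End of the last work segment = manual mark default."""
        return self.work_segments[-1].end_s

    @property
    def total_duration_s(self) -> float:
        return self.segments[-1].end_s - self.segments[0].start_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [s.kind for s in self.segments],
                "start_s": [s.start_s for s in self.segments],
                "end_s": [s.end_s for s in self.segments],
                "set_index": [s.set_index for s in self.segments],
                "cluster_index": [s.cluster_index for s in self.segments],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SessionTimeline":
        segs = []
        for row in frame.itertuples(index=False):
            set_index = None if pd.isna(row.set_index) else int(row.set_index)
            cluster_index = None if pd.isna(row.cluster_index) else int(row.cluster_index)
            segs.append(
                Segment(
                    kind=row.kind,
                    start_s=float(row.start_s),
                    end_s=float(row.end_s),
                    set_index=set_index,
                    cluster_index=cluster_index,
                )
            )
        return cls(segments=tuple(segs))

    @classmethod
    def from_csv(cls, path) -> "SessionTimeline":
        return cls.from_frame(pd.read_csv(path))


def build_timeline(
    spec: ProtocolSpec,
    work_durations: Sequence[float],
    baseline_duration_s: float = 120.0,
) -> SessionTimeline:
    """Lay out a full session on the session clock.

    ``work_durations`` gives the duration of every work segment in order
    (one per set for TS, one per cluster for CS); repetition tempo is a
    measured/simulated input, not a protocol constant.
    """
    expected = spec.n_work_segments
    if len(work_durations) != expected:
        raise TimelineError(
            f"expected {expected} work durations for {spec.label} "
            f"({spec.n_sets} sets x {spec.clusters_per_set} clusters), "
            f"got {len(work_durations)}"
        )
    if baseline_duration_s <= 0:
        raise TimelineError("baseline_duration_s must be > 0")
    if any(d <= 0 for d in work_durations):
        raise TimelineError("all work durations must be > 0")

    segs: list[Segment] = []
    t = 0.0
    segs.append(Segment("baseline", t, t + baseline_duration_s))
    t += baseline_duration_s
    it = iter(work_durations)
    for s in range(1, spec.n_sets + 1):
        for c in range(1, spec.clusters_per_set + 1):
            d = float(next(it))
            segs.append(Segment("work", t, t + d, set_index=s, cluster_index=c))
            t += d
            if c < spec.clusters_per_set:
                segs.append(
                    Segment("intra_rest", t, t + spec.intra_set_rest_s, set_index=s, cluster_index=c)
                )
                t += spec.intra_set_rest_s
        if s < spec.n_sets:
            segs.append(Segment("inter_rest", t, t + spec.inter_set_rest_s, set_index=s))
            t += spec.inter_set_rest_s
    segs.append(Segment("final_recovery", t, t + spec.final_recovery_s))
    return SessionTimeline(segments=tuple(segs), spec=spec)
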
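"""Three-component (PCr-La-O2) energy partitioning for one session.

Aerobic energy is the baseline-adjusted V-dot-O2 integral over the work
periods only: measured V-dot-O2 integrals over every intra- and inter-set
rest window are excluded from the exercise-phase integral, so what remains
is exactly the work-segment integral.  Anaerobic-alactic energy is the fast
recovery component integrated in closed form over every rest window (the
900-s final recovery, the inter-set rests and, for cluster sets, the
intra-set pauses), re-using the final-recovery fit's (a, tau_a) for each
window because the short rests do not support reliable fitting of their
own.  Anaerobic-lactic energy converts the baseline-to-peak blood-lactate
rise to an oxygen equivalent (3 mL O2 per kg body mass per mmol/L).  All
oxygen volumes convert to energy at 20.92 kJ per litre O2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import LactatePanel, ParticipantInfo
from .kinetics import BiExpFit, SmoothedSeries
from .protocol import SessionTimeline

__all__ = [
    "EnergyConstants",
    "EnergyComponents",
    "EnergyError",
    "component_integral",
    "aerobic_energy",
    "alactic_energy",
    "lactic_energy",
    "partition_session",
]


class EnergyError(ValueError):
    """Invalid input to an energy computation."""


@dataclass(frozen=True)
class EnergyConstants:
    """Conversion constants of the PCr-La-O2 method."""

    #: energy yield per litre of oxygen consumed
    caloric_equiv_kj_per_l_o2: float = 20.92
    #: oxygen equivalent of a 1 mmol/L net lactate rise, per kg body mass
    lactate_o2_equiv_ml_per_kg_per_mmol: float = 3.0

    def __post_init__(self) -> None:
        if self.caloric_equiv_kj_per_l_o2 <= 0:
            raise EnergyError("caloric equivalent must be > 0")
        if self.lactate_o2_equiv_ml_per_kg_per_mmol <= 0:
            raise EnergyError("lactate O2 equivalent must be > 0")


@dataclass(frozen=True)
class EnergyComponents:
    """Absolute (kJ) and relative (%) energies for one session."""

    aerobic_kj: float
    alactic_kj: float
    lactic_kj: float
    total_kj: float
    rel_aerobic_pct: float
    rel_alactic_pct: float
    rel_lactic_pct: float

    @classmethod
    def from_absolute(
        cls, aerobic_kj: float, alactic_kj: float, lactic_kj: float
    ) -> "EnergyComponents":
        if aerobic_kj < 0 or alactic_kj < 0:
            raise EnergyError("aerobic and alactic energies must be >= 0")
        total = aerobic_kj + alactic_kj + lactic_kj
        if total <= 0:
            raise EnergyError("degenerate session: total energy <= 0")
        return cls(
            aerobic_kj=aerobic_kj,
            alactic_kj=alactic_kj,
            lactic_kj=lactic_kj,
            total_kj=total,
            rel_aerobic_pct=100.0 * aerobic_kj / total,
            rel_alactic_pct=100.0 * alactic_kj / total,
            rel_lactic_pct=100.0 * lactic_kj / total,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "aerobic_kj": self.aerobic_kj,
            "alactic_kj": self.alactic_kj,
            "lactic_kj": self.lactic_kj,
            "total_kj": self.total_kj,
            "rel_aerobic_pct": self.rel_aerobic_pct,
            "rel_alactic_pct": self.rel_alactic_pct,
            "rel_lactic_pct": self.rel_lactic_pct,
        }


def component_integral(amplitude: float, tau: float, duration_s: float) -> float:
    """Closed-form integral of ``amplitude * exp(-t/tau)`` over [0, duration].

    Returns litres of O2 when amplitude is in L/s and times in seconds:
    ``amplitude * tau * (1 - exp(-duration/tau))``.
    """
    if tau <= 0:
        raise EnergyError("tau must be > 0")
    if duration_s < 0:
        raise EnergyError("duration_s must be >= 0")
    return amplitude * tau * (1.0 - math.exp(-duration_s / tau))


def _integrate_window(series: SmoothedSeries, start_s: float, end_s: float) -> float:
    """Trapezoidal integral of the smoothed series over [start, end] (L).

    Partial-second window edges are resolved by linear interpolation on the
    1-s grid.
    """
    t, v = series.grid_time_s, series.vo2_l_s
    if start_s < t[0] - 1e-9 or end_s > t[-1] + 1e-9:
        raise EnergyError(
            f"window [{start_s}, {end_s}] outside measured span [{t[0]}, {t[-1]}]"
        )
    inner = (t > start_s) & (t < end_s)
    ts = np.concatenate([[start_s], t[inner], [end_s]])
    vs = np.interp(ts, t, v)
    return float(np.trapezoid(vs, ts))


def aerobic_energy(
    series: SmoothedSeries,
    timeline: SessionTimeline,
    c: float,
    constants: EnergyConstants = EnergyConstants(),
    rest_subtraction: str = "measured",
    fit: BiExpFit | None = None,
) -> float:
    """Aerobic energy (kJ): baseline-adjusted V-dot-O2 over work periods.

    With the default ``rest_subtraction="measured"`` the measured rest-window
    integrals are removed from the exercise-phase integral, which is
    algebraically the integral over the work segments alone; the integrand
    is ``max(VO2 - c, 0)`` (negative slivers clipped).  The alternative
    ``"modelled"`` policy subtracts the modelled (fast + slow) component
    integrals over each rest window instead, and requires ``fit``.
    """
    if c < 0:
        raise EnergyError("baseline c must be >= 0")
    adjusted = SmoothedSeries(
        grid_time_s=series.grid_time_s,
        vo2_l_s=np.clip(series.vo2_l_s - c, 0.0, None),
        source_unit=series.source_unit,
    )
    if rest_subtraction == "measured":
        litres = 0.0
        for seg in timeline.work_segments:
            try:
                litres += _integrate_window(adjusted, seg.start_s, seg.end_s)
            except EnergyError as exc:
                raise EnergyError(
                    f"work segment set {seg.set_index} cluster {seg.cluster_index}: {exc}"
                ) from exc
    elif rest_subtraction == "modelled":
        if fit is None:
            raise EnergyError("rest_subtraction='modelled' requires the recovery fit")
        start = timeline.exercise_start_s
        end = timeline.recovery_start_s
        litres = _integrate_window(adjusted, start, end)
        for seg in timeline.of_kind("intra_rest", "inter_rest"):
            litres -= component_integral(fit.a, fit.tau_a, seg.duration_s)
            litres -= component_integral(fit.b, fit.tau_b, seg.duration_s)
        litres = max(litres, 0.0)
    else:
        raise EnergyError(f"unknown rest_subtraction policy {rest_subtraction!r}")
    return litres * constants.caloric_equiv_kj_per_l_o2


def alactic_energy(
    fit: BiExpFit,
    timeline: SessionTimeline,
    constants: EnergyConstants = EnergyConstants(),
    force: bool = False,
) -> float:
    """Anaerobic-alactic energy (kJ): fast component over every rest window.

    The final-recovery (a, tau_a) is applied to each window with local time
    restarting at 0 — an equal-repayment assumption for every cluster/set,
    adopted because short rests do not allow reliable per-window fitting.
    """
    if not fit.converged and not force:
        raise EnergyError("recovery fit did not converge; pass force=True to override")
    litres = sum(
        component_integral(fit.a, fit.tau_a, seg.duration_s)
        for seg in timeline.rest_segments
    )
    return litres * constants.caloric_equiv_kj_per_l_o2


def lactic_energy(
    panel: LactatePanel,
    participant: ParticipantInfo,
    constants: EnergyConstants = EnergyConstants(),
    negative_policy: str = "floor",
) -> float:
    """Anaerobic-lactic energy (kJ) from the baseline-to-peak lactate rise.

    ``delta_lactate * 3 mL O2 / (kg * mmol/L) * body mass``, then 20.92 kJ/L.
    A negative net rise is floored at 0 by default (``negative_policy=
    "floor"``); ``"allow"`` propagates the negative value.
    """
    rise = panel.rise_mmol_l
    if rise < 0:
        if negative_policy == "floor":
            warnings.warn(
                f"negative lactate rise ({rise:.2f} mmol/L) floored at 0", stacklevel=2
            )
            rise = 0.0
        elif negative_policy != "allow":
            raise EnergyError(f"unknown negative_policy {negative_policy!r}")
    litres = (
        rise
        * constants.lactate_o2_equiv_ml_per_kg_per_mmol
        * participant.body_mass_kg
        / 1000.0
    )
    return litres * constants.caloric_equiv_kj_per_l_o2


def partition_session(
    series: SmoothedSeries,
    timeline: SessionTimeline,
    fit: BiExpFit,
    panel: LactatePanel,
    participant: ParticipantInfo,
    constants: EnergyConstants = EnergyConstants(),
    rest_subtraction: str = "measured",
    negative_lactate_policy: str = "floor",
) -> EnergyComponents:
    """Full three-component partition for one session."""
    aerobic = aerobic_energy(
        series, timeline, fit.c, constants, rest_subtraction=rest_subtraction, fit=fit
    )
    alactic = alactic_energy(fit, timeline, constants)
    lactic = lactic_energy(panel, participant, constants, negative_policy=negative_lactate_policy)
    return EnergyComponents.from_absolute(aerobic, alactic, lactic)
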
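"""End-to-end orchestration: per-session analysis and cohort comparison.

``analyze_session`` chains the per-session stages in order (preprocess →
recovery fit → energy partition → velocity loss) and returns a plain-dict
report; ``compare_cohort`` runs the group layer (paired t on velocity
loss, exact Wilcoxon + Hedges' g on the lactate rise, mixed model on the
relative energy shares).  Both are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (
    BreathSeries,
    LactatePanel,
    ParticipantInfo,
    PhaseMarks,
    RepetitionTable,
)
from .energy import EnergyConstants, partition_session
from .kinetics import fit_recovery, preprocess
from .protocol import SessionTimeline
from .stats import (
    PairedSample,
    fit_energy_lmm,
    paired_t,
    hedges_g_paired,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from .velocity import session_velocity_loss

__all__ = ["AnalysisPolicies", "analyze_session", "compare_cohort"]


@dataclass(frozen=True)
class AnalysisPolicies:
    """Named policy switches, with the defaults used throughout."""

    smoothing_centring: str = "before"       # 10-point window i-5..i+4
    rest_subtraction: str = "measured"       # aerobic integral excludes measured rests
    negative_lactate_policy: str = "floor"
    fit_window_s: float = 900.0
    fit_skip_s: float = 10.0          # drop smoothing-contaminated start of recovery
    constants: EnergyConstants = field(default_factory=EnergyConstants)

    def as_dict(self) -> dict:
        return {
            "smoothing_centring": self.smoothing_centring,
            "rest_subtraction": self.rest_subtraction,
            "negative_lactate_policy": self.negative_lactate_policy,
            "fit_window_s": self.fit_window_s,
            "fit_skip_s": self.fit_skip_s,
            "caloric_equiv_kj_per_l_o2": self.constants.caloric_equiv_kj_per_l_o2,
            "lactate_o2_equiv_ml_per_kg_per_mmol": (
                self.constants.lactate_o2_equiv_ml_per_kg_per_mmol
            ),
        }


def analyze_session(
    breath: BreathSeries,
    reps: RepetitionTable,
    lactate: LactatePanel,
    marks: PhaseMarks,
    timeline: SessionTimeline,
    participant: ParticipantInfo,
    policies: AnalysisPolicies = AnalysisPolicies(),
) -> dict:
    """Run the full per-session analysis; returns a JSON-ready report."""
    smoothed = preprocess(
        breath, body_mass_kg=participant.body_mass_kg, centring=policies.smoothing_centring
    )
    fit = fit_recovery(
        smoothed, marks, fit_window_s=policies.fit_window_s, skip_s=policies.fit_skip_s
    )
    energies = partition_session(
        smoothed,
        timeline,
        fit,
        lactate,
        participant,
        constants=policies.constants,
        rest_subtraction=policies.rest_subtraction,
        negative_lactate_policy=policies.negative_lactate_policy,
    )
    vl = session_velocity_loss(reps)
    return {
        "participant_id": participant.id,
        "body_mass_kg": participant.body_mass_kg,
        "fit": {
            "a_l_s": fit.a,
            "tau_a_s": fit.tau_a,
            "b_l_s": fit.b,
            "tau_b_s": fit.tau_b,
            "c_l_s": fit.c,
            "c_ml_kg_min": fit.baseline_ml_kg_min(participant.body_mass_kg),
            "rss": fit.rss,
            "converged": fit.converged,
            "n_points": fit.n_points,
            "recovery_start_s": fit.recovery_start_s,
        },
        "energy": energies.as_dict(),
        "velocity": vl.as_dict(),
        "lactate_rise_mmol_l": lactate.rise_mmol_l,
        "policies": policies.as_dict(),
    }


def sessions_frame(reports: list[dict], protocols: list[str]) -> pd.DataFrame:
    """Tidy per-session table from a list of analyze_session reports."""
    rows = []
    for rep, proto in zip(reports, protocols):
        rows.append(
            {
                "participant": rep["participant_id"],
                "protocol": proto,
                "session_vl_pct": rep["velocity"]["session_vl_pct"],
                "lactate_rise_mmol_l": rep["lactate_rise_mmol_l"],
                "c_ml_kg_min": rep["fit"]["c_ml_kg_min"],
                **rep["energy"],
            }
        )
    return pd.DataFrame(rows)


def compare_cohort(sessions: pd.DataFrame) -> dict:
    """Group comparison on a tidy per-session table.

    Expects one CS and one TS row per participant (columns as produced by
    :func:`sessions_frame`).  Mirrors the study's inferential layer.
    """
    pivot_check = sessions.groupby(["participant", "protocol"]).size()
    if (pivot_check != 1).any():
        raise ValueError("each participant needs exactly one CS and one TS session")
    wide = sessions.pivot(index="participant", columns="protocol")
    for proto in ("CS", "TS"):
        if proto not in sessions["protocol"].unique():
            missing = sorted(sessions["participant"].unique())
            raise ValueError(f"missing {proto} sessions for participants {missing}")
    unpaired = wide.isna().any(axis=1)
    if unpaired.any():
        raise ValueError(f"unpaired participants: {list(wide.index[unpaired])}")

    def paired(col: str) -> PairedSample:
        return PairedSample(
            cs=wide[(col, "CS")].to_numpy(),
            ts=wide[(col, "TS")].to_numpy(),
            participants=tuple(wide.index),
        )

    vl = paired("session_vl_pct")
    lac = paired("lactate_rise_mmol_l")

    long_rows = []
    for system in ("aerobic", "alactic", "lactic"):
        col = f"rel_{system}_pct"
        for proto in ("CS", "TS"):
            for part, value in wide[(col, proto)].items():
                long_rows.append(
                    {"participant": part, "protocol": proto, "system": system,
                     "rel_pct": value}
                )
    energy_long = pd.DataFrame(long_rows)

    summary = {
        col: {
            proto: {
                "mean": float(wide[(col, proto)].mean()),
                "sd": float(wide[(col, proto)].std(ddof=1)),
            }
            for proto in ("CS", "TS")
        }
        for col in (
            "session_vl_pct", "lactate_rise_mmol_l", "c_ml_kg_min",
            "rel_aerobic_pct", "rel_alactic_pct", "rel_lactic_pct",
        )
    }

    return {
        "n_pairs": int(len(wide)),
        "summary": summary,
        "velocity_loss": {
            "shapiro_diff": shapiro_wilk(vl.diff),
            "paired_t": paired_t(vl),
        },
        "lactate_rise": {
            "shapiro_diff": shapiro_wilk(lac.diff),
            "wilcoxon": wilcoxon_signed_rank(lac),
            "hedges_g": hedges_g_paired(lac),
        },
        "energy_lmm": fit_energy_lmm(energy_long),
    }
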
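"""Synthetic cluster-set / traditional-set sessions with known ground truth.

The generator produces every measurement stream the analysis consumes —
irregular breath-by-breath V-dot-O2, per-repetition barbell velocities, a
lactate panel and phase marks — from an explicit generative model, plus a
ground-truth energy ledger, so the whole pipeline can be tested without any
recorded data.

Generative model
----------------
* V-dot-O2 is baseline ``c`` plus an elevation ``e(t)``: during work,
  ``e`` rises mono-exponentially toward ``work_demand_l_s`` with time
  constant ``on_tau_s``; at every rest onset it decays bi-exponentially
  with the configured time constants, the fast/slow amplitudes scaled to
  the current elevation in the configured a:b ratio so the path is
  continuous at each work-to-rest transition.
* Breaths are sampled at jittered intervals with additive Gaussian noise
  (default SD 5% of the noiseless peak), reported in L/min.
* MPV per repetition is ``base * (1 - fatigue)``; fatigue accumulates by a
  fixed increment per repetition and decays exponentially during rests
  (time constant ``rest_recovery_tau_s``) — cluster sets therefore lose
  less velocity than traditional sets at identical parameters.
* Blood lactate rises by a fixed increment for each repetition performed
  above a fatigue threshold and is cleared exponentially toward baseline
  during rests and recovery; the panel samples it at +60/+180/+300 s.

The truth ledger applies the *analysis* attribution rules in closed form
to the noiseless path: aerobic = elevation integral over work segments;
alactic = the final-recovery fast amplitude integrated over every rest
window; lactic = the lactate rise as seen at the post-exercise sampling
times.  It is therefore the value an exact analysis of noiseless data
should report, the right yardstick for pipeline-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import BreathSeries, LactatePanel, ParticipantInfo, PhaseMarks, RepetitionTable
from .energy import EnergyComponents, EnergyConstants, component_integral
from .protocol import ProtocolSpec, SessionTimeline, build_timeline

import pandas as pd

__all__ = [
    "VelocityModel",
    "LactateModel",
    "SyntheticConfig",
    "SyntheticSession",
    "SynthError",
    "generate_session",
    "truth_energy",
    "generate_cohort",
]

POST_SAMPLE_OFFSETS_S = (60, 180, 300)


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class VelocityModel:
    base_mpv_m_s: float = 0.70
    per_rep_fatigue_increment: float = 0.04
    rest_recovery_tau_s: float = 60.0


@dataclass(frozen=True)
class LactateModel:
    baseline_mmol_l: float = 1.2
    per_rep_increment_mmol_l: float = 0.55
    fatigue_threshold: float = 0.10
    clearance_rate_per_s: float = 0.004


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for one synthetic session."""

    body_mass_kg: float = 72.0
    baseline_vo2_l_s: float = 0.006       # ~5 mL/kg/min at 72 kg
    on_tau_s: float = 15.0
    work_demand_l_s: float = 0.050        # elevation asymptote above baseline
    a_l_s: float = 0.022                  # fast amplitude (sets the fast:slow ratio)
    tau_a_s: float = 25.0
    b_l_s: float = 0.013
    tau_b_s: float = 300.0
    breath_interval_s: float = 3.0
    breath_jitter_frac: float = 0.3
    noise_sd_l_s: float | None = None     # None -> 5% of noiseless peak
    rep_duration_s: float = 3.5
    baseline_duration_s: float = 120.0
    velocity: VelocityModel = field(default_factory=VelocityModel)
    lactate: LactateModel = field(default_factory=LactateModel)
    seed: int = 0
    participant_id: str = "synthetic"

    def __post_init__(self) -> None:
        positive = (
            "body_mass_kg", "on_tau_s", "work_demand_l_s", "a_l_s", "tau_a_s",
            "b_l_s", "tau_b_s", "breath_interval_s", "rep_duration_s",
            "baseline_duration_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be > 0")
        if self.baseline_vo2_l_s < 0:
            raise SynthError("baseline_vo2_l_s must be >= 0 (negative VO2 impossible)")
        if not self.tau_a_s < self.tau_b_s:
            raise SynthError("tau_a_s must be < tau_b_s")
        if not 0 <= self.breath_jitter_frac < 1:
            raise SynthError("breath_jitter_frac must be in [0, 1)")

    @property
    def fast_fraction(self) -> float:
        return self.a_l_s / (self.a_l_s + self.b_l_s)


@dataclass
class SyntheticSession:
    breath: BreathSeries
    reps: RepetitionTable
    lactate: LactatePanel
    marks: PhaseMarks
    timeline: SessionTimeline
    participant: ParticipantInfo
    truth: dict


# ---------------------------------------------------------------------------
# noiseless path


def _path_pieces(config: SyntheticConfig, timeline: SessionTimeline) -> list[dict]:
    """Per-segment closed-form elevation parameters along the timeline."""
    fa, fb = config.fast_fraction, 1.0 - config.fast_fraction
    pieces = []
    e = 0.0
    for seg in timeline:
        piece = {"seg": seg, "e0": e}
        if seg.kind == "work":
            D, tau = config.work_demand_l_s, config.on_tau_s
            e = D + (e - D) * math.exp(-seg.duration_s / tau)
        elif seg.kind in ("intra_rest", "inter_rest", "final_recovery"):
            decay = fa * math.exp(-seg.duration_s / config.tau_a_s) + fb * math.exp(
                -seg.duration_s / config.tau_b_s
            )
            e = piece["e0"] * decay
        pieces.append(piece)
    return pieces


def _elevation_at(config: SyntheticConfig, pieces: list[dict], t: np.ndarray) -> np.ndarray:
    """Vectorized noiseless elevation above baseline at session times ``t``."""
    t = np.asarray(t, dtype=float)
    starts = np.array([p["seg"].start_s for p in pieces])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(pieces) - 1)
    out = np.zeros_like(t)
    fa, fb = config.fast_fraction, 1.0 - config.fast_fraction
    for i, piece in enumerate(pieces):
        m = idx == i
        if not np.any(m):
            continue
        seg, e0 = piece["seg"], piece["e0"]
        dt = t[m] - seg.start_s
        if seg.kind == "baseline":
            out[m] = e0
        elif seg.kind == "work":
            D, tau = config.work_demand_l_s, config.on_tau_s
            out[m] = D + (e0 - D) * np.exp(-dt / tau)
        else:
            out[m] = e0 * (
                fa * np.exp(-dt / config.tau_a_s) + fb * np.exp(-dt / config.tau_b_s)
            )
    return out


def vo2_truth_l_s(config: SyntheticConfig, timeline: SessionTimeline, t: np.ndarray) -> np.ndarray:
    """Noiseless V-dot-O2 (L/s) at arbitrary session times."""
    pieces = _path_pieces(config, timeline)
    return config.baseline_vo2_l_s + _elevation_at(config, pieces, t)


# ---------------------------------------------------------------------------
# mechanical / lactate state walk


def _walk_reps_and_lactate(config: SyntheticConfig, spec: ProtocolSpec, timeline: SessionTimeline):
    vel, lac = config.velocity, config.lactate
    fatigue = 0.0
    lactate = lac.baseline_mmol_l
    pre_final = None
    rows = []
    lactate_at_recovery = lac.baseline_mmol_l
    for seg in timeline:
        if seg.kind == "work":
            for j in range(spec.reps_per_work_segment):
                if fatigue >= 1.0:
                    raise SynthError("velocity model implies non-positive MPV")
                rep_index = (seg.cluster_index - 1) * spec.reps_per_work_segment + j + 1 \
                    if spec.cluster_size is not None else j + 1
                rows.append(
                    {
                        "set_index": seg.set_index,
                        "rep_index": rep_index,
                        "mpv_m_s": vel.base_mpv_m_s * (1.0 - fatigue),
                    }
                )
                if fatigue > lac.fatigue_threshold:
                    lactate += lac.per_rep_increment_mmol_l
                fatigue += vel.per_rep_fatigue_increment
        elif seg.kind in ("intra_rest", "inter_rest", "final_recovery"):
            if seg.kind == "final_recovery":
                lactate_at_recovery = lactate
            if (
                seg.kind == "inter_rest"
                and seg.set_index == spec.n_sets - 1
                and seg.duration_s > 60.0
            ):
                # sample drawn 60 s before the final set starts
                pre_final = lac.baseline_mmol_l + (lactate - lac.baseline_mmol_l) * math.exp(
                    -lac.clearance_rate_per_s * (seg.duration_s - 60.0)
                )
            fatigue *= math.exp(-seg.duration_s / vel.rest_recovery_tau_s)
            lactate = lac.baseline_mmol_l + (lactate - lac.baseline_mmol_l) * math.exp(
                -lac.clearance_rate_per_s * seg.duration_s
            )
    post = {
        off: lac.baseline_mmol_l
        + (lactate_at_recovery - lac.baseline_mmol_l)
        * math.exp(-lac.clearance_rate_per_s * off)
        for off in POST_SAMPLE_OFFSETS_S
    }
    table = RepetitionTable(frame=pd.DataFrame(rows))
    panel = LactatePanel(
        baseline_mmol_l=lac.baseline_mmol_l,
        post_mmol_l=post,
        pre_final_set_mmol_l=pre_final,
    )
    return table, panel, lactate_at_recovery


# ---------------------------------------------------------------------------
# public API


def _session_timeline(config: SyntheticConfig, spec: ProtocolSpec) -> SessionTimeline:
    work = [config.rep_duration_s * spec.reps_per_work_segment] * spec.n_work_segments
    return build_timeline(spec, work, baseline_duration_s=config.baseline_duration_s)


def truth_energy(config: SyntheticConfig, spec: ProtocolSpec) -> dict:
    """Ground-truth energy ledger under the analysis attribution rules.

    Closed-form integrals of the generative components: aerobic from the
    work-segment elevation, alactic from the final-recovery fast amplitude
    applied to every rest window, lactic from the lactate rise observable
    at the post-exercise sampling times.
    """
    timeline = _session_timeline(config, spec)
    pieces = _path_pieces(config, timeline)
    constants = EnergyConstants()

    aerobic_l = 0.0
    for piece in pieces:
        seg = piece["seg"]
        if seg.kind != "work":
            continue
        D, tau, e0 = config.work_demand_l_s, config.on_tau_s, piece["e0"]
        aerobic_l += D * seg.duration_s + (e0 - D) * tau * (
            1.0 - math.exp(-seg.duration_s / tau)
        )

    e_final = next(p["e0"] for p in pieces if p["seg"].kind == "final_recovery")
    a_fast = config.fast_fraction * e_final
    alactic_l = sum(
        component_integral(a_fast, config.tau_a_s, seg.duration_s)
        for seg in timeline.rest_segments
    )

    _, panel, _ = _walk_reps_and_lactate(config, spec, timeline)
    rise = max(panel.rise_mmol_l, 0.0)
    lactic_l = rise * constants.lactate_o2_equiv_ml_per_kg_per_mmol * config.body_mass_kg / 1000.0

    kj = constants.caloric_equiv_kj_per_l_o2
    components = EnergyComponents.from_absolute(aerobic_l * kj, alactic_l * kj, lactic_l * kj)
    return {
        "components": components,
        "a_l_s": a_fast,
        "b_l_s": (1.0 - config.fast_fraction) * e_final,
        "tau_a_s": config.tau_a_s,
        "tau_b_s": config.tau_b_s,
        "c_l_s": config.baseline_vo2_l_s,
        "elevation_at_recovery_l_s": e_final,
        "lactate_rise_mmol_l": rise,
    }


def generate_session(config: SyntheticConfig, spec: ProtocolSpec) -> SyntheticSession:
    """Generate one complete synthetic session (deterministic in the seed)."""
    timeline = _session_timeline(config, spec)
    pieces = _path_pieces(config, timeline)
    rng = np.random.default_rng(config.seed)

    total = timeline.total_duration_s
    times = []
    t = 0.0
    while t <= total:
        times.append(t)
        jitter = rng.uniform(-config.breath_jitter_frac, config.breath_jitter_frac)
        t += config.breath_interval_s * (1.0 + jitter)
    times = np.array(times)
    noiseless = config.baseline_vo2_l_s + _elevation_at(config, pieces, times)
    sd = config.noise_sd_l_s
    if sd is None:
        sd = 0.05 * float(noiseless.max())
    vo2_l_s = noiseless + (rng.normal(0.0, sd, size=len(times)) if sd > 0 else 0.0)
    vo2_l_min = np.clip(vo2_l_s, 0.0, None) * 60.0

    breath = BreathSeries(
        time_s=times, vo2=vo2_l_min, unit="L/min", participant_id=config.participant_id
    )
    reps, panel, _ = _walk_reps_and_lactate(config, spec, timeline)
    marks = PhaseMarks(
        exercise_start_s=timeline.exercise_start_s,
        recovery_start_s=timeline.recovery_start_s,
    )
    participant = ParticipantInfo(id=config.participant_id, body_mass_kg=config.body_mass_kg)
    return SyntheticSession(
        breath=breath,
        reps=reps,
        lactate=panel,
        marks=marks,
        timeline=timeline,
        participant=participant,
        truth=truth_energy(config, spec),
    )


def generate_cohort(
    n_participants: int = 6,
    master_seed: int = 0,
    base_config: SyntheticConfig = SyntheticConfig(),
) -> list[dict]:
    """Generate a crossover cohort: each participant performs CS and TS.

    Per-participant physiology (body mass, baseline, demand, recovery
    kinetics, fatigue and lactate responsiveness) is drawn once around the
    defaults, then shared between that participant's two sessions; only
    the breath noise differs between sessions.  One master seed fixes the
    entire cohort.
    """
    if n_participants < 2:
        raise SynthError("need >= 2 participants")
    rng = np.random.default_rng(master_seed)

    def draw(mean, sd, lo):
        return float(max(rng.normal(mean, sd), lo))

    cohort = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        a = draw(base_config.a_l_s, 0.004, 0.010)
        b = draw(base_config.b_l_s, 0.002, 0.003)
        cfg = replace(
            base_config,
            participant_id=pid,
            body_mass_kg=draw(base_config.body_mass_kg, 8.0, 50.0),
            baseline_vo2_l_s=draw(base_config.baseline_vo2_l_s, 0.0006, 0.003),
            work_demand_l_s=draw(base_config.work_demand_l_s, 0.005, 0.02),
            on_tau_s=draw(base_config.on_tau_s, 3.0, 10.0),
            a_l_s=a,
            b_l_s=b,
            tau_a_s=draw(base_config.tau_a_s, 5.0, 15.0),
            tau_b_s=draw(base_config.tau_b_s, 30.0, 180.0),
            velocity=VelocityModel(
                base_mpv_m_s=draw(base_config.velocity.base_mpv_m_s, 0.05, 0.4),
                per_rep_fatigue_increment=draw(
                    base_config.velocity.per_rep_fatigue_increment, 0.006, 0.01
                ),
                rest_recovery_tau_s=draw(base_config.velocity.rest_recovery_tau_s, 8.0, 20.0),
            ),
            lactate=LactateModel(
                baseline_mmol_l=draw(base_config.lactate.baseline_mmol_l, 0.2, 0.5),
                per_rep_increment_mmol_l=draw(
                    base_config.lactate.per_rep_increment_mmol_l, 0.08, 0.1
                ),
                fatigue_threshold=draw(base_config.lactate.fatigue_threshold, 0.01, 0.02),
                clearance_rate_per_s=draw(
                    base_config.lactate.clearance_rate_per_s, 0.0005, 0.001
                ),
            ),
        )
        seeds = rng.integers(0, 2**31 - 1, size=2)
        sessions = {
            "CS": generate_session(replace(cfg, seed=int(seeds[0])), ProtocolSpec.cs()),
            "TS": generate_session(replace(cfg, seed=int(seeds[1])), ProtocolSpec.ts()),
        }
        cohort.append({"participant_id": pid, "config": cfg, "sessions": sessions})
    return cohort
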
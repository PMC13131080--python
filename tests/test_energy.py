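"""Energy partitioning: closed-form integrals, attribution rules, shares."""

import numpy as np
import pytest

from ergopart.dataio import LactatePanel, ParticipantInfo
from ergopart.energy import (
    EnergyComponents,
    EnergyConstants,
    EnergyError,
    aerobic_energy,
    alactic_energy,
    component_integral,
    lactic_energy,
    partition_session,
)
from ergopart.kinetics import BiExpFit, SmoothedSeries
from ergopart.protocol import ProtocolSpec, Segment, SessionTimeline, build_timeline

KJ_PER_L = 20.92


def _fit(a=0.030, tau_a=35.0, b=0.010, tau_b=300.0, c=0.05, converged=True):
    return BiExpFit(a=a, tau_a=tau_a, b=b, tau_b=tau_b, c=c, rss=0.0,
                    converged=converged, n_points=900, recovery_start_s=0.0)


def _flat_series(value, duration):
    t = np.arange(0.0, duration + 0.5)
    return SmoothedSeries(grid_time_s=t, vo2_l_s=np.full_like(t, value))


def _timeline(*segs):
    return SessionTimeline(segments=tuple(segs))


# ---------------------------------------------------------------------------
# component_integral


def test_component_integral_zero_amplitude():
    assert component_integral(0.0, 35.0, 30.0) == 0.0


def test_component_integral_matches_hand_value():
    # 0.030 L/s over a 30-s window with tau 35 s
    assert component_integral(0.030, 35.0, 30.0) == pytest.approx(0.604, abs=5e-4)


def test_component_integral_asymptote_is_amplitude_times_tau():
    assert component_integral(0.030, 35.0, 1e9) == pytest.approx(1.05, rel=1e-12)


def test_component_integral_matches_trapezoid_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        amp = rng.uniform(0.001, 0.1)
        tau = rng.uniform(5.0, 600.0)
        dur = rng.uniform(1.0, 1200.0)
        t = np.arange(0.0, dur + 1e-9, 0.01)
        if t[-1] < dur:
            t = np.append(t, dur)
        oracle = np.trapezoid(amp * np.exp(-t / tau), t)
        closed = component_integral(amp, tau, dur)
        assert abs(closed - oracle) / oracle < 1e-6


def test_component_integral_rejects_bad_tau():
    with pytest.raises(EnergyError):
        component_integral(0.03, -1.0, 30.0)


# ---------------------------------------------------------------------------
# aerobic


def test_aerobic_zero_when_vo2_equals_baseline():
    c = 0.05
    tl = _timeline(
        Segment("baseline", 0, 100),
        Segment("work", 100, 200, set_index=1),
        Segment("final_recovery", 200, 1100),
    )
    assert aerobic_energy(_flat_series(c, 1100), tl, c) == 0.0


def test_aerobic_constant_elevation_single_work_segment():
    c = 0.05
    tl = _timeline(
        Segment("baseline", 0, 100),
        Segment("work", 100, 200, set_index=1),
        Segment("final_recovery", 200, 1100),
    )
    # 0.02 L/s above baseline for 100 s -> 2 L -> 41.84 kJ
    kj = aerobic_energy(_flat_series(c + 0.02, 1100), tl, c)
    assert kj == pytest.approx(2.0 * KJ_PER_L, rel=1e-9)


def test_aerobic_excludes_rest_window_inside_exercise_phase():
    c = 0.05
    tl = _timeline(
        Segment("baseline", 0, 100),
        Segment("work", 100, 135, set_index=1, cluster_index=1),
        Segment("intra_rest", 135, 165, set_index=1, cluster_index=1),
        Segment("work", 165, 200, set_index=1, cluster_index=2),
        Segment("final_recovery", 200, 1100),
    )
    # 100 s of work at +0.02 L/s; the 30-s rest at the same elevation is excluded
    kj = aerobic_energy(_flat_series(c + 0.02, 1100), tl, c)
    assert kj == pytest.approx(1.4 * KJ_PER_L, rel=1e-9)  # 29.288 kJ


def test_aerobic_errors_when_work_outside_span():
    tl = _timeline(
        Segment("baseline", 0, 100),
        Segment("work", 100, 200, set_index=1),
        Segment("final_recovery", 200, 1100),
    )
    with pytest.raises(EnergyError, match="work segment"):
        aerobic_energy(_flat_series(0.06, 150), tl, 0.05)


# ---------------------------------------------------------------------------
# alactic


def test_alactic_ts_windows_match_closed_form():
    tl = build_timeline(ProtocolSpec.ts(), [21.0] * 4)
    fit = _fit(a=0.030, tau_a=35.0)
    kj = alactic_energy(fit, tl)
    # windows: 900 s once, 180 s three times
    litres = 0.030 * 35.0 * (1 - np.exp(-900 / 35.0)) + 3 * 0.030 * 35.0 * (
        1 - np.exp(-180 / 35.0)
    )
    assert kj == pytest.approx(litres * KJ_PER_L, rel=1e-12)
    assert kj == pytest.approx(87.48, abs=0.02)


def test_cs_minus_ts_alactic_is_exactly_eight_intra_windows():
    fit = _fit()
    cs = alactic_energy(fit, build_timeline(ProtocolSpec.cs(), [7.0] * 12))
    ts = alactic_energy(fit, build_timeline(ProtocolSpec.ts(), [21.0] * 4))
    expected = 8 * component_integral(fit.a, fit.tau_a, 30.0) * KJ_PER_L
    assert cs - ts == pytest.approx(expected, rel=1e-12)
    assert cs > ts


def test_alactic_zero_amplitude_and_flagged_fit():
    tl = build_timeline(ProtocolSpec.ts(), [21.0] * 4)
    assert alactic_energy(_fit(a=0.0), tl) == 0.0
    bad = BiExpFit(a=np.nan, tau_a=np.nan, b=np.nan, tau_b=np.nan, c=np.nan,
                   rss=np.inf, converged=False, n_points=0, recovery_start_s=0.0)
    with pytest.raises(EnergyError, match="converge"):
        alactic_energy(bad, tl)


# ---------------------------------------------------------------------------
# lactic


def test_lactic_hand_value():
    panel = LactatePanel(baseline_mmol_l=1.0, post_mmol_l={60: 3.0})
    person = ParticipantInfo(id="p", body_mass_kg=75.0)
    # 2 mmol/L * 3 mL/kg/mmol * 75 kg = 450 mL = 0.45 L -> 9.414 kJ
    assert lactic_energy(panel, person) == pytest.approx(0.45 * KJ_PER_L, rel=1e-12)


def test_lactic_peak_is_max_post_minus_baseline():
    panel = LactatePanel(baseline_mmol_l=1.2, post_mmol_l={60: 1.9, 180: 3.1, 300: 2.8})
    assert panel.rise_mmol_l == pytest.approx(1.9)


def test_negative_rise_policies():
    panel = LactatePanel(baseline_mmol_l=2.0, post_mmol_l={60: 1.5})
    person = ParticipantInfo(id="p", body_mass_kg=70.0)
    with pytest.warns(UserWarning, match="floored"):
        assert lactic_energy(panel, person) == 0.0
    allowed = lactic_energy(panel, person, negative_policy="allow")
    assert allowed == pytest.approx(-0.5 * 3 * 70 / 1000 * KJ_PER_L)


# ---------------------------------------------------------------------------
# partition


def test_equal_components_give_equal_shares():
    comp = EnergyComponents.from_absolute(10.0, 10.0, 10.0)
    for share in (comp.rel_aerobic_pct, comp.rel_alactic_pct, comp.rel_lactic_pct):
        assert share == pytest.approx(100.0 / 3.0, abs=1e-12)


def test_shares_sum_to_100_for_random_components():
    rng = np.random.default_rng(99)
    for _ in range(200):
        comp = EnergyComponents.from_absolute(*rng.uniform(0.01, 100.0, 3))
        total = comp.rel_aerobic_pct + comp.rel_alactic_pct + comp.rel_lactic_pct
        assert abs(total - 100.0) < 1e-9


def test_degenerate_total_rejected():
    with pytest.raises(EnergyError, match="degenerate"):
        EnergyComponents.from_absolute(0.0, 0.0, 0.0)


def test_lactic_share_monotone_in_lactate_rise():
    tl = build_timeline(ProtocolSpec.ts(), [21.0] * 4)
    fit = _fit(c=0.05)
    series = _flat_series(0.06, tl.total_duration_s)
    person = ParticipantInfo(id="p", body_mass_kg=70.0)
    prev_kj, prev_share = -1.0, -1.0
    for rise in (0.5, 1.0, 2.0, 4.0):
        panel = LactatePanel(baseline_mmol_l=1.0, post_mmol_l={60: 1.0 + rise})
        comp = partition_session(series, tl, fit, panel, person)
        assert comp.lactic_kj > prev_kj
        assert comp.rel_lactic_pct > prev_share
        prev_kj, prev_share = comp.lactic_kj, comp.rel_lactic_pct
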
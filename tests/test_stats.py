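"""Paired tests, exact Wilcoxon, Hedges' g, Holm, and the energy mixed model.

The mixed-model test is checked two ways: against frozen values produced by
R's lmerTest/emmeans on the identical fixture, and live against Rscript.
"""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ergopart.stats import (
    PairedSample,
    StatsError,
    fit_energy_lmm,
    hedges_g_paired,
    holm_adjust,
    paired_t,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def _sample(diffs):
    diffs = np.asarray(diffs, dtype=float)
    ts = np.linspace(10.0, 20.0, len(diffs))
    return PairedSample(cs=ts + diffs, ts=ts)


# ---------------------------------------------------------------------------
# paired t and Hedges' g


def test_paired_t_matches_one_sample_t_on_differences():
    rng = np.random.default_rng(5)
    diffs = rng.normal(-2.0, 3.0, 8)
    res = paired_t(_sample(diffs))
    t_ref, p_ref = sps.ttest_1samp(diffs, 0.0)
    assert res["t"] == pytest.approx(float(t_ref), rel=1e-12)
    assert res["p_two_sided"] == pytest.approx(float(p_ref), rel=1e-12)
    assert res["df"] == 7


def test_t_sign_follows_shift_direction():
    assert paired_t(_sample([3.0, 3.1, 2.9, 3.05]))["t"] > 0
    assert paired_t(_sample([-3.0, -3.1, -2.9, -3.05]))["t"] < 0


def test_antisymmetric_differences_give_t_zero():
    res = paired_t(_sample([-2.0, -1.0, 1.0, 2.0]))
    assert res["t"] == pytest.approx(0.0, abs=1e-12)


def test_zero_variance_differences_rejected():
    with pytest.raises(StatsError, match="variance"):
        paired_t(_sample([1.0, 1.0, 1.0]))


def test_hedges_g_formula_on_six_differences():
    """Six differences with mean -11.0, sd ~5.77 give t ~ -4.67, g ~ -1.60."""
    pattern = np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0])
    target_sd = 11.0 * np.sqrt(6.0) / 4.67
    diffs = -11.0 + pattern * (target_sd / np.std(pattern, ddof=1))
    assert np.mean(diffs) == pytest.approx(-11.0)
    assert np.std(diffs, ddof=1) == pytest.approx(5.77, abs=0.01)
    res = paired_t(_sample(diffs))
    assert res["t"] == pytest.approx(-4.67, abs=0.005)
    assert res["hedges_g"] == pytest.approx(-1.60, abs=0.01)


def test_hedges_g_is_scale_free():
    diffs = np.array([-3.0, -1.0, -2.0, -4.0, -2.5])
    g1 = hedges_g_paired(_sample(diffs))
    g2 = hedges_g_paired(_sample(diffs * 7.3))
    assert g1 == pytest.approx(g2, rel=1e-12)


# ---------------------------------------------------------------------------
# exact Wilcoxon


def test_wilcoxon_six_one_signed_differences_exact_p():
    res = wilcoxon_signed_rank(_sample([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
    assert res["p_exact_two_sided"] == pytest.approx(2.0 / 64.0)  # 0.03125


def test_wilcoxon_one_flip_increases_p():
    res = wilcoxon_signed_rank(_sample([-1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
    assert res["p_exact_two_sided"] > 0.03125


def test_wilcoxon_minimum_p_for_two_pairs():
    res = wilcoxon_signed_rank(_sample([1.0, 2.0]))
    assert res["p_exact_two_sided"] == pytest.approx(0.5)


def test_wilcoxon_matches_scipy_exact_for_n12():
    rng = np.random.default_rng(11)
    diffs = rng.normal(0.8, 1.0, 12)
    res = wilcoxon_signed_rank(_sample(diffs))
    ref = sps.wilcoxon(diffs, method="exact")
    assert abs(res["p_exact_two_sided"] - float(ref.pvalue)) < 0.005


def test_wilcoxon_drops_zero_differences_with_warning():
    with pytest.warns(UserWarning, match="zero difference"):
        res = wilcoxon_signed_rank(_sample([0.0, 1.0, 2.0, 3.0]))
    assert res["n_used"] == 3


def test_wilcoxon_all_zero_rejected():
    with pytest.raises(StatsError, match="zero"):
        wilcoxon_signed_rank(_sample([0.0, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# Shapiro-Wilk and Holm


def test_shapiro_contract():
    with pytest.raises(StatsError):
        shapiro_wilk([1.0, 2.0])
    rng = np.random.default_rng(3)
    normal = shapiro_wilk(rng.normal(0, 1, 50))
    skewed = shapiro_wilk(rng.exponential(1.0, 50))
    assert 0 < skewed["W"] < normal["W"] <= 1.0


def test_holm_monotone_and_bounded():
    raw = np.array([0.001, 0.04, 0.03])
    adj = holm_adjust(raw)
    assert np.all(adj >= raw)
    order = np.argsort(raw)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert holm_adjust([0.02])[0] == pytest.approx(0.02)


# ---------------------------------------------------------------------------
# mixed model


def _lmm_fixture() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    eff = {
        ("aerobic", "CS"): 35, ("aerobic", "TS"): 45,
        ("alactic", "CS"): 62, ("alactic", "TS"): 47,
        ("lactic", "CS"): 3, ("lactic", "TS"): 8,
    }
    rows = []
    for i in range(6):
        u = rng.normal(0, 2)
        for s in ("aerobic", "alactic", "lactic"):
            for p in ("CS", "TS"):
                rows.append(
                    {"participant": f"P{i}", "system": s, "protocol": p,
                     "rel_pct": eff[(s, p)] + u + rng.normal(0, 3)}
                )
    return pd.DataFrame(rows)


def test_lmm_matches_frozen_lmerTest_values():
    """Interaction F / Satterthwaite ddf / contrasts frozen from R lmerTest
    + emmeans run on this exact fixture."""
    res = fit_energy_lmm(_lmm_fixture())
    assert res["interaction"]["F"] == pytest.approx(75.2941, rel=1e-4)
    assert res["interaction"]["ndf"] == 2
    assert res["interaction"]["ddf"] == pytest.approx(25.0, abs=0.1)
    assert res["interaction"]["p"] == pytest.approx(2.6115e-11, rel=1e-3)
    by_system = {c["system"]: c for c in res["contrasts"]}
    assert by_system["aerobic"]["estimate"] == pytest.approx(-10.8949, abs=1e-3)
    assert by_system["aerobic"]["se"] == pytest.approx(1.5924, abs=1e-3)
    assert by_system["alactic"]["t"] == pytest.approx(9.3285, abs=1e-3)
    assert by_system["lactic"]["df"] == pytest.approx(25.0, abs=0.1)


def test_lmm_matches_live_lmerTest(tmp_path):
    """Independent oracle: fit the same fixture with lme4/lmerTest in R."""
    data_path = tmp_path / "lmm.csv"
    _lmm_fixture().to_csv(data_path, index=False)
    script = tmp_path / "check.R"
    script.write_text(
        """
suppressMessages({library(lme4); library(lmerTest); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$system <- factor(d$system); d$protocol <- factor(d$protocol)
contrasts(d$system) <- contr.sum; contrasts(d$protocol) <- contr.sum
m <- lmer(rel_pct ~ system * protocol + (1 | participant), data = d)
a <- anova(m, type = 3)
row <- a["system:protocol", ]
cat(toJSON(list(F = row$`F value`, ddf = row$DenDF, p = row$`Pr(>F)`),
           digits = 12, auto_unbox = TRUE))
"""
    )
    out = subprocess.run(
        ["Rscript", str(script), str(data_path)],
        capture_output=True, text=True, timeout=300,
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    res = fit_energy_lmm(_lmm_fixture())
    assert res["interaction"]["F"] == pytest.approx(ref["F"], rel=1e-5)
    assert res["interaction"]["ddf"] == pytest.approx(ref["ddf"], abs=0.05)
    assert res["interaction"]["p"] == pytest.approx(ref["p"], rel=1e-3)


def test_lmm_null_table_gives_near_zero_interaction():
    rows = []
    profile = {"aerobic": 40.0, "alactic": 52.0, "lactic": 8.0}
    rng = np.random.default_rng(0)
    for i in range(6):
        u = rng.normal(0, 2)
        for s, v in profile.items():
            noise = rng.normal(0, 0.5, 2)
            for p, eps in zip(("CS", "TS"), noise):
                rows.append(
                    {"participant": f"P{i}", "system": s, "protocol": p,
                     "rel_pct": v + u + eps}
                )
    res = fit_energy_lmm(pd.DataFrame(rows))
    assert res["interaction"]["p"] > 0.05
    assert all(c["p_holm"] > 0.05 for c in res["contrasts"])


def test_lmm_missing_cell_rejected():
    table = _lmm_fixture()
    table = table[~((table.participant == "P0") & (table.system == "lactic")
                    & (table.protocol == "TS"))]
    with pytest.raises(StatsError, match="missing cells"):
        fit_energy_lmm(table)


def test_lmm_needs_three_participants():
    table = _lmm_fixture()
    with pytest.raises(StatsError, match="participants"):
        fit_energy_lmm(table[table.participant.isin(["P0", "P1"])])
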
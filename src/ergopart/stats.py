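"""Inferential statistics for the two-condition (CS vs TS) crossover.

Small-sample tools: Student's paired t-test with a difference-score Hedges'
g (small-sample correction 1 - 3/(4*df - 1)), an exact Wilcoxon signed-rank
test by full enumeration of sign assignments (n <= 12), Shapiro-Wilk
normality checks, and a linear mixed-effects model on relative energy
contributions (rel_pct ~ system * protocol with participant random
intercepts) with a type-III interaction F test using Satterthwaite
denominator degrees of freedom and Holm-corrected protocol contrasts per
energy system.

The mixed model itself is fitted by REML through statsmodels; the
Satterthwaite machinery (not available in statsmodels) is implemented here
on the profiled REML likelihood of the two variance components, following
the standard approach of propagating the uncertainty of the variance
estimates into each contrast's variance via the delta method, with the
multi-df F handled by the Fai-Cornelius eigen-decomposition used by
lmerTest.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "StatsError",
    "paired_t",
    "hedges_g_paired",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "holm_adjust",
    "fit_energy_lmm",
    "SYSTEMS",
    "PROTOCOLS",
]

SYSTEMS = ("aerobic", "alactic", "lactic")
PROTOCOLS = ("CS", "TS")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSample:
    """Per-participant value pairs for the two protocols."""

    cs: np.ndarray
    ts: np.ndarray
    participants: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        cs = np.asarray(self.cs, dtype=float)
        ts = np.asarray(self.ts, dtype=float)
        object.__setattr__(self, "cs", cs)
        object.__setattr__(self, "ts", ts)
        if cs.shape != ts.shape or cs.ndim != 1:
            raise StatsError("cs and ts must be 1-d arrays of equal length")
        if len(cs) < 2:
            raise StatsError("need >= 2 pairs")
        if not (np.all(np.isfinite(cs)) and np.all(np.isfinite(ts))):
            raise StatsError("non-finite values in paired sample")

    @property
    def diff(self) -> np.ndarray:
        """CS - TS differences."""
        return self.cs - self.ts

    @property
    def n(self) -> int:
        return len(self.cs)


def hedges_g_paired(sample: PairedSample) -> float:
    """Hedges' g for paired data: mean(diff)/sd(diff) * (1 - 3/(4*df - 1)).

    Standardizes by the SD of the difference scores (ddof=1) and applies
    the usual small-sample correction with df = n - 1.
    """
    d = sample.diff
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise StatsError("zero difference variance: g undefined")
    df = sample.n - 1
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(np.mean(d)) / sd * correction


def paired_t(sample: PairedSample) -> dict:
    """Student's paired t-test (two-sided) on CS - TS with Hedges' g."""
    d = sample.diff
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise StatsError("zero difference variance: t undefined")
    n = sample.n
    t = float(np.mean(d)) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return {"t": t, "df": df, "p_two_sided": p, "hedges_g": hedges_g_paired(sample)}


def wilcoxon_signed_rank(sample: PairedSample, max_exact_n: int = 12) -> dict:
    """Exact two-sided Wilcoxon signed-rank test by sign enumeration.

    Zero differences are dropped (Wilcoxon's original treatment) with a
    warning; ties among |differences| get average ranks, and the exact
    two-sided p enumerates all 2^n sign assignments of the observed
    absolute differences: p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = sample.diff
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise StatsError("all differences are zero: test undefined")
    if nonzero.size < d.size:
        warnings.warn(
            f"dropping {d.size - nonzero.size} zero difference(s)", stacklevel=2
        )
    n = nonzero.size
    if n > max_exact_n:
        raise StatsError(f"exact enumeration limited to n <= {max_exact_n} (got {n})")
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    # all achievable W+ values over 2^n sign assignments of these ranks
    totals = np.zeros(2**n)
    for i, signs in enumerate(itertools.product((0.0, 1.0), repeat=n)):
        totals[i] = float(np.dot(signs, ranks))
    le = float(np.mean(totals <= w_plus + 1e-12))
    ge = float(np.mean(totals >= w_plus - 1e-12))
    p = min(1.0, 2.0 * min(le, ge))
    return {"statistic": w_plus, "n_used": n, "p_exact_two_sided": p}


def shapiro_wilk(values) -> dict:
    """Shapiro-Wilk normality test (W in (0, 1])."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise StatsError("Shapiro-Wilk requires n >= 3")
    w, p = sps.shapiro(values)
    return {"W": float(w), "p": float(p)}


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (order preserved)."""
    p_values = np.asarray(p_values, dtype=float)
    return multipletests(p_values, method="holm")[1]


# ---------------------------------------------------------------------------
# linear mixed model with Satterthwaite degrees of freedom


def _design_row(system: str, protocol: str) -> np.ndarray:
    """Sum-to-zero (deviation) coded row: [1, s1, s2, p1, s1*p1, s2*p1]."""
    s1 = {"aerobic": 1.0, "alactic": 0.0, "lactic": -1.0}[system]
    s2 = {"aerobic": 0.0, "alactic": 1.0, "lactic": -1.0}[system]
    p1 = {"CS": 1.0, "TS": -1.0}[protocol]
    return np.array([1.0, s1, s2, p1, s1 * p1, s2 * p1])


def _group_blocks(X, y, groups):
    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], np.asarray(groups)[order]
    blocks = []
    for g in pd.unique(groups):
        m = groups == g
        blocks.append((X[m], y[m]))
    return blocks


def _beta_cov(theta, blocks):
    """GLS fixed-effect covariance C(theta) and estimate for the
    random-intercept model V_i = s2e*I + s2b*J (Woodbury inverse)."""
    s2b, s2e = theta
    p = blocks[0][0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for Xi, yi in blocks:
        ni = len(yi)
        w = s2b / (s2e + ni * s2b)
        xs = Xi.sum(axis=0)
        ys = yi.sum()
        xtvx += (Xi.T @ Xi - w * np.outer(xs, xs)) / s2e
        xtvy += (Xi.T @ yi - w * xs * ys) / s2e
    C = np.linalg.inv(xtvx)
    beta = C @ xtvy
    return C, beta


def _reml_loglik(theta, blocks):
    s2b, s2e = theta
    if s2e <= 0 or s2b < 0:
        return -np.inf
    p = blocks[0][0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for Xi, yi in blocks:
        ni = len(yi)
        w = s2b / (s2e + ni * s2b)
        xs = Xi.sum(axis=0)
        ys = yi.sum()
        xtvx += (Xi.T @ Xi - w * np.outer(xs, xs)) / s2e
        xtvy += (Xi.T @ yi - w * xs * ys) / s2e
        ytvy += (yi @ yi - w * ys * ys) / s2e
        logdet += (ni - 1) * np.log(s2e) + np.log(s2e + ni * s2b)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    C = np.linalg.inv(xtvx)
    beta = C @ xtvy
    ytpy = ytvy - xtvy @ beta
    return -0.5 * (logdet + logdet_xtvx + ytpy)


def _fd_hessian(f, theta, rel_step=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = np.maximum(np.abs(theta), 1e-8) * rel_step
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _satterthwaite_df(l, theta, blocks, theta_cov, rel_step=1e-4):
    """nu = 2*phi^2 / (grad phi' A grad phi), phi(theta) = l' C(theta) l."""
    def phi(th):
        C, _ = _beta_cov(th, blocks)
        return float(l @ C @ l)

    h = np.maximum(np.abs(theta), 1e-8) * rel_step
    grad = np.zeros(2)
    for i in range(2):
        ei = np.zeros(2); ei[i] = h[i]
        grad[i] = (phi(theta + ei) - phi(theta - ei)) / (2 * h[i])
    denom = float(grad @ theta_cov @ grad)
    phi0 = phi(theta)
    if denom <= 0:
        return np.inf
    return 2.0 * phi0**2 / denom


def fit_energy_lmm(table: pd.DataFrame) -> dict:
    """Mixed model on relative energy shares: rel_pct ~ system * protocol
    + (1 | participant).

    ``table`` must be long with columns participant, protocol, system,
    rel_pct and a complete 3x2 grid per participant (>= 3 participants).
    Returns the type-III interaction F test (numerator df 2, Satterthwaite
    denominator df) and the three Holm-corrected CS-TS contrasts on the
    estimated marginal means, one per energy system.
    """
    required = {"participant", "protocol", "system", "rel_pct"}
    if not required <= set(table.columns):
        raise StatsError(f"table must have columns {sorted(required)}")
    participants = pd.unique(table["participant"])
    if len(participants) < 3:
        raise StatsError("need >= 3 participants")
    expected = {(s, p) for s in SYSTEMS for p in PROTOCOLS}
    missing = []
    for part in participants:
        sub = table[table["participant"] == part]
        got = set(zip(sub["system"], sub["protocol"]))
        missing.extend((part, s, p) for (s, p) in expected - got)
    if missing:
        raise StatsError(f"missing cells: {missing[:6]}")

    X = np.vstack([
        _design_row(s, p) for s, p in zip(table["system"], table["protocol"])
    ])
    y = table["rel_pct"].to_numpy(dtype=float)
    groups = table["participant"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary-variance convergence chatter
        res = MixedLM(y, X, groups=groups).fit(reml=True)
    s2e = float(res.scale)
    s2b = float(np.asarray(res.cov_re)[0, 0])
    theta = np.array([max(s2b, 1e-10), s2e])

    blocks = _group_blocks(X, y, groups)
    C, beta = _beta_cov(theta, blocks)

    H = _fd_hessian(lambda th: _reml_loglik(th, blocks), theta)
    try:
        theta_cov = np.linalg.inv(-H)
        if np.any(np.diag(theta_cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # boundary / singular information: fall back to residual df on t tests
        theta_cov = None

    n_obs, p_fix = X.shape
    resid_df = n_obs - p_fix - (len(participants) - 1)

    def contrast_df(l):
        if theta_cov is None:
            return float(resid_df)
        return float(_satterthwaite_df(l, theta, blocks, theta_cov))

    # type III interaction F (coefficients 4 and 5)
    L = np.zeros((2, 6))
    L[0, 4] = 1.0
    L[1, 5] = 1.0
    M = L @ C @ L.T
    lb = L @ beta
    q = 2
    F = float(lb @ np.linalg.solve(M, lb)) / q
    # Fai-Cornelius: eigen-decompose the contrast covariance into 1-df parts
    eigval, eigvec = np.linalg.eigh(M)
    nus = []
    for m in range(q):
        lm = eigvec[:, m] @ L
        nus.append(contrast_df(lm))
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    ddf = 2.0 * E / (E - q) if E > q else float(resid_df)
    p_inter = float(sps.f.sf(F, q, ddf))

    contrasts = []
    for system in SYSTEMS:
        l = _design_row(system, "CS") - _design_row(system, "TS")
        est = float(l @ beta)
        se = float(np.sqrt(l @ C @ l))
        df = contrast_df(l)
        t = est / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
        contrasts.append(
            {"system": system, "estimate": est, "se": se, "t": t, "df": df, "p_raw": p}
        )
    adj = holm_adjust([c["p_raw"] for c in contrasts])
    for c, pa in zip(contrasts, adj):
        c["p_holm"] = float(pa)

    emm = {
        (s, p): float(_design_row(s, p) @ beta) for s in SYSTEMS for p in PROTOCOLS
    }
    return {
        "sigma2_participant": s2b,
        "sigma2_residual": s2e,
        "fixed_effects": beta.tolist(),
        "interaction": {"F": F, "ndf": q, "ddf": float(ddf), "p": p_inter},
        "contrasts": contrasts,
        "emm": {f"{s}:{p}": v for (s, p), v in emm.items()},
    }
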
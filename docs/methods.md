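# Methods

This note documents the modelling choices, conventions and numerical
decisions in `ergopart`, in the spirit of a methods appendix: what the
package computes, under which assumptions, and where the genuinely open
choices were resolved.

## The PCr-La-O₂ partition for intermittent exercise

The method attributes the energy turnover of a resistance-exercise session
to three pathways. Aerobic energy is the baseline-adjusted oxygen uptake
integrated over the work periods; anaerobic-alactic energy is the fast
component of post-exercise V̇O₂ decay — conventionally read as
phosphocreatine resynthesis — integrated over every rest window; and
anaerobic-lactic energy is the net baseline-to-peak blood-lactate rise
converted through a fixed oxygen equivalent. Conversion constants:
20.92 kJ per litre O₂ and 3 mL O₂ per kg body mass per mmol·L⁻¹ lactate.

Key modelling assumptions, made explicit because they are assumptions and
not measurements:

- **One recovery fit serves every rest window.** The bi-exponential model
  is fitted once, to the 900-s final recovery; its fast-component
  parameters (a, τₐ) are re-used for each 30-s intra-set and 180-s
  inter-set window with local time restarting at 0. Short rests do not
  contain enough decay to support their own fits. This encodes an
  equal-repayment assumption — the fast-component amplitude after every
  cluster/set is taken to equal that after the final set.
- **Rest attribution.** Measured V̇O₂ integrals over rest windows are
  removed from the aerobic (exercise) integral — algebraically, the
  aerobic integral runs over work segments only — while the alactic credit
  uses the modelled fast component. The slow component during inter-set
  rests is deliberately attributed to neither side. An alternative policy
  (`rest_subtraction="modelled"`) subtracts modelled fast+slow component
  integrals from the whole exercise-phase integral instead.
- **Lactate is time-independent.** ΔLa uses the maximum of the
  post-exercise samples (+1/+3/+5 min) minus baseline; the pre-final-set
  sample is quality control only and enters no formula. A negative net
  rise is floored at 0 with a warning by default (`"allow"` propagates it).

## V̇O₂ preprocessing conventions

Breath-by-breath samples arrive at irregular intervals. They are linearly
interpolated onto a whole-second grid, smoothed with a centred 10-point
moving average, and expressed in L/s (relative units are converted using
body mass).

- **Even-window centring.** A "centred" 10-point window is ambiguous for
  even lengths; the default averages samples i−5…i+4, and the alternative
  i−4…i+5 is a policy switch (`smoothing_centring`). The window shrinks at
  the series edges. Two provable consequences are worth knowing: the
  smoother delays a linear trend by exactly half a sample, and it rescales
  any exponential component's amplitude by mean(exp(s/τ)) over the window
  offsets — about +2.7% for τ = 25 s, +1.8% for τ = 35 s, negligible for
  slow components. Time constants and constant baselines are untouched.
  The tests assert amplitude recovery at 3% for this reason, while time
  constants and baseline are held to 1%.
- **Fit window.** The recovery fit uses the smoothed series from the
  manual recovery mark over 900 s by default, *excluding the first 10 s*
  (`fit_skip_s`): those grid points' smoothing windows straddle the
  exercise→recovery transition and mix exercise samples into the decay
  curve. Numerically, including them biases τₐ upward by ~8–12% even on
  noise-free data; excluding them removes the bias entirely. The model's
  t = 0 remains at the mark regardless.
- **Fitting.** Bounded least squares (`scipy.optimize.curve_fit`) with
  a, b, c ∈ [0, 3 × window peak], τₐ ∈ [5, 120] s, τ_b ∈ [120, 1800] s —
  the bound at 120 s encodes the physiological fast/slow separation.
  Initialisation: c₀ = mean of the final 120 s, the initial elevation
  split 70/30 between fast and slow, (τₐ₀, τ_b₀) = (30, 300) s, with a
  5-point multi-start over (τₐ₀, τ_b₀) if the first attempt fails. After
  fitting, components are sorted so τₐ < τ_b. Non-convergence yields a
  flagged result; energy operations refuse flagged fits unless forced.
- **Integration.** Measured-series integrals use the trapezoidal rule on
  the 1-s grid with linearly interpolated partial-second window edges;
  modelled component integrals use the closed form a·τ·(1 − e^(−D/τ)).

## Velocity loss

Per set, VL = 100·(fastest − last)/fastest using mean propulsive velocity;
the fastest repetition may occur at any position, so normalized profiles
(percent of the set's fastest rep) need not start at 100%. Ties for fastest
are resolved by value (index irrelevant). Values are kept at full precision;
rounding is presentation-only.

## Group statistics

- **Paired t / Hedges' g.** g standardizes the mean difference by the SD of
  the difference scores with the small-sample correction 1 − 3/(4·df − 1).
  This difference-score variant (rather than a pooled-SD variant) is the
  one whose value is numerically consistent with a printed paired
  t-statistic at n = 6: g = t/√n × correction.
- **Exact Wilcoxon.** The two-sided p enumerates all 2ⁿ sign assignments of
  the observed absolute differences (n ≤ 12), handling rank ties by average
  ranks; zero differences are dropped with a warning. For n = 6 one-signed
  differences this gives p = 2/64 = 0.03125.
- **Mixed model.** `rel_pct ~ system × protocol + (1 | participant)` is
  fitted by REML via statsmodels; type-III tests and per-system CS−TS
  contrasts use Satterthwaite denominator degrees of freedom implemented on
  the profiled REML likelihood of the two variance components (delta-method
  variance of each contrast's variance; Fai–Cornelius eigen-decomposition
  for the 2-df interaction F). The implementation reproduces R's
  lmerTest/emmeans to four significant figures on a fixed test dataset,
  which the suite checks both against frozen values and live through
  Rscript. Relative percentages are modelled untransformed; their
  compositional non-independence (shares sum to 100) is acknowledged, not
  corrected. α = 0.05 two-sided throughout; Holm correction across the
  three contrasts. If the participant variance collapses to the boundary
  the Satterthwaite information matrix is singular; the code then falls
  back to the residual degrees of freedom.

## The synthetic-session generator

The generator emulates the measurement conditions of a four-set, six-rep
back-squat crossover: irregular breath timing (3 s mean interval, ±30%
uniform jitter), additive Gaussian V̇O₂ noise (default SD 5% of the
noiseless peak), mono-exponential on-kinetics toward a work demand during
lifting, bi-exponential off-kinetics at every rest onset (amplitudes scaled
to the current elevation in the configured fast:slow ratio so the path is
continuous), per-rep velocity decline with exponential recovery during
rests, and threshold-triggered lactate accumulation with exponential
clearance.

Defaults (per-session ground truth): body mass 72 kg; baseline 0.006 L/s
(5 mL·kg⁻¹·min⁻¹); on-kinetics τ 15 s toward a 0.050 L/s elevation demand;
recovery fast/slow amplitudes 0.022/0.013 L/s with τₐ = 25 s, τ_b = 300 s;
repetition duration 3.5 s; MPV base 0.70 m/s, fatigue increment 0.04/rep,
rest-recovery τ 60 s; lactate baseline 1.2 mmol/L, +0.55 mmol/L per rep
performed above fatigue 0.10, clearance 0.004 s⁻¹. These were chosen once
so that noiseless sessions land near the magnitudes reported for this kind
of protocol (CS alactic share ~70%, TS aerobic share ~40%, VL ~11 vs ~20%,
lactate rise ~0.7 vs ~2.4 mmol/L) while remaining a deliberately simple
caricature. Cohort generation draws per-participant physiology around these
defaults from one master seed; a participant's two sessions share their
physiology and differ only in breath noise.

The **truth ledger** applies the analysis attribution rules in closed form
to the noiseless path: work-segment elevation integrals (aerobic), the
final-recovery fast amplitude over every rest window (alactic), and the
lactate rise as observable at the post-exercise sampling times (lactic).
It is therefore the value an exact analysis of noiseless data should
produce — the right yardstick for pipeline-recovery tests — rather than a
per-window generative bookkeeping, which would differ from any analysis
bound by the one-fit-serves-all-windows assumption.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: Valsalva-induced breathing artefacts, true
breath-by-breath variability structure (noise is white Gaussian), slow-
component growth across sets, repetition-tempo variability, lactate
kinetics beyond single-pool exponential clearance, and any between-session
biological drift. Velocity has no stochastic term, so a "duplicated
cohort" has exactly zero VL difference variance and the paired t is
(correctly) undefined there.

## Problem sizes

The test suite and the acceptance script run full pipelines on simulated
sessions of ~1 600–1 900 s at 1 Hz grids (~650 breaths): a CS/TS pair
analyses in ~20 ms, so the directional check over 100 seeded pairs and the
200-replicate noisy-recovery comparison against a 40×40 grid-search oracle
complete in seconds. The acceptance cohort uses n = 6 participants,
matching the crossover design the defaults emulate.

## Known limitations

- The equal-repayment assumption almost certainly overstates the alactic
  credit of early intra-set pauses, when elevation is still low; the truth
  ledger adopts the same convention, so this bias cancels in recovery tests
  but not in reality.
- The moving-average amplitude rescale (+~2–3% on the fast amplitude)
  propagates into the alactic energy; it is a property of the prescribed
  smoothing, documented rather than corrected.
- Baseline c is estimated per session from the recovery fit; no cross-
  session constraint is applied, and simulated single-session noise can
  move it visibly (the README example shows 3.4 vs the generative
  5 mL·kg⁻¹·min⁻¹).
- Synthetic effect sizes for velocity loss are larger than a heterogeneous
  human cohort would produce, because between-participant variation enters
  only through the drawn physiology parameters.
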
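# Methods

## Load-dependent detachment model

The core quantity is the detachment rate of a myosin head from actin under
load. Instantaneously the rate follows a Bell/Arrhenius law,
k(t) = k₀·exp(−δ·F(t)/k_BT); in the harmonic-force-spectroscopy (HFS)
geometry the load during one binding event is F(t) = F + ΔF·cos(ωt + φ)
with the binding phase φ random. Averaging the instantaneous hazard over
one oscillation period gives the closed form

    k_det(F, ΔF) = k₀ · I₀(ΔF·δ/k_BT) · exp(−F·δ/k_BT),

where I₀ is the zero-order modified Bessel function of the first kind
(`scipy.special.i0`; a power-series oracle in the tests verifies it to
1e-10). Positive F is resistive throughout the package. The cycle average
is a good description of the dwell-time distribution when the oscillation
is fast relative to detachment; at the default 200 Hz drive and rates up
to ~150 s⁻¹ the residual finite-frequency error measured against the exact
thinning simulation is ~0.2%.

Constants: k_BT defaults to 4.0888 pN·nm (23 °C, the trap temperature);
`TrapConstants.at_temperature` rebuilds consistent constants elsewhere in
the 21–23 °C band. Trap stiffnesses default to 0.09 pN/nm each; the
stiffness acting on a bound head is taken as their sum (a series-dumbbell
simplification that ignores actin and linkage compliance).

## Synthetic data: what it emulates and what it does not

`simulate_events` draws, per event, a mean force F ~ U(−5, 5) pN, an
amplitude ΔF ~ U(1, 4) pN and a uniform binding phase, then samples the
dwell from the exact inhomogeneous-exponential survival law by thinning
(rejection against the envelope hazard at the most load-relieved instant).
The experimental distributions of per-event F and ΔF are not published for
this kind of assay; the uniform ranges are package choices wide enough to
exercise the fit. Events shorter than `min_detectable_duration` (default
two oscillation periods, 10 ms) are dropped — the hard-truncation model of
what a lock-in detector can score. Displacements are step + Gaussian noise
(default SD 1.4 nm, matching the molecule-to-molecule step spread of a
wild-type-like motor).

`simulate_trace` renders events as a sampled dumbbell trace: unbound beads
carry a weak stage-frequency carrier (3 nm, lagging phase, viscous
coupling); bound beads oscillate at ΔF/κ_sys with an elastic phase and a
mean offset of F/κ_sys. In this trace model the bound-state mean offset
*is* the load observable — the working stroke is subsumed in where the
dumbbell settles — so trace-derived `displacement` is load-proportional
and is not a step-size estimate; step sizes come from event tables. Real
traces additionally contain slow drift, bead-size asymmetries, actin
compliance, and double-motor events, none of which are simulated; passing
the round-trip tests therefore validates the estimator chain, not
robustness to every instrumental pathology.

Bulk generators: Michaelis-Menten plates with multiplicative lognormal
replicate noise (CV 5% default, matching plate-reader practice) and
optional planted >50% outliers; biexponential single-turnover decays with
plateau and dead time (defaults: 57% slow amplitude, rates 0.030 and
0.003 s⁻¹, 16 min read — typical for a two-headed construct with tail);
linear gel dilution series (ELC/HC 0.19, RLC/HC 0.11) with optional
saturation of the top load.

## Event detection

Detection follows the amplitude/phase signature of binding: a sliding
rectangular window (default two periods, hop = window/2) is projected onto
the stage-frequency quadratures; events are maximal excursions of the
window amplitude from its trace-wide median, scored in robust sigma units
(MAD × 1.4826) with 5σ entry, 50% hysteresis exit, and both-bead
coincidence required. Phase is computed and carried along but does not
trigger, as no numeric phase criterion is established for this assay.

Boundary refinement matters because the hop (~5 ms) is comparable to fast
dwells (~7 ms at zero load): a quantization-scale duration error feeds
straight into the rate MLE. Each coarse boundary is refined by a
maximum-likelihood change point on the raw bead-averaged signal, comparing
explicit unbound and bound signal models (offset + complex oscillation
amplitude, the latter estimated from a Hann-weighted sample-resolution
demodulation whose kernel nulls DC leakage at the drive frequency). The
refined boundaries are exact on noiseless traces and have ~0.2 ms RMS
error at 2 nm position noise; simpler schemes (window-center interpolation
of the demodulated amplitude) were measured to leave 0.5–1 ms systematic
biases worth 10–15% in k₀ and were rejected. Per event, the load is
κ_sys × mean offset and the harmonic amplitude is κ_sys × bound oscillation
amplitude (an amplitude *difference* would under-read because the unbound
carrier has a different phase).

## Dwell-time fitting

Per force bin, the rate MLE for left-truncated exponential data is
n/Σ(tᵢ − t_min) with SE rate/√n; records at or below t_min are rejected as
censoring-inconsistent. Ignoring the truncation biases rates, k₀ and δ
strongly *downward* (each observed dwell is ~t_min longer than an
untruncated draw would be; measured ~−50% at default censoring), so t_min
is threaded through the whole chain and defaults to the simulator's
detectability floor.

Per molecule, two routes produce (k₀, δ):

* **Per-event truncated MLE (default).** Each event contributes
  log kᵢ − kᵢ(tᵢ − t_min) with kᵢ evaluated at the event's own (Fᵢ, ΔFᵢ);
  maximized over (log k₀, δ) by Nelder-Mead, SEs from the numerically
  differentiated observed information. This uses all per-event covariates
  and has no small-bin pathology: measured bias <1% with ~2% seed-to-seed
  spread at the 10-molecule scale.
* **Binned weighted NLS (`method="binned"`).** Fixed 1 pN bins (≥5 events,
  within-bin mean F and ΔF), bin rates fitted to the closed form with
  1/SE² weights. This is the classic presentation-style route; because the
  weights correlate with downward rate fluctuations it carries a small
  (~3%) systematic bias, which is why it is not the default. The two
  routes are tested to agree within 5% (k₀) and 10% (δ) on 3×10⁴-event
  data.

Group summaries average molecule-level values (mean ± SEM; step mean ± SD,
without compliance correction) and compare groups by Welch's t-test with
each molecule as one replicate. Percent changes are 100·(mutant/WT − 1)
with first-order ratio SE propagation, computed from unrounded means.

## Ensemble mechanics

Duty ratio, average force, velocity and power follow the cycle algebra in
the README, evaluated on a resistive grid (0–10 pN, 0.1 pN). The ensemble
k_det uses ΔF = 0 by default: the sinusoid is an instrument artifact, not
physiology (`duty_ratio(..., include_harmonic_amp=...)` re-enables the
Bessel factor). Error bands are Monte Carlo: independent Gaussian draws of
(k₀, δ, k_cat, d) at their SEMs, truncated to the validity region
k₀ > k_cat > 0, δ ≥ 0 (redraw on violation; >20% redraws abort because the
Gaussian error model is then inconsistent with the means), pointwise
16th/84th percentiles over 10⁴ draws. A first-order delta-method band is
provided as a cross-check and agrees within 15% of the MC half-width when
relative errors are ≲10%. Independence of the parameter errors is an
acknowledged simplification — within a molecule k₀ and δ estimates are
correlated, so the bands are approximate. Qualitative comparisons label a
construct hyper-/hypocontractile by the majority sign of the power
difference over grid points where the bands are disjoint (the whole grid
and its upper half are reported separately, since power differences
concentrate at high load).

## Bulk assays

* **Triplicate rejection**: a technical replicate is rejected iff it
  differs from *each* companion by >50% of that companion's value; at most
  one of three is removed. Under the simulator's default 5% noise the rule
  fires on <5% of points — it is a gross-error filter, not a trimming rule.
* **Michaelis-Menten**: unweighted least squares in rate space (plate-reader
  practice), zero-actin basal rates reported separately and never fitted;
  K_app beyond the tested actin range is flagged. Same-day normalization
  divides by a control k_cat and is exactly idempotent.
* **Biexponential single turnover**: F(t) = a_f·e^(−r_f t) + a_s·e^(−r_s t) + c,
  with %slow = 100·a_s/(a_f + a_s) — the plateau is excluded, consistent
  with normalizing fitted curves to Y₀ = 1, plateau = 0. The alternative
  (including the plateau in the denominator) is deliberately not used.
  "Ambiguous" is operationalized as rate separation < 3× or an amplitude
  95% CI crossing zero; such fits are flagged, never silently dropped.
* **Gel stoichiometry**: per chain, the highest load is greedily pruned
  while its removal improves the linear-fit R² by >0.02 (≥3 points kept) —
  a concrete stand-in for by-eye removal of saturated loads; ratios are
  slope ratios with propagated SE.
* **t-tests**: paired and Welch (Welch-Satterthwaite df) via scipy;
  degenerate zero-variance identical inputs return t = 0, p = 1 rather
  than NaN. The Welch null calibration (type-I error 0.05 ± 0.01 at 10⁴
  replicates) is part of the test suite.

## Problem sizes and numerical choices

Seeded simulations in the tests and the acceptance script use 10 molecules
× 2000 attempted events (~450 surviving the 10 ms floor per molecule),
sizes at which the recovery tolerances (5% on k₀, 8% on δ) sit several
seed-level standard deviations from the thresholds. The trace benchmark
renders ~60 s of 10 kHz data per molecule. Nelder-Mead tolerances are
xatol 1e-8 / fatol 1e-10; curve fits run with non-negativity bounds and
log-linear warm starts; δ fitted below 1e-4 nm is reported as "pinned at
zero" and the molecule is excluded from group summaries with a warning.

## Known limitations

* The trace model is phenomenological: no Brownian bead dynamics, trap
  asymmetry, drift, or multi-motor events; detector performance numbers
  are meaningful relative to this model only.
* Step sizes are reported without compliance correction and are therefore
  smaller than the true working stroke, by design.
* Ensemble error bands assume independent parameter errors.
* The attachment rate is treated as force-independent; duty-ratio algebra
  requires k_cat < k₀ and refuses otherwise.
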
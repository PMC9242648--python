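# hfskit

Single-molecule and bulk kinetics analysis for β-cardiac myosin motors:
harmonic force spectroscopy (HFS) detachment-rate modelling, ensemble
duty-ratio/force/power calculation, actin-activated ATPase autoinhibition
ratios, and single-turnover SRX/DRX decomposition — together with
synthetic-data generators that stand in for the optical trap and the
plate reader.

## Who this is for

Hypertrophic cardiomyopathy mutations in β-cardiac myosin change the
motor's intrinsic mechanochemistry, its load sensitivity, and its tail-based
autoinhibition. Dissecting those changes requires combining a dual-beam
optical-trap dumbbell assay (where the stage oscillates so each binding
event feels a mean load *F* plus a sinusoidal component of amplitude *ΔF*)
with plate-scale ATPase and fluorescence assays. `hfskit` implements the
full analysis chain for such a study as a tested, reusable library, and
ships simulators with the statistical structure the analysis assumes so
every estimator can be validated against known ground truth.

## The model

A bound myosin head detaches at a load-dependent Bell/Arrhenius rate. Under
a harmonic load the cycle-averaged rate picks up a zero-order modified
Bessel correction:

    k_det(F, ΔF) = k₀ · I₀(ΔF·δ/k_BT) · exp(−F·δ/k_BT)

with k₀ the detachment rate at zero load, δ the force-sensitivity distance,
and F > 0 resistive. Per molecule, dwell times are fitted by left-truncated
exponential maximum likelihood (the detector cannot see sub-window events);
molecules are averaged into characteristic (k₀, δ, step) values and compared
by Welch's t-test. From (k₀, δ, k_cat, step d) the ensemble behaviour follows:

    k_attach = 1/(1/k_cat − 1/k₀)        r(F) = k_attach/(k_attach + k_det(F))
    F_av(F)  = F·r(F)                    vel(F) = k_det(F)·d
    P_av(F)  = vel(F)·F_av(F)

Bulk modules add Michaelis-Menten fitting with the >50% triplicate-rejection
rule and ratio SE propagation, five-parameter biexponential single-turnover
fits (%SRX = slow-phase amplitude fraction), and light-chain stoichiometry
from gel dilution-series slopes.

## Worked example

Simulate a wild-type-like and a D778V-like experiment, fit every molecule,
and compare — all from the library:

```python
import hfskit as h

consts = h.TrapConstants()                       # 23 °C, 200 Hz, ~0.09 pN/nm traps
wt   = h.MotorParams(k0=147.0, delta=1.04, kcat=5.0, step_d=4.3, label="WT")
d778 = h.MotorParams(k0=315.6, delta=0.68, kcat=5.8, step_d=4.5, label="D778V")

groups = {}
for truth, seed, epm in ((wt, 1, 2000), (d778, 2, 6000)):
    cfg = h.SimConfig(true_params=truth, n_molecules=10,
                      events_per_molecule=epm, seed=seed)
    events = h.simulate_events(cfg)
    fits = h.fit_molecules(events, consts, t_min=cfg.min_detectable_duration)
    groups[truth.label] = (fits, h.summarize_group(fits, label=truth.label))
```

prints, via the summaries:

```
WT:    k0 = 144.4 ± 1.9 /s, delta = 1.021 ± 0.036 nm, step = 4.33 ± 0.06 nm (n = 10)
D778V: k0 = 317.6 ± 7.1 /s, delta = 0.689 ± 0.019 nm, step = 4.50 ± 0.09 nm (n = 10)
D778V detachment-rate change: +120 ± 6%
Welch t-test on k0: t = 23.6, df = 10.4, p = 2.3e-10
power at 8 pN resistive: WT 140, D778V 199 pN*nm/s -> hypercontractile
```

That is: the generator's true parameters are recovered within their quoted
uncertainties (faster motors carry wider errors — the 10 ms detectability
floor censors most of their events); the percent change, Welch comparison,
and ensemble power curves then quantify the mutant as hypercontractile at
high resistive load. The last three lines come from `h.percent_change`,
`h.compare_groups`, and `h.ensemble_curves`/`h.compare_ensembles`.

A full trace-level round trip (render traces, detect events by lock-in
amplitude/phase demodulation, refit) is exercised by
`tests/test_acceptance.py::test_end_to_end_trace_pipeline`.

## Command line

A thin `hfskit` console script wraps the library:

```
hfskit simulate-trap --params wt.json --seed 1 --out events.csv
hfskit detect-events --trace trace.csv --out events.csv
hfskit fit-hfs --events events.csv --label WT --out fits.json
hfskit compare-hfs wt_fits.json mut_fits.json
hfskit ensemble --params wt.json --compare mut.json --out curves.csv
hfskit fit-atpase --plate plate.csv
hfskit fit-turnover --trace turnover.csv
hfskit gel-stoich --bands bands.csv
hfskit run-pipeline --params wt.json --seed 1 --out summary.csv
```

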
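"""Dwell-time MLE, force-dependence fitting, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from hfskit import (
    MotorParams,
    SimConfig,
    bessel_i0,
    bin_events,
    compare_groups,
    detachment_rate,
    estimate_step,
    fit_events_mle,
    fit_force_dependence,
    fit_molecule,
    fit_molecules,
    mle_bin_rate,
    percent_change,
    simulate_events,
    summarize_group,
)
from hfskit.fitting import ForceBin, welch_from_values


def events_frame(durations, forces=0.0, amps=0.0, disps=4.3):
    n = len(durations)
    return pd.DataFrame(
        {
            "molecule_id": "m",
            "duration_s": durations,
            "mean_force_pN": np.broadcast_to(forces, n).copy(),
            "force_amp_pN": np.broadcast_to(amps, n).copy(),
            "displacement_nm": np.broadcast_to(disps, n).copy(),
        }
    )


class TestMleBinRate:
    def test_untruncated_worked_example(self):
        rate, se = mle_bin_rate([0.01, 0.02, 0.03], t_min=0.0)
        assert rate == pytest.approx(50.0)
        assert se == pytest.approx(50.0 / np.sqrt(3), abs=0.01)

    def test_truncated_matches_numeric_likelihood(self):
        durations = [0.01, 0.02, 0.03]
        t_min = 0.005
        rate, _ = mle_bin_rate(durations, t_min)
        assert rate == pytest.approx(3 / 0.045, rel=1e-12)
        # independent oracle: numerically maximize the truncated likelihood
        nll = lambda k: -sum(np.log(k) - k * (t - t_min) for t in durations)
        opt = optimize.minimize_scalar(nll, bounds=(1, 1000), method="bounded")
        assert rate == pytest.approx(opt.x, rel=1e-5)

    def test_truncated_estimator_unbiased_at_scale(self):
        rng = np.random.default_rng(0)
        t_min = 0.002
        t = t_min + rng.exponential(1 / 100.0, size=100_000)
        rate, _ = mle_bin_rate(t, t_min)
        assert rate == pytest.approx(100.0, rel=0.01)

    def test_censoring_inconsistent_record_rejected(self):
        with pytest.raises(ValueError, match="t_min"):
            mle_bin_rate([0.004, 0.02], t_min=0.005)


class TestBinEvents:
    def test_counting_and_min_occupancy(self):
        ev = events_frame([0.01, 0.02, 0.03], forces=np.array([-1.2, -0.8, 0.3]))
        assert bin_events(ev, bin_width=1.0, min_bin_events=3) == []
        bins = bin_events(ev, bin_width=1.0, min_bin_events=1)
        assert [b.n_events for b in bins] == [1, 1, 1]
        assert [b.f_lo for b in bins] == [-2.0, -1.0, 0.0]

    def test_single_force_gives_one_bin(self):
        ev = events_frame(np.full(50, 0.02), forces=1.5)
        bins = bin_events(ev, 1.0, 5)
        assert len(bins) == 1
        assert bins[0].mean_force == pytest.approx(1.5)

    def test_uniform_forces_fill_bins_multinomially(self):
        rng = np.random.default_rng(1)
        n = 10_000
        ev = events_frame(
            rng.exponential(0.01, n) + 1e-4, forces=rng.uniform(-5, 5, n)
        )
        bins = bin_events(ev, 1.0, 5)
        interior = [b for b in bins if -5 <= b.f_lo and b.f_hi <= 5]
        expect = n / 10
        for b in interior:
            assert abs(b.n_events - expect) < 3 * np.sqrt(expect * 0.9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_events(events_frame([]), 1.0, 5)


class TestForceDependenceFit:
    def make_noiseless_bins(self, params, consts, forces, amp=2.0):
        return [
            ForceBin(
                f_lo=f - 0.5,
                f_hi=f + 0.5,
                mean_force=f,
                mean_amp=amp,
                n_events=100,
                rate=detachment_rate(f, amp, params, consts),
                rate_se=detachment_rate(f, amp, params, consts) / 10,
            )
            for f in forces
        ]

    def test_noiseless_recovery_to_four_digits(self, wt_params, consts):
        bins = self.make_noiseless_bins(wt_params, consts, np.arange(-4, 4.5, 1.0))
        k0, delta, _ = fit_force_dependence(bins, consts)
        assert k0 == pytest.approx(147.0, rel=1e-4)
        assert delta == pytest.approx(1.04, rel=1e-4)

    def test_seeded_molecule_within_two_se(self, wt_params, consts):
        cfg = SimConfig(
            true_params=wt_params,
            n_molecules=1,
            events_per_molecule=3000,
            min_detectable_duration=0.0,
            seed=10,
        )
        ev = simulate_events(cfg)
        fit = fit_molecule(ev, consts, t_min=0.0)
        assert abs(fit.k0 - 147.0) < 2.5 * fit.k0_se
        assert abs(fit.delta - 1.04) < 2.5 * fit.delta_se

    def test_flat_force_dependence_flagged(self, consts):
        flat = MotorParams(k0=100.0, delta=0.0)
        bins = self.make_noiseless_bins(flat, consts, np.arange(-3, 3.5, 1.0), amp=0.0)
        with pytest.raises(RuntimeError, match="delta pinned"):
            fit_force_dependence(bins, consts)

    def test_too_few_or_narrow_bins_rejected(self, wt_params, consts):
        bins = self.make_noiseless_bins(wt_params, consts, [0.0, 1.0])
        with pytest.raises(ValueError):
            fit_force_dependence(bins, consts)
        bins = self.make_noiseless_bins(wt_params, consts, [0.0, 0.5, 1.0])
        with pytest.raises(ValueError, match="2 pN"):
            fit_force_dependence(bins, consts)

    def test_binned_and_per_event_routes_agree(self, wt_params, consts):
        cfg = SimConfig(
            true_params=wt_params,
            n_molecules=1,
            events_per_molecule=30_000,
            min_detectable_duration=0.0,
            seed=11,
        )
        ev = simulate_events(cfg)
        binned = fit_molecule(ev, consts, t_min=0.0, method="binned")
        k0_mle, delta_mle = fit_events_mle(ev, consts, t_min=0.0)
        assert binned.k0 == pytest.approx(k0_mle, rel=0.05)
        assert binned.delta == pytest.approx(delta_mle, rel=0.10)

    def test_censoring_handled_and_direction_of_naive_bias(self, wt_params, consts):
        """With the detectability floor passed as t_min the fit is unbiased;
        pretending there is no floor biases both parameters downward
        (observed dwells are all longer than 1/rate would suggest)."""
        cfg = SimConfig(
            true_params=wt_params, n_molecules=4, events_per_molecule=3000, seed=12
        )
        ev = simulate_events(cfg)
        t_min = cfg.min_detectable_duration
        good = [fit_events_mle(g, consts, t_min=t_min) for _, g in ev.groupby("molecule_id")]
        naive = [fit_events_mle(g, consts, t_min=0.0) for _, g in ev.groupby("molecule_id")]
        k0_good = np.mean([k for k, _ in good])
        k0_naive = np.mean([k for k, _ in naive])
        assert k0_good == pytest.approx(147.0, rel=0.05)
        assert k0_naive < 0.8 * 147.0
        assert np.mean([d for _, d in naive]) < 0.8 * 1.04

    def test_two_se_coverage_across_replicates(self, wt_params, consts):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                true_params=wt_params,
                n_molecules=1,
                events_per_molecule=2000,
                seed=100 + seed,
            )
            ev = simulate_events(cfg)
            fit = fit_molecule(ev, consts, t_min=cfg.min_detectable_duration)
            hits += abs(fit.k0 - 147.0) < 2 * fit.k0_se
        assert hits >= 16  # ~95% nominal coverage, allow sampling slack


class TestStepAndGroups:
    def test_step_exact_and_clt(self, rng):
        ev = events_frame(np.full(10, 0.02), disps=4.3)
        mean0, sd0 = estimate_step(ev)
        assert mean0 == pytest.approx(4.3)
        assert sd0 == pytest.approx(0.0, abs=1e-12)
        big = events_frame(
            rng.exponential(0.01, 10_000) + 1e-4,
            disps=4.3 + rng.normal(0, 1.4, 10_000),
        )
        mean, sd = estimate_step(big)
        assert mean == pytest.approx(4.3, abs=0.05)
        assert sd == pytest.approx(1.4, abs=0.05)

    def test_step_needs_five_events(self):
        with pytest.raises(ValueError):
            estimate_step(events_frame([0.01] * 4))

    def test_step_difference_detectable_at_twenty_molecules(self, rng):
        # WT-like 4.3 nm vs L781P-like 2.5 nm molecule means, SD 1.4 nm
        wt = rng.normal(4.3, 1.4, 20)
        mut = rng.normal(2.5, 1.4, 20)
        t, df, p = welch_from_values(mut, wt)
        assert p < 0.01

    def test_sem_convention(self):
        # SEM = SD/sqrt(n): {100, 120, 140} -> mean 120, SEM 11.547
        vals = np.array([100.0, 120.0, 140.0])
        assert vals.mean() == 120.0
        assert vals.std(ddof=1) / np.sqrt(3) == pytest.approx(11.547, abs=1e-3)

    def test_identical_groups_not_significant(self):
        t, df, p = welch_from_values(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert p > 0.99

    def test_paperlike_k0_difference_highly_significant(self, rng):
        wt = rng.normal(147.0, 6.8 * np.sqrt(10), 10)
        mut = rng.normal(315.6, 14.0 * np.sqrt(12), 12)
        t, df, p = welch_from_values(mut, wt)
        assert p < 1e-4

    def test_summarize_and_compare_pipeline(self, wt_params, consts):
        cfg = SimConfig(true_params=wt_params, n_molecules=3, events_per_molecule=1500, seed=13)
        fits = fit_molecules(simulate_events(cfg), consts, t_min=cfg.min_detectable_duration)
        s = summarize_group(fits, label="WT")
        assert s.n_molecules == 3
        assert s.k0_sem > 0
        mut_params = MotorParams(k0=315.6, delta=0.68, step_d=4.5)
        mcfg = SimConfig(true_params=mut_params, n_molecules=3, events_per_molecule=1500, seed=14)
        mfits = fit_molecules(simulate_events(mcfg), consts, t_min=mcfg.min_detectable_duration)
        report = compare_groups(mfits, fits)
        k0_row = report[report["parameter"] == "k0"].iloc[0]
        assert k0_row["p"] < 0.05
        assert k0_row["mean_a"] > k0_row["mean_b"]


class TestPercentChange:
    @pytest.mark.parametrize(
        "mutant,wt,expected_rounded",
        [
            (315.6, 147.0, 115),  # k0, D778V
            (101.7, 147.0, -31),  # k0, L781P
            (0.68, 1.04, -35),  # delta, D778V
            (0.81, 1.04, -22),  # delta, L781P
            (2.5, 4.3, -42),  # step, L781P
        ],
    )
    def test_published_style_percent_changes(self, mutant, wt, expected_rounded):
        assert round(percent_change(mutant, wt)) == expected_rounded

    def test_no_change(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_sem_propagation(self):
        pct, sem = percent_change(315.6, 147.0, sem_mutant=14.0, sem_wt=6.8)
        ratio = 315.6 / 147.0
        expected = 100 * ratio * np.sqrt((14.0 / 315.6) ** 2 + (6.8 / 147.0) ** 2)
        assert sem == pytest.approx(expected)

    def test_zero_wt_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)
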
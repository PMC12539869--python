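import numpy as np
import pandas as pd
import pytest

from respirox.errors import ConfigError, DomainError, MetricsError
from respirox.metrics import (
    AnimalMetrics,
    ScalingFit,
    alpha0_series,
    alpha_from_hypoxia,
    bin_width_scan,
    estimate_alpha,
    fit_mass_scaling,
    mass_correct,
    mmr_from_trial,
    pcmax,
    select_bin_width,
)
from respirox.simulate import AnimalModel, ChamberSpec, TrialProtocol, simulate_trial
from respirox.traces import Trace, bin_slopes
from respirox.units import WaterConditions, solubility_per_kpa

COND = WaterConditions(temperature_c=26.0, salinity_psu=32.0)


def three_period_trace(rates, volume=40.0, mass=800.0, cond=COND,
                       period_s=900.0):
    """Piecewise-linear kPa trace whose period slopes encode given rates."""
    beta = solubility_per_kpa(cond)
    veff = volume - mass / 1000.0
    t_all, p_all, phases = [], [], []
    t0, p0 = 0.0, 25.0
    for i, rate in enumerate(rates):
        slope_h = -rate * mass / (beta * veff)
        t = t0 + np.arange(0.0, period_s + 1.0)
        p = p0 + slope_h * (t - t0) / 3600.0
        t_all.append(t)
        p_all.append(p)
        phases += [f"sealed_{i}"] * t.size
        t0 = t[-1] + 1.0
        p0 = 25.0
    return Trace(time_s=np.concatenate(t_all), o2=np.concatenate(p_all),
                 unit="kpa", cond=cond, phase=np.asarray(phases, dtype=object))


class TestMmrFromTrial:
    def test_max_across_periods(self):
        tr = three_period_trace([5.0, 6.2, 5.8])
        mmr, rates = mmr_from_trial(tr, 40.0, 800.0)
        assert mmr == pytest.approx(6.2, rel=1e-9)
        assert rates == pytest.approx([5.0, 6.2, 5.8], rel=1e-9)

    def test_single_period_identity(self):
        tr = three_period_trace([4.4])
        mmr, _ = mmr_from_trial(tr, 40.0, 800.0)
        assert mmr == pytest.approx(4.4, rel=1e-9)

    def test_modes_agree_for_constant_demand(self, cond32):
        d = 6.0
        animal = AnimalModel(mass=800.0, smr=d * (1 - 1e-12), mmr0=d,
                             alpha_true=100.0, recovery_tau=1e9)
        protocol = TrialProtocol(trial_type="mmr", start_po2=27.0, noise_sd=0.0)
        sim = simulate_trial(animal, protocol, ChamberSpec(40.0), cond32, 0)
        for mode in ("period_regression", "max_bin"):
            mmr, _ = mmr_from_trial(sim.trace, 40.0, 800.0, mode=mode)
            assert mmr == pytest.approx(d, rel=0.01)

    def test_background_subtracted(self):
        tr = three_period_trace([5.0, 6.2, 5.8])
        mmr, _ = mmr_from_trial(tr, 40.0, 800.0, background_umol_h=80.0)
        assert mmr == pytest.approx(6.2 - 0.1, rel=1e-9)

    def test_all_flagged_raises(self):
        t = np.arange(0.0, 901.0)
        tr = Trace(time_s=t, o2=10.0 + t / 1000.0, unit="kpa", cond=COND)
        with pytest.raises(MetricsError, match="flagged"):
            mmr_from_trial(tr, 40.0, 800.0)

    def test_unknown_mode_rejected(self):
        tr = three_period_trace([5.0])
        with pytest.raises(ConfigError):
            mmr_from_trial(tr, 40.0, 800.0, mode="bogus")


class TestMassScaling:
    def test_exact_power_law_recovered(self):
        w = np.array([160.0, 400.0, 800.0, 1036.0])
        y = 8.0 * w ** -0.1
        fit = fit_mass_scaling(w, y)
        assert fit.c == pytest.approx(8.0, rel=1e-6)
        assert fit.b == pytest.approx(-0.1, rel=1e-6)

    def test_constant_rate_gives_b_zero(self):
        w = np.array([160.0, 400.0, 800.0, 1036.0])
        fit = fit_mass_scaling(w, np.full(4, 6.0))
        assert fit.b == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery(self):
        # b recovered within +-0.05 on average at n=18, 5 % lognormal noise
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.uniform(160.0, 1036.0, 18)
            y = 8.0 * w ** -0.1 * rng.lognormal(0.0, 0.05, 18)
            errs.append(fit_mass_scaling(w, y).b - (-0.1))
        errs = np.abs(errs)
        assert errs.mean() < 0.05
        assert (errs < 0.1).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            fit_mass_scaling([500.0, 500.0, 500.0], [6.0, 6.0, 6.0])
        with pytest.raises(ConfigError):
            fit_mass_scaling([500.0, 600.0], [6.0, 6.1])


class TestMassCorrect:
    FIT = ScalingFit(c=8.0, b=-0.1, common_mass=600.0)

    def test_b_zero_identity(self):
        fit = ScalingFit(c=8.0, b=0.0, common_mass=600.0)
        assert mass_correct(6.0, 300.0, fit) == 6.0

    def test_common_mass_identity(self):
        assert mass_correct(6.0, 600.0, self.FIT) == pytest.approx(6.0)

    def test_hand_arithmetic(self):
        # 6.0 * (600/300)^-0.1 = 6.0 * 2^-0.1 = 5.598
        assert mass_correct(6.0, 300.0, self.FIT) == pytest.approx(5.598, abs=1e-3)

    def test_monotone_in_mass(self):
        vals = [mass_correct(6.0, m, self.FIT) for m in (200, 400, 600, 800)]
        assert np.all(np.diff(vals) > 0)  # b < 0: heavier -> larger corrected


class TestAlpha0AndAlpha:
    def _bins(self, mo2, po2, flags=None):
        n = len(mo2)
        return pd.DataFrame({
            "t_mid_s": np.arange(n, dtype=float),
            "po2_kpa": np.asarray(po2, dtype=float),
            "slope_kpa_h": -1.0,
            "mo2_umol_g_h": np.asarray(mo2, dtype=float),
            "n": 45, "r2": 1.0,
            "flags": flags if flags is not None else [""] * n,
        })

    def test_alpha0_arithmetic(self):
        a0 = alpha0_series(self._bins([5.6], [10.0]))
        assert a0[0] == pytest.approx(0.56)

    def test_po2_floor_and_flags_excluded(self):
        bins = self._bins([5.6, 5.6, 5.6], [10.0, 0.4, 10.0],
                          flags=["", "", "positive_slope"])
        assert alpha0_series(bins).size == 1

    def test_empty_raises(self):
        with pytest.raises(MetricsError):
            alpha0_series(self._bins([], []))

    def test_supply_limited_alpha0_constant(self, cond32):
        animal = AnimalModel(mass=800.0, smr=1.0, mmr0=1e6, alpha_true=0.68,
                             recovery_tau=1e9)
        protocol = TrialProtocol(trial_type="hypoxia", start_po2=11.7,
                                 n_measure_periods=1, noise_sd=0.0)
        sim = simulate_trial(animal, protocol, ChamberSpec(40.0), cond32, 0)
        tr = Trace(time_s=sim.truth.time_s, o2=sim.truth.po2_kpa, unit="kpa",
                   cond=cond32, phase=sim.truth.phase)
        bins = bin_slopes(tr, 45.0, "sealed_0", 40.0, 800.0)
        a0 = alpha0_series(bins)
        np.testing.assert_allclose(a0, 0.68, rtol=0.01)

    def test_demand_limited_alpha0_rises_as_po2_falls(self, cond32):
        d = 5.0
        animal = AnimalModel(mass=800.0, smr=d * (1 - 1e-12), mmr0=d,
                             alpha_true=100.0, recovery_tau=1e9)
        protocol = TrialProtocol(trial_type="mmr", start_po2=21.0,
                                 n_measure_periods=1, noise_sd=0.0)
        sim = simulate_trial(animal, protocol, ChamberSpec(40.0), cond32, 0)
        tr = Trace(time_s=sim.truth.time_s, o2=sim.truth.po2_kpa, unit="kpa",
                   cond=cond32, phase=sim.truth.phase)
        bins = bin_slopes(tr, 45.0, "sealed_0", 40.0, 800.0)
        a0 = alpha0_series(bins)
        assert np.all(np.diff(a0) > 0)

    def test_estimate_alpha_top3(self):
        est = estimate_alpha([0.1, 0.2, 0.3, 0.4, 0.5])
        assert est.alpha == pytest.approx(0.4)
        assert est.top3 == pytest.approx((0.5, 0.4, 0.3))

    def test_estimate_alpha_identical(self):
        assert estimate_alpha([0.68] * 5).alpha == pytest.approx(0.68)

    def test_estimate_alpha_needs_three(self):
        with pytest.raises(MetricsError):
            estimate_alpha([0.5, 0.6])

    def test_noisy_trial_recovers_alpha_true(self, noisy_hypoxia):
        est = alpha_from_hypoxia(noisy_hypoxia.trace, 40.0, 594.1)
        assert est.alpha == pytest.approx(0.68, rel=0.10)
        assert min(est.top3) <= est.alpha <= max(est.top3)


class TestBinWidthScan:
    def test_noiseless_scan_flat(self, noiseless_hypoxia):
        scan = bin_width_scan(noiseless_hypoxia.trace, 40.0, 594.1,
                              widths=(45.0, 90.0, 180.0, 300.0))
        alphas = scan["alpha"].to_numpy()
        assert np.all(np.abs(alphas - alphas.mean()) / alphas.mean() < 0.01)

    def test_noisy_scan_elevated_at_small_widths(self, noisy_hypoxia):
        scan = bin_width_scan(noisy_hypoxia.trace, 40.0, 594.1)
        width, _ = select_bin_width(scan)
        a_small = scan["alpha"].iloc[0]
        a_sel = scan.loc[scan["width_s"] == width, "alpha"].iloc[0]
        assert a_small >= a_sel

    def test_n_bins_decreasing_in_width(self, noisy_hypoxia):
        scan = bin_width_scan(noisy_hypoxia.trace, 40.0, 594.1)
        assert np.all(np.diff(scan["n_bins"]) <= 0)


class TestSelectBinWidth:
    @staticmethod
    def _scan(widths, alphas, sds):
        return pd.DataFrame({
            "width_s": widths, "alpha": alphas, "sd_top3": sds,
            "n_bins": 10, "n_alpha0": 10,
        })

    def test_constant_scan_picks_smallest(self):
        scan = self._scan([30, 45, 60, 90], [0.6] * 4, [0.01] * 4)
        width, stable = select_bin_width(scan)
        assert width == 30
        assert stable

    def test_dominating_width_wins(self):
        scan = self._scan([30, 45, 60, 90],
                          [0.80, 0.610, 0.600, 0.605],
                          [0.05, 0.020, 0.010, 0.015])
        width, stable = select_bin_width(scan)
        assert width == 60
        assert stable

    def test_no_stable_region_falls_back_with_warning(self):
        scan = self._scan([30, 45, 60], [1.0, 0.7, 0.4], [0.3, 0.2, 0.1])
        with pytest.warns(UserWarning, match="no stable"):
            width, stable = select_bin_width(scan)
        assert not stable
        assert width == 60  # global rank-sum minimum

    def test_needs_three_widths(self):
        with pytest.raises(MetricsError):
            select_bin_width(self._scan([30, 45], [0.6, 0.6], [0.01, 0.01]))

    @pytest.mark.slow
    def test_selected_width_beats_fixed_45s(self, cond6, chamber40,
                                            hypoxia_protocol):
        # across seeds, the auto-selected width must lower alpha RMSE
        # against the generating value relative to fixed 45-s bins
        err_sel, err_45 = [], []
        for seed in range(12):
            root = np.random.SeedSequence([seed, 55])
            rng = np.random.default_rng(root)
            a_true = max(float(rng.normal(0.68, 0.05)), 0.05)
            animal = AnimalModel(mass=594.1, smr=3.0, mmr0=9.0,
                                 alpha_true=a_true)
            sim = simulate_trial(animal, hypoxia_protocol, chamber40, cond6,
                                 root.spawn(1)[0])
            est = alpha_from_hypoxia(sim.trace, 40.0, 594.1)
            err_sel.append((est.alpha - a_true) / a_true)
            seg = sim.trace.sealed_segments()[-1][0]
            bins = bin_slopes(sim.trace, 45.0, seg, 40.0, 594.1)
            est45 = estimate_alpha(alpha0_series(bins))
            err_45.append((est45.alpha - a_true) / a_true)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))  # noqa: E731
        assert rmse(err_sel) < rmse(err_45)


class TestPcmax:
    def test_unit_ratio(self):
        assert pcmax(0.68, 0.68) == pytest.approx(1.0)

    def test_group_mean_arithmetic(self):
        # ratio of group means differs from the mean of individual ratios
        assert pcmax(7.46, 0.68) == pytest.approx(10.97, abs=0.01)

    def test_identity_by_construction(self):
        mmr, alpha = 7.46, 0.68
        assert pcmax(mmr, alpha) * alpha == pytest.approx(mmr, rel=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            pcmax(7.0, 0.0)
        with pytest.raises(DomainError):
            pcmax(-1.0, 0.68)

    def test_recovered_pcmax_near_truth(self, noisy_hypoxia, cond6, chamber40):
        # alpha from the hypoxia trial, MMR from the over-saturation trial
        # (the hypoxia trial itself is supply-limited from the start)
        sim = noisy_hypoxia
        est = alpha_from_hypoxia(sim.trace, 40.0, 594.1)
        animal = AnimalModel(mass=594.1, smr=3.0, mmr0=9.0, alpha_true=0.68)
        protocol = TrialProtocol(trial_type="mmr", start_po2=27.0)
        mmr_sim = simulate_trial(animal, protocol, chamber40, cond6, seed=12)
        mmr, _ = mmr_from_trial(mmr_sim.trace, 40.0, 594.1)
        pc_true = 9.0 / 0.68
        assert pcmax(mmr, est.alpha) == pytest.approx(pc_true, rel=0.10)


class TestAnimalMetricsInvariants:
    def test_identity_enforced(self):
        with pytest.raises(MetricsError):
            AnimalMetrics(animal_id="x", mmr_per_trial={}, mmr_max=7.0,
                          alpha=0.7, pcmax=9.0, selected_bin_width_s=300.0,
                          alpha0_top3=(0.71, 0.70, 0.69))

    def test_alpha_within_top3(self):
        with pytest.raises(MetricsError):
            AnimalMetrics(animal_id="x", mmr_per_trial={}, mmr_max=7.0,
                          alpha=0.9, pcmax=7.0 / 0.9,
                          selected_bin_width_s=300.0,
                          alpha0_top3=(0.71, 0.70, 0.69))

    def test_valid_instance(self):
        m = AnimalMetrics(animal_id="x", mmr_per_trial={21.0: 7.0},
                          mmr_max=7.0, alpha=0.7, pcmax=10.0,
                          selected_bin_width_s=300.0,
                          alpha0_top3=(0.71, 0.70, 0.69))
        assert m.pcmax * m.alpha == pytest.approx(m.mmr_max)
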
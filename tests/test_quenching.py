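"""Stern-Volmer and double-log fitting, mechanism calls, thermodynamics."""

import numpy as np
import pytest

from hsabind.datamodel import (
    FitDegenerateError,
    GroundTruth,
    QuenchFit,
    TitrationSeries,
)
from hsabind.quenching import (
    bimolecular_rate,
    classify_mechanism,
    double_log_fit,
    gibbs_free_energy,
    ksv_fold_ratio,
    stern_volmer_fit,
)
from hsabind.synthetic import simulate_titration, titration_from_binding_law
from conftest import ols_normal_equations


def make_series(q, f, **kw):
    return TitrationSeries(protein_conc=2e-6, quencher_concs=q, intensities=f, **kw)


class TestSternVolmer:
    @pytest.mark.parametrize("ksv", [2.64e3, 60.73e3])
    def test_exact_recovery_from_linear_law(self, ksv, design_grid):
        truth = GroundTruth(kb=ksv, mode="stern_volmer", noise_sd_fraction=0.0)
        fit = stern_volmer_fit(simulate_titration(truth, quencher_concs=design_grid))
        assert fit.ksv == pytest.approx(ksv, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points_used == design_grid.size - 1

    def test_constant_intensities_give_zero_slope(self, design_grid):
        fit = stern_volmer_fit(make_series(design_grid, np.full(design_grid.size, 500.0)))
        assert fit.ksv == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_on_noisy_points(self):
        q = np.array([0.0, 3e-6, 6e-6, 9e-6, 12e-6, 15e-6])
        rng = np.random.default_rng(42)
        f = 1000.0 / (1 + 5e4 * q) * (1 + 0.02 * rng.standard_normal(q.size))
        series = make_series(q, np.abs(f))
        fit = stern_volmer_fit(series)
        x, y = q[1:], series.f0 / series.intensities[1:]
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.ksv == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_kq_identity_on_fit(self, design_grid):
        truth = GroundTruth(kb=60.73e3, mode="stern_volmer")
        series = simulate_titration(truth, quencher_concs=design_grid, tau0=6.3e-9)
        fit = stern_volmer_fit(series)
        assert fit.kq == fit.ksv / 6.3e-9

    def test_pinned_intercept(self, design_grid):
        truth = GroundTruth(kb=2.64e3, mode="stern_volmer", noise_sd_fraction=0.0)
        fit = stern_volmer_fit(
            simulate_titration(truth, quencher_concs=design_grid), pin_intercept=True
        )
        assert fit.intercept == 1.0 and fit.intercept_se == 0.0
        assert fit.ksv == pytest.approx(2.64e3, rel=1e-9)

    def test_rescaling_invariance(self, design_grid):
        truth = GroundTruth(kb=6e4, mode="stern_volmer", noise_sd_fraction=0.01, seed=5)
        series = simulate_titration(truth, quencher_concs=design_grid)
        fit1 = stern_volmer_fit(series)
        series.intensities = series.intensities * 37.5
        fit2 = stern_volmer_fit(series)
        assert fit2.ksv == pytest.approx(fit1.ksv, rel=1e-12)
        assert fit2.intercept == pytest.approx(fit1.intercept, rel=1e-12)

    def test_too_few_points_raise(self):
        q = np.array([0.0, 3e-6, 6e-6])
        with pytest.raises(FitDegenerateError):
            stern_volmer_fit(make_series(q, np.array([1000.0, 900.0, 800.0])))


class TestBimolecularRate:
    def test_reference_strong_ligand_value(self):
        # 60.73e3 / 6.3e-9 = 96.397e11, printed as 96.40 x 10^11
        assert bimolecular_rate(60.73e3, 6.3e-9) / 1e11 == pytest.approx(96.40, abs=0.005)

    def test_zero_slope_gives_zero(self):
        assert bimolecular_rate(0.0, 6.3e-9) == 0.0

    def test_weak_ligand_full_precision(self):
        # direct division gives 4.190e11 (tables print 4.18, a rounding of
        # unrounded slope); we report full precision
        assert bimolecular_rate(2.64e3, 6.3e-9) == pytest.approx(4.190e11, rel=1e-3)

    def test_invalid_tau0(self):
        with pytest.raises(ValueError):
            bimolecular_rate(1e3, 0.0)


def _fit(kq, intercept, se):
    return QuenchFit(
        ksv=kq * 6.3e-9, ksv_se=0.0, kq=kq, intercept=intercept,
        intercept_se=se, r_squared=0.95, n_points_used=11, tau0=6.3e-9,
    )


class TestMechanism:
    def test_static_when_interval_brackets_one(self):
        call = classify_mechanism(_fit(96.40e11, 0.91, 0.06))
        assert call.label == "static"
        assert call.kq_exceeds_threshold and call.intercept_within_tolerance

    def test_mixed_when_intercept_excludes_one(self):
        call = classify_mechanism(_fit(4.18e11, 1.10, 0.01))
        assert call.label == "mixed_flagged"
        assert call.kq_exceeds_threshold and not call.intercept_within_tolerance

    def test_dynamic_below_threshold(self):
        assert classify_mechanism(_fit(5e9, 1.0, 0.01)).label == "dynamic_consistent"

    def test_tolerance_alone_can_admit_intercept(self):
        # |1.04 - 1| <= 0.05 even with a tiny SE
        assert classify_mechanism(_fit(1e12, 1.04, 1e-6)).label == "static"


class TestDoubleLog:
    def test_exact_recovery_of_generating_parameters(self, design_grid):
        series = titration_from_binding_law(10**4.80, 1.02, quencher_concs=design_grid)
        fit = double_log_fit(series)
        assert fit.log_kb == pytest.approx(4.80, abs=1e-9)
        assert fit.n_sites == pytest.approx(1.02, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.kb == pytest.approx(10**4.80, rel=1e-9)
        assert fit.excluded_points == []

    def test_identity_line(self):
        # (F0-F)/F = Q exactly: logKb = 0, n = 1; quench fractions are tiny
        # so the blow-up exclusion must be disabled
        q = np.array([0.0, 1e-3, 2e-3, 5e-3, 1e-2, 3e-2])
        series = make_series(q, 1000.0 / (1.0 + q))
        fit = double_log_fit(series, min_quench_fraction=0.0)
        assert fit.log_kb == pytest.approx(0.0, abs=1e-10)
        assert fit.n_sites == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, design_grid):
        rng = np.random.default_rng(3)
        series = titration_from_binding_law(10**4.5, 1.1, quencher_concs=design_grid)
        series.intensities = np.abs(
            series.intensities * (1 + 0.01 * rng.standard_normal(design_grid.size))
        )
        fit = double_log_fit(series, min_quench_fraction=0.0)
        f0 = series.f0
        mask = (design_grid > 0) & (f0 - series.intensities > 0)
        x = np.log10(design_grid[mask])
        y = np.log10((f0 - series.intensities[mask]) / series.intensities[mask])
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.n_sites == pytest.approx(slope, rel=1e-10)
        assert fit.log_kb == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_low_quench_points_are_excluded_and_recorded(self, design_grid):
        # weak binder: earliest additions quench < 2%
        series = titration_from_binding_law(2.0e3, 1.0, quencher_concs=design_grid)
        fit = double_log_fit(series)
        assert fit.excluded_points  # at least the 3 uM point
        assert all(
            (series.f0 - series.intensities[i]) / series.f0 < 0.02
            for i in fit.excluded_points
        )
        assert fit.n_points_used + len(fit.excluded_points) == design_grid.size - 1

    def test_rescaling_invariance(self, design_grid):
        series = titration_from_binding_law(10**4.8, 1.02, quencher_concs=design_grid)
        fit1 = double_log_fit(series)
        series.intensities = series.intensities * 0.125
        fit2 = double_log_fit(series)
        assert fit2.log_kb == pytest.approx(fit1.log_kb, rel=1e-12)
        assert fit2.n_sites == pytest.approx(fit1.n_sites, rel=1e-12)

    def test_insufficient_usable_points_raise(self, design_grid):
        series = titration_from_binding_law(10.0, 1.0, quencher_concs=design_grid)
        with pytest.raises(FitDegenerateError):
            double_log_fit(series)  # nothing quenches > 2%

    def test_recovery_under_noise_median(self, design_grid):
        """Median recovered (logK_b, n) over 200 seeded 1%-noise replicates
        of the 12-point design stays within (0.02, 0.05) of truth."""
        truth_log_kb, truth_n = 4.80, 1.02
        rng = np.random.default_rng(2024)
        log_kbs, ns = [], []
        for _ in range(200):
            series = titration_from_binding_law(
                10**truth_log_kb, truth_n, quencher_concs=design_grid
            )
            series.intensities = np.abs(
                series.intensities
                * (1 + 0.01 * rng.standard_normal(design_grid.size))
            )
            fit = double_log_fit(series)
            log_kbs.append(fit.log_kb)
            ns.append(fit.n_sites)
        assert abs(np.median(log_kbs) - truth_log_kb) < 0.02
        assert abs(np.median(ns) - truth_n) < 0.05


class TestThermodynamics:
    def test_weak_ligand_free_energy_to_one_decimal(self):
        assert round(gibbs_free_energy(13.64e3, 298.0), 1) == -23.6

    def test_unit_constant_gives_zero(self):
        assert gibbs_free_energy(1.0, 310.0) == 0.0

    def test_strong_ligand_full_precision(self):
        # direct arithmetic gives -27.4 to 1 decimal (tables print -27.3)
        assert round(gibbs_free_energy(63.67e3, 298.0), 1) == -27.4

    def test_strictly_decreasing_in_kb_with_sign_flip_at_one(self):
        kbs = np.logspace(-3, 6, 25)
        dgs = np.array([gibbs_free_energy(k, 298.0) for k in kbs])
        assert np.all(np.diff(dgs) < 0)
        assert np.all(dgs[kbs < 1] > 0) and np.all(dgs[kbs > 1] < 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(0.0, 298.0)
        with pytest.raises(ValueError):
            gibbs_free_energy(1e4, -1.0)


class TestFoldRatio:
    def test_reference_ratio_full_precision(self):
        a, b = _fit(1, 1, 0), _fit(1, 1, 0)
        a.ksv, b.ksv = 60.73e3, 2.64e3
        # 60.73/2.64 = 23.0 to 3 s.f.
        assert ksv_fold_ratio(a, b) == pytest.approx(23.0, abs=0.05)
        assert ksv_fold_ratio(b, a) == pytest.approx(1 / ksv_fold_ratio(a, b))

    def test_identity_and_zero_denominator(self):
        a = _fit(1, 1, 0)
        assert ksv_fold_ratio(a, a) == 1.0
        b = _fit(1, 1, 0)
        b.ksv = 0.0
        with pytest.raises(ValueError):
            ksv_fold_ratio(a, b)
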
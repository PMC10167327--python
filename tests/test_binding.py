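"""Ligand-depletion binding model: exact quadratic, fits, profile CIs, folds."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from spxlab import binding, synthetic
from spxlab.binding import BindingModel
from spxlab.io import ValidationError


def bisection_bound_complex(pt, lt, kd):
    """Independent root of K_D = (P_t - PL)(L_t - PL)/PL by bisection."""
    if lt == 0:
        return 0.0

    def f(pl):
        return (pt - pl) * (lt - pl) - kd * pl

    hi = min(pt, lt)
    return brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)


class TestBoundComplex:
    def test_zero_ligand_gives_zero(self):
        assert binding.bound_complex(0.2, 0.0, 10.0) == 0.0

    def test_stoichiometric_limit(self):
        # K_D -> 0 with excess ligand: everything is bound
        assert binding.bound_complex(0.2, 5.0, 1e-12) == pytest.approx(0.2, rel=1e-6)

    def test_symmetric_unit_case(self):
        # P_t = L_t = K_D = 1: the quadratic root is (3 - sqrt(5))/2
        expected = (3.0 - np.sqrt(5.0)) / 2.0
        assert binding.bound_complex(1.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert bisection_bound_complex(1.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-10)

    def test_bisection_oracle_grid(self):
        # dense parameter grid: closed form vs. independent bisection
        pts = np.array([0.05, 0.2, 1.0, 10.0, 100.0])
        lts = np.array([0.0, 0.01, 0.2, 3.0, 50.0, 1000.0])
        kds = np.array([0.01, 0.1, 1.0, 13.8, 500.0, 1e4])
        for pt in pts:
            for lt in lts:
                for kd in kds:
                    closed = binding.bound_complex(pt, lt, kd)
                    oracle = bisection_bound_complex(pt, lt, kd)
                    assert abs(closed - oracle) < 1e-10

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0.01, 100.0), st.floats(0.0, 1000.0), st.floats(1e-3, 1e4)
    )
    def test_physical_bounds_property(self, pt, lt, kd):
        pl = binding.bound_complex(pt, lt, kd)
        assert 0.0 <= pl <= min(pt, lt) + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            binding.bound_complex(0.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            binding.bound_complex(1.0, -1.0, 1.0)


class TestObservedSignal:
    model = BindingModel(P_t=0.2, K_D=10.0, alpha_P=800.0, alpha_PL=900.0,
                        eps_P=1.0, eps_PL=1.4)

    def test_zero_ligand_gives_free_state_signal(self):
        assert binding.observed_signal(self.model, 0.0) == pytest.approx(800.0)

    def test_equal_eps_reduces_to_population_mean(self):
        m = BindingModel(P_t=0.2, K_D=10.0, alpha_P=800.0, alpha_PL=900.0)
        lt = 25.0
        pl = binding.bound_complex(m.P_t, lt, m.K_D)
        p = m.P_t - pl
        expected = (m.alpha_P * p + m.alpha_PL * pl) / (p + pl)
        assert binding.observed_signal(m, lt) == pytest.approx(expected, rel=1e-12)

    def test_two_step_composition_oracle(self):
        # independent evaluation: quadratic root first, then the weighted mean
        lt = 10.0
        pl = bisection_bound_complex(0.2, lt, 10.0)
        p = 0.2 - pl
        expected = (p * 1.0 * 800.0 + pl * 1.4 * 900.0) / (p * 1.0 + pl * 1.4)
        assert binding.observed_signal(self.model, lt) == pytest.approx(
            expected, abs=1e-9
        )

    def test_bounded_between_state_signals(self):
        lt = np.logspace(-3, 4, 50)
        s = binding.observed_signal(self.model, lt)
        assert np.all(s >= 800.0 - 1e-9) and np.all(s <= 900.0 + 1e-9)

    def test_monotone_in_ligand(self):
        lt = np.logspace(-3, 4, 200)
        s = binding.observed_signal(self.model, lt)
        assert np.all(np.diff(s) > 0)


class TestFitKd:
    def test_noiseless_exact_recovery_with_vanishing_ci(self, quiet_spec):
        series = synthetic.sim_titration(quiet_spec, K_D=10.0)
        fit = binding.fit_kd(series, P_t=0.2)
        assert fit.K_D == pytest.approx(10.0, rel=1e-6)
        assert fit.alpha_P == pytest.approx(800.0, rel=1e-6)
        assert fit.alpha_PL == pytest.approx(900.0, rel=1e-6)
        lo, hi = fit.ci95
        assert hi / lo - 1.0 < 1e-3  # CI collapses without noise

    def test_affine_rescaling_invariance(self, default_spec):
        series = synthetic.sim_titration(default_spec, K_D=13.8)
        fit = binding.fit_kd(series, P_t=0.2)
        from spxlab.io import TitrationSeries

        scaled = TitrationSeries(
            series.concentrations, 3.0 * series.observable + 117.0,
            series.replicate_ids,
        )
        fit2 = binding.fit_kd(scaled, P_t=0.2)
        assert fit2.K_D == pytest.approx(fit.K_D, rel=1e-6)
        assert fit2.alpha_P == pytest.approx(3 * fit.alpha_P + 117, rel=1e-6)
        assert fit2.alpha_PL == pytest.approx(3 * fit.alpha_PL + 117, rel=1e-6)

    def test_weak_binding_reports_lower_limit(self):
        spec = synthetic.SimSpec(seed=5)
        series = synthetic.sim_titration(spec, K_D=100.0 * 1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = binding.fit_kd(series, P_t=0.2)
        assert fit.lower_limit
        assert fit.describe().startswith("K_D >")

    def test_delta_fnorm_mode_recovers_kd(self, default_spec):
        series = synthetic.sim_titration(default_spec, K_D=13.8)
        fit = binding.fit_kd(series, P_t=0.2, mode="delta_fnorm")
        assert fit.K_D == pytest.approx(13.8, rel=0.25)

    def test_global_mode_shares_kd_with_fluorescence(self, quiet_spec):
        series = synthetic.sim_titration(quiet_spec, K_D=13.8, eps_ratio=1.4)
        fluo = synthetic.sim_fluorescence_titration(
            synthetic.SimSpec(seed=11, mst_noise_frac=0.0), K_D=13.8,
            eps_P=1000.0, eps_PL=1400.0,
        )
        fit = binding.fit_kd(
            series, P_t=0.2, mode="global_fnorm_plus_fluorescence",
            fluorescence_series=fluo,
        )
        assert fit.K_D == pytest.approx(13.8, rel=1e-4)
        assert fit.eps_ratio == pytest.approx(1.4, rel=1e-4)

    def test_ci_calibration_near_95_percent(self):
        # coverage of the profile-likelihood CI over seeded titrations
        n, cover = 200, 0
        for seed in range(n):
            series = synthetic.sim_titration(synthetic.SimSpec(seed=seed), K_D=13.8)
            fit = binding.fit_kd(series, P_t=0.2)
            if fit.ci95[0] <= 13.8 <= fit.ci95[1]:
                cover += 1
        # 0.95 +/- 3 binomial sigma for n = 200
        sigma = np.sqrt(0.95 * 0.05 / n)
        assert 0.95 - 3 * sigma <= cover / n <= min(0.95 + 3 * sigma, 1.0)


class TestAffinityFoldChange:
    def fit_at(self, kd, seed=0):
        series = synthetic.sim_titration(synthetic.SimSpec(seed=seed), K_D=kd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return binding.fit_kd(series, P_t=0.2)

    def test_identical_fits_give_unity(self):
        fit = self.fit_at(13.8)
        fold = binding.affinity_fold_change(fit, fit)
        assert fold.fold == pytest.approx(1.0)

    def test_lower_limit_condition_formats_as_bound(self):
        ref = self.fit_at(13.8)
        cond = self.fit_at(13.8 * 1e4, seed=3)
        assert cond.lower_limit
        fold = binding.affinity_fold_change(ref, cond)
        assert fold.is_lower_bound
        assert fold.describe().startswith("> ")

    def test_lower_limit_reference_rejected(self):
        ref = self.fit_at(13.8 * 1e4, seed=3)
        cond = self.fit_at(13.8)
        with pytest.raises(ValidationError, match="undefined"):
            binding.affinity_fold_change(ref, cond)

    def test_85_fold_ratio_recovered_within_20_percent(self):
        folds = []
        for seed in range(100):
            ref = self.fit_at(13.8, seed=seed)
            cond = self.fit_at(13.8 * 85.0, seed=seed + 5000)
            if cond.lower_limit:
                continue
            folds.append(binding.affinity_fold_change(ref, cond).fold)
        assert abs(np.median(folds) / 85.0 - 1.0) < 0.20
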
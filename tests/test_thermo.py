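import math

import numpy as np
import pytest

from sortbind import (
    AllosteryParams,
    RepressorTitrationFit,
    ThermoParams,
    fit_eps_R,
    fold_change_from_fluorescence,
    fold_change_induction,
    fold_change_simple,
    kbt_to_kcal_per_mol,
    make_titration,
    p_bound,
    phenotypes,
)

N_NS = 4.6e6


def test_thermal_energy_at_37C_rounds_to_062():
    assert round(kbt_to_kcal_per_mol(1.0, 37.0), 2) == 0.62


class TestPBound:
    def test_no_polymerase_means_never_bound(self):
        assert p_bound(ThermoParams(P=0)) == 0.0

    def test_weak_promoter_limit(self):
        tp = ThermoParams(P=10, eps_P=-2.0, R=0)
        approx = (tp.P / tp.N_NS) * math.exp(-tp.eps_P)
        assert p_bound(tp) == pytest.approx(approx, rel=1e-4)

    def test_longhand_scalar_evaluation(self):
        # independent arithmetic, term by term
        pol = 1000 / 4.6e6 * math.exp(5.0)
        rep = 2 * 130 / 4.6e6 * math.exp(15.3)
        expected = pol / (1 + pol + rep)
        tp = ThermoParams(P=1000, eps_P=-5.0, R=130, eps_R=-15.3)
        assert p_bound(tp) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_R_increasing_in_P(self):
        for R1, R2 in [(0, 10), (10, 100), (100, 1000)]:
            assert p_bound(ThermoParams(R=R1)) > p_bound(ThermoParams(R=R2))
        for P1, P2 in [(1, 10), (10, 100)]:
            assert p_bound(ThermoParams(P=P1)) < p_bound(ThermoParams(P=P2))

    def test_invalid_nns_rejected(self):
        with pytest.raises(ValueError):
            ThermoParams(N_NS=0)


class TestFoldChangeSimple:
    def test_no_repressor_means_unity(self):
        assert fold_change_simple(0, -15.3) == 1.0

    def test_very_weak_binding_approaches_unity(self):
        assert fold_change_simple(130, 30.0) == pytest.approx(1.0, abs=1e-8)

    def test_longhand_scalar_evaluation(self):
        expected = 1.0 / (1.0 + (260 / 4.6e6) * math.exp(15.3))
        assert fold_change_simple(130, -15.3) == pytest.approx(expected, rel=1e-12)

    def test_bounds_and_derivative_signs(self):
        grid_R = np.linspace(1, 2000, 40)
        fc = fold_change_simple(grid_R, -13.9)
        assert np.all((fc > 0) & (fc <= 1))
        assert np.all(np.diff(fc) < 0)  # decreasing in R
        grid_e = np.linspace(-16, -8, 40)
        fc_e = fold_change_simple(130, grid_e)
        assert np.all(np.diff(fc_e) > 0)  # increasing in eps_R

    def test_weak_promoter_consistency_with_p_bound(self):
        # expression ratio from the occupancy model matches the reduced
        # fold-change formula within 5% for P <= 1000 on a lacUV5-like promoter
        for P in [10, 100, 1000]:
            tp_R = ThermoParams(P=P, eps_P=-5.0, R=130, eps_R=-13.9)
            tp_0 = ThermoParams(P=P, eps_P=-5.0, R=0)
            ratio = p_bound(tp_R) / p_bound(tp_0)
            assert ratio == pytest.approx(fold_change_simple(130, -13.9), rel=0.05)


class TestFoldChangeInduction:
    AP = AllosteryParams()  # K_A=139, K_I=0.53, eps_AI=4.5, n=2

    def test_zero_inducer_equals_leakiness(self):
        ph = phenotypes(self.AP, 130, -13.9)
        assert fold_change_induction(self.AP, 0.0, 130, -13.9) == pytest.approx(
            ph.leakiness, rel=1e-9)

    def test_equal_dissociation_constants_flat_in_c(self):
        ap = AllosteryParams(K_A=10.0, K_I=10.0)
        vals = [fold_change_induction(ap, c, 130, -13.9) for c in [0, 1, 10, 100, 5000]]
        assert max(vals) - min(vals) < 1e-12

    def test_matches_longhand_evaluation_on_c_grid(self):
        for c in [0.0, 1.0, 10.0, 100.0, 5000.0]:
            a = (1 + c / 139.0) ** 2
            i = (1 + c / 0.53) ** 2
            bracket = a / (a + math.exp(-4.5) * i)
            expected = 1.0 / (1.0 + bracket * (260 / 4.6e6) * math.exp(13.9))
            got = fold_change_induction(self.AP, c, 130, -13.9)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_always_active_repressor_collapses_to_simple_repression(self):
        ap = AllosteryParams(eps_AI=60.0)  # e^(-eps_AI) -> 0
        for c in [0.0, 10.0, 1000.0]:
            assert fold_change_induction(ap, c, 130, -13.9) == pytest.approx(
                fold_change_simple(130, -13.9), rel=1e-9)

    def test_monotone_nondecreasing_when_KI_below_KA(self):
        grid = np.logspace(-2, 4, 60)
        fc = fold_change_induction(self.AP, grid, 130, -13.9)
        assert np.all(np.diff(fc) >= -1e-15)


class TestPhenotypes:
    AP = AllosteryParams()

    def test_no_repressor_gives_flat_unity_response(self):
        ph = phenotypes(self.AP, 0, -13.9)
        assert ph.leakiness == ph.saturation == 1.0
        assert ph.dynamic_range == 0.0
        assert math.isnan(ph.ec50)

    def test_always_active_leakiness_is_simple_fold_change(self):
        ap = AllosteryParams(eps_AI=60.0)
        ph = phenotypes(ap, 130, -13.9)
        assert ph.leakiness == pytest.approx(fold_change_simple(130, -13.9), rel=1e-9)

    def test_ec50_satisfies_midpoint_equation(self):
        ph = phenotypes(self.AP, 130, -13.9)
        mid = 0.5 * (ph.leakiness + ph.saturation)
        at_ec50 = fold_change_induction(self.AP, ph.ec50, 130, -13.9)
        assert at_ec50 == pytest.approx(mid, rel=1e-6)
        assert 0 <= ph.leakiness <= ph.saturation <= 1
        assert ph.dynamic_range == pytest.approx(ph.saturation - ph.leakiness)

    def test_ec50_decreases_as_binding_weakens(self):
        ec50s = [phenotypes(self.AP, 130, e).ec50 for e in np.linspace(-16, -9, 8)]
        assert all(a > b for a, b in zip(ec50s, ec50s[1:]))

    def test_equal_dissociation_constants_rejected(self):
        with pytest.raises(ValueError, match="EC50"):
            phenotypes(AllosteryParams(K_A=5.0, K_I=5.0), 130, -13.9)

    def test_limits_match_curve_extremes(self):
        ph = phenotypes(self.AP, 130, -13.9)
        assert fold_change_induction(self.AP, 0.0, 130, -13.9) == pytest.approx(
            ph.leakiness, abs=1e-6)
        assert fold_change_induction(self.AP, 1e9, 130, -13.9) == pytest.approx(
            ph.saturation, abs=1e-6)


class TestFoldChangeFromFluorescence:
    def test_autofluorescence_only_gives_zero(self):
        assert fold_change_from_fluorescence(100.0, 1100.0, 100.0) == 0.0

    def test_unrepressed_signal_gives_one(self):
        assert fold_change_from_fluorescence(1100.0, 1100.0, 100.0) == 1.0

    def test_arithmetic(self):
        assert fold_change_from_fluorescence(300.0, 1100.0, 100.0) == pytest.approx(0.2)

    def test_bad_denominator_rejected(self):
        with pytest.raises(ValueError, match="autofluorescence"):
            fold_change_from_fluorescence(300.0, 90.0, 100.0)


class TestFitEpsR:
    R_VALUES = [11, 30, 62, 130, 610, 870]

    def test_noiseless_titration_recovered_exactly(self):
        pts = [(r, fold_change_simple(r, -13.9)) for r in self.R_VALUES]
        res = fit_eps_R(pts)
        assert res.estimate == pytest.approx(-13.9, abs=1e-6)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_single_point_closed_form_inversion(self):
        res = fit_eps_R([(130, 0.5)])
        # invert fc = 1/(1 + (2R/N)e^(-e)) by hand
        expected = -math.log((1 / 0.5 - 1) * 4.6e6 / 260)
        assert res.estimate == pytest.approx(expected, rel=1e-12)

    def test_noisy_simulation_mean_bias_below_02_kbt(self):
        estimates = []
        for i in range(200):
            pts = make_titration(-13.9, self.R_VALUES, noise_cv=0.1, seed=i)
            estimates.append(fit_eps_R(pts).estimate)
        assert abs(np.mean(estimates) + 13.9) < 0.2

    def test_all_zero_R_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_eps_R([(0, 1.0), (0, 1.0)])

    def test_estimator_protocol(self):
        est = RepressorTitrationFit()
        assert est.get_params()["heads"] == 2
        est.set_params(heads=4)
        assert est.heads == 4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
        pts = [(r, fold_change_simple(r, -12.0)) for r in self.R_VALUES]
        est = RepressorTitrationFit().fit([p[0] for p in pts], [p[1] for p in pts])
        np.testing.assert_allclose(est.predict([p[0] for p in pts]),
                                   [p[1] for p in pts], rtol=1e-6)
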
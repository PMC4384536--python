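"""Thermogram simulation and fitting against independent heat oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clampeq.equilibria import BindingParameters, InvalidParameterError
from clampeq.itc import (
    OneSiteBindingModel,
    Thermogram,
    TitrationExperiment,
    TwoSiteBindingModel,
    TwoSiteParameters,
    concentrations_after_injection,
    fit_one_site,
    fold_change,
    one_site_cumulative_heat,
    simulate_thermogram,
    simulate_two_site_thermogram,
)
from clampeq.synthetic import GeneratorConfig, gen_itc

from .conftest import bisect_hetero_bound


def serial_mixing_concentrations(exp, index):
    """Independent oracle: continuous serial-mixing mass tracking.

    During each injection the cell overflows the instantaneous mixture,
    giving exponential depletion of anything initially in the cell and the
    corresponding accumulation integral for the titrant.
    """
    v = float(np.cumsum(exp.injection_volumes)[index])
    f = math.exp(-v / exp.cell_volume)
    mt = exp.cell_concentration_initial * f
    xt = exp.syringe_concentration * (1.0 - f)
    return mt, xt


def cumulative_from_injection_heats(dq, exp):
    """Invert the displacement-corrected differential-heat recursion."""
    q = np.zeros(len(dq))
    prev = 0.0
    for i, (d, dv) in enumerate(zip(dq, exp.injection_volumes)):
        half = dv / (2.0 * exp.cell_volume)
        q[i] = (d + prev * (1.0 - half)) / (1.0 + half)
        prev = q[i]
    return q


class TestConcentrations:
    def test_continuity_at_small_volume(self):
        exp = TitrationExperiment(200e-6, 14e-6, 210e-6, (1e-12,))
        mt, xt = concentrations_after_injection(exp, 0)
        assert mt == pytest.approx(14e-6, rel=1e-6)
        assert xt == pytest.approx(0.0, abs=1e-11)

    def test_cell_species_strictly_decreasing(self, pre_fusion_experiment):
        mts = [
            concentrations_after_injection(pre_fusion_experiment, i)[0]
            for i in range(pre_fusion_experiment.n_injections)
        ]
        assert np.all(np.diff(mts) < 0)

    def test_against_serial_mixing_oracle(self, pre_fusion_experiment):
        """Displacement correction tracks the serial-mixing simulation to
        better than 0.5% over the printed 210/14 uM geometry."""
        for i in range(pre_fusion_experiment.n_injections):
            mt, xt = concentrations_after_injection(pre_fusion_experiment, i)
            mt_o, xt_o = serial_mixing_concentrations(pre_fusion_experiment, i)
            assert mt == pytest.approx(mt_o, rel=5e-3)
            assert xt == pytest.approx(xt_o, rel=5e-3)

    def test_index_out_of_range(self, pre_fusion_experiment):
        with pytest.raises(IndexError):
            concentrations_after_injection(pre_fusion_experiment, 20)


class TestOneSiteHeat:
    def test_zero_titrant_zero_heat(self, pre_fusion_params):
        assert one_site_cumulative_heat(pre_fusion_params, 14e-6, 0.0, 200e-6) == 0.0

    def test_full_saturation_limit(self):
        p = BindingParameters(1e-15, -10.0, 1.0)
        q = one_site_cumulative_heat(p, 14e-6, 30e-6, 200e-6)
        assert q == pytest.approx(1.0 * 14e-6 * -10.0 * 200e-6 * 1e9, rel=1e-6)

    def test_matches_bound_complex_oracle(self, pre_fusion_params):
        """Q equals V0*dH*[bound] with [bound] from an independent bisection
        solver on the n-site mass balance."""
        q = one_site_cumulative_heat(pre_fusion_params, 14e-6, 7e-6, 200e-6)
        bound = bisect_hetero_bound(1.0 * 14e-6, 7e-6, 457e-9)
        assert q == pytest.approx(200e-6 * -10.0 * bound * 1e9, rel=1e-8)

    @given(
        log_kd=st.floats(-9, -4),
        mt=st.floats(1e-6, 50e-6),
        ratio=st.floats(0.05, 5.0),
        n=st.floats(0.5, 2.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_oracle_equivalence_sweep(self, log_kd, mt, ratio, n):
        kd = 10.0**log_kd
        p = BindingParameters(kd, -8.0, n)
        xt = ratio * mt
        q = one_site_cumulative_heat(p, mt, xt, 200e-6)
        bound = bisect_hetero_bound(n * mt, xt, kd)
        assert q == pytest.approx(200e-6 * -8.0 * bound * 1e9, rel=1e-8, abs=1e-6)


class TestSimulation:
    def test_zero_enthalpy_zero_heats(self, pre_fusion_experiment):
        p = BindingParameters(457e-9, 0.0, 1.0)
        tg = simulate_thermogram(pre_fusion_experiment, p)
        assert np.all(tg.injection_heats == 0.0)

    def test_telescoping_identity(self, pre_fusion_experiment, pre_fusion_params):
        """Sum of injection heats equals the final cumulative heat plus the
        displacement-correction terms, exactly."""
        tg = simulate_thermogram(pre_fusion_experiment, pre_fusion_params)
        q = cumulative_from_injection_heats(tg.injection_heats, pre_fusion_experiment)
        dvi = np.asarray(pre_fusion_experiment.injection_volumes)
        qprev = np.concatenate([[0.0], q[:-1]])
        dilution = np.sum(dvi / pre_fusion_experiment.cell_volume * (q + qprev) / 2)
        assert tg.injection_heats.sum() == pytest.approx(q[-1] + dilution, rel=1e-10)

    def test_high_c_first_injection_returns_enthalpy(self):
        """At c = 1000 all early titrant binds: first NDH ~ dH."""
        m0 = 100e-6
        exp = TitrationExperiment(200e-6, m0, 1.5e-3, (2e-6,) * 20)
        p = BindingParameters(m0 / 1000.0, -10.0, 1.0)
        tg = simulate_thermogram(exp, p)
        assert tg.normalized_heats[0] == pytest.approx(-10.0, rel=2e-3)

    def test_ndh_sign_matches_enthalpy_sign(self, pre_fusion_experiment):
        for dh in (-10.0, 4.0):
            tg = simulate_thermogram(
                pre_fusion_experiment, BindingParameters(457e-9, dh, 1.0)
            )
            assert np.all(np.sign(tg.normalized_heats) == np.sign(dh))

    def test_sigmoid_inflection_near_stoichiometry(self):
        """High-c thermograms drop steepest near molar ratio = n."""
        exp = TitrationExperiment(200e-6, 50e-6, 750e-6, (2e-6,) * 20)
        tg = simulate_thermogram(exp, BindingParameters(1e-7, -10.0, 1.0))
        steepest = tg.molar_ratios[np.argmax(np.diff(tg.normalized_heats)) + 1]
        assert steepest == pytest.approx(1.0, abs=0.25)


class TestTwoSite:
    fig3_exp = TitrationExperiment(200e-6, 7.5e-6, 150e-6, (2e-6,) * 20)
    site_cen = BindingParameters(457e-9, -10.0, 1.0)
    site_acc = BindingParameters(2e-6, -5.0, 1.0)

    def test_silent_class_reduces_to_one_site(self, pre_fusion_experiment):
        tp = TwoSiteParameters(self.site_cen, BindingParameters(2e-6, 0.0, 1.0))
        two = simulate_two_site_thermogram(pre_fusion_experiment, tp)
        one = simulate_thermogram(pre_fusion_experiment, self.site_cen)
        np.testing.assert_allclose(two.normalized_heats, one.normalized_heats, rtol=1e-9)

    def test_nonbinding_class_reduces_to_one_site(self, pre_fusion_experiment):
        tp = TwoSiteParameters(self.site_cen, BindingParameters(math.inf, -5.0, 1.0))
        two = simulate_two_site_thermogram(pre_fusion_experiment, tp)
        one = simulate_thermogram(pre_fusion_experiment, self.site_cen)
        np.testing.assert_allclose(two.normalized_heats, one.normalized_heats, rtol=1e-9)

    def test_site_class_order_invariance(self):
        a = simulate_two_site_thermogram(
            self.fig3_exp, TwoSiteParameters(self.site_cen, self.site_acc)
        )
        b = simulate_two_site_thermogram(
            self.fig3_exp, TwoSiteParameters(self.site_acc, self.site_cen)
        )
        np.testing.assert_allclose(a.normalized_heats, b.normalized_heats, rtol=1e-12)

    def test_saturation_total_heat(self):
        """At large titrant excess the cumulative heat approaches
        V0*Mt*(n1*dH1 + n2*dH2)."""
        exp = TitrationExperiment(200e-6, 7.5e-6, 5e-3, (2e-6,) * 20)
        tp = TwoSiteParameters(self.site_cen, self.site_acc)
        tg = simulate_two_site_thermogram(exp, tp)
        q = cumulative_from_injection_heats(tg.injection_heats, exp)
        from clampeq.itc import _all_concentrations

        mt, _ = _all_concentrations(exp)
        expected = 200e-6 * mt[-1] * (-10.0 - 5.0) * 1e9
        assert q[-1] == pytest.approx(expected, rel=5e-3)

    def test_multiphasic_signature_at_bivalent_conditions(self):
        """At the 150 uM into 7.5 uM geometry the two-class curve cannot be
        absorbed by any single-class isotherm (systematic lack of fit)."""
        tg = simulate_two_site_thermogram(
            self.fig3_exp, TwoSiteParameters(self.site_cen, self.site_acc)
        )
        res = OneSiteBindingModel(tg, self.fig3_exp).fit()
        assert res.ssr > 1e-2  # noise-free single-class fits reach ~1e-20

    def test_two_site_fit_self_consistency(self):
        tp = TwoSiteParameters(self.site_cen, self.site_acc)
        tg = simulate_two_site_thermogram(self.fig3_exp, tp)
        truth = np.array([
            math.log(self.site_cen.association_constant), -10.0, 1.0,
            math.log(self.site_acc.association_constant), -5.0, 1.0,
        ])
        res = TwoSiteBindingModel(tg, self.fig3_exp).fit(start_params=truth * 1.05)
        sp = res.site_parameters
        assert sp.site_cen.dissociation_constant == pytest.approx(457e-9, rel=1e-4)
        assert sp.site_acc.dissociation_constant == pytest.approx(2e-6, rel=1e-4)


class TestFitting:
    def test_noise_free_self_consistency(self, pre_fusion_experiment, pre_fusion_params):
        tg = simulate_thermogram(pre_fusion_experiment, pre_fusion_params)
        fitted, res = fit_one_site(tg, pre_fusion_experiment)
        assert fitted.dissociation_constant == pytest.approx(457e-9, rel=1e-6)
        assert fitted.enthalpy == pytest.approx(-10.0, rel=1e-6)
        assert fitted.stoichiometry == pytest.approx(1.0, rel=1e-6)
        assert not res.warnings

    def test_fixed_stoichiometry_noise_free(self, pre_fusion_experiment, pre_fusion_params):
        tg = simulate_thermogram(pre_fusion_experiment, pre_fusion_params)
        fitted, res = fit_one_site(tg, pre_fusion_experiment, fix_stoichiometry=1.0)
        assert fitted.dissociation_constant == pytest.approx(457e-9, rel=1e-6)
        assert res.stoichiometry_se == 0.0

    def test_initial_guess_accepted(self, pre_fusion_experiment, pre_fusion_params):
        tg = simulate_thermogram(pre_fusion_experiment, pre_fusion_params)
        guess = BindingParameters(1e-6, -8.0, 1.2)
        fitted, _ = fit_one_site(tg, pre_fusion_experiment, initial_guess=guess)
        assert fitted.dissociation_constant == pytest.approx(457e-9, rel=1e-6)

    def test_low_c_raises_warning_flag(self):
        """A titration with c << 1 flags the affinity as poorly determined."""
        exp = TitrationExperiment(200e-6, 5e-6, 100e-6, (2e-6,) * 20)
        p = BindingParameters(500e-6, -10.0, 1.0)  # c = 0.01
        tg = simulate_thermogram(exp, p)
        _, res = fit_one_site(tg, exp, fix_stoichiometry=1.0)
        assert any("c-value" in w for w in res.warnings)

    def test_standard_errors_cover_noise(self, pre_fusion_experiment, pre_fusion_params):
        cfg = GeneratorConfig(seed=7, noise_fraction=0.02, replicate_count=1)
        tg = gen_itc(pre_fusion_experiment, pre_fusion_params, cfg)[0]
        _, res = fit_one_site(tg, pre_fusion_experiment)
        # fitted Kd within ~4 SE of truth and SE itself a sane magnitude
        assert abs(res.kd - 457e-9) < 4 * res.kd_se
        assert 1e-9 < res.kd_se < 457e-9

    @pytest.mark.parametrize("c_value", [5.0, 50.0, 500.0])
    def test_identifiability_across_c_range(self, c_value):
        """Replicate-mean recovery bias stays below 2% at 1% noise for
        c between 5 and 500."""
        m0 = 20e-6
        kd = m0 / c_value
        exp = TitrationExperiment(200e-6, m0, 15 * m0, (2e-6,) * 20)
        p = BindingParameters(kd, -10.0, 1.0)
        cfg = GeneratorConfig(seed=11, noise_fraction=0.01, replicate_count=25)
        kds = [fit_one_site(t, exp)[0].dissociation_constant for t in gen_itc(exp, p, cfg)]
        assert np.mean(kds) == pytest.approx(kd, rel=0.02)

    def test_requires_six_injections(self, pre_fusion_params):
        exp = TitrationExperiment(200e-6, 14e-6, 210e-6, (2e-6,) * 4)
        tg = simulate_thermogram(exp, pre_fusion_params)
        with pytest.raises(InvalidParameterError):
            OneSiteBindingModel(tg, exp)

    def test_summary_reports_thermodynamics(self, pre_fusion_experiment, pre_fusion_params):
        tg = simulate_thermogram(pre_fusion_experiment, pre_fusion_params)
        _, res = fit_one_site(tg, pre_fusion_experiment)
        text = res.summary()
        for token in ("Kd", "dH", "dG", "TdS", "c-value"):
            assert token in text


class TestFoldChange:
    def test_wild_type_vs_super_clamp(self):
        """16 uM vs 2 uM blocked-complex affinities: eightfold."""
        assert fold_change(16e-6, 2e-6) == pytest.approx(8.0)

    def test_identity(self):
        assert fold_change(3e-6, 3e-6) == 1.0

    def test_pre_vs_post_fusion(self):
        assert fold_change(457e-9, 43e-9) == pytest.approx(10.63, abs=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            fold_change(0.0, 1e-6)
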
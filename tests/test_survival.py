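"""Survival sub-models, their composition, and the mean inactivation dose."""

import math

import numpy as np
import pytest

from radrepair import (
    CellPhenotype,
    ExposureScenario,
    combined_survival,
    g1_escape,
    mean_inactivation_dose,
    mitotic_survival,
    survival_g1_noncycling,
    survival_g2,
)


class TestSubModels:
    def test_zero_dose_everywhere(self, human, params):
        assert survival_g1_noncycling(0.0, human, params) == 1.0
        assert survival_g2(0.0, human, params) == 1.0
        assert mitotic_survival(0.0, params) == 1.0
        assert g1_escape(0.0, human, params) == 1.0

    def test_poisson_zero_class_links_survival_to_lethal_yield(self, human, params):
        from radrepair import aberration_yields

        sc = ExposureScenario(dose=2.5, phase="G1")
        y = aberration_yields(sc, human, params, t=float("inf"))
        lethal = y.n_dicentric + y.n_deletion_visible
        assert survival_g1_noncycling(2.5, human, params) == pytest.approx(
            math.exp(-lethal)
        )

    def test_mitotic_scalar_value(self, params):
        assert mitotic_survival(35.0, params) == pytest.approx(math.exp(-0.49))
        assert mitotic_survival(35.0, params) == pytest.approx(0.6126, abs=5e-5)

    def test_mitotic_log_linear(self, params):
        s1, s2 = mitotic_survival(10.0, params), mitotic_survival(20.0, params)
        assert math.log(s2) == pytest.approx(2 * math.log(s1))

    def test_g1_escape_scalar_value(self, human, params):
        got = g1_escape(35.0, human, params)
        assert got == pytest.approx(math.exp(-0.2975))
        assert got == pytest.approx(0.7427, abs=5e-5)

    def test_checkpoint_defective_always_escapes(self, params):
        cho_like = CellPhenotype(g1_checkpoint_competent=False)
        assert g1_escape(500.0, cho_like, params) == 1.0

    def test_noncycling_never_arrests(self, human, params):
        assert g1_escape(500.0, human, params, cycling=False) == 1.0

    def test_g1_monotone_decreasing(self, human, params):
        doses = np.arange(0, 10.5, 0.5)
        s = [survival_g1_noncycling(d, human, params) for d in doses]
        assert all(b < a for a, b in zip(s, s[1:]))

    def test_nhej_defect_sensitises_g1(self, human, human_nhej_defective, params):
        for d in (0.5, 1, 2, 4, 6, 8, 10):
            assert survival_g1_noncycling(d, human_nhej_defective, params) < (
                survival_g1_noncycling(d, human, params)
            )

    def test_nhej_defective_more_resistant_in_g2(self, human_nhej_defective, params):
        for d in (0.5, 1, 2, 4, 6, 8):
            assert survival_g2(d, human_nhej_defective, params) >= (
                survival_g1_noncycling(d, human_nhej_defective, params)
            )


class TestCombined:
    def test_all_channels_off_gives_unity(self, human, params):
        p = params.with_values(mitosis_sensitivity=0.0, arrest_sensitivity=0.0)
        sc = ExposureScenario(dose=0.0, phase="M", cycling=True)
        curve = combined_survival(sc, human, p, doses=[0.0, 2.0])
        assert curve.surviving_fraction[0] == 1.0
        assert curve.surviving_fraction[1] == 1.0  # mitotic channel disabled

    def test_delayed_plating_g1_is_aberration_only(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="G1", cycling=False, plating="delayed")
        curve = combined_survival(sc, human, params, doses=[2.0])
        assert curve.surviving_fraction[0] == pytest.approx(
            survival_g1_noncycling(2.0, human, params)
        )

    def test_cycling_immediate_plating_adds_arrest(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="G1", cycling=True, plating="immediate")
        curve = combined_survival(sc, human, params, doses=[2.0])
        n0 = 5.738 * 6.1 * 2.0
        expected = survival_g1_noncycling(2.0, human, params) * math.exp(
            -params.arrest_sensitivity * n0
        )
        assert curve.surviving_fraction[0] == pytest.approx(expected)

    def test_mitotic_irradiation_is_mitotic_death_only(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="M")
        curve = combined_survival(sc, human, params, doses=[1.0])
        n0 = 5.738 * 6.1 * 2  # replicated genome
        assert curve.surviving_fraction[0] == pytest.approx(
            math.exp(-params.mitosis_sensitivity * n0)
        )

    def test_g2_checkpoint_caps_breaks_fed_to_mitosis(self, human, params):
        # above threshold the mitotic factor saturates at exp(-psi * 20)
        sc = ExposureScenario(dose=0.0, phase="G2", cycling=True)
        curve = combined_survival(sc, human, params, doses=[4.0])
        expected = survival_g2(4.0, human, params) * math.exp(
            -params.mitosis_sensitivity * params.checkpoint_threshold
        )
        assert curve.surviving_fraction[0] == pytest.approx(expected)

    def test_survival_always_a_probability(self, human, params):
        for phase, cycling in [("G1", False), ("G1", True), ("G2", True), ("M", False)]:
            sc = ExposureScenario(dose=0.0, phase=phase, cycling=cycling,
                                  plating="immediate")
            curve = combined_survival(sc, human, params, doses=np.linspace(0, 12, 25))
            s = curve.surviving_fraction
            assert s[0] == 1.0
            assert np.all((s > 0) & (s <= 1))
            assert np.all(np.diff(s) <= 1e-12)

    def test_removing_a_death_channel_never_decreases_survival(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="G2", cycling=True)
        base = combined_survival(sc, human, params, doses=[3.0]).surviving_fraction[0]
        relaxed = combined_survival(
            sc, human, params.with_values(mitosis_sensitivity=0.0), doses=[3.0]
        ).surviving_fraction[0]
        assert relaxed >= base

    def test_negative_dose_rejected(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="G1")
        with pytest.raises(ValueError):
            combined_survival(sc, human, params, doses=[-1.0])


class TestMeanInactivationDose:
    def test_pure_exponential_closed_form(self):
        d = np.arange(0, 15.0001, 0.02)
        assert mean_inactivation_dose(d, np.exp(-0.5 * d)) == pytest.approx(2.0, abs=1e-4)

    def test_linear_quadratic_against_fine_quadrature(self):
        alpha, beta = 0.3, 0.03
        d = np.arange(0, 12.0001, 0.05)
        s = np.exp(-alpha * d - beta * d**2)
        d_fine = np.linspace(0, 60, 2_000_001)
        oracle = np.trapezoid(np.exp(-alpha * d_fine - beta * d_fine**2), d_fine)
        assert mean_inactivation_dose(d, s) == pytest.approx(oracle, abs=1e-4)

    def test_flat_curve_warns_and_returns_grid_integral(self, caplog):
        d = np.arange(0, 5.0001, 0.05)
        with caplog.at_level("WARNING"):
            mid = mean_inactivation_dose(d, np.ones_like(d))
        assert mid == pytest.approx(5.0)
        assert any("tail" in rec.message for rec in caplog.records)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            mean_inactivation_dose([0, 1], [1.0, 1.5])
        with pytest.raises(ValueError):
            mean_inactivation_dose([1, 0], [1.0, 0.5])
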
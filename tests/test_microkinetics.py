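"""Rate-constant formulas, mechanism construction and the steady-state
surface kinetics of H2 oxidation on Pd(111)."""

import numpy as np
import pytest

import jargas as jg
from jargas.microkinetics import (
    ConvergenceError,
    MechanismError,
    Mechanism,
    SiteAreaInputs,
    Step,
    gas_consumption,
)

R = 8.31446261815324


class TestVibrationalEntropy:
    def test_single_mode_at_unit_reduced_frequency(self):
        """x = h v / (k_B T) = 1 gives S/k_B = 1/(e-1) - ln(1 - 1/e),
        frozen from a scalar hand evaluation."""
        kB, h = 1.380649e-23, 6.62607015e-34
        t = 300.0
        spec = jg.VibrationalSpec((kB * t / h,))
        assert jg.vib_entropy(spec, t) == pytest.approx(1.0406519, rel=1e-6)

    def test_stiff_modes_contribute_nothing(self):
        spec = jg.VibrationalSpec((1e16, 2e16))
        assert jg.vib_entropy(spec, 300.0) < 1e-10

    def test_entropy_decreases_with_frequency(self):
        t = 300.0
        freqs = [1e12, 5e12, 2e13, 1e14]
        entropies = [
            jg.vib_entropy(jg.VibrationalSpec((f,)), t) for f in freqs
        ]
        assert all(a > b for a, b in zip(entropies, entropies[1:]))

    def test_empty_spectrum_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert jg.vib_entropy(jg.VibrationalSpec(()), 300.0) == 0.0

    def test_wavenumber_conversion(self):
        spec = jg.VibrationalSpec.from_wavenumbers((1000.0,))
        assert spec.frequencies[0] == pytest.approx(2.99792458e13)


class TestRateConstantFormulas:
    def test_tst_prefactor_reduces_to_attempt_frequency(self):
        """Zero activation entropy leaves k_B T / h, about 6.15e12 s^-1 at
        295.15 K."""
        assert jg.tst_prefactor(0.0, 295.15) == pytest.approx(6.1499e12, rel=1e-4)

    def test_hertz_knudsen_h2(self):
        """H2 sticking on the reference site: frozen scalar evaluation with
        CODATA constants."""
        p = jg.AdsorptionParams(
            mass_amu=2.0, sticking=0.5, site_area=4.37e-26,
            e_des=96e3, theta_rot=87.9, sigma=2,
        )
        assert jg.hertz_knudsen_ads(p, 295.0) == pytest.approx(
            2.37011e-3, rel=1e-5
        )

    def test_zero_sticking_means_no_adsorption(self):
        p = jg.AdsorptionParams(2.0, 0.0, 4.37e-26, 96e3, 87.9, 2)
        assert jg.hertz_knudsen_ads(p, 295.0) == 0.0

    def test_nonactivated_adsorption_scales_as_inverse_sqrt_t(self):
        p = jg.AdsorptionParams(32.0, 1.0, 4.37e-26, 77e3, 2.1, 2)
        ratio = jg.hertz_knudsen_ads(p, 400.0) / jg.hertz_knudsen_ads(p, 100.0)
        assert ratio == pytest.approx(0.5, rel=1e-12)

    def test_desorption_o2_frozen_value(self):
        """O2 desorption from Pd(111) at 295 K, frozen scalar evaluation."""
        p = jg.AdsorptionParams(32.0, 1.0, 4.37e-26, 77e3, 2.1, 2)
        assert jg.desorption_rate(p, 295.0) == pytest.approx(
            1.35774e-3, rel=1e-5
        )

    def test_desorption_scales_as_t_cubed_without_barrier(self):
        p = jg.AdsorptionParams(32.0, 1.0, 4.37e-26, 0.0, 2.1, 2)
        ratio = jg.desorption_rate(p, 600.0) / jg.desorption_rate(p, 300.0)
        assert ratio == pytest.approx(8.0, rel=1e-12)

    def test_desorption_vanishes_at_infinite_binding(self):
        p = jg.AdsorptionParams(32.0, 1.0, 4.37e-26, 1e7, 2.1, 2)
        assert jg.desorption_rate(p, 295.0) == 0.0


class TestSiteArea:
    def test_inverse_proportionality_to_crystallite_size(self):
        base = SiteAreaInputs(36.149e-9, 1.37e-10, 106.42, 12.02)
        doubled = SiteAreaInputs(2 * 36.149e-9, 1.37e-10, 106.42, 12.02)
        assert jg.site_area(doubled) == pytest.approx(
            jg.site_area(base) / 2, rel=1e-12
        )

    def test_density_unit_variants_differ_by_1e6(self):
        cgs = SiteAreaInputs(36.149e-9, 1.37e-10, 106.42, 12.02)
        si = SiteAreaInputs(36.149e-9, 1.37e-10, 106.42, 12.02e6)
        assert jg.site_area(cgs) == pytest.approx(1e6 * jg.site_area(si), rel=1e-12)

    def test_same_order_as_reference_site_area(self):
        est = jg.site_area(SiteAreaInputs(36.149e-9, 1.37e-10, 106.42, 12.02))
        assert 1e-26 < est < 1e-25  # reference model uses 4.37e-26 m^2


class TestMechanismConstruction:
    def test_reference_model_steps(self, reference_model):
        assert reference_model.step_names == (
            "O2+2*<->2O*", "H2+2*<->2H*", "H*+O*<->OH*+*",
            "H*+OH*<->H2O*+*", "2OH*<->H2O*+O*", "H2O*->H2O+*",
        )
        water_desorption = reference_model.steps[-1]
        assert not water_desorption.reversible

    def test_unbalanced_step_rejected(self):
        with pytest.raises(MechanismError):
            Mechanism(
                (Step("bad", {"H*": 1}, {"OH*": 1}, lambda T: 1.0, None),)
            )

    def test_site_imbalance_rejected(self):
        with pytest.raises(MechanismError):
            Mechanism(
                (Step("bad", {"H2": 1, "*": 1}, {"H*": 2}, lambda T: 1.0, None),)
            )

    @pytest.mark.parametrize("temperature", [291.15, 295.15, 310.15])
    def test_thermodynamic_consistency(self, temperature):
        """k_f/k_b of each reversible surface step equals the equilibrium
        constant exp(dS/R) exp(-dH/RT) with dS = R ln(beta_f/beta_b),
        dH = E_f - E_b."""
        from jargas.microkinetics import PD111_SURFACE_STEPS

        for name, sp in PD111_SURFACE_STEPS.items():
            if sp.beta_b == 0:
                continue
            constraint = jg.ThermoConstraint(
                delta_s=R * np.log(sp.beta_f / sp.beta_b),
                delta_h=sp.e_f - sp.e_b,
            )
            ratio = sp.k_forward(temperature) / sp.k_backward(temperature)
            assert ratio == pytest.approx(
                constraint.k_equ(temperature), rel=1e-9
            )


def two_step_toy():
    """Water adsorption-desorption loop with a closed-form steady state:
    theta_H2O = k1 p / (k1 p + k2)."""
    k1, k2, p = 3.0e-4, 7.0, 2000.0
    mech = Mechanism(
        (
            Step("ads", {"H2O": 1, "*": 1}, {"H2O*": 1}, lambda T: k1, None),
            Step("des", {"H2O*": 1}, {"H2O": 1, "*": 1}, lambda T: k2, None),
        )
    )
    cond = jg.OperatingConditions(300.0, {"H2O": p})
    theta_exact = k1 * p / (k1 * p + k2)
    return mech, cond, theta_exact


class TestSteadyState:
    def test_two_step_toy_matches_closed_form(self):
        mech, cond, theta_exact = two_step_toy()
        state = jg.steady_state(mech, cond)
        assert state.coverages["H2O*"] == pytest.approx(theta_exact, abs=1e-8)
        # adsorption and desorption fluxes balance, so no net gas turnover
        assert state.tof == pytest.approx(0.0, abs=1e-10)

    def test_no_hydrogen_no_turnover(self, reference_model):
        cond = jg.OperatingConditions(295.15, {"O2": 4762.0, "H2": 0.0})
        state = jg.steady_state(reference_model, cond)
        assert state.tof == pytest.approx(0.0, abs=1e-12)

    def test_hydrogen_blocks_the_surface(self, reference_model, catalyst_conditions):
        state = jg.steady_state(reference_model, catalyst_conditions)
        assert state.dominant_species == "H*"
        assert state.coverages["H*"] > 0.5

    def test_coverages_normalized_and_bounded(
        self, reference_model, catalyst_conditions
    ):
        state = jg.steady_state(reference_model, catalyst_conditions)
        total = sum(state.coverages.values())
        assert total == pytest.approx(1.0, abs=1e-8)
        assert all(0.0 <= v <= 1.0 for v in state.coverages.values())

    @pytest.mark.parametrize("temperature", [291.15, 310.15])
    def test_steady_flux_stoichiometry(
        self, reference_model, catalyst_conditions, temperature
    ):
        """Water formation consumes H2 1:1 and O2 1:2 at steady state."""
        cond = catalyst_conditions.with_temperature(temperature)
        state = jg.steady_state(reference_model, cond)
        h2 = gas_consumption(state, reference_model, "H2")
        o2 = gas_consumption(state, reference_model, "O2")
        assert state.tof == pytest.approx(h2, rel=1e-6)
        assert state.tof == pytest.approx(2 * o2, rel=1e-6)


class TestDegreeOfRateControl:
    def test_sum_rule_and_rds(self, reference_model, catalyst_conditions):
        drc = jg.degree_of_rate_control(reference_model, catalyst_conditions)
        assert sum(drc.values()) == pytest.approx(1.0, abs=0.05)
        assert max(drc, key=drc.get) == "H*+OH*<->H2O*+*"

    def test_quasi_equilibrated_step_has_no_control(
        self, reference_model, catalyst_conditions
    ):
        """Speeding one step a million-fold equilibrates it; its DRC
        vanishes (checked against an independent one-sided perturbation)."""
        fast = reference_model.scaled("2OH*<->H2O*+O*", 1e6)
        drc = jg.degree_of_rate_control(fast, catalyst_conditions)
        assert abs(drc["2OH*<->H2O*+O*"]) < 1e-3
        # brute-force oracle: single large forward+backward perturbation
        tof0 = jg.steady_state(fast, catalyst_conditions).tof
        tof1 = jg.steady_state(
            fast.scaled("2OH*<->H2O*+O*", 1.5), catalyst_conditions
        ).tof
        assert abs(np.log(tof1 / tof0) / np.log(1.5)) < 1e-3


class TestApparentActivationEnergy:
    def test_positive_with_modest_variation(self, reference_model, catalyst_conditions):
        temps = np.arange(291.15, 310.16, 2.0)
        result = jg.apparent_ea(reference_model, catalyst_conditions, temps)
        assert np.all(result.apparent_ea > 0)
        variation = result.apparent_ea.max() - result.apparent_ea.min()
        assert 2.5e3 < variation < 1e4

    def test_gradient_matches_local_polynomial_oracle(
        self, reference_model, catalyst_conditions
    ):
        """Central-difference Ea agrees with an independent quadratic fit
        of ln TOF against 1/T around the same midpoint."""
        temps = np.array([294.15, 295.15, 296.15])
        result = jg.apparent_ea(reference_model, catalyst_conditions, temps)
        tofs = [
            jg.steady_state(
                reference_model, catalyst_conditions.with_temperature(t)
            ).tof
            for t in temps
        ]
        coeffs = np.polyfit(1.0 / temps, np.log(tofs), 2)
        slope_mid = 2 * coeffs[0] / 295.15 + coeffs[1]
        assert result.apparent_ea[1] == pytest.approx(-R * slope_mid, rel=0.02)

    def test_grid_bounds_enforced(self, reference_model, catalyst_conditions):
        with pytest.raises(ValueError):
            jg.apparent_ea(
                reference_model, catalyst_conditions, np.array([250.0, 260.0, 270.0])
            )


class TestReactionOrders:
    def test_orders_invariant_under_prefactor_rescaling(
        self, reference_model, catalyst_conditions
    ):
        orders = jg.reaction_orders(reference_model, catalyst_conditions)
        scaled = reference_model
        for name in reference_model.step_names:
            scaled = scaled.scaled(name, 3.0)
        orders_scaled = jg.reaction_orders(scaled, catalyst_conditions)
        for gas in orders:
            assert orders[gas] == pytest.approx(orders_scaled[gas], abs=1e-3)

    def test_step_size_robustness(self, reference_model, catalyst_conditions):
        """Richardson check: the log-derivative is stable between 1% and
        2% pressure perturbations (ln TOF has real curvature in ln p, so
        large dithers drift)."""
        small = jg.reaction_orders(reference_model, catalyst_conditions, delta=0.01)
        large = jg.reaction_orders(reference_model, catalyst_conditions, delta=0.02)
        for gas in small:
            assert np.isfinite(small[gas])
            assert small[gas] == pytest.approx(large[gas], abs=0.05)
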
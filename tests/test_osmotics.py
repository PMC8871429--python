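"""Mixing/ionic pressure models, virial extraction and equilibrium swelling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import R as R_GAS

import gelosmo as g
from gelosmo.osmotics import EquilibriumRoot

from conftest import brute_force_roots


class TestMixingPressure:
    def test_zero_virials_give_zero(self, solvent):
        phi = np.array([0.01, 0.05, 0.2])
        assert np.all(g.mixing_pressure_virial(phi, 0.0, 0.0) == 0.0)

    def test_hand_value(self, solvent):
        # A2=0.1, A3=0.5 at phi=0.05: (RT/V1)(2.5e-4 + 6.25e-5)
        expected = solvent.pressure_scale * (0.1 * 0.05**2 + 0.5 * 0.05**3)
        assert g.mixing_pressure_virial(0.05, 0.1, 0.5) == pytest.approx(expected, rel=1e-14)

    def test_leading_order_limit(self, solvent):
        phi = 1e-6
        ratio = g.mixing_pressure_virial(phi, 0.1, 0.5) / phi**2
        assert ratio == pytest.approx(0.1 * solvent.pressure_scale, rel=1e-5)

    def test_flory_huggins_hand_value(self, solvent):
        chi = g.ChiParameters(0.0, 0.0)
        expected = -solvent.pressure_scale * (np.log(0.9) + 0.1)
        assert g.mixing_pressure_flory_huggins(0.1, chi) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.1, 1.5])
    def test_phi_domain_errors(self, phi):
        with pytest.raises(ValueError):
            g.mixing_pressure_virial(phi, 0.1, 0.1)

    @pytest.mark.parametrize("chi0,chi1", [(0.0, 0.0), (0.45, 0.1), (0.6, -0.2)])
    def test_fh_virial_taylor_remainder_bound(self, solvent, chi0, chi1):
        # truncating -ln(1-phi)-phi at phi^3 leaves sum_{k>=4} phi^k/k
        # <= phi^4 / (4 (1 - phi))
        chi = g.ChiParameters(chi0, chi1)
        A2, A3 = g.chi_to_virial(chi)
        phi = np.linspace(0.01, 0.2, 40)
        fh = g.mixing_pressure_flory_huggins(phi, chi)
        vir = g.mixing_pressure_virial(phi, A2, A3)
        bound = phi**4 / (4.0 * (1.0 - phi))
        assert np.all(np.abs(fh - vir) / solvent.pressure_scale <= bound + 1e-15)


class TestChiVirialMapping:
    def test_series_expansion_oracle(self):
        # independent oracle: symbolic Taylor expansion of the FH bracket
        import sympy as sp
        phi, chi0, chi1 = sp.symbols("phi chi0 chi1")
        bracket = -(sp.log(1 - phi) + phi + chi0 * phi**2 + chi1 * phi**3)
        series = sp.series(bracket, phi, 0, 4).removeO().expand()
        a2_sym = series.coeff(phi, 2)
        a3_sym = series.coeff(phi, 3)
        for c0, c1 in [(0.0, 0.0), (0.5, 0.2), (-0.3, 1.1)]:
            A2, A3 = g.chi_to_virial(g.ChiParameters(c0, c1))
            assert A2 == pytest.approx(float(a2_sym.subs({chi0: c0})), abs=1e-12)
            assert A3 == pytest.approx(float(a3_sym.subs({chi1: c1})), abs=1e-12)

    def test_theta_condition(self):
        A2, _ = g.chi_to_virial(g.ChiParameters(0.5))
        assert A2 == 0.0

    def test_athermal_limit(self):
        assert g.chi_to_virial(g.ChiParameters(0.0, 0.0)) == (0.5, pytest.approx(1 / 3))

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_identity(self, c0, c1):
        A2, A3 = g.chi_to_virial(g.ChiParameters(c0, c1))
        back = g.virial_to_chi(A2, A3)
        assert back.chi0 == pytest.approx(c0, abs=1e-12)
        assert back.chi1 == pytest.approx(c1, abs=1e-12)


class TestDonnan:
    def closed_form(self, c_f, c_s, T):
        """1:1 salt closed form Pi = RT (sqrt(c_f^2 + 4 c_s^2) - 2 c_s)."""
        return R_GAS * T * (np.sqrt(c_f**2 + 4 * c_s**2) - 2 * c_s)

    def test_no_fixed_charge_is_zero(self, solvent):
        ions = g.IonicCondition.from_salts(c_nacl=40.0, fixed_charge_per_monomer=0.0)
        assert g.donnan_pressure(0.05, ions) == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form(self, solvent):
        ions = g.IonicCondition.from_salts(c_nacl=40.0, fixed_charge_per_monomer=0.3)
        c_f = ions.fixed_charge_concentration(0.05)
        expected = self.closed_form(c_f, 40.0, solvent.T)
        assert g.donnan_pressure(0.05, ions) == pytest.approx(expected, rel=1e-10)

    def test_salt_free_counterion_limit(self, solvent):
        ions = g.IonicCondition.from_salts(fixed_charge_per_monomer=0.3)
        c_f = ions.fixed_charge_concentration(0.05)
        assert g.donnan_pressure(0.05, ions) == pytest.approx(
            R_GAS * solvent.T * c_f, rel=1e-12)

    def test_monotone_decreasing_in_salt(self):
        pressures = [
            g.donnan_pressure(0.05, g.IonicCondition.from_salts(
                c_nacl=c, fixed_charge_per_monomer=0.3))
            for c in [1.0, 10.0, 100.0, 1000.0]
        ]
        assert all(a > b > 0 for a, b in zip(pressures, pressures[1:]))

    def test_mixed_nacl_cacl2_bath_positive(self):
        ions = g.IonicCondition.from_salts(c_nacl=40.0, c_cacl2=1.0,
                                           fixed_charge_per_monomer=0.3)
        assert g.donnan_pressure(0.05, ions) > 0

    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutral"):
            g.IonicCondition((("Na+", 1, 10.0),))


class TestDecomposition:
    def test_round_trip_with_forward_model(self, solvent):
        ions = g.IonicCondition.from_salts(c_nacl=40.0, fixed_charge_per_monomer=0.1)
        model = g.GelModel(A2=0.06, A3=0.2, elastic_C=8000.0, phi_ref=0.05, ions=ions)
        phi = np.logspace(-2, np.log10(0.2), 12)
        curve = g.OsmoticCurve(phi, model.swelling_pressure(phi), "total")
        mixing = g.decompose_swelling_pressure(
            curve, (model.elastic_C, model.phi_ref), ions=ions)
        np.testing.assert_allclose(mixing.pressure, model.mixing_pressure(phi),
                                   rtol=1e-10, atol=1e-8)

    def test_identity_map_without_network_or_ions(self):
        phi = np.array([0.02, 0.05, 0.1])
        curve = g.OsmoticCurve(phi, np.array([100.0, 500.0, 2000.0]), "total")
        mixing = g.decompose_swelling_pressure(curve, 0.0)
        np.testing.assert_array_equal(mixing.pressure, curve.pressure)
        assert mixing.pressure_kind == "mixing"

    def test_zero_fixed_charge_equals_ions_off(self):
        phi = np.array([0.02, 0.05, 0.1])
        curve = g.OsmoticCurve(phi, np.array([100.0, 500.0, 2000.0]), "total")
        ions = g.IonicCondition.from_salts(c_nacl=40.0, fixed_charge_per_monomer=0.0)
        with_ions = g.decompose_swelling_pressure(curve, 1000.0, ions=ions)
        without = g.decompose_swelling_pressure(curve, 1000.0)
        np.testing.assert_allclose(with_ions.pressure, without.pressure, atol=1e-8)

    def test_requires_total_kind(self):
        phi = np.array([0.02, 0.05, 0.1])
        curve = g.OsmoticCurve(phi, np.ones(3), "mixing")
        with pytest.raises(ValueError, match="total/swelling"):
            g.decompose_swelling_pressure(curve, 0.0)


class TestVirialFit:
    def make_mixing_curve(self, A2, A3, phi=None, uncertainty=None):
        if phi is None:
            phi = np.logspace(-2, np.log10(0.2), 15)
        pressure = g.mixing_pressure_virial(phi, A2, A3)
        return g.OsmoticCurve(phi, pressure, "mixing", uncertainty=uncertainty)

    def test_noiseless_exact_recovery(self):
        fit = g.fit_virial_coefficients(self.make_mixing_curve(0.09, 0.4))
        assert fit.A2 == pytest.approx(0.09, rel=1e-10)
        assert fit.A3 == pytest.approx(0.4, rel=1e-10)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_pressures(self):
        phi = np.logspace(-2, -1, 10)
        curve = g.OsmoticCurve(phi, np.zeros(10), "mixing")
        fit = g.fit_virial_coefficients(curve)
        assert fit.A2 == pytest.approx(0.0, abs=1e-14)
        assert fit.A3 == pytest.approx(0.0, abs=1e-14)
        assert fit.residual_rms == 0.0

    def test_order_invariance(self, rng):
        phi = np.logspace(-2, np.log10(0.2), 15)
        pressure = g.mixing_pressure_virial(phi, 0.05, -0.2)
        perm = rng.permutation(15)
        a = g.fit_virial_coefficients(g.OsmoticCurve(phi, pressure, "mixing"))
        b = g.fit_virial_coefficients(g.OsmoticCurve(phi[perm], pressure[perm], "mixing"))
        assert a.A2 == pytest.approx(b.A2, rel=1e-12)
        assert a.A3 == pytest.approx(b.A3, rel=1e-12)

    def test_rank_deficient_design_rejected(self):
        phi = np.full(5, 0.05)
        curve = g.OsmoticCurve(phi, np.ones(5), "mixing")
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            g.fit_virial_coefficients(curve)

    def test_coverage_with_known_noise(self, solvent):
        # quick Monte-Carlo: 95% CIs from the weighted fit should cover
        # the truth at close to nominal rate (full-size run in acceptance)
        rng = np.random.default_rng(7)
        A2t, A3t = 0.05, 0.3
        phi = np.logspace(-2, np.log10(0.2), 15)
        clean = g.mixing_pressure_virial(phi, A2t, A3t)
        sigma = 0.05 * np.abs(clean)
        hits2 = hits3 = 0
        n_rep = 150
        for _ in range(n_rep):
            noisy = clean + rng.normal(0, 1, 15) * sigma
            curve = g.OsmoticCurve(phi, noisy, "mixing", uncertainty=sigma)
            fit = g.fit_virial_coefficients(curve)
            ci = fit.conf_int()
            hits2 += ci[0, 0] <= A2t <= ci[0, 1]
            hits3 += ci[1, 0] <= A3t <= ci[1, 1]
        assert 0.88 <= hits2 / n_rep <= 1.0
        assert 0.88 <= hits3 / n_rep <= 1.0


class TestSwellingPressureAndEquilibrium:
    def test_reduces_to_mixing_without_network(self):
        model = g.GelModel(A2=0.05, A3=0.3, elastic_C=0.0)
        phi = np.array([0.01, 0.05, 0.2])
        np.testing.assert_array_equal(model.swelling_pressure(phi),
                                      model.mixing_pressure(phi))

    def test_monotone_decreasing_in_elastic_prefactor(self):
        phi = 0.05
        vals = [g.GelModel(A2=0.05, A3=0.3, elastic_C=c).swelling_pressure(phi)
                for c in [0.0, 1000.0, 5000.0]]
        assert vals[0] > vals[1] > vals[2]

    def test_single_stable_root_matches_oracle(self, simple_gel, solvent):
        roots = simple_gel.equilibrium()
        assert len(roots) == 1 and roots[0].stable
        oracle, spacing = brute_force_roots(simple_gel, n=200_000)
        assert len(oracle) == 1
        assert roots[0].phi == pytest.approx(oracle[0], rel=3 * spacing)
        # the root genuinely solves Pi_tot = 0
        assert abs(simple_gel.swelling_pressure(roots[0].phi)) <= 1e-9 * solvent.pressure_scale

    def test_no_network_no_root(self):
        model = g.GelModel(A2=0.05, A3=0.3, elastic_C=0.0)
        assert model.equilibrium() == []

    def test_negative_A3_two_roots_matches_oracle(self):
        model = g.GelModel(A2=0.05, A3=-0.4, elastic_C=5000.0, phi_ref=0.05)
        roots = model.equilibrium()
        oracle, spacing = brute_force_roots(model, n=200_000)
        assert len(roots) == len(oracle)
        for r, o in zip(sorted(x.phi for x in roots), oracle):
            assert r == pytest.approx(o, rel=3 * spacing)

    def test_ionic_term_shifts_equilibrium(self):
        ions = g.IonicCondition.from_salts(c_nacl=10.0, fixed_charge_per_monomer=0.05)
        neutral = g.GelModel(A2=0.05, A3=0.3, elastic_C=10_000.0)
        charged = g.GelModel(A2=0.05, A3=0.3, elastic_C=10_000.0, ions=ions)
        phi_n = neutral.equilibrium()[0].phi
        phi_c = [r for r in charged.equilibrium() if r.stable][0].phi
        assert phi_c < phi_n  # Donnan pressure swells the gel further

    def test_stability_classification(self):
        model = g.GelModel(A2=0.05, A3=-0.4, elastic_C=5000.0, phi_ref=0.05)
        roots = sorted(model.equilibrium(), key=lambda r: r.phi)
        assert [r.stable for r in roots] == [True, False]


class TestLongitudinalModulus:
    def test_vanishing_mixing_limit(self):
        m = g.longitudinal_modulus(1e-9, (0.05, 0.3), G_s=3000.0)
        assert m == pytest.approx(4.0 / 3.0 * 3000.0, rel=1e-6)

    def test_matches_finite_difference_of_mixing_pressure(self, solvent):
        phi, A2, A3 = 0.07, 0.05, -0.2
        h = 1e-7
        dPi = (g.mixing_pressure_virial(phi + h, A2, A3)
               - g.mixing_pressure_virial(phi - h, A2, A3)) / (2 * h)
        expected = phi * dPi + 4.0 / 3.0 * 2000.0
        got = g.longitudinal_modulus(phi, (A2, A3), G_s=2000.0)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_elastic_derivative_convention(self):
        # keeping phi d(-G_s)/dphi = -G_s/3 turns (4/3)G_s into G_s
        base = g.longitudinal_modulus(0.05, (0.05, 0.3), G_s=3000.0)
        alt = g.longitudinal_modulus(0.05, (0.05, 0.3), G_s=3000.0,
                                     include_elastic_derivative=True)
        assert base - alt == pytest.approx(3000.0 / 3.0, rel=1e-12)

    def test_positive_at_stable_equilibria(self):
        # thermodynamic stability: M_os (with elastic derivative) > 0
        rng = np.random.default_rng(3)
        for _ in range(20):
            model = g.GelModel(A2=rng.uniform(0.01, 0.1),
                               A3=rng.uniform(-0.5, 0.5),
                               elastic_C=rng.uniform(1e3, 2e4), phi_ref=0.05)
            for root in model.equilibrium():
                if root.stable:
                    m = model.longitudinal_modulus(root.phi,
                                                   include_elastic_derivative=True)
                    assert m > 0

    def test_drops_approaching_transition(self):
        # polyelectrolyte scenario: M_os at equilibrium falls off as the
        # volume transition is approached (sharpest drop at the last
        # surviving conditions), while staying positive on the branch
        config = g.polyelectrolyte_salt_sweep(noise_rel=0.0)
        values = []
        for c in config.control:
            model = config.gel_model(c)
            stable = [r for r in model.equilibrium() if r.stable]
            if not stable:
                break
            phi = min(r.phi for r in stable)
            values.append(model.longitudinal_modulus(phi))
        assert len(values) >= 4
        assert all(v > 0 for v in values)
        # strictly decreasing over the approach to the transition
        tail = values[len(values) // 2:]
        assert all(a > b for a, b in zip(tail, tail[1:]))
        assert values[-1] < 0.9 * max(values)


class TestVolumeTransition:
    def test_polyelectrolyte_transition_detected_and_bracketed(self):
        config = g.polyelectrolyte_salt_sweep(noise_rel=0.0)
        result = g.detect_volume_transition(config.control,
                                            model_fn=config.gel_model)
        assert result.transition_detected
        # oracle: dense continuation over the control variable
        cs = np.linspace(config.control[0], config.control[-1], 200)
        last_ok = None
        first_bad = None
        prev = None
        for c in cs:
            roots = [r for r in config.gel_model(c).equilibrium() if r.stable]
            phi = min((r.phi for r in roots), default=None)
            if phi is None or (prev is not None and prev / phi < 0.5):
                first_bad = c
                break
            last_ok, prev = c, phi
        assert first_bad is not None
        assert last_ok <= result.c_critical <= first_bad + 1e-9

    def test_neutral_scenario_no_transition(self):
        config = g.neutral_temperature_sweep(noise_rel=0.0)
        result = g.detect_volume_transition(config.control,
                                            model_fn=config.gel_model)
        assert not result.transition_detected
        assert np.all(np.isfinite(result.phi_eq))

    def test_bottlebrush_scenario_no_transition(self):
        config = g.bottlebrush_salt_sweep(noise_rel=0.0)
        result = g.detect_volume_transition(config.control,
                                            model_fn=config.gel_model)
        assert not result.transition_detected

    def test_jump_ratio_exceeds_threshold_when_reported(self):
        config = g.polyelectrolyte_salt_sweep(noise_rel=0.0)
        result = g.detect_volume_transition(config.control,
                                            model_fn=config.gel_model)
        assert result.jump_ratio >= result.jump_threshold

    def test_requires_enough_control_values(self):
        config = g.polyelectrolyte_salt_sweep(noise_rel=0.0)
        with pytest.raises(ValueError, match="at least 4"):
            g.detect_volume_transition([0.0, 1.0, 2.0],
                                       model_fn=config.gel_model)
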
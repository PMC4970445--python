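"""Kinetic scheme construction and the analytic population solver."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from porcycle.errors import InvalidParameterError
from porcycle.schemes import (
    InstrumentResponse,
    KineticScheme,
    build_branched_scheme,
    build_sequential_scheme,
    flux_fraction,
    solve_populations,
)

from conftest import random_scheme, scheme_time_grid


class TestBuildSequential:
    def test_single_compartment(self):
        s = build_sequential_scheme([1.0])
        assert s.n_compartments == 1
        np.testing.assert_allclose(s.rate_matrix, [[-1.0]])

    def test_eigenvalues_are_inverse_lifetimes(self):
        s = build_sequential_scheme([1.0, 2.0])
        eig = np.sort(np.linalg.eigvals(s.rate_matrix).real)
        assert eig == pytest.approx([-1.0, -0.5], abs=1e-14)

    def test_three_components_terminal_persists(self):
        s = build_sequential_scheme([4e-12, 200e-12, np.inf], terminal_persists=True)
        assert s.n_compartments == 3
        assert s.outflow(2) == 0.0
        # same via the flag alone
        s2 = build_sequential_scheme([4e-12, 200e-12, 30e-9], terminal_persists=True)
        assert s2.outflow(2) == 0.0

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_lifetime_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            build_sequential_scheme([1e-9, bad, 1e-6])


class TestBuildBranched:
    def test_closed_catalytic_limb(self):
        s = build_branched_scheme(0.0)
        t = np.geomspace(1e-13, 1e-5, 100)
        pops = solve_populations(s, t).populations
        ir, i696 = s.index("ICT_reactive"), s.index("I696")
        assert np.abs(pops[:, [ir, i696]]).max() < 1e-12

    def test_equal_limbs_symmetry(self):
        rate = 1e8
        s = build_branched_scheme(
            0.5, {"solvated_decay": rate, "intermediate_formation": rate}
        )
        t = np.geomspace(1e-13, 1e-6, 200)
        pops = solve_populations(s, t).populations
        a = pops[:, s.index("ICT_solvated")]
        b = pops[:, s.index("ICT_reactive")]
        assert np.abs(a - b).max() < 1e-12

    def test_fraction_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            build_branched_scheme(1.5)

    def test_branch_fractions_recorded(self):
        s = build_branched_scheme(0.4)
        assert s.branch_fractions["S_ICT"]["ICT_reactive"] == pytest.approx(0.4)


class TestFluxFraction:
    def test_catalytic_flux_matches_branch_fraction(self):
        s = build_branched_scheme(0.4)
        assert flux_fraction(s, "ICT_reactive") == pytest.approx(0.40, abs=1e-12)

    def test_sequential_everything_passes_through(self):
        s = build_sequential_scheme([3e-12, 5e-9, 1e-6])
        assert flux_fraction(s, "S2") == pytest.approx(1.0, abs=1e-12)

    def test_solvated_flux_against_numerical_integration(self):
        s = build_branched_scheme(0.25)
        # entry flux into ICT_solvated = (1-f) k_branch * P_S_ICT(t)
        kb = s.outflow(s.index("S_ICT"))
        t = np.linspace(0, 60.0 / kb, 40001)
        p = solve_populations(s, t).populations[:, s.index("S_ICT")]
        numeric = np.trapezoid(0.75 * kb * p, t)
        analytic = flux_fraction(s, "ICT_solvated")
        assert analytic == pytest.approx(0.75, abs=1e-12)
        assert numeric == pytest.approx(analytic, rel=1e-6)

    @pytest.mark.parametrize("f", [0.0, 0.17, 0.4, 0.5, 0.93, 1.0])
    def test_limb_fluxes_sum_to_one(self, f):
        s = build_branched_scheme(f)
        total = flux_fraction(s, "ICT_reactive") + flux_fraction(s, "ICT_solvated")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unknown_compartment(self):
        with pytest.raises(KeyError):
            flux_fraction(build_branched_scheme(0.4), "nope")


class TestSolvePopulations:
    def test_initial_condition_single_compartment(self):
        s = build_sequential_scheme([1.0])
        cm = solve_populations(s, np.array([0.0, 0.5, 1.0]))
        assert cm.populations[0, 0] == pytest.approx(1.0)
        assert cm.populations[2, 0] == pytest.approx(np.exp(-1.0))

    def test_intermediate_peak_time(self):
        k1, k2 = 2.21e6, 2.72e4
        s = build_sequential_scheme([1.0 / k1, 1.0 / k2])
        t_peak = np.log(k1 / k2) / (k1 - k2)
        assert t_peak == pytest.approx(2.01e-6, rel=0.005)
        t = np.linspace(0.8 * t_peak, 1.2 * t_peak, 20001)
        p2 = solve_populations(s, t).populations[:, 1]
        assert t[np.argmax(p2)] == pytest.approx(t_peak, rel=1e-4)

    def test_analytic_matches_ode_on_random_schemes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scheme = random_scheme(rng)
            times = scheme_time_grid(scheme)
            cm = solve_populations(scheme, times)
            sol = solve_ivp(
                lambda _t, p: scheme.rate_matrix @ p,
                (0.0, times[-1]),
                scheme.initial_vector,
                t_eval=times,
                method="LSODA",
                rtol=1e-10,
                atol=1e-13,
            )
            assert np.abs(cm.populations - sol.y.T).max() < 1e-6

    def test_irf_convolution_against_quadrature(self):
        rng = np.random.default_rng(11)
        scheme = random_scheme(rng, max_compartments=4)
        sigma = 0.2e-12
        irf = InstrumentResponse(center_time=0.0, width_sigma=sigma)
        check_times = np.array([-2e-13, 1e-13, 1e-12, 3e-11])
        cm = solve_populations(scheme, check_times, irf)
        lam_v = np.linalg.eig(scheme.rate_matrix)
        for it, t in enumerate(check_times):
            for ic in range(scheme.n_compartments):
                def integrand(tau):
                    lam, v = lam_v
                    c = np.linalg.solve(v, scheme.initial_vector.astype(complex))
                    if t - tau < 0:
                        return 0.0
                    p = (v @ (c * np.exp(lam * (t - tau)))).real[ic]
                    return p * np.exp(-0.5 * (tau / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
                ref, _ = quad(integrand, -8 * sigma, min(8 * sigma, t), limit=400)
                assert cm.populations[it, ic] == pytest.approx(ref, abs=1e-6)

    def test_conservation_with_explicit_sink(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            scheme = random_scheme(rng).with_ground_sink()
            times = scheme_time_grid(scheme)
            cm = solve_populations(scheme, times)
            assert np.abs(cm.populations.sum(axis=1) - 1.0).max() < 1e-9

    def test_conservation_after_irf_rise(self):
        scheme = build_branched_scheme(0.4)
        irf = InstrumentResponse(0.0, 0.2e-12)
        t = np.geomspace(2e-12, 1e-5, 200)  # > 10 sigma after t0
        total = solve_populations(scheme, t, irf).populations.sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-9

    def test_sigma_to_zero_converges_to_step_solution(self):
        scheme = build_branched_scheme(0.4)
        t = np.geomspace(1e-12, 1e-5, 150)
        no_irf = solve_populations(scheme, t).populations
        tiny = solve_populations(scheme, t, InstrumentResponse(0.0, 1e-18)).populations
        assert np.abs(tiny - no_irf).max() < 1e-8

    def test_per_time_sigma_matches_uniform(self):
        scheme = build_branched_scheme(0.4)
        t = np.geomspace(1e-12, 1e-6, 100)
        uniform = solve_populations(scheme, t, InstrumentResponse(0.0, 0.5e-9)).populations
        per_time = solve_populations(
            scheme, t, InstrumentResponse(0.0, 123.0), np.full(t.size, 0.5e-9)
        ).populations
        assert np.abs(uniform - per_time).max() == 0.0

    def test_non_monotone_times_rejected(self):
        with pytest.raises(InvalidParameterError):
            solve_populations(build_sequential_scheme([1.0]), np.array([0.0, 2.0, 1.0]))


class TestSchemeValidation:
    def test_negative_offdiagonal_rejected(self):
        k = np.array([[-1.0, 0.5], [-0.1, -0.5]])
        with pytest.raises(InvalidParameterError):
            KineticScheme(("a", "b"), k, np.array([1.0, 0.0]))

    def test_inflow_exceeding_outflow_rejected(self):
        k = np.array([[-1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(InvalidParameterError):
            KineticScheme(("a", "b"), k, np.array([1.0, 0.0]))

    def test_yaml_roundtrip(self, tmp_path):
        s = build_branched_scheme(0.4)
        p = tmp_path / "scheme.yaml"
        s.to_yaml(p)
        s2 = KineticScheme.from_yaml(p)
        assert s2.compartment_names == s.compartment_names
        np.testing.assert_array_equal(s2.rate_matrix, s.rate_matrix)
        assert s2.branch_fractions == s.branch_fractions
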
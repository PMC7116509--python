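"""Equilibrium solvers and exchange rate matrices for all binding schemes."""

import numpy as np
import pytest
from scipy.optimize import bisect

from nmrlineshape.binding import (
    EquilibriumPopulations,
    ModelParameters,
    available_models,
    build_rate_matrix,
    closed_cycle_kd4,
    exchange_rate,
    free_ligand_concentration,
    get_model,
    solve_equilibrium,
    uM,
    mM,
)
from nmrlineshape.errors import InvalidArgumentError


def random_params(name: str, rng: np.random.Generator) -> ModelParameters:
    """Plausible random constants for each scheme."""
    def conc():
        return 10.0 ** rng.uniform(-7, -3)

    def rate():
        return 10.0 ** rng.uniform(0, 4)

    values = {
        "no_exchange": {},
        "two_state": {"K_d": conc(), "k_off": rate()},
        "two_state_flex_stoich": {"K_d": conc(), "k_off": rate(),
                                  "n": rng.uniform(0.5, 2.5)},
        "induced_fit": {"K_d": conc(), "k_off": rate(),
                        "k_open": rate(), "k_close": rate()},
        "conformational_selection": {"K_d": conc(), "k_off": rate(),
                                     "k_open": rate(), "k_close": rate()},
        "four_state": {"K_d_app": conc(), "k_off_A": rate(), "k_off_B": rate(),
                       "K_AB": 10.0 ** rng.uniform(-2, 2),
                       "K_AB2": 10.0 ** rng.uniform(-2, 2),
                       "k_ex": rate(), "k_ex2": rate()},
        "dimerization": {"K_d": conc(), "k_off": rate()},
        "two_binding_sites": {"K_d1": conc(), "K_d2": conc(), "K_d3": conc(),
                              "k_off1": rate(), "k_off2": rate(),
                              "k_off3": rate(), "k_off4": rate()},
    }[name]
    return ModelParameters(values)


class TestFreeLigand:
    def test_no_protein_all_free(self):
        assert free_ligand_concentration(0.0, 50 * uM, 2 * uM) == 50 * uM

    def test_stoichiometric_limit_consumes_ligand(self):
        L = free_ligand_concentration(100 * uM, 100 * uM, 1e-12 * uM)
        assert L == pytest.approx(0.0, abs=1e-9)

    def test_matches_bisection_root_of_mass_balance(self):
        P, Lt, Kd = 1000 * uM, 500 * uM, 2 * uM
        f = lambda L: Kd * (Lt - L) - L * (P - Lt + L)
        oracle = bisect(f, 0.0, Lt, xtol=1e-25)
        assert free_ligand_concentration(P, Lt, Kd) == pytest.approx(
            oracle, rel=1e-10
        )

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            free_ligand_concentration(-1.0, 1.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            free_ligand_concentration(1.0, 1.0, 0.0)


class TestExchangeRate:
    def test_no_ligand_gives_koff(self):
        assert exchange_rate(100.0, 2 * uM, 0.0) == 100.0

    def test_at_kd_doubles(self):
        assert exchange_rate(100.0, 2 * uM, 2 * uM) == pytest.approx(200.0)

    def test_arithmetic_oracle(self):
        assert exchange_rate(250.0, 10 * uM, 35 * uM) == pytest.approx(
            250.0 * (1 + 35.0 / 10.0)
        )

    def test_monotone_in_ligand(self):
        ks = [exchange_rate(100.0, 2 * uM, L * uM) for L in np.linspace(0, 50, 20)]
        assert np.all(np.diff(ks) > 0)

    def test_negative_ligand_rejected(self):
        with pytest.raises(InvalidArgumentError):
            exchange_rate(100.0, 2 * uM, -1.0)


class TestSolveEquilibrium:
    def test_two_state_matches_closed_form(self):
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        eq = solve_equilibrium("two_state", p, 1 * mM, 2 * mM)
        L = free_ligand_concentration(1 * mM, 2 * mM, 2 * uM)
        assert eq.free_ligand == pytest.approx(L, rel=1e-9)
        assert eq.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert eq.fractions[1] == pytest.approx(L / (L + 2 * uM), rel=1e-9)

    def test_numeric_route_agrees_with_closed_form_over_decades(self):
        model = get_model("two_state")
        for P in 10.0 ** np.arange(-7, -1):
            for Lt in 10.0 ** np.arange(-7, -1):
                for Kd in 10.0 ** np.arange(-8, -2):
                    p = ModelParameters({"K_d": Kd, "k_off": 100.0})
                    num = model.solve_numeric(p, P, Lt).free_ligand
                    ref = free_ligand_concentration(P, Lt, Kd)
                    assert num == pytest.approx(ref, rel=1e-9, abs=1e-18)

    @pytest.mark.parametrize("name", available_models())
    def test_no_ligand_populates_free_states(self, name):
        model = get_model(name)
        p = random_params(name, np.random.default_rng(1))
        eq = model.solve(p, 100 * uM, 0.0)
        free = [i for i, s in enumerate(model.states) if s in model.free_states]
        assert eq.fractions[free].sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimer_weak_limit_is_monomeric(self):
        p = ModelParameters({"K_d": 1e6, "k_off": 100.0})
        eq = solve_equilibrium("dimerization", p, 100 * uM, 0.0)
        assert eq.fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_dimer_mass_balance(self):
        model = get_model("dimerization")
        p = ModelParameters({"K_d": 50 * uM, "k_off": 80.0})
        M_tot = 300 * uM
        M = model.free_monomer(p, M_tot)
        D = M * M / p["K_d"]
        assert M + 2 * D == pytest.approx(M_tot, rel=1e-9)

    def test_bound_fraction_monotone_in_ligand(self):
        p = ModelParameters({"K_d": 20 * uM, "k_off": 100.0})
        fb = [
            solve_equilibrium("two_state", p, 100 * uM, L * uM).fractions[1]
            for L in np.linspace(0, 500, 40)
        ]
        assert np.all(np.diff(fb) >= 0)

    def test_flex_stoich_ligand_mass_balance_uses_n(self):
        model = get_model("two_state_flex_stoich")
        p = ModelParameters({"K_d": 10 * uM, "k_off": 100.0, "n": 1.7})
        P, Lt = 100 * uM, 150 * uM
        eq = model.solve(p, P, Lt)
        consumed = 1.7 * eq.fractions[1] * P
        assert eq.free_ligand + consumed == pytest.approx(Lt, rel=1e-9)

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidArgumentError):
            get_model("three_state_teleport")

    def test_missing_parameter_rejected(self):
        with pytest.raises(InvalidArgumentError):
            solve_equilibrium("induced_fit",
                              ModelParameters({"K_d": uM, "k_off": 10.0}),
                              uM, uM)


class TestRateMatrix:
    def test_two_state_dissociation_only(self):
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        K = build_rate_matrix("two_state", p, 0.0)
        assert np.allclose(K, [[0.0, 100.0], [0.0, -100.0]])

    def test_two_state_eigenvalues_give_kex(self):
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        K = build_rate_matrix("two_state", p, 2 * uM)
        ev = np.sort(np.abs(np.linalg.eigvals(K)))
        assert ev == pytest.approx([0.0, exchange_rate(100.0, 2 * uM, 2 * uM)])

    def test_four_state_kab_split(self):
        p = random_params("four_state", np.random.default_rng(7))
        K = build_rate_matrix("four_state", p, 0.0)
        K_AB, k_ex = p["K_AB"], p["k_ex"]
        k_AB = k_ex * K_AB / (1 + K_AB)
        k_BA = k_ex / (1 + K_AB)
        assert K[1, 0] == pytest.approx(k_AB)
        assert K[0, 1] == pytest.approx(k_BA)
        assert k_AB + k_BA == pytest.approx(k_ex)

    @pytest.mark.parametrize("name", available_models())
    def test_stationarity_and_column_sums(self, name):
        """K columns sum to zero and annihilate the equilibrium fractions."""
        rng = np.random.default_rng(42)
        model = get_model(name)
        for _ in range(25):
            p = random_params(name, rng)
            P = 10.0 ** rng.uniform(-6, -3)
            Lt = 10.0 ** rng.uniform(-6, -2)
            eq = model.solve(p, P, Lt)
            K = model.rate_matrix(p, eq.free_ligand)
            assert np.allclose(K.sum(axis=0), 0.0, atol=1e-9 * np.abs(K).max())
            resid = K @ eq.fractions
            assert np.max(np.abs(resid)) <= 1e-9 * max(np.abs(K).max(), 1.0)
            assert np.all(K - np.diag(np.diag(K)) >= 0)

    def test_missing_rate_parameter_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_rate_matrix("two_state", ModelParameters({"K_d": uM}), 0.0)


class TestThermodynamicCycle:
    def test_equal_constants_cancel(self):
        assert closed_cycle_kd4(5 * uM, 5 * uM, 7 * uM) == pytest.approx(7 * uM)

    def test_arithmetic(self):
        assert closed_cycle_kd4(10 * uM, 5 * uM, 20 * uM) == pytest.approx(40 * uM)

    def test_cycle_product_is_unity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k1, k2, k3 = 10.0 ** rng.uniform(-7, -3, size=3)
            k4 = closed_cycle_kd4(k1, k2, k3)
            assert k1 * k3 / (k2 * k4) == pytest.approx(1.0, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(InvalidArgumentError):
            closed_cycle_kd4(0.0, 1.0, 1.0)


class TestTwoBindingSites:
    def test_pairing_switch_changes_rates_not_equilibrium(self):
        p = random_params("two_binding_sites", np.random.default_rng(5))
        eqs, Ks = [], []
        for pairing in ("kon2", "kon3"):
            model = get_model("two_binding_sites", kd2_pairing=pairing)
            eq = model.solve(p, 100 * uM, 150 * uM)
            eqs.append(eq.fractions)
            Ks.append(model.rate_matrix(p, eq.free_ligand))
        assert np.allclose(eqs[0], eqs[1], rtol=1e-12)
        assert not np.allclose(Ks[0], Ks[1])
        for K, eq in zip(Ks, eqs):
            assert np.max(np.abs(K @ eq)) <= 1e-9 * np.abs(K).max()

    def test_populations_sum_and_mass_balance(self):
        model = get_model("two_binding_sites")
        p = random_params("two_binding_sites", np.random.default_rng(11))
        P, Lt = 200 * uM, 350 * uM
        eq = model.solve(p, P, Lt)
        bound = P * (eq.fractions[1] + eq.fractions[2] + 2 * eq.fractions[3])
        assert eq.free_ligand + bound == pytest.approx(Lt, rel=1e-9)
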
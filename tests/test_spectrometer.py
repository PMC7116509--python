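"""Virtual-spectrometer generators, transfers and full-sequence properties."""

import numpy as np
import pytest

from nmrlineshape.binding import ModelParameters, get_model, uM, mM
from nmrlineshape.errors import (
    ConfigurationError,
    InvalidArgumentError,
    UnsupportedExperimentError,
)
from nmrlineshape.processing import ProcessingParams, process_interferogram
from nmrlineshape.spectrometer import (
    GAMMA_RATIO_N_H,
    PulseSequenceConfig,
    delta_omega,
    direct_evolution_generator,
    indirect_evolution_generators,
    simulate_group,
    simulate_interferogram,
    transfer_propagator,
)
from nmrlineshape.spins import ROI, SpinGroup, SpinSystem, StateResonance


def cfg(**kw):
    base = dict(experiment="HSQC", f_spec_H=700.0, offset_H=8.2,
                offset_S=119.0, sw_H=2000.0, sw_S=600.0, n_H=64, n_S=32,
                J_HNHA=0.0)
    base.update(kw)
    return PulseSequenceConfig(**base)


def two_state_group(dH=1.0, dN=0.5, r2=20.0):
    spin = SpinSystem("A1", {
        "P": StateResonance(8.2, 119.0, r2, r2),
        "PL": StateResonance(8.2 + dH, 119.0 + dN, r2, r2),
    })
    return SpinGroup("g", [spin])


class TestFrequencies:
    def test_rad_per_s_anchors_at_700_mhz(self):
        # 1 ppm 1H and 0.5 ppm 15N at 700 MHz, two significant figures
        dw_h = delta_omega(1.0, 700.0)
        dw_n = delta_omega(0.5, 700.0 * GAMMA_RATIO_N_H)
        assert round(dw_h, -2) == 4400.0
        assert round(dw_n, -1) == 220.0

    def test_inconsistent_nitrogen_frequency_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cfg(f_spec_S=80.0)

    def test_trosy_not_supported(self):
        with pytest.raises(UnsupportedExperimentError):
            cfg(experiment="TROSY")

    def test_default_inept_delay(self):
        assert cfg().inept_delay == pytest.approx(1.0 / (4 * 92.0))


class TestGenerators:
    def test_single_state_direct_eigenvalue_exact(self):
        group = SpinGroup("g", [SpinSystem(
            "a", {"A": StateResonance(8.5, 119.0, 17.0, 12.0)})])
        c = cfg()
        (Lp, Lm) = direct_evolution_generator(group, np.zeros((1, 1)), c, ["A"])
        omega = 2 * np.pi * (8.5 - c.offset_H) * c.f_spec_H
        assert Lp[0, 0] == pytest.approx(1j * omega - 17.0)
        assert Lm[0, 0] == pytest.approx(1j * omega - 17.0)

    def test_fast_limit_population_weighted_shift(self):
        model = get_model("two_state")
        p = ModelParameters({"K_d": 2 * uM, "k_off": 1e6})
        eq = model.solve(p, 1 * mM, 0.5 * mM)
        K = model.rate_matrix(p, eq.free_ligand)
        group = two_state_group()
        c = cfg(sw_H=3000.0)
        (Lp, _) = direct_evolution_generator(group, K, c, model.states)
        ev = np.linalg.eigvals(Lp)
        dominant = ev[np.argmax(ev.real)]
        omegas = np.array([
            2 * np.pi * (8.2 - c.offset_H) * c.f_spec_H,
            2 * np.pi * (9.2 - c.offset_H) * c.f_spec_H,
        ])
        expected = float(eq.fractions @ omegas)
        assert dominant.imag == pytest.approx(expected, rel=1e-3)

    def test_slow_limit_two_lines_at_state_shifts(self):
        model = get_model("two_state")
        p = ModelParameters({"K_d": 2 * uM, "k_off": 1e-3})
        eq = model.solve(p, 1 * mM, 0.5 * mM)
        K = model.rate_matrix(p, eq.free_ligand)
        group = two_state_group()
        c = cfg(sw_H=3000.0)
        (Lp, _) = direct_evolution_generator(group, K, c, model.states)
        ev = np.sort(np.linalg.eigvals(Lp).imag)
        omegas = np.sort([
            2 * np.pi * (8.2 - c.offset_H) * c.f_spec_H,
            2 * np.pi * (9.2 - c.offset_H) * c.f_spec_H,
        ])
        assert np.allclose(ev, omegas, rtol=1e-3)

    def test_hmqc_generators_are_zq_and_dq(self):
        model = get_model("two_state")
        p = ModelParameters({"K_d": 2 * uM, "k_off": 500.0})
        K = model.rate_matrix(p, 1 * uM)
        group = two_state_group()
        c = cfg(experiment="HMQC")
        zq, dq = indirect_evolution_generators(group, K, c, model.states)
        sq = indirect_evolution_generators(
            group, K, cfg(experiment="HSQC"), model.states)[0]
        omega_H = np.diag((dq - zq).imag) / 2.0
        expected_H = 2 * np.pi * (np.array([8.2, 9.2]) - c.offset_H) * c.f_spec_H
        assert np.allclose(omega_H, expected_H)
        assert np.allclose((zq + dq) / 2.0, sq)

    def test_causality_eigenvalues_decay(self):
        rng = np.random.default_rng(0)
        model = get_model("two_state")
        for _ in range(20):
            p = ModelParameters({
                "K_d": 10.0 ** rng.uniform(-7, -4),
                "k_off": 10.0 ** rng.uniform(0, 5),
            })
            K = model.rate_matrix(p, 10.0 ** rng.uniform(-7, -4))
            group = two_state_group(r2=rng.uniform(1, 60))
            for L in (direct_evolution_generator(group, K, cfg(), model.states)
                      + indirect_evolution_generators(group, K, cfg(),
                                                      model.states)):
                assert np.linalg.eigvals(L).real.max() <= 1e-9


class TestTransfers:
    def test_zero_delays_identity(self):
        K = np.array([[-5.0, 3.0], [5.0, -3.0]])
        P = transfer_propagator(K, [(0.0, "zz"), (0.0, "inept")],
                                r2i=np.ones(2), J_IS=92.0)
        assert np.allclose(P, np.eye(2))

    def test_ideal_inept_amplitude_without_exchange(self):
        J = 92.0
        P = transfer_propagator(np.zeros((1, 1)), [(1.0 / (2 * J), "inept")],
                                r2i=np.zeros(1), J_IS=J)
        assert P[0, 0] == pytest.approx(1.0)

    def test_zz_filter_matches_series_expansion_oracle(self):
        model = get_model("two_state")
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        K = model.rate_matrix(p, 2 * uM)  # k_ex = 200 /s
        tau = 5e-3
        P = transfer_propagator(K, [(tau, "zz")])
        # scaling-and-squaring series oracle: (sum_k (K tau/2^s)^k / k!)^(2^s)
        s, terms = 20, 25
        A = K * tau / 2 ** s
        E = np.zeros_like(A)
        T = np.eye(2)
        for k in range(terms):
            E += T
            T = T @ A / (k + 1)
        for _ in range(s):
            E = E @ E
        assert np.allclose(P, E, atol=1e-10)

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            transfer_propagator(np.zeros((1, 1)), [(-1.0, "zz")])


class TestFullSequence:
    def test_zero_protein_gives_zero_signal(self):
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        group = two_state_group()
        ifg = simulate_interferogram(group, "two_state", p, 0.0, 0.0, cfg())
        assert np.all(ifg.cos == 0) and np.all(ifg.sin == 0)

    def test_amplitude_linear_in_scans(self):
        p = ModelParameters({"K_d": 2 * uM, "k_off": 100.0})
        group = two_state_group()
        a = simulate_interferogram(group, "two_state", p, 100 * uM, 50 * uM,
                                   cfg(), ns=1)
        b = simulate_interferogram(group, "two_state", p, 100 * uM, 50 * uM,
                                   cfg(), ns=2)
        assert np.allclose(b.cos, 2 * a.cos) and np.allclose(b.sin, 2 * a.sin)

    def test_peak_integral_scales_with_ptot_ns_rg(self):
        rng = np.random.default_rng(4)
        group = SpinGroup("g", [SpinSystem(
            "a", {"A": StateResonance(8.2, 119.0, 20.0, 20.0)})])
        c = cfg()
        vals = []
        for _ in range(5):
            P_tot = rng.uniform(1e-5, 1e-3)
            ns = rng.integers(1, 64)
            rg = rng.uniform(0.5, 200.0)
            ifg = simulate_group(group, np.zeros((1, 1)), np.array([1.0]),
                                 P_tot * ns * rg, c, ["A"])
            spec = process_interferogram(ifg, ProcessingParams(), c)
            vals.append(spec.data.sum() / (P_tot * ns * rg))
        assert np.ptp(vals) <= 1e-9 * abs(np.mean(vals))

    def test_single_state_hsqc_equals_hmqc(self):
        group = SpinGroup("g", [SpinSystem(
            "a", {"A": StateResonance(8.35, 119.4, 22.0, 18.0)})])
        specs = {}
        for exp in ("HSQC", "HMQC"):
            c = cfg(experiment=exp)
            ifg = simulate_group(group, np.zeros((1, 1)), np.array([1.0]),
                                 1.0, c, ["A"])
            specs[exp] = process_interferogram(ifg, ProcessingParams(), c).data
        assert np.allclose(specs["HSQC"], specs["HMQC"], atol=1e-12)

    def test_indirect_aliasing_wraps_by_sweep_width(self):
        c = cfg()
        sw_ppm = c.sw_S / c.f_spec_S
        inside = SpinGroup("g", [SpinSystem(
            "a", {"A": StateResonance(8.2, 119.5, 20.0, 20.0)})])
        folded = SpinGroup("g", [SpinSystem(
            "a", {"A": StateResonance(8.2, 119.5 + sw_ppm, 20.0, 20.0)})])
        s1 = simulate_group(inside, np.zeros((1, 1)), np.array([1.0]), 1.0,
                            c, ["A"])
        s2 = simulate_group(folded, np.zeros((1, 1)), np.array([1.0]), 1.0,
                            c, ["A"])
        assert np.allclose(s1.cos, s2.cos, atol=1e-9)

    def test_mismatched_state_count_rejected(self):
        group = two_state_group()
        with pytest.raises(ConfigurationError):
            simulate_group(group, np.zeros((3, 3)),
                           np.array([0.5, 0.3, 0.2]), 1.0, cfg(),
                           ["P", "PL"])


class TestMcConnellOracle:
    def test_direct_dimension_matches_closed_form_two_site_lineshape(self):
        """The t2 cross-section through an exchange-free-t1 HSQC equals the
        discrete two-site Bloch-McConnell lineshape built from the 2x2
        quadratic-formula eigensystem and explicit geometric sums."""
        model = get_model("two_state")
        p = ModelParameters({"K_d": 2 * uM, "k_off": 800.0})
        eq = model.solve(p, 1 * mM, 0.5 * mM)
        K = model.rate_matrix(p, eq.free_ligand)
        # identical 15N shifts/linewidths: t1 and transfers scale all states
        # by a common 2x2 mixing that the oracle reproduces
        spin = SpinSystem("a", {
            "P": StateResonance(8.0, 119.0, 20.0, 20.0),
            "PL": StateResonance(8.9, 119.0, 20.0, 20.0),
        })
        group = SpinGroup("g", [spin])
        c = cfg(sw_H=2500.0, n_H=512, n_S=8, sw_S=600.0)
        proc = ProcessingParams(lb_H=4.0, lb_S=0.0, zf_H=1024, zf_S=8)
        ifg = simulate_group(group, K, eq.fractions, 1.0, c, model.states)
        spec = process_interferogram(ifg, proc, c)
        iy = np.argmax(spec.data.max(axis=1))
        row = spec.data[iy]

        # --- independent discrete oracle -------------------------------
        omega = 2 * np.pi * (np.array([8.0, 8.9]) - c.offset_H) * c.f_spec_H
        L2 = np.diag(1j * omega - 20.0) + K
        # closed-form eigensystem of the 2x2 generator
        a, b_, c_, d = L2[0, 0], L2[0, 1], L2[1, 0], L2[1, 1]
        tr, det = a + d, a * d - b_ * c_
        root = np.sqrt(tr * tr / 4 - det)
        lam = np.array([tr / 2 + root, tr / 2 - root])
        v0 = eq.fractions.astype(complex)
        # amplitudes: 1^T e^{L2 t} v0 = sum_k w_k e^{lam_k t}
        V = np.array([[b_, b_], [lam[0] - a, lam[1] - a]])
        coef = np.linalg.solve(V, v0)
        w = V.sum(axis=0) * coef
        t2 = np.arange(c.n_H) / c.sw_H
        fid = (w[:, None] * np.exp(np.outer(lam, t2))).sum(axis=0)
        fid = fid * np.exp(-np.pi * proc.lb_H * t2)
        fid[0] *= 0.5
        fid = np.concatenate([fid, np.zeros(1024 - c.n_H)])
        F = np.fft.fft(fid)
        N = 1024
        oracle = F[(N // 2 - np.arange(N)) % N].real

        scale = row[np.argmax(np.abs(row))] / oracle[np.argmax(np.abs(oracle))]
        assert np.max(np.abs(row - scale * oracle)) <= 1e-6 * np.max(np.abs(row))
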
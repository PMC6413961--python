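"""Cortical networks: transfer function, synapses, connectivity, dynamics."""

import numpy as np
import pytest

from corticalpitch.cortex import (CorticalParams, NetworkState,
                                  build_connectivity, compute_inputs,
                                  effective_tau, simulate, synaptic_step,
                                  transfer, transfer_derivative)
from corticalpitch.periodicity import LagGrid, SACFOutput, SACFParams, regularize

P = CorticalParams()
GRID = LagGrid()


def _regularized_zero(n_steps=600):
    A = np.zeros((GRID.n, n_steps))
    out = SACFOutput(A, 1e-3, GRID, Ahat=A.copy(), mode="single")
    return out


def _inject_harmonics(harmonic_counts, *, period=6e-3, amp=55.0, n_steps=500,
                      t_on=50, t_off=None):
    """Noiseless runs driven by Gaussian current bumps (the width of a real
    periodicity-detector peak) at the first n harmonics of ``period``."""
    lags = GRID.lags
    results = []
    for n_harm in harmonic_counts:
        prof = np.zeros(GRID.n)
        for h in range(1, n_harm + 1):
            prof += amp * np.exp(-0.5 * ((lags - h * period) / GRID.step) ** 2)
        A = np.zeros((GRID.n, n_steps))
        A[:, t_on:t_off] = prof[:, None]
        drive = SACFOutput(A, 1e-3, GRID, Ahat=A.copy(), mode="single")
        results.append(simulate(drive, P, seed=None))
    return results


class TestTransferFunction:
    def test_removable_singularity_limit(self):
        """phi -> 1/d as aI - b -> 0 (6.25 Hz for excitatory ensembles)."""
        i_star = P.b_e / P.a_e
        assert transfer(i_star, "exc", P) == pytest.approx(1.0 / P.d_e)
        eps = 1e-9 / P.a_e
        for i in (i_star - eps, i_star + eps):
            assert transfer(i, "exc", P) == pytest.approx(6.25, rel=1e-6)

    def test_silent_at_zero_current(self):
        assert transfer(0.0, "exc", P) == pytest.approx(2.6e-7, rel=0.1)

    def test_linear_regime_at_high_current(self):
        """At 1 nA the exponential term is negligible: phi ~ aI - b = 185 Hz."""
        assert transfer(1.0, "exc", P) == pytest.approx(185.0, rel=1e-6)

    def test_derivative_matches_finite_differences(self):
        """Analytic phi' agrees with central differences to 1e-6 relative over
        the physiological current range, for both populations."""
        I = np.linspace(0.0, 2.0, 401)
        h = 1e-7
        for which in ("exc", "inh"):
            analytic = transfer_derivative(I, which, P)
            numeric = (transfer(I + h, which, P) - transfer(I - h, which, P)) / (2 * h)
            np.testing.assert_allclose(analytic, numeric, rtol=1e-6)

    def test_derivative_limits(self):
        # at the singular point phi' -> a/2
        assert transfer_derivative(P.b_e / P.a_e, "exc", P) == pytest.approx(
            P.a_e / 2, rel=1e-6)
        # far in the linear regime phi' -> a
        assert transfer_derivative(2.0, "exc", P) == pytest.approx(P.a_e, rel=1e-9)

    def test_derivative_everywhere_positive(self):
        I = np.linspace(-1.0, 3.0, 1000)
        assert np.all(transfer_derivative(I, "exc", P) > 0)
        assert np.all(transfer_derivative(I, "inh", P) > 0)


class TestEffectiveTau:
    def test_steady_state_substitution(self):
        I = 0.6
        H = float(transfer(I, "exc", P))
        expected = P.tau_pop0 * P.delta_T * float(transfer_derivative(I, "exc", P)) / H
        assert effective_tau(H, I, "exc", P) == pytest.approx(
            np.clip(expected, P.tau_pop_min, P.tau_pop_max))

    def test_inverse_proportionality_before_clamp(self):
        I = 2.0  # large current so tau falls inside the clamp window
        t1 = effective_tau(400.0, I, "exc", P)
        t2 = effective_tau(800.0, I, "exc", P)
        assert t2 == pytest.approx(t1 / 2, rel=1e-9)

    def test_zero_rate_maps_to_clamp_maximum(self):
        assert effective_tau(0.0, 0.5, "exc", P) == P.tau_pop_max
        assert effective_tau(np.zeros(3), 0.5, "inh", P)[0] == P.tau_pop_max

    def test_clamped_range_in_simulation(self, irn_run):
        """tau_pop stays within [tau_min, tau_max] along a standard run."""
        res = irn_run(8.0, 11)
        # reconstruct tau for decoder excitatory rates at a mid-run time
        H = res.H_e[900].astype(float)
        tau = effective_tau(np.maximum(H, 1e-9), 0.5, "exc", res.params)
        assert tau.min() >= res.params.tau_pop_min - 1e-12
        assert tau.max() <= res.params.tau_pop_max + 1e-12


class TestSynapticSteps:
    def _step_to_steady(self, H, n_steps=20000, dt=1e-4):
        state = NetworkState.zeros(4)
        for _ in range(n_steps):
            state.H_e[:] = H
            state.H_i[:] = H
            synaptic_step(state, P, dt, np.zeros(4), rng=None)
        return state

    def test_ampa_and_gaba_fixed_points(self):
        H = 40.0
        state = self._step_to_steady(H)
        np.testing.assert_allclose(state.S_ampa_e, P.tau_ampa * H, rtol=1e-3)
        np.testing.assert_allclose(state.S_gaba_i, P.tau_gaba * H, rtol=1e-3)

    def test_nmda_fixed_point_saturates(self):
        H = 40.0
        state = self._step_to_steady(H)
        g = P.gamma * P.tau_nmda * H
        np.testing.assert_allclose(state.S_nmda_e, g / (1 + g), rtol=1e-3)
        assert np.all(state.S_nmda_e < 1.0)

    def test_exponential_decay_half_life(self):
        state = NetworkState.zeros(2)
        state.S_ampa_e[:] = 1.0
        dt = 1e-5
        n_half = int(round(P.tau_ampa * np.log(2) / dt))
        for _ in range(n_half):
            synaptic_step(state, P, dt, np.zeros(2), rng=None)
        np.testing.assert_allclose(state.S_ampa_e, 0.5, rtol=5e-3)

    def test_noise_is_reproducible_and_bounded(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        s1, s2 = NetworkState.zeros(8), NetworkState.zeros(8)
        for _ in range(100):
            synaptic_step(s1, P, 1e-3, np.zeros(8), rng1)
            synaptic_step(s2, P, 1e-3, np.zeros(8), rng2)
        np.testing.assert_array_equal(s1.S_nmda_e, s2.S_nmda_e)
        assert s1.S_ampa_e.min() >= 0.0
        assert s1.S_nmda_e.max() <= 1.0


@pytest.fixture(scope="module")
def mats():
    return build_connectivity(GRID, P)


class TestConnectivity:

    def test_cee_is_identity(self, mats):
        np.testing.assert_array_equal(mats.C_ee, np.eye(GRID.n))

    def test_cii_structure(self, mats):
        expected = (1 - P.c0_ie) * np.eye(GRID.n) + P.c0_ie
        np.testing.assert_allclose(mats.C_ii, expected)
        assert mats.C_ii[0, 0] == pytest.approx(1.0)
        assert mats.C_ii[0, 1] == pytest.approx(0.1)

    def test_cei_support_at_first_three_harmonics(self, mats):
        """The inhibitory ensemble nearest 5 ms listens at 5, 10 and 15 ms."""
        j = GRID.nearest(5e-3)
        row = mats.C_ei[j]
        support = np.nonzero(row > 0.02 * row.max())[0]
        centers_ms = GRID.lags[support] * 1e3
        for h in (5.0, 10.0, 15.0):
            assert np.any(np.abs(centers_ms - h) < 0.4)
        # nothing outside the three smeared harmonics
        assert all(min(abs(c - h) for h in (5.0, 10.0, 15.0)) < 0.8
                   for c in centers_ms)

    def test_cie_targets_lower_harmonics_only(self, mats):
        """Inhibition from the 5 ms column lands at {10, 15, 20, 25, 30} ms and
        spares the fundamental."""
        k = GRID.nearest(5e-3)
        col = mats.C_ie[:, k]
        support = GRID.lags[np.nonzero(col > 0.02)[0]] * 1e3
        assert np.all(support > 8.0)
        for h in (10.0, 15.0, 20.0, 25.0):
            assert np.any(np.abs(support - h) < 0.5)

    def test_all_weights_nonnegative(self, mats):
        for M in (mats.C_ee, mats.C_ei, mats.C_ie, mats.C_ii):
            assert M.min() >= 0.0

    def test_singleton_rows_deweighted(self, mats):
        """Columns whose 2nd harmonic falls off-grid cannot sum to a full
        trio's drive (structural 15 ms decoding limit)."""
        j_single = GRID.nearest(20e-3)
        j_full = GRID.nearest(5e-3)
        assert mats.C_ei[j_single].sum() < 0.3 * mats.C_ei[j_full].sum()


class TestComputeInputs:
    def test_zero_gating_gives_baselines(self):
        mats = build_connectivity(GRID, P)
        state = NetworkState.zeros(GRID.n)
        I_e, I_i, Ih_e, Ih_i = compute_inputs(state, mats, P)
        np.testing.assert_allclose(I_e, P.I0_e)
        np.testing.assert_allclose(I_i, P.I0_i)
        np.testing.assert_allclose(Ih_e, P.Ihat0_e + P.I0_sus)
        np.testing.assert_allclose(Ih_i, P.Ihat0_i + P.I0_sus)

    def test_inhibitory_input_sparsity(self):
        """With one active decoder excitatory column, inhibitory ensembles are
        driven iff their C^ei row covers that column."""
        mats = build_connectivity(GRID, P)
        state = NetworkState.zeros(GRID.n)
        k = GRID.nearest(5e-3)
        state.S_nmda_e[k] = 0.5
        _, I_i, _, _ = compute_inputs(state, mats, P)
        driven = np.nonzero(I_i > P.I0_i + 1e-9)[0]
        expected = np.nonzero(mats.C_ei[:, k] * P.J_ei_nmda * 0.5 > 1e-9)[0]
        np.testing.assert_array_equal(driven, expected)


class TestSimulation:
    def test_stationary_baseline_without_input(self):
        """sigma=0, zero subcortical drive: decoder excitatory silent, sustainer
        inhibitory at a positive steady rate, for a full second."""
        res = simulate(_regularized_zero(1000), P, seed=None)
        assert res.H_e[-500:].max() < 1.0
        tail = res.Hh_i[-500:]
        assert tail.min() > 50.0
        assert np.ptp(tail) < 1.0  # settled

    def test_noiseless_run_is_deterministic(self):
        r1 = simulate(_regularized_zero(300), P, seed=7)
        r2 = simulate(_regularized_zero(300), P, seed=7)
        np.testing.assert_array_equal(r1.Hh_i, r2.Hh_i)

    def test_rates_bounded_by_transfer_at_max_current(self, irn_run):
        res = irn_run(8.0, 11)
        # generous bound: no rate exceeds phi at a 3 nA current
        bound = float(transfer(3.0, "exc", P))
        assert res.H_e.max() < bound
        assert res.Hh_e.max() < bound

    def test_euler_step_agrees_with_fine_step_oracle(self):
        """1 ms Euler rate trajectories match a 0.1 ms integration within 5%
        RMS on a 500 ms noiseless run with constant subcortical drive."""
        n_steps = 500
        A = np.zeros((GRID.n, n_steps))
        j = GRID.nearest(6e-3)
        for h in (1, 2, 3):
            A[GRID.nearest(h * 6e-3)] = 60.0
        coarse_in = SACFOutput(A, 1e-3, GRID, Ahat=A.copy(), mode="single")
        res_coarse = simulate(coarse_in, P, seed=None)

        fine = 10
        A_fine = np.repeat(A, fine, axis=1)
        params_fine = P.with_updates(dt=1e-4)
        fine_in = SACFOutput(A_fine, 1e-4, GRID, Ahat=A_fine.copy(), mode="single")
        res_fine = simulate(fine_in, params_fine, seed=None)

        coarse = res_coarse.H_e[:, j].astype(float)
        fine_ds = res_fine.H_e[::fine, j].astype(float)
        rms_err = np.sqrt(np.mean((coarse - fine_ds) ** 2))
        rms_ref = np.sqrt(np.mean(fine_ds**2))
        assert rms_err <= 0.05 * rms_ref

    def test_winner_take_all_contiguity(self, irn_run):
        """At 250-300 ms post onset exactly one contiguous (+/-2 columns)
        decoder-inhibitory group exceeds half the maximum."""
        res = irn_run(8.0, 11)
        on = int(res.pitch_onset / res.dt)
        prof = res.H_i[on + 250:on + 300].mean(axis=0)
        above = np.nonzero(prof > 0.5 * prof.max())[0]
        assert above.size >= 1
        assert above.max() - above.min() <= 4

    def test_three_harmonic_activation_rule(self):
        """Under controlled current injection at the amplitude of a typical
        periodicity-detector peak, an inhibitory decoder ensemble ignites only
        when all three of its harmonic inputs are driven simultaneously."""
        res_rates = [float(r.H_i[:, GRID.nearest(6e-3)].max())
                     for r in _inject_harmonics((1, 2, 3))]
        one, two, three = res_rates
        assert one < 10.0            # one harmonic: silent
        assert two < 25.0            # two harmonics: sub-threshold hum
        assert three > 60.0          # three harmonics: full ignition
        assert three > 4 * two

    def test_sustainer_outlasts_decoder_after_offset(self):
        """After input offset the winning sustainer ensemble decays more slowly
        than its decoder counterpart (relaxation asymmetry)."""
        j = GRID.nearest(6e-3)
        res, = _inject_harmonics((3,), n_steps=900, t_off=450)

        def time_to_half(traj, start):
            ref = traj[start]
            if ref <= 1.0:
                return 0.0
            below = np.nonzero(traj[start:] < 0.5 * ref)[0]
            return float(below[0]) if below.size else float(traj.size - start)

        t_dec = time_to_half(res.H_e[:, j].astype(float), 449)
        t_sus = time_to_half(res.Hh_e[:, j].astype(float), 449)
        assert res.Hh_e[449, j] > 40.0  # the sustainer did latch
        assert t_sus > t_dec

    def test_mismatched_time_step_rejected(self):
        out = _regularized_zero(100)
        out.dt = 2e-3
        with pytest.raises(ValueError, match="step"):
            simulate(out, P, seed=None)

    def test_unregularized_input_rejected(self):
        A = np.zeros((GRID.n, 100))
        with pytest.raises(ValueError, match="regularized"):
            simulate(SACFOutput(A, 1e-3, GRID), P, seed=None)


def test_params_roundtrip_and_unknown_key():
    p2 = P.with_updates(tau_nmda=0.025)
    assert p2.tau_nmda == 0.025 and P.tau_nmda == 0.030
    with pytest.raises(KeyError, match="tau_nmda_x"):
        P.with_updates(tau_nmda_x=1.0)


def test_table_defaults_echo_back():
    """The parameter set reloads bit-identically through its dict round trip."""
    d = P.as_dict()
    assert d["gamma"] == 0.641
    assert d["a_e"] == 310.0 and d["b_e"] == 125.0 and d["d_e"] == 0.16
    assert d["sigma"] == 0.0007
    p2 = CorticalParams(**d)
    assert p2 == P
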
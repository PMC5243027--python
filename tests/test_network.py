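"""Biophysical primitives, wiring, and integrator contracts."""

import numpy as np
import pytest
import scipy.optimize

from attractorchoice.network import (
    G_EXT,
    G_BG,
    G_GABA,
    H_NMDA_DECAY,
    NumericalInstabilityError,
    biexp_conductance,
    build_network,
    exp_conductance,
    membrane_derivative,
    nmda_gating,
    steady_state_polarization,
    synaptic_current,
    total_current,
)
from attractorchoice.params import (
    INTERNEURON,
    PYRAMIDAL,
    Architecture,
    NetworkConfig,
    NeuronParams,
    StimulationCurrents,
    SynapseKind,
    default_synapses,
)


class TestConductancePrimitives:
    @pytest.mark.parametrize(
        "G, tau, t, expected",
        [
            (1.6, 2.0, 0.0, 1.6),  # spike arrival sets g to its maximum
            (1.6, 2.0, 2.0, 1.6 / np.e),
            (1.6, 2.0, 1e4, 0.0),
        ],
    )
    def test_exponential_decay(self, G, tau, t, expected):
        assert exp_conductance(G, tau, t) == pytest.approx(expected, abs=1e-12)

    def test_exponential_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            exp_conductance(1.0, 0.0, 1.0)

    def test_biexponential_shape(self):
        # zero at onset, non-negative, decays to zero
        assert biexp_conductance(1.0, 2.0, 100.0, 0.0) == pytest.approx(0.0)
        t = np.linspace(0.0, 1000.0, 2001)
        wave = biexp_conductance(1.0, 2.0, 100.0, t)
        assert (wave >= -1e-15).all()
        assert wave[-1] == pytest.approx(0.0, abs=1e-4)

    def test_biexponential_peak_location(self):
        # oracle: numerical maximization of the waveform
        res = scipy.optimize.minimize_scalar(
            lambda t: -biexp_conductance(1.0, 2.0, 100.0, t), bounds=(0.0, 50.0),
            method="bounded",
        )
        analytic = 2.0 * 100.0 / 98.0 * np.log(50.0)
        assert res.x == pytest.approx(analytic, rel=1e-4)
        assert analytic == pytest.approx(7.99, abs=0.01)

    def test_biexponential_rejects_bad_taus(self):
        with pytest.raises(ValueError):
            biexp_conductance(1.0, 100.0, 2.0, 1.0)

    @pytest.mark.parametrize(
        "g, V, E, expected",
        [
            (1.0, -55.0, -55.0, 0.0),  # reversal point
            (1.0, -70.0, 0.0, -70.0),  # inward (negative) excitatory current
            (1.0, -70.0, -70.0, 0.0),  # GABA_A at rest
        ],
    )
    def test_ohmic_current(self, g, V, E, expected):
        assert synaptic_current(g, V, E) == pytest.approx(expected)

    def test_nmda_gating_values(self):
        assert nmda_gating(0.0, 1.0) == pytest.approx(3.57 / 4.57, rel=1e-6)
        assert nmda_gating(200.0, 1.0) == pytest.approx(1.0, abs=1e-5)
        v = np.linspace(-90.0, 0.0, 50)
        assert np.allclose(nmda_gating(v, 0.0), 1.0)  # no magnesium block

    def test_nmda_gating_monotone_and_bounded(self):
        v = np.linspace(-100.0, 50.0, 500)
        gate = nmda_gating(v, 1.0)
        assert (np.diff(gate) > 0).all()
        assert ((gate > 0) & (gate <= 1)).all()

    @pytest.mark.parametrize(
        "terms, expected",
        [((0.0, 0.0, 0.0, 0.0), 0.0), ((-10.0, -5.0, 20.0, 0.0), 5.0)],
    )
    def test_total_current_sum(self, terms, expected):
        assert total_current(*terms) == pytest.approx(expected)

    def test_total_current_reduces_without_stimulation(self, rng):
        a, b, c = rng.normal(size=3)
        assert total_current(a, b, c, 0.0) == a + b + c


class TestMembrane:
    def test_derivative_at_rest_is_exponential_term_only(self):
        dv = membrane_derivative(-70.0, 0.0, PYRAMIDAL)
        expected = 25.0 * 3.0 * np.exp(-5.0) / 500.0  # g_L*Delta_T*e^((E_L-V_T)/dT)/C
        assert dv == pytest.approx(expected, rel=1e-9)
        assert dv == pytest.approx(0.00101, abs=2e-5)

    def test_stable_fixed_point_slightly_above_rest(self):
        # oracle: root finding on the zero-input derivative
        v_star = scipy.optimize.brentq(
            lambda v: membrane_derivative(v, 0.0, PYRAMIDAL), -70.5, -60.0
        )
        assert -70.0 < v_star < -69.5
        # stability: derivative decreasing through the root
        eps = 1e-3
        assert membrane_derivative(v_star - eps, 0.0, PYRAMIDAL) > 0
        assert membrane_derivative(v_star + eps, 0.0, PYRAMIDAL) < 0

    def test_inward_current_depolarizes(self):
        v = -60.0
        assert membrane_derivative(v, -50.0, PYRAMIDAL) > membrane_derivative(
            v, 0.0, PYRAMIDAL
        )
        currents = np.linspace(-100, 100, 21)
        dvs = [membrane_derivative(v, i, PYRAMIDAL) for i in currents]
        assert (np.diff(dvs) < 0).all()  # linear, decreasing in I_total

    def test_integrator_convergence_under_dt_halving(self):
        # 1 s single-neuron trace with constant subthreshold input
        def integrate(dt):
            v = -70.0
            n = int(1000.0 / dt)
            trace = np.empty(n)
            for k in range(n):
                v = v + dt * membrane_derivative(v, -200.0, PYRAMIDAL)
                trace[k] = v
            return trace

        coarse = integrate(0.5)
        fine = integrate(0.25)
        assert np.abs(coarse - fine[1::2]).max() < 0.1

    def test_steady_state_polarization_values(self):
        assert steady_state_polarization(0.375, 20.0) == pytest.approx(0.01875)
        assert round(steady_state_polarization(0.375, 20.0), 3) == 0.019
        assert steady_state_polarization(0.75, 20.0) == pytest.approx(0.0375)
        assert steady_state_polarization(0.0, 31.4) == 0.0
        with pytest.raises(ValueError):
            steady_state_polarization(1.0, 0.0)


class TestParams:
    def test_reference_presets(self):
        assert PYRAMIDAL.C == 0.5 and PYRAMIDAL.g_L == 25.0 and PYRAMIDAL.tau_r == 2.0
        assert INTERNEURON.C == 0.2 and INTERNEURON.g_L == 20.0 and INTERNEURON.tau_r == 1.0
        for p in (PYRAMIDAL, INTERNEURON):
            assert (p.E_L, p.Delta_T, p.V_T, p.V_s, p.V_r) == (-70.0, 3.0, -55.0, -20.0, -53.0)
        syn = default_synapses()
        assert syn[(SynapseKind.AMPA_background, "pyramidal")].G == 2.1
        assert syn[(SynapseKind.AMPA_background, "interneuron")].G == 1.53
        assert syn[(SynapseKind.NMDA, "pyramidal")].G == 0.145
        assert syn[(SynapseKind.GABA_A, "pyramidal")].E == -70.0
        assert syn[(SynapseKind.NMDA, "interneuron")].Mg == 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(C=-1, g_L=25, E_L=-70, Delta_T=3, V_T=-55, V_s=-20, V_r=-53, tau_r=2)
        with pytest.raises(ValueError):
            NeuronParams(C=0.5, g_L=25, E_L=-70, Delta_T=3, V_T=-55, V_s=-60, V_r=-53, tau_r=2)
        with pytest.raises(ValueError):
            NetworkConfig(n_pyramidal=100, n_selective=60)
        with pytest.raises(ValueError):
            NetworkConfig(dt=0.3)  # delay not a multiple of dt
        with pytest.raises(ValueError):
            StimulationCurrents(np.inf, 0.0)


class TestWiring:
    def test_wiring_is_deterministic_in_seed(self, small_config):
        a = build_network(small_config, rng_seed=3).wiring
        b = build_network(small_config, rng_seed=3).wiring
        c = build_network(small_config, rng_seed=4).wiring
        assert np.array_equal(a.exc_indices, b.exc_indices)
        assert np.array_equal(a.inh_indices, b.inh_indices)
        assert not np.array_equal(a.exc_indices, c.exc_indices)

    def test_selective_recurrent_count_binomial(self, full_network):
        cfg = full_network.config
        w = full_network.wiring
        n_sel = cfg.n_selective
        # connections from pool L staying within pool L
        count = 0
        for i in range(n_sel):
            tgt = w.exc_indices[w.exc_indptr[i] : w.exc_indptr[i + 1]]
            count += ((tgt < n_sel)).sum()
        p = cfg.connectivity.p_pyr_recurrent
        n_pairs = n_sel * (n_sel - 1)
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(count - p * n_pairs) < 4 * sd

    def test_int_to_pyr_count_binomial(self, full_network):
        cfg = full_network.config
        w = full_network.wiring
        count = (w.inh_indices < cfg.n_pyramidal).sum()
        p = cfg.connectivity.p_int_to_pyr
        n_pairs = cfg.n_interneurons * cfg.n_pyramidal
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(count - p * n_pairs) < 4 * sd

    def test_no_autapses(self, small_network):
        w = small_network.wiring
        n_pyr = small_network.config.n_pyramidal
        for i in range(n_pyr):
            tgt = w.exc_indices[w.exc_indptr[i] : w.exc_indptr[i + 1]]
            assert i not in tgt

    def test_accumulator_has_no_cross_pool_inhibition(self):
        cfg = NetworkConfig(
            n_pyramidal=40, n_selective=10, n_interneurons=10,
            architecture=Architecture.accumulator,
        )
        net = build_network(cfg, rng_seed=5)
        w = net.wiring
        half = cfg.n_interneurons // 2
        for ii in range(cfg.n_interneurons):
            tgt = w.inh_indices[w.inh_indptr[ii] : w.inh_indptr[ii + 1]]
            pool_l = tgt[tgt < cfg.n_selective]
            pool_r = tgt[(tgt >= cfg.n_selective) & (tgt < 2 * cfg.n_selective)]
            if ii < half:
                assert len(pool_r) == 0
            else:
                assert len(pool_l) == 0

    def test_delay_is_one_step(self, small_config):
        assert small_config.connectivity.delay == 0.5
        assert small_config.delay_steps == 1


class TestStep:
    def test_above_threshold_neuron_spikes_once_and_resets(self, small_network):
        state = small_network.initial_state()
        state.V[0] = -15.0  # above V_s
        spiked = small_network.step(state)
        assert spiked[0]
        assert state.V[0] == small_network.V_r[0]
        # refractory on the next step: no second spike
        spiked2 = small_network.step(state)
        assert not spiked2[0]

    def test_quiescent_network_stays_near_fixed_point(self, small_network):
        # oracle: the zero-input subthreshold fixed point from root finding
        v_star = scipy.optimize.brentq(
            lambda v: membrane_derivative(v, 0.0, PYRAMIDAL), -70.5, -60.0
        )
        state = small_network.initial_state()
        for _ in range(200):  # 100 ms
            small_network.step(state)
        assert np.abs(state.V - v_star).max() < 1.0

    def test_conductances_decay_monotonically_between_spikes(self, small_network):
        state = small_network.initial_state()
        state.g[G_BG, :] = 2.0
        state.g[G_GABA, :] = 1.0
        prev = state.g.copy()
        for _ in range(20):
            small_network.step(state)
            assert (state.g <= prev + 1e-12).all()
            assert (state.g >= 0).all()
            prev = state.g.copy()

    def test_external_events_set_conductance(self, small_network):
        state = small_network.initial_state()
        ext = np.zeros(small_network.config.n_total, dtype=bool)
        ext[0] = True
        small_network.step(state, external_spikes={"AMPA_ext": ext})
        assert state.g[G_EXT, 0] > 0
        assert state.g[G_EXT, 1:].max() == 0.0

    def test_constant_current_spiking_matches_fine_step_reference(self):
        # isolated neuron: constant suprathreshold current, period vs dt=0.01 ms
        def spike_period(dt, I):
            v = PYRAMIDAL.E_L
            t = 0.0
            spikes = []
            while t < 500.0:
                v += dt * membrane_derivative(v, I, PYRAMIDAL)
                t += dt
                if v >= PYRAMIDAL.V_s:
                    spikes.append(t)
                    v = PYRAMIDAL.V_r
                    t += PYRAMIDAL.tau_r
            isis = np.diff(spikes)
            return isis[len(isis) // 2 :].mean()

        fine = spike_period(0.01, -600.0)
        err = [abs(spike_period(dt, -600.0) - fine) / fine for dt in (0.5, 0.25, 0.125)]
        # first-order convergence: error shrinks roughly with dt
        assert err[0] < 0.20 and err[1] < 0.10
        assert err[0] > err[1] > err[2]

    def test_non_finite_voltage_raises_named_error(self, small_network):
        state = small_network.initial_state()
        state.V[3] = np.nan
        with pytest.raises(NumericalInstabilityError) as err:
            small_network.step(state)
        assert err.value.neuron == 3

    def test_kernel_matches_reference_step(self, small_network):
        """Compiled kernel and plain-numpy step agree on a deterministic run."""
        stim = StimulationCurrents(I_pyr=400.0, I_int=400.0)  # drive spiking
        s_ref = small_network.initial_state()
        s_ker = small_network.initial_state()
        for _ in range(60):
            small_network.step(s_ref, stim=stim)
        counts, _ = small_network.run_steps(s_ker, 60, stim=stim, seed=0)
        assert counts.sum() > 0  # the drive did elicit spikes
        assert np.abs(s_ref.V - s_ker.V).max() < 1e-3
        assert np.abs(s_ref.g - s_ker.g).max() < 1e-6
        assert np.array_equal(s_ref.pending_exc, s_ker.pending_exc)


class TestWinnerTakeAll:
    def test_high_coherence_separates_pools(self, full_network):
        """At 51.2% coherence one pool exceeds 20 Hz while the other stays
        below 5 Hz in at least 90% of trials."""
        from attractorchoice.task import coherence_to_rates

        net = full_network
        rng = np.random.default_rng(21)
        n_sel = net.config.n_selective
        bg = 900.0 * 2.8
        mu_hi, mu_lo = coherence_to_rates(0.512)
        wins = 0
        n_trials = 50
        state = net.initial_state()
        for trial in range(n_trials):
            net.reinitialize(state)
            net.run_steps(state, 1200, background_rate=bg, seed=100 + 3 * trial)
            frames_hi = np.maximum(rng.normal(mu_hi, 4.0, 61), 0).repeat(34)[:2000]
            frames_lo = np.maximum(rng.normal(mu_lo, 4.0, 61), 0).repeat(34)[:2000]
            hi_left = trial % 2 == 0
            rates = (frames_hi, frames_lo) if hi_left else (frames_lo, frames_hi)
            counts, _ = net.run_steps(
                state, 2000,
                background_rate=bg,
                task_rates=(rates[0] * 8.0, rates[1] * 8.0),
                seed=200 + 3 * trial,
            )
            # the decision read-out works on the smoothed population rate:
            # the winner's trace must exceed 20 Hz during the input period
            # while the loser's smoothed rate stays below 5 Hz late on
            from attractorchoice.neural import population_rate_trace

            sm_l = population_rate_trace(counts[:, 0], n_sel, 0.5).rates
            sm_r = population_rate_trace(counts[:, 1], n_sel, 0.5).rates
            win_tr, lose_tr = (sm_l, sm_r) if hi_left else (sm_r, sm_l)
            if win_tr.max() > 20.0 and lose_tr[1000:].mean() < 5.0:
                wins += 1
        assert wins >= 0.9 * n_trials
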
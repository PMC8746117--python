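"""Spiking network: HH kinetics, wiring statistics, simulation contracts."""

import numpy as np
import pytest
import scipy.integrate
import scipy.optimize

from corticonn.connectome import DistanceMatrix, FLNMatrix
from corticonn.network import (
    LongRangeSpec,
    NetworkSpec,
    NeuronParameters,
    PopulationSpec,
    SpikeRaster,
    SynapseParams,
    build_intra,
    build_long_range,
    firing_rate,
    gate_rates,
    hh_step,
    run_simulation,
    steady_state_gates,
)


def _resting_potential(params=NeuronParameters()):
    def f(v):
        m, h, n = steady_state_gates(v)
        return (
            -params.g_Na * m**3 * h * (v - params.E_Na)
            - params.g_K * n**4 * (v - params.E_K)
            - params.g_L * (v - params.E_L)
        )

    return scipy.optimize.brentq(f, -75.0, -50.0, xtol=1e-12)


class TestGateRates:
    @pytest.mark.parametrize(
        "V,which,expect",
        [
            (-16.0, 0, 1.0),  # alpha_m singular point -> limit 0.1 * 10
            (-41.0, 1, 4.0),  # beta_m exponent zero
            (-30.0, 2, 0.07),  # alpha_h exponent zero
            (-30.0, 5, 0.125),  # beta_n exponent zero
            (-20.0, 4, 0.1),  # alpha_n singular point
        ],
    )
    def test_reference_values(self, V, which, expect):
        assert gate_rates(V)[which] == pytest.approx(expect, abs=1e-9)

    def test_rates_nonnegative_and_continuous_at_singularities(self):
        v = np.linspace(-120, 60, 2001)
        rates = gate_rates(v)
        for r in rates:
            assert np.all(r >= 0)
        for v0, idx in ((-16.0, 0), (-20.0, 4)):
            near = gate_rates(np.array([v0 - 1e-5, v0, v0 + 1e-5]))[idx]
            assert np.ptp(near) < 1e-4


class TestHHStep:
    def test_resting_fixed_point(self):
        v0 = _resting_potential()
        m, h, n = steady_state_gates(v0)
        state = hh_step((v0, m, h, n), 0.0, NeuronParameters(), 0.1)
        assert abs(state[0] - v0) < 1e-9

    def test_spike_rate_matches_adaptive_ode_oracle(self):
        # constant suprathreshold drive; reference = high-accuracy LSODA
        params = NeuronParameters(I_ext=2.0)
        v0 = _resting_potential()
        m0, h0, n0 = steady_state_gates(v0)

        def rhs(t, y):
            v, m, h, n = y
            am, bm, ah, bh, an, bn = gate_rates(v)
            dv = (
                -params.g_Na * m**3 * h * (v - params.E_Na)
                - params.g_K * n**4 * (v - params.E_K)
                - params.g_L * (v - params.E_L)
                + params.I_ext
            ) / params.C_m_exc
            return [dv, am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                    an * (1 - n) - bn * n]

        sol = scipy.integrate.solve_ivp(
            rhs, (0, 1000.0), [v0, m0, h0, n0], method="LSODA",
            rtol=1e-10, atol=1e-10, dense_output=False, max_step=1.0,
            t_eval=np.arange(0, 1000.0, 0.05),
        )
        v_ref = sol.y[0]
        ref_spikes = np.sum((v_ref[1:] >= 0) & (v_ref[:-1] < 0))

        state = (v0, m0, h0, n0)
        count, prev = 0, v0
        for _ in range(10_000):
            state = hh_step(state, 0.0, params, 0.1)
            if state[0] >= 0 and prev < 0:
                count += 1
            prev = state[0]
        assert ref_spikes > 10  # drive really is suprathreshold
        assert abs(count - ref_spikes) / ref_spikes <= 0.02

    def test_gates_stay_in_unit_interval_under_strong_drive(self):
        params = NeuronParameters(I_ext=10.0)
        state = (-65.0, 0.9, 0.05, 0.9)  # far from steady state
        for _ in range(5000):
            state = hh_step(state, 0.0, params, 0.1)
            assert all(0.0 <= g <= 1.0 for g in state[1:])

    def test_dt_refinement_converges(self):
        params = NeuronParameters(I_ext=0.3)  # subthreshold, smooth approach
        v0 = _resting_potential()
        m0, h0, n0 = steady_state_gates(v0)

        def v_at_100ms(dt):
            state = (v0, m0, h0, n0)
            for _ in range(int(round(100.0 / dt))):
                state = hh_step(state, 0.0, params, dt)
            return state[0]

        ref = v_at_100ms(0.0125)
        errs = [abs(v_at_100ms(dt) - ref) for dt in (0.4, 0.2, 0.1)]
        assert errs[0] > errs[1] > errs[2]


class TestBuildIntra:
    def test_connection_count_binomial(self):
        pop = PopulationSpec(N_E=400, N_I=100)
        rng = np.random.default_rng(0)
        src, tgt, w, d, pool = build_intra(pop, SynapseParams(), rng)
        n_pairs = 500 * 499
        expect = n_pairs * 0.1
        sd = np.sqrt(n_pairs * 0.1 * 0.9)
        assert abs(src.size - expect) < 3 * sd
        assert np.all(src != tgt)

    def test_ee_weight_mean(self):
        pop = PopulationSpec(N_E=400, N_I=100)
        rng = np.random.default_rng(1)
        src, tgt, w, d, pool = build_intra(pop, SynapseParams(), rng)
        ee = w[(src < 400) & (tgt < 400)]
        se = 1.0 / np.sqrt(ee.size)
        assert abs(ee.mean() - 2.5) < 3 * se + 0.02  # truncation shifts slightly
        assert np.all(w > 0)

    def test_p_zero_empty(self):
        pop = PopulationSpec(N_E=10, N_I=2, p_intra=0.0)
        out = build_intra(pop, SynapseParams(), np.random.default_rng(0))
        assert out[0].size == 0


class TestBuildLongRange:
    @pytest.fixture
    def small_net(self):
        fln = FLNMatrix(np.array([[0.0, 0.1], [0.2, 0.0]]))
        dist = DistanceMatrix(np.array([[0.0, 7.0], [7.0, 0.0]]))
        pop = PopulationSpec(N_E=80, N_I=20)
        return fln, dist, pop

    def test_weights_and_delays(self, small_net):
        fln, dist, pop = small_net
        rng = np.random.default_rng(2)
        src, tgt, w, d, pool = build_long_range(fln, dist, LongRangeSpec(), pop, rng)
        # area 0 neurons are 0..99; targets in area 0 receive FLN_01 = 0.1
        onto0 = tgt < 100
        exc_t = (tgt % 100) < 80
        np.testing.assert_allclose(w[onto0 & exc_t], 50 * 0.1)
        np.testing.assert_allclose(w[onto0 & ~exc_t], 25 * 0.1)
        assert np.all(d == 20)  # 7 mm / 3.5 m/s = 2 ms = 20 steps of 0.1 ms
        assert np.all(src[onto0] >= 100)  # sources in area 1
        assert np.all((src[onto0] % 100) < 80)  # excitatory sources only

    def test_zero_fln_creates_no_edges(self):
        fln = FLNMatrix(np.array([[0, 0.3, 0.0], [0.2, 0, 0.1], [0.0, 0.4, 0]]))
        dist_v = np.array([[0, 5.0, 6.0], [5.0, 0, 7.0], [6.0, 7.0, 0]])
        pop = PopulationSpec(N_E=40, N_I=10)
        rng = np.random.default_rng(3)
        src, tgt, w, d, pool = build_long_range(
            fln, DistanceMatrix(dist_v), LongRangeSpec(), pop, rng
        )
        # FLN_02 = 0: no connections from area 2 into area 0
        assert not np.any((tgt < 50) & (src >= 100))

    def test_zero_distance_rejected(self, small_net):
        fln, _, pop = small_net
        dist = DistanceMatrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="delay undefined"):
            build_long_range(fln, dist, LongRangeSpec(), pop, np.random.default_rng(0))

    def test_total_incoming_weight_expectation(self, small_net):
        fln, dist, pop = small_net
        rng = np.random.default_rng(4)
        lr = LongRangeSpec()
        src, tgt, w, d, pool = build_long_range(fln, dist, lr, pop, rng)
        onto0_exc = (tgt < 80)
        total = w[onto0_exc].sum()
        w_edge = lr.mu_E * fln.values[0, 1]
        n_possible = pop.N_E * pop.N_E
        expect = lr.p_inter * n_possible * w_edge
        sd = np.sqrt(n_possible * lr.p_inter * (1 - lr.p_inter)) * w_edge
        assert abs(total - expect) < 3 * sd


class TestRunSimulation:
    def test_no_drive_is_quiescent(self):
        fln = FLNMatrix(np.array([[0.0, 0.4], [0.3, 0.0]]))
        dist = DistanceMatrix(np.array([[0.0, 5.0], [5.0, 0.0]]))
        pop = PopulationSpec(N_E=40, N_I=10, background_rate=0.0)
        spec = NetworkSpec(
            fln=fln, distances=dist, duration=1.0, seed=2, population=pop,
            long_range=LongRangeSpec(p_inter=0.0),
        )
        raster, currents = run_simulation(spec)
        assert raster.times.size == 0
        assert np.all(currents.abs_I_bkg == 0)

    def test_seed_determinism_and_sensitivity(self, tiny_spec, tiny_run):
        raster, _ = tiny_run
        again, _ = run_simulation(tiny_spec)
        np.testing.assert_array_equal(raster.times, again.times)
        np.testing.assert_array_equal(raster.neuron_ids, again.neuron_ids)
        other, _ = run_simulation(tiny_spec.with_(seed=tiny_spec.seed + 1))
        assert (other.times.size != raster.times.size) or (
            not np.array_equal(other.times, raster.times)
        )

    def test_network_fires_and_currents_recorded(self, tiny_run):
        raster, currents = tiny_run
        assert raster.times.size > 0
        assert np.all(np.diff(np.sort(raster.times)) >= 0)
        assert currents.n_steps == 20_000  # 2 s at 0.1 ms
        assert np.all(currents.abs_I_E >= 0)
        assert currents.abs_I_bkg[1000:].max() > 0


class TestFiringRate:
    def _raster(self, times, ids, n_neurons=1, duration=10_000.0):
        return SpikeRaster(
            np.asarray(times, dtype=float),
            np.asarray(ids, dtype=np.int32),
            np.zeros(n_neurons, dtype=np.int32),
            np.ones(n_neurons, dtype=bool),
            duration,
        )

    def test_periodic_train(self):
        t = np.arange(50.0, 10_000.0, 100.0)
        raster = self._raster(t, np.zeros(t.size))
        _, _, mean = firing_rate(raster, transient=0.0)
        assert mean == pytest.approx(10.0, rel=0.02)

    def test_empty_raster(self):
        raster = self._raster([], [], n_neurons=5)
        _, _, mean = firing_rate(raster)
        assert mean == 0.0

    def test_poisson_raster_mean(self):
        rng = np.random.default_rng(8)
        n, rate, dur = 1600, 5.0, 10_000.0
        counts = rng.poisson(rate * dur / 1000.0, n)
        ids = np.repeat(np.arange(n), counts)
        times = rng.uniform(0, dur, ids.size)
        order = np.argsort(times)
        raster = self._raster(times[order], ids[order], n_neurons=n, duration=dur)
        _, _, mean = firing_rate(raster, transient=0.0)
        se = np.sqrt(rate / (n * dur / 1000.0))
        assert abs(mean - rate) < 3 * se + 0.05

    def test_window_longer_than_duration_rejected(self, tiny_run):
        raster, _ = tiny_run
        with pytest.raises(ValueError):
            firing_rate(raster, window=10_000.0)
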
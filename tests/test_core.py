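"""Core L1 engine: weights, fractional coefficient, memory trace, stepping."""

import math

import numpy as np
import pytest

from flif.core import (
    MemoryKernel,
    NeuronState,
    SimulationOptions,
    advance_one_step,
    gamma_coefficient,
    lag_weights,
    memory_weights,
    simulate,
    voltage_memory_trace,
)
from flif.params import ModelParams, TimeGrid, table1_params
from flif.analysis import SpikeTrain, extract_isis, first_spike_latency


CLASSICAL_ISI = 5.0 + 20.0 * math.log(1.2)  # tau_ref + tau_m*ln(1.2) for I=3 nA
CLASSICAL_LATENCY = -20.0 * math.log(1.0 - 20.0 * 0.025 / 3.0)


class TestMemoryWeights:
    def test_classical_limit_all_zero(self):
        for N in (2, 5, 50):
            assert np.all(memory_weights(1.0, N) == 0.0)

    def test_one_step_back_weight_half_order(self):
        # hand evaluation of the L1 power-law difference: 2^0.5 - 1
        w = memory_weights(0.5, 10)
        assert w[-1] == pytest.approx(math.sqrt(2.0) - 1.0, abs=1e-12)

    def test_weights_increase_as_alpha_decreases(self):
        w_low, w_high = memory_weights(0.2, 40), memory_weights(0.8, 40)
        assert np.all(w_low >= w_high)
        assert np.all(w_low >= 0.0) and np.all(w_high >= 0.0)

    def test_weights_telescope_to_power_law(self):
        # sum of all lag weights including the unit most-recent one is N^(1-alpha)
        for alpha in (0.2, 0.5, 0.9):
            w = lag_weights(alpha, 30)
            assert w[1:].sum() == pytest.approx(30 ** (1 - alpha), rel=1e-12)

    @pytest.mark.parametrize("bad_alpha", [0.0, -0.1, 1.5])
    def test_alpha_domain(self, bad_alpha):
        with pytest.raises(ValueError):
            memory_weights(bad_alpha, 5)

    def test_insufficient_history(self):
        with pytest.raises(ValueError):
            memory_weights(0.5, 1)


class TestGammaCoefficient:
    def test_integer_order_limit(self):
        assert gamma_coefficient(1.0, 0.1) == pytest.approx(0.1, abs=1e-15)

    def test_half_order_value(self):
        expected = math.sqrt(0.1) * math.gamma(1.5)
        assert gamma_coefficient(0.5, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_grows_as_alpha_decreases_for_submillisecond_step(self):
        assert gamma_coefficient(0.2, 0.1) > gamma_coefficient(1.0, 0.1)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            gamma_coefficient(0.5, 0.0)


class TestVoltageMemoryTrace:
    def test_constant_history_gives_zero(self):
        kernel = MemoryKernel.build(0.4, 9, 0.1)
        assert voltage_memory_trace(np.full(9, -70.0), kernel) == 0.0

    def test_depolarizing_history_positive(self):
        kernel = MemoryKernel.build(0.4, 9, 0.1)
        history = np.linspace(-70.0, -60.0, 9)
        assert voltage_memory_trace(history, kernel) > 0.0

    def test_reset_step_negative(self):
        kernel = MemoryKernel.build(0.4, 9, 0.1)
        history = np.concatenate([np.linspace(-60.0, -50.0, 8), [-70.0]])
        assert voltage_memory_trace(history, kernel) < 0.0

    def test_shape_mismatch(self):
        kernel = MemoryKernel.build(0.4, 9, 0.1)
        with pytest.raises(ValueError):
            voltage_memory_trace(np.zeros(5), kernel)


class TestAdvanceOneStep:
    def test_classical_limit_is_forward_euler(self, table1):
        opt = SimulationOptions(dt=0.1)
        st = NeuronState(params=table1, options=opt)
        advance_one_step(st, 1.0)
        advance_one_step(st, 1.0)
        v = table1.V_0
        for _ in range(2):
            v = v + (0.1 / table1.C_m) * (-table1.g_L * (v - table1.V_L) + 1.0)
        assert st.voltage[-1] == pytest.approx(v, abs=1e-12)

    def test_threshold_crossing_is_inclusive(self):
        p = ModelParams(V_0=-50.5, alpha=1.0)
        opt = SimulationOptions(dt=0.1)
        st = NeuronState(params=p, options=opt)
        # current chosen so the Euler step lands exactly on threshold
        drive = p.g_L * (p.V_0 - p.V_L) + p.C_m * 0.5 / opt.dt
        advance_one_step(st, drive)
        assert st.voltage[-1] == p.V_th
        assert len(st.spike_times) == 1

    def test_refractory_clamp_ignores_current(self, table1):
        opt = SimulationOptions(dt=0.1)
        st = NeuronState(params=table1, options=opt)
        for _ in range(200):
            advance_one_step(st, 10.0)
            if st.spike_times:
                break
        for _ in range(10):
            advance_one_step(st, 100.0)
            assert st.voltage[-1] == table1.V_reset

    @pytest.mark.parametrize("mode", ["full", "reset_on_spike"])
    def test_matches_compiled_kernel(self, mode, rng):
        p = table1_params(0.3)
        opt = SimulationOptions(dt=0.5, memory_mode=mode)
        I = 3.0 + 0.5 * rng.standard_normal(401)
        res = simulate(p, I, opt)
        st = NeuronState(params=p, options=opt)
        for k in range(400):
            advance_one_step(st, I[k])
        assert np.allclose(st.voltage, res.voltage, atol=1e-10)
        assert np.allclose(st.spike_times, res.spike_times)


class TestSimulate:
    def test_classical_steady_isi(self, table1):
        res = simulate(table1, np.full(10_001, 3.0), SimulationOptions(dt=0.1))
        isis = np.diff(res.spike_times)
        assert abs(isis[-1] - CLASSICAL_ISI) <= 0.1
        train = SpikeTrain.from_result(res)
        assert abs(first_spike_latency(train) - CLASSICAL_LATENCY) <= 0.1

    def test_subthreshold_approaches_steady_state(self, table1):
        # 0.3 nA is below the 0.5 nA rheobase: no spikes, V -> -58 mV from below
        res = simulate(table1, np.full(50_001, 0.3), SimulationOptions(dt=0.1))
        assert res.n_spikes == 0
        assert res.voltage[-1] == pytest.approx(-58.0, abs=0.01)
        assert np.all(res.voltage <= -58.0 + 1e-9)

    def test_fractional_latency_and_adaptation(self):
        res1 = simulate(table1_params(1.0), np.full(20_001, 3.0), SimulationOptions(dt=0.1))
        res_frac = simulate(table1_params(0.2), np.full(20_001, 3.0), SimulationOptions(dt=0.1))
        assert res_frac.spike_times[0] > res1.spike_times[0]
        isis = np.diff(res_frac.spike_times)
        # inter-spike intervals shorten over successive spikes
        assert isis[-1] < isis[0]
        assert np.all(np.diff(isis[:10]) < 0)

    def test_voltage_never_exceeds_threshold_and_refractory_gap(self):
        p = table1_params(0.4)
        res = simulate(p, np.full(20_001, 4.0), SimulationOptions(dt=0.1))
        assert np.max(res.voltage) <= p.V_th
        assert np.all(np.diff(res.spike_times) >= p.tau_ref)

    def test_memory_reset_gives_regular_spiking(self):
        p = table1_params(0.2)
        res = simulate(p, np.full(30_001, 3.0), SimulationOptions(dt=0.1, memory_mode="reset_on_spike"))
        isis = np.diff(res.spike_times)
        assert isis.size >= 3
        assert np.max(isis[1:]) - np.min(isis[1:]) <= 0.1 + 1e-9

    def test_memory_trace_negative_after_reset(self):
        p = table1_params(0.2)
        res = simulate(p, np.full(20_001, 3.0), SimulationOptions(dt=0.1))
        i_spike = int(round(res.spike_times[0] / 0.1))
        n_ref = int(round(p.tau_ref / 0.1))
        post = res.memory_trace[i_spike + n_ref + 1]
        assert post < 0.0

    def test_non_finite_current_raises_with_step_index(self, table1):
        I = np.full(101, 0.3)  # sub-threshold: no refractory skipping
        I[50] = np.inf
        with pytest.raises(FloatingPointError, match="step 51"):
            simulate(table1, I, SimulationOptions(dt=0.1))

    def test_deterministic(self, table1):
        I = np.full(2001, 3.0)
        a = simulate(table1, I, SimulationOptions(dt=0.1))
        b = simulate(table1, I, SimulationOptions(dt=0.1))
        assert np.array_equal(a.voltage, b.voltage)
        assert np.array_equal(a.spike_times, b.spike_times)


class TestSubthresholdPowerLaw:
    def test_loglog_slope_tracks_alpha(self):
        # early response to a constant sub-threshold step rises like t**alpha
        for alpha in (0.2, 0.3, 0.5):
            p = table1_params(alpha)
            res = simulate(p, np.full(20_001, 0.3), SimulationOptions(dt=0.1))
            tmax = (0.15 * p.tau_m * math.gamma(1 + alpha)) ** (1 / alpha)
            i1 = max(int(tmax / 0.1), 30)
            t = res.times[5:i1]
            v = res.voltage[5:i1] - p.V_0
            slope = np.polyfit(np.log(t), np.log(v), 1)[0]
            assert abs(slope - alpha) <= 0.05


class TestParams:
    def test_tau_m_is_derived(self, table1):
        assert table1.tau_m == table1.C_m / table1.g_L == 20.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.2},
            {"C_m": -1.0},
            {"g_L": 0.0},
            {"tau_ref": -1.0},
            {"V_reset": -40.0},
            {"V_0": -30.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            TimeGrid(dt=0.0, n_steps=10)
        g = TimeGrid.from_duration(1000.0, 0.1)
        assert g.n_steps == 10_000
        assert g.times[0] == 0.0 and g.times[-1] == pytest.approx(1000.0)
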
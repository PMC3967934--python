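"""Quantification operators: spike statistics, impedance, fits, reliability."""

import math

import numpy as np
import pytest

from flif import protocols
from flif.analysis import (
    ISISeries,
    SpikeTrain,
    cycle_recovery_metric,
    extract_isis,
    first_spike_latency,
    fit_adaptation_tau,
    gain_phase_at_period,
    impedance_profile,
    instantaneous_rate,
    isi_powerlaw_fit,
    mean_rate,
    pause_after_pulse,
    reliability,
)
from flif.core import SimulationOptions, simulate
from flif.params import TimeGrid, table1_params
from flif.stimuli import SineCurrent


def make_train(times, duration=1000.0, dt=0.1):
    return SpikeTrain(times=np.asarray(times, dtype=float), grid=TimeGrid.from_duration(duration, dt))


class TestSpikeStatistics:
    def test_isis_are_consecutive_differences(self):
        s = extract_isis(make_train([10.0, 20.0, 35.0]))
        assert np.array_equal(s.isis, [10.0, 15.0])
        assert np.array_equal(s.index, [0, 1])

    def test_too_few_spikes_warns_not_raises(self):
        with pytest.warns(UserWarning):
            s = extract_isis(make_train([10.0]))
        assert s.n == 0

    def test_latency_and_subthreshold_absence(self):
        assert first_spike_latency(make_train([12.0, 20.0]), 10.0) == 2.0
        assert first_spike_latency(make_train([]), 0.0) is None

    def test_constant_isi_rate(self):
        isi = 8.6464
        times = np.arange(1, 20) * isi
        rate = instantaneous_rate(make_train(times))
        assert np.allclose(rate.rates, 1000.0 / isi)
        assert rate.times[0] == pytest.approx(1.5 * isi)

    def test_mean_rate_counts_window(self):
        tr = make_train([100.0, 200.0, 300.0, 900.0])
        assert mean_rate(tr, 0.0, 500.0) == pytest.approx(6.0)
        assert mean_rate(tr, 400.0, 800.0) == 0.0
        with pytest.raises(ValueError):
            mean_rate(tr, 500.0, 500.0)

    def test_type_i_threshold_current(self, table1):
        # rheobase g_L*(V_th-V_L) = 0.5 nA: silent at it, firing just above
        opt = SimulationOptions(dt=0.1)
        silent = simulate(table1, np.full(20_001, 0.5), opt)
        firing = simulate(table1, np.full(20_001, 0.6), opt)
        assert silent.n_spikes == 0
        assert firing.n_spikes > 0


class TestImpedance:
    def test_classical_model_matches_rc_form(self, table1):
        _, prof = protocols.run_zap_impedance(table1, amplitude=0.1)
        f = prof.frequencies
        rc = 1.0 / (table1.g_L * np.sqrt(1.0 + (2 * np.pi * f * table1.tau_m / 1000.0) ** 2))
        band = (f >= 1.0) & (f <= 99.0)  # the sweep reaches 99% of the band edge
        rel = np.abs(prof.magnitude[band] - rc[band]) / rc[band]
        assert rel.max() < 0.02
        assert prof.magnitude[0] == pytest.approx(1.0 / table1.g_L, rel=0.02)  # 40 MOhm at DC
        # phase: ~0 at DC, approaching -90 deg at high frequency
        assert prof.phase_deg[band][0] > -10.0
        assert prof.phase_deg[band][-1] < -80.0

    def test_fractional_impedance_flattens_and_phase_shrinks(self, table1):
        _, prof1 = protocols.run_zap_impedance(table1, amplitude=0.1)
        _, prof_frac = protocols.run_zap_impedance(table1.with_alpha(0.2), amplitude=0.1)
        band1 = (prof1.frequencies >= 1.0) & (prof1.frequencies <= 99.0)
        bandf = (prof_frac.frequencies >= 1.0) & (prof_frac.frequencies <= 99.0)
        ratio1 = prof1.magnitude[band1].max() / prof1.magnitude[band1].min()
        ratiof = prof_frac.magnitude[bandf].max() / prof_frac.magnitude[bandf].min()
        assert ratiof < ratio1 / 3.0  # much flatter across the band
        assert prof_frac.phase_deg[bandf].min() > prof1.phase_deg[band1].min()  # less negative
        spread = prof_frac.phase_deg[bandf].max() - prof_frac.phase_deg[bandf].min()
        assert spread < 15.0  # nearly frequency-insensitive

    def test_refuses_spiking_epoch(self, table1):
        grid = TimeGrid.from_duration(100.0, 0.1)
        v = np.full(grid.n_samples, -50.0)  # at threshold
        i = np.ones(grid.n_samples)
        with pytest.raises(ValueError, match="sub-threshold"):
            impedance_profile(v, i, grid, v_th=-50.0)


class TestGainPhaseFit:
    def test_recovers_synthetic_sine_exactly(self):
        P = 2000.0
        t = np.arange(100.0, 10_000.0, 7.0)
        rate_vals = 50.0 + 10.0 * np.sin(2 * np.pi * t / P + np.radians(30.0))
        from flif.analysis import RateSeries

        rate = RateSeries(times=t, rates=rate_vals)
        res = gain_phase_at_period(rate, SineCurrent(offset=3.0, amplitude=0.5, period=P))
        assert res.rate_amplitude == pytest.approx(10.0, rel=1e-6)
        assert res.phase_lead_deg == pytest.approx(30.0, abs=1e-6)
        assert res.gain == pytest.approx(20.0, rel=1e-6)

    def test_too_few_cycles_diagnosed(self):
        from flif.analysis import RateSeries

        rate = RateSeries(times=np.linspace(0, 1000, 20), rates=np.full(20, 10.0))
        with pytest.raises(ValueError, match="cycles"):
            gain_phase_at_period(rate, SineCurrent(offset=3.0, amplitude=0.5, period=2000.0))


class TestAdaptationFit:
    def test_recovers_synthetic_time_constant(self):
        from flif.analysis import RateSeries

        t = np.arange(0.0, 2000.0, 5.0)
        r = 30.0 + 20.0 * np.exp(-t / 500.0)
        fit = fit_adaptation_tau(RateSeries(times=t, rates=r), (0.0, 2000.0), "downward")
        assert fit.tau == pytest.approx(500.0, rel=1e-4)
        assert fit.r_inf == pytest.approx(30.0, rel=1e-4)


class TestPowerLawFit:
    def test_degenerate_isis_rejected(self):
        s = ISISeries(isis=np.full(30, 8.0), index=np.arange(30))
        with pytest.raises(ValueError):
            isi_powerlaw_fit(s)

    def test_pareto_exponent_recovered(self, rng):
        # log-binned counts of a Pareto(2) sample fall on slope -2
        x = 10.0 * (1.0 + rng.pareto(2.0, size=20_000))
        fit = isi_powerlaw_fit(ISISeries(isis=x, index=np.arange(x.size)))
        assert fit.slope == pytest.approx(-2.0, abs=0.3)
        assert 0.9 <= fit.r_squared <= 1.0

    def test_fractional_isis_prefer_power_law_over_exponential(self):
        res = simulate(table1_params(0.2), np.full(40_001, 3.0), SimulationOptions(dt=0.5))
        s = extract_isis(SpikeTrain.from_result(res))
        fit = isi_powerlaw_fit(s)
        assert fit.r_squared > fit.r_squared_exponential


class TestReliability:
    def test_identical_trains_fully_reliable(self):
        trains = [make_train([100.0, 300.0, 700.0]) for _ in range(4)]
        assert reliability(trains, smoothing_sigma=3.0).R == pytest.approx(1.0, abs=1e-12)

    def test_distant_spikes_uncorrelated(self):
        a = make_train([100.0])
        b = make_train([900.0])
        assert reliability([a, b], smoothing_sigma=3.0).R == pytest.approx(0.0, abs=1e-6)

    def test_permutation_and_shift_invariance(self, rng):
        trains = [
            make_train(np.sort(rng.uniform(50, 900, size=12)), duration=1000.0, dt=1.0)
            for _ in range(4)
        ]
        base = reliability(trains, smoothing_sigma=5.0).R
        perm = reliability(trains[::-1], smoothing_sigma=5.0).R
        shifted = [make_train(t.times + 40.0, duration=1000.0, dt=1.0) for t in trains]
        shift = reliability(shifted, smoothing_sigma=5.0).R
        assert perm == pytest.approx(base, abs=1e-12)
        assert shift == pytest.approx(base, abs=1e-3)

    def test_empty_train_excluded_with_warning(self):
        a = make_train([100.0, 200.0])
        b = make_train([110.0, 210.0])
        c = make_train([])
        with pytest.warns(UserWarning):
            res = reliability([a, b, c], smoothing_sigma=3.0)
        assert res.n_trials == 2


class TestPauseAndRecovery:
    def test_pause_measured_from_pulse_end(self):
        tr = make_train([100.0, 200.0, 300.0, 850.0])
        res = pause_after_pulse(tr, 300.5)
        assert res.pause == pytest.approx(549.5)
        assert not res.censored

    def test_censored_when_no_spike_follows(self):
        tr = make_train([100.0, 200.0], duration=1000.0)
        res = pause_after_pulse(tr, 500.0)
        assert res.censored and res.pause == pytest.approx(500.0)

    def test_requires_pre_pulse_spiking(self):
        with pytest.raises(ValueError):
            pause_after_pulse(make_train([800.0]), 500.0)

    def test_identical_cycles_ratio_one(self):
        cyc = ISISeries(isis=np.array([50.0, 40.0, 30.0]), index=np.arange(3))
        assert cycle_recovery_metric([cyc] * 5) == 1.0

    def test_requires_five_cycles_with_isis(self):
        cyc = ISISeries(isis=np.array([50.0, 40.0, 30.0]), index=np.arange(3))
        short = ISISeries(isis=np.array([50.0]), index=np.arange(1))
        with pytest.raises(ValueError):
            cycle_recovery_metric([cyc] * 4)
        with pytest.raises(ValueError):
            cycle_recovery_metric([cyc, cyc, cyc, cyc, short])


class TestConditioningHistory:
    def test_first_interval_rate_depends_on_conditioning(self):
        # depolarizing pre-stimulus leaves a memory that speeds the first interval
        p = table1_params(0.2)
        rates = {}
        for pre in (-3.0, 3.0):
            res = protocols.run_prepost(p, pre, 1000.0, 3.0, 6000.0)
            tr = SpikeTrain.from_result(res).restrict(1000.0, 7000.0)
            rates[pre] = instantaneous_rate(tr).first_interval_rate
        assert rates[3.0] > rates[-3.0]

    def test_steady_rate_approximately_conditioning_independent(self):
        p = table1_params(0.2)
        steady = {}
        for pre in (-3.0, 3.0):
            res = protocols.run_prepost(p, pre, 1000.0, 3.0, 6000.0)
            tr = SpikeTrain.from_result(res)
            steady[pre] = mean_rate(tr, 4000.0, 7000.0)
        assert steady[3.0] == pytest.approx(steady[-3.0], rel=0.15)
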
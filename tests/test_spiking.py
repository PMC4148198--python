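import numpy as np
import pytest

from gclnet.patterns import poissonize
from gclnet.spiking import (
    GCParams,
    STPParams,
    SpikeRaster,
    SynapseParams,
    _HAVE_NUMBA,
    calibrate_excitation,
    count_window,
    mg_block,
    simulate,
    stp_amplitudes,
    synaptic_conductance_trace,
    weight_scale_for,
)

SINGLE_GC = np.array([[0, 1, 2, 3]])


def active_pattern(k, n=4):
    pattern = np.zeros(n, dtype=np.uint8)
    pattern[:k] = 1
    return pattern


class TestSTP:
    def test_single_spike_is_baseline(self):
        assert stp_amplitudes([5.0], STPParams()) == pytest.approx([1.0])

    def test_regular_train_depresses_monotonically(self):
        amps = stp_amplitudes(np.arange(0, 100, 10.0), STPParams(U=0.45, tau_rec_ms=50))
        assert np.all(np.diff(amps) < 1e-12)
        assert amps[-1] < 0.5  # clearly depressed steady state

    def test_long_interval_recovers_baseline(self):
        amps = stp_amplitudes([0.0, 5000.0], STPParams(U=0.45, tau_rec_ms=50))
        assert amps[1] == pytest.approx(1.0, abs=1e-6)

    def test_facilitation_raises_second_amplitude(self):
        stp = STPParams(U=0.1, tau_rec_ms=10.0, tau_facil_ms=100.0)
        amps = stp_amplitudes([0.0, 5.0], stp)
        assert amps[1] > 1.0

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            stp_amplitudes([5.0, 1.0], STPParams())


class TestMgBlock:
    def test_limits_and_monotonicity(self):
        assert mg_block(300.0) == pytest.approx(1.0, abs=1e-3)
        v = np.linspace(-120, 60, 50)
        b = mg_block(v)
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b <= 1))

    def test_strong_block_at_hyperpolarized_potentials(self):
        assert mg_block(-70.0) < 0.2


class TestWeightScale:
    @pytest.mark.parametrize("d,expected", [(4, 1.0), (8, 0.5), (2, 2.0), (1, 4.0)])
    def test_reference_conservation(self, d, expected):
        assert weight_scale_for(d) == pytest.approx(expected)

    def test_total_conductance_integral_invariant_across_d(self, rng):
        """Scaling peaks by 4/d conserves the summed excitatory conductance."""
        base_train = np.sort(rng.random(6) * 50.0)
        integrals = []
        for d in (2, 4, 8):
            trains = poissonize(np.zeros(d, dtype=int), 0, 0, 60.0, rng)
            trains.times = [base_train.copy() for _ in range(d)]
            syn = SynapseParams(weight_scale=weight_scale_for(d))
            _, g_a, g_n = synaptic_conductance_trace(trains, syn, duration=60.0)
            integrals.append(np.trapezoid(g_a + g_n, dx=0.025))
        ref = integrals[1]
        assert all(abs(i - ref) / ref < 0.01 for i in integrals)


class TestSimulate:
    def test_no_input_stays_at_rest_without_spikes(self):
        trains = poissonize(active_pattern(0), 0.0, 0.0, 60.0, 0)
        raster = simulate(SINGLE_GC, trains)
        assert all(len(t) == 0 for t in raster.times)
        # tonic reversal (-79.1) is ~at rest (-79.9): V barely moves
        assert abs(raster.v_max - (-79.9)) < 1.0
        assert abs(raster.v_min - (-79.9)) < 1.0

    def test_passive_steady_state_matches_conductance_divider(self):
        """With only constant conductances, V relaxes to the analytic value."""
        gc = GCParams(tonic_pS=2000.0, gaba_reversal_mV=-60.0)
        trains = poissonize(active_pattern(0), 0.0, 0.0, 100.0, 0)
        raster = simulate(SINGLE_GC, trains, gc)
        g_l, g_t = gc.leak_nS, 2.0
        v_ss = (g_l * gc.rest_mV + g_t * gc.gaba_reversal_mV) / (g_l + g_t)
        assert abs(raster.v_max - v_ss) < 0.1

    def test_io_curve_monotone_and_supralinear_near_threshold(self):
        """Firing grows with the number of active 80-Hz inputs, steepest
        around the 2-to-3 input transition (>=3 of 4 typically required)."""
        rng = np.random.default_rng(7)
        rates = []
        for k in (1, 2, 3, 4):
            total = 0
            for _ in range(40):
                trains = poissonize(active_pattern(k), 80.0, 10.0, 60.0, rng)
                total += count_window(simulate(SINGLE_GC, trains), 30.0, 30.0)[0]
            rates.append(total / 40)
        assert rates[0] < rates[1] < rates[2] < rates[3]
        assert rates[2] - rates[1] > rates[1] - rates[0]  # supralinear rise
        assert rates[0] < 0.5  # a lone active input rarely drives spikes

    def test_dt_convergence(self):
        rng = np.random.default_rng(3)
        trains = poissonize(active_pattern(3), 80.0, 10.0, 60.0, rng)
        c1 = count_window(simulate(SINGLE_GC, trains, dt=0.05), 30.0, 30.0)
        c2 = count_window(simulate(SINGLE_GC, trains, dt=0.025), 30.0, 30.0)
        assert np.all(np.abs(c1 - c2) <= 1)

    def test_nadt_sparsifies_at_high_input_activity(self, pinned_network):
        adj = pinned_network.adjacency()
        rng = np.random.default_rng(11)
        pattern = np.zeros(pinned_network.n_rosette, dtype=np.uint8)
        pattern[rng.choice(len(pattern), size=int(0.8 * len(pattern)), replace=False)] = 1
        trains = poissonize(pattern, 80.0, 10.0, 60.0, rng)
        tonic = simulate(adj, trains, GCParams(nadt_scale=0.0), p_mf=0.8)
        nadt = simulate(adj, trains, GCParams(nadt_scale=1.0), p_mf=0.8)
        assert sum(map(len, nadt.times)) < sum(map(len, tonic.times))

    def test_membrane_stays_within_physical_bounds(self, pinned_network):
        rng = np.random.default_rng(1)
        pattern = np.zeros(pinned_network.n_rosette, dtype=np.uint8)
        pattern[: len(pattern) // 2] = 1
        trains = poissonize(pattern, 80.0, 10.0, 60.0, rng)
        raster = simulate(pinned_network.adjacency(), trains, p_mf=0.5)
        assert raster.v_min >= -79.9 - 5.0
        assert raster.v_max <= 0.0 + 1e-6

    @pytest.mark.skipif(not _HAVE_NUMBA, reason="needs both engines")
    def test_jit_and_numpy_engines_agree(self):
        rng = np.random.default_rng(5)
        adj = np.array([[0, 1, 2], [1, 2, 3], [0, 2, 3]])
        trains = poissonize(np.array([1, 1, 1, 0]), 80.0, 10.0, 60.0, rng)
        a = simulate(adj, trains, engine="numba")
        b = simulate(adj, trains, engine="numpy")
        for ta, tb in zip(a.times, b.times):
            assert np.allclose(ta, tb)

    def test_missing_trains_rejected(self):
        trains = poissonize(active_pattern(1, n=2), 80.0, 10.0, 30.0, 0)
        with pytest.raises(ValueError, match="missing input trains"):
            simulate(SINGLE_GC, trains)

    def test_coarse_dt_rejected(self):
        trains = poissonize(active_pattern(0), 0.0, 0.0, 30.0, 0)
        with pytest.raises(ValueError):
            simulate(SINGLE_GC, trains, dt=0.5)


class TestCountWindow:
    def test_empty_raster_gives_zero_vector(self):
        raster = SpikeRaster(times=[np.empty(0)] * 3, duration=60.0)
        assert count_window(raster, 30.0, 30.0).tolist() == [0, 0, 0]

    def test_half_open_window_convention(self):
        raster = SpikeRaster(
            times=[np.array([30.0, 45.0, 60.0 - 1e-9]), np.array([29.999])],
            duration=60.0,
        )
        counts = count_window(raster, 30.0, 30.0)
        assert counts.tolist() == [3, 0]  # start inclusive, end exclusive

    def test_window_must_fit(self):
        raster = SpikeRaster(times=[np.empty(0)], duration=50.0)
        with pytest.raises(ValueError):
            count_window(raster, 30.0, 30.0)

    def test_poisson_rate_recovered(self, rng):
        # single 80-Hz cell counted over 30 ms -> mean 2.4
        total = 0
        reps = 500
        for _ in range(reps):
            trains = poissonize([1], 80.0, 10.0, 30.0, rng)
            raster = SpikeRaster(times=[trains.times[0]], duration=30.0)
            total += count_window(raster, 30.0, 0.0)[0]
        se = np.sqrt(2.4 / reps)
        assert abs(total / reps - 2.4) < 3 * se


def test_calibrated_defaults_require_three_of_four_inputs():
    """The shipped synaptic peaks sit at the calibration point: the scale
    returned for the defaults is ~1."""
    scale = calibrate_excitation(trials=30)
    assert 0.6 < scale < 1.6
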
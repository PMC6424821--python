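"""Theta-cycle segmentation, correlograms, surrogates, scores, PSP kinetics."""
import numpy as np
import pytest
from scipy.special import i0, i1

from ca1nac import synthetic, timing
from ca1nac.core import ThetaCycles
from ca1nac.timing import (
    cross_correlogram,
    detect_theta_cycles,
    light_rate_score,
    psp_kinetics,
    score_density,
    theta_modulation_depth,
    theta_shift_surrogates,
)


class TestDetectThetaCycles:
    def test_pure_8hz_sinusoid(self):
        fs = 1000.0
        t = np.arange(0.0, 10.0, 1 / fs)
        cyc = detect_theta_cycles(np.sin(2 * np.pi * 8.0 * t), fs)
        assert cyc.n_cycles == 79  # 80 cycles, minus edge effects
        # cycle lengths exact to well below the 1-ms sample interval
        np.testing.assert_allclose(cyc.cycle_lengths[2:-2], 0.125, atol=1e-4)
        assert np.median(cyc.cycle_lengths) == pytest.approx(0.125, abs=1e-5)

    def test_phase_channel_round_trip(self):
        cfg = synthetic.SessionConfig(duration=20.0, n_pyr=1, seed=0)
        _, cycles, *_ = synthetic.generate_session(cfg)
        fs = 1000.0
        t = np.arange(0.0, 20.0, 1 / fs)
        phase = (2 * np.pi * cfg.theta_freq * t) % (2 * np.pi)
        detected = detect_theta_cycles(phase, fs, is_phase=True)
        inner = cycles.boundaries[
            (cycles.boundaries > 0.01) & (cycles.boundaries < detected.stop)
        ]
        got = detected.boundaries
        for b in inner:
            assert np.min(np.abs(got - b)) < 1e-6

    def test_noisy_8hz_median_cycle(self, rng):
        fs = 1000.0
        t = np.arange(0.0, 30.0, 1 / fs)
        sig = np.sin(2 * np.pi * 8.0 * t) + 0.5 * rng.standard_normal(t.size)
        cyc = detect_theta_cycles(sig, fs)
        med = np.median(cyc.cycle_lengths[cyc.valid])
        assert abs(med - 0.125) / 0.125 < 0.05

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            detect_theta_cycles(np.zeros(50), 1000.0)

    def test_out_of_band_cycles_flagged(self):
        # 2-Hz "cycles" from a phase ramp are flagged invalid
        boundaries = np.arange(0.0, 5.0, 0.5)
        cyc = ThetaCycles(boundaries)
        assert not cyc.valid.any()


class TestCrossCorrelogram:
    def test_fixed_lag_all_mass_in_one_bin(self, rng):
        ref = np.arange(500) * 0.2 + rng.uniform(0, 0.05, 500)  # sparse train
        ccg = cross_correlogram(ref, ref + 0.0042, window_s=0.01)
        i = np.argmin(np.abs(ccg.lag_centers_s - 0.0042))
        assert ccg.probability[i] >= 1.0  # every ref has its +4.2 ms partner
        # the rest of the window is empty (min ISI of ref >> window)
        assert ccg.probability.sum() == pytest.approx(ccg.probability[i], rel=0.05)

    def test_independent_poisson_flat(self, rng):
        lam = 10.0
        ref = np.sort(rng.uniform(0.0, 500.0, 2500))
        tgt = np.sort(rng.uniform(0.0, 500.0, int(lam * 500)))
        ccg = cross_correlogram(ref, tgt, bin_s=0.005)
        expect = lam * 0.005
        assert ccg.probability.mean() == pytest.approx(expect, rel=0.05)
        assert ccg.probability.std() < 3 * np.sqrt(expect / ref.size)

    def test_mass_conservation(self, rng):
        ref = np.sort(rng.uniform(0.0, 50.0, 200))
        tgt = np.sort(rng.uniform(0.0, 50.0, 300))
        ccg = cross_correlogram(ref, tgt)
        n_pairs = sum(
            np.sum(np.abs(tgt - r) < 0.2 - 1e-12) for r in ref
        )
        assert ccg.probability.sum() * ref.size == pytest.approx(n_pairs, abs=1.5)

    def test_empty_train_raises(self):
        with pytest.raises(ValueError):
            cross_correlogram(np.array([]), np.array([1.0]))

    def test_theta_comodulated_pair_oscillates(self, rng):
        """Anti-phased 8-Hz rate modulation: ~125-ms periodicity in the
        correlogram with a trough near lag zero."""

        def train(sign):
            rate_max = 8.0
            cand = np.sort(rng.uniform(0, 300.0, rng.poisson(rate_max * 300.0)))
            rate = 4.0 * (1 + sign * 0.9 * np.cos(2 * np.pi * 8.0 * cand))
            return cand[rng.random(cand.size) < rate / rate_max]

        ccg = cross_correlogram(train(+1), train(-1), bin_s=0.005)
        lag = ccg.lag_centers_ms
        center = ccg.probability[np.abs(lag) < 15].mean()
        side = ccg.probability[(np.abs(lag) > 50) & (np.abs(lag) < 75)].mean()
        far = ccg.probability[(np.abs(lag) > 110) & (np.abs(lag) < 140)].mean()
        assert side > center  # phase opposition: trough at lag 0
        assert side > far  # ~125-ms periodicity: next trough near 125 ms


class TestThetaShiftSurrogates:
    @staticmethod
    def _session(seed=0, coupling=None):
        cfg = synthetic.SessionConfig(
            duration=120.0,
            n_pyr=1,
            n_fsi=1,
            rates={"PYR": 3.0, "MSN": 1.5, "FSI": 12.0, "TAN": 5.0},
            coupling_spec=coupling or [],
            place_depth=0.0,
            seed=seed,
        )
        return cfg, synthetic.generate_session(cfg)

    def test_spike_count_and_phase_multiset_preserved(self):
        cfg, (spikes, cycles, *_ ) = self._session()
        ccg, trains = theta_shift_surrogates(
            spikes[0], spikes[1], cycles, n_surrogates=20, seed=1, return_trains=True
        )
        ref = spikes[0]
        ref = ref[(ref >= cycles.start) & (ref < cycles.stop)]
        orig_phases = np.sort(cycles.phase(ref))
        for tr in trains:
            assert tr.size == ref.size
            np.testing.assert_allclose(
                np.sort(cycles.phase(tr)), orig_phases, atol=1e-9
            )

    def test_coupled_pair_exceeds_band(self):
        cfg, (spikes, cycles, *_ ) = self._session(
            seed=3, coupling=[(0, 1, 4.0, 0.3)]
        )
        ccg = theta_shift_surrogates(
            spikes[0], spikes[1], cycles, n_surrogates=200, seed=0
        )
        assert ccg.exceeds_band((3.2, 8.0))

    def test_uncoupled_pair_mostly_inside_band(self):
        hits = 0
        for seed in range(5):
            _, (spikes, cycles, *_ ) = self._session(seed=seed + 50)
            ccg = theta_shift_surrogates(
                spikes[0], spikes[1], cycles, n_surrogates=200, seed=0
            )
            hits += ccg.exceeds_band((3.2, 8.0))
        assert hits <= 1

    def test_spikes_outside_cycles_warned_and_excluded(self):
        cycles = ThetaCycles(np.arange(0.0, 1.01, 0.125))
        ref = np.array([0.2, 0.5, 5.0])  # last spike outside coverage
        tgt = np.array([0.3, 0.6])
        with pytest.warns(UserWarning, match="outside covered"):
            ccg, trains = theta_shift_surrogates(
                ref, tgt, cycles, n_surrogates=5, seed=0, return_trains=True
            )
        assert all(tr.size == 2 for tr in trains)


class TestRateScores:
    def test_full_suppression_is_minus_one(self):
        spikes = np.array([1.0, 2.0, 3.0])  # only during OFF
        assert light_rate_score(spikes, [(10.0, 20.0)], [(0.0, 10.0)]) == -1.0

    def test_equal_rates_zero(self):
        spikes = np.arange(0.0, 20.0, 0.5)
        s = light_rate_score(spikes, [(10.0, 20.0)], [(0.0, 10.0)])
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_exchange(self, rng):
        spikes = np.sort(rng.uniform(0.0, 30.0, 300))
        on, off = [(0.0, 10.0)], [(10.0, 30.0)]
        assert light_rate_score(spikes, on, off) == pytest.approx(
            -light_rate_score(spikes, off, on)
        )

    def test_silent_unit_undefined(self):
        s = light_rate_score(np.array([50.0]), [(0.0, 10.0)], [(10.0, 20.0)])
        assert np.isnan(s)

    @pytest.mark.parametrize("factor", [0.0, 0.25, 1.0])
    def test_generator_suppression_closed_form(self, factor):
        fsi = 0
        cfg = synthetic.SessionConfig(
            duration=600.0,
            n_pyr=0,
            n_fsi=1,
            light_epochs=[(200.0, 400.0, {fsi: factor})],
            place_depth=0.0,
            seed=8,
        )
        spikes, *_ = synthetic.generate_session(cfg)
        on = [(200.0, 400.0)]
        off = [(0.0, 200.0), (400.0, 600.0)]
        score = light_rate_score(spikes[fsi], on, off)
        expect = (factor - 1.0) / (factor + 1.0)
        r = cfg.rates["FSI"]
        # delta-method Poisson SE of the score
        a, b = factor * r, r
        var = (2 * b / (a + b) ** 2) ** 2 * a / 200.0 + (
            2 * a / (a + b) ** 2
        ) ** 2 * b / 400.0
        assert abs(score - expect) <= max(3 * np.sqrt(var), 1e-12)


class TestScoreDensity:
    def test_integrates_to_one(self, rng):
        grid, dens = score_density(rng.uniform(-1, 1, 50))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_point_mass_peaks_at_zero(self):
        grid, dens = score_density(np.zeros(10))
        assert abs(grid[np.argmax(dens)]) < 0.01

    def test_bimodal_modes_recovered(self, rng):
        scores = np.concatenate(
            [-0.9 + 0.03 * rng.standard_normal(40), 0.03 * rng.standard_normal(40)]
        )
        grid, dens = score_density(scores)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(dens, height=0.2 * dens.max())
        locs = np.sort(grid[peaks])
        assert np.any(np.abs(locs + 0.9) < 0.1)
        assert np.any(np.abs(locs) < 0.1)


class TestThetaModulationDepth:
    def test_single_phase_gives_one(self):
        assert theta_modulation_depth(np.arange(5.0), np.full(5, 1.3)) == pytest.approx(
            1.0
        )

    def test_uniform_phases_near_zero(self, rng):
        n = 50000
        r = theta_modulation_depth(np.arange(n), rng.uniform(0, 2 * np.pi, n))
        assert r < 5 / np.sqrt(n)

    @pytest.mark.parametrize("kappa", [1.0, 4.0])
    def test_von_mises_closed_form(self, kappa, rng):
        phases = rng.vonmises(0.0, kappa, 30000) % (2 * np.pi)
        r = theta_modulation_depth(np.arange(phases.size), phases)
        assert r == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)

    def test_rotation_invariance(self, rng):
        phases = rng.vonmises(0.0, 2.0, 1000)
        r0 = theta_modulation_depth(np.arange(1000.0), phases)
        r1 = theta_modulation_depth(np.arange(1000.0), (phases + 1.1) % (2 * np.pi))
        assert r0 == pytest.approx(r1, abs=1e-12)


class TestPSPKinetics:
    def test_linear_ramp_rise_time(self):
        fs = 10000.0
        y = np.zeros(1000)
        ramp = np.linspace(0.0, 1.0, 100)  # 0 -> 1 mV over 10 ms
        y[500:600] = ramp
        y[600:] = 1.0
        k = psp_kinetics(y, fs, (0.0, 0.05))
        assert k.event_found
        assert k.amplitude == pytest.approx(1.0, abs=0.02)
        assert k.rise_time_s == pytest.approx(0.006, abs=2e-4)

    def test_equal_pulse_pair_ppr_one(self):
        fs = 10000.0
        y = np.zeros(2000)
        bump = np.exp(-((np.arange(200) - 40.0) ** 2) / 200.0)
        y[500:700] += bump
        y[1200:1400] += bump
        k = psp_kinetics(y, fs, (0.0, 0.04), n_pulses=2)
        assert k.paired_pulse_ratio == pytest.approx(1.0, abs=0.05)

    def test_amplitude_scale_law(self):
        fs = 10000.0
        y = np.zeros(1000)
        y[500:600] = np.linspace(0.0, 1.0, 100)
        y[600:] = 1.0
        k1 = psp_kinetics(y, fs, (0.0, 0.05))
        k3 = psp_kinetics(3.0 * y, fs, (0.0, 0.05))
        assert k3.amplitude == pytest.approx(3.0 * k1.amplitude, rel=1e-6)
        assert k3.rise_time_s == pytest.approx(k1.rise_time_s, rel=1e-6)

    def test_no_event_flagged(self, rng):
        y = 0.01 * rng.standard_normal(1000)
        k = psp_kinetics(y, 10000.0, (0.0, 0.05))
        assert not k.event_found
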
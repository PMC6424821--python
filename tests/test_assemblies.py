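"""Assembly detection, strength tracking and cross-session matching."""
import numpy as np
import pytest

from ca1nac import assemblies, synthetic
from ca1nac.assemblies import (
    AssemblyPattern,
    bin_and_zscore,
    count_significant_patterns,
    detect_activations,
    extract_patterns,
    marcenko_pastur_lambda_max,
    match_across_sessions,
    similarity,
)
from ca1nac.core import PositionTrace, SpikeTrainSet


def _poisson_set(n_neurons, duration, rate, seed):
    rng = np.random.default_rng(seed)
    return SpikeTrainSet(
        {
            i: np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
            for i in range(n_neurons)
        }
    )


class TestBinAndZscore:
    def test_two_level_toy_example(self):
        spikes = SpikeTrainSet({0: np.array([0.010, 0.030]), 1: np.array([])})
        b = bin_and_zscore(spikes, (0.0, 0.1), 0.025)
        assert b.n_bins == 4
        assert b.excluded_ids == [1]
        assert b.neuron_ids == [0]
        np.testing.assert_allclose(b.Z[0], [1.0, 1.0, -1.0, -1.0])

    def test_constant_rows_excluded(self):
        # one spike in every bin: zero count variance
        spikes = SpikeTrainSet(
            {0: np.arange(0.0125, 1.0, 0.025), 1: np.array([0.1, 0.11])}
        )
        b = bin_and_zscore(spikes, (0.0, 1.0), 0.025)
        assert b.excluded_ids == [0]

    def test_all_zero_variance_raises(self):
        spikes = SpikeTrainSet({0: np.array([]), 1: np.array([])})
        with pytest.raises(ValueError, match="zero count variance"):
            bin_and_zscore(spikes, (0.0, 1.0))

    def test_rows_standardized(self):
        b = bin_and_zscore(_poisson_set(5, 100.0, 3.0, 0), (0.0, 100.0))
        np.testing.assert_allclose(b.Z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(b.Z.std(axis=1), 1.0, atol=1e-9)

    def test_half_open_bins(self):
        spikes = SpikeTrainSet({0: np.array([0.025, 0.05]), 1: np.array([0.01, 0.06])})
        b = bin_and_zscore(spikes, (0.0, 0.1), 0.025)
        # spike at exactly 0.025 belongs to the second bin
        counts = b.Z[b.neuron_ids.index(0)]
        assert counts[0] == counts[3]  # bins 0 and 3 both empty


class TestPatternCounting:
    def test_mp_bound_formula(self):
        assert marcenko_pastur_lambda_max(100, 100) == pytest.approx(4.0)

    def test_precondition_bins_exceed_neurons(self):
        spikes = _poisson_set(30, 0.7, 50.0, 0)  # 28 bins < 30 neurons
        b = bin_and_zscore(spikes, (0.0, 0.7))
        with pytest.raises(ValueError, match="more bins than neurons"):
            count_significant_patterns(b)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_independent_poisson_yields_no_patterns(self, seed):
        spikes = _poisson_set(30, 500.0, 5.0, seed)
        b = bin_and_zscore(spikes, (0.0, 500.0))
        assert b.n_bins == 20000
        assert count_significant_patterns(b) == 0

    def test_duplicated_trains_produce_a_pattern(self):
        spikes = _poisson_set(20, 500.0, 5.0, 3)
        dup = dict(spikes.trains)
        dup[20] = dup[0].copy()  # a perfect copy of neuron 0
        b = bin_and_zscore(SpikeTrainSet(dup), (0.0, 500.0))
        assert count_significant_patterns(b) >= 1
        # eigen-decomposition oracle: the duplicate pair eigenvalue is ~2
        corr = b.Z @ b.Z.T / b.n_bins
        assert np.linalg.eigvalsh(corr)[-1] == pytest.approx(2.0, abs=0.1)


class TestExtraction:
    def test_single_embedded_assembly_recovered(self):
        cfg = synthetic.SessionConfig(
            duration=600.0,
            n_pyr=40,
            n_msn=0,
            n_fsi=0,
            n_tan=0,
            assembly_spec=[(tuple(range(6)), 2.0, 0.9)],
            place_depth=0.0,
            seed=21,
        )
        spikes, *_ , truth = synthetic.generate_session(cfg)
        b = bin_and_zscore(spikes, (0.0, 600.0))
        n = count_significant_patterns(b)
        assert n == 1
        (pat,) = extract_patterns(b, 1, seed=0)
        assert pat.members == truth.assembly_memberships[0]

    def test_shape_and_determinism(self, recovery_session):
        _, (spikes, _, _, _, _) = recovery_session
        b = bin_and_zscore(spikes, (0.0, 1200.0))
        n = count_significant_patterns(b)
        pats1 = extract_patterns(b, n, seed=4)
        pats2 = extract_patterns(b, n, seed=4)
        assert len(pats1) == n
        for p, q in zip(pats1, pats2):
            assert p.w.size == b.n_neurons
            np.testing.assert_array_equal(p.w, q.w)
            assert np.linalg.norm(p.w) == pytest.approx(1.0)
            assert p.w[np.argmax(np.abs(p.w))] > 0

    def test_recovered_patterns_mutually_distinct(self, recovery_session):
        """Recovered patterns resemble their matched truth more than each
        other (near-orthogonal ground-truth memberships)."""
        cfg, (spikes, _, _, _, truth) = recovery_session
        b = bin_and_zscore(spikes, (0.0, 1200.0))
        pats = extract_patterns(b, 5, seed=0)
        truths = [
            AssemblyPattern(
                np.isin(b.neuron_ids, sorted(m)).astype(float), b.neuron_ids
            )
            for m in truth.assembly_memberships
        ]
        S, matching = match_across_sessions(pats, truths)
        matched = np.mean([S[i, j] for i, j in matching])
        cross = np.mean(
            [similarity(pats[i], pats[j]) for i in range(5) for j in range(i + 1, 5)]
        )
        assert cross < matched

    def test_invalid_n_patterns(self):
        b = bin_and_zscore(_poisson_set(5, 50.0, 5.0, 0), (0.0, 50.0))
        with pytest.raises(ValueError):
            extract_patterns(b, 0)
        with pytest.raises(ValueError):
            extract_patterns(b, 6)


class TestActivationStrength:
    def test_brute_force_oracle(self, rng):
        """A(t) equals sum_{i != j} w_i w_j z_i z_j to 1e-9 on 5 neurons."""
        spikes = _poisson_set(5, 20.0, 8.0, 9)
        w = rng.standard_normal(5)
        pat = AssemblyPattern(w, [0, 1, 2, 3, 4])
        trace = assemblies.activation_strength(pat, spikes, (0.0, 20.0), step=0.005)
        _, z, _ = assemblies._smoothed_zscored_rates(
            spikes, [0, 1, 2, 3, 4], (0.0, 20.0), assemblies.DEFAULT_KERNEL_SD_S, 0.005
        )
        w = pat.w
        brute = np.zeros(z.shape[1])
        for i in range(5):
            for j in range(5):
                if i != j:
                    brute += w[i] * w[j] * z[i] * z[j]
        np.testing.assert_allclose(trace.strength, brute, atol=1e-9)

    def test_single_active_neuron_gives_zero(self):
        spikes = SpikeTrainSet(
            {0: np.array([0.3, 0.5, 0.9]), 1: np.array([]), 2: np.array([])}
        )
        pat = AssemblyPattern([1.0, 1.0, 1.0], [0, 1, 2])
        trace = assemblies.activation_strength(pat, spikes, (0.0, 1.0))
        np.testing.assert_allclose(trace.strength, 0.0, atol=1e-12)

    def test_synchronous_pair_peaks_at_event(self):
        t_ev = 0.5
        spikes = SpikeTrainSet(
            {
                0: np.array([t_ev]),
                1: np.array([t_ev]),
            }
        )
        pat = AssemblyPattern([1.0, 1.0], [0, 1])
        trace = assemblies.activation_strength(pat, spikes, (0.0, 1.0))
        i_peak = np.argmax(trace.strength)
        assert abs(trace.times[i_peak] - t_ev) < 0.01
        # peak height matches the explicit quadratic form z^T P z
        _, z, _ = assemblies._smoothed_zscored_rates(
            spikes, [0, 1], (0.0, 1.0), assemblies.DEFAULT_KERNEL_SD_S, 0.001
        )
        P = pat.projector()
        expect = np.einsum("it,ij,jt->t", z, P, z)
        np.testing.assert_allclose(trace.strength, expect, atol=1e-9)

    def test_anticorrelated_members_nonpositive(self):
        spikes = SpikeTrainSet(
            {0: np.arange(0.1, 5.0, 0.4), 1: np.arange(0.3, 5.0, 0.4)}
        )
        pat = AssemblyPattern([1.0, 1.0], [0, 1])
        trace = assemblies.activation_strength(pat, spikes, (0.0, 5.0))
        spike_idx = np.searchsorted(trace.times, spikes[0])
        spike_idx = spike_idx[spike_idx < trace.strength.size]
        assert np.all(trace.strength[spike_idx] <= 1e-9)

    def test_missing_pattern_neuron_raises(self):
        spikes = SpikeTrainSet({0: np.array([0.1])})
        pat = AssemblyPattern([1.0, 1.0], [0, 5])
        with pytest.raises(ValueError, match="absent"):
            assemblies.activation_strength(pat, spikes, (0.0, 1.0))


class TestDetectActivations:
    def test_constant_below_threshold(self):
        tr = assemblies.ActivationTrace(np.arange(100) * 0.001, np.full(100, 4.9))
        assert detect_activations(tr).size == 0

    def test_single_sample_above(self):
        s = np.full(100, 1.0)
        s[50] = 5.1
        tr = assemblies.ActivationTrace(np.arange(100) * 0.001, s)
        peaks = detect_activations(tr)
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(0.050)

    def test_embedded_event_rate_recovered(self):
        """Detected activation rate tracks the embedded event rate.

        Chance near-coincidences of two co-members also clear the
        strength threshold (a genuine co-activation, but not an embedded
        event), so the clean probe of event recovery uses a sparse
        background (0.5 Hz baseline) where such coincidences are rare.
        """
        cfg = synthetic.SessionConfig(
            duration=600.0,
            n_pyr=20,
            rates={"PYR": 0.5, "MSN": 1.5, "FSI": 12.0, "TAN": 5.0},
            assembly_spec=[(tuple(range(6)), 1.0, 0.9)],
            place_depth=0.0,
            seed=13,
        )
        spikes, *_ , truth = synthetic.generate_session(cfg)
        b = bin_and_zscore(spikes, (0.0, 600.0))
        (pat,) = extract_patterns(b, 1, seed=0)
        trace = assemblies.activation_strength(pat, spikes, (0.0, 600.0))
        peaks = detect_activations(trace)
        embedded = truth.event_times[0].size / 600.0
        assert peaks.size / 600.0 == pytest.approx(embedded, rel=0.2)

    def test_rate_monotone_in_participation(self):
        rates = []
        for part in (0.3, 0.6, 0.9):
            cfg = synthetic.SessionConfig(
                duration=300.0,
                n_pyr=20,
                assembly_spec=[(tuple(range(6)), 1.0, part)],
                place_depth=0.0,
                seed=17,
            )
            spikes, *_ = synthetic.generate_session(cfg)
            b = bin_and_zscore(spikes, (0.0, 300.0))
            (pat,) = extract_patterns(b, 1, seed=0)
            trace = assemblies.activation_strength(pat, spikes, (0.0, 300.0))
            rates.append(detect_activations(trace).size)
        assert rates[0] <= rates[1] <= rates[2]


class TestAssemblyMap:
    def _still_position(self):
        t = np.arange(0.0, 10.0, 0.04)
        return PositionTrace(t, np.full(t.size, 5.0), np.full(t.size, 5.0))

    def test_peaks_in_single_bin(self):
        pos = self._still_position()
        rate, xe, ye = assemblies.assembly_map([1.0, 2.0, 3.0], pos, 4.0)
        assert np.nansum(rate > 0) == 1

    def test_no_peaks_zero_map(self):
        pos = self._still_position()
        rate, _, _ = assemblies.assembly_map([], pos, 4.0)
        visited = ~np.isnan(rate)
        assert visited.any()
        assert np.all(rate[visited] == 0)

    def test_uncovered_peaks_raise(self):
        pos = self._still_position()
        with pytest.raises(ValueError, match="cover"):
            assemblies.assembly_map([99.0], pos, 4.0)


class TestSimilarityAndMatching:
    def test_identity_orthogonal_and_sign(self):
        a = AssemblyPattern([1.0, 0.0, 0.0], [0, 1, 2])
        b = AssemblyPattern([0.0, 1.0, 0.0], [0, 1, 2])
        assert similarity(a, a) == pytest.approx(1.0)
        assert similarity(a, b) == pytest.approx(0.0)
        flipped = AssemblyPattern(-a.w, [0, 1, 2])
        assert similarity(a, flipped) == pytest.approx(1.0)

    def test_disjoint_neuron_sets_raise(self):
        a = AssemblyPattern([1.0, 1.0], [0, 1])
        b = AssemblyPattern([1.0, 1.0], [2, 3])
        with pytest.raises(ValueError, match="share no neurons"):
            similarity(a, b)

    def test_self_matching_is_identity(self, rng):
        pats = [
            AssemblyPattern(rng.standard_normal(8), list(range(8))) for _ in range(4)
        ]
        S, matching = match_across_sessions(pats, pats)
        assert matching == [(i, i) for i in range(4)]
        assert all(S[i, i] == pytest.approx(1.0) for i in range(4))

    def test_permutation_recovered(self, rng):
        pats = [
            AssemblyPattern(rng.standard_normal(8), list(range(8))) for _ in range(4)
        ]
        perm = [2, 0, 3, 1]
        S, matching = match_across_sessions(pats, [pats[p] for p in perm])
        assert sorted(matching) == sorted((perm[j], j) for j in range(4))

    def test_independent_sessions_less_similar_than_identical(self):
        rng = np.random.default_rng(0)
        pats_a = [
            AssemblyPattern(rng.standard_normal(30), list(range(30)))
            for _ in range(5)
        ]
        pats_b = [
            AssemblyPattern(rng.standard_normal(30), list(range(30)))
            for _ in range(5)
        ]
        S_same, m_same = match_across_sessions(pats_a, pats_a)
        S_ind, m_ind = match_across_sessions(pats_a, pats_b)
        mean_same = np.mean([S_same[i, j] for i, j in m_same])
        mean_ind = np.mean([S_ind[i, j] for i, j in m_ind])
        # shuffled-weight null: shuffling entries of a's weights gives the
        # same distribution of |inner products| as genuinely unrelated b's
        null = []
        for _ in range(200):
            w = pats_a[0].w.copy()
            rng.shuffle(w)
            null.append(similarity(AssemblyPattern(w, list(range(30))), pats_a[0]))
        assert mean_ind < mean_same - 0.5
        assert abs(mean_ind - np.mean(null)) < 0.25
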
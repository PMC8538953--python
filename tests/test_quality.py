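import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppg_hrv import quality as q
from ppg_hrv.scalogram_ridges import RidgeLine


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestCorrelationSimilarity:
    def test_self_similarity_is_one(self):
        x = np.sin(np.linspace(0, 4, 80))
        assert q.correlation_similarity(x, x) == pytest.approx(1.0)

    def test_anticorrelation_clipped_to_zero(self):
        x = np.sin(np.linspace(0, 4, 80))
        assert q.correlation_similarity(x, -x) == 0.0

    def test_same_shape_different_length(self):
        t1 = np.linspace(0, 1, 60)
        t2 = np.linspace(0, 1, 110)
        shape = lambda t: np.exp(-((t - 0.3) ** 2) / 0.02)
        assert q.correlation_similarity(shape(t1), shape(t2)) == \
            pytest.approx(1.0, abs=5e-3)

    def test_constant_chunk_scores_zero(self):
        assert q.correlation_similarity(np.ones(30), np.sin(np.arange(30))) == 0.0


class TestAmplitudeSimilarity:
    def test_equal_amplitudes(self):
        x = np.array([0.0, 1.0])
        assert q.amplitude_similarity(x, x) == pytest.approx(sigmoid(5.0))
        assert sigmoid(5.0) == pytest.approx(0.9933, abs=1e-4)

    def test_ratio_three_and_half_is_half(self):
        assert q.amplitude_similarity(np.array([0.0, 3.5]),
                                      np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_ratio_five(self):
        val = q.amplitude_similarity(np.array([0.0, 5.0]), np.array([0.0, 1.0]))
        assert val == pytest.approx(sigmoid(-3.0))
        assert val == pytest.approx(0.0474, abs=1e-4)

    def test_zero_amplitude_scores_zero(self):
        assert q.amplitude_similarity(np.zeros(10), np.array([0.0, 1.0])) == 0.0


class TestSimilarityQuality:
    def _train(self, n_beats=6, period=80):
        t = np.arange(n_beats * period) / 100.0
        x = np.zeros(t.size)
        for b in range(n_beats):
            x += np.exp(-((t - (b + 0.5) * period / 100.0) ** 2) / 0.02)
        peaks = np.array([(b + 0.5) * period for b in range(n_beats)], dtype=int)
        return x, peaks

    def test_identical_pulses_uniform_quality(self):
        x, peaks = self._train()
        qs = q.similarity_quality(x, peaks)
        # s_corr = 1, s_amp = sigmoid(5) => every s = sqrt(sigmoid(5))
        expected = np.sqrt(sigmoid(5.0))
        np.testing.assert_allclose(qs, expected, atol=2e-3)
        assert expected == pytest.approx(0.9966, abs=1e-4)

    def test_uncorrelated_middle_interval_scores_zero(self):
        x, peaks = self._train()
        rng = np.random.default_rng(0)
        # destroy the waveform inside the middle interval
        x[peaks[2]:peaks[3]] = rng.normal(size=peaks[3] - peaks[2])
        qs = q.similarity_quality(x, peaks)
        # the middle interval correlates with neither neighbour
        assert qs[2] < 0.4

    def test_end_intervals_use_single_neighbor(self):
        x, peaks = self._train(n_beats=4)
        qs = q.similarity_quality(x, peaks)
        # q[0] = s_2 and q[-1] = s_n exactly (no geometric mean)
        s2 = q.shape_similarity(x[peaks[0]:peaks[1] + 1],
                                x[peaks[1]:peaks[2] + 1])
        assert qs[0] == pytest.approx(s2)

    def test_single_interval_scores_zero(self):
        assert q.similarity_quality(np.sin(np.arange(200) / 10),
                                    np.array([10, 150]))[0] == 0.0


class TestCwtQuality:
    def _line(self, ks, positions):
        return RidgeLine(np.asarray(ks), np.asarray(positions))

    def test_parallel_lines_near_one(self):
        a = self._line(range(0, 50), [100] * 50)
        b = self._line(range(0, 50), [180] * 50)
        assert q.cwt_quality(a, b, 100.0) == pytest.approx(sigmoid(10.0))

    def test_spread_fifty_ms_is_half(self):
        # two shared levels with distances 100 and 200 samples at 100 Hz:
        # std = 50 samples = 500 ms ... scale down: distances 5 and 15
        # samples -> std 5 samples = 50 ms -> sigmoid(0) = 0.5
        a = self._line([0, 1], [0, 0])
        b = self._line([0, 1], [5, 15])
        assert q.cwt_quality(a, b, 100.0) == pytest.approx(0.5)

    def test_diverging_lines_near_zero(self):
        # separation ramps over 380 ms across the shared scales; the
        # oracle std of that ramp is ~113 ms >> 50 ms center
        a = self._line(range(0, 20), [0] * 20)
        b = self._line(range(0, 20), 100 + 2 * np.arange(20))
        d_ms = (100 + 2 * np.arange(20)) * 10.0
        expected = sigmoid((50.0 - np.std(d_ms)) / 5.0)
        assert q.cwt_quality(a, b, 100.0) == pytest.approx(expected)
        assert expected < 0.01

    def test_as_printed_flips_direction(self):
        a = self._line(range(0, 50), [100] * 50)
        b = self._line(range(0, 50), [180] * 50)
        assert q.cwt_quality(a, b, 100.0, as_printed=True) == \
            pytest.approx(sigmoid(-10.0))

    def test_too_few_shared_levels(self):
        a = self._line([0, 1, 2], [10, 10, 10])
        b = self._line([10, 11], [50, 50])
        assert q.cwt_quality(a, b, 100.0) == 0.0


def exhaustive_cutoff(qualities, rigid=0.8):
    """Independent brute-force of the adaptive threshold rule."""
    surv = sorted([x for x in qualities if x > rigid], reverse=True)
    if not surv:
        return None
    best_i, best_prod = 0, -np.inf
    for i in range(1, len(surv) + 1):
        prod = i * surv[i - 1]
        if prod >= best_prod:  # ties toward larger i
            best_prod, best_i = prod, i
    return surv[best_i - 1]


class TestAdaptiveThreshold:
    @pytest.mark.parametrize("qs,expected_kept", [
        ([0.9, 0.9, 0.9], [True, True, True]),
        ([1.0, 0.85], [True, True]),
        ([0.99, 0.99, 0.81], [True, True, True]),
        ([0.99, 0.99, 0.5], [True, True, False]),
        ([0.5, 0.6], [False, False]),
    ])
    def test_worked_examples(self, qs, expected_kept):
        kept, _ = q.adaptive_threshold_filter(np.array(qs))
        assert kept.tolist() == expected_kept

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=40))
    def test_matches_exhaustive_search(self, qs):
        kept, cutoff = q.adaptive_threshold_filter(np.array(qs))
        expected = exhaustive_cutoff(qs)
        if expected is None:
            assert not kept.any() and np.isnan(cutoff)
        else:
            assert cutoff == pytest.approx(expected)
            manual = [(x > 0.8) and (x >= expected) for x in qs]
            assert kept.tolist() == manual


def outlier_transcription(rr):
    """Independent literal transcription of the outlier rules, written
    as four separate passes over 1-based pseudocode indices."""
    n = len(rr)
    marked = set()
    for i in range(n):
        window = [rr[j] for j in range(max(0, i - 13), min(n, i + 14))]
        p10 = np.percentile(window, 10)
        m = np.percentile(window, 50)
        p90 = np.percentile(window, 90)
        amp = p90 - p10
        if i + 1 < n:
            rrmax, rrmin = max(rr[i], rr[i + 1]), min(rr[i], rr[i + 1])
            if (rrmin < min(m - 50, p10 - 0.2 * amp)
                    and rrmax > max(m + 50, p90 + 0.2 * amp)
                    and p10 < (rrmax + rrmin) / 2 < p90):
                marked.add(i)
                marked.add(i + 1)
            if rr[i] < m * 0.7 and rr[i + 1] < m * 0.7 \
                    and p10 < rr[i] + rr[i + 1] < p90:
                marked.add(i)
                marked.add(i + 1)
        if rr[i] > 1.6 * m:
            marked.add(i)
        if rr[i] < min(0.7 * m, p10):
            marked.add(i)
    return np.array([i in marked for i in range(n)]) if n >= 2 \
        else np.zeros(n, dtype=bool)


class TestOutlierFilter:
    def test_constant_sequence_clean(self):
        assert not q.outlier_filter(np.full(30, 800.0)).any()

    def test_long_interval_flagged(self):
        rr = np.full(30, 800.0)
        rr[15] = 1400.0
        flags = q.outlier_filter(rr)
        assert flags[15] and flags.sum() == 1

    def test_spike_pair_flagged(self):
        # background needs natural variability so p10 < midpoint < p90
        # holds strictly; a short/long pair splitting one beat is then
        # caught by the spike-pair rule
        rng = np.random.default_rng(1)
        rr = 800.0 + rng.uniform(-30, 30, size=30)
        rr[14], rr[15] = 400.0, 1200.0
        flags = q.outlier_filter(rr)
        assert flags[14] and flags[15]

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.floats(300.0, 2000.0), min_size=0, max_size=60))
    def test_matches_independent_transcription(self, rr):
        np.testing.assert_array_equal(q.outlier_filter(np.array(rr)),
                                      outlier_transcription(rr))


class TestAssessIntervals:
    def _lines(self, peaks):
        return [RidgeLine(np.arange(50), np.full(50, p)) for p in peaks]

    def test_zero_cwt_quality_forces_discard(self):
        t = np.arange(800) / 100.0
        x = np.zeros(t.size)
        peaks = np.array([50, 130, 210, 290, 370, 450, 530, 610])
        for p in peaks:
            x += np.exp(-((t - p / 100.0) ** 2) / 0.02)
        lines = self._lines(peaks)
        # give one bounding line a wildly bending shape
        lines[3] = RidgeLine(np.arange(50),
                             (peaks[3] + np.arange(50) * 2).astype(int))
        out = q.assess_intervals(x, peaks, lines, 100.0)
        assert not out[2].kept and not out[3].kept
        assert out[0].kept

    def test_quality_bounded_by_components(self):
        t = np.arange(800) / 100.0
        x = np.sin(2 * np.pi * 1.2 * t)
        peaks = np.arange(40, 800, 83)
        lines = self._lines(peaks)
        for iq in q.assess_intervals(x, peaks, lines, 100.0):
            assert 0.0 <= iq.q <= 1.0
            assert iq.q <= iq.q_sim + 1e-12
            assert iq.q <= iq.q_cwt + 1e-12
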
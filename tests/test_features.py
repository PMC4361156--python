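import math

import numpy as np
import pytest

import swallowkit as sk
from swallowkit.errors import DegenerateSignalError, ParameterError


class TestTimeMoments:
    def test_symmetric_signal_has_zero_skewness(self):
        x = np.tile([-1.0, 1.0], 50)
        skew, kurt = sk.time_moments(x)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0, rel=1e-9)  # two-point distribution

    def test_gaussian_kurtosis_is_three(self, rng):
        _, kurt = sk.time_moments(rng.standard_normal(10**6))
        assert 2.95 <= kurt <= 3.05

    def test_exponential_skewness_is_two(self, rng):
        skew, _ = sk.time_moments(rng.exponential(size=10**6))
        assert 1.9 <= skew <= 2.1

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sk.time_moments(np.full(10, 3.0))


class TestQuantize:
    def test_uniform_ramp_fills_levels_evenly(self):
        q = sk.quantize(np.linspace(0.0, 1.0, 1000), levels=10)
        counts = np.bincount(q.symbols, minlength=10)
        np.testing.assert_array_equal(counts, np.full(10, 100))

    def test_two_valued_signal_maps_to_extremes(self):
        q = sk.quantize(np.tile([0.0, 5.0], 20), levels=10)
        assert set(np.unique(q.symbols)) == {0, 9}

    def test_max_maps_to_top_level(self, rng):
        q = sk.quantize(rng.standard_normal(1000), levels=100)
        assert q.symbols.min() == 0
        assert q.symbols.max() == 99

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sk.quantize(np.zeros(100), levels=10)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "symbols,expected",
        [
            (np.zeros(50, dtype=int), 0.0),
            (np.repeat(np.arange(10), 7), math.log(10)),
            (np.array([0, 0, 1, 2]), 1.0397207708399179),
        ],
    )
    def test_closed_forms(self, symbols, expected):
        assert sk.shannon_entropy(symbols) == pytest.approx(expected, abs=1e-12)


def _brute_force_entropy_rate(symbols, levels, max_len):
    """Oracle: literal L-gram dictionary counting with Python dicts."""
    n = len(symbols)
    counts1 = {}
    for s in symbols:
        counts1[s] = counts1.get(s, 0) + 1
    se1 = -sum((c / n) * math.log(c / n) for c in counts1.values())
    if se1 == 0:
        return 1.0
    best = math.inf
    prev_se = 0.0
    for L in range(1, max_len + 1):
        grams = {}
        m = n - L + 1
        for i in range(m):
            g = tuple(symbols[i : i + L])
            grams[g] = grams.get(g, 0) + 1
        se = -sum((c / m) * math.log(c / m) for c in grams.values())
        ce = se - prev_se
        perc = sum(1 for c in grams.values() if c == 1) / m
        best = min(best, (ce + perc * se1) / se1)
        prev_se = se
    return min(1.0, max(0.0, 1.0 - best))


class TestEntropyRate:
    def test_constant_sequence_is_perfectly_regular(self):
        seq = sk.QuantizedSequence(np.full(10**4, 4, dtype=int), levels=10)
        assert sk.entropy_rate(seq) == 1.0

    def test_iid_sequence_is_nearly_random(self, rng):
        seq = sk.QuantizedSequence(rng.integers(0, 10, 10**6), levels=10)
        assert sk.entropy_rate(seq) <= 0.05

    def test_repeating_pattern_is_regular(self):
        seq = sk.QuantizedSequence(np.tile(np.arange(10), 1000), levels=10)
        assert sk.entropy_rate(seq) >= 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of regular and random stretches
        sym = np.concatenate(
            [np.tile([0, 1, 2], 60), rng.integers(0, 10, 150)]
        )
        seq = sk.QuantizedSequence(sym, levels=10)
        expected = _brute_force_entropy_rate(sym.tolist(), 10, 6)
        assert sk.entropy_rate(seq, max_pattern_len=6) == pytest.approx(
            expected, abs=1e-12
        )

    def test_short_sequence_rejected(self):
        seq = sk.QuantizedSequence(np.arange(5) % 3, levels=10)
        with pytest.raises(ParameterError):
            sk.entropy_rate(seq, max_pattern_len=10)


def _brute_force_lz_phrases(symbols):
    """Oracle parser: accumulate the phrase list by linear scanning."""
    phrases = []
    current = []
    for s in symbols:
        current.append(s)
        if current not in phrases:
            phrases.append(list(current))
            current = []
    if current:  # trailing prefix already seen as a phrase
        phrases.append(list(current))
    return phrases


class TestLZComplexity:
    def test_single_symbol_is_zero(self):
        seq = sk.QuantizedSequence(np.array([7]), levels=100)
        assert sk.lz_complexity(seq) == 0.0

    def test_alternating_sequence_matches_oracle(self):
        sym = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        k = len(_brute_force_lz_phrases(sym.tolist()))
        expected = k * math.log(10) / math.log(100) / 10
        seq = sk.QuantizedSequence(sym, levels=100)
        assert sk.lz_complexity(seq) == pytest.approx(expected, abs=1e-12)

    def test_iid_complexity_near_one(self, rng):
        seq = sk.QuantizedSequence(rng.integers(0, 100, 10**4), levels=100)
        assert 0.8 <= sk.lz_complexity(seq) <= 1.2


class TestSpectralFeatures:
    def test_pure_tone_at_bin(self):
        fs, n = 1000.0, 10000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 100.0 * t)
        peak, centre, bw, summary = sk.spectral_features(x, fs)
        bin_hz = fs / n
        assert peak == pytest.approx(100.0, abs=bin_hz)
        assert centre == pytest.approx(100.0, abs=bin_hz)
        assert bw <= bin_hz
        assert summary.freqs[0] == 0.0 and summary.freqs[-1] == fs / 2

    def test_two_equal_tones_symmetric(self):
        fs, n = 1000.0, 10000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t)
        _, centre, bw, _ = sk.spectral_features(x, fs)
        bin_hz = fs / n
        assert centre == pytest.approx(200.0, abs=bin_hz)
        assert bw == pytest.approx(100.0, abs=bin_hz)

    def test_white_noise_moments_of_uniform_mass(self, rng):
        x = rng.standard_normal(2**18)
        _, centre, bw, _ = sk.spectral_features(x, 1000.0)
        assert centre == pytest.approx(250.0, abs=5.0)
        assert bw == pytest.approx(500.0 / math.sqrt(12.0), abs=5.0)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(4096)
        _, c1, b1, _ = sk.spectral_features(x, 1000.0)
        _, c2, b2, _ = sk.spectral_features(100.0 * x, 1000.0)
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_all_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sk.spectral_features(np.zeros(100), 1000.0)


class TestWaveletFeatures:
    def test_near_dc_signal_has_near_zero_entropy(self):
        t = np.arange(2**14)
        x = np.sin(2 * np.pi * t / 2**13)  # nearly all energy in approximation
        _, _, rel, entropy = sk.wavelet_features(x, levels=10)
        assert rel[0] > 0.99
        assert entropy < 0.1

    def test_relative_energies_sum_to_one(self, rng):
        _, _, rel, _ = sk.wavelet_features(rng.standard_normal(5000), levels=10)
        assert rel.sum() == pytest.approx(1.0, rel=1e-9)

    def test_white_noise_half_energy_in_finest_detail(self, rng):
        _, _, rel, _ = sk.wavelet_features(rng.standard_normal(2**15), levels=10)
        assert rel[-1] == pytest.approx(0.5, abs=0.05)

    def test_energy_conservation(self, rng):
        x = rng.standard_normal(2**13)
        energies, total, _, _ = sk.wavelet_features(x, levels=10)
        assert total == pytest.approx(energies.sum(), rel=1e-6)
        assert total == pytest.approx(np.sum(x**2), rel=0.01)

    def test_all_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sk.wavelet_features(np.zeros(4096))


class TestExtractFeatures:
    def test_cardinality_one_segment_three_channels(self, rng):
        rec = sk.MultiChannelRecording(
            fs=2000.0,
            channels={c: rng.standard_normal(6000) for c in ("AP", "SI", "SOUND")},
            subject=sk.SubjectMeta("S1", "male", 40.0),
        )
        seg = [sk.SwallowSegment.from_samples(1000, 5000, 2000.0)]
        table = sk.extract_features(rec, seg)
        assert len(table) == 3 * 8 + 1
        dur = table[table.feature == "duration_s"]
        assert len(dur) == 1
        assert dur.iloc[0]["value"] == pytest.approx(2.0)

    def test_identical_channels_identical_spectral_features(self):
        t = np.arange(8000) / 2000.0
        tone = np.sin(2 * np.pi * 100 * t)
        rec = sk.MultiChannelRecording(
            fs=2000.0,
            channels={c: tone.copy() for c in ("AP", "SI", "SOUND")},
            subject=sk.SubjectMeta("S1", "female", 25.0),
        )
        seg = [sk.SwallowSegment.from_samples(0, 8000, 2000.0)]
        table = sk.extract_features(rec, seg)
        for feat in ("peak_freq_hz", "centre_freq_hz", "bandwidth_hz"):
            vals = table[table.feature == feat]["value"].to_numpy()
            assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)

    def test_generator_burst_centroid_roundtrip(self):
        params = sk.BurstParams(duration_s=2.0, centroid_hz=150.0)
        x = sk.gen_swallow_burst(params, fs=4000.0, seed=17)
        rec = sk.MultiChannelRecording(
            fs=4000.0,
            channels={"AP": x},
            subject=sk.SubjectMeta("S1", "female", 25.0),
        )
        seg = [sk.SwallowSegment.from_samples(0, len(x), 4000.0)]
        table = sk.extract_features(rec, seg)
        centre = table[table.feature == "centre_freq_hz"]["value"].iloc[0]
        assert centre == pytest.approx(150.0, rel=0.15)

    def test_degenerate_segment_yields_nan_not_crash(self):
        x = np.zeros(4000)
        x[:100] = 1.0
        rec = sk.MultiChannelRecording(
            fs=2000.0,
            channels={"AP": x},
            subject=sk.SubjectMeta("S1", "female", 25.0),
        )
        segs = [sk.SwallowSegment.from_samples(2000, 4000, 2000.0)]  # all-zero span
        table = sk.extract_features(rec, segs)
        vals = table[table.feature != "duration_s"]["value"]
        assert vals.isna().all()
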
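"""Feature extraction: turns-amplitude, Willison rate, energy, entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgipa import (
    EMGRecording,
    detect_turns,
    extract_features,
    mean_interspike_amplitude,
    peak_ratio,
    permutation_entropy,
    signal_energy,
    turns_per_second,
    willison_rate,
)
from emgipa.features import PEConfig, FEATURE_NAMES

from conftest import make_recording
from oracles import (
    energy_oracle,
    permutation_entropy_oracle,
    turns_oracle,
    willison_rate_oracle,
)


# ---------------------------------------------------------------------------
# turn detection
# ---------------------------------------------------------------------------

class TestDetectTurns:
    def test_constant_signal_has_no_turns(self):
        ts = detect_turns(make_recording(np.full(100, 42.0)))
        assert len(ts) == 0

    def test_subthreshold_peak_is_ignored(self):
        # single triangular bump of 50 µV never crosses the 100 µV rule
        x = np.concatenate([np.linspace(0, 50, 10), np.linspace(50, 0, 10)])
        assert len(detect_turns(make_recording(x))) == 0

    def test_triangle_wave_turns_match_oracle_and_periodicity(self):
        # ±100 µV triangle, 5 periods: one max + one min per period, but
        # the trailing reversal is unconfirmed at the record edge
        from scipy.signal import sawtooth

        t = np.arange(0, 1, 1 / 1000)
        x = 100 * sawtooth(2 * np.pi * 5 * t, 0.5)
        ts = detect_turns(make_recording(x, fs=1000.0))
        oracle = turns_oracle(x, 100.0)
        assert list(ts.indices) == [i for i, _ in oracle]
        assert 2 * 5 - 2 <= len(ts) <= 2 * 5

    def test_turn_sequence_invariants_on_noise(self, noise_recording):
        ts = detect_turns(noise_recording)
        assert np.all(np.diff(ts.indices) > 0)
        d = np.diff(ts.amplitudes)
        assert np.all(np.abs(d) >= ts.threshold)
        assert np.all(d[1:] * d[:-1] < 0)  # alternating maxima/minima

    def test_matches_bruteforce_oracle_on_many_random_signals(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(5, 400))
            scale = rng.choice([30.0, 80.0, 200.0])
            x = np.cumsum(rng.normal(0, scale, size=n))
            ts = detect_turns(make_recording(x), threshold=100.0)
            expect = turns_oracle(x, 100.0)
            assert list(ts.indices) == [i for i, _ in expect]
            assert list(ts.amplitudes) == [v for _, v in expect]

    @given(st.lists(st.integers(-300, 300), min_size=2, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_matches_oracle_on_integer_signals_with_ties(self, values):
        x = np.asarray(values, float)
        ts = detect_turns(make_recording(x), threshold=100.0)
        expect = turns_oracle(x, 100.0)
        assert list(ts.indices) == [i for i, _ in expect]

    def test_offset_invariance(self, noise_recording):
        shifted = make_recording(noise_recording.samples + 1234.5)
        a = detect_turns(noise_recording)
        b = detect_turns(shifted)
        assert list(a.indices) == list(b.indices)


class TestTurnsDerivedFeatures:
    def test_turns_per_second_arithmetic(self):
        ts = detect_turns(make_recording(np.zeros(10)))
        assert turns_per_second(ts, 4.0) == 0.0

    def test_hundred_turns_over_four_seconds(self, noise_recording):
        ts = detect_turns(noise_recording)
        assert turns_per_second(ts, 4.0) == len(ts) / 4.0

    def test_mean_interspike_amplitude_two_turns(self):
        # one full swing +100 -> -100 µV with a confirming rebound
        x = np.array([0.0, 100.0, -100.0, 10.0])
        ts = detect_turns(make_recording(x))
        assert len(ts) == 2
        assert mean_interspike_amplitude(ts) == pytest.approx(200.0)

    def test_square_alternation_constant_differences(self):
        x = np.tile([150.0, -150.0], 8)
        ts = detect_turns(make_recording(x))
        assert mean_interspike_amplitude(ts) == pytest.approx(300.0)

    def test_fewer_than_two_turns_is_flagged_nan(self):
        ts = detect_turns(make_recording(np.zeros(50)))
        assert math.isnan(mean_interspike_amplitude(ts))

    def test_amplitude_matches_oracle_turn_list(self, noise_recording):
        ts = detect_turns(noise_recording)
        vals = [v for _, v in turns_oracle(noise_recording.samples, 100.0)]
        expect = np.mean(np.abs(np.diff(vals)))
        assert mean_interspike_amplitude(ts) == pytest.approx(expect, rel=1e-12)

    def test_peak_ratio(self):
        assert peak_ratio(200.0, 100.0) == pytest.approx(2.0)
        assert peak_ratio(0.0, 123.0) == 0.0
        assert math.isnan(peak_ratio(10.0, math.nan))


# ---------------------------------------------------------------------------
# Willison rate and energy
# ---------------------------------------------------------------------------

class TestWillisonRate:
    def test_constant_signal(self):
        assert willison_rate(make_recording(np.full(100, 5.0))) == 0.0

    def test_steep_ramp_counts_every_difference(self):
        n, fs = 10, 100.0
        rec = make_recording(np.arange(n) * 150.0, fs=fs)
        assert willison_rate(rec) == pytest.approx(fs * (n - 1) / n)

    def test_matches_bruteforce_loop_on_noise(self, noise_recording):
        expect = willison_rate_oracle(noise_recording.samples, 100.0, noise_recording.fs)
        assert willison_rate(noise_recording) == pytest.approx(expect, rel=1e-12)

    def test_strict_threshold_comparison(self):
        # differences exactly equal to the threshold do not count
        rec = make_recording(np.array([0.0, 100.0, 200.0, 300.0]), fs=10.0)
        assert willison_rate(rec, threshold=100.0) == 0.0

    def test_offset_invariance(self, noise_recording):
        shifted = make_recording(noise_recording.samples - 777.0, fs=noise_recording.fs)
        assert willison_rate(shifted) == willison_rate(noise_recording)


class TestSignalEnergy:
    def test_zero_signal(self):
        assert signal_energy(make_recording(np.zeros(100))) == 0.0

    def test_constant_one_millivolt_gives_fs(self):
        fs = 500.0
        rec = make_recording(np.full(1000, 1000.0), fs=fs)  # 1 mV
        assert signal_energy(rec) == pytest.approx(fs)

    def test_matches_bruteforce_sum(self, noise_recording):
        expect = energy_oracle(noise_recording.samples, noise_recording.fs)
        assert signal_energy(noise_recording) == pytest.approx(expect, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=30, derandomize=True)
    def test_absolute_homogeneity(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 50, 400)
        base = signal_energy(make_recording(x))
        assert signal_energy(make_recording(c * x)) == pytest.approx(abs(c) * base, rel=1e-9)


# ---------------------------------------------------------------------------
# permutation entropy
# ---------------------------------------------------------------------------

class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        rec = make_recording(np.arange(50.0))
        for tau in (1, 2, 3):
            assert permutation_entropy(rec, PEConfig(3, tau)) == 0.0

    def test_white_noise_approaches_log2_factorial_bound(self):
        # iid noise populates all 3! rank patterns uniformly
        rng = np.random.default_rng(11)
        rec = make_recording(rng.normal(0, 1, 50_000))
        h = permutation_entropy(rec, PEConfig(3, 1))
        assert h <= math.log2(6) + 1e-12
        assert h == pytest.approx(math.log2(6), abs=0.01)

    def test_seven_point_worked_example(self):
        x = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
        expect = permutation_entropy_oracle(x, 3, 1)
        got = permutation_entropy(make_recording(x), PEConfig(3, 1))
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(1.5219, abs=1e-4)

    def test_matches_exhaustive_oracle_on_random_series(self, rng):
        for n, tau in [(2, 1), (3, 1), (3, 2), (4, 3), (5, 1)]:
            x = rng.normal(0, 1, 300)
            expect = permutation_entropy_oracle(x, n, tau)
            got = permutation_entropy(make_recording(x), PEConfig(n, tau))
            assert got == pytest.approx(expect, abs=1e-12)

    def test_invariance_under_strictly_monotone_transforms(self, rng):
        x = rng.normal(0, 100, 1000)
        cfg = PEConfig(3, 2)
        base = permutation_entropy(make_recording(x), cfg)
        for f in (lambda v: v + 5.0, lambda v: 3.0 * v, np.exp, lambda v: v**3):
            assert permutation_entropy(make_recording(f(x / 100)), cfg) == pytest.approx(
                permutation_entropy(make_recording(x / 100), cfg), abs=1e-12
            )
        assert permutation_entropy(make_recording(x + 5), cfg) == base

    def test_ties_rank_in_temporal_order(self):
        # constant series: every window maps to the identity pattern
        rec = make_recording(np.full(30, 7.0))
        assert permutation_entropy(rec, PEConfig(3, 1)) == 0.0

    def test_normalization_divides_by_order_minus_one(self, rng):
        x = rng.normal(0, 1, 500)
        h = permutation_entropy(make_recording(x), PEConfig(4, 1, normalize=False))
        hn = permutation_entropy(make_recording(x), PEConfig(4, 1, normalize=True))
        assert hn == pytest.approx(h / 3, rel=1e-12)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(make_recording([1.0, 2.0, 3.0]), PEConfig(3, 2))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_zero_signal_flags_undefined_amplitude(self):
        fv = extract_features(make_recording(np.zeros(100)))
        assert fv.turns_per_s == 0.0
        assert fv.energy == 0.0
        assert math.isnan(fv.mean_interspike_amplitude)
        assert not fv.is_complete

    def test_composition_equals_individual_calls(self, noise_recording):
        fv = extract_features(noise_recording)
        ts = detect_turns(noise_recording)
        assert fv.turns_per_s == turns_per_second(ts, noise_recording.duration_s)
        assert fv.mean_interspike_amplitude == mean_interspike_amplitude(ts)
        assert fv.energy == signal_energy(noise_recording)
        assert fv.permutation_entropy == permutation_entropy(noise_recording)
        assert fv.willison_rate == willison_rate(noise_recording)

    def test_determinism_bit_identical(self, noise_recording):
        a = extract_features(noise_recording)
        b = extract_features(noise_recording)
        assert a == b

    def test_feature_vector_field_order_is_canonical(self, noise_recording):
        fv = extract_features(noise_recording)
        assert tuple(fv.as_dict().keys()) == FEATURE_NAMES
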
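import dataclasses

import numpy as np
import pytest

from spikedet import (
    DEFAULT_THRESHOLDS,
    HalfWaveFeatures,
    Thresholds,
    apply_thresholds,
    detect_candidates,
    detect_peaks,
    extract_waveform,
    halfwave_features,
)
from spikedet.synthetic import spike_template


def _plant(templates_at, n, rate=100.0, noise_sd=0.0, seed=0):
    """Zero trace of n samples with spike templates planted at given vertices."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * noise_sd
    for vertex_idx, params in templates_at:
        wf, v = spike_template(*params, rate)
        x[vertex_idx - v:vertex_idx - v + len(wf)] += wf
    return x


class TestDetectPeaks:
    def test_deeper_of_two_close_minima_kept(self):
        rate = 1000.0
        x = np.zeros(1000)
        x[400] = -80.0
        x[450] = -30.0  # 50 ms away, shallower
        peaks = detect_peaks(x, rate)
        assert list(peaks) == [400]

    def test_constant_signal_empty(self):
        assert len(detect_peaks(np.full(500, 3.0), 100.0)) == 0

    def test_planted_vertices_recovered_within_one_sample(self):
        # V-shaped dips of 60 μV depth, ≥ 300 ms apart, in σ = 2 μV noise
        rate = 100.0
        vertices = [100, 150, 220, 300, 380]
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500) * 2.0
        v_shape = np.concatenate([np.linspace(0, -60, 6), np.linspace(-60, 0, 6)[1:]])
        for v in vertices:
            x[v - 5:v + 6] += v_shape
        peaks = detect_peaks(x, rate)
        assert len(peaks) == 5
        for v, p in zip(vertices, peaks):
            assert abs(p - v) <= 1

    def test_separation_enforced(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000) * 30
        peaks = detect_peaks(x, 500.0, min_separation_ms=100.0)
        assert np.all(np.diff(peaks) >= 50)

    def test_invert_flips_polarity(self):
        x = _plant([(100, (60, 80, 40, 60))], 300)
        np.testing.assert_array_equal(
            detect_peaks(x, 100.0), detect_peaks(-x, 100.0, invert=True)
        )


class TestExtractWaveform:
    def test_default_window_is_31_samples_at_100hz(self):
        x = np.zeros(500)
        wf = extract_waveform(x, 100.0, 100)
        assert len(wf) == 31

    def test_vertex_near_edge_discarded(self):
        assert extract_waveform(np.zeros(500), 100.0, 3) is None
        assert extract_waveform(np.zeros(500), 100.0, 495) is None

    def test_alignment_identity(self):
        x = np.arange(500.0)
        wf = extract_waveform(x, 100.0, 123)
        assert wf[10] == x[123]


class TestHalfWaveFeatures:
    def test_hand_constructed_waveform(self):
        # max 40 μV 30 ms before the vertex, vertex −20 μV, max 30 μV 50 ms after
        rate = 1000.0
        wf = np.full(201, -10.0)
        wf[70] = 40.0
        wf[100] = -20.0
        wf[150] = 30.0
        f = halfwave_features(wf, rate, 100)
        assert (f.a1, f.d1, f.a2, f.d2) == (60.0, 30.0, 50.0, 50.0)

    def test_symmetric_wave_has_equal_halfwaves(self):
        wf, v = spike_template(70, 70, 50, 50, 100.0)
        f = halfwave_features(wf, 100.0, v)
        assert f.a1 == pytest.approx(f.a2)
        assert f.d1 == pytest.approx(f.d2)

    def test_monotone_pre_segment_uses_first_sample(self):
        wf = np.concatenate([np.linspace(50, -20, 11), np.linspace(-15, 30, 10)])
        f = halfwave_features(wf, 100.0, 10)
        assert f.a1 == 70.0       # window start is the surrogate maximum
        assert f.d1 == 100.0      # 10 samples at 100 Hz

    def test_vertex_at_edge_rejected(self):
        with pytest.raises(ValueError):
            halfwave_features(np.zeros(31), 100.0, 0)
        with pytest.raises(ValueError):
            halfwave_features(np.zeros(31), 100.0, 30)

    def test_negative_amplitude_invalid(self):
        with pytest.raises(ValueError):
            HalfWaveFeatures(a1=-1, a2=0, d1=10, d2=10)


class TestApplyThresholds:
    @pytest.mark.parametrize(
        "feats,expected",
        [
            ((30, 60, 100, 80), True),    # comfortably inside all ranges
            ((30, 40, 100, 80), False),   # A2 below its 50 μV floor
            ((600, 60, 100, 80), False),  # A1 above the 500 μV ceiling
            ((30, 60, 100, 160), False),  # D2 above 150 ms
            ((20, 50, 200, 150), True),   # inclusive at every boundary
        ],
    )
    def test_threshold_rules(self, feats, expected):
        f = HalfWaveFeatures(*feats)
        assert apply_thresholds(f, DEFAULT_THRESHOLDS) is expected

    def test_min_above_max_invalid(self):
        with pytest.raises(ValueError):
            Thresholds(a1_min=600.0, a1_max=500.0)


@pytest.fixture(scope="module")
def planted_trace():
    rate = 100.0
    spikes = [(200 + 300 * i, (60 + 5 * i, 80, 40, 60)) for i in range(10)]
    # distractors each violating exactly one bound
    distractors = [
        (3400 + 300 * i, params)
        for i, params in enumerate(
            [(650, 80, 40, 60), (60, 650, 40, 60), (60, 30, 40, 60)] * 3
            + [(650, 80, 40, 60)]
        )
    ]
    x = _plant(spikes + distractors, 6500, rate=rate, noise_sd=2.0, seed=4)
    return x, rate, [v for v, _ in spikes], [v for v, _ in distractors]


class TestDetectCandidates:
    def test_planted_recovered_distractors_rejected(self, planted_trace):
        x, rate, spike_v, dis_v = planted_trace
        cands = detect_candidates(x, rate)
        passing = [c.peak_index for c in cands if c.passed]
        hits = sum(any(abs(p - v) <= 1 for p in passing) for v in spike_v)
        false_pass = sum(any(abs(p - v) <= 1 for p in passing) for v in dis_v)
        assert hits >= 9
        assert false_pass == 0

    def test_pure_low_noise_yields_no_passing(self):
        x = np.random.default_rng(5).standard_normal(2000) * 2.0
        cands = detect_candidates(x, 100.0)
        assert sum(c.passed for c in cands) == 0

    def test_vacuous_thresholds_pass_every_contextual_peak(self, planted_trace):
        x, rate, *_ = planted_trace
        relaxed = DEFAULT_THRESHOLDS.relaxed()
        cands = detect_candidates(x, rate, thresholds=relaxed)
        assert all(c.passed for c in cands)
        peaks = detect_peaks(x, rate)
        with_context = [p for p in peaks if 10 <= p < len(x) - 20]
        assert len(cands) == len(with_context)

    def test_features_reproducible_from_stored_waveform(self, planted_trace):
        x, rate, *_ = planted_trace
        for c in detect_candidates(x, rate):
            f = halfwave_features(c.waveform, rate, c.vertex_offset)
            assert f == c.features

    def test_candidates_time_ordered_and_separated(self, planted_trace):
        x, rate, *_ = planted_trace
        times = np.array([c.peak_time for c in detect_candidates(x, rate)])
        assert np.all(np.diff(times) >= 0.1)

    @pytest.mark.parametrize("field,delta", [
        ("a1_min", -5.0), ("a2_min", -5.0), ("a1_max", 100.0),
        ("a2_max", 100.0), ("d1_max", 50.0), ("d2_max", 50.0),
    ])
    def test_relaxing_any_threshold_is_monotone(self, planted_trace, field, delta):
        x, rate, *_ = planted_trace
        base = sum(c.passed for c in detect_candidates(x, rate))
        relaxed = dataclasses.replace(DEFAULT_THRESHOLDS, **{field: getattr(DEFAULT_THRESHOLDS, field) + delta})
        widened = sum(c.passed for c in detect_candidates(x, rate, thresholds=relaxed))
        assert widened >= base
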
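import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikedet import (
    AnnotationSet,
    MatchResult,
    crossvalidate_stage2,
    label_candidates,
    match,
    metrics,
    realign_markers,
)
from spikedet.mimetic import HalfWaveFeatures, SpikeCandidate
from spikedet.synthetic import generate_candidate_set


class TestRealignMarkers:
    def test_marker_shifted_onto_planted_vertex(self):
        rate = 100.0
        x = np.zeros(1000)
        x[500] = -60.0
        ann = AnnotationSet(times=np.array([4.98]))  # 20 ms left of the dip
        out = realign_markers(ann, x, rate)
        assert out.times[0] == pytest.approx(5.0)

    def test_marker_on_minimum_unchanged(self):
        x = np.zeros(1000)
        x[500] = -60.0
        ann = AnnotationSet(times=np.array([5.0]))
        out = realign_markers(ann, x, 100.0)
        assert out.times[0] == pytest.approx(5.0)

    def test_flat_neighborhood_takes_earliest(self):
        x = np.zeros(1000)
        ann = AnnotationSet(times=np.array([5.0]))
        out = realign_markers(ann, x, 100.0, radius_ms=50.0)
        assert out.times[0] == pytest.approx(4.95)  # left edge of ±50 ms

    def test_marker_outside_signal_rejected(self):
        with pytest.raises(ValueError):
            realign_markers(AnnotationSet(times=np.array([99.0])), np.zeros(100), 100.0)


class TestMatch:
    def test_within_latency_is_tp(self):
        res = match([10.03], [10.0], latency_ms=50.0)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_beyond_latency_is_fp_and_fn(self):
        res = match([10.06], [10.0], latency_ms=50.0)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_no_detections_all_fn(self):
        res = match([], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert (res.tp, res.fp, res.fn) == (0, 0, 5)

    def test_one_to_one_matching(self):
        # two detections near one marker: only one can match
        res = match([10.0, 10.02], [10.01])
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    @given(
        st.lists(st.floats(0, 100), max_size=10),
        st.lists(st.floats(0, 100), max_size=10),
        st.floats(1.0, 200.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_counting_identities(self, det, mark, latency):
        res = match(det, mark, latency_ms=latency)
        assert res.tp + res.fn == len(mark)
        assert res.tp + res.fp == len(det)
        assert res.tp == len(res.pairs)
        for d, m in res.pairs:
            assert abs(d - m) <= latency / 1000.0 + 1e-9

    @given(
        st.lists(st.floats(0, 100), max_size=8),
        st.lists(st.floats(0, 100), max_size=8),
        st.floats(-1000, 1000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_translation_invariance(self, det, mark, shift):
        a = match(det, mark)
        b = match([d + shift for d in det], [m + shift for m in mark])
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)


class TestMetrics:
    def test_headline_confusion_arithmetic(self):
        m = metrics(MatchResult(tp=98, fp=58, fn=3), duration_min=540.0)
        assert m.sensitivity == pytest.approx(98 / 101)
        assert m.selectivity == pytest.approx(98 / 156)
        assert m.fp_per_min == pytest.approx(58 / 540)
        assert m.fscore == pytest.approx(196 / 257)

    def test_all_zero_convention(self):
        m = metrics(MatchResult(tp=0, fp=0, fn=0))
        assert (m.sensitivity, m.selectivity, m.fscore) == (0.0, 0.0, 0.0)

    def test_perfect_detection(self):
        m = metrics(MatchResult(tp=10, fp=0, fn=0), duration_min=10.0)
        assert m.fscore == 1.0
        assert m.fp_per_min == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            metrics(MatchResult(tp=1, fp=1, fn=1), duration_min=0.0)


def _mk_candidates(X, y):
    feats = HalfWaveFeatures(a1=30, a2=60, d1=40, d2=40)
    return [
        SpikeCandidate(
            peak_index=i,
            peak_time=float(i),
            waveform=X[:, i],
            features=feats,
            passed=True,
            vertex_offset=10,
            label="spike" if y[i] == 1 else "non-spike",
        )
        for i in range(X.shape[1])
    ]


class TestLabelCandidates:
    def test_latency_rule_boundary(self):
        X = np.zeros((31, 3))
        cands = _mk_candidates(X, np.zeros(3))
        cands[0].peak_time = 10.00
        cands[1].peak_time = 10.04
        cands[2].peak_time = 11.00
        label_candidates(cands, np.array([10.0]), latency_ms=50.0)
        assert [c.label for c in cands] == ["spike", "spike", "non-spike"]


@pytest.fixture(scope="module")
def cv_result():
    X, y = generate_candidate_set(n_pos=60, n_neg=240, seed=8)
    cands = _mk_candidates(X, y)
    return y, crossvalidate_stage2(cands, folds=5, seed=3)


class TestCrossValidation:
    def test_partition_identity(self, cv_result):
        y, (pooled, per_fold, _avg) = cv_result
        assert pooled.tp + pooled.fn == int(np.sum(y == 1))
        assert sum(f.tp + f.fp + f.fn + f.tn for f in per_fold) == len(y)

    def test_separable_classes_high_fscore(self, cv_result):
        _y, (pooled, _folds, avg) = cv_result
        assert pooled.fscore >= 0.9
        assert avg.fscore >= 0.85

    def test_same_seed_reproducible(self):
        X, y = generate_candidate_set(n_pos=60, n_neg=240, seed=8)
        a = crossvalidate_stage2(_mk_candidates(X, y), folds=5, seed=3)[0]
        b = crossvalidate_stage2(_mk_candidates(X, y), folds=5, seed=3)[0]
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)

    def test_too_few_positives_rejected(self):
        X, y = generate_candidate_set(n_pos=4, n_neg=60, seed=9)
        with pytest.raises(ValueError):
            crossvalidate_stage2(_mk_candidates(X, y), folds=10, seed=0)

    def test_unlabeled_candidates_rejected(self):
        X, y = generate_candidate_set(n_pos=20, n_neg=60, seed=10)
        cands = _mk_candidates(X, y)
        cands[0].label = "unknown"
        with pytest.raises(ValueError):
            crossvalidate_stage2(cands, folds=5, seed=0)
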
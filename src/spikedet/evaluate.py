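"""Latency-windowed scoring against expert markers and stage-2 cross-validation.

A detection counts as a true positive when it falls within the detection
latency (50 ms by default) of an expert marker; matching is one-to-one.
Sensitivity = TP/(TP+FN), selectivity (precision) = TP/(TP+FP), FP/min is
the clinical review burden, and the F-score 2TP/(2TP+FP+FN) is the harmonic
mean of sensitivity and precision.

Because manual marks are placed by eye, they are first re-aligned to the
largest negative peak within the latency window — the same tolerance used
for scoring.

The mimetic stage is rule-based (no training), so cross-validation covers
stage 2 only: in each fold the embedding and classifier are learnt on the
training candidates alone (inductive default; a transductive mode learns the
projection from train+test waveforms jointly) and applied to the held-out
fold.  Folds are stratified so each contains positives despite the heavy
class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import (
    LABEL_NONSPIKE,
    LABEL_SPIKE,
    ClassifierParams,
    predict,
    train,
)
from .io import AnnotationSet, time_to_index
from .manifold import GraphParams, estimate_intrinsic_dim, fit_lpp, transform
from .mimetic import SpikeCandidate

__all__ = [
    "MatchResult",
    "Metrics",
    "FoldResult",
    "realign_markers",
    "match",
    "metrics",
    "label_candidates",
    "crossvalidate_stage2",
]


@dataclass
class MatchResult:
    """Outcome of latency-windowed one-to-one matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[float, float]] = field(default_factory=list)
    unmatched_detections: list[float] = field(default_factory=list)
    unmatched_markers: list[float] = field(default_factory=list)


@dataclass
class Metrics:
    """Detection quality summary; fractions in [0, 1], fp_per_min in min⁻¹."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    selectivity: float
    fscore: float
    fp_per_min: float | None
    duration_min: float | None


@dataclass
class FoldResult:
    fold: int
    tp: int
    fp: int
    fn: int
    tn: int
    l: int
    gamma: float


def realign_markers(
    ann: AnnotationSet,
    signal: np.ndarray,
    rate: float,
    radius_ms: float = 50.0,
    start_time: float = 0.0,
) -> AnnotationSet:
    """Shift each marker to the largest negative peak within ±radius_ms.

    Corrects imprecise manual placement; the neighbourhood equals the
    detection latency.  Ties in the minimum resolve to the earliest sample.
    A marker outside the signal span is an error.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    rad = int(round(radius_ms / 1000.0 * rate))
    new_times = []
    for t in ann.times:
        i = time_to_index(t, rate, start_time)
        if not 0 <= i < n:
            raise ValueError(
                f"marker at {t:.3f}s falls outside the signal (0–{n / rate:.3f}s)"
            )
        lo = max(0, i - rad)
        hi = min(n, i + rad + 1)
        j = lo + int(np.argmin(signal[lo:hi]))  # argmin takes earliest on ties
        new_times.append(start_time + j / rate)
    return AnnotationSet(
        times=np.asarray(new_times, dtype=float), channels=ann.channels
    )


def match(
    detections: np.ndarray | list[float],
    markers: np.ndarray | list[float],
    latency_ms: float = 50.0,
) -> MatchResult:
    """Greedy one-to-one matching of detections to markers within the latency.

    All detection/marker pairs within ``latency_ms`` are considered in order
    of increasing |Δt| (ties: earlier detection, then earlier marker); each
    event matches at most once.  Leftover detections are false positives,
    leftover markers false negatives.
    """
    det = np.sort(np.asarray(detections, dtype=float))
    mark = np.sort(np.asarray(markers, dtype=float))
    lat = latency_ms / 1000.0
    pairs_all: list[tuple[float, float, float, int, int]] = []
    for di, dt in enumerate(det):
        lo = np.searchsorted(mark, dt - lat)
        hi = np.searchsorted(mark, dt + lat, side="right")
        for mi in range(lo, hi):
            pairs_all.append((abs(dt - mark[mi]), dt, mark[mi], di, mi))
    pairs_all.sort()
    used_d: set[int] = set()
    used_m: set[int] = set()
    matched: list[tuple[float, float]] = []
    for _, dt, mk, di, mi in pairs_all:
        if di in used_d or mi in used_m:
            continue
        used_d.add(di)
        used_m.add(mi)
        matched.append((dt, mk))
    unmatched_d = [float(t) for i, t in enumerate(det) if i not in used_d]
    unmatched_m = [float(t) for i, t in enumerate(mark) if i not in used_m]
    return MatchResult(
        tp=len(matched),
        fp=len(unmatched_d),
        fn=len(unmatched_m),
        pairs=sorted(matched),
        unmatched_detections=unmatched_d,
        unmatched_markers=unmatched_m,
    )


def metrics(m: MatchResult, duration_min: float | None = None) -> Metrics:
    """Sensitivity, selectivity, F-score and FP/min from matched counts.

    0/0 ratios resolve to 0 by convention; FP/min is ``None`` when no
    recording duration is supplied (e.g. pooled cross-validation folds).
    """
    tp, fp, fn = m.tp, m.fp, m.fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    sel = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    fpm: float | None = None
    if duration_min is not None:
        if duration_min <= 0:
            raise ValueError("duration_min must be positive")
        fpm = fp / duration_min
    return Metrics(
        tp=tp, fp=fp, fn=fn,
        sensitivity=sens, selectivity=sel, fscore=f,
        fp_per_min=fpm, duration_min=duration_min,
    )


def label_candidates(
    candidates: list[SpikeCandidate],
    markers: AnnotationSet | np.ndarray,
    latency_ms: float = 50.0,
) -> list[SpikeCandidate]:
    """Assign stage-2 ground truth: spike iff within the latency of a marker.

    Candidates not matching any (re-aligned) marker are the negative class —
    nonspecific sharp transients that passed the shape thresholds.  Labels
    are set in place and the list is returned for chaining.
    """
    times = markers.times if isinstance(markers, AnnotationSet) else np.asarray(markers)
    lat = latency_ms / 1000.0
    times = np.sort(times)
    for c in candidates:
        i = np.searchsorted(times, c.peak_time)
        near = [times[j] for j in (i - 1, i) if 0 <= j < len(times)]
        is_spike = any(abs(c.peak_time - t) <= lat for t in near)
        c.label = "spike" if is_spike else "non-spike"
    return candidates


def _candidate_matrix(candidates: list[SpikeCandidate]) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([c.waveform for c in candidates])
    y = np.array(
        [LABEL_SPIKE if c.label == "spike" else LABEL_NONSPIKE for c in candidates]
    )
    return X, y


def crossvalidate_stage2(
    candidates: list[SpikeCandidate],
    l: int | str = "mle",
    graph: GraphParams | None = None,
    clf: ClassifierParams | None = None,
    folds: int = 10,
    seed: int = 0,
    mode: str = "inductive",
    duration_min: float | None = None,
) -> tuple[Metrics, list[FoldResult], Metrics]:
    """Stratified k-fold cross-validation of embedding + classification.

    Per fold: the embedding dimensionality (MLE unless ``l`` is an integer),
    the LPP map, the γ calibration and the classifier are all learnt from
    the training folds; the held-out fold is embedded through the linear
    out-of-sample map and classified.  ``mode="transductive"`` instead
    learns the projection from train+test waveforms jointly (labels still
    come only from training folds).

    Returns ``(pooled_metrics, per_fold, averaged_metrics)``: confusion
    counts pooled over folds, the per-fold breakdown, and per-fold metrics
    averaged (both conventions are reported since either may be quoted).
    """
    if mode not in ("inductive", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    labeled = [c for c in candidates if c.label in ("spike", "non-spike")]
    if len(labeled) < len(candidates):
        raise ValueError("all candidates must be labeled before cross-validation")
    X, y = _candidate_matrix(labeled)
    n_pos = int(np.sum(y == LABEL_SPIKE))
    n_neg = int(np.sum(y == LABEL_NONSPIKE))
    if n_pos < folds or n_neg < folds:
        raise ValueError(
            f"need at least {folds} candidates per class for {folds}-fold "
            f"stratified CV (have {n_pos} spikes, {n_neg} non-spikes)"
        )
    graph = graph or GraphParams()
    clf = clf or ClassifierParams()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[FoldResult] = []
    tp = fp = fn = tn = 0
    fold_metrics: list[Metrics] = []
    for f, (tr, te) in enumerate(skf.split(X.T, y)):
        X_tr, y_tr = X[:, tr], y[tr]
        X_te, y_te = X[:, te], y[te]
        l_fold = estimate_intrinsic_dim(X_tr) if l == "mle" else int(l)
        l_fold = min(l_fold, X.shape[0])
        X_fit = np.concatenate([X_tr, X_te], axis=1) if mode == "transductive" else X_tr
        emb = fit_lpp(X_fit, l_fold, graph)
        Y_tr = transform(emb, X_tr)
        model = train(Y_tr, y_tr, clf)
        pred, _scores = predict(model, transform(emb, X_te))
        f_tp = int(np.sum((pred == LABEL_SPIKE) & (y_te == LABEL_SPIKE)))
        f_fp = int(np.sum((pred == LABEL_SPIKE) & (y_te == LABEL_NONSPIKE)))
        f_fn = int(np.sum((pred == LABEL_NONSPIKE) & (y_te == LABEL_SPIKE)))
        f_tn = int(np.sum((pred == LABEL_NONSPIKE) & (y_te == LABEL_NONSPIKE)))
        per_fold.append(
            FoldResult(fold=f, tp=f_tp, fp=f_fp, fn=f_fn, tn=f_tn,
                       l=l_fold, gamma=model.gamma)
        )
        fold_metrics.append(metrics(MatchResult(tp=f_tp, fp=f_fp, fn=f_fn)))
        tp += f_tp
        fp += f_fp
        fn += f_fn
        tn += f_tn
    pooled = metrics(MatchResult(tp=tp, fp=fp, fn=fn), duration_min)
    averaged = Metrics(
        tp=tp, fp=fp, fn=fn,
        sensitivity=float(np.mean([m.sensitivity for m in fold_metrics])),
        selectivity=float(np.mean([m.selectivity for m in fold_metrics])),
        fscore=float(np.mean([m.fscore for m in fold_metrics])),
        fp_per_min=pooled.fp_per_min,
        duration_min=duration_min,
    )
    return pooled, per_fold, averaged
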
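"""Stage 1 — mimetic candidate detection by half-wave shape thresholding.

An interictal spike is a brief pointed transient; a neurophysiologist judges
it by the steepness and size of the two flanks around its (negative) peak.
This stage mimics those visual criteria: the primary vertex is a local
minimum of the trace, the two half-waves run from the vertex to the closest
local maximum on each side, and each half-wave is characterised by its
amplitude difference (A1 preceding, A2 following, μV) and duration (D1, D2,
ms).  A candidate passes when all four values fall inside fixed threshold
ranges; the thresholds are deliberately loose — the stage aims at near-total
sensitivity and leaves specificity to the embedding/classification stage.

Default thresholds (inclusive): A1 ∈ [20, 500] μV, A2 ∈ [50, 500] μV,
D1 ≤ 200 ms, D2 ≤ 150 ms.  The amplitude ceilings discard movement and
electrode artifacts; the asymmetric floors reflect that the following
(repolarising) flank of a genuine spike is the larger one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "HalfWaveFeatures",
    "Thresholds",
    "SpikeCandidate",
    "DEFAULT_THRESHOLDS",
    "detect_peaks",
    "extract_waveform",
    "halfwave_features",
    "apply_thresholds",
    "detect_candidates",
]


@dataclass(frozen=True)
class HalfWaveFeatures:
    """Half-wave shape parameters of one candidate.

    a1, a2 : amplitude difference in μV between the closest local maximum
        before / after the primary vertex and the vertex value (≥ 0).
    d1, d2 : time in ms from that maximum to the vertex (before) and from
        the vertex to the maximum (after) (> 0).
    """

    a1: float
    a2: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("half-wave amplitudes must be non-negative")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("half-wave durations must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Inclusive pass ranges for the four half-wave parameters."""

    a1_min: float = 20.0
    a1_max: float = 500.0
    a2_min: float = 50.0
    a2_max: float = 500.0
    d1_max: float = 200.0
    d2_max: float = 150.0

    def __post_init__(self) -> None:
        if self.a1_min > self.a1_max or self.a2_min > self.a2_max:
            raise ValueError("amplitude minimum exceeds maximum")

    def relaxed(self) -> "Thresholds":
        """Vacuous thresholds (every candidate passes)."""
        return replace(
            self,
            a1_min=0.0, a1_max=np.inf, a2_min=0.0, a2_max=np.inf,
            d1_max=np.inf, d2_max=np.inf,
        )


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class SpikeCandidate:
    """A detected peak with its extracted waveform and shape features.

    ``waveform`` spans ``pre_ms`` before to ``post_ms`` after the vertex
    (31 samples at the 100 Hz / 100–200 ms defaults); ``waveform[vertex_offset]``
    equals the signal at ``peak_index``.  ``label`` is set by the evaluation
    stage ("spike" / "non-spike") and is "unknown" until then.
    """

    peak_index: int
    peak_time: float
    waveform: np.ndarray
    features: HalfWaveFeatures
    passed: bool
    vertex_offset: int
    label: str = "unknown"


def detect_peaks(
    x: np.ndarray,
    rate: float,
    min_separation_ms: float = 100.0,
    min_prominence: float = 10.0,
    invert: bool = False,
) -> np.ndarray:
    """Locate primary vertices: prominent local minima ≥ 100 ms apart.

    The primary vertex of a spike is its negative peak, so minima are
    detected (``invert=True`` flips polarity for positive-going montages).
    Small deflections riding close to a larger one are ignored: of any two
    minima closer than ``min_separation_ms`` the deeper is kept (ties break
    to the earlier index), and every kept minimum must have topographic
    prominence ≥ ``min_prominence`` μV.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    y = x if invert else -x  # peaks of y are the minima we want
    idx, _props = sps.find_peaks(y, prominence=min_prominence)
    if len(idx) == 0:
        return idx
    sep = int(round(min_separation_ms / 1000.0 * rate))
    # greedy deepest-first with deterministic earlier-index tie-break
    order = sorted(range(len(idx)), key=lambda i: (-y[idx[i]], idx[i]))
    kept: list[int] = []
    for i in order:
        p = idx[i]
        if all(abs(p - q) >= sep for q in kept):
            kept.append(p)
    return np.array(sorted(kept), dtype=int)


def extract_waveform(
    x: np.ndarray,
    rate: float,
    peak_index: int,
    pre_ms: float = 100.0,
    post_ms: float = 200.0,
) -> np.ndarray | None:
    """Slice the waveform window around a vertex; ``None`` without full context.

    The window runs inclusively from ``pre_ms`` before the vertex to
    ``post_ms`` after it: 10 + 1 + 20 = 31 samples at 100 Hz defaults.  A
    vertex too close to either end of the trace cannot supply the full
    window and is discarded (logged), not an error.
    """
    pre = int(round(pre_ms / 1000.0 * rate))
    post = int(round(post_ms / 1000.0 * rate))
    if peak_index - pre < 0 or peak_index + post >= len(x):
        logger.debug("candidate at sample %d discarded: incomplete window", peak_index)
        return None
    return np.asarray(x[peak_index - pre: peak_index + post + 1], dtype=float)


def _closest_max_before(seg: np.ndarray) -> int:
    """Index (into seg) of the local maximum closest to the segment end.

    ``seg`` is the waveform up to but excluding the vertex.  When no
    interior local maximum exists (e.g. the pre-segment decreases
    monotonically into the vertex) the segment's maximum sample serves as
    surrogate, which for a monotone decrease is the first sample.
    """
    peaks, _ = sps.find_peaks(seg)
    if len(peaks):
        return int(peaks[-1])
    return int(np.argmax(seg))


def _closest_max_after(seg: np.ndarray) -> int:
    peaks, _ = sps.find_peaks(seg)
    if len(peaks):
        return int(peaks[0])
    return int(np.argmax(seg))


def halfwave_features(
    waveform: np.ndarray, rate: float, vertex_offset: int
) -> HalfWaveFeatures:
    """Measure A1/A2 (μV) and D1/D2 (ms) from a waveform around its vertex.

    Amplitudes are maximum-minus-vertex; durations are index distances over
    the sampling rate.  The vertex must be strictly inside the waveform.
    """
    waveform = np.asarray(waveform, dtype=float)
    if not 0 < vertex_offset < len(waveform) - 1:
        raise ValueError(
            f"vertex offset {vertex_offset} must be strictly inside the "
            f"waveform (length {len(waveform)})"
        )
    v = waveform[vertex_offset]
    i1 = _closest_max_before(waveform[:vertex_offset])
    seg_after = waveform[vertex_offset + 1:]
    i2 = vertex_offset + 1 + _closest_max_after(seg_after)
    return HalfWaveFeatures(
        a1=float(waveform[i1] - v),
        a2=float(waveform[i2] - v),
        d1=(vertex_offset - i1) / rate * 1000.0,
        d2=(i2 - vertex_offset) / rate * 1000.0,
    )


def apply_thresholds(f: HalfWaveFeatures, t: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """Inclusive-range test of all four half-wave parameters."""
    return (
        t.a1_min <= f.a1 <= t.a1_max
        and t.a2_min <= f.a2 <= t.a2_max
        and f.d1 <= t.d1_max
        and f.d2 <= t.d2_max
    )


def detect_candidates(
    x: np.ndarray,
    rate: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    min_separation_ms: float = 100.0,
    min_prominence: float = 10.0,
    pre_ms: float = 100.0,
    post_ms: float = 200.0,
    invert: bool = False,
) -> list[SpikeCandidate]:
    """Run the full mimetic stage and return time-ordered candidates.

    Every prominent vertex with full window context yields a
    :class:`SpikeCandidate` whose ``passed`` flag records the threshold
    test; only passing candidates flow into stage 2.
    """
    x = np.asarray(x, dtype=float)
    sig = -x if invert else x
    peaks = detect_peaks(x, rate, min_separation_ms, min_prominence, invert=invert)
    vertex_offset = int(round(pre_ms / 1000.0 * rate))
    out: list[SpikeCandidate] = []
    for p in peaks:
        wf = extract_waveform(sig, rate, int(p), pre_ms, post_ms)
        if wf is None:
            continue
        feats = halfwave_features(wf, rate, vertex_offset)
        out.append(
            SpikeCandidate(
                peak_index=int(p),
                peak_time=p / rate,
                waveform=wf,
                features=feats,
                passed=apply_thresholds(feats, thresholds),
                vertex_offset=vertex_offset,
            )
        )
    return out
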
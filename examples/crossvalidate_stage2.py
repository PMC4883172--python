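"""Ten-fold cross-validation of the embedding + classification stage.

Stage 1 is rule-based (no training), so cross-validation covers stage 2
only: in each stratified fold the LPP map, the kernel width and the
classifier are learnt from the training folds and applied to the held-out
candidates through the exact linear out-of-sample extension.
"""

from spikedet import generate_candidate_set
from spikedet.evaluate import crossvalidate_stage2
from spikedet.mimetic import HalfWaveFeatures, SpikeCandidate

X, y = generate_candidate_set(n_pos=300, n_neg=1700, seed=3)
feats = HalfWaveFeatures(a1=30, a2=60, d1=40, d2=40)
candidates = [
    SpikeCandidate(
        peak_index=i, peak_time=float(i), waveform=X[:, i], features=feats,
        passed=True, vertex_offset=10,
        label="spike" if y[i] == 1 else "non-spike",
    )
    for i in range(X.shape[1])
]

pooled, per_fold, averaged = crossvalidate_stage2(candidates, folds=10, seed=0)
print(f"candidates: {X.shape[1]} ({(y == 1).sum()} spikes, "
      f"{(y == -1).sum()} sharp transients), waveform dim {X.shape[0]}")
print(f"per-fold l: {[f.l for f in per_fold]}  (MLE per training fold)")
print(f"pooled:     TP {pooled.tp}, FP {pooled.fp}, FN {pooled.fn} -> "
      f"sensitivity {pooled.sensitivity:.3f}, F-score {pooled.fscore:.3f}")
print(f"fold-avg:   sensitivity {averaged.sensitivity:.3f}, "
      f"F-score {averaged.fscore:.3f}")
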
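"""Four-way architecture ablation on one synthetic subject.

Compares the instance-based CNN, the sequence-based LSTM, the sequential
CNN-LSTM baseline and the parallel multi-frame network under identical
leave-one-seizure-out folds.  Takes several minutes on one CPU core.
"""

from preictal import (ModelSpec, SynthSpec, TrainConfig, build_segments,
                      generate_subject, run_ablation)
from preictal.models import MODEL_KINDS
from preictal.pipeline import config_for_synth

spec = SynthSpec(n_channels=8, fs=64, n_seizures=4,
                 interictal_minutes_per_block=5, preictal_minutes=2,
                 effect_size=1.0, seed=42)
segs = build_segments(generate_subject(spec), config_for_synth(spec))

specs = {kind: ModelSpec(kind=kind, n_channels=8, seq_len=64,
                         conv_filters=(8, 16, 32), lstm_units=64)
         for kind in MODEL_KINDS}
cfg = TrainConfig(batch_size=64, learning_rate=3e-3, max_epochs=60,
                  patience=12, seed=0)
result = run_ablation(segs, specs, cfg, n_seeds=2)
print(result.summary.round(3).to_string())
print("\nmean-metric deltas (multi-frame minus single-frame):")
print(result.deltas("multiframe").round(3).to_string())
# On a subject carrying both a correlation and a spectral pre-ictal
# signature the multi-frame network matches or beats every single-frame
# model; the deltas mirror the ablation the architecture was designed for.
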
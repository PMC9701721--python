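"""Leave-one-seizure-out evaluation of the multi-frame network.

Trains the parallel CNN+LSTM classifier on a synthetic subject, holding
out each seizure's pre-ictal block (with its paired inter-ictal block) in
turn, and prints the per-fold metric table.  Takes a couple of minutes on
one CPU core.
"""

from preictal import (ModelSpec, SynthSpec, TrainConfig, build_segments,
                      generate_subject, loo_evaluate)
from preictal.pipeline import config_for_synth

spec = SynthSpec(n_channels=8, fs=64, n_seizures=4,
                 interictal_minutes_per_block=5, preictal_minutes=2,
                 effect_size=1.0, seed=42)
segs = build_segments(generate_subject(spec), config_for_synth(spec))
print(f"{len(segs)} balanced segments "
      f"({int((segs.y == 1).sum())} pre-ictal)")

model_spec = ModelSpec(kind="multiframe", n_channels=8, seq_len=64,
                       conv_filters=(8, 16, 32), lstm_units=64)
cfg = TrainConfig(batch_size=64, learning_rate=3e-3, max_epochs=60,
                  patience=12, seed=0)
report = loo_evaluate(segs, model_spec, cfg)
print(report.to_frame().round(3).to_string(index=False))
# Each row is one held-out seizure; the mean row is the subject-level
# result.  With the programmed effect size of 1 the mean AUC is ~0.99;
# at effect size 0 it would sit at chance (~0.5).
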
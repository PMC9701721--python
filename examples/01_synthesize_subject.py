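"""Generate a synthetic annotated EEG subject and label its timeline.

Builds a 4-seizure subject whose pre-ictal minutes differ from the
inter-ictal baseline by a programmed correlation and spectral shift, then
applies the clinical labeling rules (pre-ictal horizon, seizure merging,
post-ictal exclusion) and prints the resulting block structure.
"""

from preictal import SynthSpec, generate_subject, label_intervals
from preictal.pipeline import config_for_synth

spec = SynthSpec(n_channels=8, fs=64, n_seizures=4,
                 interictal_minutes_per_block=5, preictal_minutes=2,
                 effect_size=1.0, seed=42)
rec = generate_subject(spec, subject_id="demo")
print(f"subject {rec.subject_id}: {rec.n_channels} channels, "
      f"{rec.duration_s / 60:.1f} min, {len(rec.annotations)} seizures")

cfg = config_for_synth(spec)
intervals = label_intervals(rec, preictal_min=cfg.preictal_min,
                            postictal_buffer_min=cfg.postictal_buffer_min,
                            merge_gap_min=cfg.merge_gap_min)
for iv in intervals:
    print(f"  {iv.label:>10s} block {iv.block_id}: "
          f"{iv.start_s / 60:7.2f} - {iv.end_s / 60:7.2f} min "
          f"({iv.duration_s:.0f} s)")
# Each pre-ictal block ends exactly at a seizure onset; the seizure itself
# and a post-ictal buffer are excluded from both classes.
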
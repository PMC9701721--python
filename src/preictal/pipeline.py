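"""End-to-end convenience: recording -> balanced, labeled segment set.

Chains the standard stages in order: bandpass filter, resample to the
common rate, label pre-ictal/inter-ictal intervals from the (merged)
seizure annotations, cut 1-s segments, and balance the classes.  Each stage
remains individually accessible in :mod:`preictal.ingest` and
:mod:`preictal.preprocess`; this wrapper just fixes the order and records
the settings in the segment-set metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .ingest import RawRecording, label_intervals
from .preprocess import SegmentSet, balance, bandpass, resample, segment

__all__ = ["PreprocessConfig", "build_segments", "config_for_synth"]


@dataclass
class PreprocessConfig:
    """Settings of the recording-to-segments chain."""
    band_low_hz: float = 0.5
    band_high_hz: float = 70.0
    filter_order: int = 4
    target_fs: float = 256.0
    preictal_min: float = 30.0
    postictal_buffer_min: float = 30.0
    merge_gap_min: float = 30.0
    balance_seed: int = 0


def config_for_synth(spec, balance_seed: int = 0) -> PreprocessConfig:
    """Preprocessing settings matched to a synthetic subject's layout.

    The clinical defaults (30-min pre-ictal horizon, 30-min seizure merging,
    30-min post-ictal buffer) assume seizures many tens of minutes apart.
    Desk-scale synthetic subjects compress the timeline, so the labeling
    windows must shrink with it: the pre-ictal horizon becomes the generated
    pre-ictal block length, the merge gap stays below the generated seizure
    spacing, and the post-ictal buffer takes at most a quarter of each
    inter-ictal block.
    """
    return PreprocessConfig(
        band_high_hz=min(70.0, 0.9 * spec.fs / 2.0),
        target_fs=float(spec.fs),
        preictal_min=spec.preictal_minutes,
        merge_gap_min=min(30.0, 0.9 * spec.interictal_minutes_per_block),
        postictal_buffer_min=min(30.0, spec.interictal_minutes_per_block / 4.0),
        balance_seed=balance_seed)


def build_segments(rec: RawRecording, cfg: PreprocessConfig | None = None,
                   balanced: bool = True) -> SegmentSet:
    """Run the full preprocessing chain on one annotated recording."""
    cfg = cfg or PreprocessConfig()
    high = min(cfg.band_high_hz, 0.98 * rec.fs / 2.0, 0.98 * cfg.target_fs / 2.0)
    rec = bandpass(rec, cfg.band_low_hz, high, cfg.filter_order)
    rec = resample(rec, cfg.target_fs)
    intervals = label_intervals(
        rec, preictal_min=cfg.preictal_min,
        postictal_buffer_min=cfg.postictal_buffer_min,
        merge_gap_min=cfg.merge_gap_min)
    segs = segment(rec, intervals)
    if balanced:
        segs = balance(segs, seed=cfg.balance_seed)
    return SegmentSet.from_segments(segs, fs=rec.fs,
                                    meta={"preprocess": asdict(cfg)})
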
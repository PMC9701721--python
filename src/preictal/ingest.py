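"""Recording ingestion: EDF I/O, channel selection, and clinical labeling.

The ingestion contract turns an annotated multichannel recording into labeled
continuous intervals ready for segmentation:

* seizures closer than 30 min are treated as one seizure,
* the 30 min before each (merged) seizure onset is the pre-ictal class,
* the ictal span plus a post-ictal buffer is excluded from both classes,
* everything else is inter-ictal.

EDF reading goes through mne; writing uses a minimal 16-bit EDF writer (1-s
data records) so synthetic subjects can round-trip through the same on-disk
format as scalp-EEG datasets.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording", "SeizureAnnotation", "LabeledInterval",
    "CHB_MIT_18_CHANNELS", "read_edf", "write_edf",
    "read_annotations", "write_annotations",
    "select_channels", "merge_seizures", "label_intervals",
    "concatenate_recordings", "save_intervals", "load_intervals",
]

#: The 18 bipolar scalp channels shared by most CHB-MIT style recordings.
CHB_MIT_18_CHANNELS = [
    "P8-O2", "F8-T8", "F7-T7", "P7-O1", "FZ-CZ", "FP1-F7", "FP2-F8",
    "T8-P8", "F3-C3", "C4-P4", "CZ-PZ", "T7-P7", "F4-C4", "C3-P3",
    "P3-O1", "FP2-F4", "FP1-F3", "P4-O2",
]


@dataclass
class SeizureAnnotation:
    """One seizure event, in seconds from recording start."""
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"seizure annotation needs 0 <= onset < offset, got "
                f"[{self.onset_s}, {self.offset_s}]")


@dataclass
class RawRecording:
    """A continuous multichannel recording with seizure annotations."""
    data: np.ndarray            # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class LabeledInterval:
    """A continuous stretch of one class. ``block_id`` numbers blocks of each
    label 1..K in time order (pre-ictal block k ends at seizure k's onset)."""
    start_s: float
    end_s: float
    label: str                  # "interictal" | "preictal"
    block_id: int

    def __post_init__(self) -> None:
        if self.label not in ("interictal", "preictal"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.end_s <= self.start_s:
            raise ValueError("interval must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _format_physical(v: float) -> str:
    """Format a physical min/max into <= 8 ASCII chars."""
    for fmt in ("%g", "%.4g", "%.3g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 chars")


def write_edf(rec: RawRecording, path: str | Path,
              annotation_path: str | Path | None = None) -> Path:
    """Write a recording as a plain 16-bit EDF file with 1-s data records.

    Requires an integer sampling rate; a trailing partial second is dropped.
    Signals are stored with a symmetric physical range per channel in
    microvolt units, so amplitudes survive the 16-bit quantization to within
    ``range / 65535``.  If ``annotation_path`` is given the seizure list is
    written there as a CSV sidecar.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    ns = rec.n_channels
    data = rec.data[:, :n_records * fs]

    # per-channel symmetric physical range with a short ASCII representation
    amp = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_max = np.array([float(_format_physical(a * 1.0001)) for a in amp])
    phys_max = np.maximum(phys_max, amp)  # formatting must not clip data
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / gain[:, None]
                       + dig_min).astype("<i2")

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(rec.subject_id[:80], 80),
        _ascii_field("preictal synthetic/export"[:80], 80),
        _ascii_field("01.01.01", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (ns + 1), 8),
        _ascii_field("", 44),
        _ascii_field(n_records, 8),
        _ascii_field(1, 8),
        _ascii_field(ns, 4),
    ])
    labels = [name[:16] for name in rec.channel_names]
    sig_header = b"".join(
        [b"".join(_ascii_field(lab, 16) for lab in labels)]
        + [b"".join(_ascii_field("", 80) for _ in range(ns))]
        + [b"".join(_ascii_field("uV", 8) for _ in range(ns))]
        + [b"".join(_ascii_field(_format_physical(v), 8) for v in phys_min)]
        + [b"".join(_ascii_field(_format_physical(v), 8) for v in phys_max)]
        + [b"".join(_ascii_field(dig_min, 8) for _ in range(ns))]
        + [b"".join(_ascii_field(dig_max, 8) for _ in range(ns))]
        + [b"".join(_ascii_field("", 80) for _ in range(ns))]
        + [b"".join(_ascii_field(fs, 8) for _ in range(ns))]
        + [b"".join(_ascii_field("", 32) for _ in range(ns))]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # record-major, channel-sequential int16 little-endian
        records = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())

    if annotation_path is not None:
        write_annotations(annotation_path, rec.annotations, rec.subject_id)
    return path


def write_annotations(path: str | Path, annotations: list[SeizureAnnotation],
                      subject_id: str = "") -> Path:
    path = Path(path)
    pd.DataFrame({
        "subject_id": [subject_id] * len(annotations),
        "seizure_index": np.arange(1, len(annotations) + 1),
        "onset_s": [a.onset_s for a in annotations],
        "offset_s": [a.offset_s for a in annotations],
    }).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    df = pd.read_csv(path)
    missing = {"onset_s", "offset_s"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    anns = [SeizureAnnotation(onset_s=float(r.onset_s), offset_s=float(r.offset_s))
            for r in df.sort_values("onset_s").itertuples()]
    return anns


def read_edf(path: str | Path,
             annotation_path: str | Path | None = None) -> RawRecording:
    """Read an EDF file (channels in file order, microvolt units) and,
    optionally, a seizure-annotation CSV sidecar."""
    import mne  # heavyweight import kept local

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    rec = RawRecording(
        data=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        channel_names=[str(ch) for ch in raw.ch_names],
        annotations=[],
        subject_id=path.stem,
    )
    if annotation_path is not None:
        anns = read_annotations(annotation_path)
        for a in anns:
            if a.offset_s > rec.duration_s + 1e-6:
                raise ValueError(
                    f"annotation [{a.onset_s}, {a.offset_s}] s extends beyond "
                    f"the {rec.duration_s:.1f}-s recording {path.name}")
        rec.annotations = anns
    return rec


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------

def _normalize_channel(name: str) -> str:
    """Uppercase, drop spaces and a leading 'EEG' type prefix, keep dashes."""
    s = re.sub(r"\s+", "", name.upper())
    s = re.sub(r"^EEG", "", s)
    return s


def select_channels(rec: RawRecording, wanted: list[str]) -> RawRecording:
    """Reorder/restrict a recording to the wanted channels, in wanted order.

    Matching is case-insensitive and ignores spaces and an ``EEG`` prefix, so
    EDF dialect variants of the same montage label match.  Missing channels
    raise an error naming them.
    """
    lookup: dict[str, int] = {}
    for idx, name in enumerate(rec.channel_names):
        lookup.setdefault(_normalize_channel(name), idx)
    indices, missing = [], []
    for name in wanted:
        key = _normalize_channel(name)
        if key in lookup:
            indices.append(lookup[key])
        else:
            missing.append(name)
    if missing:
        raise ValueError(
            f"recording {rec.subject_id!r} lacks requested channels "
            f"{missing}; available: {rec.channel_names}")
    return replace(rec, data=rec.data[indices],
                   channel_names=[rec.channel_names[i] for i in indices])


# ---------------------------------------------------------------------------
# Seizure merging and labeling
# ---------------------------------------------------------------------------

def merge_seizures(annotations: list[SeizureAnnotation],
                   gap_min: float = 30.0) -> list[SeizureAnnotation]:
    """Fuse consecutive seizures separated by less than ``gap_min`` minutes.

    Two seizures with ``onset2 - offset1 < gap_min * 60`` are treated as one
    seizure spanning both.  Idempotent and order-preserving.
    """
    if not annotations:
        return []
    anns = sorted(annotations, key=lambda a: a.onset_s)
    merged = [SeizureAnnotation(anns[0].onset_s, anns[0].offset_s)]
    for a in anns[1:]:
        if a.onset_s - merged[-1].offset_s < gap_min * 60.0:
            merged[-1].offset_s = max(merged[-1].offset_s, a.offset_s)
        else:
            merged.append(SeizureAnnotation(a.onset_s, a.offset_s))
    return merged


def label_intervals(rec: RawRecording, preictal_min: float = 30.0,
                    postictal_buffer_min: float = 30.0,
                    merge_gap_min: float = 30.0) -> list[LabeledInterval]:
    """Partition a recording into pre-ictal, inter-ictal and excluded time.

    For each merged seizure the window ``[onset - preictal_min, onset)`` is
    pre-ictal (truncated at the recording start or at the previous exclusion
    zone).  The ictal span plus ``postictal_buffer_min`` after each offset is
    excluded from both classes.  Everything else is inter-ictal.  Blocks of
    each label are numbered 1..K in time order.
    """
    duration = rec.duration_s
    seizures = merge_seizures(rec.annotations, gap_min=merge_gap_min)
    if not seizures:
        logger.warning("recording %s has no seizures; all time is inter-ictal",
                       rec.subject_id)

    preictal: list[tuple[float, float]] = []
    exclusions: list[tuple[float, float]] = []
    prev_blocked_end = 0.0   # end of the previous ictal+buffer zone
    for k, sz in enumerate(seizures, start=1):
        start = max(sz.onset_s - preictal_min * 60.0, prev_blocked_end, 0.0)
        if start < sz.onset_s:
            preictal.append((start, sz.onset_s))
        else:
            logger.warning(
                "seizure %d of %s: pre-ictal window swallowed by the previous "
                "exclusion zone; no pre-ictal block emitted", k, rec.subject_id)
        excl_end = min(sz.offset_s + postictal_buffer_min * 60.0, duration)
        exclusions.append((sz.onset_s, excl_end))
        prev_blocked_end = excl_end

    intervals = [LabeledInterval(s, e, "preictal", k)
                 for k, (s, e) in enumerate(preictal, start=1)]

    # inter-ictal = complement of pre-ictal and exclusion zones
    occupied = sorted(preictal + exclusions)
    cursor, inter_id = 0.0, 0
    for s, e in occupied + [(duration, duration)]:
        if s > cursor:
            inter_id += 1
            intervals.append(LabeledInterval(cursor, s, "interictal", inter_id))
        cursor = max(cursor, e)
    intervals.sort(key=lambda iv: iv.start_s)
    return intervals


def concatenate_recordings(recs: list[RawRecording],
                           subject_id: str | None = None) -> RawRecording:
    """Stitch same-montage files into one timeline, assumed contiguous.

    Annotation times of later files are shifted by the accumulated duration
    of the files before them.
    """
    if not recs:
        raise ValueError("no recordings to concatenate")
    first = recs[0]
    for r in recs[1:]:
        if r.fs != first.fs or r.channel_names != first.channel_names:
            raise ValueError("recordings differ in fs or channel layout")
    offset, anns = 0.0, []
    for r in recs:
        anns.extend(SeizureAnnotation(a.onset_s + offset, a.offset_s + offset)
                    for a in r.annotations)
        offset += r.duration_s
    return RawRecording(
        data=np.concatenate([r.data for r in recs], axis=1), fs=first.fs,
        channel_names=list(first.channel_names), annotations=anns,
        subject_id=subject_id or first.subject_id)


def save_intervals(path: str | Path, intervals: list[LabeledInterval],
                   meta: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "meta": meta or {},
        "intervals": [
            {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label,
             "block_id": iv.block_id} for iv in intervals],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_intervals(path: str | Path) -> list[LabeledInterval]:
    payload = json.loads(Path(path).read_text())
    return [LabeledInterval(**iv) for iv in payload["intervals"]]
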
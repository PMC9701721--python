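"""Segment construction and the dual segment representation.

A recording is bandpass filtered, resampled to a common rate, and cut into
non-overlapping 1-s segments of shape (N channels, M samples) with M = fs.
Each segment then gets two views:

* the raw (N, M) matrix, read column-by-column as a length-M time series of
  N-dimensional samples by the sequence (LSTM) branch, and
* a (2, N, N) tensor for the instance (CNN) branch, stacking
  plane 0: the PCA score matrix — channels are the observations, the N
  scores on the first N principal axes are the columns — and
  plane 1: the Pearson channel-correlation matrix R.

Class imbalance is handled by randomly subsampling inter-ictal segments down
to the pre-ictal count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from .ingest import LabeledInterval, RawRecording

__all__ = [
    "Segment", "SegmentSet", "bandpass", "resample", "segment",
    "pca_plane", "pearson_plane", "tensorize", "balance",
    "save_segments", "load_segments",
]

LABEL_CODES = {"interictal": 0, "preictal": 1}


@dataclass
class Segment:
    """One labeled 1-s segment: ``x`` has shape (n_channels, fs)."""
    x: np.ndarray
    label: str
    subject_id: str
    block_id: int
    t0_s: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("segment must be a (channels, samples) matrix")
        if self.label not in LABEL_CODES:
            raise ValueError(f"unknown label {self.label!r}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("segment contains NaN/Inf")


# ---------------------------------------------------------------------------
# Filtering / resampling / segmentation
# ---------------------------------------------------------------------------

def bandpass(rec: RawRecording, low_hz: float = 0.5, high_hz: float = 70.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth bandpass, applied per channel.

    The default 0.5-70 Hz band is the standard clinical EEG band below the
    Nyquist frequency of the 256 Hz target rate.  Forward-backward (filtfilt)
    application doubles the effective order and removes phase distortion.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"need 0 < low < high < fs/2; got ({low_hz}, {high_hz}) at "
            f"fs={rec.fs}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=1))


def resample(rec: RawRecording, target_hz: float = 256.0) -> RawRecording:
    """Polyphase resampling to ``target_hz``; identity if already there.

    Annotations are in seconds and carry over unchanged.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if abs(rec.fs - target_hz) < 1e-9:
        return rec
    ratio = Fraction(target_hz / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator,
                             axis=1)
    return replace(rec, data=data, fs=target_hz)


def segment(rec: RawRecording, intervals: list[LabeledInterval],
            window_s: float = 1.0) -> list[Segment]:
    """Cut labeled intervals into non-overlapping windows of ``window_s``.

    Each interval yields floor(duration / window_s) segments of exactly
    ``window_s * fs`` samples; the trailing partial window is discarded.
    Labels and block ids are inherited.
    """
    m = int(round(window_s * rec.fs))
    out: list[Segment] = []
    for iv in sorted(intervals, key=lambda i: i.start_s):
        n_seg = int(np.floor((iv.end_s - iv.start_s) / window_s + 1e-9))
        start_idx = int(round(iv.start_s * rec.fs))
        for k in range(n_seg):
            a = start_idx + k * m
            if a + m > rec.n_samples:
                break
            out.append(Segment(x=rec.data[:, a:a + m], label=iv.label,
                               subject_id=rec.subject_id, block_id=iv.block_id,
                               t0_s=a / rec.fs))
    return out


# ---------------------------------------------------------------------------
# Dual representation
# ---------------------------------------------------------------------------

def pca_plane(seg: Segment | np.ndarray) -> np.ndarray:
    """PCA score matrix of one segment: rows = electrodes, columns = scores
    on the first N principal axes in decreasing explained-variance order.

    The N channels are the observations and the M time samples the features;
    features are mean-centered across the N observations and the principal
    axes come from an SVD of the centered matrix.  With N observations the
    centered matrix has rank <= N-1, so trailing components past the rank are
    zero columns.  Each component's sign is fixed so that its
    largest-magnitude loading is positive, making the output deterministic
    across linear-algebra backends.
    """
    x = seg.x if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains NaN/Inf")
    n, m = x.shape
    if m < n:
        raise ValueError(f"need at least as many samples as channels ({m} < {n})")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s  # == xc @ vt.T, shape (n, min(n, m))
    # sign convention: dominant loading of each principal axis is positive
    for j in range(scores.shape[1]):
        if s[j] <= 1e-12 * max(1.0, s[0]):
            scores[:, j:] = 0.0
            break
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            scores[:, j] *= -1.0
    out = np.zeros((n, n))
    out[:, :scores.shape[1]] = scores[:, :n]
    return out


def pearson_plane(seg: Segment | np.ndarray) -> np.ndarray:
    """Pairwise Pearson channel-correlation matrix R of one segment.

    R is symmetric with a unit diagonal and entries in [-1, 1].  Any pair
    involving a zero-variance (flat-lined) channel is assigned correlation 0
    so the tensor stays finite; the diagonal stays 1.
    """
    x = seg.x if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 samples per channel")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc * xc).sum(axis=1))
    # flat-lined channels: variance negligible against the signal magnitude
    floor = 1e-10 * np.sqrt(m) * np.maximum(np.abs(x).max(axis=1), 1e-300)
    live = norms > floor
    denom = np.where(live, norms, 1.0)
    r = (xc @ xc.T) / np.outer(denom, denom)
    r[~live, :] = 0.0
    r[:, ~live] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def tensorize(seg: Segment | np.ndarray) -> np.ndarray:
    """Stack the PCA plane (index 0) and Pearson plane (index 1) into the
    (2, N, N) instance-branch tensor."""
    return np.stack([pca_plane(seg), pearson_plane(seg)])


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def balance(segments: list[Segment], seed: int) -> list[Segment]:
    """Subsample inter-ictal segments down to the pre-ictal count.

    All pre-ictal segments are kept; inter-ictal segments are drawn uniformly
    without replacement, deterministically under ``seed``, and the result is
    returned in time order.  If inter-ictal segments are already the minority
    (unusual in practice) everything is kept and a warning is raised.
    """
    pre = [s for s in segments if s.label == "preictal"]
    inter = [s for s in segments if s.label == "interictal"]
    if not pre or not inter:
        raise ValueError("both classes must be present before balancing")
    if len(inter) < len(pre):
        warnings.warn(
            f"inter-ictal segments ({len(inter)}) already fewer than "
            f"pre-ictal ({len(pre)}); keeping all", stacklevel=2)
        chosen = inter
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(inter), size=len(pre), replace=False)
        chosen = [inter[i] for i in sorted(idx)]
    out = pre + chosen
    out.sort(key=lambda s: s.t0_s)
    return out


# ---------------------------------------------------------------------------
# Array container + archive
# ---------------------------------------------------------------------------

@dataclass
class SegmentSet:
    """Array view over a list of segments, plus the tensorized planes.

    ``raw`` is (S, N, M); ``tensor`` is (S, 2, N, N); ``y`` holds the label
    codes (1 = pre-ictal); ``block_id`` the label-local block number;
    ``t0_s`` the segment start times.
    """
    raw: np.ndarray
    tensor: np.ndarray
    y: np.ndarray
    block_id: np.ndarray
    t0_s: np.ndarray
    subject_id: str
    fs: float
    meta: dict | None = None

    @classmethod
    def from_segments(cls, segments: list[Segment], fs: float,
                      meta: dict | None = None) -> "SegmentSet":
        if not segments:
            raise ValueError("no segments")
        raw = np.stack([s.x for s in segments])
        tensor = np.stack([tensorize(s) for s in segments])
        return cls(
            raw=raw, tensor=tensor,
            y=np.array([LABEL_CODES[s.label] for s in segments], dtype=np.int64),
            block_id=np.array([s.block_id for s in segments], dtype=np.int64),
            t0_s=np.array([s.t0_s for s in segments]),
            subject_id=segments[0].subject_id, fs=fs, meta=meta or {})

    def __len__(self) -> int:
        return self.raw.shape[0]

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(self.raw[idx], self.tensor[idx], self.y[idx],
                          self.block_id[idx], self.t0_s[idx],
                          self.subject_id, self.fs, self.meta)


def save_segments(path: str | Path, segs: SegmentSet) -> Path:
    """Persist a segment set (raw + tensor views and labels) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        # track_times=False keeps archives byte-identical across re-runs
        for name, data in [("raw", segs.raw), ("tensor", segs.tensor),
                           ("label", segs.y), ("block_id", segs.block_id),
                           ("t0_s", segs.t0_s)]:
            fh.create_dataset(name, data=data, track_times=False)
        fh.attrs["subject_id"] = segs.subject_id
        fh.attrs["fs"] = segs.fs
        fh.attrs["meta"] = json.dumps(segs.meta or {}, sort_keys=True)
    return path


def load_segments(path: str | Path) -> SegmentSet:
    with h5py.File(path, "r") as fh:
        return SegmentSet(
            raw=fh["raw"][()], tensor=fh["tensor"][()], y=fh["label"][()],
            block_id=fh["block_id"][()], t0_s=fh["t0_s"][()],
            subject_id=str(fh.attrs["subject_id"]), fs=float(fh.attrs["fs"]),
            meta=json.loads(fh.attrs["meta"]))
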
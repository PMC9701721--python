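"""Synthetic multichannel EEG with a controllable pre-ictal effect size.

Every recording is a sequence of ``n_seizures`` blocks, each laid out as

    [inter-ictal | pre-ictal | ictal (20 s)]

The inter-ictal and pre-ictal regimes share one generating model — channel-
correlated AR(1) noise plus band-limited oscillations in the theta (4-8 Hz),
alpha (8-13 Hz) and beta (13-30 Hz) bands — and differ only through two
effects, both scaled by the global effect size ``delta``:

* a channel-correlation shift: the equicorrelation level rises from
  ``base_corr`` to ``base_corr + delta * corr_shift`` in the pre-ictal regime
  (the axis the instance/CNN branch exploits), and
* a spectral shift: a fraction ``delta * spectral_shift`` of alpha-band power
  is moved, half each, into the theta and beta bands (the axis the
  sequence/LSTM branch exploits).

``delta = 0`` makes the two regimes identical by construction.  The ictal
stretch is a high-amplitude 3 Hz oscillation generated only so that labeling
code has something to exclude; it is never used as a class.

Amplitudes are on an arbitrary microvolt-like scale.  This is deliberately
not physiological EEG: no 1/f fit to real data, no artifacts — just the two
statistical axes the classifier branches are meant to detect, at a known
effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ingest import RawRecording, SeizureAnnotation

__all__ = ["SynthSpec", "generate_subject", "ICTAL_SECONDS"]

#: Duration of the synthetic ictal stretch appended after each pre-ictal block.
ICTAL_SECONDS = 20.0

# Oscillation bands (Hz) and their inter-ictal share of oscillatory power.
_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
_BASE_BAND_WEIGHTS = {"theta": 0.25, "alpha": 0.50, "beta": 0.25}


@dataclass
class SynthSpec:
    """Parameters of one synthetic subject.

    Parameters
    ----------
    n_channels
        Number of EEG channels N.
    fs
        Sampling rate in Hz (integer, so 1-s segments have a whole number of
        samples and EDF export uses 1-s records).
    n_seizures
        Number of seizures; at least 3, mirroring the eligibility rule used
        for real subjects.
    interictal_minutes_per_block
        Inter-ictal minutes preceding each pre-ictal block.
    preictal_minutes
        Pre-ictal horizon in minutes (default 30, the clinical horizon).
        Desk-scale runs typically shrink this.
    effect_size
        Global effect size ``delta`` >= 0; scales both regime differences.
    base_corr
        Inter-ictal equicorrelation level rho0.
    corr_shift
        Added to the correlation level in pre-ictal, times ``delta``.
    spectral_shift
        Fraction of alpha-band oscillatory power moved to theta+beta in
        pre-ictal, times ``delta``.  The default is deliberately large: the
        synthetic study runs on minutes rather than hours of data, so effect
        sizes are scaled up to keep the per-segment signal detectable.
    slow_wave_fraction
        Share of the moved alpha power that lands in theta; the remainder
        goes to beta.  The theta-heavy default emulates pre-ictal slowing,
        the EEG drifting toward slower rhythms before seizure onset.
    noise_fraction
        Share of per-channel variance taken by the AR(1) noise floor; the
        rest is oscillatory.
    ar_coeff
        AR(1) coefficient of the noise floor, in (-1, 1).
    amplitude
        Per-channel signal standard deviation (microvolt-like units).
    packet_seconds
        Oscillations are emitted as short tapered packets; each packet draws
        a fresh frequency and phase per channel and band, so the band's full
        width is exercised within every labeled block rather than each block
        keeping one idiosyncratic frequency.
    seed
        Seed for the generator; identical spec+seed gives identical output.
    """

    n_channels: int = 16
    fs: int = 256
    n_seizures: int = 4
    interictal_minutes_per_block: float = 10.0
    preictal_minutes: float = 30.0
    effect_size: float = 1.0
    base_corr: float = 0.2
    corr_shift: float = 0.3
    spectral_shift: float = 0.9
    slow_wave_fraction: float = 0.85
    noise_fraction: float = 0.2
    ar_coeff: float = 0.85
    amplitude: float = 30.0
    packet_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be a positive integer")
        if self.fs < 2:
            raise ValueError("fs must be a positive integer >= 2 Hz")
        if self.n_seizures < 3:
            raise ValueError(
                "n_seizures must be >= 3 (subjects need at least three "
                "seizures to be eligible for leave-one-seizure-out evaluation)"
            )
        if self.interictal_minutes_per_block <= 0:
            raise ValueError("interictal_minutes_per_block must be positive")
        if self.preictal_minutes <= 0:
            raise ValueError("preictal_minutes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size (delta) must be non-negative")
        if not 0 <= self.base_corr < 1:
            raise ValueError("base_corr must lie in [0, 1)")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in (-1, 1)")
        for corr in (self.base_corr, self.preictal_corr):
            _check_equicorrelation(corr, self.n_channels)
        moved = self.effect_size * self.spectral_shift
        if not 0 <= moved <= 1:
            raise ValueError(
                "effect_size * spectral_shift must lie in [0, 1]: it is the "
                "fraction of alpha power moved out in the pre-ictal regime"
            )
        if not 0 <= self.slow_wave_fraction <= 1:
            raise ValueError("slow_wave_fraction must lie in [0, 1]")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must lie in [0, 1]")

    @property
    def preictal_corr(self) -> float:
        """Equicorrelation level of the pre-ictal regime."""
        return self.base_corr + self.effect_size * self.corr_shift

    def band_weights(self, regime: str) -> dict[str, float]:
        """Oscillatory power share per band for ``'interictal'``/``'preictal'``."""
        w = dict(_BASE_BAND_WEIGHTS)
        if regime == "preictal":
            moved = w["alpha"] * self.effect_size * self.spectral_shift
            w["alpha"] -= moved
            w["theta"] += moved * self.slow_wave_fraction
            w["beta"] += moved * (1.0 - self.slow_wave_fraction)
        elif regime != "interictal":
            raise ValueError(f"unknown regime {regime!r}")
        return w


def _check_equicorrelation(rho: float, n: int) -> None:
    """An N x N equicorrelation matrix is positive definite iff
    -1/(N-1) < rho < 1."""
    lower = -1.0 / (n - 1) if n > 1 else -1.0
    if not lower < rho < 1.0:
        raise ValueError(
            f"requested channel correlation {rho:.3f} does not give a "
            f"positive-definite {n}x{n} correlation matrix "
            f"(need {lower:.3f} < rho < 1)"
        )


def _mixing_matrix(rho: float, n: int) -> np.ndarray:
    """Cholesky factor of the equicorrelation matrix with off-diagonal rho."""
    _check_equicorrelation(rho, n)
    corr = np.full((n, n), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _ar1_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               phi: float) -> np.ndarray:
    """Unit-variance stationary AR(1) noise, independent across channels."""
    innov_sd = np.sqrt(1.0 - phi * phi)
    burn = max(50, int(np.ceil(8.0 / max(1e-6, 1.0 - abs(phi)))))
    e = rng.standard_normal((n_channels, n_samples + burn)) * innov_sd
    u = sps.lfilter([1.0], [1.0, -phi], e, axis=1)
    return u[:, burn:]


def _band_oscillations(rng: np.random.Generator, spec: SynthSpec,
                       n_samples: int, regime: str) -> np.ndarray:
    """Unit-variance sum of band-limited sinusoid packets, per channel.

    Each channel draws its own frequency and phase per band and per packet,
    so distinct channels are essentially uncorrelated over a block and the
    cross-channel correlation is controlled entirely by the mixing matrix
    applied afterwards.  Packet edges carry a cosine taper to avoid hard
    discontinuities.
    """
    weights = spec.band_weights(regime)
    nyq = spec.fs / 2.0
    packet_len = max(int(round(spec.packet_seconds * spec.fs)), 2)
    out = np.zeros((spec.n_channels, n_samples))
    for start in range(0, n_samples, packet_len):
        n = min(packet_len, n_samples - start)
        t = np.arange(n) / spec.fs
        window = sps.windows.tukey(n, alpha=0.2)
        window /= np.sqrt(np.mean(window * window))
        packet = np.zeros((spec.n_channels, n))
        for band, (lo, hi) in _BANDS.items():
            hi = min(hi, 0.95 * nyq)
            if hi <= lo:  # band not representable at this rate
                continue
            freqs = rng.uniform(lo, hi, size=spec.n_channels)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
            amp = np.sqrt(2.0 * weights[band])
            packet += amp * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                                   + phases[:, None])
        out[:, start:start + n] = packet * window[None, :]
    return out


def _regime_block(rng: np.random.Generator, spec: SynthSpec, seconds: float,
                  regime: str) -> np.ndarray:
    """One block of correlated signal in the given regime, shape (N, n)."""
    n = int(round(seconds * spec.fs))
    rho = spec.base_corr if regime == "interictal" else spec.preictal_corr
    mix = _mixing_matrix(rho, spec.n_channels)
    z = (np.sqrt(spec.noise_fraction)
         * _ar1_noise(rng, spec.n_channels, n, spec.ar_coeff)
         + np.sqrt(1.0 - spec.noise_fraction)
         * _band_oscillations(rng, spec, n, regime))
    return spec.amplitude * (mix @ z)


def _ictal_block(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """High-amplitude 3 Hz discharge; labeling fodder only, never a class."""
    n = int(round(ICTAL_SECONDS * spec.fs))
    t = np.arange(n) / spec.fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
    wave = np.sin(2.0 * np.pi * 3.0 * t[None, :] + phases[:, None])
    noise = 0.2 * rng.standard_normal((spec.n_channels, n))
    return 3.0 * spec.amplitude * (wave + noise)


def generate_subject(spec: SynthSpec, subject_id: str = "synth") -> RawRecording:
    """Generate one synthetic subject as a continuous annotated recording.

    Returns a :class:`~preictal.ingest.RawRecording` with ``n_seizures``
    seizure annotations, each preceded by ``preictal_minutes`` of
    pre-ictal-regime signal, preceded in turn by
    ``interictal_minutes_per_block`` of inter-ictal-regime signal.
    Reproducible bit-for-bit from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pieces: list[np.ndarray] = []
    annotations: list[SeizureAnnotation] = []
    t = 0.0
    for _ in range(spec.n_seizures):
        pieces.append(_regime_block(
            rng, spec, spec.interictal_minutes_per_block * 60.0, "interictal"))
        pieces.append(_regime_block(
            rng, spec, spec.preictal_minutes * 60.0, "preictal"))
        t += (spec.interictal_minutes_per_block + spec.preictal_minutes) * 60.0
        pieces.append(_ictal_block(rng, spec))
        annotations.append(SeizureAnnotation(onset_s=t, offset_s=t + ICTAL_SECONDS))
        t += ICTAL_SECONDS
    data = np.concatenate(pieces, axis=1)
    names = [f"CH{i + 1:02d}" for i in range(spec.n_channels)]
    return RawRecording(data=data, fs=float(spec.fs), channel_names=names,
                        annotations=annotations, subject_id=subject_id)
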
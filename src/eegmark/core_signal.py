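"""Shared signal-processing primitives for scalp EEG.

Filtering, re-referencing, epoching, amplitude-based artifact rejection and
the complex Morlet wavelet transform used by every analysis stage. All
filters are zero-phase (forward-backward second-order sections), so event-
related latencies are preserved.

Conventions
-----------
* Voltages are microvolts throughout.
* Sample ``k`` of an epoch sits at ``t_start + k / rate``; every window is
  closed on the left and open on the right.
* The Morlet transform is normalized so that a unit-amplitude sinusoid at a
  center frequency yields coefficient magnitude 1 in steady state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "StageSeries",
    "EpochSet",
    "WaveletSpec",
    "MorletTF",
    "bandpass",
    "bandpass_array",
    "notch",
    "rereference",
    "epoch",
    "reject_amplitude",
    "morlet_kernel",
    "morlet_transform",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM", "ARTIFACT")


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    rate : float
        Sampling rate in samples/s (the study systems ran at 400 Hz).
    channel_labels : sequence of str
        One label per data row, e.g. ``"Cz"``.
    montage : mapping label -> (x, y), optional
        2-D layout coordinates (unitless); must cover every channel if given.
    reference_note : str
        Free-text provenance of the current reference.
    """

    data: np.ndarray
    rate: float
    channel_labels: Sequence[str]
    montage: Mapping[str, tuple[float, float]] | None = None
    reference_note: str = "as recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voltage values must be finite")
        if self.montage is not None:
            missing = [c for c in self.channel_labels if c not in self.montage]
            if missing:
                raise ValueError(f"montage missing channels: {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording ({self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.index(label)]


@dataclass
class StageSeries:
    """Hypnogram: one sleep-stage label per fixed-length scoring epoch."""

    labels: Sequence[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        bad = sorted(set(self.labels) - set(SLEEP_STAGES))
        if bad:
            raise ValueError(f"unknown stage labels {bad}; allowed {SLEEP_STAGES}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_length

    def minutes(self, stage: str) -> float:
        return self.labels.count(stage) * self.epoch_length / 60.0

    def sample_mask(self, rate: float, n_samples: int, stages: Sequence[str]) -> np.ndarray:
        """Boolean mask over samples belonging to any of ``stages``."""
        mask = np.zeros(n_samples, dtype=bool)
        per_epoch = int(round(self.epoch_length * rate))
        wanted = set(stages)
        for i, lab in enumerate(self.labels):
            if lab in wanted:
                mask[i * per_epoch : min((i + 1) * per_epoch, n_samples)] = True
        return mask

    def stage_at(self, t: float) -> str:
        """Stage label of the scoring epoch containing time ``t`` (seconds)."""
        i = int(t // self.epoch_length)
        if not 0 <= i < len(self.labels):
            raise IndexError(f"time {t} s outside staged range")
        return self.labels[i]


@dataclass
class EpochSet:
    """Stimulus-locked trials cut from a continuous recording."""

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    rate: float
    t_start: float
    condition: np.ndarray  # per-trial label
    kept_mask: np.ndarray  # per-trial bool
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        self.condition = np.asarray(self.condition)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        n = self.data.shape[0]
        if len(self.condition) != n or len(self.kept_mask) != n:
            raise ValueError("condition and kept_mask must have one entry per trial")
        self.channel_labels = list(self.channel_labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Data of kept trials, optionally restricted to one condition."""
        sel = self.kept_mask.copy()
        if condition is not None:
            sel &= self.condition == condition
        return self.data[sel]


@dataclass
class WaveletSpec:
    """Family of complex Morlet wavelets.

    ``cycles`` may be a scalar (shared by all frequencies) or a per-frequency
    array. Normalization is fixed to the unit-sinusoid convention.
    """

    center_freqs: np.ndarray
    cycles: float | np.ndarray = 7.0
    normalization: str = "unit-sinusoid"

    def __post_init__(self) -> None:
        self.center_freqs = np.atleast_1d(np.asarray(self.center_freqs, dtype=float))
        if np.any(self.center_freqs <= 0):
            raise ValueError("center frequencies must be positive")
        cyc = np.asarray(self.cycles, dtype=float)
        if np.any(cyc <= 0):
            raise ValueError("cycles must be positive")
        if cyc.ndim == 0:
            cyc = np.full_like(self.center_freqs, float(cyc))
        elif cyc.shape != self.center_freqs.shape:
            raise ValueError("cycles must be scalar or match center_freqs")
        self.cycles = cyc


class MorletTF(NamedTuple):
    """Complex Morlet coefficients plus an edge-validity mask."""

    coefs: np.ndarray  # (..., n_freqs, n_samples) complex
    valid: np.ndarray  # (n_freqs, n_samples) bool, False inside edge half-support


def _check_band(lo: float, hi: float, rate: float) -> None:
    nyq = rate / 2.0
    if lo <= 0:
        raise ValueError(f"low edge {lo} Hz must be positive")
    if hi <= lo:
        raise ValueError(f"high edge {hi} Hz must exceed low edge {lo} Hz")
    if hi >= nyq:
        raise ValueError(f"high edge {hi} Hz must be below Nyquist ({nyq} Hz)")


def bandpass_array(x: np.ndarray, rate: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    _check_band(lo, hi, rate)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase bandpass of every channel; returns a new Recording."""
    out = bandpass_array(rec.data, rec.rate, lo, hi, order=order)
    return replace(rec, data=out, reference_note=rec.reference_note + f"; bp {lo}-{hi} Hz")


def notch(rec: Recording, freq: float, q: float = 30.0) -> Recording:
    """Zero-phase notch (line-noise) filter at ``freq`` Hz."""
    if not 0 < freq < rec.rate / 2:
        raise ValueError(f"notch frequency {freq} Hz must lie in (0, Nyquist)")
    b, a = sps.iirnotch(freq, q, fs=rec.rate)
    out = sps.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=out, reference_note=rec.reference_note + f"; notch {freq} Hz")


def rereference(rec: Recording, ref_channels: Sequence[str]) -> Recording:
    """Subtract the mean of ``ref_channels`` from every channel, sample-wise."""
    if not ref_channels:
        raise ValueError("at least one reference channel required")
    idx = [rec.index(c) for c in ref_channels]
    ref = rec.data[idx].mean(axis=0)
    return replace(
        rec,
        data=rec.data - ref,
        reference_note=f"avg of {list(ref_channels)}",
    )


def epoch(
    rec: Recording,
    onsets: Sequence[float],
    t_start: float,
    t_end: float,
    condition: Sequence[str] | None = None,
) -> EpochSet:
    """Cut stimulus-locked windows ``[onset + t_start, onset + t_end)``.

    Events whose window falls outside the recording are dropped with a
    warning rather than raising.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    onsets = np.asarray(onsets, dtype=float)
    if condition is None:
        condition = np.array(["stim"] * len(onsets))
    condition = np.asarray(condition)
    if len(condition) != len(onsets):
        raise ValueError("one condition label per event required")

    n_samp = int(round((t_end - t_start) * rec.rate))
    starts = np.round((onsets + t_start) * rec.rate).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} event(s) with windows outside the recording",
            stacklevel=2,
        )
    starts = starts[ok]
    trials = np.stack(
        [rec.data[:, s : s + n_samp] for s in starts], axis=0
    ) if len(starts) else np.empty((0, rec.n_channels, n_samp))
    return EpochSet(
        data=trials,
        rate=rec.rate,
        t_start=t_start,
        condition=condition[ok],
        kept_mask=np.ones(len(starts), dtype=bool),
        channel_labels=rec.channel_labels,
    )


def reject_amplitude(ep: EpochSet, limit: float) -> EpochSet:
    """Mark trials containing any |sample| > ``limit`` microvolts as rejected.

    The data are untouched; only ``kept_mask`` changes (a trial already
    rejected stays rejected).
    """
    if limit <= 0:
        raise ValueError("amplitude limit must be positive")
    if ep.n_trials == 0:
        return ep
    peak = np.abs(ep.data).max(axis=(1, 2))
    kept = ep.kept_mask & (peak <= limit)
    return replace(ep, kept_mask=kept)


def morlet_kernel(freq: float, rate: float, cycles: float, trunc_sd: float = 4.0) -> np.ndarray:
    """Complex Morlet kernel, unit-sinusoid normalized.

    The Gaussian envelope has sigma_t = cycles / (2 pi f) and is truncated at
    ``trunc_sd`` standard deviations. Scaled so that convolving a
    unit-amplitude sinusoid at ``freq`` gives |coefficient| = 1.
    """
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.floor(trunc_sd * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kern = env * np.exp(2j * np.pi * freq * t)
    # real cosine splits into +/- frequency halves; the analytic kernel picks
    # up only the positive one, hence the factor 2
    return kern * (2.0 / env.sum())


def morlet_transform(signal: np.ndarray, rate: float, spec: WaveletSpec) -> MorletTF:
    """Complex Morlet transform along the last axis.

    Returns coefficients of shape ``(..., n_freqs, n_samples)`` and a
    ``(n_freqs, n_samples)`` validity mask that is False within half the
    wavelet support of either end (edge samples must not feed baselines or
    thresholds).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    kernels = [
        morlet_kernel(f, rate, c) for f, c in zip(spec.center_freqs, spec.cycles)
    ]
    longest = max(len(k) for k in kernels)
    if longest > n:
        raise ValueError(
            f"signal of {n} samples shorter than the longest wavelet "
            f"({longest} samples at {spec.center_freqs[np.argmax([len(k) for k in kernels])]:.3g} Hz); "
            f"need at least {longest} samples"
        )
    coefs = np.empty(x.shape[:-1] + (len(kernels), n), dtype=complex)
    valid = np.ones((len(kernels), n), dtype=bool)
    for i, k in enumerate(kernels):
        kb = k.reshape((1,) * (x.ndim - 1) + (-1,))
        coefs[..., i, :] = sps.fftconvolve(x, kb, mode="same", axes=-1)
        half = len(k) // 2
        if half > 0:
            valid[i, :half] = False
            valid[i, n - half :] = False
    return MorletTF(coefs=coefs, valid=valid)
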
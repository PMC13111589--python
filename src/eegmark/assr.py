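"""Auditory steady-state response: evoked power and phase consistency.

Click trains at 20/30/40/80 Hz entrain the EEG; the strength of the
entrainment is read out from a complex Morlet decomposition (7-cycle
wavelets at 30 linearly spaced frequencies, 10-100 Hz) of stimulus-locked
epochs:

* evoked power — power of the *trial-averaged* waveform (phase-locked
  content only), in dB relative to the mean power in a [-150, -50] ms
  pre-stimulus baseline: ``10 log10(P / P_baseline)``;
* inter-trial phase consistency (ITPC) — the resultant length
  ``| mean_trials exp(i phi) |`` of single-trial phases, in [0, 1].

Epochs are cut wider than the analysis window and cropped after the
transform so that wavelet edge effects (which at 10 Hz extend several
hundred ms) never touch the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_signal import (
    EpochSet,
    Recording,
    WaveletSpec,
    epoch,
    morlet_kernel,
    morlet_transform,
)

__all__ = ["TFResult", "ASSRConfig", "default_wavelet_spec", "evoked_power", "itpc", "score_assr"]


def default_wavelet_spec() -> WaveletSpec:
    """7-cycle Morlets at 30 linearly spaced frequencies from 10 to 100 Hz."""
    return WaveletSpec(center_freqs=np.linspace(10.0, 100.0, 30), cycles=7.0)


@dataclass
class ASSRConfig:
    channel: str = "Cz"
    t_start: float = -0.250
    t_end: float = 0.850
    baseline: tuple[float, float] = (-0.150, -0.050)
    reject_uv: float = 100.0
    band_halfwidth: float = 5.0  # Hz around the stimulation frequency
    summary_window: tuple[float, float] = (0.0, 0.500)  # s


@dataclass
class TFResult:
    """Time-frequency maps for one stimulation-frequency block."""

    freqs: np.ndarray
    times: np.ndarray
    evoked_power_db: np.ndarray  # freqs x times
    itpc: np.ndarray  # freqs x times, in [0, 1]
    n_trials: int
    stim_freq: float
    baseline_window: tuple[float, float] = (-0.150, -0.050)

    def band_time_mean(
        self, half_bw: float = 5.0, window: tuple[float, float] = (0.0, 0.5)
    ) -> dict:
        """Mean evoked dB and ITPC over stim_freq +/- half_bw and the window."""
        fsel = np.abs(self.freqs - self.stim_freq) <= half_bw
        tsel = (self.times >= window[0]) & (self.times < window[1])
        return {
            "stim_freq": self.stim_freq,
            "evoked_db": float(np.nanmean(self.evoked_power_db[np.ix_(fsel, tsel)])),
            "itpc": float(np.nanmean(self.itpc[np.ix_(fsel, tsel)])),
            "n_trials": self.n_trials,
        }


def _tf_one_channel(ep: EpochSet, channel: str, spec: WaveletSpec):
    ci = ep.channel_index(channel) if ep.channel_labels else 0
    data = ep.data[ep.kept_mask][:, ci, :]
    return data, morlet_transform(data, ep.rate, spec)


def evoked_power(
    ep: EpochSet,
    spec: WaveletSpec | None = None,
    baseline: tuple[float, float] = (-0.150, -0.050),
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-normalized power of the trial average, in dB.

    Returns ``(freqs, times, db_map)``. Raises if no kept trials or the
    baseline window intersects wavelet edge-invalid samples (at any
    frequency), because an edge-contaminated baseline silently biases the
    whole map.
    """
    spec = spec or default_wavelet_spec()
    if not ep.kept_mask.any():
        raise ValueError("no kept trials")
    ci = ep.channel_index(channel) if channel is not None else 0
    avg = ep.data[ep.kept_mask][:, ci, :].mean(axis=0)
    tf = morlet_transform(avg, ep.rate, spec)
    times = ep.times
    bsel = (times >= baseline[0]) & (times < baseline[1])
    if not bsel.any():
        raise ValueError("baseline window outside the epoch")
    if not tf.valid[:, bsel].all():
        raise ValueError(
            "baseline window overlaps wavelet edge-invalid samples; "
            "epoch wider or shorten the wavelet"
        )
    power = np.abs(tf.coefs) ** 2
    base = power[:, bsel].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(power / base)
    db[~tf.valid] = np.nan
    return spec.center_freqs, times, db


def itpc(
    ep: EpochSet,
    spec: WaveletSpec | None = None,
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-trial phase consistency map over kept trials.

    ITPC(f, t) = | mean over trials of exp(i phi_trial(f, t)) |, the
    resultant length of unit phase vectors; 1 for perfectly reproducible
    phase, ~1/sqrt(n) for random phase. Requires >= 2 kept trials.
    Edge-invalid samples are NaN.
    """
    spec = spec or default_wavelet_spec()
    if int(ep.kept_mask.sum()) < 2:
        raise ValueError("itpc requires at least 2 kept trials")
    ci = ep.channel_index(channel) if channel is not None else 0
    data = ep.data[ep.kept_mask][:, ci, :]
    tf = morlet_transform(data, ep.rate, spec)
    mag = np.abs(tf.coefs)
    unit = np.divide(tf.coefs, mag, out=np.zeros_like(tf.coefs), where=mag > 0)
    r = np.abs(unit.mean(axis=0))
    r[~tf.valid] = np.nan
    return spec.center_freqs, ep.times, r


def _max_half_support(spec: WaveletSpec, rate: float) -> float:
    """Half the longest wavelet support, in seconds."""
    longest = max(
        len(morlet_kernel(f, rate, c)) for f, c in zip(spec.center_freqs, spec.cycles)
    )
    return (longest // 2) / rate


def score_assr(
    rec: Recording,
    events: pd.DataFrame,
    config: ASSRConfig | None = None,
    spec: WaveletSpec | None = None,
) -> dict[float, TFResult]:
    """Per-stimulation-frequency TF maps from a click-train session.

    ``events`` needs columns onset_s and condition (frequency label, e.g.
    "40"). Epochs are cut with a pad of half the longest wavelet support on
    each side, amplitude-rejected at +/-100 uV over the analysis window,
    transformed, then cropped to [-250, 850) ms.
    """
    cfg = config or ASSRConfig()
    spec = spec or default_wavelet_spec()
    pad = _max_half_support(spec, rec.rate) + 2.0 / rec.rate
    results: dict[float, TFResult] = {}
    for label in pd.unique(events["condition"]):
        stim_freq = float(label)
        onsets = events.loc[events["condition"] == label, "onset_s"].to_numpy()
        ep = epoch(rec, onsets, cfg.t_start - pad, cfg.t_end + pad)
        # reject on the analysis window only, as the recorded epoch would be
        tsel = (ep.times >= cfg.t_start) & (ep.times < cfg.t_end)
        peak = np.abs(ep.data[:, :, tsel]).max(axis=(1, 2)) if ep.n_trials else np.array([])
        kept = ep.kept_mask & (peak <= cfg.reject_uv)
        ep = EpochSet(
            data=ep.data,
            rate=ep.rate,
            t_start=ep.t_start,
            condition=ep.condition,
            kept_mask=kept,
            channel_labels=ep.channel_labels,
        )
        freqs, times_full, db = evoked_power(
            ep, spec, baseline=cfg.baseline, channel=cfg.channel
        )
        _, _, r = itpc(ep, spec, channel=cfg.channel)
        crop = (times_full >= cfg.t_start) & (times_full < cfg.t_end)
        results[stim_freq] = TFResult(
            freqs=freqs,
            times=times_full[crop],
            evoked_power_db=db[:, crop],
            itpc=r[:, crop],
            n_trials=int(kept.sum()),
            stim_freq=stim_freq,
            baseline_window=cfg.baseline,
        )
    return results
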
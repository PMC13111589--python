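"""P50 paired-click sensory-gating scoring.

The paired-click paradigm presents two identical clicks 500 ms apart; the
cortical response to the second (S2) is normally suppressed relative to the
first (S1). Gating is quantified as the ratio of S2 to S1 amplitude, where
amplitude is the most prominent positive peak in the 40-80 ms post-stimulus
window minus its preceding trough; a higher ratio means worse gating.

Scoring is deterministic: "most prominent" is formalized as the positive
local maximum maximizing peak-minus-preceding-trough, ties broken toward the
earlier latency, and a missing peak is a status, not an exception —
mirroring how subjects without a scoreable S1 are excluded rather than
crashing a cohort run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .core_signal import EpochSet, Recording, bandpass_array, epoch, reject_amplitude

__all__ = ["P50Score", "GatingConfig", "average_erp", "find_p50_s1", "find_p50_s2", "score_gating"]


@dataclass
class GatingConfig:
    channel: str = "Cz"
    t_start: float = -0.100
    t_end: float = 0.400
    band: tuple[float, float] = (10.0, 50.0)
    reject_uv: float = 100.0
    s1_window: tuple[float, float] = (0.040, 0.080)  # s post-stimulus
    s2_halfwidth: float = 0.015  # s around the S1 latency
    filter_after_epoch: bool = True


@dataclass
class P50Score:
    """Scored gating for one subject/session. Latencies in ms, amplitudes in uV."""

    s1_latency: float = np.nan
    s1_amplitude: float = np.nan
    s2_latency: float = np.nan
    s2_amplitude: float = np.nan
    ratio: float = np.nan
    n_trials_kept: int = 0
    status: str = "ok"  # ok | s1_not_detected | s2_not_detected

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def average_erp(ep: EpochSet, condition: str, channel: str = "Cz") -> np.ndarray:
    """Point-wise mean over kept trials of one condition at one channel."""
    trials = ep.kept(condition)
    if trials.shape[0] == 0:
        raise ValueError(f"no kept trials for condition {condition!r}")
    ci = ep.channel_index(channel)
    return trials[:, ci, :].mean(axis=0)


def _positive_peaks(w: np.ndarray, i_lo: int, i_hi: int) -> np.ndarray:
    """Indices of positive-valued local maxima of w within [i_lo, i_hi]."""
    maxima = argrelextrema(w, np.greater_equal, order=1)[0]
    # greater_equal admits plateaus; keep strict-neighborhood maxima only,
    # first sample of a plateau wins (earlier-latency tie-break)
    keep = []
    for i in maxima:
        if 0 < i < len(w) - 1 and w[i] > 0 and i_lo <= i <= i_hi:
            if keep and i == keep[-1] + 1 and w[i] == w[keep[-1]]:
                continue
            keep.append(i)
    return np.array(keep, dtype=int)


def _preceding_trough(w: np.ndarray, peak_i: int, i_zero: int) -> int:
    """Nearest local minimum before the peak, searching back to time zero.

    Falls back to the minimum sample in [i_zero, peak) when no interior local
    minimum exists there.
    """
    minima = argrelextrema(w, np.less, order=1)[0]  # strict: plateaus are not troughs
    minima = minima[(minima >= i_zero) & (minima < peak_i) & (minima > 0)]
    if len(minima):
        return int(minima[-1])
    seg = w[i_zero:peak_i]
    if len(seg) == 0:
        return i_zero
    return i_zero + int(np.argmin(seg))


def find_p50_s1(
    avg: np.ndarray,
    rate: float,
    t_start: float,
    window: tuple[float, float] = (0.040, 0.080),
) -> tuple[float, float, str]:
    """Locate S1: most prominent positive peak in the scoring window.

    Returns (latency_s, amplitude_uv, status); amplitude is peak minus the
    preceding trough. Without any positive local maximum in the window the
    status is ``s1_not_detected`` and latency/amplitude are NaN.
    """
    w = np.asarray(avg, dtype=float)
    i_zero = int(round(-t_start * rate))
    i_lo = i_zero + int(round(window[0] * rate))
    i_hi = i_zero + int(round(window[1] * rate))
    peaks = _positive_peaks(w, i_lo, i_hi)
    if len(peaks) == 0:
        return np.nan, np.nan, "s1_not_detected"
    best = None
    for p in peaks:
        trough = _preceding_trough(w, p, i_zero)
        amp = w[p] - w[trough]
        if best is None or amp > best[1]:  # strict > keeps earliest on ties
            best = (p, amp)
    latency = (best[0] - i_zero) / rate
    return latency, float(best[1]), "ok"


def find_p50_s2(
    avg_s2: np.ndarray,
    rate: float,
    t_start: float,
    s1_latency: float,
    window_halfwidth: float = 0.015,
) -> tuple[float, float, str]:
    """Locate S2: positive peak within +/-15 ms of the S1 latency.

    An absent positive peak is scored as amplitude 0 (complete gating) with
    status ``s2_not_detected``.
    """
    w = np.asarray(avg_s2, dtype=float)
    i_zero = int(round(-t_start * rate))
    i_lo = i_zero + int(round((s1_latency - window_halfwidth) * rate))
    i_hi = i_zero + int(round((s1_latency + window_halfwidth) * rate))
    peaks = _positive_peaks(w, max(i_lo, i_zero + 1), i_hi)
    if len(peaks) == 0:
        return np.nan, 0.0, "s2_not_detected"
    best = None
    for p in peaks:
        trough = _preceding_trough(w, p, i_zero)
        amp = w[p] - w[trough]
        if best is None or amp > best[1]:
            best = (p, amp)
    latency = (best[0] - i_zero) / rate
    return latency, float(best[1]), "ok"


def score_gating(
    rec: Recording, events: pd.DataFrame, config: GatingConfig | None = None
) -> P50Score:
    """Full paired-click scoring pipeline for one session.

    Epochs [-100, 400) ms around each S1/S2 onset, bandpasses 10-50 Hz
    (after epoching by default, configurable), rejects trials exceeding
    +/-100 uV, averages per condition at the scoring channel, and applies
    the S1/S2 peak rules. ``events`` needs columns onset_s and condition
    with labels S1/S2.
    """
    cfg = config or GatingConfig()
    work = rec
    if not cfg.filter_after_epoch:
        from .core_signal import bandpass

        work = bandpass(work, *cfg.band)
    ep = epoch(
        work,
        events["onset_s"].to_numpy(),
        cfg.t_start,
        cfg.t_end,
        events["condition"].to_numpy(),
    )
    if cfg.filter_after_epoch and ep.n_trials:
        ep = EpochSet(
            data=bandpass_array(ep.data, ep.rate, *cfg.band),
            rate=ep.rate,
            t_start=ep.t_start,
            condition=ep.condition,
            kept_mask=ep.kept_mask,
            channel_labels=ep.channel_labels,
        )
    ep = reject_amplitude(ep, cfg.reject_uv)
    n_kept = int(ep.kept_mask.sum())

    score = P50Score(n_trials_kept=n_kept)
    try:
        avg_s1 = average_erp(ep, "S1", cfg.channel)
        avg_s2 = average_erp(ep, "S2", cfg.channel)
    except ValueError:
        score.status = "s1_not_detected"
        return score

    lat1, amp1, st1 = find_p50_s1(avg_s1, ep.rate, ep.t_start, cfg.s1_window)
    if st1 != "ok":
        score.status = "s1_not_detected"
        return score
    score.s1_latency = lat1 * 1e3
    score.s1_amplitude = amp1

    lat2, amp2, st2 = find_p50_s2(avg_s2, ep.rate, ep.t_start, lat1, cfg.s2_halfwidth)
    score.s2_amplitude = amp2
    score.status = st2 if st2 != "ok" else "ok"
    if st2 == "ok":
        score.s2_latency = lat2 * 1e3
    score.ratio = amp2 / amp1
    return score
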
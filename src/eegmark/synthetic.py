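"""Synthetic multi-subject EEG with known ground truth.

Emulates the three paradigms the analysis stages consume:

* staged overnight-style sleep EEG with 12-15 Hz spindle bursts injected into
  N2/N3 at a controllable density and amplitude;
* paired-click sessions with an S1 component (biphasic trough-then-peak,
  positive peak near 55 ms) and an S2 component scaled by a gating factor,
  500 ms later, pairs every 10 s;
* click-train sessions (20/30/40/80 Hz, 150 trains of 500 ms, 1100 ms onset
  asynchrony) whose per-train phase is von Mises distributed, so the
  inter-trial phase consistency has the closed-form large-n limit
  I1(kappa)/I0(kappa).

The background is 1/f ("pink-ish") noise shared across channels through a
rank-1 spatial model: one noise process scaled by per-channel gains. That is
deliberately simple — it makes electrode-cluster statistics meaningful
without pretending to model scalp physics.

Every generator is deterministic under its seed; per-subject streams are
spawned from the cohort master seed, so a cohort is reproducible as a whole
and subject-by-subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_signal import Recording, StageSeries

__all__ = [
    "SubjectSpec",
    "CohortSpec",
    "Cohort",
    "SubjectData",
    "make_background",
    "inject_spindles",
    "make_sleep_subject",
    "make_p50_session",
    "make_assr_session",
    "make_montage",
    "make_cohort",
    "desk_cohort_spec",
    "DEFAULT_GROUP_PARAMS",
    "DEFAULT_PARAM_SD",
]

GROUPS = ("EC", "FHR", "NC")

# 10-20-ish labels for small montages; larger layouts extend with E## names.
_BASE_LABELS = ["Cz", "Fz", "Pz", "C3", "C4", "F3", "F4", "Oz"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SubjectSpec:
    """Ground-truth parameters for one synthetic subject."""

    subject_id: str
    group: str = "NC"
    age: float = 22.0
    spindle_density_true: float = 2.5  # events/min in N2 and N3
    spindle_amp_true: float = 25.0  # uV envelope peak
    gating_factor_true: float = 0.5  # S2 scale relative to S1
    p50_amp_true: float = 3.0  # S1 peak-to-trough, uV
    assr_amp_true: float | Mapping[float, float] = 1.0  # uV per stim freq
    assr_kappa_true: float | Mapping[float, float] = 2.0  # von Mises concentration
    noise_rms: float = 8.0  # uV, sleep background
    wake_noise_rms: float = 5.0  # uV, paired-click / click-train sessions
    noise_slope: float = 1.0  # 1/f exponent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.spindle_density_true < 0:
            raise ValueError("spindle_density_true must be >= 0")
        if self.gating_factor_true < 0:
            raise ValueError("gating_factor_true must be >= 0")

    def assr_amp(self, freq: float) -> float:
        if isinstance(self.assr_amp_true, Mapping):
            return float(self.assr_amp_true[freq])
        return float(self.assr_amp_true)

    def assr_kappa(self, freq: float) -> float:
        if isinstance(self.assr_kappa_true, Mapping):
            return float(self.assr_kappa_true[freq])
        return float(self.assr_kappa_true)


def make_background(
    duration: float,
    rate: float,
    rms: float,
    slope: float = 1.0,
    seed=None,
    f_floor: float = 0.5,
) -> np.ndarray:
    """Zero-mean 1/f^slope noise with the requested RMS.

    Spectral shaping is applied in the frequency domain; below ``f_floor``
    the spectrum is held flat so the variance stays finite for slope >= 1.
    """
    if rms <= 0:
        raise ValueError("rms must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration * rate must be at least 2 samples")
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    above = f >= f_floor
    shape[above] = (f[above] / f_floor) ** (-slope / 2.0)
    spec *= shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    return x * (rms / np.sqrt(np.mean(x**2)))


def _spindle_waveform(dur: float, rate: float, freq: float, amp: float) -> np.ndarray:
    """Raised-cosine (waxing-waning) burst whose carrier peaks at the center."""
    n = int(round(dur * rate))
    t = np.arange(n) / rate
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / dur))
    carrier = np.cos(2.0 * np.pi * freq * (t - dur / 2.0))
    return amp * envelope * carrier


def inject_spindles(
    background: np.ndarray,
    rate: float,
    density: float,
    amp: float,
    freq: float = 13.5,
    dur_range: tuple[float, float] = (0.5, 1.5),
    seed=None,
    t_offset: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Add non-overlapping spindle bursts at ``density`` events/min.

    Candidate onsets follow a Poisson process thinned to non-overlap (an
    event whose interval intersects an already-placed one is discarded).
    Returns the augmented signal and a truth table with one row per event
    (onset_s, duration_s, peak_s, amplitude_uv, freq_hz); ``t_offset`` shifts
    the reported times, for stitching segments into a longer recording.
    """
    lo, hi = dur_range
    if not (0.3 <= lo <= hi <= 3.0):
        raise ValueError("dur_range must lie within [0.3, 3.0] s")
    out = np.array(background, dtype=float, copy=True)
    n = len(out)
    duration_s = n / rate
    cols = ["onset_s", "duration_s", "peak_s", "amplitude_uv", "freq_hz"]
    if density == 0:
        return out, pd.DataFrame(columns=cols)
    if density < 0:
        raise ValueError("density must be >= 0")
    mean_dur = (lo + hi) / 2.0
    max_density = 60.0 / mean_dur
    if density > 0.8 * max_density:
        raise ValueError(
            f"density {density}/min infeasible without overlap; "
            f"maximum feasible is about {0.8 * max_density:.1f}/min"
        )
    rng = _rng(seed)
    n_candidates = rng.poisson(density / 60.0 * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n_candidates))
    durs = rng.uniform(lo, hi, size=n_candidates)
    rows = []
    last_end = -np.inf
    for onset, dur in zip(onsets, durs):
        if onset < last_end or onset + dur > duration_s:
            continue  # thin to non-overlap / drop truncated tail events
        i0 = int(round(onset * rate))
        wave = _spindle_waveform(dur, rate, freq, amp)
        out[i0 : i0 + len(wave)] += wave
        rows.append(
            {
                "onset_s": onset + t_offset,
                "duration_s": dur,
                "peak_s": onset + dur / 2.0 + t_offset,
                "amplitude_uv": amp,
                "freq_hz": freq,
            }
        )
        last_end = onset + dur
    return out, pd.DataFrame(rows, columns=cols)


def make_montage(n_channels: int) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Labels plus a roughly circular 2-D layout for ``n_channels`` sites.

    Channels are placed on concentric rings (vertex first), which gives a
    layout-distance adjacency comparable to a real cap.
    """
    labels = [
        _BASE_LABELS[i] if i < len(_BASE_LABELS) else f"E{i + 1}"
        for i in range(n_channels)
    ]
    pos: dict[str, tuple[float, float]] = {}
    placed = 0
    ring = 0
    while placed < n_channels:
        if ring == 0:
            pos[labels[0]] = (0.0, 0.0)
            placed = 1
        else:
            k = min(6 * ring, n_channels - placed)
            for j in range(k):
                theta = 2.0 * np.pi * j / (6 * ring)
                pos[labels[placed + j]] = (
                    ring * np.cos(theta),
                    ring * np.sin(theta),
                )
            placed += k
        ring += 1
    return labels, pos


def _channel_gains(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    gains = rng.uniform(0.7, 1.3, size=n_channels)
    gains[0] = 1.0  # Cz is the scoring channel; keep its gain at unity
    return gains


def make_sleep_subject(
    spec: SubjectSpec,
    minutes_n2: float = 10.0,
    minutes_n3: float = 5.0,
    n_channels: int = 8,
    rate: float = 400.0,
    wake_minutes: float = 1.0,
) -> tuple[Recording, StageSeries, pd.DataFrame]:
    """Staged sleep recording with spindles injected only in N2/N3.

    Layout: wake, N2 block, N3 block, wake. All channels share the spindle
    events and the background process, scaled by per-channel gains.
    """
    if minutes_n2 < 1 or minutes_n3 < 1:
        raise ValueError("at least 1 minute of each NREM stage required")
    rng = _rng(np.random.SeedSequence(spec.seed))
    epochs_per_min = 2  # 30-s scoring epochs
    labels = (
        ["W"] * int(round(wake_minutes * epochs_per_min))
        + ["N2"] * int(round(minutes_n2 * epochs_per_min))
        + ["N3"] * int(round(minutes_n3 * epochs_per_min))
        + ["W"] * int(round(wake_minutes * epochs_per_min))
    )
    stages = StageSeries(labels)
    total_s = stages.duration
    base = make_background(total_s, rate, spec.noise_rms, spec.noise_slope, seed=rng)

    density = spec.spindle_density_true
    truth_parts = []
    signal = base.copy()
    # inject per contiguous NREM block so events respect stage boundaries
    t = 0.0
    for lab in ("N2", "N3"):
        blocks = _stage_blocks(labels, lab)
        for b0, b1 in blocks:
            t0, t1 = b0 * 30.0, b1 * 30.0
            i0, i1 = int(t0 * rate), int(t1 * rate)
            seg, truth = inject_spindles(
                signal[i0:i1], rate, density, spec.spindle_amp_true, seed=rng, t_offset=t0
            )
            signal[i0:i1] = seg
            truth["stage"] = lab
            truth_parts.append(truth)
    truth_parts = [t for t in truth_parts if len(t)]
    truth_all = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame(
            columns=["onset_s", "duration_s", "peak_s", "amplitude_uv", "freq_hz", "stage"]
        )
    )
    truth_all = truth_all.sort_values("onset_s", ignore_index=True) if len(truth_all) else truth_all

    gains = _channel_gains(n_channels, rng)
    data = gains[:, None] * signal[None, :]
    ch_labels, montage = make_montage(n_channels)
    rec = Recording(data=data, rate=rate, channel_labels=ch_labels, montage=montage)
    return rec, stages, truth_all


def _stage_blocks(labels: Sequence[str], stage: str) -> list[tuple[int, int]]:
    """Contiguous runs of ``stage`` as (first_epoch, last_epoch_exclusive)."""
    blocks = []
    start = None
    for i, lab in enumerate(labels):
        if lab == stage and start is None:
            start = i
        elif lab != stage and start is not None:
            blocks.append((start, i))
            start = None
    if start is not None:
        blocks.append((start, len(labels)))
    return blocks


def p50_template(rate: float, p2t: float, peak_s: float = 0.055) -> np.ndarray:
    """Cortical paired-click component: trough-then-peak, positive peak ~55 ms.

    A 25 Hz carrier under a Gaussian envelope (sigma 24 ms), so its energy
    sits inside the 10-50 Hz scoring band and the zero-phase bandpass barely
    reshapes it. Scaled so that (positive peak minus preceding trough)
    equals ``p2t``. Returns 150 ms of waveform starting at stimulus onset.
    """
    t = np.arange(int(round(0.150 * rate))) / rate
    carrier_f = 25.0
    env = np.exp(-((t - 0.050) ** 2) / (2.0 * 0.024**2))
    w = env * np.cos(2.0 * np.pi * carrier_f * (t - peak_s))
    peak_i = int(round(peak_s * rate))
    trough_i = np.argmin(w[:peak_i])
    scale = p2t / (w[peak_i] - w[trough_i])
    return w * scale


def make_p50_session(
    spec: SubjectSpec,
    n_trials: int = 240,
    isi: float = 0.5,
    iti: float = 10.0,
    rate: float = 400.0,
    n_channels: int = 1,
) -> tuple[Recording, pd.DataFrame]:
    """Paired-click session: S1 at each trial onset, S2 ``isi`` later.

    The S2 component is the S1 template scaled by ``gating_factor_true``.
    Events table columns: onset_s, condition in {S1, S2}.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(np.random.SeedSequence((spec.seed, 1)))
    lead = 2.0
    total_s = lead + n_trials * iti + 2.0
    n = int(round(total_s * rate))
    template = p50_template(rate, spec.p50_amp_true)
    signal = np.zeros(n)
    rows = []
    for k in range(n_trials):
        for cond, t_on, scale in (
            ("S1", lead + k * iti, 1.0),
            ("S2", lead + k * iti + isi, spec.gating_factor_true),
        ):
            i0 = int(round(t_on * rate))
            signal[i0 : i0 + len(template)] += scale * template
            rows.append({"onset_s": i0 / rate, "condition": cond})
    events = pd.DataFrame(rows)

    if spec.wake_noise_rms > 0:
        noise = make_background(total_s, rate, spec.wake_noise_rms, spec.noise_slope, seed=rng)
    else:
        noise = np.zeros(n)
    gains = _channel_gains(n_channels, rng)
    data = gains[:, None] * (signal + noise)[None, :]
    ch_labels, montage = make_montage(n_channels)
    rec = Recording(data=data, rate=rate, channel_labels=ch_labels, montage=montage)
    return rec, events


def make_assr_session(
    spec: SubjectSpec,
    stim_freqs: Sequence[float] = (20.0, 30.0, 40.0, 80.0),
    n_trains: int = 150,
    train_dur: float = 0.5,
    soa: float = 1.1,
    rate: float = 400.0,
    n_channels: int = 1,
    block_gap: float = 5.0,
) -> tuple[Recording, pd.DataFrame]:
    """Click-train session: blocks of ``n_trains`` trains per stimulation rate.

    Each train contributes a sinusoid at the block frequency for
    ``train_dur`` seconds (5 ms cosine on/off ramps). The per-train phase is
    von Mises around 0 with concentration ``assr_kappa_true``, which sets the
    asymptotic inter-trial phase consistency to I1(kappa)/I0(kappa).
    Events table columns: onset_s, condition = frequency label like "40".
    """
    for f in stim_freqs:
        if not 0 < f < rate / 2:
            raise ValueError(f"stimulation frequency {f} Hz must be below Nyquist")
    rng = _rng(np.random.SeedSequence((spec.seed, 2)))
    lead = 2.0
    block_len = n_trains * soa
    total_s = lead + len(stim_freqs) * (block_len + block_gap) + 2.0
    n = int(round(total_s * rate))
    signal = np.zeros(n)
    rows = []
    n_train_samp = int(round(train_dur * rate))
    t_train = np.arange(n_train_samp) / rate
    ramp = np.ones(n_train_samp)
    n_ramp = int(round(0.005 * rate))
    if n_ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        ramp[:n_ramp] = edge
        ramp[-n_ramp:] = edge[::-1]
    for b, f in enumerate(stim_freqs):
        amp = spec.assr_amp(f)
        kappa = spec.assr_kappa(f)
        block_t0 = lead + b * (block_len + block_gap)
        if kappa >= 1e6:
            phases = np.zeros(n_trains)
        else:
            phases = rng.vonmises(0.0, kappa, size=n_trains)
        for k in range(n_trains):
            t_on = block_t0 + k * soa
            i0 = int(round(t_on * rate))
            signal[i0 : i0 + n_train_samp] += (
                amp * ramp * np.sin(2.0 * np.pi * f * t_train + phases[k])
            )
            rows.append({"onset_s": i0 / rate, "condition": f"{f:g}"})
    events = pd.DataFrame(rows)

    if spec.wake_noise_rms > 0:
        noise = make_background(total_s, rate, spec.wake_noise_rms, spec.noise_slope, seed=rng)
    else:
        noise = np.zeros(n)
    gains = _channel_gains(n_channels, rng)
    data = gains[:, None] * (signal + noise)[None, :]
    ch_labels, montage = make_montage(n_channels)
    rec = Recording(data=data, rate=rate, channel_labels=ch_labels, montage=montage)
    return rec, events


# ---------------------------------------------------------------------------
# cohort assembly


# Group-level means for the true parameters. Group sizes and age
# distributions follow the study sample (EC 15, FHR 24, NC 28; ages ~21-24);
# effect directions follow its findings: spindle-density and gating deficits
# in EC, reduced 40 Hz phase locking in both EC and FHR, other stimulation
# rates equal across groups.
DEFAULT_GROUP_PARAMS: dict[str, dict[str, float]] = {
    "EC": {
        "age_mean": 20.6,
        "age_sd": 3.8,
        "spindle_density": 1.8,
        "spindle_amp": 22.0,
        "gating_factor": 0.8,
        "assr_kappa_40": 1.0,
        "assr_amp_40": 0.7,
    },
    "FHR": {
        "age_mean": 22.9,
        "age_sd": 6.1,
        "spindle_density": 2.6,
        "spindle_amp": 25.0,
        "gating_factor": 0.5,
        "assr_kappa_40": 1.0,
        "assr_amp_40": 0.7,
    },
    "NC": {
        "age_mean": 24.0,
        "age_sd": 4.5,
        "spindle_density": 2.8,
        "spindle_amp": 25.0,
        "gating_factor": 0.45,
        "assr_kappa_40": 2.0,
        "assr_amp_40": 1.0,
    },
}

# Between-subject SDs of the true parameters.
DEFAULT_PARAM_SD: dict[str, float] = {
    "spindle_density": 0.3,
    "spindle_amp": 2.0,
    "gating_factor": 0.12,
    "assr_kappa_40": 0.25,
    "assr_amp_40": 0.1,
}

# Stimulation rates without group differences share these values.
_ASSR_OTHER = {"kappa": 1.2, "amp": 0.6}


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``group_params`` holds per-group means of every true parameter;
    ``param_sd`` the between-subject SDs. Paradigm timing defaults follow
    the study protocol (paired clicks 500 ms apart every 10 s; 150 click
    trains at 1100 ms onset asynchrony).
    """

    counts: Mapping[str, int] = field(
        default_factory=lambda: {"EC": 15, "FHR": 24, "NC": 28}
    )
    group_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_PARAMS.items()}
    )
    param_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_SD))
    noise_rms: float = 8.0
    noise_slope: float = 1.0
    master_seed: int = 0
    # paradigm/timing block
    rate: float = 400.0
    sleep_minutes_n2: float = 10.0
    sleep_minutes_n3: float = 5.0
    sleep_channels: int = 8
    p50_trials: int = 240
    p50_isi: float = 0.5
    p50_iti: float = 10.0
    assr_freqs: tuple[float, ...] = (20.0, 30.0, 40.0, 80.0)
    assr_trains: int = 150
    assr_train_dur: float = 0.5
    assr_soa: float = 1.1

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("group counts must be >= 0")


@dataclass
class SubjectData:
    """Materialized recordings for one subject."""

    spec: SubjectSpec
    sleep: tuple[Recording, StageSeries, pd.DataFrame]
    p50: tuple[Recording, pd.DataFrame]
    assr: tuple[Recording, pd.DataFrame]


class Cohort:
    """Lazy cohort: subject specs up front, recordings generated on demand.

    Recordings are sizeable (minutes of multichannel 400 Hz signal), so the
    cohort materializes one subject at a time; ``iter_subjects`` regenerates
    identical data on every pass because each subject carries its own seed.
    """

    def __init__(self, spec: CohortSpec, subject_specs: list[SubjectSpec]):
        self.spec = spec
        self.subject_specs = subject_specs

    def __len__(self) -> int:
        return len(self.subject_specs)

    @property
    def manifest(self) -> pd.DataFrame:
        """Truth manifest: one row per subject with every true parameter."""
        rows = []
        for s in self.subject_specs:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age": s.age,
                    "spindle_density_true": s.spindle_density_true,
                    "spindle_amp_true": s.spindle_amp_true,
                    "gating_factor_true": s.gating_factor_true,
                    "assr_kappa_40_true": s.assr_kappa(40.0),
                    "assr_amp_40_true": s.assr_amp(40.0),
                    "noise_rms": s.noise_rms,
                    "seed": s.seed,
                }
            )
        return pd.DataFrame(rows)

    def materialize(self, subject_id: str) -> SubjectData:
        spec = next(s for s in self.subject_specs if s.subject_id == subject_id)
        c = self.spec
        return SubjectData(
            spec=spec,
            sleep=make_sleep_subject(
                spec,
                minutes_n2=c.sleep_minutes_n2,
                minutes_n3=c.sleep_minutes_n3,
                n_channels=c.sleep_channels,
                rate=c.rate,
            ),
            p50=make_p50_session(
                spec,
                n_trials=c.p50_trials,
                isi=c.p50_isi,
                iti=c.p50_iti,
                rate=c.rate,
            ),
            assr=make_assr_session(
                spec,
                stim_freqs=c.assr_freqs,
                n_trains=c.assr_trains,
                train_dur=c.assr_train_dur,
                soa=c.assr_soa,
                rate=c.rate,
            ),
        )

    def iter_subjects(self):
        for s in self.subject_specs:
            yield self.materialize(s.subject_id)


def desk_cohort_spec(master_seed: int = 0, scale: str = "desk") -> CohortSpec:
    """Preconfigured cohort recipes.

    ``"desk"`` is sized to run end to end in a few minutes on one CPU
    (10 subjects per group, shortened recordings, the 40 Hz block only --
    10 min of N2 keeps the Poisson noise of per-subject density estimates
    well below the configured group effects);
    ``"study"`` mirrors the source study's design (15/24/28 subjects,
    full paradigm timing) and takes tens of minutes.
    """
    if scale == "desk":
        return CohortSpec(
            counts={"EC": 10, "FHR": 10, "NC": 10},
            master_seed=master_seed,
            sleep_minutes_n2=10,
            sleep_minutes_n3=2,
            p50_trials=120,
            assr_freqs=(40.0,),
            assr_trains=100,
        )
    if scale == "study":
        return CohortSpec(master_seed=master_seed)
    raise ValueError(f"unknown scale {scale!r}; use 'desk' or 'study'")


def make_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Draw per-subject true parameters and assemble a lazy cohort.

    Non-negative parameters are clipped at zero after the Gaussian draw.
    With ``out_dir`` given, writes the truth manifest as CSV there.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    rng = np.random.default_rng(ss)
    subject_specs: list[SubjectSpec] = []
    child_seeds = ss.spawn(sum(spec.counts.values()))
    i = 0
    for group in GROUPS:
        n = int(spec.counts.get(group, 0))
        gp = spec.group_params[group]
        sd = spec.param_sd
        for _ in range(n):
            subject_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
            density = max(0.0, rng.normal(gp["spindle_density"], sd["spindle_density"]))
            amp = max(1.0, rng.normal(gp["spindle_amp"], sd["spindle_amp"]))
            gating = max(0.0, rng.normal(gp["gating_factor"], sd["gating_factor"]))
            kappa40 = max(0.05, rng.normal(gp["assr_kappa_40"], sd["assr_kappa_40"]))
            amp40 = max(0.05, rng.normal(gp["assr_amp_40"], sd["assr_amp_40"]))
            age = float(np.clip(rng.normal(gp["age_mean"], gp["age_sd"]), 13, 35))
            subject_specs.append(
                SubjectSpec(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    age=age,
                    spindle_density_true=density,
                    spindle_amp_true=amp,
                    gating_factor_true=gating,
                    assr_amp_true={
                        f: (amp40 if f == 40.0 else _ASSR_OTHER["amp"])
                        for f in spec.assr_freqs
                    },
                    assr_kappa_true={
                        f: (kappa40 if f == 40.0 else _ASSR_OTHER["kappa"])
                        for f in spec.assr_freqs
                    },
                    noise_rms=spec.noise_rms,
                    noise_slope=spec.noise_slope,
                    seed=subject_seed,
                )
            )
            i += 1
    cohort = Cohort(spec, subject_specs)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.manifest.to_csv(out / "manifest.csv", index=False)
    return cohort
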
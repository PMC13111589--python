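# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the underlying methods descriptions left the design open.

## Signal primitives

All filters are zero-phase forward-backward IIR designs (4th-order
Butterworth second-order sections for bandpasses; a Q=30 biquad notch).
Zero phase matters because the P50 score depends on component latencies: a
causal filter would shift the 40–80 ms scoring window. The filter family
and order are our choice — the methods being reimplemented name only the
band edges (0.3–35 Hz sleep, 10–50 Hz P50, 60 Hz notch).

The complex Morlet kernel at frequency f with c cycles has Gaussian
envelope sigma_t = c/(2πf), truncated at ±4 sigma, and is normalized so a
unit-amplitude sinusoid at f yields |coefficient| = 1 in steady state. This
convention makes the spindle threshold and dB maps reproducible across
implementations; it is not canonical, so it is stated here. Samples within
half the kernel support of either signal edge are flagged invalid rather
than padded — padding would contaminate exactly the pre-stimulus baselines
the ASSR maps divide by. Time convention everywhere: sample k of an epoch
lies at t_start + k/rate; windows are closed on the left, open on the
right.

A consequence worth knowing: with 7-cycle wavelets near 40 Hz the kernel
half-support is ~110 ms, so a [−150, −50] ms baseline "sees" the first
~60 ms after stimulus onset. The ASSR driver therefore epochs wider than
the analysis window and crops after transforming, and abrupt test signals
used for dB calibration place their amplitude step 50 ms post-onset.

## Spindle detection

The detector follows the validated wavelet-threshold lineage: envelope =
100 ms moving average of the squared magnitude of the 13.5 Hz Morlet
coefficients (7 cycles — the cycle count is unstated in the source
methods; 7 matches the ASSR family and spans the 12–15 Hz band); threshold
= 9 × median of the envelope over all artifact-free N2+N3 samples, pooled
across stages (a literal reading of "all artifact-free data"); events are
maximal supra-threshold runs ≥ 400 ms inside eligible sleep. The stage
label comes from the 30 s epoch containing the envelope peak; amplitude is
the maximum |voltage| of the preprocessed broadband trace within ±2 s of
the peak. Because envelope and median both scale with the square of a
channel gain, detection is exactly gain-invariant (tested at gains 0.5, 2,
10).

Squaring plus smoothing smears the envelope in time by roughly the wavelet
support. Near the threshold this is negligible, but a burst tens of times
above threshold stays supra-threshold beyond its nominal duration; at
extreme SNR (~40× background RMS) a 300 ms burst can exceed the 400 ms
criterion. The recovery checks therefore define "high SNR" as burst
amplitudes ~3–4× background RMS (envelope ~20–60× median), which is the
regime real spindles occupy; the limitation is inherent to
envelope-duration detectors, not to this implementation.

Alternatives left config-exposed: smoothing window, raw-vs-squared
envelope, run merging (off), maximum duration cap (off), and the amplitude
definition (max |voltage|; peak-to-peak and envelope variants selectable).

## P50 scoring

"Most prominent positive peak" is formalized as: among positive-valued
strict local maxima in the 40–80 ms window, take the one maximizing
(peak − preceding trough), where the preceding trough is the nearest
strict local minimum searching back to 0 ms (falling back to the interval
minimum if none exists). Ties break toward earlier latency. The original
scoring was by two blinded human raters; only the amplitude rule is stated,
so this is the deterministic completion of it. S2 uses the same rule
restricted to ±15 ms around the S1 latency; an absent S2 peak scores
amplitude 0 — complete gating — rather than missing (config-exposed). A
missing S1 is a status (`s1_not_detected`), excluding the subject from
gating analyses only, mirroring how such participants were dropped.

Filtering happens after epoching by default (the methods text reads
"segmented into epochs … and filtered"); the order is configurable and at
these epoch lengths immaterial.

## ASSR maps

Evoked power is computed on the trial average — the phase-locked
definition — not on single trials; power in dB is 10·log10 relative to the
mean baseline power per frequency (mean, not median, and 10·log10 on
power: both unstated in the source, both config-exposed). ITPC is the
resultant length of unit phase vectors of single-trial coefficients;
coefficients of exactly zero magnitude contribute a zero vector. Band-time
summaries average stimulation frequency ± 5 Hz × 0–500 ms. Ocular ICA from
the original preprocessing is deliberately replaced by ±100 μV rejection:
the synthetic data contain no ocular artifacts, and ICA is out of scope.

## Group statistics

The per-feature model is the linear ANCOVA response ~ intercept + group
(dummy-coded, 3 levels) + age, fit by least squares via QR projection and
vectorized across features; F = [(SSE_red − SSE_full)/2]/[SSE_full/(n−4)],
partial η² = SS_group/(SS_group + SSE_full). Cluster correction groups
features with p_uncorrected < 0.05 under the adjacency (electrode pairs
within a layout distance; 4-neighborhood on TF grids — no diagonals),
scores clusters by Σ F, and compares against the permutation null of the
maximum cluster mass with p_corr = (1 + #{null ≥ obs})/(1 + n_perm), so a
corrected p is never below 1/(n_perm+1). Permutations shuffle group labels
only, keeping each subject's (age, response) pair intact — the literal
reading of "randomly permuting group labels"; this is not the
Freedman–Lane residual scheme, a known divergence risk documented here.
The cluster-forming threshold uses the ANCOVA p (with covariate). Post-hoc
contrasts are Welch t tests on cluster-mean responses with raw p values
(no further multiplicity correction, as reported in the source results).

The montage neighbor distance defaults to 1.5 layout units, giving a mean
degree of ~5–7 on the synthetic concentric-ring caps — comparable to
published electrode neighborhood templates, which are not available here.

## Synthetic cohort: what it emulates and what it does not

The generator states a world with known parameters:

* Background: 1/f^slope noise (slope 1, flat below 0.5 Hz, exact RMS).
  Sleep sessions default to 8 μV RMS; wake (paired-click and click-train)
  sessions to 5 μV — relaxed wake EEG lacks the high-amplitude slow
  activity of NREM, and 5 μV puts a 3 μV P50 in the standard ERP operating
  regime (invisible per trial, ~6% residual noise after 240 averages).
  One noise process is shared across channels with per-channel gains in
  [0.7, 1.3] (rank-1 spatial model); Cz always has gain 1.
* Spindles: raised-cosine-enveloped 13.5 Hz bursts ("waxing and waning"
  made analytic: the envelope peak is exactly the configured amplitude),
  durations uniform in 0.5–1.5 s, onsets Poisson-thinned to non-overlap,
  injected only into N2/N3, identical events on all channels up to gain.
* P50: a 25 Hz carrier under a 24 ms-sigma Gaussian envelope — biphasic
  trough-then-peak with the positive peak at 55 ms, normalized so its
  measured peak-minus-trough equals the configured amplitude. The carrier
  and envelope keep the template's energy inside the 10–50 Hz scoring band
  (the zero-phase bandpass changes its peak-to-trough by <1%); S2 is the
  S1 template scaled by the gating factor. The real stimuli are 1 ms
  clicks; this models the cortical response, whose morphology the source
  constrains only through the scoring windows, so it is config-exposed.
* ASSR: per-train sinusoids (5 ms cosine ramps) whose phases are von Mises
  with concentration κ, giving the analytic large-n ITPC limit
  I₁(κ)/I₀(κ) — with κ = 2, ≈ 0.698 — at high SNR. At the default unit
  amplitude in 5 μV noise the measured ITPC is attenuated below this limit
  by phase noise; the closed-form checks therefore run at amplitude 5.
* Cohort structure: group sizes default to 15/24/28 (EC/FHR/NC), ages
  drawn from the corresponding group distributions; configured effects
  are a spindle-density and gating deficit in EC and reduced 40 Hz phase
  locking (κ 1.0 vs 2.0) and amplitude (0.7 vs 1.0 μV) in both EC and
  FHR, with no group differences at other stimulation rates. Group-level
  means, between-subject SDs and every timing parameter are configurable;
  seeds propagate through `SeedSequence`, so cohorts are bit-reproducible
  as a whole and per subject.

Not emulated: realistic scalp topography (no forward model), ocular/EMG
artifacts, sleep microstructure beyond block-wise stages, REM phenomena,
spindle frequency chirp, age effects on any measure (age is noise with
respect to the responses, which is itself a testable null). A green test
on this world establishes that the estimators recover their generating
parameters and that error control holds under the stated noise model — not
that the pipeline handles every pathology of clinical recordings.

## Desk-scale defaults and budgets

The `desk` cohort recipe (10/10/10 subjects, 10+2 min N2/N3, 120 click
pairs, one hundred 40 Hz trains) runs the full pipeline in a few minutes
on one
CPU and is what the acceptance battery and `scripts/acceptance.py` use;
`study` restores the full design. Monte-Carlo test sizes are scaled to
keep the whole suite within a CI budget (noted per test); tolerances are
never widened to compensate.

## I/O

Recordings, hypnograms, events, montages and manifests are plain-text CSV
(a commented header carries rate/reference/montage). EDF ingest is not
bundled — the EDF readers this project would use are not part of the
supported environment — but `load_recording` is the single seam where a
clinical reader would plug in; nothing downstream depends on the container
format.
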
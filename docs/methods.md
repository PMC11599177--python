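# Methods

`aadkit` implements an EEG analysis chain for neural speech tracking and
auditory attention decoding (AAD): from raw audio and multichannel EEG to
latency-resolved stimulus-reconstruction correlations, attention
classification against a binomial chance level, and the group statistics
built on top. Because the kind of recordings it targets (mobile,
multistream, ~9 min per condition) are rarely shareable, the package also
ships a forward-model cohort generator so the entire chain can be
exercised and validated against known ground truth.

## The decoding model

Low-frequency cortical activity follows the amplitude envelope of attended
speech. A *backward* (decoding) model inverts this: it maps time-lagged
multichannel EEG to the envelope,

    ŝ(t) = Σ_c Σ_τ w(c, τ) · r(c, t + τ) + b,

where `r(c, ·)` is channel `c` of the preprocessed EEG, and τ ranges over
a short window of post-stimulus lags. Rather than one decoder over the
whole 0–500 ms range, a 45-ms window is slid along the lag axis in 15-ms
hops (30 ms overlap), giving 34 window decoders and thus a latency
profile of reconstruction quality. At the 64 Hz working rate each window
holds 2–3 sample lags (the 15.625-ms sample grid does not divide 45 ms
evenly, so the per-window lag count varies; the window count does not).

Weights solve ridge-penalized normal equations per window,

    w = (XᵀX + λ·m·I)⁻¹ Xᵀy,

with `m` the mean diagonal of `XᵀX` over penalized columns, so the
λ ∈ {10⁻⁶, 10⁻⁴, …, 10⁺⁶} grid is meaningful regardless of data scale;
the intercept column is not penalized. One λ is shared by all 34 windows
and chosen by cross-validation on the mean held-out attended correlation
(ties go to the smaller λ — least smoothing at equal fit). Envelope
targets are divided by their per-trial SD before training; Pearson
correlations are unaffected, λ comparability across conditions improves.

Two variants:

- **subject-independent** — all subjects' non-overlapping 60-s trials of
  a condition are pooled; leave-one-trial-out cross-validation (so a
  20-subject × 9-min condition gives 180 folds, 19 subjects give 171);
- **subject-dependent** — each subject's 9 trials are cross-validated on
  their own, with a per-subject λ.

λ selection and evaluation share the same leave-one-fold-out structure,
so the per-trial tracking curves at λ\* are exactly the held-out
correlations computed during the λ search; nothing is retrained. This
selects λ using all folds (including each eventual test fold), a small
optimism shared by the sequential procedure it mirrors; with 160+ folds
and a 7-point grid the effect on curves is negligible.

Gram matrices per trial and window are accumulated once (one symmetric
rank-k update over the full lag range, then submatrix extraction), so
leave-one-trial-out training is a subtraction, not a refit.

Per-trial decoding is scored by whether the reconstruction correlates
more with the attended than with the ignored envelope (ties count as
incorrect). Decoding accuracy is the percentage of correctly classified
trials; its chance level is the smallest k with Binomial(n, ½) CDF ≥ 1−α,
expressed as 100·k/n (n = 360, α = 0.05 → 54.4%).

## Envelope extraction

The reconstruction target is the block-RMS of the audio at the working
rate — one block of ⌊fs_audio/64⌋ samples per output sample — compressed
with a power law, `env = rms^0.3`, approximating perceived loudness. For
non-integer rate ratios, block starts are truncated to the nearest audio
sample (error bounded by one audio sample per block). The envelope is
homogeneous of degree 0.3 in the audio amplitude, which the tests assert.
Peak normalization of stimuli (−1 dBFS) is a separate helper, not part of
extraction.

## Preprocessing

The minimal cleaning chain, in fixed order: high-pass 0.5 Hz (Hamming
FIR, order 1652) → low-pass 40 Hz (order 86) → bad-channel rejection
(RMS > mean + 2 SD across channels) with interpolation → bad-section
excision → low-pass 15 Hz (order 222) → common average reference →
polyphase resample 250→64 Hz → per-channel division by SD.

Numerical choices:

- Zero net phase by group-delay compensation of one linear-phase pass;
  all orders are even, so the delay is an integer sample count.
- Edges are padded by *odd* (value-continuous) reflection, as `filtfilt`
  does; plain symmetric reflection leaves a low-frequency transient after
  the 0.5 Hz high-pass large enough to trip the section detector on the
  first second of every recording. Resamplers use line-extension padding
  for the same reason.
- Channel interpolation is inverse-distance weighting over good channels
  (plain mean when no positions are given). Spherical splines would need
  a montage; synthetic layouts have none.
- Section rejection tiles the recording with 1-s windows and flags a
  window when more than 25% of channels exceed their own across-window
  mean + 3 SD of windowed RMS; adjacent flags merge. All three
  parameters are config-exposed since only the qualitative rule is fixed.
- Excised sections are dropped from the EEG *and* from the envelope
  streams over the same intervals, keeping stimulus and response
  sample-aligned; event markers are remapped onto the excised timeline
  (`remap_marker_times`). Alignment is otherwise undefined.

## The synthetic cohort generator

Each channel of a synthetic recording is

    eeg[c] = g_att·(k[c] ∗ env_att) + g_ign·(k[c] ∗ env_ign)
             [+ g_bg·(k[c] ∗ env_bg)] + noise [+ artifacts]

- **Stimuli** are white-noise carriers amplitude-modulated by a smooth
  log-normal modulator (log = low-passed Gaussian noise, cutoff 8 Hz, the
  rate range of syllabic energy fluctuations). All subjects of a
  condition share the stimulus pair, as listeners in a speaker-ring
  protocol would, and the attended stream is counterbalanced across
  subjects (half attend each voice). Counterbalancing matters beyond
  realism: with every subject attending the same stream, the pooled
  subject-independent cross-validation would let the decoder learn
  minute-specific separation of the shared stimulus from sibling
  subjects' training folds, pushing equal-gain (null) decoding accuracy
  above chance. The known modulator is returned for oracle checks.
- **Kernels** are differences of two Gaussians (positive peak, weaker
  negative lobe ~100 ms later — the biphasic morphology of
  envelope-following responses), sampled at 64 Hz over [0, 0.5] s.
  Defaults: 150 ms latency, 40 ms width, per-subject latency jitter
  ±30 ms, a smooth frontocentral-like topography with a floor so every
  channel carries signal. The convolution uses the *mean-centered*
  envelope: cortical responses track fluctuations, and a raw nonnegative
  envelope would imprint a DC onset step that the high-pass smears into
  a spurious artifact at the start of every recording.
- **Noise** is 1/f-amplitude Gaussian noise plus 10% white, scaled per
  channel so the 1–15 Hz band (the decoder's working band) sits at the
  configured SNR against the noise-free response; out-of-band power is
  removed by the filters anyway. Realized band SNR is exact by
  construction and asserted to within 1 dB in tests.
- **Artifacts** multiply short (0.2–1 s) all-channel windows by a large
  factor (bursts, emulating movement) or scale one channel throughout
  (bad channel); both are logged with positions. Walking conditions get
  bursts at 2/min by default.
- **Protocol structure**: three blocks (two lab, one beyond-the-lab) of
  four ~9-min conditions — single/dual speaker, with/without an
  envelope-band background stream, sit/walk. Attended-side switches every
  60–120 s are recorded as metadata only; the simulated response is
  side-agnostic because the decoder uses no spatial cues. Walking
  recordings carry street entry/exit markers delimiting a 2-min busy
  span; entry times are drawn per subject (uniform over the middle of
  the recording) because each participant walks the route at their own
  pace — a fixed entry time would make every subject's busy segment
  cover the same minutes of the shared stimulus and so correlate
  segment-difficulty across subjects.
- All randomness flows through one seeded generator; identical configs
  give byte-identical datasets.

Defaults (20 subjects, 32 channels, 250 Hz, 9 min, g_att = 1.0,
g_ign = 0.4, 0 dB) are the cohort conditions under which the package
validates itself. What the generator does *not* emulate: spatial
structure from a head model, inter-subject kernel-shape variability
beyond latency jitter, nonstationary attention (lapses, switches),
eye/cardiac artifacts, or reverberant acoustics. Consequently decoding on
these cohorts is easier than on real recordings — synthetic
subject-independent accuracy saturates near 100% where comparable
real-data studies report 60–80% — so passing tests demonstrate the
correctness of the chain and its statistics, not expected field
performance.

## Evaluation statistics

- **Tracking magnitude**: mean reconstruction r over the analysis windows
  whose start lag lies in [120, 270] ms (closed interval; 11 windows),
  the latency range where envelope-following responses are strongest.
  Both bounds are config-exposed.
- **Condition contrasts**: Wilcoxon signed-rank with zero differences
  dropped, average ranks on ties, tie-corrected variance, continuity
  correction, and a signed normal Z with two-sided p. Implemented
  in-package (the signed Z is the quantity of interest);
  cross-checked in tests against `scipy.stats.wilcoxon(method="approx")`
  and an exact sign-pattern enumeration at small n.
- **Robustness**: subjects ranked by attended tracking within each
  condition; condition pairs get the Pearson correlation of rank vectors
  (Spearman's ρ) with a two-sided permutation p (10⁴ seeded shuffles —
  t-approximations are fragile at n ≈ 20).
- **Street segments**: quiet = first 2 min of the walking recording,
  busy = 2 min from the street-entry marker. A 60-s trial contributes to
  a segment when at least 30 s of it (half a trial) lies inside —
  the boundary rule is otherwise arbitrary and this choice keeps
  assignments unambiguous. Per-subject segment tracking pairs feed the
  Wilcoxon contrast.

## Problem sizes used in validation

The acceptance-style checks run the full chain at the emulated study's
scale: 20 subjects × 9 min of dual-speaker listening at 32 channels,
five seeds for the asymmetric-gain cohorts and two for the equal-gain
(null) cohorts. The street-segment null uses 20 replicates of a reduced
cohort (10 subjects, 8 channels, 5-min walks, 8 kHz audio — the
AM-noise envelope statistics are rate-invariant) — the contrast consumes
only 4 trials per subject, so a longer recording adds cost without
information. `scripts/acceptance.py` runs one asymmetric cohort, one
null cohort and one street cohort at the same scales from a single seed.

## Known limitations

- The lag profile on synthetic cohorts peaks at, or one hop after, the
  mean simulated latency: the kernel's late negative lobe adds
  information on the late side of the peak. Tests allow ±1 window.
- The two-stage cross-validation's λ optimism (above) is accepted, not
  corrected.
- `read_multistream` reads the package's own HDF5 multistream container
  (same information model as LSL/XDF recordings: named streams,
  per-stream timestamps, linear clock alignment); it does not parse the
  binary XDF format itself.
- Accuracy saturation on default synthetic cohorts (above) means the
  generator cannot calibrate absolute accuracies to real-data levels
  without adding the nuisances it deliberately omits.
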
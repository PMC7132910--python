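# Methods

This note documents the analysis model implemented in `somnolearn`, the
choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Study design and data model

One recording is a participant-night of polysomnography: EEG at C3 and
C4 (µV, referenced to opposite mastoids at acquisition), nasal airflow
(L/min), tone events, sleep stages (W/N1/N2/N3/REM) and arousal
intervals. Tones are presented in blocks of six trials — two reinforced
with a pleasant odor, two with an unpleasant odor, two non-reinforced
(one per conditioned tone) — with onset gaps of 25–40 s. Non-reinforced
trials are the probes: they carry the learned response without odor
interference. Training phases split at block 5 (early: blocks 1–5,
late: 6 onward); participants whose night ended early contribute to the
early phase only.

Trial inclusion: an epoch spans −5500…+5000 ms around tone onset,
end-inclusive (10 501 samples at 1 kHz). A trial is excluded if (i) EEG
exceeds ±300 µV at any sample on either channel, or is flat below
0.5 µV peak-to-peak — the amplitude criterion is our stand-in for an
unspecified original artifact rule, chosen because it is deterministic
and standard in sleep EEG; both thresholds are configurable; (ii) any
wake or arousal interval intersects ±30 s around tone onset; (iii) the
onset is not in N2/N3 (the stage is stored, so an N2-vs-N3 breakdown
remains possible). Exclusion is first-reason-sticky and idempotent.
Participants with fewer than 10 clean non-reinforced trials are
dropped (threshold inclusive).

## Spectral decomposition

Per 0.5 Hz bin (centers 0.5…40 Hz), each epoch is mirror-padded by 2 s,
band-passed ±0.25 Hz around the bin center with a Hamming-windowed-sinc
FIR (transition width = max(0.25 × lower edge, 2 Hz); order
3.3·fs/transition, odd), the analytic signal's squared magnitude is
taken, and the padding trimmed. Where the transition cannot fit above
DC (bins at 0.5 and 1 Hz), the design degrades to a low-pass over the
bin's upper cutoff — the "where possible" escape of the transition
rule, so those bins measure 0-to-upper-edge power.

Numerically, the analytic signal is evaluated by **complex
demodulation**: the Hamming-sinc bandpass over [lo, hi] is exactly a
low-pass prototype modulated to the band center, so
`2·e^{iω_c t}·((x·e^{-iω_c t}) * lowpass)` equals the band-passed
analytic signal for band-limited content. We use this form rather than
an FFT Hilbert transform because it is strictly local — each output
sample depends on half a kernel length of data — which makes the
trimmed epoch provably independent of the pad length (tested at 1e-6
z-units) and leaves no circular-wraparound leakage. For bins containing
DC the demodulated power counts the DC component once rather than
twice; this is the operator's definition for those bins.

Each trial's power is z-scored per frequency bin over the **whole
10.5-s epoch** (population SD, ddof 0; both the normalization window
and ddof are switchable). Whole-epoch was chosen over baseline-only
because the per-trial normalization claim carries no window
restriction and baseline correction is applied separately downstream;
the alternative remains one flag away. Trials are averaged across the
two electrodes first, then across trials, into one map per participant
× condition × phase; empty cells are explicit missing markers. Band
envelopes are means of the z-scored bin powers whose centers lie in the
closed band interval (delta 0.5–4 Hz: 8 bins; theta 4–7: 7; sigma
11–16: 11).

For inference the pipeline decimates epochs to 100 Hz (FIR, zero
phase). The per-bin filters are identical in Hz terms, every band of
interest sits far below the 50 Hz Nyquist, and the cluster machinery
scales linearly in samples; 1 kHz analysis is a config change
(`decimate_to_hz`).

## Cluster inference

Pointwise one-sample t across participants (ddof 1), cluster-forming
threshold at two-tailed α = 0.05 (the original analysis states only the
cluster-level α; the pointwise threshold is the field-standard default
and configurable), clusters scored by mass (sum of t; max-t available),
1-D runs or 4-neighbour time×frequency components. The null flips signs
of whole participant maps: exhaustive over 2ⁿ patterns when 2ⁿ ≤ the
requested permutation count (p exact), else Monte-Carlo with the
add-one convention and p-floor 1/(N+1). Default 1000 permutations
(original count unstated).

Two stages: (1) pooled-condition, pooled-phase envelopes are
baseline-corrected (−5500…−500 ms mean) and tested against baseline
with a positive tail over 0…5000 ms; the largest significant cluster
per band is that band's restriction window; a band with no significant
pooled cluster is flagged untestable and its condition tests are
explicitly skipped, never silently empty. (2) CSu-vs-CSp per phase and
the early-vs-late interaction run as paired tests (sign flips of
within-participant differences) inside the restriction window. Cell
envelopes are baseline-corrected before differencing; for a paired
contrast this only removes each participant's baseline offset and does
not change exchangeability.

Effect size: Wilcoxon signed-rank on participant-level cluster-mean
differences — zeros dropped, mid-ranks with tie-corrected variance,
0.5 continuity correction toward the null — normal-approximation z,
reported as r = z/√n with n the participant count and the sign of the
median difference. The convention's z-source is uncited in the original
report; the signed-rank choice matches its nonparametric framing and is
validated against exact enumeration for n ≤ 10.

## Sniff-response analysis

A sniff is the first inspiratory (positive-flow) lobe of at least
200 ms beginning within 10 s of tone onset; its volume is the time
integral of flow (L/min → L). Retention-session volumes are normalized
by the mean of the 15 baseline inhalations preceding the session
(errors below 15). Night trials are normalized by the 15 inhalations
preceding each tone — the original defines normalization only for the
retention session; a local baseline was chosen for robustness to slow
drifts in breathing depth (a session-level switch exists). Participants
whose mean nvu deviates more than 3 group-SD (single pass, leave-one-in)
are excluded. The learning curve uses the first five clean
non-reinforced presentations per condition (trials lost to arousals do
not count, implementing the "or first arousal" truncation); the
blocks 4–5 vs 1–2 contrast uses a Wilcoxon signed-rank (the original
test is unnamed; a paired t is available). Retention: paired two-sided
t of CSu vs CSp per-participant means, df = n−1, novel tone reported
descriptively.

## Synthetic generator

The generator emulates the design end to end so that every planted
quantity is recoverable: block structure with counterbalanced
tone→valence mapping (balanced within one participant), ITI 25–40 s
with onsets snapped to the sample grid, N2/N3 alternation in 10-min
stretches, 1/f^1.5 EEG background (RMS 20 µV) plus a continuous 0.8 Hz
slow oscillation (15 µV), and event-locked bursts per band:
K-complex-like 1.5 Hz transient (1.8 s support), 5.5 Hz theta burst
(1.5 s), 13 Hz spindle (1.2 s), each with 300 ms onset-latency jitter
and log-normal amplitude noise (σ = 0.2).

Three generator decisions matter for validity:

* **Gaussian burst envelopes.** A 1–2-cycle Hann-windowed delta
  transient is spectrally broad and leaks planted delta effects into
  the theta analysis band; Gaussian (Morlet-style) envelopes confine
  each planted effect to its own band.
* **Amplitudes relative to in-band background.** Condition effects are
  multiplicative burst-amplitude ratios (CSu = ratio × CSp), so the
  per-trial z-scoring stage is genuinely exercised — and z-scoring
  *normalizes away* a multiplicative effect whose burst dominates the
  trial's in-band variance. Burst amplitudes (delta 20, theta 3, sigma
  1.5 µV) therefore place burst power at a few background-SDs in each
  band, the regime where z-scored power remains informative.
* **Planted-window ground truth** is the support where the expected
  condition power difference exceeds 5 % of its peak (±√(ln 20) power
  SDs around the burst center, widened by the latency window): Gaussian
  tails carry no usable effect energy and would make overlap scores
  meaningless.

Default planted ratios (delta early 2.0, sigma early 1.6, theta late
1.8, all CSu > CSp) are free parameters — the original reports no
effect magnitudes in µV² — chosen so the pattern is detectable at desk
scale (12 participants × 8 blocks, 100 Hz); delta needs the largest
ratio because its 1/f background is strongest, and late theta has the
fewest trials per cell. Sniff: tidal breathing (4 s period, 6 L/min
peak), conditioned lobes scaled by a ramp saturating at block 5
(CSp/CSu = 1.3), retention means CSu 1.15 / CSp 0.95 / novel 1.0 nvu
with 0.2 between-participant and 0.1 within-participant SD. Nuisance:
Poisson arousals (alpha bursts + noise, annotated) and rectangular
±450–700 µV artifact transients at 2/h each; the rectangle makes
interval-intersection and amplitude-detection provably equivalent, so
exclusion ledgers can be compared with ground truth *exactly*.
Low-quality participants (for exclusion-rule studies) get artifacts on
all but a configured number of their non-reinforced trials.

What the generator does **not** emulate: realistic full-night
hypnograms (no REM/wake architecture beyond inserted arousals),
biophysical neural-mass dynamics, spatial EEG structure beyond a shared
background component between C3 and C4, respiratory events, or
non-stationary background spectra. Passing the validation studies
therefore establishes the *statistical machinery* — error control,
recovery, exactness, bookkeeping — under plausible spectral structure,
not performance on any particular real dataset.

## Error-rate studies (validation module)

* Type-I: 200 null replicates per band (exchangeable smooth envelopes,
  12 participants, 500 permutations, 0–3 s at 100 Hz) against the exact
  binomial 95 % band around α = 0.05. Envelope-level simulation is used
  because sign-flip exchangeability makes the test's level independent
  of the envelope's autocorrelation; waveform synthesis would add cost,
  not information.
* Recovery: 25 full-pipeline replicates at the default desk scale;
  success requires significant positive clusters in exactly the three
  planted cells and Jaccard ≥ 0.5 between each detected and planted
  window.
* Behavioral: 50 replicates of the learning contrast from the
  volume-level generator (power with ratio 1.3; false-positive rate
  with ratio 1.0); the trace-level path is validated separately against
  planted volumes (2 % tolerance, noise-free).

## Numerical conventions and degenerate inputs

Milliseconds relative to tone onset, windows closed (end-inclusive),
cluster extents reported as inclusive [start, end] ms, internal indices
0-based. Constant power bins z-score to 0 with a warning; all-zero maps
yield empty cluster lists; degenerate t (zero variance) is treated as
0. All randomness flows from one seed: per-participant generator
substreams are derived by fixed offsets, so any participant is
reproducible in isolation, and every result file echoes config, seed,
and a config hash (output paths excluded). EDF writing quantizes to
16 bits over each channel's observed range; round-trips are exact to
one quantization step.

## Known limitations

* The artifact criterion, per-bin filter-bank construction, z-scoring
  window, cluster-forming threshold, permutation count, and the
  night-sniff normalization denominator are all unstated in the
  original description; each implemented choice is flagged above and
  configurable where feasible.
* The 2-D time×frequency permutation path is exercised at small sizes
  only; the pipeline's standard route is the three 1-D band envelopes.
* Between-group (unpaired) designs, TFCE, FDR across bands, wavelet or
  multitaper decompositions, and automatic sleep staging are out of
  scope.
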
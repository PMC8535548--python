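# Methods

This note documents the model and the numerical choices behind `pqrst`:
what each stage assumes, which constants matter, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## Background prediction with an adaptive bilateral filter

The detector's central assumption is a *scale separation*: the QRS
complex is narrow (0.06–0.10 s) and steep, while the P- and T-waves and
the baseline are wide and gentle.  A bilateral filter — the product of a
domain (spatial) Gaussian and a range (intensity) Gaussian — can be
steered between two regimes: with small standard deviations it passes
the signal through; with large ones it behaves like a wide low-pass
filter.  Driving both standard deviations from the *local variance* of
the 15-sample window puts the filter in the smoothing regime exactly
where the QRS lives and in the pass-through regime everywhere else, so
its output B is a prediction of the ECG background without the QRS.

Numerical conventions:

- Variance is the population variance of the window (divide by count):
  deterministic for tiny windows and matching the plain reading of
  "variance of the sample points".
- The window is truncated at record edges and the normalization runs
  over the available points, preserving the convex-combination property
  (min ≤ B(x) ≤ max of the window).  Constant signals are exact fixed
  points.
- The adaptive law σ = log2(σ²(Ω)/σ²max + 1)·σmax + σmin is applied as
  stated for variances above σ²max as well (no clamping); a config flag
  `clamp_sigmas` enables clamping for experimentation.
- The normalization factor uses the same adaptive σ values as the
  weighted sum — any other reading breaks flat-region conservation.
- All computation is double precision; the vectorized implementation is
  tested to ≤1e−12 against a naive double loop.

## R-peak detection

Each sliding window is min–max normalized to [0, 1] (a `literal_eq1`
mode divides by Smax instead; min–max is the default because division by
Smax alone does not map signals with negative baseline into [0, 1]).
The residual D = I − B is enhanced by an 11-sample moving sum (half
width n = 5 at 360 Hz ≈ 30 ms of context, scaled with the sampling
rate).  Candidate-R intervals are maximal runs of |E| > max|E|/2 of
length ≥ 8 samples (scaled with rate).  The absolute value is essential:
an inverted QRS produces a *negative* residual, and thresholding signed
E could never reach the γ = −1 branch of the peak rule.  Within a run
the R-peak is the argmax of I when the maximum rises at least as far
above the window mean as the minimum falls below it (γ = +1), else the
argmin (γ = −1).  Tied extrema (flat tops) resolve to the floor of the
mean tied position and set a flat-top flag.

Two rules are this package's own additions, both configurable:

- A 0.2 s refractory merge keeps the larger-deviation peak when two
  candidate runs collide; without it a notch that splits a run would
  double-count a beat.  0.2 s is well under any physiologic RR.
- The fragmented-R scan skips samples whose value ties the R apex
  exactly, so a flat top is not reported as a stack of fragments.

Fragmented R-peaks are accepted at γ-oriented slope-sign reversals whose
rebound amplitude — the 10-term sum of two-step sample differences
moving *away* from the main peak, oriented by γ — exceeds Thf = 0.1 in
normalized units, searching within αf = 22 samples (at 360 Hz) of the
most recently accepted peak, recursively, so double-notch patterns are
found.  Sums that run off the window terminate early and are compared
against the same threshold.

## Q/S and P/T delineation

Q and S are the first strict γ-oriented troughs scanning away from R (or
from the outermost accepted fragment peak) within αQ = round(Fs·QRS/2)+8
samples; their shoulders (Q-onset, S-offset) are the first *relaxed*
extrema — slope levels off or reverses, with a two-point look-ahead —
within round(Fs·QRS).  sign(0) satisfies the relaxed inequalities, so a
flat PQ or ST stretch terminates the scan at its first sample.  When a
scan predicate never fires the fiducial falls back to the end of its
range and is flagged mapped.

P/T fiducials are detected on the background B, where QRS energy is gone
but P/T lobes survive.  The symmetric point filter at candidate x
requires at least ρ·(l+r) of the wing slopes to rise toward x on the
left and fall away on the right (ω-oriented), with wings l = r = 10 − v
(P) and 20 − v (T).  The deformation recursion v = 0…5 (P) / 0…10 (T)
skips the v samples nearest the candidate, letting dented apexes pass; v
is increased only after *no* candidate fires in the whole range, so the
reported v is minimal.  Three numerical choices matter here:

- sign(0) passes both wing inequalities, so exactly flat plateaus are
  accepted at v = 0 (the recursion is needed for *wrong-sign* ripple,
  not for flats).
- A candidate is rejected unless its wing pattern is non-degenerate (at
  least one strictly rising and one strictly falling wing point): on an
  all-flat stretch every sign is 0 and the filter would otherwise fire
  at the first scanned sample, making absent P-waves undetectable as
  absent.
- With ρ = 0.95 the filter tolerates ⌊0.05·(l+r)⌋ violations and hence
  fires one or two samples *before* the apex in scan order; the returned
  peak is therefore the ω-extremum of B over the contiguous accepted
  run (floor-mean on ties, which centers plateaus).  ρP follows ρT at
  0.95 by default; both are configurable.

Onsets and offsets use short asymmetric filters (2 outer / 4 inner wing
points, all conditions required) oriented as an ω-trough: at the toe the
inner wing still carries the flank's slope while the outer wing is flat,
and sign(0) lets the flat side pass.  Scan ranges follow the mirrored
geometry: the P-onset range is the Q-onset distance reflected about the
P-peak, the T-offset range is the S-offset distance reflected about the
T-peak; the P search is additionally clipped at the previous T-offset
(an empty range maps the P-wave) and the T search at the next R.

When both an upright and an inverted candidate wave exist, the inverted
one is chosen only if it is strictly wider *and* subtends a strictly
larger triangle (absolute shoelace area of the onset/peak/offset
vertices on B).  Missing fiducials are then mapped: a missing P-peak
collapses all P fiducials onto the Q-onset, a missing T-peak onto the
S-offset; with the peak present, a missing onset maps to the peak (P) or
S-offset (T) and a missing offset to the Q-onset (P) or peak (T).  After
mapping, every beat carries all 11 fiducials in non-decreasing order.

## Windowing and stitching

Windows are 2000 samples with a 1600-sample step at 360 Hz (scaled with
rate), and all statistics (Smin/Smax, Imean, max|E|) are per-window, as
streaming operation requires.  A beat is *perfect* when its full
delineation support fits inside the window — αQ+αQL+αP plus a margin on
the left, αS+αSR+αT plus a margin on the right (about 0.47 s and 0.58 s
at 360 Hz).  Beats closer to an edge are provisional; the stitcher keeps
a perfect representative from the earliest window reporting one and
falls back to the earliest provisional detection only when no window
re-detects the beat (record boundaries).  Beats from different windows
within 50 ms are one beat.  The margins were chosen as the full search
support rather than a token few samples: a smaller margin would freeze
truncated P/T fiducials from the earlier window at every seam.  The
window geometry guarantees interior coverage for steps up to
window − left − right ≈ 1620 samples; larger steps still stitch the
R-peak stream exactly but may leave seam beats with mapped P/T points.

## HRV

Time-domain metrics follow the standard definitions: NN50 counts strict
|ΔRR| > 50 ms, pNN50 normalizes by the number of adjacent pairs, RMSSD
is the root mean square of successive differences, the HR spread is the
standard deviation of the per-interval instantaneous rate 60/RR while
the mean heart rate is 60 divided by the mean RR.  HTI and TINN use an
RR histogram with 1/128 s bins (the conventional width); TINN is the
baseline of the least-squares triangular interpolation of the histogram
(0 for single-bin histograms, where HTI is 1).  No ectopic-interval
filtering is applied by default; a config flag can exclude RR outside
[0.2, 3] s.

Frequency-domain metrics integrate a Welch periodogram of the tachogram
linearly resampled at 4 Hz (segments of up to 120 s), mean removed, over
VLF [0, 0.04), LF [0.04, 0.15) and HF [0.15, 0.40) Hz; total power is
the full integral up to Nyquist, so band percentages sum to ≤ 100 and
normalized units are 100·LF/(total − VLF) and 100·HF/(total − VLF).  A
Lomb-Scargle mode evaluates the unevenly sampled intervals directly for
users who prefer no resampling.  Intervals: ST = S-offset → T-onset,
PR = P-onset → Q-onset, QT = Q-onset → T-offset; beats whose P-wave was
mapped legitimately produce near-zero PR.

## The synthetic generator

Each beat is a sum of compact-support Gaussian bumps (amplitude mV,
center s, width s), shifted and rescaled so each component reaches
exactly zero where its envelope falls below 1 % of its amplitude.
Defaults describe a typical adult lead-II beat: P 0.15 mV/σ 20 ms at
−170 ms, Q −0.10 mV, R 1.0 mV/σ 15 ms (FWHM ≈ 35 ms), S −0.15 mV, T
0.30 mV/σ 26 ms at +250 ms, RR 0.8 s.  Truth apexes and notch positions
are read off the rendered composite (so component overlap is exact);
truth onsets/offsets are the support edges.  Morphology switches cover
inverted R, the four fragment patterns plus flat top, and five T shapes;
white noise is calibrated to a stated record-level SNR and baseline
wander is a slow sinusoid.

What the generator does *not* emulate — and what passing tests therefore
do not show — matters for interpreting results: real ECG has colored
noise, electrode artifacts, rhythm changes, beat-to-beat morphology
variation and no exactly flat segments.  Two consequences are worth
stating explicitly.  First, the exact flat baseline makes toe detection
sample-exact, so the ±1/±3-sample recovery results are a correctness
check of the predicates, not a field accuracy claim.  Second, because
every synthetic beat is identical and the QRS support is compact, the
per-window max|E|/2 threshold is brittle under heavy noise: sensitivity
degrades monotonically with SNR as required, but faster than on clinical
records, whose wider and more variable QRS complexes keep candidate runs
above the L ≥ 8 rule longer.

## Problem sizes

The test suite and acceptance script use 30-beat records (≈ 24 s at
360 Hz), 50 records for clean-recovery statistics, 10 records per SNR
level for the noise sweep and 10 records for delineation statistics —
sizes at which every reported statistic is stable to well under its
assertion tolerance while the whole suite runs in seconds.

## Known limitations

- Single-lead only; no multi-lead fusion or beat classification.
- The delineation thresholds assume the 360 Hz-referenced constants
  scale linearly with sampling rate; rates far below 250 Hz leave too
  few samples per wing for the T point filter.
- The stitcher finalizes a beat as soon as a window covers it fully; it
  does not revisit fiducials if a later window would have delineated
  them differently (by construction the earlier window's view is kept).
- Heavy noise (SNR ≤ 10 dB) degrades sensitivity sharply on synthetic
  records; see above.
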
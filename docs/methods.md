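# Methods

## Overview

`ssvepchair` implements the signal path of a steady-state visual evoked
potential (SSVEP) brain-controlled wheelchair: four flickering stimuli on a
monitor evoke occipital EEG oscillations at the gazed stimulus's frequency
and its harmonics; a single-channel recording at 250 Hz is filtered,
segmented into overlapping windows, scored against harmonic reference
signals, classified into five classes (four frequencies + rest), and mapped
to debounced motion commands. A Kano-model requirements classifier for the
wheelchair's user-needs survey is included as an auxiliary module.

## Stimulus planning

A black/white pattern-reversal stimulus on a monitor with refresh rate `r`
can only flicker at `f = r/k` for integer `k >= 2`. `available_frequencies`
enumerates these; values are kept exact internally and only rounded for
display (printed tables of such frequencies mix one- and two-decimal
rounding, so comparisons use an absolute tolerance of 0.05 Hz).

Two concurrent stimuli conflict when one frequency is an integer multiple of
the other (their SSVEP responses overlap at the harmonic). The default
frequency set {7.5, 10, 12, 15} Hz itself contains such a pair
(15 = 2 x 7.5); the planner deliberately reports conflicts as warnings, not
errors, so this deployed configuration remains constructible.

Frame schedules use a 50% duty cycle. For an even period `p = r/f` frames,
each half-cycle is exactly `p/2` frames. For odd `p` an exact 50% duty cycle
per period is impossible in whole frames; runs alternate between
`(p+1)/2` and `(p-1)/2` frames, arranged so every two consecutive periods
contain exactly `p` ON and `p` OFF frames. The frequency-to-position
assignment (7.5→up, 10→down, 12→left, 15→right) is an arbitrary documented
default; any bijection is configurable.

## Synthetic EEG

No public recordings exist for this system, so all testing runs on a
generator that emulates the assumed signal structure:

- **SSVEP component** — `sum_h a_h sin(2*pi*h*f*t + phi_h)` over harmonics
  `h = 1..4`, with geometric amplitude decay `a_h = 0.5^(h-1)` and uniform
  random phases per seed. Absent for REST trials.
- **Background noise** — unit-RMS pink (1/f) noise, the standard model of
  spontaneous EEG, generated by spectral shaping of white Gaussian noise,
  plus white sensor noise at 0.3 RMS.
- **Mains component** — a 50 Hz sinusoid (configurable to 60 Hz), default
  amplitude 0.5 relative to the unit-RMS background.

The SSVEP component is rescaled so that its power over the total background
noise power equals the requested SNR in dB exactly (the mains component is
excluded from the noise budget since the notch removes it). The default SNR
is −10 dB, reflecting the barely prominent spectral peaks of real
single-channel occipital recordings. `snr_db="noise-free"` produces the pure
SSVEP component; a noise-free REST trial is consequently all-zero.

Default trial length is 4 s (16 sliding windows). The real acquisition
protocol records one 20 s segment per fixation target; discrete 4 s trials
are used instead so that class-balanced datasets of tens of trials per class
remain cheap to generate and representative of command-length gaze epochs.

What the generator does **not** emulate: inter-subject and inter-trial
amplitude variability, alpha-band structure, eye-blink and movement
artifacts, electrode drift, non-stationarity, or latency jitter of the SSVEP
onset. Passing tests therefore demonstrate correctness of the pipeline's
processing and its behaviour under the assumed signal model — not expected
accuracy on real EEG.

## Preprocessing

A second-order IIR notch (Q = 30, a conventional narrow-band choice; the
width is not critical since the band-pass already attenuates 50 Hz) is
applied before a 2nd-order Butterworth band-pass of 0.5–45 Hz, matching the
deployed order of stages even though the notch frequency lies above the
band edge. Filtering is causal by default — a wheelchair controller cannot
use future samples — with zero-phase (`sosfiltfilt`) available offline.

Windows are 1 s advanced by 200 ms, giving `floor((T - 1)/0.2) + 1` windows
per recording; at 250 Hz each window holds 250 samples. Recordings shorter
than one window yield an empty window list with a warning rather than an
error, so streaming callers degrade gracefully.

## Decoding

For each candidate frequency `f` the reference matrix stacks
`sin(2*pi*h*f*t)` and `cos(2*pi*h*f*t)` rows for `h = 1..N`, `N = 4`. With a
single-channel window the maximum canonical correlation against this
reference reduces to the square root of the projection R²: the window is
mean-centered and projected onto an orthonormal (QR) basis of the centered
reference rows. Degenerate zero-variance windows score 0 with a warning.
Ties in the argmax decoder break toward the lowest frequency, using a 1e-12
tolerance so floating-point noise cannot flip a genuine tie.

Spectral features are amplitudes at exactly 7.5, 10, 12 and 15 Hz. With a
1 s window the FFT grid is 1 Hz, leaving 7.5 Hz off-grid, so amplitudes are
computed by a Goertzel-style single-frequency correlation sum at the exact
target frequency, normalised so a unit on-grid sinusoid scores 1.0 (equal to
`2/n |FFT bin|` at on-grid frequencies). This matches "amplitudes of the
spectrum at the stimulation frequencies" without zero-padding artifacts.

The default classifier features are the four spectral amplitudes; the four
CCA correlations can be appended (`feature_set="fft+cca"`) or used alone.
Whether the deployed system combined them is ambiguous, so both routes are
exposed with FFT-only as the default. The training-free CCA argmax decoder
is retained as a fallback; its rest threshold (default 0.5) is a free
parameter with no published value — for 1 s windows, background noise
typically scores 0.2–0.4 against an 8-row reference, and pure signal near 1.

## Classification

A degree-3 polynomial-kernel SVM (regularization C = 1, scikit-learn's
native one-vs-one multiclass scheme) on per-feature z-scores learned from
the training partition only; polynomial kernels are scale-sensitive and
leakage of validation statistics into the scaler is guarded by a regression
test. The split is stratified 80/20, deterministic per seed. Evaluation
reports the 5x5 confusion matrix (rows = true), accuracy = trace/total, and
per-class recall. Splitting operates on windows, matching the published
protocol's ratio; windows from one trial can land on both sides of the
split, so validation accuracy on synthetic data is an optimistic measure of
window-level separability, not of cross-session generalisation.

## Command mapping

Each 200 ms window contributes one label. A motion command is emitted only
when the same non-rest class wins `debounce_k = 3` consecutive windows
(600 ms of agreement) *and* differs from the currently active command —
preventing command flicker on a safety-critical actuator. REST holds the
current state rather than braking; braking is an explicit STOP token that
bypasses debouncing, mirroring the hardware emergency button.

## Kano module

Attributes are classified to their modal response category over
{M, O, A, I, Q, R}; ties break by the conventional requirement priority
M > O > A > I > R > Q. The rule is invariant under row rescaling, so counts
versus percentages is immaterial. On the packaged 15-attribute wheelchair
survey table the modal rule reproduces the surveyors' published evaluation
column in all 15 rows (the table itself contains no ties).

## Numerical and testing choices

- Determinism: every stochastic component takes an explicit integer seed;
  dataset seeds derive from one base seed through `np.random.SeedSequence`.
- Property tests run hypothesis in derandomised mode.
- End-to-end checks use 8 noise-free trials/class for the separability test,
  40 trials/class at −10 dB for the accuracy floor, and 12 trials/class x
  20 seeds x 5 SNR levels (+10, 0, −5, −10, −15 dB) for noise monotonicity,
  with a 0.02 Monte-Carlo tolerance on adjacent 20-seed means. These sizes
  keep the whole suite under a minute on one CPU while leaving the Monte-
  Carlo estimates stable.
- EDF export writes one data record with a symmetric physical range rounded
  to 3 significant digits (the 8-byte ASCII header constraint); round-trips
  agree to one 16-bit quantization step.

## Known limitations

- Single-channel only; no spatial filtering, filter-bank/extended CCA, or
  transfer learning.
- The published whole-system validation accuracy (83.1% on one subject's
  recordings) cannot be checked: the underlying EEG was never deposited.
  The property-based acceptance above replaces it.
- No stimulus rendering, device drivers, or motor control — frame schedules
  and command events are computed, never executed.
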
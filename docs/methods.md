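# Methods

This note documents the models, defaults and numerical choices behind
`remoteeg`, and what the synthetic benchmarks do and do not show.

## Signal model

A simulated session is the sum of four independent per-channel components,
all in microvolts:

1. **Background noise.** White Gaussian noise is shaped in the frequency
   domain by f^(−β/2) (DC bin zeroed) and rescaled to a target RMS, giving
   exact control of the power-law exponent β. Defaults: 10 µV RMS, β = 1
   ("pink" noise, the canonical broadband EEG background). Optional mains
   interference is a fixed-phase sinusoid at 50/60 Hz of configurable RMS.
   Channels draw from independent child streams of one seed, so a whole
   recording is bit-reproducible from its plan.
2. **State-gated alpha.** A sinusoid (default 10 Hz, 5 µV amplitude)
   multiplied by a per-state gain: 1 with eyes open, 2 with eyes closed.
   The gain applies within the behavioral-state intervals implied by the
   task sequence; phase is continuous across intervals.
3. **Event-related responses.** A template is a sum of Gaussian bumps
   (latency, width, signed peak amplitude, per-channel gain). The default
   oddball response is N200 (−3 µV at 200 ms, σ = 30 ms) plus P300
   (+5 µV at 300 ms, σ = 50 ms), added at each oddball onset. Gaussians
   were chosen over schematic waveforms because the peak semantics are
   directly testable (template value at the latency equals the stated
   amplitude).
4. **Markers.** Each scheduled event writes its integer code on the sample
   nearest its onset (0 = no event). Oddball trial j is presented at the
   center of its ISI slot, and task-end markers sit on the task's last
   sample, so distinct events always occupy distinct samples; if a user
   schedule nevertheless collides, the later event shifts one sample
   rather than being dropped.

Amplitude scales are conventions chosen to be realistic for dry-electrode
scalp EEG (clean background ≈ 10 µV RMS, alpha a visible fraction of it,
ERPs a few µV recoverable only by averaging); no published values
constrain them.

What the simulator does **not** model: volume conduction / channel
correlation, eye-blink and EMG artifact morphology, electrode drift and
impedance changes, non-stationary alpha (the rhythm is a fixed-frequency
sinusoid), latency jitter of the evoked response, or timestamp jitter of
the acquisition path. Passing benchmarks therefore demonstrate the
correctness and calibration of the pipeline's statistics under an idealized
but honestly parameterized signal, not performance on real recordings.

## Session engine

A session config is an ordered task list (`rest_eyes_open`,
`rest_eyes_closed`, `free_recording`, `oddball`) with a device name, a
marker map (defaults standard = 1, oddball = 2; task boundaries 100+i /
200+i) and a seed. Oddball sequences are i.i.d. Bernoulli draws
(default p = 0.1) repaired against runs of more than 2 consecutive
oddballs by re-drawing the violating trial from the same generator, which
preserves determinism. Defaults per block: 200 trials, ISI 1 s, stimulus
duration 0.2 s — configurable, as no convention is universal. The engine
emits renderer-agnostic stimulus descriptors (green circle for standards,
blue for oddballs) and never draws.

`run_session` consumes an ordered chunk stream (the acquisition-thread
abstraction). For replayed or simulated sources the stream's own
timestamps are the session clock, so a separate clock argument is accepted
but unused. A source that ends early raises a truncation error naming the
last fully covered task.

## Quality gate

Per-electrode variability is the sample standard deviation over a ≥ 1 s
window; state is accepted (σ ≤ 20 µV), rejected (σ ≥ 40 µV) or near
otherwise. The thresholds are order-of-magnitude choices (clean scalp EEG
vs motion artifact) and are parameters, not facts. A flat electrode
(σ = 0) is accepted by the stated rule; no disconnection heuristic is
layered on top.

## Recording format

`data.csv` (header `timestamp,<channels...>,Marker`) is written with 10
significant digits, which bounds the round-trip voltage error below
1e-6 µV for physiological amplitudes; markers are integers and round-trip
exactly. Metadata are JSON; ZIP entries carry a fixed date stamp so
archives are bit-reproducible (the manifest's creation time is a fixed
placeholder unless real-time stamping is requested).

## Spectral analysis

Bandpass: zero-phase Butterworth, 1–55 Hz. The order defaults to 10 per
edge (forward-backward) because the passband edge (55 Hz) sits close to
mains (60 Hz): lower orders fail a 20 dB suppression contract at 60 Hz
(order 4 achieves ≈ 11.5 dB, order 10 ≈ 22.9 dB). PSDs: Welch, 1 s Hann
segments, 50% overlap. Relative powers normalize by total 1–55 Hz power,
so each epoch's bands sum to 1; a consequence worth remembering is that a
genuine increase in one band mechanically depresses the relative share of
all others, so the scalp-wide change table should be read by sign and
magnitude, not by significance alone. Tests are Welch (unequal-variance)
t-tests; the channel × band table reports raw and Benjamini–Hochberg
adjusted p-values. Two constant equal groups yield p = 1 with a
degeneracy flag rather than a division by zero.

## ERP statistics

Epochs span −0.2…0.8 s around each stimulus marker (the conventional P300
window) with per-epoch, per-channel baseline correction over −0.2…0 s;
epochs crossing a recording edge are dropped and counted. The cluster
test uses pooled-variance two-sample t values, a two-sided cluster-forming
threshold at p = 0.05, one-signed contiguous clusters, mass Σ|t|, and a
max-cluster-mass permutation null (label shuffling, default 1000 draws,
vectorized as membership-matrix products). Cluster p-values use the
add-one estimator, flooring at 1/(n_perm+1). The two-sided null takes the
maximum |mass| over clusters of either sign — slightly conservative but
exactly the advertised family-wise construction; an external reference
implementation that only tracks positive cluster sums in its two-sided
null will report somewhat smaller mid-range p-values on the same data
while agreeing exactly on cluster boundaries and masses.

## MDM classifier

Covariances are prototype-augmented "super-trials": the mean training
oddball response stacked over the epoch, sample covariance, then shrinkage
(1−λ)Σ + λ·(tr Σ/d)·I with λ = 0.1 by default (λ > 0 is required whenever
T − 1 < 2C). The affine-invariant distance is computed via the symmetric
generalized eigenproblem; Karcher means use the standard fixed-point
iteration on the tangent-space average (arithmetic-mean initialization,
tolerance 1e-8 on the tangent norm, 50 iterations max, convergence failure
is an error carrying the final norm). A Euclidean (Frobenius/arithmetic
mean) mode exists for ablation. Ties in the nearest-center rule break
toward the lexicographically first class and are flagged. Evaluation is
stratified 5-fold cross-validation with pooled out-of-fold predictions;
AUC is the rank (Mann–Whitney) statistic of the distance-difference score;
chi-square is Pearson's on the 2×2 confusion table without continuity
correction, defined as (0, p = 1) when a margin is empty.

## Benchmark problem sizes

The repeated-simulation benchmarks (tests and `scripts/acceptance.py`) use:
100 randomized short sessions for marker fidelity; 2000 trials for the
oddball rate; 100 (tests) / 20 (script) random recordings for round-trip
fidelity; 20 sessions of 60 s per rest condition (30 two-second epochs
each, eyes-closed alpha gain 2) for alpha blocking; 200 pure-noise runs of
30 + 30 single-channel epochs × 1000 permutations for type-I calibration;
20 runs of 40 oddball / 360 standard epochs with a +5 µV deflection at
0.25–0.40 s for detection power; and a default synthetic oddball dataset
of 40/360 four-channel epochs for the classifier, with balanced 50/50
shuffled-label runs as its chance-level control. The direct epoch
generator slices its epochs from a bandpassed continuous noise stream so
benchmark epochs carry the same spectral content the session pipeline
produces after filtering.

## Known limitations

- Cluster connectivity is temporal only (per-channel), matching the
  analysis the toolkit validates; no spatio-temporal clustering.
- The classifier's chi-square treats pooled out-of-fold predictions as one
  contingency table; fold-to-fold dependence is ignored, as is standard.
- The quality gate is variability-only and cannot distinguish a perfect
  contact from a disconnected (flat) electrode.
- EPOC X's registry entry is provisional: its channel layout is included
  for completeness but not vendor-verified.
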
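# Methods

## The problem and the pipeline

A gaze-independent BCI can be driven by *imagined* flickering patterns:
imagining a checkerboard that flickers at f Hz produces occipital EEG
power at f and (weakly) 2f, resembling a steady-state visually evoked
potential (SSVEP) of reduced amplitude and broadened spectral shape.
The analysis pipeline implemented here is:

1. **Screening (evoked).** The subject views checkerboards flickering
   at the four candidate frequencies {5, 7, 9, 12} Hz; 15 repetitions
   of 3 s per class plus rest. A 1-s window from 1.8 to 2.8 s of each
   event is scored to pick the subject's two best frequencies.
2. **Offline imagery.** Ten recordings of 3 classes (imagery at the
   lower frequency, rest, imagery at the higher frequency), 20
   repetitions of 9 s each; the 1–7 s window of each event is used.
3. **Online imagery.** One recording with the fixed event sequence
   (lower, rest, higher) × 20, 5 s events, windows 1–4 s, classified by
   the model of the best offline cross-validation fold.

## Signal model of the simulator

Each channel c carries

x_c(t) = g_c · n(t) + g_c · a_k · [sin(2πf̃t + φ₁) + r · sin(4πf̃t + φ₂)]

during an event of class k, where n(t) is Gaussian 1/f^α noise
(α = 1 by default) synthesized in the frequency domain, g_c is a fixed
spatial gain (1.0 occipital, 0.6 parietal, 0.35 temporal/frontal),
a_k the subject's response amplitude at the class frequency, r the
second-harmonic ratio and φᵢ random per-event phases. For imagery
events a_k is multiplied by the attenuation factor and the event
frequency f̃ = f + ε with ε ~ N(0, σ_j²), producing the weaker, smeared
imagery peaks; rest events carry background only. Events are laid
back-to-back; the 2-minute breaks between recordings carry no signal
of interest and are not simulated.

Background amplitude is normalized so its RMS **within 1–40 Hz** equals
`noise_scale`. This makes signal-to-noise independent of the sampling
rate (a total-RMS convention would dilute the band as Nyquist grows).

Defaults, chosen once as physiologically plausible values: fundamental
response amplitudes drawn uniformly from 2–4 µV (occipital SSVEPs of a
few microvolts), harmonic ratio 0.3 (second harmonics visible but
weak, and often absent for imagery), imagery attenuation 0.5, imagery
frequency jitter SD 0.1 Hz, background 10 µV RMS in 1–40 Hz with
α = 1. Sampling rate defaults to 256 Hz and is freely configurable;
the validation suite runs its Monte-Carlo experiments at 160 Hz, which
the band-RMS noise convention makes statistically equivalent while
roughly halving the cost. "Planted dominant" experiments set the
dominant pair's amplitudes to 4 µV against 2 µV for the others,
i.e. an amplitude SNR of about 2.

**What the simulator does not emulate:** eye blinks, muscle and
movement artifacts, electrode drift and impedance changes, alpha-band
nonstationarity, inter-subject montage variability, or any forward
head model. Passing tests therefore show that the *pipeline* is
correct and honest (no leakage, chance-level behavior without signal),
not that the reported human accuracies would be reproduced on real
EEG — those enter only through the packaged per-subject tables.

## Preprocessing

Low-pass (60 Hz, Butterworth order 4), notch (50 Hz, −3 dB edges at
48/52 Hz, second-order IIR) and band-pass 3–36 Hz. "Order 8" for the
band-pass is read as the overall transfer order (scipy
`butter(4, band)`), the convention of MATLAB-style band-pass design.
All three are applied forward-backward (zero phase): the analysis is
offline, and zero-phase filtering keeps event onsets aligned with the
annotations. In the original acquisition the first two filters ran
causally on the recorder; for the simulated data the distinction only
affects group delay, which zero-phase application removes entirely.

Epoch windows are half-open [start, end) seconds from event onset with
sample index floor(t·fs), so adjacent epochs never share a boundary
sample. The chain requires fs > 120 Hz so the 60 Hz edge stays inside
Nyquist.

## Features

Welch PSD per trial and electrode: 2-s Hamming segments, 50% overlap,
density scaling — 5 averaged segments for a 6-s epoch, 2 for a 3-s
epoch, grid spacing 0.5 Hz. The feature vector is the PSD restricted
to the closed band [3, 36] Hz (67 bins) concatenated over the 10
analysis electrodes in fixed order: 670 columns. The Welch scaling
convention is immaterial downstream because features are z-scored from
training data.

The peak-scoring rule needs ±0.05 Hz neighborhoods, far finer than any
short epoch's native resolution, so scoring uses a single
Hamming-windowed periodogram zero-padded to a 0.025 Hz grid.
Zero-padding interpolates the spectral shape; the window main lobe
(≈1.3 Hz for 1-s epochs) still sets the physical resolution, which is
fine for the purpose: the score compares relative peak shapes across
candidates on a common grid.

## Frequency selection

For candidate frequency f and each screening epoch and occipital
electrode (Oz, O1, O2): Δp± = M± − m± with M± the PSD maximum within
±0.05 Hz and m± the minimum within ±0.5 Hz, computed separately on
the left and right sides, both intervals anchored at f (sharing the
center keeps Δp ≥ 0 by construction); S = max(Δp₊, Δp₋)/ι with ι the
half-height width of the peak. ι is measured from the apex within
±0.05 Hz, crossing apex/2 by linear interpolation within ±0.5 Hz,
clamping at the window edge when a side never crosses, and flooring at
one grid step so a single-bin spike cannot divide by zero. Scores at f
and 2f are summed with equal weight, then over the 15 repetitions and
the 3 electrodes (a plain sum; no baseline correction from rest
epochs). The two top-scoring candidates win unless the lower one's
second harmonic falls within 0.25 Hz of the higher (never the case
inside {5, 7, 9, 12}); ties break toward lower frequencies.

The score is linear in the PSD, hence quadratic in signal amplitude;
selection is invariant under any positive rescaling.

## Classifier

`LinearSVC` (liblinear, one-vs-rest, C = 1, fixed random state),
preceded by per-feature z-scoring fitted on training rows only. A
linear one-vs-rest machine is used because unscaled PSDs span orders
of magnitude across electrodes and frequencies and because the
published design specifies a linear kernel; no hyperparameter search
is performed. Temporal cross-validation groups the ten offline
recordings into five consecutive pairs; fold i tests on pair i and
trains on the remaining eight recordings, so each recording is tested
exactly once and test data is always temporally contiguous. Reported
spread across folds is the population SD. The online model is the
best fold's (earliest on ties). Familiarization (Step 2) recordings
can be simulated but are not consumed by the classifier.

## Statistics

*Chance bounds.* The accuracy of a random k-class classifier over
n = n_per_class · k balanced trials is bounded with the adjusted-Wald
(Agresti–Coull) construction: with z the upper 1 − α/2 normal
quantile, ñ = n + z², p̃ = (n/k + z²/2)/ñ, bound = p̃ + z·√(p̃(1−p̃)/ñ).
This reproduces the quoted 39.0% (160/class, 99%), 37.7% (95%) and
50% (20/class, 99%) anchors to within 0.1 points. The quoted 45%
(20/class, 95%) is **not** reproduced by this construction (it gives
≈46.0%) and is deliberately excluded from the validation anchors.

*Summaries.* Subject-level accuracy summaries use the population
(divisor-n) SD — the only convention consistent with the quoted online
SD of 8.62 across the 20 subjects.

*Welch's t.* t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) from group summaries,
df from Welch–Satterthwaite with nᵢ − 1 weights. Feeding in the online
summary (population SD) against the random-classification reference
(mean 33.33, SD 26.05, n = 20) yields t ≈ 2.83, df ≈ 23.1. The quoted
pair (2.82, 23.1) is not exactly attainable under any single variance
convention (sample-SD input gives 2.82 with df 23.3), so the
validation tolerances are ±0.05 on t and ±0.3 on df.

*Counts.* `count_above` counts strictly; applied to the packaged
online column it gives 8 subjects above 50% and 14 above 45%, the
direct enumeration of the printed values.

## Persistence

EDF+C writing is implemented in-package (16-bit quantization over each
channel's physical range, one 1-s data record per second, events as
EDF+ TAL annotations); reading goes through MNE, which doubles as an
independent check of the writer. EDF export requires an integer
sampling rate and whole-second recordings; the CSV dialect (data
matrix + events sidecar + JSON metadata sidecar) round-trips samples
bit-exactly and has no such restriction.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds;
  identical (protocol, profile, couple, seed) inputs reproduce
  recordings exactly, and `run_pipeline` reports are byte-identical
  for equal configurations (the config hash is recorded in each
  report).
- The validation suite's Monte-Carlo sizes follow the experiment
  design: 100 seeded screenings for frequency-recovery and null
  selection, 100 zero-gain subjects for chance-level honesty, 20
  high-SNR subjects for power, 100 label permutations for leakage.
- Degenerate inputs: all-zero recordings filter to all-zero; all-zero
  epochs produce all-zero features and zero scores; flat PSDs score
  S = 0; single-bin peaks hit the ι floor of one grid step.

## Known limitations

- **The peak score is level-biased.** S is linear in the PSD with no
  normalization by the local spectral level, so over a 1/f background
  the noise-driven component of the score is systematically larger at
  lower frequencies (≈2.4× between 5 and 12 Hz). On recordings with no
  evoked response at all, the selection therefore degenerates to the
  lowest-frequency couple rather than a uniform draw — the score
  separates *which peaks are strongest*, not *whether any peak exists*.
  In practice this is harmless for screening data with real responses
  (planted couples are recovered essentially always at amplitude SNR
  ≈ 2), but the selection output alone should not be read as evidence
  that a response is present; the band-power-vs-rest comparison is the
  appropriate null check.
- The simulator's stationary per-event sinusoid is a deliberately
  simple response model; real SSVEP/imagery responses wax and wane
  within events and across fatigue.
- The online stage is a replay of a simulated recording, not a
  real-time loop; information-transfer-rate and latency questions are
  out of scope.
- Only the analysis montage's 10 electrodes are simulated; reference
  and ground electrodes of the physical 12-electrode cap carry no
  analyzable signal and are omitted.
- The empirical distribution of selected couples across human subjects
  cannot be reproduced from simulation and is not attempted.
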
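# Methods

This note documents the models, algorithms, parameters and design choices
behind `scoper`, in the order the pipeline applies them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and sample rates

A recording holds six channels on one shared time axis: ECG at 128 Hz (mV),
three acceleration axes at 500 Hz (g), and red/infrared PPG at 50 Hz
(ADC units). These are the firmware's operational rates: the ECG front end
samples at 128 Hz, the accelerometer at 500 Hz behind a 125-Hz anti-alias
filter, and the PPG is 4x-oversampled at 200 Hz so 50-Hz streams are
broadcast. The device z-axis points out of the chest, so the dorso-ventral
axis carries the seismocardiogram (SCG) and tidal chest motion, and supine
posture puts gravity along -z.

Offline filtering is third-order Butterworth band-pass applied
forward-backward (zero phase): SCG 4-24 Hz, ECG 0.5-50 Hz, PPG 0.3-7 Hz,
and a widened 0.1-24 Hz SCG band for the apnea scalograms. Zero-phase
filtering is a deliberate choice: PEP and LVET are timing measurements and
cannot tolerate group delay.

## Synthetic generator

The generator is phenomenological and built for recoverability, not
biophysical fidelity:

* **ECG** — a 5-lobe sum-of-Gaussians PQRST template repeated at beat times
  drawn from the stage heart rate with Gaussian inter-beat jitter
  (`hrv_sd`, ms).
* **SCG** — Gaussian-windowed 22-Hz tone bursts (about 60-ms envelope) on
  the dorso-ventral axis: AO at R + PEP, AC at R + PEP + LVET, and a
  smaller ACM burst 40 ms before AC. The 22-Hz carrier sits inside the
  4-24-Hz analysis band and inside the 20-25-Hz kinetic-energy band.
* **Respiration / position** — a tidal sinusoid of amplitude `re_amp` (g)
  at the breathing rate on the dorso-ventral axis; gravity is a unit
  vector set by posture, cross-faded over 2 s at position changes; wake
  epochs add band-limited (0.7-3 Hz) movement noise that drives the
  actigraphy feature.
* **PPG** — both channels share one cardiac pulse waveform; the red/IR
  pulsatile-amplitude ratio is set by inverting the oximetry calibration
  line at the scripted SpO2, which makes the oximetry round trip
  calibration-independent.
* **Events** — during an apnea/hypopnea of severity `s` the tidal
  amplitude is scaled by (1 - s); SpO2 relaxes first-order toward a
  desaturation of depth 35 %·s after a 10-s central-to-peripheral
  transport delay (fall tau 20 s, recovery tau 10 s); for 15 s after the
  event a sympathetic transient raises HR (+12·s bpm) and shortens PEP
  (-12·s ms) and LVET (-20·s ms) while raising the AO burst amplitude.
  The magnitudes of the post-event transients are free parameters of the
  generator (the literature gives directions, not magnitudes).

Stage-dependent operating points (wake / light / deep / REM) differ in HR
(70/60/55/66 bpm), HRV, PEP (95/100/105/78 ms), respiratory amplitude and
movement level. They are chosen to be separable by the downstream stager;
they are not claimed physiology. Raw scripted events may overlap; the
AASM-style rule that no two scored events occur within 10 s merges them in
the ground-truth annotations.

What the generator does **not** emulate: motion artifacts beyond additive
noise and posture flips, baseline wander, electrode pops, perfusion
changes, arrhythmias, or any hemodynamic feedback (no Windkessel or
baroreflex). Passing the round-trip suite therefore demonstrates
correctness of the estimators under the stated signal model, not clinical
performance on real patients.

## Cardiac chain

R peaks: the band-passed ECG is normalized, narrowed to 5-22 Hz (QRS
enhancement), differentiated, squared and integrated over 150 ms; peaks
above an adaptive per-10-s threshold with a 200-ms refractory are refined
to the local ECG maximum. Per-beat quality is the correlation with the
mean beat template. A flatline yields an empty, flagged beat table.

HR/HRV per window: HR = 60 / mean RR; SDNN = sample SD of RR; RMSSD = RMS
of successive RR differences.

SCG beats are cut [R, R + 0.5 s), quality-filtered, and ensemble-averaged
per 60-s section. On the average beat, AO is the largest positive peak in
the S1 window (default 20-150 ms post-R), AC the largest positive peak in
the S2 window (default 250-450 ms), and ACM the last local peak between AO
and 10 ms before AC. PEP is operationalized as the R-to-AO interval (the
device has no Q-onset measure) and LVET as AO-to-AC. |AO| defaults to the
analytic-envelope magnitude at AO, with a raw-sample option, since the
field uses both conventions. Empty search windows flag the fiducial
missing rather than fabricate one.

Cardiac kinetic energy: mean analytic-signal magnitude of the SCG filtered
to 20-25/25-30/30-35/35-40 Hz, per 5-s window with 50 % overlap.

## Oximetry

Per 4-s window (50 % overlap), AC is the peak-to-trough amplitude of the
0.3-7-Hz pulsatile PPG and DC the sub-0.3-Hz trend mean; the ratio of
ratios R = (AC_red/DC_red)/(AC_ir/DC_ir) maps to SpO2 = a - b·R, clipped
to [0, 100]. The default (a, b) = (110, 25) is a conventional uncalibrated
reflectance line and lives in the run configuration; because the generator
inverts the same line, tests are calibration-independent. A +10-s shift
utility aligns the central (sternal) reading with peripheral references.

## Respiration and position

The dorso-ventral axis filtered to 0.1-0.7 Hz gives the respiratory
waveform; RE is its mean Hilbert-envelope amplitude per 10-s window
(reported in g — the device never defines displacement units, so
acceleration amplitude is used; the band-passed waveform is also emitted).
RR is the dominant in-band spectral peak per 60-s window, parabolic-refined;
windows whose in-band RMS falls below 5 % of the record median are flagged
missing (an apnea window has no rate). Position is the angle of the
low-passed (<0.1 Hz) gravity vector in the transverse plane,
theta = atan2(g_y, -g_z), quantized into counterclockwise-closed quadrants
[theta0 - 45°, theta0 + 45°) for supine/left/prone/right; windows with
| |g| - 1 | > 0.3 g are labelled `moving`. The quadrant convention and the
tie-break at exactly 45° (the boundary belongs to the quadrant it opens,
counterclockwise) are this package's choices.

## Quality metrics and gate

Periodicity is the overlap-normalized autocorrelation ratio at the
one-beat (mean RR) lag, searched within ±10 % of the nominal lag; the
two-beat lag is also reported. It is 1 for a perfectly periodic signal and
~0 for noise; beat-to-beat jitter lowers it even on clean signals, which
is why the gate threshold is calibrated rather than fixed at a round
number. DTW repeatability warps each beat of a 60-s section onto the
section's average beat (symmetric steps, no window, squared-Euclidean cost
on z-normalized beats — the distance and normalization are unstated in the
original description, so they are design choices here) and reports the RMS
pointwise distance along the paths, averaged over beats.

The gate rejects a segment when periodicity < 0.1 or repeatability > 0.4.
These defaults were calibrated once on the clean synthetic corpus so that
clean rejection stays below 1 % while pure-noise segments (periodicity
~0.03, repeatability ~0.7) are rejected; the only field anchor available
is that no more than 15 % of real data should be rejected.

## Morse wavelet element analysis

The analyzing wavelet is the generalized Morse wavelet, defined in the
frequency domain as psihat_{k,gamma}(w) = a·w^k·e^{-w^gamma} for w >= 0.
Two normalizations coexist: unit energy (the `morse_wavelet` default) and
the bandpass normalization a = alpha_{k,gamma} = 2(e·gamma/k)^{k/gamma},
which the element-analysis identities require. The transform is computed
by frequency-domain multiplication per scale on a log-spaced grid (8
voices per octave by default); only positive frequencies are kept, so a
real signal's transform is half its analytic transform, which is exactly
the convention under which an element Re{c·psi_mu((t-t0)/rho)} produces a
transform maximum of value c·zeta_max/2.

Event inversion: at each strict 2-D local modulus maximum (tau, s) —
sharpened by parabolic interpolation in time and log-scale — the
estimators are t = tau, rho = s·((mu+1)/beta)^{1/gamma}, and
c = 2·w(tau, s)/zeta_max(beta, mu, gamma). The scale relation follows
from maximizing |zeta(0, r)| at r^gamma = beta/(mu+1); the printed source
for this exponent is typographically garbled, so the derivation-consistent
reading is implemented and validated by the injected-element round trip
(the helper `scale_ratio` keeps it pluggable). Reconstruction synthesizes
each element in the frequency domain on the signal's own DFT grid, which
is alias-safe at any inferred scale.

Scalogram images for the apnea classifier: each 30-s epoch of the
0.1-24-Hz SCG (decimated to 64 Hz) is transformed, maxima above 5x the
median modulus are inverted into at most 60 elements, the sparse
reconstruction is re-transformed, and |w| is normalized to [0, 1] and
rasterized (128x128 by default; 32x32 at desk scale). The sparse step
suppresses background noise and keeps coherent cardiorespiratory
structure. Default (beta, mu, gamma) = (3, 2, 3); the original values are
not published, so these are configuration.

## Sleep staging

Per 30-s epoch, mean/sd/min/max of each vital (HR, SDNN, RMSSD, PEP, LVET,
|AO|, RR, RE, SpO2) over the epoch and over the ±1-epoch context window,
the four kinetic-energy band means, and the 0.7-3-Hz actigraphy power —
min-max normalized, missing values imputed by neighbor interpolation, and
epochs over 50 % missing flagged unscorable. The published feature count
is internally inconsistent (262 vs 120), so this package fixes the
*architecture* — one hidden layer of 120 sigmoid units with a softmax
4-class output — and logs whatever feature count the builder emits.
Training is full-batch conjugate-gradient backpropagation (500 iterations
by default, small L2), deterministic per seed; a fourfold
cross-validation utility partitions contiguous equal segments. At
prediction, light+deep pool into NREM (wake and REM probabilities are
untouched), labels are the merged argmax with ties broken toward the
earlier class, and unscorable epochs carry the nearest scorable label,
flagged.

## Apnea detection

Epochs are 30 s at a 10-s stride (20-s overlap); an epoch is labelled
positive when at least 50 % of a scored event's duration overlaps it (the
labelling rule is this package's choice). The classifier is a residual CNN
over the scalogram images: a stride-2 stem convolution, then blocks
computing y = H(x) + x with H = conv3x3-ReLU-conv3x3 and an identity
shortcut (strided 1x1 projection when the shape changes; no post-add
activation, so a zero-weight identity block is exactly the identity).
The head concatenates global average and global max pooling — the mean
branch summarizes the epoch while the max branch keeps localized cues
from events at the window edge. Desk scale is 8 blocks (~18 weighted
layers, width doubling as resolution halves); a 115-layer configuration
is constructible but not trained at desk scale. Training is Adam on
weighted binary cross-entropy (positive class weighted by the prevalence
ratio) with small weight decay and time-flip augmentation, deterministic
per seed.

The parametric gate is a boosted decision-tree ensemble with random
undersampling of the majority class per round (RUS boosting, 30 rounds of
depth-3 trees). Its features aggregate each 30-s epoch window with the
extremum an event would drive (periodicity/PEP/LVET/RR minimum, HR and
DTW-repeatability maximum), and express the oximetry and effort channels
relative to the subject's own baseline: desaturation depth below the
record median SpO2 and respiratory effort as a fraction of the record
median. In the default veto mode the gate rejects a detection only when
its vote score is confidently event-inconsistent (margin 0.3) — its job
is stripping systemic noise such as posture changes, not re-deciding
borderline epochs; the quality-gate mask vetoes outright. A fusion mode,
in which the ensemble takes the CNN confidence as an additional feature
and emits the final score, is also provided.

Post-processing merges consecutive positive epochs into events, merges
events separated by less than 10 s (simultaneous apnea/hypopnea report as
one event — the two types are detected without distinction), and computes
AHI against total sleep time from the hypnogram. By default the reported
event interval is the raw positive-epoch span; the optional onset
refinement deconvolves the 50 %-overlap epoch support (a two-regime
midpoint estimator, since positive-epoch starts span exactly one epoch
length for events shorter than an epoch and the event duration beyond
that), which localizes onsets and offsets to within 10 s of truth for any
event duration and grid phase when the epoch detections are correct.

## Laminate bending stiffness

The flexible circuit (PI/Cu/PI/Cu/PI at 2.6/1.5/8.7/1.5/2.8 um, E_PI =
2.5 GPa, E_Cu = 119 GPa, 22 x 43 mm) is modelled by the transformed-section
method: widths scale by E_i/E_ref, the neutral axis is the transformed-area
centroid, I comes from the parallel-axis theorem, and k = 8·E_ref·I/L^3.
Two deliberate decisions: (1) the transfer term uses d_i^2 — the printed
final formula drops the square, which is dimensionally inconsistent with
the parallel-axis statement preceding it; the as-printed variant stays
available behind a flag for comparison. (2) The published stiffness value
could not be reproduced from the published inputs under either variant;
the package reports its computed value and the as-printed variant side by
side rather than forcing agreement. An independent brute-force oracle
integrates E(y) and E(y)·(y - ybar)^2 over layer-aligned quadrature grids.

## Desk-scale study conditions

The acceptance benchmarks use: a 1-h zero-noise record for the vitals
round trip (four posture segments, four desaturations of 5/15/25/35 %
depth); and an end-to-end benchmark that trains the stager, the CNN and
the gate on two symptomatic synthetic subjects (2 h each with dense,
50-event schedules, so every stage x severity combination is represented
— the analogue of training on symptomatic patients) and evaluates on an
unseen subject's 8-h night containing 25 scripted events under moderate
noise, with the CNN at a 32x32 raster, 8 blocks, and a detection
threshold of 0.4. Onset localization is reported against the 10-s
epoch-grid bound.

## Numerical notes and limitations

* Frequency-domain wavelet evaluation requires the wavelet's spectral
  support to fit below the grid Nyquist; `morse_wavelet` raises on scales
  too small for the sampling rate, while the frequency-domain
  reconstruction path has no such restriction.
* Parabolic refinement of transform maxima is clipped to ±0.5 grid steps;
  degenerate curvature falls back to the grid point.
* Min-max normalization maps a zero-range column to 0.5 with a warning;
  reapplied training parameters may take new data outside [0, 1].
* EDF export uses 1-s records with 16-bit samples, so values round-trip to
  about 1/65000 of the channel range and rates must be integral.
* The end-to-end performance floors are properties of the synthetic
  corpus at its fixed benchmark seeds; they stand in for — and do not
  establish — the clinical numbers reported for overnight human
  recordings. Across different corpus seeds the epoch-level apnea
  precision varies noticeably (staging is stable), because small
  synthetic training corpora leave the CNN's false-alarm behavior
  subject-dependent; a larger training corpus would be the first lever on
  real data.
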
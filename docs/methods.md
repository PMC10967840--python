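# Methods

## Signal model of the synthetic scenes

No public corpus of chest-wall accelerometer recordings with wheeze labels
exists, so `wheezekit.synthetic` defines an explicit generative model whose
components occupy the bands a contact sensor sees them in. All amplitudes
are relative units on one common scale; the defaults below are the
conditions under which every test and the acceptance script run.

| component | model | default |
|---|---|---|
| chest-wall motion | quasi-triangular sub-1 Hz displacement, rising during inspiration (upright posture, deep breaths), corners softened by a short Hann kernel | amplitude 1.0 |
| breath noise | Gaussian noise band-shaped to 60–1200 Hz (4th-order Butterworth), multiplied by a half-sine airflow envelope per phase; inspiration gain 1.0, expiration 0.75 | level 0.2 |
| wheeze | harmonic stack Σₕ sin(h·φ(t))/h with instantaneous fundamental f₀ + drift·t, 10 ms raised-cosine on/off ramps; optional gating to one respiration phase with 20 ms ramps | amplitude per event |
| crackle | exponentially damped 650 Hz burst, τ = 3 ms, 15 ms long | amplitude per event |
| heart sounds | paired S1/S2 damped pulses (35 / 45 Hz, τ 40 / 30 ms, S2 at +320 ms, 0.6× S1) at the configured heart rate | level 0.1 |
| sensor noise | white floor standing for the front end's thermal noise | 5 × 10⁻⁴ |
| ambient interference | voice-like syllables (2–3 formant tones in 100–1200 Hz, 120–280 ms, ~3/s) plus 900 Hz monitor-alarm beeps; RMS-normalized then scaled | level per call |

Ambient interference is mixed **only** into a separate "air-microphone" copy
of a scene, never the contact channel — this encodes the physical claim that
a skin-coupled accelerometer does not hear airborne sound. The breathing
cycle uses an inspiratory fraction of 0.4 (inspiration shorter than
expiration, as in quiet adult breathing).

Ground truth records the audible support of each wheeze (its event window
intersected with its gate), exact phase intervals, and per-5 s-segment
labels: a segment is *wheeze* iff its overlap with wheeze intervals is at
least a configurable fraction (default 0.1) of the segment length.

What the simulator does **not** model: BMI-dependent tissue transfer
functions, polyphonic wheezes beyond independent simultaneous stacks,
posture changes, coughs, sensor detachment. Passing tests therefore
demonstrate algorithmic correctness under the stated signal model, not
clinical performance.

Wheeze loudness relative to breath sounds is only qualitatively constrained
by auscultation practice (adventitious sounds are louder); corpus generation
draws amplitudes log-uniformly against breath noise 0.2 — 0.3–0.7 for the
"separable" corpus and 0.25–0.6 for the benchmark corpus.

## Preprocessing

Bandpass 60–2000 Hz with an order-10 Butterworth prototype; the filter runs
zero-phase (`sosfiltfilt`, second-order sections for numerical stability) so
detector timing and respiration alignment are not skewed by group delay.
Savitzky–Golay uses window 9 with polynomial order 3 (the order is not
dictated by the design; 3 is the common smoothing default and is
configurable). Wavelet denoising is db3 at level 4 with soft thresholding at
the universal threshold σ√(2 ln N), σ from the MAD of the finest detail
band; a numeric threshold of 0 makes the stage an exact identity, which is
the tested round-trip contract. Segmentation is non-overlapping 5 s windows;
the trailing partial window is dropped and counted. Scaling to [−1, 1] is
per segment by its own max-abs (all-zero segments stay zero), which makes
the whole chain invariant to overall input gain. The air channel receives
only the generic bandpass (a stand-in for a stethoscope's built-in pulmonary
filter) — no SG or wavelet stages.

## Mel front end

Unpadded framing: frame k covers samples [k·hop, k·hop + window), so N
samples yield ⌊(N − window)/hop⌋ + 1 frames; a 5 s, 20 kHz segment with
window 1024 / hop 512 gives exactly 194 frames. Frame times are frame
*centers* — this is what lets event onset/offset estimates land within one
hop of truth. The mel map is the HTK form m = 2595·log₁₀(1 + f/700)
(1000 Hz ≈ 1000 mel). 64 triangular filters have centers equally spaced in
mel between 60 and 1200 Hz, peak-normalized (area normalization is a config
option); a triangle too narrow to contain an FFT bin gets unit weight at the
nearest bin so no band is dead. dB is relative to the matrix maximum with an
−80 dB floor; silence returns the uniform floor.

A resolution caveat: at the contact configuration the 64 bands oversample
the STFT bin width (19.5 Hz) below ≈700 Hz, so a pure tone's energy
concentrates in its two bracketing bands only in the upper half of the
range, and single tones could otherwise split into twin local maxima —
which is why the detector's peak test requires dominance over a ±2-band
neighbourhood.

## Time–frequency detector

Per frame, peaks are interior bands strictly above both immediate
neighbours, no smaller than second neighbours, and more than
`baseline_margin_db` (default 8 dB) above the frame's **median** dB — the
median is robust to the ridge itself, and "frame median + margin" is the
concrete reading of a constant spectrogram baseline. Linking is greedy
frame-to-frame on the Hz axis: a peak may extend a track if it is within
50 Hz of the track head; the closest |Δf| wins, exact ties go to the lower
frequency; each peak joins at most one track; `max_gap_frames` defaults to 0
(strict continuity — a wheeze is a near-constant tone). A track becomes a
`WheezeEvent` when its span (n−1)·hop strictly exceeds 100 ms and, with the
default minimum-frequency rule enabled, its mean frequency is ≥ 100 Hz (the
rule is toggleable since low-frequency ridges may still be of interest).

With hop 25.6 ms this means ≥ 6 linked frames: a 77 ms tone can register at
most ~5 detectable frames (76.8 ms span) and is rejected, while a genuine
ridge's onset/offset (frame centers) are recovered to within one hop.

Per-frame noise peaks are not rare — single-bin mel bands are χ²-distributed
and exceed the frame median + 10 dB in a few percent of frames — so the
detector's specificity rests on the continuity and duration rules; in tests,
noise-only segments produce zero events across all seeds.

## CNN classifier

Architecture (valid/unpadded convolutions):
4 × [conv 3×3 (32/64/128/256) → ReLU → dropout 0.25 → maxpool 2×2] →
flatten → dense 128 (ReLU) → dropout 0.5 → dense 1 → sigmoid, binary
cross-entropy, Adam at lr 0.001. For a 64×194 input the spatial sizes after
each block are 31×96, 14×47, 6×22, 2×10. The implementation is plain numpy
(im2col + BLAS matmul, float32) with an explicit seeded generator for
initialization, shuffling and dropout, so a run is bit-reproducible on a
given BLAS. Inputs are per-spectrogram standardized dB matrices — the only
input normalization.

Protocol: a stratified 20% test hold-out, five-fold stratified CV on the
pool (each fold the early-stopping validation set of its model), then a
final fit on the pool — with a 10% carve-out purely for early stopping —
scored once on the test set. Splits are grouped by recording by default so
segments of one recording never straddle train and test; grouping uses a
label-stratified group k-fold (a plain group shuffle can leave a badly
unbalanced test side when recordings are label-homogeneous). Dense width
(128), batch size (32), max epochs (100) and patience (10) are free
parameters with those defaults.

An optimization note that matters for schedules: at these pool sizes
(hundreds of segments) the loss typically sits at chance (ln 2) for several
epochs before breaking away and then converging rapidly — at 64×194 inputs
the plateau lasts ~7 epochs on the benchmark corpus and longer for fainter
wheezes. Early-stopping patience therefore has to exceed the plateau; the
test suite and acceptance script use batch 16 with patience 8 (benchmark,
15 epochs max) or patience 3 (separable corpus, 10 epochs max, where the
plateau is short).

The channel benchmark (`wheezekit.benchmark`) scores the deterministic
detector and a single trained CNN per channel on one shared held-out test
set — the comparison-table protocol; cross-validated evaluation is the
classifier module's separate protocol.

## Respiration

Low-pass 5 Hz (order-10 Butterworth, zero-phase) → centered moving average
(default 0.5 s) → mean centering. Phase boundaries are local extrema of the
smoothed motion with a prominence floor of 10% of the motion range (ignores
micro-ripples); rising intervals are inspiration. Leading/trailing partial
ramps are labeled by their slope so the intervals tile the trace; with no
usable extremum the whole trace is "unknown". Rate = 60 / median duration of
complete inspiration+expiration cycles (median resists a single irregular
breath); at least two complete cycles are required. Events are tagged with
the phase holding the majority of their duration. The ramp-to-phase mapping
assumes an upright subject taking deep breaths; the module documents rather
than compensates for posture.

## Problem sizes

Synthesis and training sizes are chosen to exercise every code path at
desk scale: the classifier sanity corpus is 72 recordings × 30 s at 8 kHz
(432 segments, 64×77 mel inputs); the contact-vs-air benchmark corpus is
36 recordings at the nominal 20 kHz (216 segments, 64×194 inputs — the
deterministic detector needs the 25.6 ms hop, so it is never run at reduced
rates); respiration recovery uses 60 s scenes at 8 kHz across 8–30
breaths/min. Detector/oracle equivalence runs on 500 random 8-band × 12-frame
grids against a naive brute-force reimplementation of the rules.

## Known limitations

- The synthetic scenes are far cleaner than hospital recordings; absolute
  metric values here say nothing about clinical accuracy — only orderings
  and contracts (e.g. contact ≥ air, CNN ≥ deterministic under the stated
  conditions) are meaningful.
- The deterministic detector reports one event per harmonic of a strong
  stack; event counts are per-ridge, not per-wheeze (segment flags are
  unaffected).
- Mel-band oversampling below ≈700 Hz limits frequency attribution to about
  two band widths there.
- The numpy CNN is single-threaded BLAS-bound; it is sized for hundreds of
  segments, not the thousands a clinical corpus would bring.
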
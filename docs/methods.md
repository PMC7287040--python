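# Methods

This note records the models, parameter choices and numerical conventions
behind `hfopipe`, and what the synthetic benchmark does and does not
establish about real recordings.

## Signal model and preprocessing

Recordings are held in microvolts throughout; the extreme-amplitude
screening rule is stated in µV, so units are fixed at read time. EDF is the
interchange format (reading via mne; a minimal built-in writer produces
plain 16-bit EDF with symmetric per-channel physical scaling, so round-trip
error is bounded by half a quantization step of range/65535).

Line noise is removed with one 3rd-order zero-phase Butterworth band-stop
per harmonic (50, 100, … 450 Hz), stop-band half-width ±2 Hz — the
conventional width for clinical line noise; the filter order and harmonic
range are the method's stated parameters, the width is ours. Bipolar
re-referencing pairs adjacent contacts along each shaft as contact k minus
contact k+1 (deep minus shallow); polarity is a convention only, since all
downstream statistics are amplitude-based.

### Channel screening parameters

| rule | parameter | default | note |
|---|---|---|---|
| outside brain | — | — | either contact on a zero voxel of the brain mask, or off-grid |
| gray-matter cube | cube, minimum count | 3×3×3 voxels, ≥ 9 gray | midpoint mapped by nearest voxel under the mask affine; off-grid cube voxels count non-gray; assumes ≈1 mm isotropic masks |
| low amplitude | RMS percentile | 35th | interpreted as the 35th percentile of the RMS distribution over in-brain channels (not 35 % of the maximum); whole-clip RMS |
| extreme amplitude | threshold, duration | 1000 µV, > 1 s | strict consecutive-sample run on the bipolar trace |

The percentile reading of the "below 35 % of all channels" rule and the
bipolar (rather than monopolar) trace for the extreme-amplitude test are
documented choices; both are configurable.

## Detector

Per band (80–500 Hz, then 250–500 Hz): 64-order zero-phase forward–reverse
FIR band-pass; envelope by cubic spline through the local maxima of the
rectified signal (held at the nearest maximum beyond the first/last one);
threshold 5 × median of the standard deviations of consecutive 100 ms
epochs (truncated final epoch dropped). An excursion of the envelope above
threshold is an event if strictly longer than 6 ms; events whose run peaks
lie closer than 20 ms chain into one (single linkage), the merged event's
peak being the envelope maximum over the union span. Event boundaries are
the threshold-crossing samples. The duration test runs before merging by
default (both orders available). Fast-ripple-band events that overlap a
broad-band event in span, or peak within 20 ms of one, set that event's FR
flag; the rest are appended.

Note that a literal 64-order FIR at 2048 Hz has a transition band of
roughly 100 Hz, so the nominal 80 Hz edge reaches flat gain only above
~130 Hz; ripples near the band edge are detected against a threshold
derived from the same filtered signal, which preserves the
scale-invariance of the rule. The whole detector is gain-invariant:
envelope and threshold scale linearly, so detections are unchanged under
any positive channel gain.

## Scalogram

Each candidate is epoched in a 600 ms window centered on its envelope peak
with 200 ms guard padding per side (mirror-padded at clip edges). The raw
trace is whitened first with a 1st-order zero-phase 8–490 Hz Butterworth —
shallow roll-off deliberately preserves spike morphology while flattening
the 1/f background. The wavelet family is constant-Q Morlet defined by the
mother wavelet at 1 Hz with 3 s time-domain FWHM, giving FWHM(f) = 3/f s
(≈ 8 cycles at every frequency). Implementation is an FFT-domain Gaussian
filter bank — one FFT of the epoch, then per center frequency a Gaussian
of σ_f = f·2√(2 ln 2)/(3·2π) on the positive-frequency axis — which avoids
truncating the (3 s long) low-frequency wavelets against the 1 s epoch.
Power is stored float32 and cropped to the 600 ms window.

Classifier images are log10 power with an epsilon floor of 1e-12 × max,
Gaussian-smoothed (σ = 1 frequency bin × 2 time samples), cropped to the
central 200 ms, min-max scaled to [0,1] and resampled to the configured
raster (224×224 by default; 64×64 in the training corpora for speed).

## Sequential classification

Four binary flags in fixed order — artifact, spike, ripple, fast ripple —
map onto 9 categories; a positive artifact decision finalizes the label and
an all-negative combination is "other" (treated as artifact downstream).
qHFOs are non-artifact, non-other candidates carrying an R or FR flag: a
pure spike is an interictal discharge, not an oscillation, so it does not
enter HFO rates (the literal reading, qHFO = anything non-artifact, is
available via a switch).

### Reference classifier

The deterministic backend encodes how a trained reader interprets
time-frequency maps. All scores are log10-power contrasts ("decades")
against the per-row temporal median of the 600 ms window — a reference
that is robust to the centered event and much stabler than the window
edges. Rules and calibrated defaults (fixed once against simulated
development corpora):

* **ripple / fast ripple** — an isolated peak of the per-row peak-activation
  profile inside 80–250 / 250–500 Hz with height > 1.6 and prominence
  > 0.5: the band-limited "blob" that distinguishes a true oscillation.
* **spike** — band-averaged 12–40 Hz log power in a ±30 ms window around
  the apex more than 0.18 decades above its median: the low-frequency
  ridge. Averaging across rows *before* the temporal reduction is what
  makes this weak signature detectable.
* **artifact** — either an EMG-like burst (300–500 Hz activation above 0.5
  decades sustained > 80 ms — several times any HFO blob's duration) or a
  sharp transient (broadband column: > 1.2 decades above 300 Hz, > 80 % of
  the 100–490 Hz rows peaking within ±12 ms of the event center, mean
  center-column contrast > 1 decade, and high-band width < 40 ms).

### Trainable classifier

A compact transfer-learning-style image classifier in plain numpy: a
seeded random 16-filter 5×5 convolutional bank (ReLU, stride 2, 4×4 average
pooling) plus global row/column average-pooling profiles on the
per-image-standardized raster, feeding a logistic head trained with SGD
(momentum 0.9, minibatch 32, cross-entropy, learning rate 1e-4, ≤ 3
epochs). Features are standardized and scaled by a constant (30) that sets
the effective step size of that fixed schedule. Deterministic given the
seed; training/validation split is stratified and seeded (default 80/20).

## Synthetic benchmark

The simulator emulates the published simulated-HFO dataset's *structure*,
not its waveforms: per channel, 2 min at 2048 Hz with 42 events — 6 of each
of 7 types — at uniformly drawn times with ≥ 500 ms spacing (so the 100 ms
scoring windows can never overlap, keeping the TP/FP/FN partition
unambiguous).

* **Background**: pink (1/f-power) noise, flattened below 1 Hz, RMS 50 µV —
  the standard surrogate for interictal intracranial EEG.
* **Ripples / fast ripples**: Gaussian-windowed sinusoids, 80–250 Hz ×
  30–100 ms and 250–500 Hz × 10–30 ms, with a duration floor of 4 cycles
  (the field's working definition of an HFO).
* **Spikes**: biphasic transients of total width 30–70 ms with a sharp
  exponential apex and an opposing slow Gaussian lobe — the morphology that
  gives real epileptiform spikes their broadband time-frequency ridge —
  scaled to a fixed visibility of 3× the background SD (spikes are not
  HFOs, so they carry no SNR).
* **SNR definition**: each oscillatory component is scaled so that its
  band-limited power over the event span is the requested dB above the
  band-limited background power there, both estimated by periodogram on a
  window widened to ≥ 100 ms (a 10–30 ms span alone is spectrally too
  unstable to define the ratio); the post-hoc check recomputes the same
  estimator and agrees within 1 dB by construction.
* **Artifact classes** (training corpora only): EMG-like broadband noise
  bursts (100–300 ms, 30–500 Hz, 4× background SD) and isolated sharp
  biphasic transients (1–4 ms, 6× background SD).

Everything derives deterministically from one seed via seed fan-out.

### What the benchmark does and does not show

Detection metrics on this emulation reproduce the expected regime — median
per-channel sensitivity near zero at 0 dB, ≈ 50 % at 5 dB and > 90 % at
10–15 dB with precision near 100 % — but the background is stationary
Gaussian 1/f: no sleep–wake cycles, no physiological ripples, no sharp-wave
context, no electrode artifacts beyond the two synthetic classes. Passing
here demonstrates correctness of the algorithmic chain and its scale/SNR
behavior, not clinical performance. Likewise the classifier accuracies
measured on simulated corpora bound what these backends can see in *these*
morphologies; the spike flag in particular sits at its information limit,
because a 3×SD spike against pink background leaves only ≈ 0.9 separability
in the cropped classifier image — real interictal spikes are usually far
more visible. SOZ concordance on toy patients checks the ranking/ROC
machinery, not localization validity.

## Numerical conventions and degenerate inputs

* Epoch SD windows truncated at the clip end are dropped, not padded.
* An all-constant channel yields threshold 0 and no detections (warned).
* Envelope of a signal with < 2 local maxima falls back to |signal|.
* A detection "falls in" a CI iff its peak time lies in the closed window;
  detections at spike-only events are false positives (no CI is defined).
* Prec = 1 and F1 = 0 whenever TP + FP = 0, at every SNR.
* Rate-ranking ties at the top-N cutoff keep stable input (recording)
  order; the ROC is anchored at (0,0) so the trapezoid is defined at N = 0.
* Heatmap cubes are painted around *both* member contacts of a bipolar
  channel (midpoint-only available); overlaps keep the maximum; the
  "[4 4 4] Gaussian" smoothing is read as 4 mm FWHM per axis, and the
  smoothed volume is rescaled so a max-normalized input stays
  max-normalized. Display thresholding exists but defaults to off.
* The scalogram epsilon floor (1e-12 of max) prevents −∞ under log; a
  constant-power scalogram min-max-degenerates to an all-zero image.

## Benchmark problem sizes

The packaged benchmark runs use 48 channels per SNR level (the original
dataset has 240); classifier corpora use 25–50 events per class. These
sizes give medians stable to a few percentage points while keeping a full
run in minutes on one CPU.

## Known limitations

* Electrode localization, brain extraction and tissue segmentation are out
  of scope: masks and contact coordinates are consumed as inputs.
* The trainable classifier is a desk-scale stand-in for large pretrained
  CNNs; with the fixed 3-epoch schedule it tracks, but does not exceed,
  the separability of its input images.
* The 64-order FIR's wide transition band softens sensitivity to ripples
  right at 80 Hz; this is inherent to the specified filter.
* Cohort-level statistics (per-patient AUC tables, group tests) are
  exposed as thin wrappers and demonstrated on synthetic toys only.
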
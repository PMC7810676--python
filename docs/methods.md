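# Methods

`wingbeat` implements an end-to-end analysis for classifying flying (and
jumping) insects from the signals of a four-channel near-infrared optical
sensor: event segmentation from continuous backscatter time series,
spectral and scalar featurization, three one-vs-all classification
methods, and a bootstrapped evaluation design.  Because no public
recordings of this kind exist, the package ships a first-class synthetic
signal generator that defines the study conditions under which the
pipeline is exercised and tested.

## Signal model

An insect transiting a collimated laser beam produces, on each detector
channel, an amplitude-modulated oscillation:

    x_c(t) = g_c · A(t) · [ √β · b(t) + √(1−β) · Σ_{k=1..K} r^{k−1} cos(2π k f₀ t + φ_k) ] + ε_c(t)

* `A(t)` — transit envelope, Gaussian with σ = T/6 for an event of
  duration `T` (a smooth passage through the beam waist).
* `f₀` — the individual's wingbeat frequency (WBF), drawn per event from
  the species' normal distribution `N(f0_mean, f0_sd²)`.
* `r` — harmonic decay: the amplitude ratio between successive wingbeat
  harmonics (K = 4 by default).
* `b(t)` — slow "body reflection" term (the envelope itself, <30 Hz),
  carrying fraction `β` (`body_fraction`) of the signal energy.
* `g_c` — per-channel gains encoding the de-/co-polarized amplitude
  ratio at each wavelength (`depol_ratio`) and the λ1/λ2 ratio
  (`wavelength_ratio`); channel order is (co-λ1, de-λ1, co-λ2, de-λ2).
* `ε_c(t)` — white Gaussian sensor noise low-passed at the 5 kHz
  analog bandwidth and rescaled to the requested standard deviation.

Jumper species (flea beetles) replace the harmonic sum with an
envelope-shaped broadband transient (low-passed white noise), so their
spectra show no WBF peak — only the slow body term and a noise-like
band.

Between-individual variation: besides the WBF spread, the decay, body
fraction and channel ratios of each generated event are jittered
log-normally with coefficient of variation `individual_cv` (default
0.15).  Without this, the channel-ratio features would be noise-free
species fingerprints and any feature-based classifier would be trivially
perfect; 0.15 gives partially overlapping feature distributions, which
is the regime the classifiers are meant to discriminate in.  Set
`individual_cv = 0` to obtain events at exactly the nominal species
parameters (used by the recovery tests).

### The default nine-species library

`default_species_library()` returns nine profiles loosely modelled on an
oilseed-rape insect community: slow, strongly harmonic heavy flyers
(pollen beetle ~95 Hz, sawfly ~65 Hz), intermediate flyers (seed weevil
~140 Hz, parasitoid wasp ~210 Hz), fast midges (pod midge ~320 Hz), a
deliberately overlapping sciarid midge pair (~430 vs ~455 Hz with
45 Hz spreads, separable mainly by harmonic decay and polarization), and
two jumpers with no periodic component.  Mean event durations average
85.6 ms across the library.  **All parameter values are invented,
plausible defaults of this simulator — they are not measurements of the
real species.**  Default acquisition: 20 kHz sampling, 5 kHz bandwidth,
wavelengths 808 and 980 nm; events are generated at peak SNR 30 against
unit-variance noise.

Continuous recordings place events at Poisson times, rejecting
placements within 100 ms of another event or the recording edge, so a
dilated detection cannot merge two true events.

## Event detection

The per-sample SNR is `max_c |x_c − median_c| / σ_c` with `σ_c` the
scaled median absolute deviation of the whole channel (events are
sparse, so global robust statistics track the noise floor; channels
with zero spread are excluded).  The supra-threshold mask (threshold
10) is binary-eroded with a flat structuring element of ⌈0.25 ms·fs⌉
samples (rounded up to odd), deleting any run shorter than 0.25 ms, and
the survivors are dilated by 40 ms in total — 20 ms per side — to
recover the faint start and end of each transit.  We read "dilated by
40 ms" as the total widening under standard symmetric-structuring-element
morphology semantics; an option (`dilation_per_side=True`) gives the
alternative reading of 40 ms per side.  Runs that merge after dilation
become one event; runs touching either recording edge are discarded as
truncated transits.

`frequency_resolution` returns `1/duration`: 85.6 ms → 11.7 Hz.  (For a
40 ms window this is 25 Hz, which is what the implementation returns.)

## Spectral processing

Per channel: subtract the mean (the body/baseline term otherwise
dominates bin 0 and leaks), zero-pad to 20,000 samples — 1 s at 20 kHz,
i.e. exactly 1 Hz bin spacing — and take the DFT magnitude (magnitude,
not squared magnitude).  Events longer than 1 s are centre-truncated,
preserving the transit peak.  No window taper is applied.  Padding
refines the bin grid but not the physical resolution, which remains
1/duration.

The classifier input resamples the 1000 sub-kHz bins of each channel to
512 points by linear interpolation (block averaging is available as
`method="bin_mean"`) and concatenates the four channels in fixed order
into a 2048-vector, which is L2-normalized to remove the
range/size amplitude confound (amplitude information survives only in
the relative channel levels).

Group-average spectra are the across-event pointwise mean of the
channel-averaged magnitudes with the 25th–75th percentile band.

## Features

The canonical 12-feature set (order fixed, see
`wingbeat.features.FEATURE_NAMES`): the raw dominant frequency in
30–1000 Hz taken as the WBF (deliberately uncorrected, so a dominant
second harmonic yields 2f₀ — a failure mode the classifier can learn
around), amplitudes at 1–3× that frequency searched within ±1/duration,
their ratios to the fundamental, spectral centroid, duration, total
energy, the band-integrated (30–1000 Hz, excluding DC/body leakage)
de-/co-polarized ratios per wavelength, and the λ1/λ2 band ratio.
Degenerate values (harmonic beyond 1 kHz, zero denominators) are encoded
as 0 and flagged.  Extraction is total: every detected event yields a
feature vector.

## Classification

All three methods are one-vs-all binary classifiers with decision
threshold 0.5 (the training design is nearly balanced, 333 vs 336):

* **wbf** — the single WBF scalar fed to the same Random Forest
  machinery as the features method, so the comparison isolates the
  representation rather than the learner; a univariate Gaussian
  class-conditional classifier is available via
  `ForestConfig(wbf_mode="gaussian")`.
* **features** — the 12-feature vector in a Random Forest (500 trees,
  √p feature subsampling, unlimited depth, seeded).
* **nn** — the 2048-vector in a three-hidden-layer ReLU network,
  2000/1500/1000 nodes, one sigmoid output, trained with cross-entropy,
  Adam (lr 10⁻³), batch 32, 30 epochs, and inverted dropout 0.5 on the
  last hidden layer only; no early stopping.  The network is
  implemented in numpy (`wingbeat._mlp`) for exact seeded determinism;
  inference applies no dropout, so predictions are deterministic.

Experiment grids in the tests and the acceptance script train a scaled
network (layers 200/150/100, 15 epochs) — the architecture's form and
training rules are unchanged, only the layer widths and epochs are
reduced; the reference 2000/1500/1000 chain is verified structurally.

## Evaluation design

Per target species and fold: 333 training events from the target + 42
from each of the 8 other species (669), tested on 50 held-out events
per species (450).  Accuracy is (TP + TN)/N, reported on the full
450-event set and pairwise on each 100-event target-vs-one-other
subset.  The grid is 9 targets × 3 methods × F folds (the reference
F=100 gives 2700 training and 21,600 pairwise test sessions).  Fold
seeds derive from SHA-256 of (master seed, target, method, fold), so
any cell is reproducible in isolation.

Strict mode draws train and test disjointly (needs ≥383 events per
species); lenient mode samples the test set from the full pool with a
logged warning, accommodating pools between the design counts and 383.
Fold spread is summarised by the 90% bootstrapping interval, the
5th–95th percentile under the linear-interpolation convention; the
"hardest other" species per (target, method) minimises the mean
pairwise accuracy, ties broken lexicographically.  No p-values are
computed for method comparisons; methods are compared by per-pair win
counts over the 72 (target, other) cells and by interval overlap.

## Problem sizes and numerical choices

* Default synthetic study: 9 species × 500 events (4500 events; the
  strict 333/42/50 design needs ≥383 per species).  Tests and the
  acceptance script run the grid at 20 folds (method comparison) and
  2 folds (session accounting); the 100-fold reference design is the
  package default in `RunConfig`.
* MAD→σ scale 1.4826 (Gaussian consistency).
* Percentiles: numpy `method="linear"` everywhere.
* Erosion element width rounded up to odd for symmetry; half-open
  0-based sample intervals throughout.
* All generators and trainers are pure functions of their seeds;
  float32 arithmetic inside the network, float64 elsewhere.

## What passing tests do and do not show

The generator emulates harmonic structure, channel ratios, durations,
jumper transients and sensor noise — not optics (beam profile, range
dependence, detector physics), not within-event WBF modulation, not
multi-insect windows, and not the real species' absolute spectra.
Passing recovery and ordering tests therefore validates the pipeline's
correctness and its qualitative behaviour (frequency-only
classification is weakest; the spectral network and feature ensemble
are comparable and much stronger), not field-level accuracy on real
insects.  On these synthetic conditions the features and nn methods are
near-parity — the synthetic feature set summarises the generative model
almost losslessly, which real hand-crafted features would not.
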
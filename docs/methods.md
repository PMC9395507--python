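# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `eegclean`. Defaults quoted here are the package's
shipped values; all are configurable through `PipelineConfig`.

## Pipeline model

The package assumes continuous, task-free multichannel EEG in microvolts.
Stages are pure functions `Recording -> Recording`; each appends one
history entry, and the batch runner saves the intermediate after every
stage, so any step can be audited. A recording without electrode positions
can still be filtered, line-noise corrected, wavelet corrected and
segmented; bad-channel detection, interpolation and re-referencing require
a montage.

## Preliminary filtering

A zero-phase Hamming-windowed sinc FIR band-pass, 1–100 Hz by default
(low-pass-only in the ERP hand-off mode, which leaves slow potentials for a
downstream ERP-specific pipeline). The quoted cutoff is the half-amplitude
point. Transition widths are 1 Hz at the low edge and 5 Hz at the high
edge: the low edge must be sharp to protect delta-band signal adjacent to
the 1 Hz cutoff, while a generous high-edge width keeps the kernel around
800 taps at 250 Hz. Kernels are odd-length (type-I linear phase) applied in
one pass with group-delay compensation — exactly zero phase. Edges are
reflect-padded by one kernel length, which suppresses onset transients in
short files.

## Line-noise removal

Mains noise is modelled as a deterministic sinusoid of slowly varying
amplitude. In 4 s windows stepped by 1 s, the frequency grid spanning the
target ±2 Hz is scanned with DPSS multitaper eigencoefficients
(time-half-bandwidth set so the analysis bandwidth is ≈ 2 Hz, 7 tapers at
the defaults); at each grid point Thomson's complex amplitude estimate and
F statistic are computed, and the peak-F frequency is taken. Windows are
gated at p = 0.01 (F with 2 and 2K−2 df).

Two numerical choices matter:

* **Cross-window amplitude smoothing.** Each window's complex amplitude is
  re-expressed at a common reference frequency (the amplitude-weighted mean
  of the per-window peaks) in the absolute time frame, then smoothed across
  windows with an exponential kernel of width `smoothing_tau` (default 100
  window steps). The mains tone is phase-coherent between windows and
  survives the average; the recording's own energy at that frequency is
  incoherent and averages out. Without this, subtraction removes the
  genuine background at the line frequency too (we measured the post-removal
  60 Hz floor ~8 dB *below* the artifact-free floor without smoothing,
  within 1 dB with it).
* **Collective significance.** Once smoothing is on, a window is corrected
  whenever the smoothed amplitude has support in its kernel neighbourhood,
  not only when its own F-test passes; otherwise low-SNR channels leave the
  tone untouched in scattered chunks. The `legacy` mode disables both the
  smoothing and the collective gate, reproducing the older chunk-wise
  behaviour, and is retained as a comparison option.

The QC metric band-passes pre and post data ±1 Hz around the line frequency
and at ±1, ±2, ±5 Hz neighbours (zero-phase Butterworth) and reports
channel-averaged Pearson r. One second at each end is discarded before
correlating: the narrowband filter rings at the recording edges, and that
ringing differs between a recording with and without a strong tone, which
would otherwise dominate the statistic.

## Bad-channel detection

Criteria run in order; flat channels are excluded from the later criteria's
statistics so a dead channel cannot mask a noisy one.

* **Flatline**: successive-difference < 1e−8 µV counts as flat; a run of
  ≥ 5 s flags the channel.
* **Line-noise ratio**: noisiness = MAD(x − lowpass(x)) / MAD(lowpass(x)),
  split at 45 Hz. The cross-channel z-score uses robust centre and scale
  (median, 1.4826·MAD). This is deliberate: with a plain mean/std z-score,
  two comparably noisy channels among twelve mathematically cannot both
  exceed 2.5 SD (each inflates the std the other is measured against), so
  multiple bad channels would mask each other. Threshold 2.5.
* **Channel correlation**: in 5 s windows, a channel whose best absolute
  correlation with any other channel is below 0.7 is bad-in-window; bad in
  > 40% of windows flags it. A channel with zero variance in a window
  counts as bad there.
* **Spectrum outliers**: mean log10 Welch PSD (2 s segments, 50% overlap)
  over 1–100 Hz, z-scored across channels with mean/std, |z| > 2.75. This
  realises the "joint probability of average log power" semantics as a
  closed-form outlier test; it is an approximation of that construction
  and is applied once, not iterated.
* **Legacy method** (single criterion, comparison only): two iterations of
  3-SD outlier removal on mean log power 1–125 Hz, the second iteration
  recomputing statistics on the survivors.

Robust z-criteria at low channel counts are conservative in the
false-positive direction: when one channel is extremely deviant, the MAD of
the remainder is small and a second, mildly unusual channel can cross
threshold. The per-criterion report makes such flags auditable.

## Wavelet artifact correction

* **Transform**: stationary (undecimated) wavelet transform, coif4, depth
  10, reflect-padded to a multiple of 2^level and truncated after
  inversion. The depth is auto-capped when 2^level would exceed the signal
  length (logged in the stage history). Unnormalised à trous filters are
  used, so each level's coefficients of white noise have approximately the
  generating σ; the per-level cascade gain of coif4 deviates from unity by
  up to ~20% at mid levels, which is irrelevant in level-dependent mode
  (σ_l is estimated empirically per level) and documented for users of the
  level-independent mode.
* **Threshold**: per level, σ_l = MAD/0.6745 and the Johnstone–Silverman
  empirical-Bayes construction — spike-and-slab prior with Laplace slab
  (a = 0.5), weight by bounded marginal-ML, threshold at the
  posterior-median zero-crossing found by bisection. Exact numerical
  equality with any particular reference toolbox is not claimed; the
  construction is validated by its behavioural properties (weight near 0 on
  pure noise with threshold near universal; weight rising and threshold
  falling as sparse outliers are added).
* **Rules**: hard (default) assigns coefficients with |d| ≥ t to the
  artifact; soft assigns sign(d)·max(|d|−t, 0); median assigns the
  posterior-median shrinkage. The artifact decomposition always includes
  the approximation band, so content below the deepest detail band
  (≈ 0.12 Hz at 250 Hz, depth 10) is removed from the cleaned signal —
  harmless after the 1 Hz high-pass, and noted in the stage history.
* **Semantics**: the artifact (large-coefficient reconstruction) is
  subtracted; `clean + artifact == input` holds exactly because clean is
  computed by subtraction. Correction is strictly per channel, hence
  bitwise identical across channel subsets and orderings.
* **Locality**: on a clean channel plus one injected 500 µV transient, the
  correction is concentrated at the transient (peak reduced > 80%); far
  from it the median change is below 1 µV, but isolated samples can move by
  a visible fraction of the signal amplitude, because supra-threshold tail
  coefficients of the genuine signal are occasionally captured. This is
  inherent to hard thresholding, not a defect of the implementation.
* **Level-independent mode** reuses the finest level's σ and threshold at
  every level. Since deep-level EEG coefficients are far larger than
  fine-level noise, nearly everything crosses threshold and the "clean"
  output loses most low-frequency signal — the recovery harness shows its
  1–35 Hz log-PSD error an order of magnitude above the level-dependent
  mode. It is kept as the comparison arm, default off, as are the
  universal, minimax and SURE threshold selectors.

## Segmentation and rejection

Fixed-length segments (default 2 s), overlap as a start-grid advance of
`len·(1−overlap)`, trailing remainder dropped. Rejection criteria:

* **Amplitude**: any retained channel outside [−150, 150] µV flags the
  segment; an optional mode requires a designated channel group (e.g. both
  frontal electrodes, the blink rule) to breach.
* **Joint probability**: per channel, the empirical amplitude density is a
  1000-bin histogram over the pooled segments with Laplace smoothing; each
  segment's score is the mean −log p of its samples. A segment is rejected
  when any channel's score, or the channel-averaged score, is more than 2
  SD from the mean across segments (one threshold for both, since a single
  value is specified); a single pass, no iteration after removals. Needs
  ≥ 10 segments, else skipped with a warning.
* **Both**: the union of the two criteria.

Overlapping segments are independent units; rejection does not reconcile
shared samples (standard epoch-based practice). The optional within-segment
repair computes four per-channel metrics per segment — variance, median
absolute successive difference, amplitude range, and |segment mean − channel
grand mean| — z-scores them across channels, and spherical-spline
interpolates channels with any |z| > 3 from the segment's remaining
channels; segments with more than half their channels flagged are left
unmodified and noted. Note the grand-mean deviation metric couples segments
through the channel mean: a large one-sided excursion in one segment shifts
that channel's grand mean and can flag the channel elsewhere.

## Interpolation and re-referencing

Spherical splines use the Legendre kernel of order 7 with stiffness m = 4
and ridge regularisation 1e−5 on the good-electrode system (the order is
the shipped default; stiffness and ridge are this package's choices to keep
the 12-electrode system well-conditioned). Interpolation requires ≥ 4 good
channels and runs whenever bad-channel detection ran, so analyses can
exclude interpolated channels using the report.

REST re-references to an approximate point at infinity: a three-concentric-
sphere head model (relative radii 0.87/0.92/1.0; conductivities 1 :
0.0125 : 1 brain:skull:scalp) with ~3000 radial dipoles on a Fibonacci
shell at 0.7 of the brain radius. Shell coefficients are solved per
spherical-harmonic degree (60 degrees) from the boundary conditions as a
5×5 linear system; the REST estimator is `G · pinv(G_avg) · V_avg` on
average-referenced data, which makes the output independent of the input's
original reference by construction. All head-model constants are
configurable; they are conventional values, not fitted.

## Synthetic data

The generator emulates the validation substrate used for wavelet-parameter
evaluation: four band-limited Gaussian sources (1.00–3.91, 3.91–7.81,
7.81–15.62, 15.62–31.25 Hz) with distinct spatial patterns, plus white
sensor noise. Package choices where the substrate is not further
specified: fs = 250 Hz, 120 s, 12 channels on the F3/F4/Fz/C3/C4/P3/P4/Pz/
O1/O2/T7/T8 layout, source scale 10 µV, background noise 1 µV — yielding
channel RMS around 15–25 µV, a realistic scalp amplitude. Spatial patterns
are random first-order functions of electrode position (baseline plus
linear term), so loadings vary smoothly over the scalp the way volume
conduction smears real sources; without this, weakly loaded channels are
genuinely uncorrelated with their neighbours and the correlation criterion
flags clean channels.

Artifact injection returns the exact added matrix: blinks are biphasic
difference-of-Gaussians pulses (~0.3 s, default 100–200 µV peak, weight
1.0 on F3/F4 and 0.2 elsewhere — a parametric stand-in for a real blink
component), EMG bursts are 20–45 Hz enveloped noise, plus line sinusoids,
flat/noisy channel faults, and replay of user-supplied component
timeseries through given weights.

The correction-vs-rejection harness applies 1 Hz high-pass and 35 Hz
low-pass, 2 s epochs with 50% overlap, a ±100 µV threshold and the
both-frontal-electrodes blink rule, and compares epochs retained by
rejection alone versus wavelet correction followed by rejection.

**What passing these tests shows — and does not.** The sources are
stationary Gaussian, mixed instantaneously, with no 1/f background,
no non-stationary rhythms and no volume-conduction forward model. Results
on this substrate demonstrate algorithmic correctness under known ground
truth (recovery ordering, specificity, retention contrast); they do not
by themselves quantify performance on any particular recording system or
population.

## Problem sizes

The shipped tests and the acceptance script use 20–120 s recordings at
250 Hz with 12 channels, 10 seeds for the recovery ordering, and ~360
randomized instances for the detector-vs-brute-force equivalences — sizes
chosen so the whole suite completes in a few minutes on one core while
every statistic is still well away from its decision boundary.

## Known limitations

* EDF files are read (via mne) but not written; outputs are delimited text
  or the JSON native container.
* The spectrum "joint probability" criterion is realised as a cross-channel
  z-score of mean log power — the semantics, not a reimplementation of any
  specific toolbox's internals.
* Hard thresholding occasionally captures genuine-signal tail coefficients
  (see Locality above); the soft and median rules trade that for residual
  artifact.
* z-score criteria (bad channels, joint probability) assume enough
  channels/segments for the reference distribution; below ~4 channels or
  10 segments the criteria are skipped with warnings.
* REST uses an idealised spherical head; no realistic BEM/FEM geometry.
* Event-locked (ERP) epoching, baseline correction and ICA-based
  comparisons are out of scope.
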
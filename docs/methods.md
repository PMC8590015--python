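# Methods

## Scope and data model

The package quantifies macropinosome formation and maturation from
multi-channel 2D time-lapse movies (TIFF, T×C×Y×X, with pixel size in µm
and frame interval in s) or from pre-extracted per-track intensity tables
(CSV). All stages share one track schema — `track_id, frame, t_s, x_px,
y_px, area_um2, ch_<name>_mean` — so simulated and real data flow through
identical code. Frame indices are 0-based, time is `frame ×
frame_interval_s`, and coordinates are (x, y) in pixels with the origin at
the top-left pixel center.

## Synthetic data: what is emulated

No public imaging dataset accompanies the biology this package targets,
so the simulators are first-class, tested code; every generator returns a
`GroundTruth` record (event frames, fates, kinetic parameters, seed) and
is bit-reproducible for a fixed (parameters, seed) pair.

**Kinetic template.** Each vesicle is born (sealed) at a frame drawn so
the full kinetic program fits inside the movie, then shows:

1. a **first-phase pulse** on the anchor channel — a raised cosine
   $\tfrac{A}{2}(1 + \cos(\pi\tau/W))$ whose full width at half maximum
   $W$ is `first_phase_duration_s` (default 40 s). A smooth pulse with an
   analytically known above-half-maximum duration makes lifetime recovery
   testable; the true peak is placed midway between two frame samples so
   that sampling straddles it symmetrically (at 40 s FWHM and 5 s frames
   the sampled pulse spends exactly 8 frames above half-maximum, and the
   two straddling samples tie, resolved to the earlier frame everywhere);
2. for vesicles with fate *success* (Bernoulli, `success_prob`, default
   0.4), a **second phase**: a logistic rise (time constant
   `second_phase_rise_s`, 30 s) to a plateau beginning `gap_s` (60 s)
   after the pulse ends, emitted on both the anchor and the
   endosomal-marker channel, truncated to exactly zero before its onset
   so the first phase is strictly the only pre-onset signal;
3. **companion channels** (APPL1/RAB5-like) as raised-cosine pulses whose
   peaks are offset from the anchor peak by `marker_offsets_s` (defaults
   20 s and 60 s), emitted on success tracks only;
4. for fate *collapse*: track termination `collapse_delay_s` (30 s) after
   the pulse ends, with the area decaying as the vesicle recedes, and no
   endosomal-marker gain.

Track-level noise is additive Gaussian (`noise_sd`); first-frame areas
come from a log-normal radius (default µ = ln 0.8 µm, σ = 0.25, i.e. a
median area of ≈ 2 µm², comfortably above the 0.64 µm² analysis floor with
a small sub-threshold tail). Tracks start `pre_frames` (5) baseline frames
before the pulse so baseline statistics are estimable. Births are
restricted so that the pulse, the gap, and the phase-2 rise to its
midpoint all fall inside the movie: without this, late-born successful
vesicles would be censored by the acquisition window and fate-rate
recovery would be biased.

**Rendering.** `render_movie` draws each vesicle as a uniform disk whose
total expected photon count is `intensity × poisson_gain`, blurs it with
a Gaussian PSF (sum-preserving), applies Poisson shot noise to the photon
image, then adds a constant camera background and Gaussian read noise.
Noise-free renders return the expectation image, so photon-sum
conservation (`Σ(pixels − background) = intensity × gain`) is exact up to
floating point. The light-sheet pixel-size preset is 0.091 µm (91 nm).

**Scission traces.** The quench reporter follows the external buffer
square wave (half-period 5 s) until the true sealing frame, after which
it holds the bright level (the sealed lumen no longer follows the
buffer); `polarity="quench-high"` mirrors the alternation (EGTA/Ca²⁺
mode). The recruitment channel rises logistically with its half-maximum
exactly `recruit_lag_s` after sealing, so lag recovery is well-defined.

**What the simulators do not emulate** — and hence what passing tests do
not show about real data: membrane-ruffle morphology and real image
texture, vesicle–vesicle crowding and fusion, bleaching, focus drift, 3D
geometry, and any quantitative rate constants for the underlying biology
(none are published; the kinetic shapes are stand-ins constrained only by
the printed durations, orderings and proportions: 5 s frames, ~40 s first
phase, ~40% vs ~20% success).

## Detection and tracking

Detection normalizes each frame to robust-noise units (1.4826 × MAD),
finds multi-scale Laplacian-of-Gaussian maxima (scales bracketing
`blob_scale_um`, permissive LoG threshold), and accepts blobs whose
lightly smoothed amplitude exceeds `detection_threshold` (default 4)
noise units. Each accepted blob's area is the Otsu-thresholded connected
region in a local window, converted with `pixel_size_um²`; the centroid is
background-subtracted intensity-weighted. A constant image has zero
robust noise and yields no detections by definition.

Linking is greedy: candidate (track, detection) pairs within
`max_displacement_um` per elapsed frame are accepted in order of
increasing distance (ties toward the lower track id — deterministic);
tracks unmatched for more than `max_gap_frames` (2) frames close;
unmatched detections seed new tracks. On well-separated instances (≤ 5
objects, steps small against separations) greedy assignment coincides
with exhaustive minimum-total-distance matching, which the tests verify
by enumeration. The macropinosome selection filters are: first-appearance area
≥ 0.64 µm² for the size analysis (the boundary value is kept — the filter
removes vesicles *below* 0.64 µm²), and equivalent diameter
$2\sqrt{A/\pi} > 1$ µm with birth inside `formation_window_s` (1200 s)
for formation counts.

## Recruitment profiles

The ROI is the set of pixels whose centers lie within
`roi_diameter_px / 2` (default radius 5 px) of the tracked point;
off-frame pixels are excluded and flagged. Alignment finds each track's
anchor maximum within its first `search_window_frames` (15) frames — ties
to the earliest frame — and shifts it to t = 0; the window is counted from
track birth. Normalization is per track and channel: min–max between the
(1, 99) percentiles, clipped to [0, 1]; constant series map to zero and
are flagged; a baseline-relative mode is available behind
`normalization="baseline"`. Ensemble statistics are the per-timepoint mean
and Student-t 95% CI (df = n − 1) over contributing tracks; timepoints
with fewer than `min_tracks_for_ci` (3) tracks carry the mean only.

**First-phase lifetime** is the contiguous time the (box-3 smoothed)
anchor profile stays above baseline + ½(peak − baseline), with the two
crossings linearly interpolated between samples; the baseline is the
median of the first `baseline_frames` (5) samples. The short box average
suppresses single-sample noise dips that would otherwise truncate the
above-threshold run (a ~7 s downward bias at SNR 5); it leaves flat-top
pulses exact and moves half-maximum crossings on locally linear flanks
only through peak attenuation (≲ 3% on a triangular pulse, under one
frame on the raised cosine). The estimator is invariant under adding a
constant or scaling by a positive factor. Profiles that never cross, or
that start/end above threshold, return NaN with a flag rather than a
truncated number.

**Marker timing** reports, per channel of an aligned ensemble, the onset
(first time the ensemble mean exceeds baseline + ½ its own dynamic range)
and peak (argmax of the mean), both relative to the anchor peak. On
mixed-fate ensembles the late mean is subject to composition effects
(collapsed tracks drop out), so offset-recovery tests use success-only
ensembles; the onset ordering (anchor → APPL1-like → RAB5-like/phase 2)
is robust to composition.

## Scission assay

Sealing is detected from the quench channel in two steps. *Gate*: frames
are classified into buffer phases by the square wave (phase and sign
registered from the trace itself by maximizing the early demodulated
amplitude); sliding two-period windows give signed amplitudes
mean(phase A) − mean(phase B); the reference amplitude is the median over
the first four periods, and sealing is called if `confirm_windows` (2)
consecutive windows drop below `amplitude_drop_fraction` (0.25) × the
reference. A trace whose reference amplitude is indistinguishable from
zero is flagged `pre_sealed` with sealing at frame 0; a trace that never
drops is flagged `no_sealing`. *Refinement*: because adjacent windows
share most of their frames, window-level rules can be displaced a full
period by one noisy frame, so the reported time is the least-squares
change point of the trace itself against the model "square wave before
sealing, constant after" (levels estimated from the phase-wise medians),
searched within ±4 periods of the gate call. At SNR 5 this places ≥ 99%
of calls within one perfusion period of the truth; the call is
amplitude-based and therefore invariant to mirroring the trace
(pH vs EGTA/Ca²⁺ polarity). The original study determined sealing
manually; this rule is the package's declared automated surrogate, and
its agreement with any manual call cannot be checked without raw traces.

Sealing-aligned ensembles re-index the recruitment channel to t = 0 at
each trace's sealing frame and reuse the Student-t CI machinery; traces
without a sealing call are excluded and counted.

## Population statistics

Fate classification: *success* requires the endosomal marker to exceed
baseline + 3 robust SD (both estimated from the first 5 frames) for ≥ 3
consecutive frames, on a vesicle whose first-frame equivalent diameter
exceeds 1 µm; tracks that end early without the event are *collapses*;
tracks alive at the movie end are *censored* and excluded from the rate
successes / (successes + collapses).

The two-sided Fisher exact test uses the probability-mass criterion — the
sum of hypergeometric probabilities of all same-margin tables no more
probable than the observed one — computed in exact rational arithmetic
(`Fraction`), so ties are handled without floating-point fudge factors;
degenerate margins return p = 1. scipy's implementation serves as an
independent cross-check in the tests, never as the implementation.
Two-group comparisons use the pooled-variance Student t-test (not Welch,
matching the stated analysis convention); more than two groups use
one-way ANOVA with Tukey HSD via the studentized-range distribution.
Hierarchical data are aggregated track → cell → experiment before
testing: per-experiment means when every group has ≥ 3 experiments,
otherwise per-cell means, and the unit actually tested is recorded in the
result. Identical constant groups return statistic 0, p = 1; constant but
unequal groups are an error (undefined t).

The liposome coincidence-enhancement ratio is
bound(both lipids) / max(single-lipid bound fractions) — the
max-denominator convention, flagged here because the alternative
(sum-denominator) is not distinguishable from the published phrasing;
band intensities enter as numbers (densitometry is out of scope).

## Uptake quantification

Inputs are sum-projected 2D endpoint images. The cell mask comes from the
membrane-marker channel (Gaussian smooth, Otsu, fill holes, largest
component) or is supplied directly; masks touching the border or below an
area floor are flagged for manual-mask input rather than silently used.
The background is the mean over a user-provided cell-free ROI (an overlap
with any cell mask is an error), and the integrated intensity is
(mean in-cell − background) × cell area, floored at 0 with a flag when
negative. Dot counting takes 8-connected components above an intensity
threshold (default mean + 4 robust SD of the in-cell background) and
keeps those strictly larger than `min_dot_area_px` (30 px).

## Numerical and design choices

- Percentile computations use linear interpolation (NumPy default);
  normalization of a zero-range series yields zeros plus a flag rather
  than NaN.
- CI half-widths use `t.ppf(0.975, n−1)`; n = 1 yields mean-only output.
- Argmax ties everywhere resolve to the earliest index.
- The simulators draw from `numpy.random.default_rng(seed)` only, so all
  outputs are bit-reproducible; rendered-noise images are reproducible
  including the Poisson sampling.
- Problem sizes in the test-suite and acceptance script (200 tracks for
  lifetime recovery, a 50-vesicle/60-frame movie for detection, 200
  scission traces, 2000/1000 replicates for calibration) were chosen so
  each Monte-Carlo bound has comfortable margin while the whole suite
  runs in well under a minute of compute.

## Known limitations

- The detector assumes blob-like vesicles on a flat background; it is not
  designed for ruffle segmentation, touching vesicles, or textured
  cytoplasm.
- The greedy linker is optimal only on uncrowded scenes; it does not
  model merges/splits (macropinosome fusion enters as a categorical
  outcome, not a tracking event).
- Ensemble means over mixed-fate tracks are composition-weighted at late
  times (shorter tracks drop out); timing recovery is therefore defined
  on fate-homogeneous ensembles.
- The scission rule is an automated surrogate for a manual call; θ and
  the confirmation span are tunable, and the refinement assumes a single
  change point.
- All accuracy statements are properties on synthetic data under the
  stated noise models; they do not certify performance on real movies.
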
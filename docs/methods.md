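# Methods

This note records the models, conventions and numerical choices behind the
package, the defaults and why they were chosen, and what the synthetic data
do and do not establish about real recordings.

## Signal model for ventral-root recordings

Real ventral-root recordings are band-passed extracellular signals; every
analysis here, as in common practice, operates on the **rectified envelope**.
The synthetic generator therefore renders envelopes directly rather than raw
waveforms: each burst is a raised-cosine rise (25% of the burst), a flat
plateau, and a symmetric fall, at the programmed amplitude, with additive
Gaussian noise on top.  This gives well-defined peaks and valleys, smooth
onsets, and exact ground truth for every burst.  Envelopes are synthesized at
1 kHz — ample for rhythms at 0.1–0.5 Hz with ~1 s bursts; raw extracellular
sampling rates (10 kHz) are only needed before rectification, which is out of
scope.

Channel phase offsets are applied to burst **onset times** as cycle-fraction
shifts (not by resampling waveforms), so a 180° offset at 0.2 Hz delays every
onset by 2.5 s.  The default offset map {lL2: 0°, rL2: 180°, lL5: 180°,
rL5: 0°} realizes the alternating gait: left–right alternation on both
segments and ipsilateral flexor–extensor alternation.

The chemogenetic-decline generator treats burst timing as a rate-1 phase
oscillator driven by a piecewise-linear instantaneous rate (baseline →
linear ramp → plateau at `baseline × (1 + %change/100)`); onsets fall where
the integrated rate crosses integers.  The light-epoch generator restarts
the burst lattice at each rate step, so a 0 Hz baseline yields bursts only
inside light windows.

### What the generator does not emulate

No motor-unit structure, no slow amplitude drift, no electrode artifacts, no
burst-to-burst jitter beyond additive envelope noise, no coupling between
channels other than the programmed offsets.  Passing recovery tests on this
data shows the estimators are unbiased and correctly calibrated under the
stated signal model — not that the detector thresholds are optimal for any
particular rig's noise.

## Burst detection and locomotor parameters

Detection uses a fractional-range threshold: bursts are maximal intervals
where the envelope exceeds `floor + threshold_frac × (peak − floor)`
(defaults: threshold_frac 0.3, merge gaps < 0.3 s, drop bursts < 0.2 s,
smoothing window 0.1 s).  These rules are deliberately simple, monotone in
the threshold, and fully logged; they are declared defaults, not values
inferred from any particular dataset.  Two consequences worth knowing:

- The measured **burst duration is the supra-threshold duration**, so the
  recovered duty cycle of a raised-cosine burst train programmed at duty 0.3
  comes out near 0.24.  Frequency, period and phase relationships are
  unaffected; duty comparisons are meaningful within a fixed threshold.
- The **valley** of each burst is the minimum of the preceding inter-burst
  gap (the first burst uses the pre-burst stretch from the window start).

Windows follow the experimental designs: chronic silencing is analyzed in
the 5-min window 25–30 min after drug-induced activity onset; acute
silencing compares the last 4 min before CNO with the last 4 min of CNO
before washout, with 2-min frequency bins over time; optogenetic epochs use
a 20 s pre-light baseline, the light window, and an equally long post-light
window.  Bursts belong to a window if their **onset** lies inside it, which
makes frequency = count/length exact; windows therefore carry up to one
burst of quantization per boundary.  The flexor (L2) root is the analysis
root for every protocol except local lower-lumbar (L5/L6) stimulation, which
is analyzed on the extensor (L5) root.

CVs use the sample (n−1) standard deviation.  The CV of frequency needs
repeated measurements, so it is computed over per-cycle instantaneous
frequencies (reciprocal inter-onset intervals).

## Circular statistics

Phases are extracted per reference cycle `[onset_i, onset_{i+1})` as
`360° × (t_test − onset_i)/(onset_{i+1} − onset_i)`; cycles with zero or
multiple test onsets are skipped and counted, never interpolated.  This
cycle-onset referencing replaces wavelet-coherence phase extraction: for
burst-like signals the two agree in mean angle and r, which are the only
quantities reported downstream.  Angles are degrees in [0, 360) at the API,
radians internally.

The Rayleigh p-value uses `Z = nR̄²` with the approximation
`p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))` — the same formula the
pycircstat family implements — and is cross-checked in the tests against a
100,000-resample uniform null.  When preparation structure exists, Rayleigh
runs on the per-preparation mean angles (optionally weighted by each
preparation's r; unweighted by default, since the weighted reading of the
convention is ambiguous).  The Watson–Williams F uses the standard
concentration correction `K = 1 + 3/(8κ̂)` with κ̂ from Fisher's piecewise
approximation; pooled mean resultant lengths below 0.45 flag the result as
low-concentration rather than suppressing it.  The grand mean is the
unweighted circular mean of preparation means.

## Calcium pipeline

**Field normalization.**  Output geometry is fixed at 400 rows × 500
columns.  Each hemifield is scaled independently — left edge → column 0,
central canal → column boundary 249.5, right edge → column 499; dorsal →
row 0, ventral → row 399 — with bilinear interpolation (implemented as two
separable 1-D linear passes, chunked over frames for memory locality).  A
movie already in canonical geometry maps to itself exactly.

**Grid.**  Each 250 × 400 px hemifield is tiled into 10 columns × 25 rows of
25 × 16 px tiles (any exact 250-tile tiling satisfies the 500-ROI contract;
this one is reproducible and keeps tiles near-isotropic).  IDs 1–250 cover
the right hemifield, 251–500 the left, rastered lateral→medial then
dorsal→ventral.

**ΔF.**  Per ROI, F_t is the footprint-mean intensity, F0 the mean of F_t
over the **last** 100 frames (the stated convention, kept even though a
leading-frames baseline is more common), ΔF = F_t − F0, and all 500 traces
share one divisor: the global maximum ΔF.  A non-positive global maximum
leaves traces unnormalized with a flag.

**Filtering.**  Zero-phase 4th-order Butterworth low-pass, default cutoff
2 Hz (well above locomotor frequencies, well below the 5 Hz Nyquist of
10 frame/s movies), then subtraction of a rolling 10th-percentile baseline
over 20 s and of the residual mean.  The cutoff, window and percentile are
configurable; no specific values are canonical.

**Oscillation index.**  The autocorrelation is normalized so r(0) = 1 and
the lag-k product sum is divided by the number of overlapping samples, so a
long noiseless sinusoid attains ≈ +1 again at one period.  The index is
`r(first side peak) − r(first trough)`, with the side peak sought between
0.5× and 2× the expected locomotor period (taken from the concurrent root
rhythm) and the trough the minimum before that peak.  This peak-minus-trough
reading matches the stated ±1 endpoints (a perfect oscillation scores 2);
ratio or peak-only readings would not.  Index maps are normalized by the
**single** maximum over all 500 ROIs — one divisor for both hemifields, so a
weaker hemifield keeps values below 1.  The reference ROI is the argmax of
the across-preparation averaged map (ties go to the lowest ID, logged).

**Phase maps.**  Each ROI's phase is the lag of its cross-correlation
maximum against the reference ROI, searched within ±half the cycle period,
refined by 3-point parabolic interpolation (sub-sample resolution matters:
one lag sample at 10 frames/s is 0.04 cycles at 0.4 Hz), divided by the
period and mapped to [0, 1).  Positive phase means the ROI lags the
reference; the reference's own phase is exactly 0; flat traces yield NaN,
not 0.  Alternation appears as phase ≈ 0.5 (the cycle-fraction convention
throughout; a 0-to-1 "in-phase to out-of-phase" color scale is a rescaling
of the same quantity).  Against ventral-root burst trains the same machinery
runs with a low-pass-filtered burst-occupancy indicator as the reference;
note that indicator dynamics delay the calcium trace relative to the root by
roughly the indicator decay time (τ = 0.4 s ≈ 0.1 cycle at 0.4 Hz), so
"in-phase" ROIs show a small positive lag while the ipsi/contra separation
stays at 0.5 cycles.

**Synthetic movies.**  Oscillators are rectangles in the dorsolateral
intermediate zone of each hemicord, driven by the same raised-cosine burst
train as the root generator and convolved with a single-exponential
indicator kernel (default τ = 0.4 s, typical of fast indicators), on a
constant background with Gaussian noise.  Landmarks place the central canal
off the geometric midline so normalization genuinely rescales the two
hemifields differently.  Default problem sizes (3-minute movies at
10 frames/s, 200 × 250 raw pixels; 10-minute recordings) keep the full
pipeline's memory footprint around 1.5 GB and its runtime in minutes.

## Table screens

The DE filter consumes a finished DESeq2-style results table; the model fit
itself (Wald tests, outlier handling, independent filtering) is a declared
scope boundary.  Thresholds are inclusive (padj ≤ 0.05, |log2FC| ≥ 0.59,
i.e. 1.5-fold).  "Top-k transcription factors" ranks by descending |log2FC|
with ties broken by ascending padj then gene ID — fold-change ordering is a
declared choice, as is the 0.05 Shapiro gate in the test selector (both
configurable).  For three or more non-Gaussian groups the selector falls
back to Kruskal–Wallis (unpaired) or Friedman (paired); the parametric
branches delegate to pingouin (Welch ANOVA, repeated-measures ANOVA with
Geisser–Greenhouse correction) and scipy (t, Mann–Whitney, Wilcoxon).
Section coordinates normalize each side of the central canal by its own
extent, so the canal maps to (0, 0) and the bounding box to [−1, 1]²; the
inverse map restores pixel coordinates exactly.

## Degenerate inputs and tie-breaks

Flat envelopes detect no bursts (with a warning); zero-event windows report
frequency 0 and *missing* ratio parameters, never 0.  A resultant length
below 1e−12 flags the circular mean as undefined.  All-zero oscillation maps
are returned flagged rather than divided by zero.  Degenerate landmarks
(zero-width hemifield, inverted edges, zero coordinate extents) raise
errors naming the offending quantity.

## Known limitations

- Detector parameters interact with noise level; at noise SD above ~0.3 of
  the burst amplitude the fractional-range threshold starts missing bursts.
- The Watson–Williams correction is unreliable for dispersed samples; the
  low-concentration flag must be honored by callers.
- The oscillation index conflates rhythm strength and regularity by design
  (that is what a peak-to-trough autocorrelation span measures).
- Cross-correlation phases assume a dominant common period; multi-frequency
  activity would need time-resolved methods that are out of scope here.
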
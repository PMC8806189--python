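# Methods

This note documents the models, conventions and numerical choices behind
`gliawave`, in the order data flows through the pipeline.

## Synthetic recordings

The generator emulates a two-photon recording of GCaMP6f-expressing Müller
glia in a developing retinal whole mount, imaged in an IPL optical section
while a nearby ganglion cell is held in voltage clamp.

**Field layout.** Stalks are bright discs (default diameter 2.5 µm, the
middle of the 2–3 µm range seen in average-intensity projections) placed on
a hexagonal grid with uniform jitter up to 25% of the grid spacing —
"semiregular" spacing. Placement fails loudly if the requested stalk count
cannot fit at ≥1.5 diameters spacing. The space between stalks carries
diffuse lateral-process signal at lower baseline intensity (defaults 1000
vs. 300 a.u.), which is what makes stalks segmentable. The interstitial
space is partitioned into process *units* (10 µm tiles): the granularity at
which lateral-process participation is drawn. Units are deliberately larger
than the 2.5 µm analysis squares so that a random square usually samples a
single unit; a square near a unit boundary sees a mixture, which slightly
dilutes its transient (see *Limitations*).

**Waves and participation.** Waves are field-wide point events. Inter-wave
intervals are uniform within ±30% of the mean interval (default rate
1.5 min⁻¹, i.e. ~40 s IWI, the realistic developmental range). For each
wave, each stalk and each process unit independently participates with its
compartment's probability (defaults 0.5 stalk, 0.9 process). Participating
units receive one calcium transient; stalk transients peak
`latency_offset_s` (default 0.5 s) after the wave, process transients at
the wave time. Spontaneous transients are homogeneous Poisson per unit
(default 0.005 Hz); their amplitude is a free parameter (`spont_amp`, default
1.0) since no empirical distribution is asserted for them.

**Transient kernel.** A difference of exponentials
`k(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)` (defaults τ_rise 0.5 s,
τ_decay 2.0 s, a GCaMP6f-like glial time course), normalized to unit peak so
the configured amplitude *is* the true peak ΔF/F, and the analytic peak time
`t* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)` makes true peak times exact. Pixel
intensity is `baseline × (1 + ΔF/F_true)`.

**Noise.** Gaussian read noise (SD `noise_sigma`, default 10 a.u.) plus a
signal-dependent term with variance `photon_scale × signal` (default 0.5),
approximating two-photon shot statistics. Both switch off exactly at zero
for the noiseless oracles. With the defaults, a stalk transient of
ΔF/F = 1 has amplitude-to-noise of roughly 30.

**EPSC trace.** Inward currents are negative (holding −60 mV); each wave
contributes a negative Gaussian deflection with peak magnitude
`epsc_amp_pA` (default 300 pA) and FWHM `epsc_width_s` (default 1 s), plus
5 pA Gaussian noise, sampled at 1 kHz. Magnitudes are reported downstream as
absolute values.

**Motility series.** Default six timepoints emulate a 10-min volumetric
series at 2-min intervals. Motile categories step by ≥1.5 µm per interval;
"new" trajectories begin absent (NaN), "lost" end absent; two-phase
categories reverse at a random interior timepoint. Category counts follow
the requested mix exactly (largest-remainder allocation) so recovery tests
are deterministic in composition.

What the generator does **not** emulate: wave spatial propagation (waves are
field-wide; participation, amplitude and latency statistics do not depend on
wavefront geometry), motion artifacts and bleaching (the pipeline assumes
registered, bleach-corrected input), and sub-ROI spatial structure of the
calcium signal. Passing recovery tests therefore validate the measurement
chain, not robustness to registration failures.

## Segmentation

The time-averaged image is filtered with a negated, scale-normalized
Laplacian of Gaussian with σ = d/(2√2) pixels (d = expected stalk diameter),
the scale-matched blob detector. The response is binarized at a user-defined
threshold, defaulting to Otsu on the response — a reproducible stand-in for
the interactive threshold an analyst would choose. Touching blobs are split
by watershed on the negated Euclidean distance transform, seeded at local
distance maxima with minimum separation of **half** the minimum stalk
diameter: this is close enough to split two discs whose centers sit 0.7
diameters apart (the hardest case the pipeline must resolve) while a single
digitized disc still yields one seed. Components with equivalent diameter
outside [2, 3] µm are discarded as non-stalk structures; both bounds are
config. Manual ROI curation is supported as an edit table
(`apply_roi_edits`), not a GUI.

Process squares (default 250 of 2.5 × 2.5 µm², rounded to ≥1 px) are drawn
uniformly with replacement over all top-left positions whose square contains
no stalk pixel; squares may overlap each other (only stalk overlap is
excluded). Placement is deterministic given its seed.

## Signal processing and detection

ΔF/F uses the whole-trace median as F₀ — robust to transients occupying a
minority of the trace. The two-frame median filter is implemented causally:
frame *t* is the median of frames {t−1, t} (= their mean), with the first
frame passed through; this convention is asserted in tests. z-scores use the
whole-trace mean/SD of the smoothed ΔF/F (smoothing before z-scoring); a
median/MAD alternative is available (`robust_z`) but off by default.
Transients are maximal runs of z ≥ 3; onset is the first frame of the run,
the event time is the peak (argmax z) frame. No minimum-duration filter is
applied by default (`min_duration_frames` exposed).

Two consequences worth knowing. First, the causal even-window median can
shift a detected peak by one frame relative to the unsmoothed signal; exact
oracles therefore compare against the smoothed analytic kernel. Second,
whole-trace z-scoring assumes transients are sparse in time: if waves were
so frequent that transients dominated the trace, the z-denominator would
inflate and detection would fail. At the realistic ~40 s IWI the duty cycle
is ~6% and the method is well-behaved; the verification scenarios use that
regime.

## Wave detection and association

The EPSC trace is median-baseline-subtracted and rectified; a 2 Hz
Butterworth low-pass smooths the envelope; excursions above the threshold
(default 50 pA) lasting ≥50 ms are events, events closer than `min_iwi_s`
(default 5 s) merge keeping the larger peak. The wave peak is the maximum
|current| sample in the excursion and its absolute value is the magnitude;
IWI is the interval between successive peaks. Reading the magnitude from the
raw (unfiltered) current means noise biases it slightly upward (~+2 SD of the
noise at 1 kHz sampling).

Association uses transient **peak** times (the only time both the 3-s rule
and the latency definition can share): a transient joins the nearest wave
if |Δt| ≤ 3 s, ties toward the earlier wave, otherwise it is spontaneous.
Each transient gets at most one wave, so participation counts each
(ROI, wave) pair at most once. Per-wave, per-compartment participation
divides responding ROIs by the compartment's ROI count. The chance baseline
draws `n_times` (default 100) uniform times away from the recording edges
and averages the proportion of ROIs with a transient within ±3 s; for
homogeneous-Poisson events at rate r the expectation is 1 − exp(−2·3·r),
which is the closed-form oracle used in tests.

Intercompartment latency for a wave is computed per responding stalk as
stalk peak time minus the **median** process peak time for that wave
(positive = stalk later); the per-wave value aggregates responding stalks by
median, and both granularities are emitted since the stalk-level aggregation
is a package choice, not an experimental definition. Fold-changes divide the
per-FOV mean metric in condition B by condition A (paired FOVs; unpaired ids
are an error, zero baselines warn and yield NaN). Amplitude fold-changes are
defined on both the z-scored and the raw ΔF/F peak; only the raw scale is
proportional to a true amplitude manipulation (the z denominator changes
with the manipulation itself), so recovery is judged on `amplitude_dff`.

## Morphometry

Tips are process-type nodes with no children; branch points process-type
nodes with ≥2 children; primary branches process nodes whose parent lies on
the stalk; total process length sums parent–child Euclidean distances over
process segments (the stalk is not process length). Sholl profiles project
process segments to a plane, subdivide to ≤0.1 µm, and count ring crossings
by sign change of the radial distance: a segment crossing a ring twice
counts twice, tangency counts zero, and a point exactly on a ring is treated
as inside so a path through it counts once. The XY center is the stalk path
collapsed to its mean lateral position (registration of stalk XY
displacement); XZ/YZ centers sit at the stalk end nearest the INL, with the
convention that z grows from INL to GCL. Radii normalized to IPL thickness
are resampled by linear interpolation onto a 0–1 grid (step 0.01) so cells
with different IPL thicknesses are comparable. Convex-hull area is the 2-D
hull (QHull) of the subdivided XY projection; degenerate geometries return 0
with a warning. Tip depths map to five equal sublayer bins, half-open with
the last bin closed at the GCL border; tips outside the IPL are dropped with
a warning.

## Motility classification

The original scoring of temporally color-coded projections was manual; this
package substitutes an explicit rule. Appearance (absent→present) anywhere
makes a process "new", otherwise disappearance "lost"; for continuously
present processes, per-interval steps smaller than `delta_um` are zeroed and
the sign pattern of the remaining steps decides among extending, retracting,
the two combination categories (first two phases, also for multi-reversal
patterns) and stable. The default `delta_um` = 0.5 µm is a declared
convention (about half the 1 µm axial step of the source volumes), not an
empirical value; classification is provably invariant to per-timepoint noise
below `delta_um`/2 when true steps are 0 or ≥ `delta_um`. A sensitivity
sweep is one line: classify the same table at several `delta_um` values and
compare summaries.

## Statistics

χ² goodness-of-fit (df = k−1) and contingency χ² (no continuity correction,
df = (r−1)(c−1)) come from scipy; expected counts below 5 warn but do not
switch tests. Wilcoxon signed-rank (zeros dropped) and rank-sum tests use
exact null distributions up to n = 25 and the continuity-corrected normal
approximation beyond; all tests are two-sided by default. BH adjustment is
statsmodels' step-up procedure (order-invariant). Post hoc contrasts after
omnibus comparisons are plain paired/two-sample t-tests with BH; omnibus
mixed ANOVAs are out of scope — the long-format tables are exported for any
external model fitting. Reports emit both ROI-pooled and per-FOV
granularities, leaving the unit-of-analysis choice to the analyst.

## Verification scenarios and problem sizes

The recovery benchmarks (`gliawave.recovery`, driven by the test suite and
`scripts/acceptance.py`) use 60 × 60 µm fields with 16 stalks at 0.5 µm
pixels and 2 Hz — a scaled-down FOV that preserves full stalk/process
geometry while keeping a ~100-wave recording to a few thousand frames:

* participation: one ~4150 s recording (~100 waves), p = 0.5/0.9; the
  estimate is compared to the realized truth of the units each measured ROI
  samples, within 3 SE of the wave-level mean;
* chance baseline: 50 Poisson realizations at r = 0.01 Hz vs. 1 − exp(−6r);
* latency: ten ~2100 s recordings (~50 waves each), offset 0.5 s, tolerance
  one frame interval;
* fold-change: six paired FOVs (~1200 s each), amplitude ×2 and
  participation ×0.5 on stalks;
* segmentation: twenty noiseless fields; motility: 700 noiseless
  trajectories over all seven categories;
* calibration: 1000 null replicates per test at nominal α = 0.05.

## Known limitations

* Process squares straddling unit boundaries in the synthetic data dilute
  the sampled transient; with the default unit size this depresses recovered
  process participation by ≲1.5% — visible as the small gap between the
  recovered value and the generator probability, and the reason recovery is
  judged against realized unit-level truth.
* Wave "magnitude" is a raw-current peak and inherits noise bias; IWI and
  peak times are unaffected.
* The z-threshold detector has no amplitude calibration below z = 3; very
  small or very frequent events are by design invisible to it.
* Sholl and hull computations subdivide segments at 0.1 µm; features finer
  than that are not resolved.
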
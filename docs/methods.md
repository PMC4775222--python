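# Methods

This note documents the models, conventions and numerical choices behind
`edgepulse`, and what the synthetic-data validation does and does not
establish about real microscopy data.

## Coordinate and unit conventions

All modules share one frame: image origin at the top-left, x increasing
rightward (the embryo's anterior–posterior axis by default, overridable),
y increasing downward (dorso-ventral). Space is in µm, time in s, rates of
change in units/min, angles in degrees. Interface orientation is the acute
angle from the AP axis, folded into [0°, 90°]; 90° is the DV axis.

## The measurement pipeline

**Vertex resolution.** The onset t₀ of resolution is the first sample at
which the nascent interface length strictly exceeds the 1-µm threshold
("exceeded" is read strictly; a length exactly at threshold does not
trigger). An event is *resolved* when some supra-threshold run spans at
least the 60-s non-resolution window, *collapsed* when it crossed but
every run fell back sooner, *unresolved* when it never crossed, and
*indeterminate* when the recording ends mid-run. Orientation is read at
the frame nearest t₀ + 150 s (ties to the earlier frame; the analysis does
not interpolate between frames). The elongation rate over a window w is
(l(t₀+w) − l(t₀)) / w in µm/min, 90 s by default; negative rates are
legitimate (collapsing interfaces).

**Oscillation analysis.** Measured series are converted to rates of change
as differences of samples one minute apart, assigned to the earlier time
point and scaled to per-minute units; a lag that is not a multiple of the
sampling interval is handled by linear interpolation and flagged.
Detrending subtracts the ordinary-least-squares line. The period estimate
is the inverse of the dominant non-DC FFT frequency of the detrended rate;
it is exact for bin-aligned sinusoids and otherwise quantised to the
record's spectral resolution (e.g. a 570-s record resolves periods only at
570/k s — the worked example's 116 s vs. a generating 126 s shows this
limit, not a defect). Pulses are maximal runs of strictly positive
(elongation) or strictly negative (shortening) rate; zero samples belong
to no pulse. Pulse areas use the rectangle rule Σ rate·dt, chosen over
higher-order quadrature because it makes the conservation identity

    total elongation − total shortening = net length change

hold exactly on sampled data. Time-shift scans recompute Pearson r over
the overlapping samples only (zero padding would bias r toward 0) at
shifts of ±240 s in 10-s steps, smooth the curve with a Gaussian kernel
(σ = 10 s, truncated at ±3σ, renormalised at the boundaries), and report
the interior local extrema closest to zero shift; a tie between equal and
opposite shifts reports the negative one and sets a flag. Positive shift
delays the first signal relative to the second, so scan(a, b) at +s equals
scan(b, a) at −s.

**Segmentation and tracking.** Watershed runs on the raw (optionally
Gaussian-presmoothed, σ = 1 px) membrane intensity of a maximum-intensity
projection of the three most apical z-slices — membranes are ridges, so no
gradient preprocessing is needed for a membrane reporter. Flooding order
is deterministic, and ridge pixels go to the basin reached first. Seed
pairs with no intensity ridge along the straight path between them are
flagged as sharing a basin. PIV uses 32-px interrogation windows on a
16-px grid, normalized cross-correlation with a parabolic subpixel fit,
and the peak correlation value as a confidence score (matches below 0.5
are not trusted); these defaults are this package's own choices. Seeds are
advected by the local displacement; a seed leaving its region is snapped
to the region centroid plus displacement, and a seed leaving the image
marks the cell lost. Cell boundaries are exported as marching-squares
contours in µm and areas as their shoelace area. Cell division and
extrusion are out of scope (germband cells do neither on these time
scales).

**Ablation velocimetry.** The instantaneous retraction velocity uses only
the last pre-ablation and first post-ablation vertex positions:
v = (post-separation − pre-separation)/(t_ablation + t_acquisition),
signed, invariant under rigid motion. Later post-ablation frames are
deliberately ignored — recoil decelerates, and the single-interval
estimate is the convention the pipeline standardises on. Interface class
(control DV / new DV / AP) is an input annotation, not inferred, because
it depends on the interface's history.

**Fluorescence.** Background is the modal integer pixel value of a
10 × 10 µm basal-projection crop around the region of interest (raw
integer bins, no histogram smoothing; modal ties take the smaller value).
Photobleaching is corrected by dividing by the mean intensity of the
apical projection at each time point (projection, not full stack).
Junctional intensity averages a 3-px-wide dilated traced path minus the
whole-image mode; medial intensity averages the polygon interior eroded by
the junctional width. Normalised traces divide by the value at the first
time point. Which z-end is apical is a stack flag.

**Statistics.** Student's t-test is the classical pooled-variance
two-sided test (Welch behind a flag); two constant equal samples return
(t, p) = (0, 1) by convention. Correlation significance transforms r to
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. The KS test defaults to
the asymptotic method; an exact mode exists for small samples. No
multiple-testing correction is applied, and outputs record that.

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes,
not tissue mechanics — oscillations are prescribed kinematically, and no
force balance is computed.

A four-cell patch surrounds one resolving vertex. Anterior/posterior
apical areas follow A(t) = A₀(1 + a·sin(2πt/P_area)); dorsal/ventral
cells oscillate in anti-phase with them. The central nascent edge is a
linear ramp plus pulses, floored at zero. Pulses are **raised-cosine lobes
in the length rate**, r(τ) = h(1 − cos(2πτ/T))/2 with closed-form area
hT/2; when T is a multiple of the sampling interval, the rectangle-rule
sum over a lobe's strictly-positive samples equals hT/2 *exactly* (the
cosine sum over one period contributes a single −dt that offsets the
missing zero-valued boundary sample), so pulse decomposition recovers
generated pulse sizes with no quadrature error. Under `anti_phase_AP`
coupling, elongation lobes occupy the quarters of the cycle where the AP
cells' area derivative is negative.

Generator defaults are the measured study conditions: edge oscillation
period 126 s, area period 130 s, elongation pulses of 0.772 µm against
shortening pulses of 0.114 µm, base apical area 30 µm², and a ramp of
0.16 µm/min chosen so the mean elongation rate is close to the measured
0.47 µm/min control rate. The area-oscillation amplitude across cells is
not constrained by published measurements; it is exposed as a parameter
(default 10% of mean area) without any claim of fidelity. Noise is
additive Gaussian on coordinates/lengths and Poisson-like on images
(variance = mean/snr²), the simplest models consistent with confocal
counting noise.

Movies are rendered at 0.1 µm/px by default by rasterising polygon
boundaries (midpoint rasterisation), blurring with a Gaussian PSF and
adding the Poisson-like noise; the ground-truth label stack rasterises the
exact polygon interiors (membrane pixels are label 0, and sub-pixel
overlaps between abutting cells resolve deterministically to the higher
id). Ablation events recoil at exactly constant speed — an idealisation;
real recoils decelerate, but only the first interval enters the estimator.
Junction polylines are built symmetric about the interface axis with
mutual angle exactly θ; at θ = 180° the two junctions are collinear with
each other (perpendicular to the interface).

**Exact-sample-correlation construction.** Correlated signal pairs and
ablation cohorts enforce the *empirical* Pearson correlation, not just the
population parameter: the second series is built by Gram–Schmidt from the
component of an independent draw orthogonal to the first and mixed back
with weight √(1−ρ²), then mapped affinely to the requested scale (Pearson
r is affine-invariant). At cohort sizes of 40 the sampling spread of r
under a population-parameter draw is ≈ 0.13, which would make correlation
recovery a property of the seed rather than of the code; pinning the
sample correlation makes those recovery checks deterministic while
retaining seeded variability in every individual value.

**What passing tests show — and don't.** Recovery on synthetic data
verifies the estimators' correctness (units, conventions, quadrature,
windowing, classification logic) under the generative assumptions:
polygonal cells, prescribed sinusoids and lobes, Gaussian/Poisson-like
noise, no segmentation ambiguity beyond rendering. It does not establish
robustness to real-tissue phenomena the generator omits: membrane
intensity heterogeneity, out-of-plane motion, neighbour-exchange topology
changes mid-track, amplitude/period drift, or photodamage trends that are
not multiplicative.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances —
tissues of 4 cells over ≤ 64 frames, movies of roughly 150 × 260 px,
cohorts of 220 signal pairs and 40 ablation events, signal records of
~60–210 samples — sizes at which every check completes in seconds while
still exercising whole-cycle oscillations and full tracking loops.
Degenerate inputs are signalled, not silently patched: zero-variance
signals in correlations, zero-length edges in orientation, empty polygons
after erosion, windows extending past a trace's end (the error names the
available span). Floating-point "exact" claims are asserted at 1e-9 or
tighter on quantities of order one.

## Known limitations

- The tracker has no manual-correction pathway; badly mis-tracked cells
  are lost rather than repaired, which is acceptable for the 4-cell
  validation patches but would need curation on dense tissue.
- The FFT period estimator reports one dominant bin; closely spaced or
  drifting periods are not separated (no wavelet/autocorrelation
  alternative is provided by design).
- The shift-scan extremum search treats plateaus conservatively (strict
  inequalities), so perfectly flat smoothed curves report no extremum.
- Vertices that never exceed the 1-µm threshold have no onset and are
  excluded from angle statistics.
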
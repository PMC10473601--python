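# Methods

This note records the models behind each module, the conventions and
defaults a user may want to change, what the synthetic generators do and
do not emulate, and the numerical choices that matter. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates, units, formats

Annotation files store 0-based pixel coordinates (pixel-centre
convention, y increasing downward); loading scales them to nanometres
with the per-profile `pixel_size_nm`. All library-level geometry is in
nm. Tables are UTF-8 comma-separated CSV with a header row; images are
single-plane multi-channel TIFF; ground truth travels in JSON sidecars.
Every pipeline artifact is SHA-256-hashed into `manifest.json` together
with the seed and a hash of the configuration (output path excluded), so
fixed-seed runs are byte-reproducible and verifiable (`synaptoquant
verify`). For that reason no wall-clock timestamps are written into
artifacts; per-stage timing goes to the log stream only.

## EM morphometry

A profile is one 2D cross-section: a simple (non-self-intersecting)
membrane polyline, an active zone given as a contiguous arc-length span
of that polyline, vesicles as circles, pits as marked membrane points.

*Distance convention.* Vesicle–membrane distance is the **edge**
distance: exact minimum distance from the centre to the polyline
(orthogonal projection per segment, no sampling) minus the radius,
floored at 0. "Touching" therefore scores 0, which is what defines a
docked vesicle; a `reference="center"` switch is available. Distances
for docking/zone membership are measured to the **active-zone
sub-polyline** (a `membrane_scope="whole"` switch uses the entire
membrane; which of the two an annotator intends should be stated per
dataset).

*Classes.* docked ⇔ d ≤ `dock_tolerance` (default 0.5 nm, roughly one
EM pixel at typical magnification, absorbing annotation jitter);
replacement ⇔ undocked and d ≤ 20 nm; other otherwise. The docked count
is monotone in the tolerance by construction.

*Histograms.* Undocked distances are binned over (0, 50] into 25
half-open bins (0,2], (2,4], …, (48,50]; a distance of exactly 2 nm
falls in the first bin. Values outside (0, 50] are excluded from both
counts and the normalizing total. An empty histogram reports its
relative frequencies as undefined, never as zeros.

*Cohort tables.* Mean, SEM (SD/√n, ddof = 1) and n per
(genotype, timepoint) and measure. Normalization divides by the same
genotype's "no stim" mean and errors if that mean is zero or missing.
Profiles failing validation are skipped with a logged warning
(`strict=True` raises instead).

## Synthetic EM cohorts

Per profile the generator draws independent Poisson counts for docked,
replacement-zone and bulk vesicles, with per-group multiplicative scales
on the docked and zone means (freeze-timepoint presets are *only* scale
factors — no docking kinetics are modelled, because none are specified
by the assay itself). Defaults: 2.0 docked, 2.0 zone, 5.0 bulk per
profile; 40-nm vesicles; a 500-nm active zone centred on a 1200-nm
membrane built as a random walk with headings bounded to ±10°/segment
(so geometry code always sees curvature). These values are of the order
reported for cultured hippocampal synaptic profiles at ~100
profiles/condition.

Placement solves a 1-D root problem along the local membrane normal so
that each vesicle's *measured* edge distance equals its drawn truth
(docked: exactly 0; zone: uniform on (0, 20]; bulk: uniform on
(20, 200]) to machine precision; undocked vesicles may also sample
60-nm lateral wings past the zone ends, where the distance is measured
to the endpoint. Vesicle discs never overlap (rejection sampling, 10⁴
attempts per vesicle). A count draw that physically cannot be packed —
deep Poisson tail, probability ~1e-4 under the defaults — is redrawn
with a fresh membrane up to 10 times before erroring; this truncates
only geometrically impossible configurations. RNG is numpy PCG64,
recorded in the metadata; fixed seeds reproduce outputs exactly.

What this emulates: the count structure, distance bands and group
scaling of a freeze-timepoint × genotype design. What it does not: EM
texture, segmentation error, 3D sectioning effects, or any kinetic
model of docking — so passing recovery tests demonstrates correctness of
the measurement code, not biological realism of the fixtures.

## Boundary-relative puncta localization

Preprocessing follows the two-channel super-resolution recipe: Gaussian
blur of radius 1.2 px (interpreted as σ; an FWHM interpretation is
selectable) to tame shot noise, then two passes of blind deconvolution,
10 iterations each, the second seeded with the PSF returned by the
first. Blind deconvolution is implemented as alternating Richardson–Lucy
multiplicative updates of PSF and image (Poisson maximum-likelihood,
reflective boundaries, PSF renormalized to unit sum each iteration) —
deterministic, flux-preserving to <1%, and nonnegative. Commercial
blind-deconvolution routines differ in detail; downstream geometry
(peaks, half-max contours) is robust to the variant and nothing here
claims numerical identity with any particular implementation.

Boundaries: for every reference-channel local maximum above a noise
floor (default median + 3·MAD), the marching-squares iso-contour at
**half that peak's value** that encloses the peak, with sub-pixel
interpolation. Note one consequence of the half-of-local-peak
definition: deconvolution steepens edges and overshoots at rims, raising
the local peak and pulling the contour slightly (<1 px) inward relative
to the half-max contour of the unprocessed image. The end-to-end
signed-distance error measured on synthetic fixtures (~0.8 px RMS) is
dominated by this deterministic term, not by noise.

Puncta: local maxima above `rel_threshold` × ROI max (default 0.3), at
least `min_separation_px` apart (default 3; brighter wins), centres
refined by 3×3 intensity centroid. A punctum whose half-max support
region touches the ROI border is kept but flagged excluded ("edge").
None of these three defaults is prescribed by the assay; they are this
package's conventions and are configurable.

Signed distance: exact minimum distance from the centre to the boundary
polygon, negative if the centre is inside by the even-odd rule; points
exactly on the contour (including vertices) count as inside with
distance 0. Distribution summaries treat d ≤ 0 as "inside"; the
cumulative curve is the empirical CDF and reaches exactly 1; empty
inputs yield a flagged undefined summary.

The fixture generator defines truth against the half-max contour of the
noiseless blurred reference — the observable the analysis estimates —
and places emitters by root-finding along rays so realized signed
distances match requests to <0.01 px. Poisson noise is applied to
expected counts times a gain parameter (default 1.0, recorded).

## Condensate dynamics

The dispersion index is **variance divided by mean** (an index of
dispersion, units of intensity), high for punctate and low for diffuse
signal; the classical SD/mean is available via
`cv_definition="sd_over_mean"`. Population variance is used for line
profiles. Per-axon values are normalized by the mean of their condition,
making condition means exactly 1.

FRAP fractional recovery uses the first post-bleach frame as the floor
and the post-bleach maximum as the ceiling, mapping them to 0 and 1; the
transformation is invariant to gain/offset of the raw trace. An option
averages the first k post-bleach frames as the floor for noisy data. The
one-phase association fit plateau·(1 − e^(−t/τ)) uses deterministic
initialization (plateau₀ = max f, τ₀ = time to half-max) and bounded
least squares; non-convergence is flagged, never silently defaulted. The
fit is exactly time-scale equivariant: dilating t by k multiplies τ̂
by k.

ΔF/F₀ time courses use the per-ROI pre-stimulus mean as F₀; the summary
reports the minimum of the cohort mean during stimulation and the
fraction of that dip recovered by the trace tail (last 5 frames by
default).

Synthetic FRAP traces follow the one-phase model with additive Gaussian
noise (defaults mirror a 600-ms frame interval, 100 frames, bleach after
frame 3). Synthetic axon profiles match total integrated intensity
between punctate and diffuse modes exactly (diffuse profiles are
rescaled after noise), so dispersion comparisons isolate spatial
arrangement.

## Train analysis and the release model

The simulator is the minimal depletion–replenishment model: a pool of N
sites starts full, each pulse releases fraction p of the occupied pool
(response q·p·Pᵢ), and between pulses the pool relaxes toward N with
first-order rate k_rep over Δt = 1/frequency. Closed forms used as
oracles: with k_rep = 0 the normalized train is geometric (1−p)^(i−1)
and the cumulative curve converges to 1/p, so intercept × A₁ → Nq; with
k_rep > 0 amplitudes converge to the fixed point of the update map.

RRP back-extrapolation fits OLS to C_k vs k over a steady-state window —
default the **last 30 of 100** stimuli, a convention of this package
(r² is reported and a curvature flag warns when the window halves have
visibly different slopes). The y-intercept is in multiples of the first
response; multiply by A₁ for the raw-scale Nq proxy. The intercept is
invariant to stimuli appended after the window.

Charge transfer integrates |baseline-subtracted trace| over the train
(trapezoidal); synchronous charge sums windows of `sync_window` (default
10 ms — again a convention, the assay does not define the split) after
each stimulus, and asynchronous is the exact remainder. Peak vs slope as
the amplitude metric is always an explicit input column, never inferred.

## Statistics

Selection rules: >2 groups without zeros → Brown–Forsythe-corrected
one-way ANOVA (F\* = Σnᵢ(x̄ᵢ−x̄)²/Σ(1−nᵢ/N)sᵢ², Satterthwaite df) with
Games–Howell pairwise tests (Welch t, Welch–Satterthwaite df,
studentized-range reference with the full group count, hence
family-adjusted); any exact zero in any group → Kruskal–Wallis with tie
correction plus Dunn z-tests; two groups reduce to the Welch t (to which
Games–Howell is identical at k = 2) or, with zeros, Mann–Whitney (exact
for n ≤ 20 without ties, normal approximation with tie correction
otherwise). The zero trigger is configurable to "entire group zero".
Every plan records its rationale in the result.

Dunn's pairwise p values are multiplicity-adjusted with **Holm** by
default (Bonferroni and Šidák selectable) over the requested pairs; when
a pre-registered pair list is supplied (e.g. WT vs KO at each
timepoint), only those pairs are tested and adjusted. Which correction
the canonical "Dunn's multiple comparisons" uses varies between software
packages; Holm is this package's choice, dominating Bonferroni at equal
error control.

Degenerate inputs: groups of n < 2 are rejected; zero variance in all
groups raises rather than returning an unstable statistic.

## Problem sizes and verification

The checks in `tests/` and `scripts/acceptance.py` run at the sizes the
analyses are designed for: 1,000 random geometry cases against
dense-sampling oracles (<0.01 nm point-to-polyline, <0.2 nm polygon);
cohorts of 300 profiles/group over 20 seeds for zone-scale recovery
(95% CI over seeds covers the generating 0.65 factor); 5 noisy
two-channel ROIs × 5 puncta for signed-distance RMSE (≤ 1 px at
20 nm/px); 500 FRAP replicates at 5% noise (median relative τ error
< 10%); depletion trains at p ∈ {0.3, 0.5, 0.8} (Nq within 5%); and
2,000 simulated null datasets for type-I calibration (rejection rate
within [0.035, 0.065] at α = 0.05).

## Known limitations

- Synthetic fixtures carry no EM texture, STED photophysics beyond
  Gaussian PSF + Poisson noise, or 3D structure; recovery results
  validate the measurement code only.
- The blind-deconvolution variant is not a clone of any commercial
  routine; only geometry-level outputs are comparable across variants.
- Freeze-timepoint presets are illustrative scale factors, not a
  calibrated kinetic model.
- The steady-state window for back-extrapolation and the
  synchronous/asynchronous split are conventions; sensitivity to them
  should be checked on real data.
- No automated segmentation: annotations are inputs, produced upstream.
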
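# Methods

This note records the models, conventions and parameter defaults behind
each analysis stage, what the synthetic generators do and do not emulate,
and the numerical choices that matter when reproducing results.

## Surface metrology

A height map is first flattened by subtracting a least-squares 2-D
polynomial (degree 1–3, default 2: degree 1 removes instrument tilt,
degree 2 the cell-body curvature).  The flattened map is split in the
frequency domain by a complementary raised-cosine filter of relative
width 0.2 around the cutoff frequency; the high band is computed as the
residual, so low + high reconstructs the input to machine precision.  The
default cutoff wavelength is **300 nm**, the approximate geometric
midpoint between the two texture scales of interest (~100 nm roughness,
~900 nm waviness); it is exposed everywhere a decomposition is run.

Band summaries use one explicit convention shared by the generator and
the estimator, since "amplitude" and "period" of a random texture are
otherwise underdefined:

* **h = 2√2 · RMS** of the band — the peak-to-valley amplitude of the
  single sinusoid with the same RMS;
* **L = 1/f_peak**, where f_peak is the parabolically interpolated
  maximum of the band's radially averaged power spectrum.

The radial PSD is Hann-windowed (normalized by the window power) and
reported as the *azimuthal mean* of the 2-D spectral density, so a
white-noise map gives a flat profile; `RadialPSD.total_power()` performs
the annulus-weighted Parseval sum and recovers the map variance to ~1% on
noise-like fields.  Coherent few-component fields can deviate by more,
because the windowed variance weights the field centre.

The period estimate is quantized by the radial bin width 1/(N·px); for a
939 nm period on a 5.12 µm field this limits accuracy to roughly 5–7%,
which dominates the L₁ recovery error.  Amplitudes are not quantized and
return to ~0.3%.

### Texture generator

Each band is an ensemble of `n_components` (default 12) equal-amplitude
plane waves with random phases and random orientations drawn from the
integer frequency lattice nearest the target ring |k| = N·px/L.
Grid-periodic wavevectors make each component leakage-free, so band
energies separate exactly at analysis time and the band RMS equals
h/(2√2) by construction (the per-component amplitude is
√2/√n · h/(2√2)).  What this does **not** emulate: AFM tip convolution,
scan-line artifacts, spatially varying roughness and 1/f background —
recovery on these textures demonstrates the decomposition algebra, not
robustness to instrument artifacts.

## Morphology

Cells are connected components above a substrate threshold (default
200 nm), excluding border-touching components and areas outside
10–80 µm².  Each cell is reduced to (a) a mean-height profile over 24
annuli of normalized radius and (b) an angular series sampled at 0.8 of
the cell radius.  The decision rule, applied in order:

1. **echinocyte** — ≥ 6 angular maxima with prominence above 2.0× the rim
   RMS (and rim RMS above 2% of cell height, so a numerically flat rim
   cannot produce spurious spicules);
2. **codocyte** — centre height exceeds the mid-radius (0.25–0.8 R)
   minimum by > 5% of cell height;
3. **discocyte** — rim maximum exceeds the centre by > 5% of cell height;
4. otherwise unclassified.

All indices are normalized by cell height, making the rule invariant to
uniform height scaling; the radial reduction makes it invariant to
translation and 90° rotation.  Thresholds separate the three parametric
archetypes with wide margin; they are config-exposed because real cells
(and intermediate stomatocyte/spherocyte shapes, which this package does
not model) will sit closer to the boundaries.

The scene generator renders radial height models — biconcave disc
(centre ≈ half rim height), dome with 10–16 sharpened rim spicules, and
annular trough with central dome — at 7.5 µm nominal diameter and 1.2 µm
rim height (textbook RBC geometry; the field of view auto-sizes to ~30%
packing).  Class counts follow largest-remainder rounding of the
requested percentages; placement is rejection sampling with an iteration
cap.  Overlapping and touching cells are not generated, matching the
segmenter's connected-component assumption.

## Cytoskeletal pores

The mesh generator tessellates Poisson-distributed seed points (intensity
set by the pore density per 2×2 µm² reference window) into Voronoi
cells, then shrinks every cell about its centroid by one global factor
calibrated so the ground-truth mean maximum-Feret length equals the
requested pore length; the shrunken polygons become pore floors and the
remaining band along tessellation edges the elevated filament (20 nm
relief).  Note the density and the pore length jointly over-determine a
plain Voronoi tessellation; fixing the count with the Poisson intensity
and the length with the shrink factor resolves this while keeping both
statistics at their targets.  Ground truth comes from the exact polygons
and lists only pores fully inside the field.

Detection: Gaussian smoothing (σ = 10 nm), markers from the h-minima
transform at depth 0.5 nm with minima closer than 3σ merged, watershed on
the relief **restricted to pixels below half the floor-to-crest relief**
— without the mask restriction every basin would extend to the ridge
crest and pore lengths would be overestimated by the filament width.
Border-touching pores are excluded from count and length; the density
uses a guard-zone correction (field side reduced by twice the mean pore
radius) that makes the interior count an unbiased density estimate.
Detected Feret lengths run ~8–10% below ground truth because smoothing
moves the half-height contour inside the pore edge; this sits within the
15% recovery tolerance and is the main known bias of the stage.

Feret length is the maximum pairwise distance between pixel centres,
computed on the convex hull (with a brute-force fallback for degenerate
masks) — identical to the all-pairs maximum by convexity.

## Hertz mechanics

Model: spherical indenter on an incompressible half-space,
F = (4/3)·E/(1 − ν²)·√R·δ^{3/2}, with ν = 0.5, R = 150 nm, k = 1 N/m
defaults.  Unit bookkeeping: with lengths in nm, E in kPa and k in N/m,
F[nN] = C·E·δ^{3/2} with C = (4/3)(1 − ν²)⁻¹√R · 10⁻⁶.

The generator solves the implicit balance k·d = C·E·((z − z₀) − d)^{3/2}
by fixed-point iteration (deflection is much smaller than indentation for
soft cells, so convergence is fast) and adds Gaussian deflection noise.
Default maximum indentation is 800 nm: on a ~4 kPa cell the peak
deflection is then ~2 nN·m⁻¹-equivalent (≈ 2 nm), a realistic
signal-to-noise for 0.3 nm deflection noise.

Fitting: for a candidate contact point the model is linear in E, so E has
a closed form; z₀ is found by a 120-point grid search minimizing the
total squared residual of the piecewise model (zero-deflection baseline
before z₀, Hertz after), refined by bounded scalar minimization.  Only
indentations up to `fit_max_indentation` (default **500 nm**) enter the E
regression — deep enough that the deflection rises well above the noise
floor while staying in the d ≪ δ regime — but deeper points are still
scored against the fitted curve so the contact search cannot cheat by
pushing z₀ forward.  Noiseless curves invert to < 0.1% in E and < 2 nm in
z₀.  Contact-point precision under noise is modulus-dependent: for stiff
curves (~20 kPa) it is a few nm, for 4 kPa cells tens of nm, which
contributes a small (< 5%) spread but no material bias to E.  Retract
segments, adhesion, and substrate (bottom-effect) corrections are out of
scope.

## Hemoglobin unmixing

D(λ) = ε_HbO₂C₁ + ε_HbC₂ + ε_MetHbC₃ + M + S·λ⁻⁴ is linear in all five
unknowns and solved with bounded linear least squares: C_i ≥ 0, S ≥ 0, M
free (a calibration offset may be slightly negative).  The geometric
light path is folded into the concentration coefficients since only
relative fractions are reported; fractions below 1% are reported as
absent.  The bundled extinction table is **synthetic**: Gaussian bands
with the oxyhemoglobin doublet at 542/577 nm (σ = 8 nm, narrow enough
that the summed profile still peaks exactly there on a 1 nm grid), a
deoxyhemoglobin band at 555 nm, a methemoglobin band at 630 nm, and small
positive baselines.  It reproduces the qualitative features the fit
relies on, not literature coefficient values; a measured table in the
same schema can be passed anywhere an `ExtinctionTable` is accepted, and
fractions from a synthetic-table fit are only meaningful against spectra
built from the same table.  Peak positions are refined by parabolic
interpolation, so mixture spectra report peaks shifted a fraction of a
nm by band overlap — the pure-HbO₂ doublet returns 542/577 within 0.1 nm.

## ROS traces

Baseline = median of the first 20% of samples; maximum = peak of the
5-sample moving-median (single-sample spikes rejected); normalized ROS =
(max − baseline)/reference.  Baseline subtraction makes the value
invariant to a constant offset on the trace — whether the reference
normalization should be baseline-corrected is a convention, declared
here, chosen for that invariance.  The max-of-noise statistic is biased
upward by roughly the smoothed noise SD times the extreme-value factor;
at realistic amperometric noise (~0.2 pA on 5–10 pA plateaus) this
cancels to < 3% in group-mean ratios.  The generator produces a logistic
rise (τ = 0.3 s) to a plateau and does not model electrode drift,
spike-like vesicular events, or approach-curve physics.

## Statistics

Two-sided tests throughout.  Mann–Whitney U uses the exact distribution
for tie-free samples with n·m ≤ 400 and the normal approximation with
tie and continuity correction otherwise; the two branches agree to ~0.013
(one continuity step) for 8 vs 8 samples.  No multiple-testing correction
is applied by default, matching per-comparison reporting practice.
Group summaries report mean, SD and SEM = SD/√n.

## Reproducibility and problem sizes

All generators are deterministic given their seed.  The recovery suite
uses 512² texture maps (20 seeds), 512–1024² meshes (10 seeds), 100-curve
modulus populations, 100-cell scenes (5 seeds for composition, 20 × 15
cells for the confusion matrix) and 1000-replicate null calibration for
the U test — sizes chosen so the full suite runs in well under a minute
per stage on one CPU while keeping Monte-Carlo error comfortably inside
each stated tolerance.
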
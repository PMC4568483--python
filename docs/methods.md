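# Methods

## The assay and its computational readout

A plate of magnetically printed spheroids is imaged from below against a
bright light pad at fixed intervals (default: every 4 min for 10 h, 151
frames). Viable spheroids contract — their projected area shrinks as cells
compact — while cytotoxic exposure slows or stops contraction. The pipeline
turns the image stack into one endpoint per well:

1. **Segmentation** measures the projected area of the dark spheroid in each
   well of each frame.
2. **Kinetics** reduces each well's area series to the contraction rate over
   the first 150 min and normalizes it to vehicle controls.
3. **Dose-response** fits the normalized endpoint against dose, extracts
   IC50s and computes screen statistics (Z′, ANOVA, Tukey HSD).

All stages are deterministic: identical inputs produce bit-identical tables.

## Coordinate, time and unit conventions

Pixel coordinates are 0-based (row, col), origin top-left; well labels are
row-letter + 1-based column. t = 0 min is the first captured frame, taken as
the moment of magnet removal / compound addition. Intensities are floats in
[0, 1] (integer images divided by their dtype maximum; RGB collapsed to
Rec. 709 luminance). Areas are mm² via `area_px2 · mm_per_px²`;
concentrations μM; rates mm²/min. The acquisition manifest maps filenames to
minutes explicitly — no timestamp parsing from filenames — and frames are
ordered by time regardless of file order. Missing frames are tolerated
everywhere downstream (the endpoint needs only ≥ 3 points in the window).

## Segmentation

Well regions are circular ROIs placed purely geometrically from an explicit
calibration (A1 center, grid pitch, analysis radius); no content-based grid
detection. Within each ROI:

* background = median intensity of the outer 20 % annulus of the ROI disk —
  a per-well estimate that absorbs smooth illumination gradients (vignetting)
  without global flat-fielding;
* candidate pixels = ROI pixels below Otsu's threshold of the ROI intensity
  distribution, accepted only if their mean is at least the contrast floor
  (default 0.05) darker than the background — otherwise the well reports
  area 0 with `no_object` + `low_contrast`, which guards empty wells where
  Otsu would split noise;
* cleanup = morphological opening with the radius-1 (plus-shaped) footprint,
  then hole filling; components labelled with 8-connectivity;
* the spheroid = the largest component; ties are broken by darker mean
  intensity, then by smaller centroid row/col, purely for determinism.

QC flags: `multi_object` when a second component of ≥ 4 px survives cleanup;
`touches_roi_boundary` when any spheroid pixel lies on the ROI's outer
~1.5-px ring (the measurement is retained but the area is likely clipped).
Circularity is `4πA/P²` (capped at 1) with the perimeter from
`skimage.measure.perimeter`, a weighted boundary-count estimator; rasterized
disks of radius ≥ 10 px score ≥ 0.9. Degenerate well content never raises —
hard errors are reserved for structural problems (frame-size mismatch,
calibration placing an ROI outside the frame).

Throughput: a 96-well × 151-frame series at 1200×800 px segments in well
under a minute on one CPU (ROIs are small crops; all operators are
C-backed).

## Endpoint: contraction rate

Per well, points flagged `no_object`/`low_contrast` are dropped (boundary
touches are kept; configurable), and the closed-form OLS slope of area vs
time is computed over points with t ≤ window, window boundary inclusive
(default 150 min; with 4-min sampling the t = 150 frame does not exist, but
inclusivity is declared rather than left to sampling accidents). The endpoint
is the negated slope, so contraction is positive and a full toxic block gives
≈ 0. No smoothing is applied before the fit. A constant series reports rate 0
with R² = 0 (the undefined 0/0 case is mapped to 0). Wells with < 3 usable
points are excluded with a warning, never an exception.

Normalization divides each rate by the mean vehicle rate of the matching
solvent group (PBS- and DMSO-vehicle families are analyzed separately; the
layout's optional `solvent` column defines the grouping, and a layout without
it forms a single group). Normalization fails loudly when a group has no
vehicle rates or their mean is ≤ 0 — a non-contracting vehicle means the
assay itself failed. Whether rates should be fitted on raw areas or on areas
pre-scaled by A(0) is not determined by the assay definition; the default
fits raw areas (normalization across wells then cancels amplitude), and
`FilterConfig(normalize_to_initial=True)` provides the per-series variant.

## Dose-response and screen statistics

The Boltzmann sigmoid `f(x) = A2 + (A1−A2)/(1+exp((x−x0)/dx))` on
x = log10(c/μM) is fitted by least squares with a deterministic multi-start
protocol: x0 initialized on a 5-point grid over the tested log-concentration
range, A1/A2 from the extreme-dose response means, dx from span/4; bounds
keep dx > 0; the best converged start wins, and parameter standard errors
come from the Jacobian at the solution. Vehicle (c = 0) responses are
anchored one decade below the lowest tested dose rather than discarded —
they are the best estimate of the top asymptote. Requirements: ≥ 4 distinct
positive doses and non-flat responses. IC50 ≡ `10^x0`, the transition
midpoint of the standard Boltzmann parameterization (for this symmetric
form the absolute half-response point coincides with it; the config option
exists for interface parity). Fits use all replicate points by default;
`use_means=True` fits per-concentration means.

Z′ uses sample standard deviations (n−1) and is undefined (signalled
distinctly) at equal means; it is computed on normalized rates. ANOVA is the
classical between/within decomposition with p from the F distribution; Tukey
HSD uses `q = |Δmean| / sqrt(MSW/2 · (1/nᵢ + 1/nⱼ))` with p-values from
scipy's studentized-range distribution (numerical integration). The screen
report runs, per compound: ANOVA over vehicle + concentration groups, then —
only if significant at α (default 0.05) — Tukey vs vehicle and the Boltzmann
fit; the IC50 is reported only with a significant ANOVA and a converged fit,
otherwise the compound is "n.s." (or "unevaluable" with a single
concentration). This is why a flat negative control never yields an IC50.

## Synthetic plate generator

The generator exists to give every stage a known answer; its defaults encode
the assay's stated acquisition conditions (4-min frames for 10 h, n = 3
replicates per concentration, one spheroid per well, bright field with
vignetting and noise).

**Kinetics.** Area follows a mono-exponential approach to an asymptote,
`A(t) = A_inf + (A0−A_inf)·exp(−k(c)·t)`, with the rate constant responding
to dose through a logistic in log10 c between k_top (no drug) and k_bot
(saturating drug); k(0) ≡ k_top. This is the simplest form that reproduces
observed contraction curves and admits analytic ground truth; it is a
synthetic-data device, not a mechanistic claim. Defaults: A0 = 1.8 mm²,
A_inf = 0.72 mm² (60 % contraction), k_top = 0.01 min⁻¹ (≈ 69 min
half-time, contraction essentially complete within the 10 h window),
slope_s = 0.3 decades.

**Ground truth.** Per well the generator stores the noiseless trajectory,
the secant rate (A(0)−A(W))/W, and the true OLS rate — the negated OLS slope
of the noiseless sampled trajectory over the window, which is the quantity
the pipeline estimates (for a convex decreasing curve it differs from the
secant, so both are recorded). The per-compound true IC50 is the half-effect
concentration of the noiseless normalized-OLS-rate dose-response curve,
solved numerically: because the endpoint is a saturating function of k, its
half-effect point is shifted from the rate-constant logistic's own midpoint,
and quoting `10^log_ic50` as "truth" would build that bias into every
recovery check. `ContractionModel.with_half_effect` inverts the map so
scenario IC50s can be placed exactly on a chosen concentration scale.

**Rendering.** One filled dark disk per non-empty well (radius
`sqrt(A/π)/mm_per_px`) at the calibrated well center with per-frame,
per-well jitter ≤ 5 % of pitch; optional dark rim annulus (off by default);
multiplicative radial vignette over the whole field (illumination model);
additive Gaussian noise; clipping to [0, 1]; 8-bit PNG output. All
randomness derives from one master seed via per-frame Philox substreams, so
experiments (including dropped-frame variants) are bit-reproducible.
Spheroids are perfect disks — projected area is the only measured quantity —
so boundary roughness, disintegration at high doses, debris and focus drift
are deliberately absent. Passing tests therefore validate the computational
pipeline, not robustness to those real-world artifacts; the default
synthetic calibration (0.05 mm/px, initial disk diameter ≈ ⅓ of the well
pitch, radii spanning ≈ 9.5–16 px) is a documented stand-in for a user
measurement, since real capture geometry varies by device.

**Default screen.** One 96-well plate: rows A–G hold seven compounds (ATRA
and dexamethasone in DMSO; doxorubicin, 5-fluorouracil, forskolin, SDS and
penicillin-G in PBS; SDS as positive control, penicillin-G as dose-flat
negative control) at four concentrations × three replicates per row — a 1:6
serial dilution from ~8× the intended IC50 (top dose 5.98 mM for the
negative control) — and row H holds six PBS + six DMSO vehicle wells. True
endpoint IC50s are placed at 82.8, 84.6, 46.7, 253, 4.7 and 281.8 μM,
spanning the 1–500 μM range typical of such screens. Four doses plus the
anchored vehicle group is the minimum the fit contract accepts on a single
plate; with the default noise (sd 0.02, vignette 0.15) recovery errors are
≈ 0.006 log10 units, so the design leaves ample headroom.

## Numerical choices and edge cases

* OLS is the exact closed form (centered sums), no iteration; agreement with
  a direct-summation oracle is at the 1e-12 level.
* Otsu on a uniform ROI cannot split classes → `no_object`, never an error.
* The Boltzmann model and the dose→rate logistic are evaluated through the
  numerically stable `expit`, safe at extreme doses.
* Half-effect inversion uses Brent's method on the monotone endpoint-vs-k
  map (xtol 1e-15), then the analytic logistic inverse.
* CSV readers use round-trip float parsing so written tables reload to the
  last ulp; measurement tables round-trip to < 1e-9 by test.
* Tie-breaks (equal-area components) and orderings (wells row-major, frames
  by time) are fixed so every output is deterministic.

## Known limitations

Calibration is a required input: there is no automatic grid detection, plate
detection or magnification estimation. Segmentation assumes one dominant
dark object per well with strong contrast; overlapping debris, bubbles or
fragmented spheroids will be flagged (`multi_object`) but not resolved. The
endpoint is strictly the initial-window linear rate; no full-curve kinetic
model is fitted. The Boltzmann fit assumes a monotone sigmoid response;
biphasic dose-responses are out of scope, as are mixed-effects models and
multiple-testing corrections beyond Tukey.
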
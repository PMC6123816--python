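# Methods

## Scope

`electroablate` implements the quantitative analysis by which pH modulation is
established as the mechanism of cell death in electrolytic ablation: spatial pH
and voltage fields are reconstructed from scattered probe measurements,
transmembrane potentials are estimated from the voltage field, the delivered
charge is integrated from current traces, dead regions in live/dead fluorescence
images are segmented and summarized by fitted ellipses, the "viability boundary
pH" is read off along those ellipses, and conditions are compared with Welch
t-tests, one-way ANOVA, and Bonferroni adjustment.  Because the raw experimental
measurements are not bundled with the package, every stage is exercised against
a physics-based synthetic phantom whose generative model is described below.

## The phantom

One phantom emulates one ablation in a buffered cell-encapsulation dish
(agarose gel with cells, a 6 cm dish) with needle electrodes held 1.5 cm apart
at 10 V for 90 s in the baseline condition.

**Current and charge.**  The dish presents an apparent resistance
R(B) = R₀·(1 + k·(B − B₀)) where B is the HEPES concentration (mol/L),
B₀ = 10 mM, and R₀ = 900/0.726 Ω ≈ 1239.7 Ω is calibrated so the baseline
trace (constant I = V/R sampled every 10 s for 90 s) integrates — by the same
trapezoid rule the analysis uses — to exactly 0.726 C, the reference total
charge for 90 s ablations.  The slope k = 3 L/mol makes charge fall with
buffering (an apparent impedance increase), while keeping a measurable ablation
zone in all three standard conditions (10/50/200 mM); at k = 3 the 200 mM
condition delivers ≈ 0.46 C.  Two seeded noise sources act on the trace: a
per-assay multiplicative resistance factor (SD 5%, reproducing the few-percent
dish-to-dish scatter of delivered charge, e.g. ±41 mC around 726 mC) and
additive per-sample meter noise (SD 0.2 mA).

**Electrolysis and pH.**  Water electrolysis yields one mole of hydroxide per
mole of electrons at the cathode (2H₂O + 2e⁻ → H₂ + 2OH⁻) and one mole of
hydronium per mole of electrons at the anode (6H₂O → 4H₃O⁺ + O₂ + 4e⁻), so each
electrode deposits Q/F moles (F = 96485 C/mol, unit Faradaic efficiency; side
reactions such as chlorine species and ROS are ignored).  The deposit spreads
as a 2D Gaussian areal density with σ = 2 mm, divided by the 1.5 mm gel
thickness to give a volume concentration; post-ablation diffusion for t minutes
widens the Gaussian variance by 2·D·t with D = 0.3 mm²/min (the order of the
hydroxide diffusivity, 5×10⁻⁹ m²/s).  The signed net strong acid at each point
is titrated against a single monoprotic buffer (HEPES, pKa 7.48, initialized at
pH 7.4; the gel's other buffering capacity is folded into this one term) by
solving the electroneutrality condition

    [H⁺] + b₀ − n = K_w/[H⁺] + B·K_a/(K_a + [H⁺])

for pH by bisection on [0, 14] to 10⁻⁶ (b₀ is the counter-ion concentration
implied by the initial pH, n the added net strong acid).  The resulting pH is
monotone non-increasing in n and its excursion from 7.4 shrinks as B grows —
the two properties the buffering experiment rests on.

**Voltage.**  Each electrode contributes a signed −ln r line-source potential
(clamped at its 0.25 mm surface).  The superposition is scaled so that the
anode-minus-cathode surface difference equals the applied voltage times a gel
fraction of 0.02 — most of the applied 10 V drops at the electrode interfaces,
leaving millivolt-scale gradients in the gel — and shifted to zero at the
anode–cathode midpoint.  The fraction is a free parameter of the phantom; 0.02
puts the maximum transmembrane estimate in the low-millivolt range, orders of
magnitude below the ~1 V electroporation threshold.

**Measurement template.**  pH and voltage are probed at 85 sites: per
electrode a polar grid of 8 angles × 5 radii (2, 4, 6, 8, 10 mm), plus 5 sites
on the perpendicular bisector of the electrode pair (±10, ±5, 0 mm).  The
published experiment also used 85 sites but their coordinates are not
tabulated; this symmetric layout is a deterministic stand-in.  pH is sampled
twice per site (SD 0.1), voltage four times (SD 1 mV), with seeded Gaussian
noise.

**Viability images.**  Cells die where pH < 4.8 or pH > 10.6 (the programmed
viability window).  The renderer emits a two-channel 16-bit image over the
dish bounding box at 50 µm/pixel: live pixels green-high/red-low (45000/5000),
dead pixels the reverse, with seeded Gaussian channel noise (SD 2% of full
scale).  The world transform maps pixel (0, 0)'s center to the dish corner
plus half a pixel; rows increase along +y.

## Analysis stages

* **fields** — replicates are averaged per site; voltage is re-centered by
  subtracting the interpolated value at the electrode midpoint (the signed
  field feeds the gradient; its magnitude is the reported view).  "2D linear
  interpolation" is made concrete as barycentric-linear interpolation on the
  Delaunay triangulation (scipy `LinearNDInterpolator`), rasterized at 0.1 mm
  with cells outside the convex hull masked; no extrapolation.  Iso-contours
  come from marching squares.  Linear interpolation is exact on affine fields
  and at the sites, and never overshoots triangle vertex values.
* **electro** — charge is the trapezoidal integral of the trace; apparent
  impedance is V over the time-averaged current (quasi-static, no reactive
  part).  The transmembrane potential is |∇V| × 14.2 µm (the mean cell
  diameter), with mask-aware central differences (one-sided at hull edges);
  the gradient is computed at raster resolution rather than by differencing
  at exactly 14.2 µm offsets — equivalent for a piecewise-linear interpolant
  away from triangle edges.
* **viability** — dead = red ≥ threshold AND green ≤ threshold (Otsu per
  channel by default; the original workflow's manual ImageJ thresholds are
  not published, so thresholds are overridable).  The mask is closed then
  opened (3×3), 8-connected components below 0.5 mm² are dropped, and each
  zone is attributed to its nearest electrode; components straddling the
  electrode partition are split there so one ellipse is fitted per electrode.
  The outer contour is lightly smoothed (circular moving average, window 5)
  to suppress the marching-squares staircase — this restores circle
  perimeters to within 0.5% while biasing a 5 mm radius by < 0.2 µm — and an
  ellipse is fitted by stable direct least squares (Halir–Flusser), with a
  second-moment fallback for degenerate contours.  The boundary pH is the
  mean of 360 uniform-parameter samples of a pH raster along the ellipse
  (uniform parameter rather than arc length changes the mean by < 0.05 for
  the eccentricities seen here).
* **stats** — sample (n−1) SDs; Welch's two-sided t with Satterthwaite df;
  classic one-way ANOVA (the printed df of the reference analyses imply the
  equal-variance flavor); Bonferroni min(1, m·p).  Report rounding is
  half-up; raw values are always retained.

## Boundary pH: reconstruction vs generative field

The pipeline reports the boundary pH twice per zone.  `boundary_ph_measured`
samples the 85-site reconstruction — the faithful analogue of reading the
contour map.  `boundary_ph_field` samples a fine raster (0.02 mm, chosen by a
grid-convergence check: halving to 0.01 mm moves values by ≤ 0.03 away from
front-limited cases) of the phantom's own generative pH field.  Threshold
recovery is assessed on the latter: with 2 mm site spacing across a front of
~8 pH/mm (cathode side) to ~100 pH/mm (anode side), piecewise-linear
interpolation between sites is biased by more than 1 pH unit at the margin.
That bias is a property of the sampling design, not of the estimator, and the
real experiment is far less sharp (probing takes a minute per dish, during
which diffusion relaxes the front).

The two sides are not equally recoverable.  At pH 10.6 the free hydroxide
(4×10⁻⁴ M) dominates the local buffering of the titration curve, so the basic
front crosses its threshold at ~8 pH/mm and the cathode boundary pH is robust
to boundary-localization error (a 50 µm pixel ≈ 0.2 pH).  At pH 4.8 the free
hydronium is only 1.6×10⁻⁵ M, the acid front crosses at ~100 pH/mm, and ±0.3
pH corresponds to ±3 µm of localization — at the information limit of the
50 µm pixel grid even though the ellipse fit localizes the boundary to ~3 µm
by averaging ~500 boundary pixels.  Noise-free recovery is therefore exact in
pooled terms (cathode 10.60, anode 4.66 across the three buffering presets)
and per-phantom on the baseline (10.59/4.78), while individual anode readings
scatter by up to ~0.35 around 4.8.

## What the phantom does and does not emulate

It emulates: charge-dose-dependent acid/base generation, buffering-dependent
pH excursions, contraction of the dead area and of the delivered charge with
increasing HEPES, expansion of the dead area with post-ablation diffusion,
sub-electroporation voltage gradients, dual-reporter viability images, and
seeded measurement noise at realistic scales.  It does not emulate: reaction–
diffusion transport during the ablation itself (deposits are instantaneous
Gaussians), electrode kinetics and overpotentials, 3D structure through the
gel depth, thermal or electroosmotic effects, ROS chemistry (only the
region-vs-background log₂ fold change statistic is provided), or cell-scale
image texture.  Passing tests therefore certify the analysis machinery and
the qualitative physics, not the biology of any particular cell line.

Temperature is emitted as a constant 22 °C field: electrolytic ablation is
non-thermal at these doses and the analysis only ever summarizes temperature
as mean/SD.

## Scenario presets

`baseline` (10 mM HEPES), `hepes50`, `hepes200`, `diffusion60` (90 s ablation
followed by 60 min of diffusion), and `multicathode` (eight cathodes on a
1 cm ring around a central anode, 10 V, 10 s).  The diffusion preset keeps
the baseline 90 s dose: under a mass-conserving Gaussian spread, a 10 s
deposit falls below the lethal threshold as it widens instead of expanding
the zone, so the longer dose is the configuration that exhibits the
documented zone expansion (the expansion is monotone up to ~75 min, after
which dilution wins).  The multicathode preset has no 85-site template, so
the scattered-field stages are skipped for it.

## Numerical choices and degenerate inputs

Bisection (pH tolerance 10⁻⁶) is bracket-checked and raises a diagnostic
error outside [0, 14]; loads ≥ 10 mol/L are rejected.  Duplicate sites within
10⁻⁹ mm and collinear site sets are rejected before triangulation; Delaunay
ties fall to scipy's deterministic rule.  Rasters snap their origin to the
spacing lattice so refined rasters share nodes.  Contour levels outside a
raster's range yield empty lists, not errors.  Ellipse fits require ≥ 5
points with 2D spread.  Boundary-pH extraction requires ≥ 50% of samples
inside the valid raster region.  Pipeline runs are pure functions of
(config, seed): a root seed spawns per-stage substreams, and rerunning a
configuration reproduces byte-identical summary JSON.

## Problem sizes

The shipped tests and the study runner use the native experiment geometry
(60 mm dish at 50 µm/pixel, i.e. 1200×1200 images; 85 sites; 10-sample
traces) and three conditions with 2–4 replicates; the full suite runs in
about one minute on one CPU.
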
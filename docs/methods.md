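# Methods

This note records the model, the algorithmic choices and their rationale,
what the synthetic data do and do not emulate, and the package's known
limitations. It documents how the code computes; every number quoted
elsewhere (README, tests) is produced by running the code.

## Irradiance model

Each fiber is an ideal Lambertian emitter of exponent m, derived from the
viewing half-angle θ½ by m = −ln2 / ln cos θ½. The irradiance contributed
at a sample-plane point P by a source at S (spherical pose R, θ, φ about
the origin; boresight aimed at the origin) is

    E = max(0, cos ψ)^m / |S − P′|²

with cos ψ the angle between the boresight and the ray S→P′. The `max(0, ·)`
clamp handles points behind the emitter hemisphere: the raw cosine is
negative there, and a non-integer m would otherwise produce complex
values. Relative units only: unit on-axis amplitude with inverse-square
falloff; absolute radiometry is out of scope.

Two conventions for the beam-center shift (dx, dy) are implemented:

* `translate` (default): the evaluation point is shifted,
  P′ = (x − dx, y − dy, 0) — the dx=dy=0 pattern rigidly translated.
  This is the convention the rest of the package assumes.
* `aim`: the boresight is re-aimed at (dx, dy, 0), so an off-center spot
  is dimmer and more elongated (longer, more oblique throw). This is the
  physically faithful picture of tilting a fiber; both conventions agree
  exactly when dx = dy = 0. In practice the two give very similar design
  optima; `translate` is kept as the default because the shift then has a
  clean closed form independent of the rest of the pose.

The sample plane is rasterized cell-centered on a grid covering either
the uFOV or the 3× comparison region; 0.1 mm pitch during optimization
(cost evaluations), 0.05 mm for final rendering. Halving the pitch
changes the cost terms of a converged design by < 0.5 %, so the coarse
search grid does not move optima materially.

## Net field normalization

The net field sums per-fiber fields normalized against an on-axis
reference at a short working distance (R = 5 mm, the "as close as
practical" configuration):

* `reference` (default): E_net = Σ E_n / mean(E_ref,n). Each fiber is
  divided by a per-emitter constant, so a fiber twice as far away
  contributes a quarter of the power — physical 1/R² weighting is
  preserved. This is what makes power-density comparisons between designs
  meaningful.
* `field`: E_net = Σ [E_n / mean(E_n)] · mean(E_ref,n). Every fiber is
  rescaled to contribute the same regional mean; useful for analysing
  pattern shape in isolation from throw distance, but it flattens all
  power differences by construction.

The normalization region is an argument: design optimization uses the
uFOV; rendering and cross-design power comparisons use the full rendered
frame (all designs being compared are rendered on one common frame so the
normalizing constants are identical and the comparison reduces to raw
power). The package's own design studies use an 18 × 18 mm comparison
frame at 0.05 mm pitch — the 3× region of the 6 × 6 mm design, which also
covers the 4 × 12 mm one.

## Design cost

The combined cost minimized over all 5N pose parameters is

    CF = [1 − mean(E_u)/max(E_u)]  +  mean(E_L) / mean(E_u)

with E_u the net field over the uFOV and E_L over the concentric
3×-larger region. The second (efficiency) term is oriented so that
*minimization* rewards confinement; the literal reciprocal orientation is
available behind `efficiency_mode="literal"` but rewards spilling light
when minimized, contradicting its stated purpose, so it is not the
default.

`term_normalization` controls one further choice: with `per_region` (the
default) E_u and E_L are each normalized by the reference mean taken over
their own region. Because the short-distance reference beam lands almost
entirely inside the uFOV, its mean over the 3× region is ≈ 9× smaller,
which weights the efficiency term by ≈ the area ratio and makes
confinement count on a par with uniformity. With `common`, both terms are
formed from one uFOV-normalized field; the efficiency term then spans
only [1/9, 1] and the optimizer trades confinement away for marginal
flatness gains, yielding spread, low-power designs whose character does
not match validated close-in reference placements (see `reference.py`).
`per_region` is therefore the default.

The coefficient-of-variation baseline cost is population std/mean within
the uFOV (`cv_mode="var"` gives variance/mean, a definition that also
circulates); it contains no confinement pressure at all, which is
precisely the deficiency the combined cost corrects — optimizing it
parks fibers at maximum distance and spreads flat, dim tails across the
target region.

## Optimizer

Genetic seeding followed by generalized pattern search (GPS), all in
[0, 1]-normalized coordinates (azimuths periodic):

* GA: tournament selection (k = 3), uniform crossover (p = 0.5), Gaussian
  mutation (σ = 0.1 of range, per-gene rate 0.2), one elite;
  population 120 × 80 generations by default (≈ 10 000 evaluations).
* GPS: opportunistic polling of the 2d signed coordinate directions
  (last successful direction first), mesh ×2 on success (capped at 1),
  ×0.5 after a full failed poll; initial mesh 0.25.
* Termination: mesh < 1e-6 (the usual exit), accepted step below the step
  tolerance with a comparably small mesh, or the 50 000-evaluation budget.
* Budget is shared between phases; all randomness flows from one integer
  seed, so a (config, seed) pair reproduces bit-identically.

A four-fiber design (20 parameters, 0.1 mm search pitch) takes roughly
10 000–15 000 cost evaluations and under a minute on one CPU.

The cost surface is multimodal with families of near-equivalent optima
(fiber relabelings, azimuthal rotations for square targets, and genuinely
distinct arrangements within ~2 % of each other in cost). Independent
seeds therefore converge to similar but not identical fields; the
repeatability study quantifies this with pairwise Pearson correlations of
the final uFOV fields.

## Half-angle calibration

`fit_half_angle` minimizes the sum of squared differences between the
max-normalized measured frame (after subtracting a constant background,
default the 1st percentile) and the max-normalized simulated field of the
known pose, over θ½ ∈ [1°, 30°], with scipy's bounded scalar minimizer
(Brent-style; xatol 1e-6°). Max-normalization is used because absolute
detector gain is unknown. The objective is unimodal on this interval for
realistic poses (verified by dense scans on fixtures). A fit landing on a
search bound raises rather than returning silently — that outcome means
the model cannot explain the frame, not that the bound is the answer.
Noise-free synthetic frames are recovered to < 0.01°; 8-bit frames at
30 dB peak SNR to < 5 % relative.

## Metrics conventions

* Uniform region: pixels ≥ 90 % of the frame maximum ("within 10 % of
  max"); axis-aligned bounding box of the largest 8-connected component;
  ties resolve to the component containing the argmax, then smallest
  row/column.
* Gradient maps: optional Gaussian pre-smoothing with σ = window/6 (a
  "window = 50 pixels" neighborhood ≈ ±3σ support), then central
  differences (one-sided at borders).
* Histograms: density-normalized, intensities divided by the *reference*
  configuration's maximum so different designs share one axis.
* Flat-field correction: standard slide max-normalized and floored at
  0.05 before pixel-wise division; pixels below the floor are reported in
  a validity mask rather than silently corrected.
* Probe contrast: each specific-probe pixel divided by the grand mean of
  all nonspecific images; survival = 1 − ECDF per image on a common
  ratio grid, summarized as mean ± SEM across images (images, not
  biopsies, are the averaging unit here); cohort comparison by two-sample
  Kolmogorov–Smirnov on the pooled pixel ratios.
* Population moments for the CV; OLS for linearity (slope, intercept, R²).

## Synthetic data

The detector model is linear: expected DN = gain × illumination ×
fluorophore map, optional Poisson shot noise and Gaussian read noise
(default σ = 1 DN), clipping and rounding to 8 or 16 bits. A gamma hook
exists but defaults off (the validated camera is linear). Generators:
standard slide (uniform fluorophore under a given field, exposed to 90 %
of full scale), 41-step OD 0.1–4 wedge (transmission 10^−OD), 0–25 µM
six-level dilution series with three replicates and a linear
9 DN/µM response over a 2 DN background, degraded "unoptimized"
configurations, and pre/post-injection pairs with a known uptake fold
inside a mask. The +6 mm z-shift construction translates each fiber
vertically with its *orientation fixed*, as raising a physical fiber
holder does: the source keeps its lateral position while each beam axis
crosses the plane beyond its old aim point (center displacement
(dz/Sz)·((dx, dy) − S_xy)), which is what destroys the pattern's
uniformity; the dx = dy = 0 construction collapses all beam centers onto
the origin.

What the synthetic twins do **not** emulate: optical scattering and depth-
dependent attenuation in tissue (a phantom's scattering enters only as a
gain factor), defocus/PSF blur, chromatic effects, detector nonlinearity,
fixed-pattern noise, and specimen registration error. Tests passing on
synthetic data therefore validate the computational pipeline — geometry,
normalization, estimators, statistics — not the fidelity of any physical
camera.

## Numerical details and degenerate inputs

* cos^m is computed as exp(m·log cos ψ) on the strictly positive cosine
  subset; zero elsewhere.
* Half-angles below 0.1° are rejected (m > ~10⁶ underflows the beam to a
  delta spike narrower than any realistic raster).
* Grids must have ≥ 3 samples per axis; a grid point coinciding with a
  source position is an error rather than an infinity.
* The efficiency term requires non-zero regional means; the CV and
  mean–max terms require a non-zero mean/max in the uFOV.
* Pattern-search polls whose bound-clipped step is below the step
  tolerance are skipped as no-ops (they cannot change the incumbent).

## Known limitations

* The Lambertian exponent is the only beam physics modeled: no fiber NA
  profile, no Gaussian-beam divergence, no Fresnel effects at oblique
  incidence. Close-in designs (R near 12.5 mm) are where a real fiber
  deviates most from the cos^m idealization.
* The optimizer guarantees a mesh-converged local optimum seeded by a
  global scan, not the global optimum; distinct seeds can settle in
  distinct members of the near-optimal family. Published reference
  placements for the high-aspect-ratio problem correspond to one such
  family at larger throw distances; this implementation's deeper search
  typically finds better-confined close-in solutions of lower cost, so
  cross-design power ratios measured on its own optima differ from those
  measured between the historical reference designs (the reference-design
  comparison is preserved as a fixture test).
* Survival-curve SEM treats images as independent replicates; spatial
  correlation within an image is ignored.
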
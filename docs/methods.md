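# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `cardiomorph`. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Cardiomyocyte morphometry

### Descriptor estimators

The irregularity index is the linear combination
`CII = aspect − area/box + roundness + radius ratio`. The four descriptor
names are standard image-analysis measurement labels; where several
estimator variants exist we chose the ones below and validated them on
rasterised circles and ellipses (see the acceptance tests):

- **aspect** — major/minor axis ratio of the second-moment equivalent
  ellipse (scikit-image region moments). Robust to rasterisation and
  rotation.
- **perimeter / roundness** — the region's subpixel 0.5-level contour
  (marching squares) is smoothed with a periodic moving average whose
  window scales with contour length (≥5 vertices, ~1/60 of the contour);
  the perimeter is the smoothed polyline length and
  roundness = perimeter²/(4π·contour area). A raw pixel-edge perimeter
  overestimates circle roundness by ~8–10% and, worse, is not stable under
  nearest-neighbour rescaling; the smoothed-contour length is accurate to
  <1% for circles of radius ≥ 15 px and drifts <2% under 2× upscaling.
- **area/box** — smoothed-contour polygon area divided by the area of its
  *minimum rotated* bounding rectangle (shapely). An axis-aligned box makes
  the quantity swing by ~20% as an elongated cell rotates (analytically,
  πab/4 over the rotating box extents), which would leak image orientation
  into a shape score; the rotated box keeps the ellipse value π/4 at every
  orientation and preserves the circle fixed point.
- **radius ratio** — max/min distance from the region centroid to the
  smoothed contour.
- **area** — pixel count × pixel_size². Reported in µm² when a calibration
  is supplied, px² otherwise (default pixel_size = 1).

A perfect circle sits at (1, π/4, 1, 1), CII = 3 − π/4 ≈ 2.215; all
descriptors respond monotonically to irregularity (aspect, roundness and
radius ratio increase, area/box decreases). Regions under 20 px are
rejected as unstable, and border-touching regions are excluded by default
since their cross-section is truncated.

### Thresholds and classification

Thresholds are derived from a measured control (healthy) population:
`area_low`/`area_high` are area percentiles and `cii_high` a CII
percentile. The defaults are the **1st/99th area percentiles and the 99th
CII percentile**. The gating is reference-population gating in the spirit
of nuclear morphometric analysis, where the "normal" region of the
size-vs-irregularity plane is drawn to *enclose the control cluster*.
Central-coverage gates such as 5/95/95 are deliberately not the default:
empirical quantile gates always exclude exactly their nominal tail mass of
the control-like population, so a 90%×95% gate misclassifies ≈14.5% of
genuinely normal cells *by construction* and biases the normal-class
percentage of any animal downward by ~10 points. With the 1/99/99 defaults
the built-in bias is ≈3 points, within the sampling noise of a 500-cell
animal. The quantile configuration is exposed (`QuantileConfig`) for
sensitivity analyses.

Classification is deterministic on the (area, CII) plane: atrophic below
the band, hypertrophic above, irregular above the CII cutoff; values
exactly equal to a threshold take the non-extreme branch (measure-zero
under continuous data, but it makes the map total and reproducible). The
six classes N/I/HR/HI/AR/AI partition the plane exhaustively.

Per-animal profiles report class percentages (forced to close to exactly
100), mean CII, and **area variability as the coefficient of variation** of
cell area — unitless, hence comparable across animals and calibrations;
the variance is recoverable from the profile if needed. Profiles warn (not
fail) below 50 cells, mirroring the ≥50-cells-per-animal acquisition
convention.

## Collagen quantification

Per field, stained pixels are those with red dominance
`R − (G+B)/2` above a threshold; by default the threshold is Otsu's on the
dominance image, floored at 60 (8-bit units) so that a stain-free field is
not split into a phantom stain class. An HSV hue-window rule is available
as an alternative. Both a stained **area fraction** (primary: robust to
illumination) and a mean stain **intensity** (secondary) are reported;
published "staining intensity" values from morphometric fibrosis readouts
are in arbitrary units and are not matched in scale. Animal scores are the
arithmetic mean over fields (sample SD as dispersion); the implementation
sorts values before aggregating so the score is exactly
permutation-invariant. A field count other than the conventional 10 per
animal warns.

## Atherogenic ratios

CRI-I = TC/HDLc, CRI-II = LDLc/HDLc, AC = (TC − HDLc)/HDLc. AC ≡ CRI-I − 1
is enforced as a validation invariant at 1e-12. The ratios are invariant to
any common concentration unit; HDLc ≤ 0 is a hard error naming the animal.

## 2^−ΔΔCt fold changes

ΔCt = Ct(target) − Ct(normalizer) per sample, against the cel-miR-39
spike-in. ΔΔCt subtracts the **arithmetic mean** reference-group ΔCt per
target — equivalently the geometric mean in fold space — so reference-group
folds have geometric mean exactly 1. Technical replicates are averaged at
the Ct level (cycle space) before ΔCt. Folds are exactly invariant to any
global shift of the normalizer Ct (spike-in amount cancels). No
amplification-efficiency correction is applied: the method is plain
2^−ΔΔCt. Whether group summaries should be means or medians of per-sample
folds is left to the statistics module, which summarises per-sample folds
by route.

## Group statistics

Route selection: Shapiro–Wilk per group at 0.05; **all** groups must pass
for the parametric route (one-way ANOVA + Tukey HSD), otherwise
Kruskal–Wallis + Dunn. The gate needs ≥3 values per group. A zero-variance
group makes Shapiro–Wilk undefined; such variables are flagged and forced
nonparametric. Because each group passes Shapiro–Wilk with probability
0.95 under a Gaussian null, k Gaussian groups route parametric at rate
0.95^k (≈0.77 for five groups), and the composite path is mildly
conservative: the nonparametric branch, conditioned on a failed gate, sits
below its nominal size, so the overall type-I rate measures slightly under
α (the acceptance run reports it at 2000 null replicates).

Dunn's test is implemented directly (no maintained implementation exists in
the installed stack): pooled mid-ranks, tie-corrected pairwise z statistics
`z = (R̄_i − R̄_j)/sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
two-sided normal p-values, Holm adjustment by default (none/Bonferroni
configurable, recorded in the output). Tukey HSD defaults to the exact
studentized-range distribution via statsmodels; a fast interpolated
variant (`tukey_method="approx"`, statsmodels `psturng`, accurate to ~2–3
decimals) exists for simulation studies where thousands of comparisons are
run.

The compact letter display uses insertion-and-absorption: one letter class
covering all groups, split on every significant pair, subset classes
absorbed; the result satisfies share-a-letter ⟺ adjusted p ≥ α, which the
validation experiment re-verifies pair-by-pair on every replicate. Groups
are processed in input order, making the lettering deterministic.

Summaries follow the route: mean ± SD for parametric variables, median
(25th–75th) otherwise.

## Synthetic data generator

The generator exists to give every analysis stage a ground truth; its
defaults are chosen once as realistic study conditions.

- **Cells**: noisy ellipses — an ellipse with class-dependent elongation,
  radially perturbed by random Fourier harmonics (orders 2–6) with RMS
  amplitude `boundary_noise`, renormalised to the nominal area so boundary
  noise does not inflate cell size. Classes: normal-size 300 ± 40 µm²
  (hypertrophic 550 ± 60, atrophic 120 ± 20); regular shapes elongation
  1.3 ± 0.15 with noise 0.02, irregular 2.3 ± 0.3 with noise 0.10. Default
  calibration 0.35 µm/px keeps even atrophic cells above the ~15 px radius
  where rasterised descriptors are reliable. Placement is dart-throwing
  with a 2 px margin on bounding circles (cells must not merge, since the
  analysis measures single cells); the field is auto-sized to a 0.24
  bounding-circle packing, and an unplaceable request errors with the cell
  count achieved. Rendering is deterministic given (truths, seed), with
  per-cell streams keyed by cell id.
- **Collagen fields**: a Gaussian random field (white noise smoothed at a
  6 px correlation length) thresholded at the exact quantile, so the
  rendered stain share equals the requested fraction to ±1 pixel; stain
  (165,35,45) vs background (225,215,190) colours are separable by the
  default red-dominance rule with margin.
- **Serum panels**: symmetric analytes are Gaussian; skewed analytes are
  log-normal with median at the location parameter and log-SD
  `sqrt(log1p((scale/loc)²))` (CV matching), the minimal right-skewed
  family consistent with median/IQR-style reporting.
- **Ct tables**: per sample, normalizer Ct ~ N(21, σ) and target
  Ct ~ N(base − log₂(fold), σ); the group mean of 2^−ΔΔCt then recovers
  the requested fold up to the small log-normal mean bias (exp(σ²ln²2/2),
  <2% at σ = 0.28 effective ΔCt noise). A designated reference group with
  fold exactly 1 is required.

Every generator requires an explicit seed and refuses to randomise
silently; equal spec + seed gives byte-identical output.

**What the generator does not emulate**: real H&E/picrosirius texture,
staining and illumination variability, touching or overlapping cells,
out-of-plane sectioning angle, assay chemistry noise (Luminex/ELISA), or
amplification-efficiency differences between targets. Passing the
recovery experiments therefore demonstrates correctness of the measurement
and inference chain, not robustness to real-world acquisition artifacts —
on real images the mask-input path (or careful review of the watershed
fallback) is the supported route.

## Validation experiment scales

The built-in experiments (`cardiomorph.experiments`) use: mixture recovery
— 10 replicates of a 1000-cell control plus a 500-cell mixed animal,
rendered in 100-cell fields; collagen — 4 true fractions × 10 fields of
256²; fold changes — folds {0.5, 1, 4}, Ct noise SD 0.2, n = 30/group;
statistics size — 2000 Gaussian null replicates of 5 groups × 10, with the
fast Tukey variant. These sizes make the full validation run in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
tolerances asserted by the tests.

## Known limitations

- Descriptor accuracy degrades below ~15 px radius; the 20 px area floor
  rejects only pathological fragments, so very coarse calibrations should
  be avoided rather than relied on.
- The watershed fallback segmentation is a convenience, not a validated
  segmenter; curated masks are the first-class input.
- Quantile thresholds from small control populations (<100 cells) are
  noisy; the module warns but proceeds.
- Dunn p-values use the normal approximation (standard), which is liberal
  for very small groups (n < 5) with heavy ties.
- The letter display is minimal for the insertion-absorption construction
  but not guaranteed globally minimal in pathological significance
  patterns; it is always consistent (share ⟺ not significant).
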
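# Methods

## Silhouette measurement model

A silhouette is a binary raster with a physical scale (cm per pixel) and a
fixed orientation: the keel tip — the caudal apex of the sternum, the
vertex of the apex angle M4 — points toward increasing row index, the
convention produced by vertical-rotation preprocessing of carcass
photographs. Masks must be a single 8-connected foreground component of at
least 100 px.

**Landmarks.** The keel tip is the foreground point with maximal projection
on the caudal direction; the cranial end maximises the opposite projection.
Ties are broken by the smallest column index so output is deterministic.
The unit vector keel tip → cranial end defines the *breast axis*; M0 is the
landmark distance times the scale.

**Chords.** All widths are measured perpendicular to the breast axis, not
along raster rows, so a small residual tilt of the carcass does not bias
the keel-tip offset M2 = M0/5 or the caudal width M3 taken there. Whether
the original manual calipers were axis-perpendicular or image-horizontal is
not documented; the axis-perpendicular convention is adopted as the more
robust interpretation. A chord is found by sampling the mask bilinearly
along the scanline (0.25 px steps), locating the two outermost 0.5-level
crossings by linear interpolation, and taking their distance — an
outer-caliper width that bridges small concavities, as a manual width
measurement would. M1 is the maximal such chord over axis positions in
[0.5·M0, M0] from the keel tip (256 scanlines); restricting the search to
the cranial half keeps the caudal bulge out of M1.

**Angle and areas.** M4 is the angle at the keel tip subtended by the two
endpoints of the M3 chord (for a left–right symmetric shape this closes to
2·atan(M3/(2·M2))). M5 is the exact triangle area ½·M3·M2. M6 counts
foreground pixels (unit squares, by centre position; centres exactly on
the chord line count as cranial) on the keel side of the M3 chord line,
times the squared scale. M7 = M6 − M5 holds identically by construction,
and the ratios M8–M11 follow. Degenerate inputs are signalled, not
guessed: a scanline that never meets foreground, or a keel tip lying on
the chord (M4 undefined), raises `DegenerateSilhouetteError`.

At 0.05 cm/px these conventions recover closed-form rectangle and triangle
values within 2 % (lengths, areas) and 0.5° (angle); the dominant error is
the half-pixel ambiguity of the raster boundary. Doubling the scale doubles
M0–M3, quadruples M5–M7 and leaves M4 and the ratios untouched, exactly.

**Tabulated input.** `conformation_from_table` accepts measurement rows
(M0–M3 required or derivable, the rest optional), fills M2, M4, M5 via the
symmetric-apex closures when absent, derives M7 and the ratios, and — when
a recorded M7 disagrees with M6 − M5 by more than 0.05 cm² (beyond table
rounding) — warns and recomputes.

## Detection model

The positive event is a tactile score ≥ 2.0 (moderate/severe hardness), so
coefficient signs match the published convention. `BinaryLogit` maximises
the Bernoulli likelihood by IRLS/Newton with step-halving, stopping when
the relative log-likelihood change falls below 1e-10 (max 50 iterations);
the gradient at the optimum is verified below 1e-6 max-norm in the tests.
Standard errors come from the inverse observed information; per-term
inference is Wald χ² (matching "Pr > χ²" columns of classical logistic
platforms) rather than per-term likelihood ratios. Odds ratios are
exp(β), with percent-change phrasing 100·(exp(β)−1) for β > 0 and
100·(1−exp(β)) for β < 0.

Pathologies are reported, not papered over: collinear predictors raise
(condition number of the information matrix above 1e12); complete
separation — every observation perfectly classified with saturated linear
predictor, or diverging iterates — is flagged (`converged=False`,
`separation=True`) with a warning, because the unpenalised ML estimate
does not exist there and silently regularising it would change the model.

## Evaluation statistics

Classification uses the most-likely rule (p ≥ 0.5). MR, TPR (sensitivity),
FPR and specificity are confusion-matrix percentages; AUC is the
Mann–Whitney rank statistic with ties counted ½ (identical to exhaustive
concordant-pair counting, which the tests verify on all small datasets);
RMSE and MAD are taken between the predicted probability and the 0/1
outcome. The generalized R² is Nagelkerke's rescaled Cox–Snell,
[1−(L0/L1)^(2/n)]/[1−L0^(2/n)], the "Generalized RSquare" of the
originating software; on a validation split the null likelihood L0 uses
that split's own prevalence, and values below 0 (fit worse than null) are
floored at 0.

The 70/30 training/validation split stratifies on the four ordinal-score
bins {0, 0.5}, {1, 1.5}, {2, 2.5}, {3} — the bins whose per-split counts
the original analysis reports — with largest-remainder rounding so the
totals equal round(0.7·n) exactly (900 → 630/270) and a seeded per-stratum
permutation. The Spearman screen uses average-rank tie handling with
t-approximation p-values and reports the strength bands used in the field
discussion (|rs| ≥ 0.65 high, ≥ 0.40 moderate, below low).

## Synthetic cohort generator

The generator emulates the *structure* of the 900-bird commercial yield
trial, not its images: 2 strain groups (HBY pooled from two high-yielding
hybrids, 60 per sex × age cell; SBY, 30 per cell), both sexes, ages 6–10
wk. Per bird:

- live weight ~ Normal(cell mean, cell SD) truncated at 0, with the
  published per-cell weight parameters;
- ordinal score from a proportional-odds latent model z = η + Logistic(0,1),
  η = 0.9·[HBY] + 1.1·[male] + 0.45·(age−8) + 0.8·(weight deviation, kg),
  with cutpoints (0.443, 1.615, 2.38, 3.024, 3.766, 4.616);
- baseline dimensions M0, M1, M3 = c·weight^(1/3) with strain-specific
  coefficients (SBY runs longer and narrower: c₀ 1.522/1.608, c₁
  1.079/1.045, c₃ 0.690/0.665 cm·g^(−1/3) for HBY/SBY), and a baseline
  caudal bulge of 0.33·M5;
- deformation per unit of score: widths ×(1+0.020·s) (M1) and ×(1+0.026·s)
  (M3), bulge ×(1+0.030·s), length ×(1−0.026·s) — wider, rounder, slightly
  shorter as severity grows;
- independent Gaussian measurement noise on the four measured primitives
  M0, M1, M3, M6 (SDs 0.32, 0.25, 0.30 cm and 1.25 cm², one third of the
  pooled published within-cell SDs), after which M2, M4, M5, M7 and the
  ratios are derived by the geometric identities, exactly as a measurement
  pipeline would produce them.

All draws flow from a single `numpy` generator stream in record order, so a
seed fixes the cohort byte-for-byte.

**Calibration.** The published study reports only marginal incidence rates
and the correlation ranking of the measurements, not the latent severity
process, so the severity coefficients, cutpoints and deformation
multipliers are under-determined free parameters. They were fixed once:
cutpoints as latent-scale quantiles matching the published score-bin totals
(536/213/111/40 of 900, with a 60/40 split inside each printed bin — the
half-step composition is itself unreported), and deformation multipliers
against the published correlation ranking (M11 leading near 0.68, M9 and
M4 next, M3 moderate) while keeping per-cell incidence increasing with
age, the HBY strain and the male sex and overall incidence near 16.8 %.
The defaults are study conditions, not tuning knobs.

**Rendering.** For end-to-end tests a record's true shape is rasterized:
a caudal power flank of exponent q = (1−g)/(1+g) through (M0/5, M3/2) —
chosen so the rendered caudal cap has bulge fraction M7/M5 = g exactly,
with q = 1 giving straight flanks and M7 = 0 — blended into a
superelliptic cranial lobe of width M1 closing at the cranial end. The
ground-truth apex is stored; rasters with M3 under 10 px are rejected as
too coarse. Round-trips recover M0, M1, M3 within 2 % and M4 within 1°.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation error and shackle/wing occlusion,
asymmetric or locally lumpy deformation, non-Gaussian and correlated
measurement error, allometry beyond the cube-root law (real length
coefficients drift slightly with age), and any real biological coupling
between severity and shape beyond the monotone multiplicative model. The
published real-data performance numbers are therefore not reproduction
targets; structural behaviour (identities, directions, rankings, split
arithmetic, estimator correctness) is.

## Study pipeline

`run_study` codifies the published analysis sequence. Model selection is
lowest validation MR with highest validation TPR as tie-break — the prose
rule ("lowest MR … highest ST") made explicit. Subgroup refits (strain,
sex, age, weight class at 3.402 kg = 7.5 lb, strain × weight) use their
own stratified 70/30 split with the study seed, which reproduces the
published per-subgroup 70/30 footnote counts exactly; the pooled
"as-hatched" run is the global split, so it matches the pooled model row
identically. Age-specific forms are hard-wired per the published tables:
{M1, M9} at 6–7 wk, {M1, M2, M3} at 8–10 wk. A subgroup with fewer than 5
positives (the original analysis dropped such a cell without stating a
cutoff; 5 is this package's explicit choice) or a single response class is
recorded as skipped with its reason. The profiler evaluates the selected
fit at group-mean predictors per (strain, weight class, actual status) and
reports both class probabilities and the most-likely call.

## Problem sizes and determinism

Default problem sizes are the trial's own (900 birds; 630/270 split);
estimator-recovery checks use n = 5000 and the calibration check averages
20 seeded cohorts — all chosen as the smallest sizes at which the
quantities being checked are stable. Every stochastic step (cohort
sampling, split assignment) takes an explicit integer seed; identical
seed and configuration reproduce every table byte-for-byte.
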
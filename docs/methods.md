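# Methods

## The symmetry measure

Per-axis mirror symmetry of a binary image is a weighted fraction of
matching reflected pixel pairs.  Pairs are indexed from the image border
(*j* = 1, weight 1) toward the axis (*j* = *n*, weight 2), with weight
`1 + (j−1)/(n−1)`; the score is the weighted match count divided by the
total weight, so it lies in [0, 1] and equals 1 exactly iff the image is
mirror-symmetric about the axis.  For the vertical axis this is
`s = 2/(3mn)·ΣΣ X_ij(1 + (j−1)/(n−1))` with `n = w/2` (even width) or
`(w−1)/2` (odd width; the centre column is excluded).  Two conventions
required a decision:

* **Weight direction.**  The linear weight must increase toward the
  axis (pixels near the axis matter more for human symmetry detection);
  the index *j* therefore runs border → axis.  This is the only reading
  under which the normaliser `2/(3mn)` equals the total weight.
* **Diagonal axes.**  Reflected pairs are `(i,j) ↔ (j,i)` for the main
  diagonal and `(i,j) ↔ (w−1−j, w−1−i)` for the secondary diagonal of a
  square image.  Pairs are grouped by their distance class
  `d = 1 … w−1` from the axis and weighted with the same border→axis
  linear ramp, normalised by the total weight.  This is the natural
  generalisation of the vertical-axis formula (one cannot literally
  reduce a diagonal reflection to the vertical-axis routine by
  transposition, since transposition *is* the diagonal reflection); it
  preserves every invariant that matters: scores in [0, 1], exactness at
  1, and the h↔v / d1↔d2 permutation of scores under 90° rotation.
* **Degenerate sizes.**  With a single pair (`n = 1`) the weight ramp is
  undefined; the weight is 1 and the normaliser adjusts so a full match
  still scores 1.  Width < 2 is rejected.

The aggregate is `MS = 100·mean(s_axis)`.  Non-linear per-axis
transforms sharpen the measure: power (`s^a`, `a ≥ 1`; `MSA20` uses
`a = 20`), a normalised exponential (`(e^{−a(1−s)} − e^{−a})/(1 −
e^{−a})`), and threshold-stretch (`max(0, (s−t)/(1−t))`, default
`t = 0.95`).  At `a = 1` the power transform is the identity on MS; for
any profile with some `s_axis < 1` it is strictly decreasing in `a`.
Grayscale inputs are out of scope (pixel equality only).

## The pattern simulator

Patterns are 8×8 grids of cells; each cell is empty, one of four
half-square triangles, or a full square (2 elements; triangles count 1).
Rasterisation uses even tile sizes only: the four triangle tiles (strict
half-planes of the two cell diagonals) map onto each other *exactly*
under horizontal/vertical flips and (anti-)transposition, which makes
grid-level symmetry equivalent to pixel-exact symmetry of the render.
The default render is 74 px/cell (592×592, the closest even tile size to
the conventional ~600×600 presentation format; an odd 75 px tile would
break pixel-exact mirror symmetry and is rejected).

Generation is simulated annealing (geometric schedule, defaults T₀ = 1,
factor 0.95, 200 steps/level, T_min = 10⁻³) over *orbit moves*: a move
resamples the whole orbit of a cell under the reflection group of the
target axes, with the cell state drawn from the states compatible with
its stabiliser.  Declared symmetry is therefore exact by construction,
and the energy only scores (a) the distance of the element count from a
per-pattern target and (b) a penalty for any non-target axis reaching
0.98 (the configurable asymmetry threshold).  Acceptance requires zero
energy; exhausting the schedule raises a convergence error naming the
residual energy.  Orbit moves change counts in multiples of the orbit
sizes, so only some counts are reachable per axis group (e.g. multiples
of 4 for four-axis patterns); the per-pattern target is drawn uniformly
from the *feasible* counts in 36–44, which is what makes counts vary
across patterns.

Broken-symmetric variants re-randomise a 3×3 window of a symmetric
pattern.  A uniform redraw averages ~9 elements, so the draw is first
repaired toward the admissible count range (random promotions/demotions
inside the window); a candidate is accepted only if the pattern changed,
the count stays in 36–44, and **every axis that was exactly symmetric
before is broken** — for a partially symmetric pattern the aggregate MS
is below 100 to begin with, so "just-not-symmetric" must mean the
declared symmetry itself is destroyed.  A window in which no admissible
perturbation exists (e.g. an all-empty window in a pattern already at
the count maximum) raises an explicit degenerate-window error.

## The predictor battery

* **Compression ratios** are compressed bytes per pixel, averaged over
  the image and its 90° rotation, using Pillow's GIF, PNG, TIFF-LZW and
  JPEG (quality 90) encoders.  Absolute values are encoder-specific;
  the encoder versions are recorded by `io.environment_versions()` and
  cross-encoder comparisons should be treated as rank-level.
* **Phase congruency** is computed from a log-Gabor filter bank (4
  scales, 6 orientations, minimum wavelength 3, scale factor 2.1,
  σ_onf 0.55, Rayleigh noise compensation with k = 2, spread sigmoid
  cut-off 0.5, gain 10).  Orientation maps are summed.
* **Canny** uses σ = 1 Gaussian smoothing with hysteresis thresholds
  derived automatically: high = Otsu threshold of the smoothed gradient
  magnitude, low = 0.4·high.  **PER** marks black pixels with at least
  one 4-connected white (or out-of-image) neighbour.  **RMS** is the
  local standard deviation in a 5×5 reflective window divided by the
  mean image intensity.  All window/threshold settings are configurable
  (`FeatureConfig`).
* Edge maps are summarised by mean, population SD and their product,
  and by the GIF ratio of the 8-bit linearly quantised map (max → 255,
  so binary maps are unaffected by float/bool representation).
* **APB** measures balance over eight axes through the image centre
  (vertical, horizontal, two diagonals, four 22.5° intermediates):
  `100 − 200·mean(|m₊ − m₋|/m)` of black-pixel mass per half-plane.
  **DCM** is the centroid-to-centre distance over the half-diagonal.
  **HG** is the Shannon entropy of black mass over an 8×8 block grid,
  relative to log 64.  The APB and HG constructions follow the cited
  balance literature in outline but are not validated against published
  values; no acceptance check depends on their absolute scale.

## Modelling

Predictors are z-standardised with sample SD (ddof = 1).  Mean ratings
exclude flagged repeat presentations (a stimulus re-rated in a later
session).  Best-subset selection enumerates all 1–3-predictor OLS models
(C(24,3) = 2024 fits), ranks by R² with lexicographic tie-breaks, and
reports full OLS inference for the retained models.  Linear-model R² is
the full-data fit; random-forest R² is the squared Pearson correlation
of pooled out-of-fold predictions (10-fold CV, seeded fold assignment;
500 trees, max(1, ⌊p/3⌋) split candidates, unlimited depth).
Per-participant models run the exhaustive two-predictor selection on
each participant's own rated stimuli and compare against the reference
{MS, RMSGIF} pair; constant raters are flagged and excluded from counts.

**Mixed models.**  Four random-effects structures are compared (M1:
intercepts only; M2/M3: + participant slope on one predictor; M4: both
slopes), fitted by maximum likelihood for AIC/BIC comparability.  The
statsmodels backend cannot combine crossed stimulus and participant
intercepts with participant slopes, so the stimulus intercept is
absorbed by centring ratings on per-stimulus means before fitting the
participant random-effect structure; the stimulus variance is reported
from the spread of stimulus means around the fixed-effect fit, and
fixed effects come from a companion random-intercept fit on raw
ratings.  Under the generative model the centring removes the stimulus
effect exactly and leaves slope inference intact.  Random-slope LRTs
compare nested ML fits with the p-value halved for the boundary null of
a zero variance (the χ² df counts all added covariance parameters, which
is conservative).

## The rating simulator

`synthetic_ratings` embodies the two-factor account: latent score
`β₀ + (β_q + b_q,p)·quant + (β_s + b_s,p)·sym + u_p + v_s + ε` with
independent Gaussian random effects, rounded and clipped to the 1–5
scale.  Defaults: β₀ = 3, β_q = 0.5, β_s = −0.4, participant-intercept
SD 0.2, stimulus-intercept SD 0.1, residual SD 0.5, 50 participants —
effect sizes of the order observed for abstract-pattern complexity
ratings.  Round-and-clip discretisation is simple and loses little
rank information at realistic noise (rank correlation with the latent
score > 0.9).  The structural input column is configurable: experiments
on the broken-symmetry contrast generate ratings from the *sharpened*
symmetry (power-20), reflecting the perceptual sensitivity to small
deviations; fitting models with raw MS vs MSA20 then reproduces the
signature result that the transform pays off exactly when
broken-symmetric stimuli are present.  What the simulator does *not*
emulate: presentation-order, familiarity and session effects, correlated
random effects, and any dependence of ratings on image properties
outside the two factors — so passing recovery tests demonstrate the
correctness of the estimation machinery under the assumed model, not the
validity of the model for real observers.

For model-selection and recovery experiments a statistically simulated
24-column predictor table (`synthetic_predictor_table`) mimics the
battery's correlation structure with two latent factors (RMSGIF and MS
the cleanest measures of their factors, every other column loading on a
factor plus idiosyncratic noise); it avoids rendering and measuring
thousands of images where only the modelling stack is under test.

## Problem sizes and numerics

The end-to-end acceptance run uses a 200-stimulus image study
(40 asymmetric, 16 per symmetric class, 80 broken) rendered at
16 px/cell with 50 simulated raters, 20 selection/recovery replicates at
500 stimuli, and mixed-model checks at 80 stimuli × 30 participants —
sizes chosen so the full pipeline, including feature extraction,
completes in well under a minute while keeping every estimate stable
across seeds.  Annealing energies are evaluated on 2 px/cell renders
(exactness of declared axes makes the evaluation resolution immaterial
for symmetric targets; grid-level asymmetry is far below the 0.98
threshold at any resolution).  OLS matches a normal-equations oracle to
1e−10; the symmetry implementation matches a brute-force pair
enumeration to 1e−12.

## Limitations

* Absolute compression ratios (and hence RMSGIF scales) are pinned to
  Pillow's encoders; other encoders shift the scale, though rankings
  are robust.
* APB and HG are plausible constructions of measures whose exact
  published definitions live in cited methodological work not
  reproduced here.
* The mixed-model ladder omits slope–intercept correlation structure
  beyond what `MixedLM` estimates within participants, and the
  stimulus-absorption fallback forgoes a joint crossed-effects
  likelihood.
* Reproduction of the published explained-variance values requires the
  original supplementary predictor/rating tables, which must be
  supplied by the user (`data/supplementary/`).
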
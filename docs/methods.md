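# Methods

This note records the statistical model, the defaults, and the design
choices behind `chromaqbd`, in the order the pipeline uses them.

## Factor coding

All modelling is done in coded units, x = 2(v − mid)/range, so that the low
and high level of each factor map to −1/+1 and the centre of the range to 0.
Coefficients of different factors are then directly comparable (minutes per
coded unit). Values outside the stated range are allowed — design-space
evaluation may probe the border of the knowledge space — and code to
|x| > 1 with a warning rather than an error. Coded design levels are snapped
to exact integers when they are within 1e−9 of one, so that contrast
arithmetic on generated designs is exact in floating point.

## Design generation

Regular two-level fractions 2^(k−p) are built from all ±1 combinations of
k−p basic factors plus p generated columns defined by alias words. Default
generators omit one basic factor per word, alternating between the ends of
the basic-factor list, which for 2^(6−2) gives E = ABC and F = BCD — a
resolution-IV fraction whose defining relation is I = ABCE = BCDF = ADEF.
The packaged 19-run screening table satisfies exactly these generator
relations (verified by direct column products), so the generator default
reproduces the real study's design structure; run order is not promised, and
the original run table is shipped verbatim as a fixture. Centre points are
appended after the factorial rows; a seedable shuffle flag randomizes run
order on request.

Box–Behnken designs for three factors are the twelve edge midpoints plus
replicated centre rows. The packaged optimization table contains four
identical centre rows, so the generator default is `n_center=4`; generated
and packaged tables agree as coded-row multisets.

## Screening analysis

Effects are orthogonal contrasts, effect = mean(y | +1) − mean(y | −1),
computed over the factorial rows only (centre points carry no contrast
information; they feed an informational curvature check instead). By default
*all* alias-distinct contrasts of the fraction are estimated — 15 for a
16-run regular fraction — each labelled by the shortest word in its alias
set. This matters: Lenth's pseudo standard error is a robust scale estimate
taken across the effects themselves, and it is the mostly-null interaction
contrasts that make it informative. Restricted to the six main effects
alone, the PSE of a screening study this size is so inflated that nothing
is ever flagged.

Significance uses Lenth's PSE with, by default, the simulation-calibrated
individual-error-rate critical value: the 1−α quantile of |effect|/PSE under
m i.i.d. null effects, computed once per (m, α) by a seeded internal Monte
Carlo (50 000 replicates) and cached. This calibration reproduces the
published critical-value tables (≈2.16 for m = 15, α = 0.05) and is the
standard remedy for the known conservatism of Lenth's t(1−α/2, m/3)
approximation, which remains available via `critical="t"`. α defaults
to 0.05. On the packaged screening study the calibrated criterion flags the
starting organic ratio (B) and the chaotropic salt concentration (C) for all
four early-eluting peak-time responses, and the gradient end time (F) for
the last peak — the conclusions the screening stage was run to establish.
The conservative t approximation narrowly misses C (|effect| 1.16 vs margin
1.25) on one response. Resolution-IV aliasing means two-factor-interaction
labels denote alias chains, which are reported, not resolved.

## Response-surface fitting

Linear and full quadratic models in coded units are fitted by OLS
(delegated to statsmodels); no term dropping within an order — the model
order is chosen per response by the user, with an advisory
extra-sum-of-squares F report (`sequential_order_report`) that is never
applied silently. Model adequacy is the R² triple: R² = 1 − RSS/SST,
adj R² = 1 − (RSS/(n−p))/(SST/(n−1)), and the PRESS-based predicted
R² = 1 − PRESS/SST with PRESS = Σ(eᵢ/(1−hᵢᵢ))² from the hat diagonal.
Coefficient t tests use σ̂² (X'X)⁻¹ with n − p degrees of freedom and the
usual three star levels. Natural-unit conversion is a reporting utility
only; fitting never happens in natural units.

On the packaged optimization table the fitted coefficients agree with the
study's published models at their printed precision (two decimals), but the
R² triple differs in its fourth decimal (e.g. computed R² 0.99662 vs
printed 0.99677 for the drug peak-end response). The packaged responses are
printed rounded to two decimals (0.01 min); a perturbation of under
0.005 min per response is invisible in two-decimal coefficients but moves
the R² family in the fourth decimal. The computed values are reported as-is;
nothing is adjusted toward the printed cells. (The same printed table shows
one evident sign typo, +0.16 where the fit gives −0.158 for one quadratic
term; it is not used anywhere.)

## Separation criteria and the design space

Each criterion s = t_b(later) − t_e(earlier) is **computed per run from the
measured responses and fitted as its own surface** (quadratic by default).
This is deliberate: the paired retention times come from the same
chromatogram, so their measurement errors are almost perfectly correlated
and the per-run difference is far less noisy than either response (residual
SD ≈ 0.03 min for the first criterion vs ≈ 0.12 min for the individual
retention surfaces on the packaged study). Differencing two independently
sampled response models instead would add their variances and understate π
badly — at the packaged study's working point it yields π ≈ 0.5–0.75 versus
≈ 0.98 from the directly fitted criterion surface. The independent-
difference route is retained (`cma_mode="difference"`) for sensitivity
analysis, optionally with observation noise drawn jointly from the empirical
residual covariance of the response models (`joint_across_responses`).

Uncertainty propagation is the Bayesian posterior predictive under the
noninformative prior: σ*² scaled-inverse-χ²(ν, σ̂²), b* conditionally normal,
plus N(0, σ*²) observation noise by default (`include_observation_noise`
off gives the mean-response distribution; `sample_sigma=False` gives the
fixed-σ Gaussian limit used by the closed-form oracle in the tests). The
coefficient draw enters the criterion only through x'b*, so the scalar
N(x'b̂, σ*² x'(X'X)⁻¹x) is sampled directly — exact and much cheaper than
materialising coefficient vectors.

The knowledge space is gridded per factor with `grid_levels` evenly spaced
levels including both endpoints (defaults 21 × 21 × 11 = 4851 points for the
packaged study). π is estimated with 5000 iterations per point by default;
each point uses its own RNG stream derived from (master seed, point index),
so results are independent of evaluation order and chunking. Points with
π exactly at the threshold are inside the design space (≥). An empty design
space is a reported outcome, not an error. The full default computation
(4851 points × 5000 iterations × 2 criterion surfaces) takes a few seconds
on one CPU.

The working point is a user choice from inside the design space (the
packaged default is 37.5% organic, 45 mM salt, gradient start 10.0 min);
the gradient translator holds the start composition until the gradient
start time, ramps linearly to 70% by 17.0 min (the gradient-time limit the
optimization was run under), steps back within 4 min and re-equilibrates
2 min more, ending at 23.0 min.

## Validation statistics

Calibration is simple least squares of signal on concentration
(scipy.stats.linregress) with Pearson r. LOD = 3.3 σ/S and LOQ = 10 σ/S,
where σ is taken as the standard error of the fitted intercept — with a
single calibration line, the only computable reading of "standard deviation
of the y-intercepts"; a user-supplied σ from replicate intercepts is
accepted as an override. The LOQ/LOD ratio is 10/3.3 by construction.
Recovery is 100·measured/nominal; %RSD is 100·(sample SD)/mean. Acceptance
tiers are keyed by role and an impurity's specification limit (SL, % of the
active ingredient), with left-inclusive boundaries:

| role / SL tier | recovery (%) | max %RSD | min r |
|---|---|---|---|
| active ingredient | 98.0–102.0 | 2.0 | 0.99 |
| impurity, SL ≥ 1.0% | 90.0–110.0 | 5.0 | 0.98 |
| impurity, 0.5% ≤ SL < 1.0% | 80.0–120.0 | 10.0 | 0.98 |
| impurity, 0.1% ≤ SL < 0.5% | 70.0–130.0 | 15.0 | 0.98 |

Below SL = 0.1% no tier is defined and the lookup raises.

## Synthetic data

The generator exists so every pipeline stage is testable with known ground
truth. Screening studies are drawn from y = grand mean + Σ(effect/2)x + ε;
Box–Behnken studies from a known polynomial surface; calibration series
from a known line — Gaussian i.i.d. noise throughout, deterministic under a
seed. Default true surfaces take the packaged study's fitted coefficients
(intercept ≈ 9.35 min, dominant organic-ratio effect ≈ −1.67 min per coded
unit); the default noise SD of 0.09 min (≈1% of the centre response) is a
scale choice representative of retention-time repeatability on a
well-behaved system. What the simulations do *not* emulate: correlated
errors between responses measured on the same chromatogram (the very
feature that motivates direct criterion fitting — the end-to-end recovery
tests therefore simulate the criterion gap directly), drifting or
heteroscedastic noise, peak-shape effects, and any mechanistic retention
model. Passing simulation tests show the estimators recover the truth under
the stated error model, not that the error model exhausts real
chromatographic variability.

## Numerical choices and degenerate inputs

* Constant responses: fit statistics are undefined (SST = 0) and reported
  as NaN with a degeneracy flag; effects are exactly zero and nothing is
  flagged (with a warning from the PSE).
* Lenth with all-zero effects returns PSE = 0 and an empty significant set.
* Design-space slicing at an off-grid level snaps to the nearest level with
  a warning.
* Monte Carlo with fewer than 100 iterations warns about its sampling
  error; π's binomial MC error with the 5000-iteration default is ≤ 0.007.
* All file outputs of the pipeline are byte-reproducible under a fixed
  config and seed, and the pipeline report carries a provenance block
  (config hash, seed, library versions).

## Known limitations

* Only k = 3 Box–Behnken generation is implemented (the study's case);
  D-optimal and central-composite designs, blocking and split-plot
  structures are out of scope.
* Resolution-IV alias chains are reported, not de-aliased; no fold-over
  augmentation.
* The design-space sampler treats criterion surfaces independently of each
  other; a full multivariate hierarchical model is out of scope.
* Box–Cox response transformation and weighted least squares are not
  provided.
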
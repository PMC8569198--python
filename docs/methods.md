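# Methods

## The model and its assumptions

The package treats seasonal areal biomass productivity of a raceway
photobioreactor as a smooth function of two operating variables — dilution
rate *A* (day⁻¹) and culture depth *B* (m) — approximated over a
rectangular operating box by a second-order polynomial

P_b = β₀ + β_A·A + β_B·B + β_AB·A·B + β_AA·A² + β_BB·B²,

fitted by ordinary least squares to the runs of a face-centred central
composite design (CCF). The statistical assumptions are the classical RSM
ones: responses are independent with homoscedastic Gaussian error, the
stored response of each run being the mean of a fixed number of replicate
experiments; the quadratic is a local approximation valid inside the box
only (predictions outside it are computed but flagged as extrapolation).

Fitting is performed on the coded scale (levels −1, 0, +1), where the CCF
columns are nearly orthogonal and the normal equations are well
conditioned. Actual-scale coefficients are *not* refitted: they are
obtained by exact affine substitution of the coding transform
cᵢ = (aᵢ − midᵢ)/halfᵢ, implemented as a linear map **M** on the
coefficient vector. The same map propagates the coefficient covariance, so
standard errors and confidence intervals are available on both scales.
This requires the term set to be hierarchy-closed (a quadratic or
interaction term implies its linear parents), which the fitting routine
enforces; a term set's closure is fitted when a non-hierarchical set is
requested.

## ANOVA and model reduction

Model adequacy uses the standard decomposition: SS_total = SS_model +
SS_pure-error + SS_lack-of-fit, with pure error estimated from the
replicated centre runs and lack of fit by difference. The overall F and
per-term partial (drop-one, Type-III) F statistics are referred to the
residual mean square; the lack-of-fit F to the pure-error mean square.

Non-significant terms are removed at α = 0.05. Two reduction strategies
are provided:

* **single pass** (default): one ANOVA of the full quadratic, delete every
  eligible term with p ≥ α, refit once. This mirrors the usual
  "delete after ANOVA, run a new ANOVA" practice and is the variant that
  reproduces three of the four reference seasonal equations from the
  bundled data.
* **stepwise**: delete one term at a time (largest p first), refitting and
  re-testing after each deletion. On the bundled summer data this drops
  the interaction (its p-value moves from 0.047 to 0.055 after the first
  deletion) and therefore disagrees with the reference equation; it is
  kept as an option because one-at-a-time deletion is the textbook
  backward procedure.

With `preserve_hierarchy=True` (default) linear main effects are never
deleted, so reduced models remain hierarchical and interpretable in
physical units. Elimination operates on partial F-tests computed in double
precision; p-values are reported to four decimals.

## Optimisation and desirability

A quadratic on a box attains its maximum at an interior stationary point,
on an edge, or at a corner. The optimiser enumerates this candidate set
exactly — for every assignment of a subset of factors to their bounds it
solves the reduced linear gradient system — and returns the feasible
candidate with the largest prediction. No iterative solver is used; a
0.001-step grid search is retained as a verification oracle in the tests.
Ties (within 10⁻⁹ of the best value) are broken deterministically towards
the smallest depth, then the smallest dilution rate.

Desirability is the single-response linear "maximise" ramp
d = clip((y − y_min)/(y_max − y_min), 0, 1) with the ramp endpoints
defaulting to the minimum and maximum of the season's observed responses
(configurable). Because the ramp is increasing, the desirability optimum
coincides with the raw-response optimum; when the predicted maximum
exceeds the best observed response, d saturates at 1 over a region and the
result carries a `plateau` flag — the reported point is then the
raw-response maximiser. Multi-response (geometric-mean) desirability,
target and minimise goals are out of scope.

Reported precision mirrors engineering practice for these quantities:
factors to 2 decimals, responses to 1, desirability to 2, with
half-away-from-zero rounding.

## Reactor arithmetic and nutrient accounting

Culture volume is depth × channel area (8.33 m²) × 1000, plus the 170 L
collector sump when included (default: included for volume and harvest
accounting, excluded for the areal-productivity conversion, which concerns
the light-exposed channel only; both conventions are configurable). The
stated volume range of the reference system is internally inconsistent at
the deep end (0.20 m gives 1836 L, stated 1840 L, implying ~8.35 m²); the
geometry as stated is used and a ±5 L slack accepted at that bound.

Total inorganic nitrogen is strictly ammonium-N + nitrate-N; nitrite and
organic nitrogen are excluded by construction. Removal is
100·(inlet − outlet)/inlet and may be negative (nitrification makes outlet
nitrate exceed inlet). Areal removal rates multiply the concentration
difference by the daily processed volume per unit surface. The nitrogen
balance assumes a fixed biomass nitrogen fraction (default 0.10):
assimilated = fraction × P_b, unaccounted = removed − assimilated, the
positive remainder being stripping/nitrification losses; a negative
remainder sets an infeasibility flag. To make the conservation identity
assimilated + unaccounted = removed hold *exactly* in floating point, the
balance stores the closed sum (within one rounding step of the input)
rather than echoing the input. Seasonal removal summaries are unweighted
means over runs. Discharge compliance uses the Spanish windows (N:
10–15 mg·L⁻¹, P: 1–2 mg·L⁻¹): below the window compliant, inside marginal,
above non-compliant.

## Synthetic data

`simulate_design_response` draws each run's stored response as the mean of
`n_replicates` draws of truth + N(0, noise_sd²). Defaults: duplicate
replicates and noise_sd = 1.0 g·m⁻²·day⁻¹, of the order of the spread
among the replicated centre runs of the bundled tables.
`simulate_wastewater` draws inlet concentrations uniformly within the
documented composition windows (NH₄⁺-N 55–145, NO₃⁻-N 2–11, PO₄³⁻-P 3–21,
COD 690–890 mg·L⁻¹), applies per-species removal fractions (ammonium
0.97–0.99; the others broad stand-ins, as only feed ranges are documented)
and, optionally, routes 0–8% of the removed ammonium into outlet nitrate
to emulate nitrification. A single integer seed drives all randomness.

What the generators deliberately do not emulate: temporal dynamics of the
semi-continuous culture, weather forcing, correlated or heteroscedastic
measurement error, and any ecology of the algal–bacterial consortium.
Passing tests therefore demonstrate that the estimation and optimisation
machinery is correct under its stated assumptions, not that the quadratic
model is adequate for any particular pond.

## Reproduction scope and known source discrepancies

The bundled fixture carries the 11 mean responses per season; the
underlying replicate-level data and the per-run nutrient concentrations of
the source study were published only as supplementary material and are not
available, so ANOVA p-values are matched at reduced precision and the
seasonal ammonium-removal averages are not recomputable. Within what the
printed table supports:

* Winter, summer and autumn refits reproduce the published coefficients
  within ±2% relative / ±0.05 absolute (summer's intercept misses the
  absolute band by 0.002), and winter's overall p-value (0.0018) exactly
  to the printed digits.
* The published spring equation omits the A·B interaction, yet that term
  is significant on the published means (partial-F p ≈ 0.047 in the full
  model, 0.029 after removing B²) — consistent with the source's own text,
  which states the interaction was significant in spring and summer.
  Elimination therefore retains it, and no 11-row least-squares fit
  reproduces the published spring coefficients or the published spring
  R² = 0.972 (the four-term refit gives 0.920, the five-term 0.966). These
  checks are kept as failing reproduction tests rather than silently
  relaxed.
* The published autumn R² (0.863) likewise does not match the autumn refit
  (0.966); the published winter and summer values do.
* The published winter desirability 0.99 corresponds to a computed 0.998
  (which rounds to 1.00); only the near-saturation magnitude is asserted.

Centre-point actual levels are the exact design midpoints (0.325 day⁻¹,
0.125 m) rather than the rounded printed values (0.32/0.33, 0.13), which
are mutually inconsistent across rows; the CCF midpoint is analytically
forced. The fixture is integrity-checked by a SHA-256 digest.

## Problem sizes and numerics

All reproduction computations run on the 11-run table and complete in
seconds. Monte-Carlo properties use seeded replicate counts chosen to make
the checks sharp but quick: 200 replicates for structure-recovery rates,
500 for coefficient recovery, 1000 for confidence-interval coverage
(pooled coverage 93–97% asserted against the nominal 95%) and for the
type-I retention rate of the interaction (≈ α ± 3 points). PRESS uses the
closed-form hat-matrix identity; its oracle in the tests is an explicit
leave-one-out refit loop. Rank deficiency is detected before fitting and
reported with the names of the collinear terms.
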
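# racewayrsm

Response-surface optimisation of open raceway photobioreactors treating
urban wastewater with microalgae.

Raceway operators have two levers that are cheap to adjust every day: the
**dilution rate** *A* (the fraction of the culture harvested and replaced
with wastewater, day⁻¹) and the **culture depth** *B* (m). Both act on the
areal biomass productivity *P_b* (g·m⁻²·day⁻¹) through light availability
and nutrient loading, and the best combination shifts with the seasons.
`racewayrsm` implements the design-of-experiments workflow used to find it:

1. **Design** — a face-centred central composite design (CCF) over the
   operating box (here 0.15–0.50 day⁻¹ × 0.05–0.20 m): 2ᵏ factorial
   corners, 2k face-centred axial points and replicated centre runs, all
   coded levels in {−1, 0, +1}.
2. **Fit** — ordinary least squares of the quadratic surface

   *Y* = β₀ + Σᵢ βᵢXᵢ + Σᵢ βᵢᵢXᵢ² + ΣΣ βᵢⱼXᵢXⱼ

   on the coded scale, re-expressed exactly in actual units; ANOVA with a
   pure-error / lack-of-fit split from the replicated centre points;
   deletion of non-significant second-order terms (partial-F tests at
   α = 0.05); R², adjusted R² and PRESS-based predicted R².
3. **Optimise** — analytic box-constrained maximisation of the fitted
   quadratic (stationary points, edges, corners) and a Derringer-style
   linear "maximise" desirability ramp over the observed response range.
4. **Account** — raceway volume/harvest arithmetic, nutrient removal
   percentages, areal removal rates, a nitrogen mass balance assuming 10%
   nitrogen in the biomass, and discharge-limit compliance checks.

A four-season pilot data set (11 runs × 4 seasonal productivity responses)
is bundled, together with the published seasonal equations, as the
reference fixture; synthetic-data generators reproduce the statistical
structure of both the design responses and the wastewater composition so
every stage is testable without external data.

## Worked example

```python
from racewayrsm.pipeline import run_pipeline

report = run_pipeline("winter")
print(report["model"]["equation"])
print(report["anova"]["p_model"], report["diagnostics"]["r2"])
print(report["optimization"])
```

prints (abridged):

```
8.79 +32.28*dilution_rate -15.78*depth -60.22*dilution_rate^2
0.0018 0.870
{'setting': {'dilution_rate': 0.268, 'depth': 0.05},
 'predicted_pb': 12.33, 'desirability': 1.0, 'plateau': True}
```

Reading: on the winter data the backward elimination keeps the intercept,
both main effects and the dilution-rate quadratic; the model is adequate
(p = 0.0018) with R² = 0.870; productivity is maximised at a dilution rate
of 0.27 day⁻¹ with the shallowest culture (0.05 m), predicting
12.3 g·m⁻²·day⁻¹ — shallow cultures win because self-shading, not light,
limits winter growth. The desirability ramp saturates because the
prediction slightly exceeds the best observed winter run.

The same chain runs for spring, summer and autumn; in summer the
dilution-rate × depth interaction is retained and the optimum moves to
0.49 day⁻¹, reflecting the higher light and nutrient throughput the warm
season supports.

The command-line interface exposes the stages individually
(`racewayrsm design|fit|optimize|nutrients|simulate|reproduce`).

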
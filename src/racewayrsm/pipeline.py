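"""End-to-end seasonal analysis: fit, reduce, diagnose, optimise, compare.

``run_pipeline`` chains model reduction, ANOVA, diagnostics and
desirability optimisation for one season (or any user design table) and
emits a JSON-serialisable report that places the refitted quantities next
to the published ones, with pass/fail verdicts at stated tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import (
    PRINTED_R2,
    RESPONSE_NAME,
    SEASONS,
    season_fixture,
)
from .design import DesignTable
from .errors import SchemaError
from .optimize import optimize_desirability
from .rsm import anova, backward_eliminate, diagnostics

__all__ = ["PipelineConfig", "run_pipeline", "validation_scatter"]

REPORT_VERSION = 1

# Reduced-model coefficients are compared against published equations at
# +/-2% relative or +/-0.05 absolute (whichever is larger), absorbing the
# one-decimal rounding of the responses; R2 at +/-0.01.
COEF_RTOL = 0.02
COEF_ATOL = 0.05
R2_TOL = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the seasonal analysis; defaults mirror the studied workflow."""

    alpha: float = 0.05
    preserve_hierarchy: bool = True
    elimination_method: str = "single_pass"
    grid_step: float = 0.001


def _coef_close(fitted: float, printed: float) -> bool:
    tol = max(COEF_RTOL * abs(printed), COEF_ATOL)
    return abs(fitted - printed) <= tol


def run_pipeline(
    season: str,
    config: PipelineConfig | None = None,
    design: DesignTable | None = None,
) -> dict:
    """Analyse one season end to end and report against published values.

    ``design`` overrides the bundled table (same schema, same response
    name); ``season`` must then still name one of the four seasons so the
    published reference values are known.
    """
    if season not in SEASONS:
        raise SchemaError(f"unknown season {season!r}; expected one of {SEASONS}")
    config = config or PipelineConfig()
    fixture = season_fixture(season)
    table = design if design is not None else fixture.design
    if RESPONSE_NAME not in table.responses:
        raise SchemaError(f"design table lacks response column {RESPONSE_NAME!r}")

    model = backward_eliminate(
        table,
        RESPONSE_NAME,
        alpha=config.alpha,
        preserve_hierarchy=config.preserve_hierarchy,
        method=config.elimination_method,
        season_label=season,
    )
    table_anova = anova(model, table)
    diag = diagnostics(model, table)
    optimum = optimize_desirability(model, table)

    printed = fixture.printed_model
    fitted_by_label = dict(zip(model.term_labels(), model.coefficients_actual))
    printed_by_label = dict(zip(printed.term_labels(), printed.coefficients_actual))
    terms_match = set(fitted_by_label) == set(printed_by_label)
    coef_compare = {
        label: {
            "fitted": float(fitted_by_label[label]),
            "printed": float(pc),
            "within_tolerance": _coef_close(float(fitted_by_label[label]), float(pc)),
        }
        for label, pc in printed_by_label.items()
        if label in fitted_by_label
    }
    r2_ok = abs(diag.r2 - PRINTED_R2[season]) <= R2_TOL
    all_ok = terms_match and r2_ok and all(
        c["within_tolerance"] for c in coef_compare.values()
    )

    return {
        "report_version": REPORT_VERSION,
        "season": season,
        "response": RESPONSE_NAME,
        "units": "g*m^-2*day^-1",
        "model": {
            "terms": model.term_labels(),
            "coefficients_actual": [float(c) for c in model.coefficients_actual],
            "coefficients_coded": [float(c) for c in model.coefficients_coded],
            "equation": model.equation(),
        },
        "anova": {
            "f_model": table_anova.f_model,
            "p_model": round(table_anova.p_model, 4),
            "p_lack_of_fit": None
            if table_anova.p_lack_of_fit is None
            else round(table_anova.p_lack_of_fit, 4),
            "term_p": {k: round(v, 4) for k, v in table_anova.term_p.items()},
        },
        "diagnostics": {
            "r2": diag.r2,
            "r2_adjusted": diag.r2_adjusted,
            "r2_predicted": diag.r2_predicted,
            "press": diag.press,
        },
        "optimization": {
            "setting": {
                "dilution_rate": float(optimum.optimal_setting[0]),
                "depth": float(optimum.optimal_setting[1]),
            },
            "predicted_pb": optimum.predicted_response,
            "desirability": optimum.desirability,
            "plateau": optimum.plateau,
            "boundary_flags": list(optimum.on_boundary),
        },
        "comparison_with_printed": {
            "terms_match": terms_match,
            "coefficients": coef_compare,
            "r2_fitted": diag.r2,
            "r2_printed": PRINTED_R2[season],
            "r2_within_tolerance": r2_ok,
            "all_within_tolerance": all_ok,
        },
    }


def validation_scatter(predicted, observed) -> float:
    """Squared Pearson correlation between predicted and observed responses."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise SchemaError("predicted and observed must be equal-length vectors")
    if predicted.size < 3:
        raise SchemaError("need at least 3 points for a validation statistic")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        raise SchemaError("validation statistic undefined for constant vectors")
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)
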
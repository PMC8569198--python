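"""Box-constrained maximisation of a quadratic surface and desirability.

A quadratic polynomial on a rectangular operating box attains its maximum
either at an interior stationary point, on an edge (a stationary point of
the one-dimensional restriction), or at a corner.  The candidate set is
enumerated analytically: for every assignment of a subset of factors to
their bounds, the gradient system of the remaining free factors is solved.
This is exact for any number of factors (and cheap for the two studied
here), so no iterative optimiser is involved.

Desirability follows the single-response "maximise" ramp: the predicted
response is rescaled linearly onto [0, 1] between the worst and best values
observed in the experiment, and clipped.  A desirability of 1 therefore
means "at least as good as the best observed run".  When the model predicts
responses above the observed maximum on a whole region, the ramp saturates
there and the reported optimum carries a plateau flag; the point returned is
then the one with the highest raw prediction (ties broken towards the
smallest depth, then the smallest dilution rate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import DesignTable
from .errors import DegenerateRangeError, DimensionError
from .rsm import QuadraticModel, model_matrix

__all__ = [
    "OptimizationResult",
    "desirability_max",
    "maximize_response",
    "optimize_desirability",
    "grid_max",
]

_TOL = 1e-9


@dataclass
class OptimizationResult:
    """Optimal operating point of one seasonal model."""

    optimal_setting: np.ndarray
    predicted_response: float
    desirability: float | None
    on_boundary: tuple[bool, ...]
    plateau: bool = False


def desirability_max(y: float, y_low: float, y_high: float) -> float:
    """Linear maximise-ramp desirability, clipped to [0, 1]."""
    if not y_low < y_high:
        raise DegenerateRangeError(
            f"degenerate response range [{y_low}, {y_high}]"
        )
    return float(np.clip((y - y_low) / (y_high - y_low), 0.0, 1.0))


def _quadratic_parts(model: QuadraticModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Write the surface as f(x) = c + g.x + x'Hx/2 on the actual scale."""
    k = len(model.factors)
    c = 0.0
    g = np.zeros(k)
    H = np.zeros((k, k))
    for t, b in zip(model.terms, model.coefficients_actual):
        if t.kind == "intercept":
            c += b
        elif t.kind == "linear":
            g[t.factor_indices[0]] += b
        elif t.kind == "quadratic":
            H[t.factor_indices[0], t.factor_indices[0]] += 2.0 * b
        else:
            i, j = t.factor_indices
            H[i, j] += b
            H[j, i] += b
    return c, g, H


def _evaluate(c: float, g: np.ndarray, H: np.ndarray, x: np.ndarray) -> float:
    return float(c + g @ x + 0.5 * x @ H @ x)


def _candidates(g: np.ndarray, H: np.ndarray, bounds: np.ndarray) -> list[np.ndarray]:
    """All stationary points of the surface restricted to box faces/edges."""
    k = len(g)
    out: list[np.ndarray] = []
    for assignment in itertools.product((None, 0, 1), repeat=k):
        fixed = [i for i, a in enumerate(assignment) if a is not None]
        free = [i for i, a in enumerate(assignment) if a is None]
        x = np.empty(k)
        for i in fixed:
            x[i] = bounds[i, assignment[i]]
        if free:
            Hff = H[np.ix_(free, free)]
            rhs = -(g[free] + (H[np.ix_(free, fixed)] @ x[fixed] if fixed else 0.0))
            try:
                sol = np.linalg.solve(Hff, rhs)
            except np.linalg.LinAlgError:
                continue  # flat direction: covered by the bound assignments
            x[free] = sol
            if np.any(x[free] < bounds[free, 0] - _TOL) or np.any(
                x[free] > bounds[free, 1] + _TOL
            ):
                continue
            x[free] = np.clip(x[free], bounds[free, 0], bounds[free, 1])
        out.append(x.copy())
    return out


def _resolve_bounds(model: QuadraticModel, bounds) -> np.ndarray:
    if bounds is None:
        bounds = [(f.low, f.high) for f in model.factors]
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (len(model.factors), 2):
        raise DimensionError(
            f"bounds of shape {bounds.shape} for {len(model.factors)} factors"
        )
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise DegenerateRangeError("every factor needs lower < upper bound")
    return bounds


def _tie_break_key(x: np.ndarray) -> tuple:
    # smallest depth first, then smallest dilution rate: reversed factor order
    return tuple(reversed(x.tolist()))


def maximize_response(model: QuadraticModel, bounds=None) -> OptimizationResult:
    """Maximise the predicted response over the operating box, analytically.

    ``bounds`` defaults to the factor ranges of the model (the limits within
    which the surface was fitted).  Among candidates with equal predicted
    response the setting with the smallest last factor (depth), then the
    smallest first factor, is returned, making the result deterministic.
    """
    bounds = _resolve_bounds(model, bounds)
    c, g, H = _quadratic_parts(model)
    candidates = _candidates(g, H, bounds)
    values = [_evaluate(c, g, H, x) for x in candidates]
    best = max(values)
    tied = [x for x, v in zip(candidates, values) if v >= best - _TOL]
    x_star = min(tied, key=_tie_break_key)
    on_boundary = tuple(
        bool(abs(x_star[i] - bounds[i, 0]) < _TOL or abs(x_star[i] - bounds[i, 1]) < _TOL)
        for i in range(len(x_star))
    )
    return OptimizationResult(
        optimal_setting=x_star,
        predicted_response=_evaluate(c, g, H, x_star),
        desirability=None,
        on_boundary=on_boundary,
    )


def optimize_desirability(
    model: QuadraticModel,
    design: DesignTable,
    bounds=None,
    response_range: tuple[float, float] | None = None,
) -> OptimizationResult:
    """Maximise the desirability ramp of the predicted response over the box.

    The ramp endpoints default to the min/max of the observed response
    column in ``design``.  Because the ramp is increasing in the prediction,
    the desirability optimum coincides with the raw-response optimum; when
    the prediction exceeds the observed maximum the ramp saturates at 1 over
    a region and the plateau flag is set.
    """
    if response_range is None:
        y = design.response(model.response_name)
        y_low, y_high = float(np.min(y)), float(np.max(y))
    else:
        y_low, y_high = response_range
    result = maximize_response(model, bounds)
    result.desirability = desirability_max(result.predicted_response, y_low, y_high)
    result.plateau = result.predicted_response > y_high + _TOL
    return result


def grid_max(
    model: QuadraticModel, bounds=None, step: float = 0.001
) -> tuple[np.ndarray, float]:
    """Brute-force grid maximisation used to verify the analytic optimum."""
    bounds = _resolve_bounds(model, bounds)
    axes = [
        np.arange(lo, hi + step / 2.0, step) for lo, hi in bounds
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([grid.ravel() for grid in grids])
    vals = model_matrix(pts, model.terms) @ model.coefficients_actual
    idx = int(np.argmax(vals))
    return pts[idx], float(vals[idx])
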
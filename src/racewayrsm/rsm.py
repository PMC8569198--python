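"""Quadratic response-surface fitting, ANOVA and model reduction.

The response surface is the full second-order polynomial

    Y = b0 + sum_i bi * Xi + sum_i bii * Xi^2 + sum_{i<j} bij * Xi * Xj

fitted by ordinary least squares on the coded (-1..+1) scale, where the
columns are near-orthogonal, and re-expressed exactly on the actual scale by
affine substitution of the coding transform.  Model adequacy is judged by an
ANOVA that splits the residual sum of squares into pure error (from the
replicated centre points) and lack of fit; individual terms are judged by
partial (drop-one) F-tests.

Model reduction follows the practice of deleting the second-order terms that
are not significant at ``alpha`` and refitting.  Two strategies are
provided:

* ``"single_pass"`` (default): one ANOVA of the full quadratic, remove every
  non-significant eligible term at once, refit once.
* ``"stepwise"``: repeatedly remove the eligible term with the largest
  partial-F p-value >= alpha, refitting after each removal.

With ``preserve_hierarchy=True`` (default) linear main effects are never
removed: a reduced surface then always remains interpretable in actual units
and the coded and actual parameterisations span the same term set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignTable, FactorSpec, actual_to_coded, is_extrapolation
from .errors import (
    DimensionError,
    PureErrorUnavailableError,
    SchemaError,
    SingularFitError,
    UndefinedDiagnosticsError,
)

__all__ = [
    "TermSpec",
    "QuadraticModel",
    "AnovaTable",
    "FitDiagnostics",
    "full_quadratic_terms",
    "fit_quadratic",
    "predict",
    "anova",
    "backward_eliminate",
    "diagnostics",
    "model_from_actual_coefficients",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

_KINDS = ("intercept", "linear", "interaction", "quadratic")


@dataclass(frozen=True)
class TermSpec:
    """One polynomial term: intercept, linear, quadratic or interaction."""

    kind: str
    factor_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        n = len(self.factor_indices)
        if self.kind == "intercept" and n != 0:
            raise ValueError("intercept takes no factor indices")
        if self.kind in ("linear", "quadratic") and n != 1:
            raise ValueError(f"{self.kind} term takes exactly one factor index")
        if self.kind == "interaction":
            if n != 2 or self.factor_indices[0] == self.factor_indices[1]:
                raise ValueError("interaction term takes two distinct factor indices")

    def label(self, factors: list[FactorSpec] | None = None) -> str:
        def nm(i: int) -> str:
            return factors[i].name if factors else chr(ord("A") + i)

        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return nm(self.factor_indices[0])
        if self.kind == "quadratic":
            return f"{nm(self.factor_indices[0])}^2"
        i, j = self.factor_indices
        return f"{nm(i)}*{nm(j)}"

    def _sort_key(self) -> tuple:
        return (_KINDS.index(self.kind), self.factor_indices)


INTERCEPT = TermSpec("intercept")


def full_quadratic_terms(k: int) -> list[TermSpec]:
    """Canonical full second-order term set for k factors."""
    terms = [INTERCEPT]
    terms += [TermSpec("linear", (i,)) for i in range(k)]
    terms += [
        TermSpec("interaction", (i, j)) for i in range(k) for j in range(i + 1, k)
    ]
    terms += [TermSpec("quadratic", (i,)) for i in range(k)]
    return terms


def hierarchical_closure(terms: list[TermSpec]) -> list[TermSpec]:
    """Add the intercept and any linear terms referenced by higher-order terms."""
    out = set(terms) | {INTERCEPT}
    for t in terms:
        if t.kind in ("quadratic", "interaction"):
            for i in t.factor_indices:
                out.add(TermSpec("linear", (i,)))
    return sorted(out, key=TermSpec._sort_key)


def model_matrix(settings: np.ndarray, terms: list[TermSpec]) -> np.ndarray:
    """Design matrix for ``terms`` at the given (n x k) settings."""
    settings = np.atleast_2d(np.asarray(settings, dtype=float))
    n = settings.shape[0]
    cols = []
    for t in terms:
        if t.kind == "intercept":
            cols.append(np.ones(n))
        elif t.kind == "linear":
            cols.append(settings[:, t.factor_indices[0]])
        elif t.kind == "quadratic":
            cols.append(settings[:, t.factor_indices[0]] ** 2)
        else:
            i, j = t.factor_indices
            cols.append(settings[:, i] * settings[:, j])
    return np.column_stack(cols)


def coded_to_actual_coef_matrix(
    terms: list[TermSpec], factors: list[FactorSpec]
) -> np.ndarray:
    """Linear map M with beta_actual = M @ beta_coded.

    Built by expanding each coded basis monomial through the substitution
    c_i = (a_i - mid_i)/half_i, i.e. c_i = p_i + q_i a_i with p_i =
    -mid_i/half_i and q_i = 1/half_i.  ``terms`` must be hierarchy-closed so
    that the expansion stays within the term set.
    """
    p = np.array([-f.mid / f.half_range for f in factors])
    q = np.array([1.0 / f.half_range for f in factors])
    index = {t: r for r, t in enumerate(terms)}
    M = np.zeros((len(terms), len(terms)))

    def add(kind: str, idx: tuple[int, ...], col: int, value: float) -> None:
        t = TermSpec(kind, idx)
        if t not in index:
            raise SingularFitError(
                f"re-expansion produced term {t.label()} outside the model; "
                "term set is not hierarchy-closed"
            )
        M[index[t], col] += value

    for col, t in enumerate(terms):
        if t.kind == "intercept":
            add("intercept", (), col, 1.0)
        elif t.kind == "linear":
            (i,) = t.factor_indices
            add("intercept", (), col, p[i])
            add("linear", (i,), col, q[i])
        elif t.kind == "quadratic":
            (i,) = t.factor_indices
            add("intercept", (), col, p[i] ** 2)
            add("linear", (i,), col, 2.0 * p[i] * q[i])
            add("quadratic", (i,), col, q[i] ** 2)
        else:
            i, j = t.factor_indices
            add("intercept", (), col, p[i] * p[j])
            add("linear", (i,), col, q[i] * p[j])
            add("linear", (j,), col, p[i] * q[j])
            add("interaction", (i, j), col, q[i] * q[j])
    return M


@dataclass
class QuadraticModel:
    """A fitted (or printed) quadratic surface on both scales.

    ``coefficients_actual`` multiply monomials of the factors in their
    physical units; ``coefficients_coded`` the same monomials of the coded
    variables.  Both parameterisations predict identically.  Covariance and
    residual information is carried when the model came from a fit.
    """

    response_name: str
    factors: list[FactorSpec]
    terms: list[TermSpec]
    coefficients_actual: np.ndarray
    coefficients_coded: np.ndarray
    season_label: str | None = None
    cov_coded: np.ndarray | None = None
    df_residual: int | None = None
    ss_residual: float | None = None

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def stderr_coded(self) -> np.ndarray:
        if self.cov_coded is None:
            raise UndefinedDiagnosticsError("model carries no covariance (not fitted)")
        return np.sqrt(np.diag(self.cov_coded))

    def stderr_actual(self) -> np.ndarray:
        M = coded_to_actual_coef_matrix(self.terms, self.factors)
        if self.cov_coded is None:
            raise UndefinedDiagnosticsError("model carries no covariance (not fitted)")
        return np.sqrt(np.diag(M @ self.cov_coded @ M.T))

    def confint_actual(self, level: float = 0.95) -> np.ndarray:
        """Coefficient confidence intervals on the actual scale, (p x 2)."""
        if self.df_residual is None or self.df_residual <= 0:
            raise UndefinedDiagnosticsError("no residual degrees of freedom")
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df_residual)
        se = self.stderr_actual()
        mid = self.coefficients_actual
        return np.column_stack([mid - tcrit * se, mid + tcrit * se])

    def term_labels(self) -> list[str]:
        return [t.label(self.factors) for t in self.terms]

    def equation(self, digits: int = 2) -> str:
        """Human-readable actual-scale equation, e.g. '8.68 +32.60*A ...'."""
        parts = []
        for t, c in zip(self.terms, self.coefficients_actual):
            lab = "" if t.kind == "intercept" else "*" + t.label(self.factors)
            parts.append(f"{c:+.{digits}f}{lab}")
        return " ".join(parts).lstrip("+")


def _check_rank(X: np.ndarray, terms: list[TermSpec], factors) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal does not reduce the rank
        collinear = [
            t.label(factors)
            for j, t in enumerate(terms)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SingularFitError(
            f"model matrix is rank deficient; collinear terms: {collinear}"
        )


def fit_quadratic(
    design: DesignTable,
    response_name: str,
    terms: list[TermSpec] | None = None,
    season_label: str | None = None,
) -> QuadraticModel:
    """Ordinary least squares fit of ``terms`` to one response column.

    The fit is performed on the coded scale; actual-scale coefficients are
    obtained by exact polynomial re-expansion (not a separate fit).  The term
    set is closed under hierarchy first, so the re-expansion is always
    well-defined; terms added by the closure are genuinely estimated.
    """
    if terms is None:
        terms = full_quadratic_terms(len(design.factors))
    terms = hierarchical_closure(terms)
    y = design.response(response_name)
    n = design.n_runs
    if n <= len(terms):
        raise SingularFitError(
            f"{n} runs cannot identify {len(terms)} terms plus error"
        )
    X = model_matrix(design.coded_matrix(), terms)
    _check_rank(X, terms, design.factors)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    df_res = n - len(terms)
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = xtx_inv * (ss_res / df_res)
    M = coded_to_actual_coef_matrix(terms, design.factors)
    return QuadraticModel(
        response_name=response_name,
        factors=list(design.factors),
        terms=terms,
        coefficients_actual=M @ beta,
        coefficients_coded=beta,
        season_label=season_label,
        cov_coded=cov,
        df_residual=df_res,
        ss_residual=ss_res,
    )


def predict(model: QuadraticModel, setting) -> float | np.ndarray:
    """Evaluate the actual-scale polynomial at one or more settings.

    Settings outside the factor box are evaluated anyway (the polynomial is
    global) but a warning flags the extrapolation.
    """
    setting = np.asarray(setting, dtype=float)
    single = setting.ndim == 1
    pts = np.atleast_2d(setting)
    if pts.shape[1] != len(model.factors):
        raise DimensionError(
            f"setting of length {pts.shape[1]} for {len(model.factors)} factors"
        )
    coded = actual_to_coded(pts, model.factors)
    if is_extrapolation(coded).any():
        warnings.warn(
            "prediction outside the design box (extrapolation)", stacklevel=2
        )
    out = model_matrix(pts, model.terms) @ model.coefficients_actual
    return float(out[0]) if single else out


@dataclass
class AnovaTable:
    """Sum-of-squares decomposition with pure-error / lack-of-fit split."""

    ss_model: float
    ss_residual: float
    ss_pure_error: float
    ss_lack_of_fit: float
    df_model: int
    df_residual: int
    df_pure_error: int
    df_lack_of_fit: int
    f_model: float
    p_model: float
    f_lack_of_fit: float | None
    p_lack_of_fit: float | None
    term_f: dict[str, float] = field(default_factory=dict)
    term_p: dict[str, float] = field(default_factory=dict)
    lack_of_fit_unavailable: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_model + self.ss_residual


def _replicate_groups(design: DesignTable) -> list[list[int]]:
    groups: dict[tuple, list[int]] = {}
    for idx, run in enumerate(design.runs):
        key = tuple(round(c, 9) for c in run.coded)
        groups.setdefault(key, []).append(idx)
    return [ix for ix in groups.values() if len(ix) > 1]


def pure_error(design: DesignTable, response_name: str) -> tuple[float, int]:
    """Pure-error SS and df from replicated design settings (centre runs)."""
    y = design.response(response_name)
    groups = _replicate_groups(design)
    if not groups:
        raise PureErrorUnavailableError(
            "no replicated design settings; pure error cannot be estimated"
        )
    ss = sum(float(np.sum((y[ix] - np.mean(y[ix])) ** 2)) for ix in groups)
    df = sum(len(ix) - 1 for ix in groups)
    return ss, df


def _ss_residual_for(design: DesignTable, response_name: str, terms) -> float:
    y = design.response(response_name)
    X = model_matrix(design.coded_matrix(), terms)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova(model: QuadraticModel, design: DesignTable) -> AnovaTable:
    """ANOVA of a fitted model: overall F, per-term partial F, lack of fit.

    Per-term tests are drop-one (partial, Type-III) F-tests against the
    residual mean square of the full fitted model.  The lack-of-fit F uses
    the pure-error mean square from replicated settings; when no settings are
    replicated the lack-of-fit components are omitted with a flag.
    """
    y = design.response(model.response_name)
    n = design.n_runs
    p = model.n_terms
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = _ss_residual_for(design, model.response_name, model.terms)
    ss_mod = ss_tot - ss_res
    df_mod, df_res = p - 1, n - p
    ms_res = ss_res / df_res
    f_mod = (ss_mod / df_mod) / ms_res
    p_mod = float(stats.f.sf(f_mod, df_mod, df_res))

    term_f: dict[str, float] = {}
    term_p: dict[str, float] = {}
    for t in model.terms:
        if t.kind == "intercept":
            continue
        reduced = [u for u in model.terms if u != t]
        delta = _ss_residual_for(design, model.response_name, reduced) - ss_res
        fval = delta / ms_res
        term_f[t.label(model.factors)] = fval
        term_p[t.label(model.factors)] = float(stats.f.sf(fval, 1, df_res))

    try:
        ss_pe, df_pe = pure_error(design, model.response_name)
    except PureErrorUnavailableError:
        return AnovaTable(
            ss_model=ss_mod, ss_residual=ss_res,
            ss_pure_error=float("nan"), ss_lack_of_fit=float("nan"),
            df_model=df_mod, df_residual=df_res,
            df_pure_error=0, df_lack_of_fit=df_res,
            f_model=f_mod, p_model=p_mod,
            f_lack_of_fit=None, p_lack_of_fit=None,
            term_f=term_f, term_p=term_p,
            lack_of_fit_unavailable=True,
        )

    ss_lof = ss_res - ss_pe
    df_lof = df_res - df_pe
    if df_lof > 0 and ss_pe > 0:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof, p_lof = None, None
    return AnovaTable(
        ss_model=ss_mod, ss_residual=ss_res,
        ss_pure_error=ss_pe, ss_lack_of_fit=ss_lof,
        df_model=df_mod, df_residual=df_res,
        df_pure_error=df_pe, df_lack_of_fit=df_lof,
        f_model=f_mod, p_model=p_mod,
        f_lack_of_fit=f_lof, p_lack_of_fit=p_lof,
        term_f=term_f, term_p=term_p,
    )


def _eligible(terms: list[TermSpec], preserve_hierarchy: bool) -> list[TermSpec]:
    out = []
    for t in terms:
        if t.kind == "intercept":
            continue
        if preserve_hierarchy and t.kind == "linear":
            continue
        out.append(t)
    return out


def backward_eliminate(
    design: DesignTable,
    response_name: str,
    alpha: float = 0.05,
    preserve_hierarchy: bool = True,
    method: str = "single_pass",
    season_label: str | None = None,
) -> QuadraticModel:
    """Reduce the full quadratic by deleting non-significant terms.

    Parameters
    ----------
    alpha : float
        Retention threshold: a term stays when its partial-F p-value is
        below ``alpha``.
    preserve_hierarchy : bool
        When True (default) linear main effects are never deleted, so the
        reduced model remains hierarchical.
    method : {"single_pass", "stepwise"}
        ``single_pass`` deletes every non-significant eligible term of the
        full quadratic after one ANOVA and refits once.  ``stepwise``
        deletes one term at a time (largest p-value first), refitting and
        re-testing after each deletion.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("single_pass", "stepwise"):
        raise ValueError(f"unknown elimination method {method!r}")

    terms = full_quadratic_terms(len(design.factors))
    model = fit_quadratic(design, response_name, terms, season_label=season_label)

    if method == "single_pass":
        table = anova(model, design)
        keep = [
            t
            for t in model.terms
            if t not in _eligible(model.terms, preserve_hierarchy)
            or table.term_p[t.label(model.factors)] < alpha
        ]
        if len(keep) < len(model.terms):
            model = fit_quadratic(design, response_name, keep, season_label=season_label)
        return model

    while True:
        eligible = _eligible(model.terms, preserve_hierarchy)
        if not eligible:
            return model
        table = anova(model, design)
        pvals = {t: table.term_p[t.label(model.factors)] for t in eligible}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            return model
        keep = [t for t in model.terms if t != worst]
        model = fit_quadratic(design, response_name, keep, season_label=season_label)


@dataclass
class FitDiagnostics:
    """R-squared family and the PRESS statistic."""

    r2: float
    r2_adjusted: float
    r2_predicted: float
    press: float


def diagnostics(model: QuadraticModel, design: DesignTable) -> FitDiagnostics:
    """R2, adjusted R2, PRESS and predicted R2 for a fitted model.

    PRESS uses the closed-form leave-one-out identity e_i / (1 - h_ii) with
    h_ii the hat-matrix diagonal, so no refitting is required.
    """
    y = design.response(model.response_name)
    n, p = design.n_runs, model.n_terms
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedDiagnosticsError("constant response: SStot = 0")
    X = model_matrix(design.coded_matrix(), model.terms)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
    press = float(np.sum((resid / (1.0 - hat)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return FitDiagnostics(
        r2=r2, r2_adjusted=r2_adj, r2_predicted=1.0 - press / ss_tot, press=press
    )


def model_from_actual_coefficients(
    response_name: str,
    factors: list[FactorSpec],
    terms: list[TermSpec],
    coefficients_actual,
    season_label: str | None = None,
) -> QuadraticModel:
    """Build a model from actual-scale coefficients (e.g. a published equation).

    Coded-scale coefficients are recovered through the inverse of the exact
    re-expansion map, so both parameterisations predict identically.
    """
    given = dict(zip(terms, np.asarray(coefficients_actual, dtype=float)))
    if len(given) != len(terms) or len(coefficients_actual) != len(terms):
        raise DimensionError(
            f"{len(coefficients_actual)} coefficients for {len(terms)} terms"
        )
    terms = hierarchical_closure(terms)
    coefs = np.array([given.get(t, 0.0) for t in terms])
    M = coded_to_actual_coef_matrix(terms, factors)
    return QuadraticModel(
        response_name=response_name,
        factors=list(factors),
        terms=terms,
        coefficients_actual=coefs,
        coefficients_coded=np.linalg.solve(M, coefs),
        season_label=season_label,
    )


# ---------------------------------------------------------------------------
# JSON round-trip


def model_to_dict(model: QuadraticModel) -> dict:
    return {
        "response": model.response_name,
        "season": model.season_label,
        "factors": [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in model.factors
        ],
        "terms": [
            {"kind": t.kind, "factor_indices": list(t.factor_indices)}
            for t in model.terms
        ],
        "coefficients_actual": [float(c) for c in model.coefficients_actual],
        "coefficients_coded": [float(c) for c in model.coefficients_coded],
    }


def model_from_dict(payload: dict) -> QuadraticModel:
    try:
        factors = [FactorSpec(**f) for f in payload["factors"]]
        terms = [
            TermSpec(t["kind"], tuple(t["factor_indices"])) for t in payload["terms"]
        ]
        return QuadraticModel(
            response_name=payload["response"],
            factors=factors,
            terms=terms,
            coefficients_actual=np.asarray(payload["coefficients_actual"], dtype=float),
            coefficients_coded=np.asarray(payload["coefficients_coded"], dtype=float),
            season_label=payload.get("season"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed model JSON: {exc}") from exc


def save_model(model: QuadraticModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)


def load_model(path) -> QuadraticModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
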
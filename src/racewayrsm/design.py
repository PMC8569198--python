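"""Face-centred central composite (CCF) designs and the coded/actual transform.

A CCF design for k factors consists of the 2^k factorial corners (coded
levels +/-1), 2k axial points on the face centres (one coordinate +/-1, the
rest 0) and a number of replicated centre points (all coordinates 0).  Every
coded coordinate therefore lies in {-1, 0, +1}: unlike a rotatable central
composite design there are no star points outside the factor cube, which is
what makes the design practical when a factor cannot exceed its physical
range (a raceway cannot be shallower than its drain nor deeper than its
walls).

Coded and actual units are linked by the affine map

    actual = low + (coded + 1)/2 * (high - low)

applied componentwise, so coded -1/0/+1 correspond to the low, midpoint and
high actual levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidDesignError, SchemaError

__all__ = [
    "FactorSpec",
    "DesignRun",
    "DesignTable",
    "generate_ccf",
    "coded_to_actual",
    "actual_to_coded",
    "is_extrapolation",
    "write_design_csv",
    "read_design_csv",
]

_CODED_TOL = 1e-9


@dataclass(frozen=True)
class FactorSpec:
    """An experimental factor with its actual-unit range.

    Parameters
    ----------
    name : str
        Factor name, e.g. ``"dilution_rate"``.
    low, high : float
        Actual values mapped to coded -1 and +1.
    units : str
        Unit string for reports, e.g. ``"day^-1"`` or ``"m"``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidDesignError("factor name must be non-empty")
        if not self.low < self.high:
            raise InvalidDesignError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignRun:
    """One row of a design: coded and actual settings plus a centre flag."""

    run_id: int
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    is_center: bool

    def __post_init__(self) -> None:
        if len(self.coded) != len(self.actual):
            raise DimensionError("coded and actual vectors differ in length")


@dataclass
class DesignTable:
    """A design with per-run responses.

    ``responses`` maps a response name to one value per run, in run order.
    ``replicate_count`` records how many independent experiments each stored
    (mean) response summarises; it is bookkeeping only and does not enter the
    fit.
    """

    factors: list[FactorSpec]
    runs: list[DesignRun]
    responses: dict[str, list[float]] = field(default_factory=dict)
    replicate_count: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.factors)
        for run in self.runs:
            if len(run.coded) != k:
                raise DimensionError(
                    f"run {run.run_id} has {len(run.coded)} coordinates for {k} factors"
                )
        for name, values in self.responses.items():
            if len(values) != len(self.runs):
                raise SchemaError(
                    f"response {name!r} has {len(values)} values for {len(self.runs)} runs"
                )

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_center(self) -> int:
        return sum(run.is_center for run in self.runs)

    def coded_matrix(self) -> np.ndarray:
        return np.array([run.coded for run in self.runs], dtype=float)

    def actual_matrix(self) -> np.ndarray:
        return np.array([run.actual for run in self.runs], dtype=float)

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses:
            raise SchemaError(
                f"response {name!r} not in design (have {sorted(self.responses)})"
            )
        return np.asarray(self.responses[name], dtype=float)

    def with_response(self, name: str, values) -> "DesignTable":
        """Return a copy of this table with one response column replaced/added."""
        values = list(np.asarray(values, dtype=float))
        responses = dict(self.responses)
        responses[name] = values
        return DesignTable(
            factors=list(self.factors),
            runs=list(self.runs),
            responses=responses,
            replicate_count=dict(self.replicate_count),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {"run_id": [run.run_id for run in self.runs]}
        for j, f in enumerate(self.factors):
            cols[f"{f.name}_coded"] = [run.coded[j] for run in self.runs]
        for j, f in enumerate(self.factors):
            cols[f"{f.name}_actual"] = [run.actual[j] for run in self.runs]
        for name, values in self.responses.items():
            cols[name] = list(values)
        return pd.DataFrame(cols)


def coded_to_actual(coded, factors: list[FactorSpec]) -> np.ndarray:
    """Map coded coordinates in [-1, 1] to actual factor units."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise DimensionError(
            f"coded vector of length {coded.shape[-1]} for {len(factors)} factors"
        )
    low = np.array([f.low for f in factors])
    high = np.array([f.high for f in factors])
    return low + (coded + 1.0) / 2.0 * (high - low)


def actual_to_coded(actual, factors: list[FactorSpec]) -> np.ndarray:
    """Exact inverse of :func:`coded_to_actual`.

    Values outside the factor box map outside [-1, 1]; use
    :func:`is_extrapolation` to flag them.
    """
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != len(factors):
        raise DimensionError(
            f"actual vector of length {actual.shape[-1]} for {len(factors)} factors"
        )
    low = np.array([f.low for f in factors])
    high = np.array([f.high for f in factors])
    return 2.0 * (actual - low) / (high - low) - 1.0


def is_extrapolation(coded, tol: float = 1e-9) -> np.ndarray:
    """Componentwise flag: True where a coded coordinate leaves [-1, 1]."""
    coded = np.asarray(coded, dtype=float)
    return np.abs(coded) > 1.0 + tol


def generate_ccf(factors: list[FactorSpec], n_center: int = 3) -> DesignTable:
    """Generate a face-centred central composite design.

    Runs are ordered deterministically: the 2^k factorial corners in
    lexicographic coded order, then the 2k face-centred axial points in
    lexicographic order, then the ``n_center`` centre replicates.  ``run_id``
    is assigned 1..n in that order.  (In the field the processing order is
    randomised; the fit is invariant to it.)
    """
    k = len(factors)
    if k < 2:
        raise InvalidDesignError("a central composite design needs at least 2 factors")
    if n_center < 1:
        raise InvalidDesignError("n_center must be >= 1")

    factorial = sorted(itertools.product((-1.0, 1.0), repeat=k))
    axial = sorted(
        tuple(level if j == i else 0.0 for j in range(k))
        for i in range(k)
        for level in (-1.0, 1.0)
    )
    center = [tuple(0.0 for _ in range(k))] * n_center

    runs = []
    for run_id, coded in enumerate(factorial + axial + center, start=1):
        actual = tuple(coded_to_actual(coded, factors))
        runs.append(
            DesignRun(
                run_id=run_id,
                coded=coded,
                actual=actual,
                is_center=all(abs(c) < _CODED_TOL for c in coded),
            )
        )
    return DesignTable(factors=factors, runs=runs)


def write_design_csv(design: DesignTable, path) -> None:
    """Write the design CSV schema: run_id, coded, actual, response columns."""
    design.to_dataframe().to_csv(path, index=False)


def read_design_csv(path, factors: list[FactorSpec]) -> DesignTable:
    """Read a design CSV back into a :class:`DesignTable`.

    Coded columns may be absent; they are then reconstructed from the actual
    columns via :func:`actual_to_coded`.
    """
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise SchemaError("design CSV must contain a run_id column")
    actual_cols = [f"{f.name}_actual" for f in factors]
    for col in actual_cols:
        if col not in df.columns:
            raise SchemaError(f"design CSV missing actual column {col!r}")
    coded_cols = [f"{f.name}_coded" for f in factors]
    have_coded = all(col in df.columns for col in coded_cols)

    runs = []
    for _, row in df.iterrows():
        actual = tuple(float(row[c]) for c in actual_cols)
        if have_coded:
            coded = tuple(float(row[c]) for c in coded_cols)
        else:
            coded = tuple(actual_to_coded(actual, factors))
        runs.append(
            DesignRun(
                run_id=int(row["run_id"]),
                coded=coded,
                actual=actual,
                is_center=all(abs(c) < 1e-6 for c in coded),
            )
        )
    known = {"run_id", *coded_cols, *actual_cols}
    responses = {
        col: [float(v) for v in df[col]] for col in df.columns if col not in known
    }
    return DesignTable(factors=factors, runs=runs, responses=responses)
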
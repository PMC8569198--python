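"""The in-study design/response tables and published seasonal models.

The four seasonal experiments (winter, spring, summer, autumn) share one
face-centred central composite design in dilution rate (0.15-0.50 day^-1)
and culture depth (0.05-0.20 m): four factorial corners, four face centres
and a centre point replicated three times, 11 runs in all.  Each run's
biomass productivity (g m^-2 day^-1) is the mean of two independent
experiments.

Centre-point actual levels are the exact design midpoints (0.325 day^-1,
0.125 m); the source table prints them rounded (0.32/0.33 and 0.13), which
is inconsistent across rows, whereas the midpoint is analytically forced by
the design.

``PRINTED_MODELS`` holds the published reduced equations on the actual
scale and ``PRINTED_OPTIMA`` the published per-season optimisation output;
both serve as reference values for reproduction checks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .design import DesignRun, DesignTable, FactorSpec, coded_to_actual
from .errors import FixtureChecksumError, SchemaError
from .optimize import OptimizationResult
from .rsm import (
    INTERCEPT,
    QuadraticModel,
    TermSpec,
    model_from_actual_coefficients,
)

__all__ = [
    "SEASONS",
    "RESPONSE_NAME",
    "SeasonFixture",
    "raceway_factors",
    "raceway_design",
    "load_table1",
    "PRINTED_MODELS",
    "PRINTED_OPTIMA",
    "PRINTED_R2",
]

SEASONS = ("winter", "spring", "summer", "autumn")
RESPONSE_NAME = "biomass_productivity"

# (coded A, coded B) per run, in the published run order 1..11.
_CODED = [
    (0, 0), (0, 0), (0, 0),
    (-1, 1), (-1, 0), (-1, -1),
    (1, -1), (0, 1), (1, 0), (0, -1), (1, 1),
]

# Biomass productivity (g m^-2 day^-1), mean of two experiments, runs 1..11.
_RESPONSES = {
    "winter": [12.30, 11.11, 10.32, 8.50, 10.91, 11.5, 8.5, 9.2, 8.2, 11.8, 7.0],
    "spring": [20.1, 22.7, 21.5, 12.4, 13.3, 15.4, 24.6, 17.2, 20.9, 26.3, 15.3],
    "summer": [23.9, 27.04, 22.9, 10.8, 16.9, 15.9, 32.4, 19.3, 28.5, 30.2, 17.2],
    "autumn": [15.8, 16.1, 16.7, 10.6, 11.5, 15.7, 13.9, 12.9, 11.0, 19.6, 9.1],
}

_CHECKSUM = "4badc22eafba4d82ca11eb2c1e6e7cd92fd32066bfdb6b10895a52b8479d6e6b"

_A = TermSpec("linear", (0,))
_B = TermSpec("linear", (1,))
_AB = TermSpec("interaction", (0, 1))
_A2 = TermSpec("quadratic", (0,))

# Published reduced equations, actual scale: term -> coefficient.
_PRINTED_COEFS = {
    "winter": ([INTERCEPT, _A, _B, _A2], [8.68, 32.60, -15.53, -60.56]),
    "spring": ([INTERCEPT, _A, _B, _A2], [5.90, 113.41, -47.82, -145.43]),
    "summer": (
        [INTERCEPT, _A, _B, _AB, _A2],
        [-0.23, 149.57, -6.73, -192.00, -142.74],
    ),
    "autumn": ([INTERCEPT, _A, _B, _A2], [7.33, 86.23, -36.73, -138.11]),
}

#: Published determination coefficients of the reduced seasonal models.
PRINTED_R2 = {"winter": 0.869, "spring": 0.972, "summer": 0.941, "autumn": 0.863}

# Published optima: (dilution rate day^-1, depth m, P_b, desirability).
_PRINTED_OPTIMA = {
    "winter": (0.27, 0.05, 12.3, 0.99),
    "spring": (0.39, 0.05, 25.6, 0.95),
    "summer": (0.49, 0.06, 32.7, 1.00),
    "autumn": (0.31, 0.05, 18.9, 0.94),
}


@dataclass
class SeasonFixture:
    """One season's design table, published model and published optimum."""

    season: str
    design: DesignTable
    printed_model: QuadraticModel
    printed_optimum: OptimizationResult


def raceway_factors() -> list[FactorSpec]:
    return [
        FactorSpec("dilution_rate", 0.15, 0.50, "day^-1"),
        FactorSpec("depth", 0.05, 0.20, "m"),
    ]


def _fixture_digest() -> str:
    text = ";".join(
        f"{a},{b}" for a, b in _CODED
    ) + "|" + "|".join(
        s + ":" + ",".join(repr(v) for v in _RESPONSES[s]) for s in SEASONS
    )
    return hashlib.sha256(text.encode()).hexdigest()


def raceway_design(check: bool = True) -> DesignTable:
    """The 11-run experimental design with all four seasonal responses."""
    if check and _fixture_digest() != _CHECKSUM:
        raise FixtureChecksumError("bundled design/response table is corrupted")
    factors = raceway_factors()
    runs = [
        DesignRun(
            run_id=i + 1,
            coded=(float(a), float(b)),
            actual=tuple(coded_to_actual((a, b), factors)),
            is_center=(a == 0 and b == 0),
        )
        for i, (a, b) in enumerate(_CODED)
    ]
    return DesignTable(
        factors=factors,
        runs=runs,
        responses={s: list(_RESPONSES[s]) for s in SEASONS},
        replicate_count={i + 1: 2 for i in range(len(runs))},
    )


def load_table1() -> dict[str, SeasonFixture]:
    """Season -> fixture with design, published model and published optimum."""
    base = raceway_design()
    out: dict[str, SeasonFixture] = {}
    for season in SEASONS:
        design = DesignTable(
            factors=base.factors,
            runs=base.runs,
            responses={RESPONSE_NAME: list(_RESPONSES[season])},
            replicate_count=dict(base.replicate_count),
        )
        terms, coefs = _PRINTED_COEFS[season]
        model = model_from_actual_coefficients(
            RESPONSE_NAME, base.factors, terms, coefs, season_label=season
        )
        a_opt, b_opt, pb, desirability = _PRINTED_OPTIMA[season]
        optimum = OptimizationResult(
            optimal_setting=np.array([a_opt, b_opt]),
            predicted_response=pb,
            desirability=desirability,
            on_boundary=(False, b_opt == 0.05),
        )
        out[season] = SeasonFixture(
            season=season, design=design, printed_model=model, printed_optimum=optimum
        )
    return out


def _printed_model(season: str) -> QuadraticModel:
    terms, coefs = _PRINTED_COEFS[season]
    return model_from_actual_coefficients(
        RESPONSE_NAME, raceway_factors(), terms, coefs, season_label=season
    )


#: Published reduced equations as QuadraticModel objects, actual scale.
PRINTED_MODELS: dict[str, QuadraticModel] = {s: _printed_model(s) for s in SEASONS}

#: Published optimisation output per season:
#: (dilution rate day^-1, depth m, P_b g m^-2 day^-1, desirability).
PRINTED_OPTIMA: dict[str, tuple[float, float, float, float]] = dict(_PRINTED_OPTIMA)


def season_fixture(season: str) -> SeasonFixture:
    if season not in SEASONS:
        raise SchemaError(f"unknown season {season!r}; expected one of {SEASONS}")
    return load_table1()[season]
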
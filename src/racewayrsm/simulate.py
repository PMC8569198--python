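"""Synthetic datasets with the statistical structure the analysis assumes.

Two generators are provided.  ``simulate_design_response`` draws responses
on a design from a known quadratic surface plus i.i.d. Gaussian noise,
averaging a configurable number of replicate draws per run - the situation
the fitted tables summarise (each stored response is the mean of two
independent experiments).  ``simulate_wastewater`` draws inlet
concentrations uniformly within the composition ranges typical of urban
primary wastewater (ammonium-N 55-145, nitrate-N 2-11, phosphate-P 3-21,
COD 690-890 mg/L) and derives outlets from per-species removal fractions;
an optional nitrification term routes a fraction of the removed ammonium
into the nitrate outlet, so nitrate can exceed its inlet, as observed in
open reactors.

Neither generator emulates temporal dynamics, weather forcing, or
correlated measurement error; they exercise the estimation machinery, not
the ecology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignTable
from .errors import RacewayRSMError
from .nutrients import NutrientRecord
from .rsm import QuadraticModel, model_matrix

__all__ = [
    "SyntheticSpec",
    "WastewaterSpec",
    "simulate_design_response",
    "simulate_wastewater",
]

#: Composition windows (mg/L) of the urban primary wastewater feed.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "N-NH4": (55.0, 145.0),
    "N-NO3": (2.0, 11.0),
    "P-PO4": (3.0, 21.0),
    "COD": (690.0, 890.0),
}

#: Per-species removal-fraction windows. Ammonium removal in these systems
#: is near-complete; the others are broad stand-ins (only ranges of the feed
#: are published, not per-species removal distributions).
DEFAULT_REMOVAL: dict[str, tuple[float, float]] = {
    "N-NH4": (0.97, 0.99),
    "N-NO3": (0.2, 0.6),
    "P-PO4": (0.5, 0.9),
    "COD": (0.5, 0.8),
}


@dataclass
class SyntheticSpec:
    """Ground truth for a simulated design/response experiment.

    noise_sd is the replicate-level response noise in g m^-2 day^-1; the
    default 1.0 is of the order of the spread among the replicated centre
    runs of the seasonal tables.
    """

    true_model: QuadraticModel
    noise_sd: float = 1.0
    n_replicates: int = 2
    seed: int = 0
    season_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise RacewayRSMError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise RacewayRSMError("n_replicates must be >= 1")


@dataclass
class WastewaterSpec:
    """Sampling spec for synthetic wastewater inlet/outlet tables."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    removal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REMOVAL)
    )
    nitrification_fraction: tuple[float, float] = (0.0, 0.08)
    nitrification: bool = True
    n_samples: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise RacewayRSMError("n_samples must be >= 1")
        for sp, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise RacewayRSMError(f"range for {sp} has low > high")


def simulate_design_response(
    spec: SyntheticSpec, design: DesignTable
) -> DesignTable:
    """Draw a response column on ``design`` from the spec's true surface.

    Each run's stored response is the mean of ``n_replicates`` independent
    draws of prediction + Gaussian(0, noise_sd).  Reproducible given seed.
    """
    truth = spec.true_model
    if len(truth.factors) != len(design.factors):
        raise RacewayRSMError("true model and design disagree on factor count")
    rng = np.random.default_rng(spec.seed)
    clean = model_matrix(design.actual_matrix(), truth.terms) @ truth.coefficients_actual
    noise = rng.normal(0.0, spec.noise_sd, size=(design.n_runs, spec.n_replicates))
    observed = clean + noise.mean(axis=1)
    table = design.with_response(truth.response_name, observed)
    table.replicate_count = {
        run.run_id: spec.n_replicates for run in design.runs
    }
    return table


def simulate_wastewater(spec: WastewaterSpec) -> list[NutrientRecord]:
    """Draw inlet/outlet nutrient records for ``n_samples`` runs."""
    rng = np.random.default_rng(spec.seed)
    records: list[NutrientRecord] = []
    for run_id in range(1, spec.n_samples + 1):
        inlets = {
            sp: rng.uniform(lo, hi) for sp, (lo, hi) in spec.ranges.items()
        }
        removals = {
            sp: rng.uniform(lo, hi) for sp, (lo, hi) in spec.removal.items()
        }
        outlets = {sp: inlets[sp] * (1.0 - removals[sp]) for sp in inlets}
        if spec.nitrification and "N-NH4" in inlets and "N-NO3" in outlets:
            frac = rng.uniform(*spec.nitrification_fraction)
            removed_nh4 = inlets["N-NH4"] - outlets["N-NH4"]
            outlets["N-NO3"] += frac * removed_nh4
        for sp in inlets:
            records.append(
                NutrientRecord(
                    run_id=run_id, species=sp, inlet=inlets[sp], outlet=outlets[sp]
                )
            )
    return records
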
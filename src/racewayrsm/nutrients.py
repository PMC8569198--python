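"""Nutrient removal, areal rates, nitrogen mass balance and compliance.

Total inorganic nitrogen is taken as N-NH4+ plus N-NO3- (nitrite and
organic nitrogen are outside the accounting).  The nitrogen balance assumes
a fixed nitrogen content of the produced biomass (default 10% of dry
weight): nitrogen assimilated into biomass is that fraction of the areal
biomass productivity, and whatever was removed from the water beyond it is
"unaccounted" - lost to ammonia stripping or transformed by nitrifying
bacteria.  A negative unaccounted term (more nitrogen in biomass than
removed from the water) is physically infeasible under the assumptions and
is flagged rather than silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import RacewayRSMError, SchemaError, UndefinedRemovalError
from .reactor import OperationSetting, ReactorSpec, culture_volume, daily_harvest_volume

__all__ = [
    "SPECIES",
    "NutrientRecord",
    "NitrogenBalance",
    "DischargeLimits",
    "total_inorganic_n",
    "removal_percent",
    "areal_removal_rate",
    "nitrogen_mass_balance",
    "compliance_check",
    "write_nutrient_csv",
    "read_nutrient_csv",
]

SPECIES = ("N-NH4", "N-NO3", "P-PO4", "COD")


@dataclass(frozen=True)
class NutrientRecord:
    """Inlet/outlet concentration (mg/L) of one species in one run."""

    run_id: int
    species: str
    inlet: float
    outlet: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise SchemaError(f"unknown species {self.species!r}; expected {SPECIES}")
        if self.inlet < 0 or self.outlet < 0:
            raise RacewayRSMError("concentrations must be non-negative")


@dataclass
class NitrogenBalance:
    """Areal nitrogen budget (g N m^-2 day^-1) of one run."""

    removed_areal: float
    assimilated: float
    unaccounted: float
    biomass_n_fraction: float = 0.10
    infeasible: bool = False


@dataclass(frozen=True)
class DischargeLimits:
    """Regulatory discharge windows (mg/L); defaults follow Spanish limits."""

    n_limit: tuple[float, float] = (10.0, 15.0)
    p_limit: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.n_limit, self.p_limit):
            if lo > hi:
                raise RacewayRSMError("limit range lower bound exceeds upper bound")


def total_inorganic_n(nh4: float, no3: float) -> float:
    """Total inorganic nitrogen (mg/L) = ammonium-N + nitrate-N."""
    if nh4 < 0 or no3 < 0:
        raise RacewayRSMError("concentrations must be non-negative")
    return nh4 + no3


def removal_percent(inlet: float, outlet: float) -> float:
    """Percent of the inlet concentration removed; negative = net production.

    Nitrate routinely comes out negative here: nitrifying bacteria oxidise
    part of the removed ammonium to nitrate, so outlets can exceed inlets.
    """
    if inlet == 0:
        raise UndefinedRemovalError("removal undefined for zero inlet concentration")
    return 100.0 * (inlet - outlet) / inlet


def areal_removal_rate(
    inlet: float,
    outlet: float,
    setting: OperationSetting,
    reactor: ReactorSpec = ReactorSpec(),
    include_collector: bool = True,
) -> float:
    """Signed areal removal rate (mg m^-2 day^-1).

    Concentration difference x daily processed volume / illuminated surface.
    The harvested volume is based on the total culture volume (collector
    included by default) because the whole inventory is diluted daily.
    """
    volume = culture_volume(setting.depth, reactor, include_collector)
    processed = daily_harvest_volume(setting, volume)
    return (inlet - outlet) * processed / reactor.channel_area


def nitrogen_mass_balance(
    removed_areal: float, pb: float, n_fraction: float = 0.10
) -> NitrogenBalance:
    """Split the removed nitrogen into biomass assimilation and losses.

    ``removed_areal`` and ``pb`` in g m^-2 day^-1.  assimilated =
    n_fraction x pb; unaccounted = removed - assimilated (positive means
    stripping and/or nitrification losses).
    """
    if not 0.0 < n_fraction < 1.0:
        raise RacewayRSMError("n_fraction must be in (0, 1)")
    if pb < 0:
        raise RacewayRSMError("biomass productivity must be >= 0")
    assimilated = n_fraction * pb
    unaccounted = removed_areal - assimilated
    # store the closed sum so conservation holds exactly in floating point
    # (differs from the input by at most one rounding step)
    return NitrogenBalance(
        removed_areal=assimilated + unaccounted,
        assimilated=assimilated,
        unaccounted=unaccounted,
        biomass_n_fraction=n_fraction,
        infeasible=unaccounted < 0,
    )


def _status(value: float, limit: tuple[float, float]) -> str:
    lo, hi = limit
    if value < lo:
        return "compliant"
    if value <= hi:
        return "marginal"
    return "non-compliant"


def compliance_check(
    outlet_n: float,
    outlet_p: float,
    limits: DischargeLimits = DischargeLimits(),
) -> dict[str, str]:
    """Compare outlet N and P against the discharge windows.

    Below the window: compliant; inside: marginal (meets the lenient but not
    the strict end); above: non-compliant.
    """
    if outlet_n < 0 or outlet_p < 0:
        raise RacewayRSMError("concentrations must be non-negative")
    return {
        "nitrogen": _status(outlet_n, limits.n_limit),
        "phosphorus": _status(outlet_p, limits.p_limit),
    }


def write_nutrient_csv(records: list[NutrientRecord], path) -> None:
    pd.DataFrame(
        {
            "run_id": [r.run_id for r in records],
            "species": [r.species for r in records],
            "inlet_mg_L": [r.inlet for r in records],
            "outlet_mg_L": [r.outlet for r in records],
        }
    ).to_csv(path, index=False)


def read_nutrient_csv(path) -> list[NutrientRecord]:
    df = pd.read_csv(path)
    required = {"run_id", "species", "inlet_mg_L", "outlet_mg_L"}
    if not required.issubset(df.columns):
        raise SchemaError(f"nutrient CSV must have columns {sorted(required)}")
    return [
        NutrientRecord(
            run_id=int(row.run_id),
            species=str(row.species),
            inlet=float(row.inlet_mg_L),
            outlet=float(row.outlet_mg_L),
        )
        for row in df.itertuples()
    ]
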
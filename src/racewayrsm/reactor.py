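"""Operational arithmetic of the raceway photobioreactor.

The pilot raceway has two 6 m x 0.6 m channels (8.33 m^2 illuminated
surface) plus a 170 L collector sump.  Culture volume scales linearly with
depth; in semi-continuous operation a fraction of the total volume equal to
the dilution rate is harvested and replaced with wastewater every day.
Areal biomass productivity converts the volumetric productivity (biomass
concentration x dilution rate) to the illuminated surface.

Note the published volume range 586-1840 L is internally inconsistent at
the upper end: 0.20 m x 8.33 m^2 + 170 L = 1836 L (1840 would require
~8.35 m^2).  The functions here use the stated geometry and accept the
few-litre discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RacewayRSMError

__all__ = [
    "ReactorSpec",
    "OperationSetting",
    "culture_volume",
    "daily_harvest_volume",
    "areal_productivity",
    "concentration_for_productivity",
]


@dataclass(frozen=True)
class ReactorSpec:
    """Raceway geometry: illuminated channel area (m^2) and collector (L)."""

    channel_area: float = 8.33
    collector_volume: float = 170.0
    name: str = "pilot raceway"

    def __post_init__(self) -> None:
        if self.channel_area <= 0:
            raise RacewayRSMError("channel_area must be positive")
        if self.collector_volume < 0:
            raise RacewayRSMError("collector_volume must be non-negative")


@dataclass(frozen=True)
class OperationSetting:
    """Daily operating point: dilution rate (day^-1), depth (m), C_b (g/L)."""

    dilution_rate: float
    depth: float
    biomass_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_rate <= 1.0:
            raise RacewayRSMError("dilution_rate must be in (0, 1]")
        if self.depth <= 0:
            raise RacewayRSMError("depth must be positive")
        if self.biomass_concentration < 0:
            raise RacewayRSMError("biomass_concentration must be >= 0")


def culture_volume(
    depth: float,
    reactor: ReactorSpec = ReactorSpec(),
    include_collector: bool = True,
) -> float:
    """Total culture volume in litres at the given depth.

    depth (m) x channel area (m^2) x 1000 L/m^3, plus the collector sump
    when ``include_collector`` (the default: the collector holds culture).
    """
    if depth <= 0:
        raise RacewayRSMError("depth must be positive")
    volume = depth * reactor.channel_area * 1000.0
    if include_collector:
        volume += reactor.collector_volume
    return volume


def daily_harvest_volume(setting: OperationSetting, volume: float) -> float:
    """Volume harvested and replaced per day (L/day) = D x total volume."""
    if volume <= 0:
        raise RacewayRSMError("volume must be positive")
    return setting.dilution_rate * volume


def areal_productivity(
    setting: OperationSetting,
    reactor: ReactorSpec = ReactorSpec(),
    include_collector: bool = False,
) -> float:
    """Areal biomass productivity (g m^-2 day^-1).

    C_b (g/L) x D (day^-1) x volume-per-surface (L/m^2).  By default only
    the light-exposed channel volume enters the conversion; the dark
    collector can be included for a total-inventory accounting.
    """
    volume = culture_volume(setting.depth, reactor, include_collector)
    return (
        setting.biomass_concentration
        * setting.dilution_rate
        * volume
        / reactor.channel_area
    )


def concentration_for_productivity(
    pb: float,
    dilution_rate: float,
    depth: float,
    reactor: ReactorSpec = ReactorSpec(),
    include_collector: bool = False,
) -> float:
    """Biomass concentration (g/L) needed for a target areal productivity."""
    volume = culture_volume(depth, reactor, include_collector)
    return pb * reactor.channel_area / (dilution_rate * volume)
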
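"""Greenhouse lettuce production economics: density-averaged income, resource
costs and net profit per m^2 of growing area.

The economic basis of a spaced lettuce batch is the *average crop density*:
because plants occupy more floor area after every spacing step, income and
resource use are expressed per m^2 using the harmonic mean of the daily
densities over the cycle.  Income is head price times average density; costs
are fixed costs, metered resource use (heating, on/off-peak electricity,
CO2) and a charge per manual intervention on the autonomous controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .schedule import DensitySchedule

#: kWh per MJ, exact.
MJ_TO_KWH = 1.0 / 3.6

#: On-peak electricity window, half-open clock hours [start, end).
ON_PEAK_HOURS = (7, 23)


class EconomicsError(ValueError):
    pass


@dataclass(frozen=True)
class Tariffs:
    """Resource tariffs and head prices (EUR), with the quality target weight.

    Class A heads (>= 250 g, well formed) are sold at full price, class B
    (220-250 g) at a reduced price and class C (underweight or malformed)
    is unsellable.
    """

    heating_eur_per_kwh: float = 0.0375
    electricity_on_peak_eur_per_kwh: float = 0.125
    electricity_off_peak_eur_per_kwh: float = 0.075
    co2_eur_per_kg: float = 0.12
    intervention_eur: float = 1.0
    head_prices: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.50, "B": 0.40, "C": 0.00}
    )
    target_weight_g: float = 250.0

    def __post_init__(self) -> None:
        vals = [
            self.heating_eur_per_kwh,
            self.electricity_on_peak_eur_per_kwh,
            self.electricity_off_peak_eur_per_kwh,
            self.co2_eur_per_kg,
            self.intervention_eur,
            self.target_weight_g,
            *self.head_prices.values(),
        ]
        if any(v < 0 for v in vals):
            raise EconomicsError("tariffs must be non-negative")


def classify_weight(weight_g: float, malformed: bool = False) -> str:
    """Quality class of one head: A >= 250 g, B in [220, 250) g, C otherwise."""
    if malformed:
        return "C"
    if weight_g >= 250.0:
        return "A"
    if weight_g >= 220.0:
        return "B"
    return "C"


def average_crop_density(schedule: DensitySchedule, total_days: int) -> float:
    """Average crop density over the cycle, heads/m^2.

    Defined as D / sum_d(1/density_d) over days d = 1..D — the harmonic mean
    of the daily densities, i.e. total head-days per m^2-day of occupied floor.
    """
    daily = schedule.daily_densities(total_days)
    if any(x == 0 for x in daily):
        raise EconomicsError("zero density encountered")
    return total_days / float(np.sum(1.0 / np.asarray(daily)))


def income(
    class_fractions: Mapping[str, float],
    avg_density: float,
    tariffs: Tariffs | None = None,
) -> float:
    """Income in EUR/m^2: average density times fraction-weighted head price."""
    tariffs = tariffs or Tariffs()
    total = sum(class_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise EconomicsError(f"class fractions sum to {total}, expected 1")
    unknown = set(class_fractions) - set(tariffs.head_prices)
    if unknown:
        raise EconomicsError(f"unknown quality classes: {sorted(unknown)}")
    price = sum(f * tariffs.head_prices[c] for c, f in class_fractions.items())
    return avg_density * price


def resource_costs(
    heating_mj_per_m2: float,
    electricity_kwh_by_hour: Sequence[tuple[int, float]] | Mapping[int, float],
    co2_kg_per_m2: float,
    tariffs: Tariffs | None = None,
) -> dict[str, float]:
    """Cost components in EUR/m^2 from metered resource use.

    Heating is metered in MJ/m^2 but priced per kWh (1 kWh = 3.6 MJ).
    Electricity is an hourly series of (clock hour, kWh/m^2) entries split
    into on-peak [07:00, 23:00) and off-peak tariffs.
    """
    tariffs = tariffs or Tariffs()
    if isinstance(electricity_kwh_by_hour, Mapping):
        entries = list(electricity_kwh_by_hour.items())
    else:
        entries = list(electricity_kwh_by_hour)
    if heating_mj_per_m2 < 0 or co2_kg_per_m2 < 0 or any(k < 0 for _, k in entries):
        raise EconomicsError("resource use must be non-negative")
    on = sum(k for h, k in entries if ON_PEAK_HOURS[0] <= (h % 24) < ON_PEAK_HOURS[1])
    off = sum(k for h, k in entries if not ON_PEAK_HOURS[0] <= (h % 24) < ON_PEAK_HOURS[1])
    return {
        "heating": heating_mj_per_m2 * MJ_TO_KWH * tariffs.heating_eur_per_kwh,
        "electricity": on * tariffs.electricity_on_peak_eur_per_kwh
        + off * tariffs.electricity_off_peak_eur_per_kwh,
        "co2": co2_kg_per_m2 * tariffs.co2_eur_per_kg,
    }


@dataclass(frozen=True)
class EconomicLedger:
    """One batch's income and cost components, EUR/m^2.

    ``operational_total`` may be supplied when a ledger reports a rounded
    total alongside its components (as printed tables do); when None it is
    the sum of fixed + heating + electricity + co2.
    Interventions are counted; their cost is count * tariff.
    """

    income: float = 0.0
    fixed: float = 0.0
    heating: float = 0.0
    electricity: float = 0.0
    co2: float = 0.0
    interventions: float = 0.0
    operational_total: float | None = None

    def operational_costs(self) -> float:
        if self.operational_total is not None:
            return self.operational_total
        return self.fixed + self.heating + self.electricity + self.co2

    def intervention_costs(self, tariffs: Tariffs | None = None) -> float:
        return self.interventions * (tariffs or Tariffs()).intervention_eur

    def net_profit(self, tariffs: Tariffs | None = None) -> float:
        return self.income - self.operational_costs() - self.intervention_costs(tariffs)


def net_profit(ledger: EconomicLedger, tariffs: Tariffs | None = None) -> float:
    """Net profit in EUR/m^2 = income − operational costs − intervention costs."""
    return ledger.net_profit(tariffs)


# Published worked example: the six autonomously controlled compartments of a
# greenhouse-challenge benchmark cycle (income and costs as printed, EUR/m^2;
# interventions are counts, priced at 1 EUR each).  The printed operational
# totals are carried alongside the components because three columns were
# rounded inconsistently in the source.
COMPARTMENT_LEDGERS: dict[str, EconomicLedger] = {
    "CVA": EconomicLedger(12.16, 7.85, 0.01, 0.23, 0.60, 2, operational_total=8.69),
    "VeggieMight": EconomicLedger(10.38, 6.41, 0.29, 0.00, 0.53, 1, operational_total=7.24),
    "DigitalCucumbers": EconomicLedger(15.84, 8.50, 0.16, 0.46, 0.34, 3, operational_total=9.45),
    "Koala": EconomicLedger(14.16, 7.06, 0.04, 0.00, 0.11, 1, operational_total=7.24),
    "MondayLettuce": EconomicLedger(11.83, 9.64, 0.03, 0.45, 0.18, 2, operational_total=10.30),
    "Reference": EconomicLedger(12.12, 6.59, 0.02, 0.34, 0.53, 0, operational_total=7.48),
}
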
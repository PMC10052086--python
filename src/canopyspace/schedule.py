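"""Plant-density schedules for spaced hydroponic lettuce batches.

A batch starts at a high planting density and is stepped down a fixed
ladder of densities (heads/m^2) as the canopy closes.  The schedule is the
shared contract between the scene generator, the spacing indicators and
the economics: it records on which day which density came into force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The spacing ladder available to the spacing system, heads/m^2,
#: from the planting density down to the final density.
LADDER: tuple[float, ...] = (92.0, 60.0, 45.0, 30.0, 23.0, 18.0, 15.0)


class ScheduleError(ValueError):
    """Raised for schedules that are not physically realisable."""


def next_ladder_density(density: float, ladder: Sequence[float] = LADDER) -> float | None:
    """Return the next (lower) density on the ladder, or None if exhausted.

    ``density`` is matched to the nearest ladder rung to tolerate realized
    densities that deviate slightly from the nominal values.
    """
    idx = min(range(len(ladder)), key=lambda i: abs(ladder[i] - density))
    if idx + 1 < len(ladder):
        return ladder[idx + 1]
    return None


@dataclass(frozen=True)
class DensitySchedule:
    """Ordered (day, heads/m^2) events; the first event is the planting density.

    Densities must be strictly decreasing over events — plants are never
    re-crowded.  Days are integers counted from planting (day 0).
    """

    events: tuple[tuple[int, float], ...] = field(default_factory=lambda: ((0, LADDER[0]),))

    def __post_init__(self) -> None:
        if not self.events:
            raise ScheduleError("schedule needs at least the planting event")
        days = [d for d, _ in self.events]
        dens = [x for _, x in self.events]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ScheduleError("event days must be strictly increasing")
        if any(x <= 0 for x in dens):
            raise ScheduleError("densities must be positive")
        if any(b >= a for a, b in zip(dens, dens[1:])):
            raise ScheduleError(f"density increase over time is not allowed: {dens}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "DensitySchedule":
        return cls(tuple((int(d), float(x)) for d, x in pairs))

    def density_on(self, day: int) -> float:
        """Density in force on ``day`` (events take effect on their day)."""
        if day < self.events[0][0]:
            raise ScheduleError(f"day {day} precedes planting day {self.events[0][0]}")
        current = self.events[0][1]
        for d, x in self.events:
            if d <= day:
                current = x
        return current

    def daily_densities(self, total_days: int) -> list[float]:
        """Densities for days 1..total_days (the basis of the average density)."""
        if total_days < 1:
            raise ScheduleError("total_days must be >= 1")
        return [self.density_on(d) for d in range(1, total_days + 1)]

    @property
    def transitions(self) -> list[tuple[int, float, float]]:
        """Spacing events as (day, density_before, density_after)."""
        out = []
        for (d0, x0), (d1, x1) in zip(self.events, self.events[1:]):
            out.append((d1, x0, x1))
        return out
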
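"""Domain types for phenophase-resolved bipartite networks.

The temporal unit throughout the package is the integer day-of-year; all
intervals are closed, ``[start_day, end_day]``, and an interval's length is
``end_day - start_day + 1`` days.  A species' *phenophase* is the interval
between its first and last observed interaction in a season — its network
membership period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DataError

PLANT = "plant"
POLLINATOR = "pollinator"
GUILDS = (PLANT, POLLINATOR)

#: Trophic roles a flower visitor may carry (tail visitors at the study
#: system include parasitoids and hyper-parasitoids that visit flowers).
TROPHIC_ROLES = ("visitor", "parasitoid", "hyper_parasitoid")


@dataclass(frozen=True, order=True)
class Phenophase:
    """Closed day-of-year interval during which a species is network-active."""

    species_id: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise DataError(
                f"phenophase of {self.species_id!r}: start_day {self.start_day} "
                f"> end_day {self.end_day}"
            )

    @property
    def length(self) -> int:
        """Number of days, inclusive of both endpoints (always >= 1)."""
        return self.end_day - self.start_day + 1

    def covers(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day

    def overlaps(self, other: "Phenophase") -> bool:
        return self.start_day <= other.end_day and other.start_day <= self.end_day

    def intersect_window(self, window: tuple[int, int]) -> Optional[tuple[int, int]]:
        """Intersection with a closed (start, end) window, or None if empty."""
        lo = max(self.start_day, window[0])
        hi = min(self.end_day, window[1])
        return (lo, hi) if lo <= hi else None


@dataclass(frozen=True)
class ObservationRecord:
    """One flower-visitation event: a pollinator seen on a plant on a day."""

    day: int
    plant_id: str
    pollinator_id: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DataError(
                f"observation ({self.day}, {self.plant_id}, {self.pollinator_id}): "
                f"negative count {self.count}"
            )


@dataclass(frozen=True)
class SpeciesInfo:
    """Metadata for one species: guild and optional taxonomic/trophic labels."""

    id: str
    guild: str
    group: Optional[str] = None
    trophic_role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise DataError(f"species {self.id!r}: unknown guild {self.guild!r}")
        if self.trophic_role is not None and self.trophic_role not in TROPHIC_ROLES:
            raise DataError(
                f"species {self.id!r}: unknown trophic role {self.trophic_role!r}"
            )


@dataclass(frozen=True)
class BipartiteNetwork:
    """A 2-mode plant–pollinator network, optionally restricted to a time window.

    ``plants`` and ``pollinators`` are the species active in the window
    (their phenophase intersects it); ``links`` are (plant_id, pollinator_id)
    pairs active in the window.  Species sets may contain species with no
    link in the window (isolated in that slice).
    """

    plants: frozenset[str]
    pollinators: frozenset[str]
    links: frozenset[tuple[str, str]]
    window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        overlap = self.plants & self.pollinators
        if overlap:
            raise DataError(f"species in both guilds: {sorted(overlap)[:5]}")
        for p, a in self.links:
            if p not in self.plants:
                raise DataError(f"link ({p!r}, {a!r}): plant not in plant set")
            if a not in self.pollinators:
                raise DataError(f"link ({p!r}, {a!r}): pollinator not in pollinator set")

    # -- counts, using the field's standard symbols ---------------------
    @property
    def A(self) -> int:
        """Number of pollinator (animal) species."""
        return len(self.pollinators)

    @property
    def P(self) -> int:
        """Number of plant species."""
        return len(self.plants)

    @property
    def I(self) -> int:  # noqa: E743 - standard symbol for link count
        """Number of links."""
        return len(self.links)

    @property
    def species(self) -> frozenset[str]:
        return self.plants | self.pollinators

    @property
    def is_empty(self) -> bool:
        """True when either guild has no active species (connectance undefined)."""
        return self.P == 0 or self.A == 0

    def guild_of(self, species_id: str) -> str:
        if species_id in self.plants:
            return PLANT
        if species_id in self.pollinators:
            return POLLINATOR
        raise DataError(f"species {species_id!r} not in network")

    def partners(self, species_id: str) -> frozenset[str]:
        guild = self.guild_of(species_id)
        if guild == PLANT:
            return frozenset(a for p, a in self.links if p == species_id)
        return frozenset(p for p, a in self.links if a == species_id)


@dataclass(frozen=True)
class NetworkSummary:
    """Structural summary of one network (one row of a static-vs-daily table).

    ``C`` is connectance in percent, ``100 * I / (A * P)``; it is None for
    networks where a guild is empty.  Tail/core counts use the linkage-level
    rule (tail: L <= 2; core: L > 2), and ``*_rel_tail`` is t / (c + t).
    """

    A: int
    P: int
    I: int  # noqa: E741 - standard symbol
    C: Optional[float]
    plant_tail: int
    plant_core: int
    pollinator_tail: int
    pollinator_core: int
    plant_rel_tail: Optional[float]
    pollinator_rel_tail: Optional[float]
    n_isolated: int
    window: Optional[tuple[int, int]] = None

    def to_dict(self) -> dict:
        d = {
            "A": self.A,
            "P": self.P,
            "I": self.I,
            "C": self.C,
            "plant_tail": self.plant_tail,
            "plant_core": self.plant_core,
            "pollinator_tail": self.pollinator_tail,
            "pollinator_core": self.pollinator_core,
            "plant_rel_tail": self.plant_rel_tail,
            "pollinator_rel_tail": self.pollinator_rel_tail,
            "n_isolated": self.n_isolated,
            "window_start": self.window[0] if self.window else None,
            "window_end": self.window[1] if self.window else None,
        }
        return d
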
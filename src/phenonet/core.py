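"""Network construction and basic structural metrics.

The central rule is the *activity rule*: if at least one interaction was
observed between a plant and a pollinator, the pair is scored as
interacting during their entire phenophase overlap.  A network restricted
to a time window therefore contains every species whose phenophase
intersects the window, and every observed pair whose joint phenophase
overlap intersects the window.  Cutting the season into 1-day windows
yields the dynamical (daily) view; the full-season window yields the
static view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import DataError
from .types import (
    PLANT,
    POLLINATOR,
    BipartiteNetwork,
    NetworkSummary,
    ObservationRecord,
    Phenophase,
)

TAIL_MAX_L = 2  # linkage-level threshold: tail species have L <= 2


def percent_round(x: float) -> int:
    """Round a percentage half-up to an integer, for reporting."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Phenophases and the season
# ---------------------------------------------------------------------------

def infer_phenophases(records: Sequence[ObservationRecord]) -> dict[str, Phenophase]:
    """Infer each species' phenophase from observation records.

    A species' phenophase runs from the first to the last day it was
    observed interacting, regardless of which partner it interacted with.
    Species never observed are absent from the result.
    """
    if not records:
        raise DataError("cannot infer phenophases from an empty record list")
    first: dict[str, int] = {}
    last: dict[str, int] = {}
    for rec in records:
        for sid in (rec.plant_id, rec.pollinator_id):
            if sid not in first:
                first[sid] = last[sid] = rec.day
            else:
                first[sid] = min(first[sid], rec.day)
                last[sid] = max(last[sid], rec.day)
    return {sid: Phenophase(sid, first[sid], last[sid]) for sid in first}


def season_bounds(records: Sequence[ObservationRecord]) -> tuple[int, int, int]:
    """(start_day, end_day, length) of the network season spanned by records."""
    if not records:
        raise DataError("cannot compute season bounds of an empty record list")
    days = [rec.day for rec in records]
    start, end = min(days), max(days)
    return start, end, end - start + 1


def observed_pairs(records: Sequence[ObservationRecord]) -> frozenset[tuple[str, str]]:
    """Distinct (plant, pollinator) pairs with at least one observation."""
    return frozenset((r.plant_id, r.pollinator_id) for r in records)


def filter_to_season(
    records: Sequence[ObservationRecord], season: tuple[int, int]
) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
    """Split records into (within-season, dropped) under an explicit season."""
    kept, dropped = [], []
    for rec in records:
        (kept if season[0] <= rec.day <= season[1] else dropped).append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _phenophase_extent(phenophases: Mapping[str, Phenophase]) -> tuple[int, int]:
    if not phenophases:
        raise DataError("empty phenophase table")
    return (
        min(p.start_day for p in phenophases.values()),
        max(p.end_day for p in phenophases.values()),
    )


def _guilds_from_pairs(
    pairs: Iterable[tuple[str, str]],
    phenophases: Mapping[str, Phenophase],
) -> tuple[set[str], set[str]]:
    plants: set[str] = set()
    pollinators: set[str] = set()
    for p, a in pairs:
        if p not in phenophases:
            raise DataError(f"pair ({p!r}, {a!r}) references unknown plant {p!r}")
        if a not in phenophases:
            raise DataError(f"pair ({p!r}, {a!r}) references unknown pollinator {a!r}")
        plants.add(p)
        pollinators.add(a)
    conflict = plants & pollinators
    if conflict:
        raise DataError(f"species appear in both guilds: {sorted(conflict)[:5]}")
    return plants, pollinators


def build_network(
    phenophases: Mapping[str, Phenophase],
    interacting_pairs: Iterable[tuple[str, str]],
    window: Optional[tuple[int, int]] = None,
    guilds: Optional[Mapping[str, str]] = None,
) -> BipartiteNetwork:
    """Build the network active in a time window under the activity rule.

    A species is included iff its phenophase intersects the window; a link
    iff the pair was observed and the window intersects both phenophases'
    overlap.  ``window=None`` (or the full season) yields the static
    network.  Guild membership is inferred from the pairs; pass ``guilds``
    (id -> "plant"/"pollinator") to also place species that occur in no
    pair.
    """
    pairs = frozenset(interacting_pairs)
    plants, pollinators = _guilds_from_pairs(pairs, phenophases)
    if guilds is not None:
        for sid, g in guilds.items():
            if sid not in phenophases:
                continue
            target = plants if g == PLANT else pollinators
            other = pollinators if g == PLANT else plants
            if sid in other:
                raise DataError(f"species {sid!r} declared {g} but linked as other guild")
            target.add(sid)
    if window is None:
        window = _phenophase_extent(phenophases)

    def active(sid: str) -> bool:
        return phenophases[sid].intersect_window(window) is not None

    w_plants = frozenset(s for s in plants if active(s))
    w_pollinators = frozenset(s for s in pollinators if active(s))
    w_links = set()
    for p, a in pairs:
        pp, pa = phenophases[p], phenophases[a]
        lo = max(pp.start_day, pa.start_day, window[0])
        hi = min(pp.end_day, pa.end_day, window[1])
        if lo <= hi:
            w_links.add((p, a))
    return BipartiteNetwork(w_plants, w_pollinators, frozenset(w_links), window)


def slice_daily(
    phenophases: Mapping[str, Phenophase],
    interacting_pairs: Iterable[tuple[str, str]],
    season: Optional[tuple[int, int]] = None,
    guilds: Optional[Mapping[str, str]] = None,
) -> list[BipartiteNetwork]:
    """One network per day of the season (slice thickness of one day)."""
    if season is None:
        season = _phenophase_extent(phenophases)
    pairs = frozenset(interacting_pairs)
    return [
        build_network(phenophases, pairs, (d, d), guilds=guilds)
        for d in range(season[0], season[1] + 1)
    ]


def aggregate_window(
    phenophases: Mapping[str, Phenophase],
    interacting_pairs: Iterable[tuple[str, str]],
    window_length: int,
    season: Optional[tuple[int, int]] = None,
    guilds: Optional[Mapping[str, str]] = None,
) -> list[BipartiteNetwork]:
    """Consecutive non-overlapping windows of ``window_length`` days.

    The last window is truncated at the season end; a window length equal
    to the season length reproduces the static network.
    """
    if window_length < 1:
        raise DataError(f"window_length must be >= 1, got {window_length}")
    if season is None:
        season = _phenophase_extent(phenophases)
    pairs = frozenset(interacting_pairs)
    nets = []
    d = season[0]
    while d <= season[1]:
        end = min(d + window_length - 1, season[1])
        nets.append(build_network(phenophases, pairs, (d, end), guilds=guilds))
        d = end + 1
    return nets


# ---------------------------------------------------------------------------
# Structural metrics
# ---------------------------------------------------------------------------

def connectance(net: BipartiteNetwork) -> float:
    """Connectance C = 100 * I / (A * P), in percent."""
    if net.is_empty:
        raise DataError("connectance undefined: a guild has no species")
    return 100.0 * net.I / (net.A * net.P)


def linkage_level(net: BipartiteNetwork, species_id: str) -> int:
    """L, the number of links of a species in this network."""
    if species_id not in net.species:
        raise DataError(f"species {species_id!r} not in network")
    return len(net.partners(species_id))


@dataclass(frozen=True)
class CoreTailMap:
    """Core/tail labels per species, with isolated (L = 0) species flagged.

    Behaves as a read-only mapping from species id to ``"core"``/``"tail"``.
    Isolated species are tail by the L <= 2 rule but flagged so reports can
    audit them.
    """

    labels: Mapping[str, str]
    isolated: frozenset[str]

    def __getitem__(self, sid: str) -> str:
        return self.labels[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def guild_counts(self, net: BipartiteNetwork, guild: str) -> tuple[int, int]:
        """(t, c): tail and core counts within one guild of ``net``."""
        members = net.plants if guild == PLANT else net.pollinators
        t = sum(1 for s in members if self.labels[s] == "tail")
        return t, len(members) - t


def classify_core_tail(net: BipartiteNetwork) -> CoreTailMap:
    """Partition species into tail (L <= 2) and core (L > 2)."""
    if not net.species:
        raise DataError("cannot classify an empty network")
    degree: dict[str, int] = {s: 0 for s in net.species}
    for p, a in net.links:
        degree[p] += 1
        degree[a] += 1
    labels = {s: ("tail" if d <= TAIL_MAX_L else "core") for s, d in degree.items()}
    isolated = frozenset(s for s, d in degree.items() if d == 0)
    return CoreTailMap(labels, isolated)


def relative_tail_length(
    net: BipartiteNetwork, guild: str, core_tail: Optional[CoreTailMap] = None
) -> float:
    """Relative tail length t / (c + t) for one guild."""
    members = net.plants if guild == PLANT else net.pollinators
    if not members:
        raise DataError(f"no {guild} species in network")
    if core_tail is None:
        core_tail = classify_core_tail(net)
    t, c = core_tail.guild_counts(net, guild)
    return t / (c + t)


def phenophase_L_regression(
    phenophases: Mapping[str, Phenophase],
    net: BipartiteNetwork,
    guild: Optional[str] = None,
) -> tuple[float, float, float]:
    """OLS fit of phenophase length on linkage level L.

    Returns (slope, intercept, R^2).  Restrict to one guild with ``guild``.
    """
    members = net.species if guild is None else (
        net.plants if guild == PLANT else net.pollinators
    )
    pts = [
        (linkage_level(net, s), phenophases[s].length)
        for s in sorted(members)
        if s in phenophases
    ]
    if len(pts) < 3:
        raise DataError(f"regression needs >= 3 species with phenophases, got {len(pts)}")
    xs = [x for x, _ in pts]
    if len(set(xs)) == 1:
        raise DataError("regression undefined: all linkage levels identical")
    res = stats.linregress(xs, [y for _, y in pts])
    return res.slope, res.intercept, res.rvalue**2


# ---------------------------------------------------------------------------
# Summaries (static-vs-dynamical comparison table)
# ---------------------------------------------------------------------------

def network_summary(
    net: BipartiteNetwork, core_tail: Optional[CoreTailMap] = None
) -> NetworkSummary:
    """Summarise one network.

    By default core/tail status is computed from the network's own linkage
    levels (a species generalist over the season may be a daily
    specialist); pass ``core_tail`` to impose season-wide status instead.
    """
    if net.species and core_tail is None:
        core_tail = classify_core_tail(net)
    if core_tail is not None and net.species:
        pt, pc = core_tail.guild_counts(net, PLANT)
        at, ac = core_tail.guild_counts(net, POLLINATOR)
        iso = sum(1 for s in net.species if len(net.partners(s)) == 0)
    else:
        pt = pc = at = ac = iso = 0
    return NetworkSummary(
        A=net.A,
        P=net.P,
        I=net.I,
        C=None if net.is_empty else connectance(net),
        plant_tail=pt,
        plant_core=pc,
        pollinator_tail=at,
        pollinator_core=ac,
        plant_rel_tail=(pt / (pt + pc)) if (pt + pc) else None,
        pollinator_rel_tail=(at / (at + ac)) if (at + ac) else None,
        n_isolated=iso,
        window=net.window,
    )


@dataclass(frozen=True)
class SummaryReport:
    """Per-network summaries plus means over the non-empty networks."""

    per_network: tuple[NetworkSummary, ...]
    means: Mapping[str, float]
    n_empty: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.per_network])


_MEAN_FIELDS = (
    "A", "P", "I", "C",
    "plant_tail", "plant_core", "pollinator_tail", "pollinator_core",
    "plant_rel_tail", "pollinator_rel_tail",
)


def summarize(
    nets: Sequence[BipartiteNetwork],
    core_tail: Optional[CoreTailMap] = None,
) -> SummaryReport:
    """Summarise a sequence of networks (e.g. the daily slices of a season).

    Networks where either guild is empty carry no defined connectance or
    tail fraction; they are excluded from the means and counted in
    ``n_empty``.
    """
    if not nets:
        raise DataError("summarize needs at least one network")
    rows = [network_summary(n, core_tail) for n in nets]
    full = [r for n, r in zip(nets, rows) if not n.is_empty]
    if not full:
        raise DataError("all networks empty: no means to compute")
    means = {}
    for f in _MEAN_FIELDS:
        vals = [getattr(r, f) for r in full if getattr(r, f) is not None]
        means[f] = sum(vals) / len(vals) if vals else float("nan")
    return SummaryReport(tuple(rows), means, n_empty=len(rows) - len(full))
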
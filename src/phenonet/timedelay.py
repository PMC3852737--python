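"""Directed time delays between species pairs in a phenophase-resolved network.

The delay d(i -> j) from species i to species j is the difference between
their phenophase starts, floored at one day (the clock granularity): a
species entering while another is already active can interact with it
immediately, so overlapping "backward" pairs (late source, early target...
strictly: target started before source) carry a delay of 1 day.  Pairs
with disjoint phenophases split by direction: forward in time the delay is
the start-to-start gap; backward in time the connection is *temporally
impossible* — effects cannot travel back to a species that left the
network before the source entered.  Every ordered pair of valid
phenophases falls in exactly one of the four classes.

Direct delays are tabulated over observed links (both directions); the
indirect universe is all remaining ordered pairs within the giant
component, pooling 2-mode (unlinked plant-pollinator) and 1-mode
(plant-plant, pollinator-pollinator) pairs.  Indirect connections travel
through temporal-coupler chains of directly linked species;
:func:`find_coupler_chain` verifies a time-respecting chain exists.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import networkx as nx

from .core import CoreTailMap, classify_core_tail
from .errors import DataError
from .io import to_graph
from .types import PLANT, POLLINATOR, BipartiteNetwork, Phenophase


class PairClass(str, Enum):
    """The four temporal relations of an ordered phenophase pair."""

    OVERLAP_FORWARD = "overlap_forward"    # overlap, target starts at/after source
    OVERLAP_BACKWARD = "overlap_backward"  # overlap, target started first: delay 1
    GAP_FORWARD = "gap_forward"            # disjoint, target after source ends
    GAP_IMPOSSIBLE = "gap_impossible"      # disjoint, target ended before source


def classify_ordered_pair(
    source: Phenophase, target: Phenophase
) -> tuple[PairClass, Optional[int]]:
    """Classify the ordered pair (source -> target) and give its delay in days.

    Returns ``(PairClass, delay)``; delay is None exactly for
    ``GAP_IMPOSSIBLE``.  Total over valid phenophases: every ordered pair
    receives exactly one class.
    """
    s0, sT = source.start_day, source.end_day
    t0, tT = target.start_day, target.end_day
    if t0 <= sT and s0 <= tT:  # phenophases overlap
        if t0 >= s0:
            return PairClass.OVERLAP_FORWARD, max(t0 - s0, 1)
        return PairClass.OVERLAP_BACKWARD, 1
    if t0 > sT:  # disjoint, target later
        return PairClass.GAP_FORWARD, t0 - s0
    return PairClass.GAP_IMPOSSIBLE, None


@dataclass(frozen=True)
class DelayRecord:
    """One ordered species pair with its temporal class and delay."""

    source_id: str
    target_id: str
    source_guild: str
    target_guild: str
    mode: str  # "direct" | "indirect"
    pair_class: PairClass
    delay_days: Optional[int]
    coupler_chain: Optional[tuple[str, ...]] = None

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "target_id": self.target_id,
            "source_guild": self.source_guild,
            "target_guild": self.target_guild,
            "mode": self.mode,
            "pair_class": self.pair_class.value,
            "delay_days": self.delay_days,
            "coupler_chain": ";".join(self.coupler_chain) if self.coupler_chain else "",
        }


def giant_component(net: BipartiteNetwork) -> frozenset[str]:
    """Species of the largest connected component of the static graph.

    Size ties are broken deterministically in favour of the component
    containing the smallest species id.
    """
    if not net.species:
        raise DataError("empty network has no components")
    comps = list(nx.connected_components(to_graph(net)))
    biggest = max(len(c) for c in comps)
    winners = [c for c in comps if len(c) == biggest]
    return frozenset(min(winners, key=lambda c: min(c)))


def _require_phenophase(phenophases: Mapping[str, Phenophase], sid: str) -> Phenophase:
    try:
        return phenophases[sid]
    except KeyError:
        raise DataError(f"species {sid!r} is linked but has no phenophase") from None


def direct_delays(
    net: BipartiteNetwork, phenophases: Mapping[str, Phenophase]
) -> list[DelayRecord]:
    """Two DelayRecords per link: plant -> pollinator and pollinator -> plant.

    By the activity rule directly linked species always have overlapping
    phenophases, so direct pairs always fall in an overlap class.
    """
    records = []
    for p, a in sorted(net.links):
        pp = _require_phenophase(phenophases, p)
        pa = _require_phenophase(phenophases, a)
        for src, tgt, sg, tg in ((p, a, PLANT, POLLINATOR), (a, p, POLLINATOR, PLANT)):
            phen_s = pp if sg == PLANT else pa
            phen_t = pa if sg == PLANT else pp
            cls, delay = classify_ordered_pair(phen_s, phen_t)
            records.append(DelayRecord(src, tgt, sg, tg, "direct", cls, delay))
    return records


def indirect_delays(
    net: BipartiteNetwork,
    phenophases: Mapping[str, Phenophase],
    component: Optional[frozenset[str]] = None,
) -> list[DelayRecord]:
    """Classify every ordered, not-directly-linked pair in the giant component.

    Covers 2-mode pairs (plant-pollinator never observed interacting,
    i.e. unobserved or forbidden links) and 1-mode pairs (plant-plant and
    pollinator-pollinator, which can only connect through couplers).
    Classification is by phenophase geometry alone; chain existence is a
    separate verification (:func:`find_coupler_chain`).
    """
    if component is None:
        component = giant_component(net)
    if len(component) < 3:
        raise DataError(f"giant component has {len(component)} species; need >= 3")
    linked = set(net.links)
    members = sorted(component)
    records = []
    for s in members:
        phen_s = _require_phenophase(phenophases, s)
        sg = net.guild_of(s)
        for t in members:
            if t == s:
                continue
            tg = net.guild_of(t)
            if sg != tg:
                pair = (s, t) if sg == PLANT else (t, s)
                if pair in linked:
                    continue
            cls, delay = classify_ordered_pair(phen_s, _require_phenophase(phenophases, t))
            records.append(DelayRecord(s, t, sg, tg, "indirect", cls, delay))
    return records


def find_coupler_chain(
    net: BipartiteNetwork,
    phenophases: Mapping[str, Phenophase],
    source: str,
    target: str,
) -> Optional[list[str]]:
    """Shortest time-respecting chain of temporal couplers from source to target.

    A chain follows static links, and every step must itself be temporally
    non-impossible.  Returns the interior species (the temporal couplers),
    ``[]`` for a directly linked pair, or None when no such chain exists.
    Deterministic: neighbours are explored in sorted id order.
    """
    if source == target:
        raise DataError("source and target must differ")
    for sid in (source, target):
        if sid not in net.species:
            raise DataError(f"species {sid!r} not in network")
    adjacency: dict[str, list[str]] = {s: [] for s in net.species}
    for p, a in net.links:
        adjacency[p].append(a)
        adjacency[a].append(p)
    for s in adjacency:
        adjacency[s].sort()

    def step_ok(u: str, v: str) -> bool:
        cls, _ = classify_ordered_pair(phenophases[u], phenophases[v])
        return cls is not PairClass.GAP_IMPOSSIBLE

    prev: dict[str, Optional[str]] = {source: None}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v in prev or not step_ok(u, v):
                continue
            prev[v] = u
            if v == target:
                path = [v]
                while prev[path[-1]] is not None:
                    path.append(prev[path[-1]])
                path.reverse()
                return path[1:-1]
            queue.append(v)
    return None


# ---------------------------------------------------------------------------
# Table-style aggregation
# ---------------------------------------------------------------------------

_NETWORK_TYPES = {
    (PLANT, POLLINATOR): "plant_to_pollinator",
    (POLLINATOR, PLANT): "pollinator_to_plant",
    (PLANT, PLANT): "plant_to_plant",
    (POLLINATOR, POLLINATOR): "pollinator_to_pollinator",
}
_BLOCKS = ("core_to_core", "core_to_tail", "tail_to_core", "tail_to_tail")


def _mean(values: Sequence[int]) -> Optional[float]:
    return sum(values) / len(values) if values else None


@dataclass(frozen=True)
class DelayTable:
    """Frequency and mean-delay aggregation of direct and indirect pairs.

    Percentages are over the indirect pair universe; impossible pairs are
    excluded from all delay means (they have none).
    """

    n_direct: int
    n_indirect: int
    direct_mean_delay: Mapping[str, Optional[float]]
    direct_block_mean_delay: Mapping[str, Optional[float]]
    indirect_class_counts: Mapping[str, int]
    indirect_class_pct: Mapping[str, float]
    indirect_class_mean_delay: Mapping[str, Optional[float]]
    indirect_type_mean_delay: Mapping[str, Optional[float]]
    indirect_block_pct_impossible: Mapping[str, Optional[float]]
    indirect_block_mean_delay: Mapping[str, Optional[float]]

    def to_dict(self) -> dict:
        return {
            "n_direct": self.n_direct,
            "n_indirect": self.n_indirect,
            "direct_mean_delay": dict(self.direct_mean_delay),
            "direct_block_mean_delay": dict(self.direct_block_mean_delay),
            "indirect_class_counts": dict(self.indirect_class_counts),
            "indirect_class_pct": dict(self.indirect_class_pct),
            "indirect_class_mean_delay": dict(self.indirect_class_mean_delay),
            "indirect_type_mean_delay": dict(self.indirect_type_mean_delay),
            "indirect_block_pct_impossible": dict(self.indirect_block_pct_impossible),
            "indirect_block_mean_delay": dict(self.indirect_block_mean_delay),
        }


def aggregate(
    records: Sequence[DelayRecord], core_tail: CoreTailMap
) -> DelayTable:
    """Aggregate DelayRecords into a direct/indirect frequency-and-delay table."""
    if not records:
        raise DataError("no delay records to aggregate")
    direct = [r for r in records if r.mode == "direct"]
    indirect = [r for r in records if r.mode == "indirect"]

    def block(r: DelayRecord) -> str:
        return f"{core_tail[r.source_id]}_to_{core_tail[r.target_id]}"

    direct_mean = {
        "plant_to_pollinator": _mean(
            [r.delay_days for r in direct if r.source_guild == PLANT]
        ),
        "pollinator_to_plant": _mean(
            [r.delay_days for r in direct if r.source_guild == POLLINATOR]
        ),
        "overall": _mean([r.delay_days for r in direct]),
    }
    direct_block = {
        b: _mean([r.delay_days for r in direct if block(r) == b]) for b in _BLOCKS
    }

    n_ind = len(indirect)
    counts = {c.value: 0 for c in PairClass}
    for r in indirect:
        counts[r.pair_class.value] += 1
    pct = {k: (100.0 * v / n_ind if n_ind else 0.0) for k, v in counts.items()}
    class_mean = {
        c.value: _mean(
            [r.delay_days for r in indirect
             if r.pair_class is c and r.delay_days is not None]
        )
        for c in PairClass
    }
    type_mean = {
        name: _mean(
            [r.delay_days for r in indirect
             if (r.source_guild, r.target_guild) == gt and r.delay_days is not None]
        )
        for gt, name in _NETWORK_TYPES.items()
    }
    block_pct_imp = {}
    block_mean = {}
    for b in _BLOCKS:
        rs = [r for r in indirect if block(r) == b]
        block_pct_imp[b] = (
            100.0 * sum(r.pair_class is PairClass.GAP_IMPOSSIBLE for r in rs) / len(rs)
            if rs else None
        )
        block_mean[b] = _mean([r.delay_days for r in rs if r.delay_days is not None])

    return DelayTable(
        n_direct=len(direct),
        n_indirect=n_ind,
        direct_mean_delay=direct_mean,
        direct_block_mean_delay=direct_block,
        indirect_class_counts=counts,
        indirect_class_pct=pct,
        indirect_class_mean_delay=class_mean,
        indirect_type_mean_delay=type_mean,
        indirect_block_pct_impossible=block_pct_imp,
        indirect_block_mean_delay=block_mean,
    )
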
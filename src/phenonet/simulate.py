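"""Synthetic arctic-style plant–flower-visitor community generator.

Emulates the generative structure of a short, highly seasonal pollination
community: a backbone of *core* species (long phenophases, skewed towards
the season start, densely inter-linked) on which a succession of *tail*
specialists hangs — short-phenophase species, each attached to one or two
core partners, with an optional burst of tail activity late (or early) in
the season.  Tail species attach preferentially to already well-linked
core partners, which yields the nested link structure characteristic of
real pollination networks.

Defaults are sized to a high-arctic season: 70 days, 34 plants (26 core +
8 tail), 78 flower visitors (27 core + 51 tail), core phenophases of about
31 days and tail phenophases of about 6 days, giving a static connectance
near 11% and a long pollinator nestedness tail.

The observation layer thins the deterministic phenophase overlap of each
linked pair with per-day Poisson visit counts; by default at least one
record per pair is guaranteed, so the observed network equals the intended
one and downstream results are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DataError
from .types import (
    PLANT,
    POLLINATOR,
    ObservationRecord,
    Phenophase,
    SpeciesInfo,
)

BURST_MODES = ("none", "late", "early")

# taxon-group frequencies typical of a high-arctic visitor fauna
_GROUP_PROBS = (("Diptera", 0.74), ("Hymenoptera", 0.14),
                ("Lepidoptera", 0.06), ("Heteroptera", 0.06))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic community; defaults are study-season sized."""

    season_start: int = 165
    season_length: int = 70
    n_core_plants: int = 26
    n_tail_plants: int = 8
    n_core_pollinators: int = 27
    n_tail_pollinators: int = 51
    core_phen_mean: float = 31.0
    core_phen_sd: float = 6.0
    tail_phen_mean: float = 6.0
    tail_phen_sd: float = 2.0
    tail_burst: str = "late"
    burst_weight: float = 0.6
    burst_span_frac: float = 0.35  # fraction of the season holding the burst
    core_core_link_prob: float = 0.33
    abundance_sigma: float = 0.8  # lognormal sd of core abundance weights
    tail_partner_count: int = 2
    visits_per_overlap_day: float = 0.5
    guarantee_min_one: bool = True
    max_start_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_length < 1:
            raise ConfigurationError("season_length must be >= 1")
        if self.n_core_plants < 1 or self.n_core_pollinators < 1:
            raise ConfigurationError("need at least one core species per guild")
        if min(self.n_tail_plants, self.n_tail_pollinators) < 0:
            raise ConfigurationError("tail species counts must be >= 0")
        if min(self.core_phen_mean, self.tail_phen_mean) < 1:
            raise ConfigurationError("phenophase means must be >= 1 day")
        if not (0.0 <= self.core_core_link_prob <= 1.0):
            raise ConfigurationError("core_core_link_prob must be in [0, 1]")
        if not (0.0 <= self.burst_weight <= 1.0):
            raise ConfigurationError("burst_weight must be in [0, 1]")
        if self.tail_burst not in BURST_MODES:
            raise ConfigurationError(f"tail_burst must be one of {BURST_MODES}")
        if self.tail_partner_count not in (1, 2):
            raise ConfigurationError("tail_partner_count must be 1 or 2")
        if self.visits_per_overlap_day < 0:
            raise ConfigurationError("visits_per_overlap_day must be >= 0")
        if self.abundance_sigma < 0:
            raise ConfigurationError("abundance_sigma must be >= 0")

    @property
    def season_end(self) -> int:
        return self.season_start + self.season_length - 1

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_length(rng: np.random.Generator, mean: float, sd: float, season: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 1, season))


def _core_start(rng: np.random.Generator, cfg: GeneratorConfig, length: int) -> int:
    # early-skewed but staggered: cores anchor the season start yet cover it
    mu = cfg.season_start + 0.1 * cfg.season_length
    sigma = 0.3 * cfg.season_length
    hi = cfg.season_end - length + 1
    return int(np.clip(round(rng.normal(mu, sigma)), cfg.season_start, hi))


def _tail_start(rng: np.random.Generator, cfg: GeneratorConfig, length: int) -> int:
    lo = cfg.season_start
    hi = cfg.season_end - length + 1
    if cfg.tail_burst != "none" and rng.random() < cfg.burst_weight:
        span = max(1, round(cfg.burst_span_frac * (hi - lo + 1)))
        if cfg.tail_burst == "late":
            return int(rng.integers(hi - span + 1, hi + 1))
        return int(rng.integers(lo, lo + span))
    return int(rng.integers(lo, hi + 1))


def generate_community(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, SpeciesInfo], dict[str, Phenophase], frozenset[tuple[str, str]]]:
    """Generate species, true phenophases and the intended link set.

    Core plant x core pollinator pairs whose phenophases overlap are linked
    independently with probability ``core_core_link_prob`` scaled by the
    product of the pair's lognormal abundance weights.  Each tail species
    is then attached to up to ``tail_partner_count`` core partners of the
    other guild whose phenophases overlap its own, chosen with probability
    proportional to the partner's abundance times 1 + its current linkage
    level; if no partner overlaps, the start day is redrawn (bounded
    retries).  Deterministic given ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    species: dict[str, SpeciesInfo] = {}
    phen: dict[str, Phenophase] = {}
    width_p = len(str(cfg.n_core_plants + cfg.n_tail_plants))
    width_a = len(str(cfg.n_core_pollinators + cfg.n_tail_pollinators))

    core_plants, core_polls = [], []
    for i in range(cfg.n_core_plants):
        sid = f"P{i + 1:0{width_p}d}"
        length = _draw_length(rng, cfg.core_phen_mean, cfg.core_phen_sd, cfg.season_length)
        start = _core_start(rng, cfg, length)
        species[sid] = SpeciesInfo(sid, PLANT)
        phen[sid] = Phenophase(sid, start, start + length - 1)
        core_plants.append(sid)
    for i in range(cfg.n_core_pollinators):
        sid = f"A{i + 1:0{width_a}d}"
        length = _draw_length(rng, cfg.core_phen_mean, cfg.core_phen_sd, cfg.season_length)
        start = _core_start(rng, cfg, length)
        group = _GROUP_PROBS[
            rng.choice(len(_GROUP_PROBS), p=[w for _, w in _GROUP_PROBS])
        ][0]
        species[sid] = SpeciesInfo(sid, POLLINATOR, group=group, trophic_role="visitor")
        phen[sid] = Phenophase(sid, start, start + length - 1)
        core_polls.append(sid)

    # Lognormal abundance weights (mean 1) drive both the core-core link
    # probabilities (multiplicatively) and tail attachment: abundant
    # generalists accumulate links, which is what produces the nested
    # structure of real mutualistic webs.
    w_plant = rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_core_plants)
    w_poll = rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_core_pollinators)
    abundance = dict(zip(core_plants, w_plant / w_plant.mean()))
    abundance.update(zip(core_polls, w_poll / w_poll.mean()))

    links: set[tuple[str, str]] = set()
    degree: dict[str, int] = {s: 0 for s in species}
    for p in core_plants:
        for a in core_polls:
            p_link = min(1.0, cfg.core_core_link_prob * abundance[p] * abundance[a])
            if phen[p].overlaps(phen[a]) and rng.random() < p_link:
                links.add((p, a))
                degree[p] += 1
                degree[a] += 1

    def attach_tail(sid: str, guild: str) -> None:
        length = _draw_length(rng, cfg.tail_phen_mean, cfg.tail_phen_sd, cfg.season_length)
        candidates_pool = core_polls if guild == PLANT else core_plants
        for _ in range(cfg.max_start_retries):
            start = _tail_start(rng, cfg, length)
            trial = Phenophase(sid, start, start + length - 1)
            candidates = [c for c in candidates_pool if phen[c].overlaps(trial)]
            if candidates:
                break
        else:
            raise DataError(
                f"tail species {sid!r}: no overlapping core partner found after "
                f"{cfg.max_start_retries} start redraws"
            )
        phen[sid] = trial
        degree[sid] = 0
        k = min(cfg.tail_partner_count, len(candidates))
        weights = np.array([(1.0 + degree[c]) * abundance[c] for c in candidates])
        chosen = rng.choice(len(candidates), size=k, replace=False, p=weights / weights.sum())
        for idx in np.sort(chosen):
            partner = candidates[int(idx)]
            link = (sid, partner) if guild == PLANT else (partner, sid)
            links.add(link)
            degree[sid] += 1
            degree[partner] += 1

    for i in range(cfg.n_tail_plants):
        sid = f"P{cfg.n_core_plants + i + 1:0{width_p}d}"
        species[sid] = SpeciesInfo(sid, PLANT)
        attach_tail(sid, PLANT)
    for i in range(cfg.n_tail_pollinators):
        sid = f"A{cfg.n_core_pollinators + i + 1:0{width_a}d}"
        u = rng.random()
        role = "visitor" if u < 0.75 else ("parasitoid" if u < 0.93 else "hyper_parasitoid")
        group = _GROUP_PROBS[
            rng.choice(len(_GROUP_PROBS), p=[w for _, w in _GROUP_PROBS])
        ][0]
        species[sid] = SpeciesInfo(sid, POLLINATOR, group=group, trophic_role=role)
        attach_tail(sid, POLLINATOR)

    # A network phenophase is operationally the span between a species'
    # first and last possible observation, so trim each linked species to
    # the hull of its pair overlaps (links and overlaps are preserved:
    # every pair overlap lies inside both hulls).  Unlinked species keep
    # their drawn phenophase.
    hull_lo: dict[str, int] = {}
    hull_hi: dict[str, int] = {}
    for p, a in links:
        lo = max(phen[p].start_day, phen[a].start_day)
        hi = min(phen[p].end_day, phen[a].end_day)
        for sid in (p, a):
            hull_lo[sid] = min(hull_lo.get(sid, lo), lo)
            hull_hi[sid] = max(hull_hi.get(sid, hi), hi)
    for sid in hull_lo:
        phen[sid] = Phenophase(sid, hull_lo[sid], hull_hi[sid])

    return species, phen, frozenset(links)


def generate_observations(
    phenophases: dict[str, Phenophase],
    interacting_pairs: frozenset[tuple[str, str]],
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ObservationRecord]:
    """Emit visitation records by thinning each pair's phenophase overlap.

    Each overlap day of a linked pair gets a Poisson(``visits_per_overlap_day``)
    visit count; days with zero visits emit nothing.  With
    ``guarantee_min_one`` (default) a pair whose thinning produced no record
    gets one record on a random overlap day, so observed pairs equal
    intended pairs.  Records are sorted by (day, plant, pollinator).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    records: list[ObservationRecord] = []
    for p, a in sorted(interacting_pairs):
        pp, pa = phenophases[p], phenophases[a]
        lo = max(pp.start_day, pa.start_day)
        hi = min(pp.end_day, pa.end_day)
        if lo > hi:
            raise DataError(
                f"pair ({p!r}, {a!r}) has no phenophase overlap: generator contract violated"
            )
        days = np.arange(lo, hi + 1)
        counts = rng.poisson(cfg.visits_per_overlap_day, size=len(days))
        if cfg.guarantee_min_one and counts.sum() == 0:
            counts[int(rng.integers(len(days)))] = 1
        for d, c in zip(days, counts):
            if c > 0:
                records.append(ObservationRecord(int(d), p, a, int(c)))
    records.sort(key=lambda r: (r.day, r.plant_id, r.pollinator_id))
    return records
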
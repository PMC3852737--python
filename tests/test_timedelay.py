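"""Delay classification, giant component, coupler chains and aggregation."""

import itertools

import pytest

from phenonet import (
    DataError,
    PairClass,
    Phenophase,
    aggregate,
    classify_core_tail,
    classify_ordered_pair,
    direct_delays,
    find_coupler_chain,
    giant_component,
    indirect_delays,
)
from phenonet.types import PLANT, POLLINATOR, BipartiteNetwork


def P(lo, hi, sid="x"):
    return Phenophase(sid, lo, hi)


class TestClassifyOrderedPair:
    @pytest.mark.parametrize(
        "s,t,cls,delay",
        [
            ((165, 200), (180, 220), PairClass.OVERLAP_FORWARD, 15),
            ((180, 220), (165, 200), PairClass.OVERLAP_BACKWARD, 1),
            ((165, 180), (200, 220), PairClass.GAP_FORWARD, 35),
            ((200, 220), (165, 180), PairClass.GAP_IMPOSSIBLE, None),
            ((165, 200), (165, 210), PairClass.OVERLAP_FORWARD, 1),  # same start
        ],
    )
    def test_reference_geometries(self, s, t, cls, delay):
        assert classify_ordered_pair(P(*s), P(*t)) == (cls, delay)

    def test_exhaustive_lattice_properties(self):
        """All ordered interval pairs on a 10-day lattice: totality, the
        gap duality, the overlap symmetry, and the delay floor."""
        intervals = [P(a, b) for a in range(1, 11) for b in range(a, 11)]
        for s, t in itertools.product(intervals, repeat=2):
            cls, delay = classify_ordered_pair(s, t)
            rcls, rdelay = classify_ordered_pair(t, s)
            # totality and single-valuedness
            assert cls in PairClass
            # delay defined iff not impossible, and always >= 1
            assert (delay is None) == (cls is PairClass.GAP_IMPOSSIBLE)
            if delay is not None:
                assert delay >= 1
            # impossible one way <=> forward gap the other way
            assert (cls is PairClass.GAP_IMPOSSIBLE) == (rcls is PairClass.GAP_FORWARD)
            # overlap is symmetric
            overlap = {PairClass.OVERLAP_FORWARD, PairClass.OVERLAP_BACKWARD}
            assert (cls in overlap) == (rcls in overlap)
            # late-to-early overlap carries the one-day floor
            if cls is PairClass.OVERLAP_BACKWARD:
                assert delay == 1


class TestGiantComponent:
    def test_connected_network_returns_all(self):
        net = BipartiteNetwork(
            frozenset({"P1", "P2"}),
            frozenset({"A1"}),
            frozenset({("P1", "A1"), ("P2", "A1")}),
        )
        assert giant_component(net) == net.species

    def test_isolated_pair_excluded(self):
        net = BipartiteNetwork(
            frozenset({"P1", "P2", "P3"}),
            frozenset({"A1", "A2"}),
            frozenset({("P1", "A1"), ("P2", "A1"), ("P3", "A2")}),
        )
        assert giant_component(net) == {"P1", "P2", "A1"}

    def test_equal_components_tie_break_smallest_id(self):
        net = BipartiteNetwork(
            frozenset({"P1", "P2"}),
            frozenset({"A1", "A2"}),
            frozenset({("P2", "A1"), ("P1", "A2")}),
        )
        # components {P2, A1} and {P1, A2} tie on size: pick the one with A1
        assert giant_component(net) == {"P2", "A1"}


class TestDirectDelays:
    def test_single_link_both_directions(self):
        net = BipartiteNetwork(
            frozenset({"P1"}), frozenset({"A1"}), frozenset({("P1", "A1")})
        )
        phens = {"P1": Phenophase("P1", 165, 200), "A1": Phenophase("A1", 180, 220)}
        recs = direct_delays(net, phens)
        by_dir = {(r.source_guild, r.target_guild): r for r in recs}
        assert by_dir[(PLANT, POLLINATOR)].delay_days == 15
        assert by_dir[(POLLINATOR, PLANT)].delay_days == 1
        assert all(r.mode == "direct" for r in recs)

    def test_identical_phenophases_all_delay_one(self, staggered_phenophases):
        phens, pairs = staggered_phenophases
        phens = {s: Phenophase(s, 165, 234) for s in phens}
        net = BipartiteNetwork(
            frozenset({"P1", "P2"}), frozenset({"A1", "A2", "A3"}), frozenset(pairs)
        )
        assert all(r.delay_days == 1 for r in direct_delays(net, phens))

    def test_direct_pairs_never_gap_class(self, default_community, default_static):
        _, _, phen, _, _ = default_community
        for r in direct_delays(default_static, phen):
            assert r.pair_class in (PairClass.OVERLAP_FORWARD, PairClass.OVERLAP_BACKWARD)

    def test_missing_phenophase_rejected(self):
        net = BipartiteNetwork(
            frozenset({"P1"}), frozenset({"A1"}), frozenset({("P1", "A1")})
        )
        with pytest.raises(DataError, match="A1"):
            direct_delays(net, {"P1": Phenophase("P1", 165, 200)})

    def test_grouped_means_match_brute_force(self, default_community, default_static):
        _, _, phen, _, _ = default_community
        net = default_static
        recs = direct_delays(net, phen)
        table = aggregate(recs, classify_core_tail(net))
        # independent enumeration over links
        fwd, bwd = [], []
        for p, a in net.links:
            d_pa = max(phen[a].start_day - phen[p].start_day, 1)
            d_ap = max(phen[p].start_day - phen[a].start_day, 1)
            fwd.append(d_pa)
            bwd.append(d_ap)
        assert table.direct_mean_delay["plant_to_pollinator"] == pytest.approx(
            sum(fwd) / len(fwd)
        )
        assert table.direct_mean_delay["pollinator_to_plant"] == pytest.approx(
            sum(bwd) / len(bwd)
        )
        assert table.direct_mean_delay["overall"] == pytest.approx(
            (sum(fwd) + sum(bwd)) / (2 * net.I)
        )


class TestIndirectDelays:
    def _chain_net(self):
        # plant A - pollinator X - plant B, phenophases all overlapping
        net = BipartiteNetwork(
            frozenset({"pA", "pB"}),
            frozenset({"X"}),
            frozenset({("pA", "X"), ("pB", "X")}),
        )
        phens = {
            "pA": Phenophase("pA", 165, 190),
            "X": Phenophase("X", 165, 210),
            "pB": Phenophase("pB", 180, 210),  # latest start
        }
        return net, phens

    def test_three_species_chain(self):
        net, phens = self._chain_net()
        recs = indirect_delays(net, phens)
        by_pair = {(r.source_id, r.target_id): r for r in recs}
        assert by_pair[("pA", "pB")].pair_class is PairClass.OVERLAP_FORWARD
        assert by_pair[("pA", "pB")].delay_days == 15
        assert by_pair[("pB", "pA")].pair_class is PairClass.OVERLAP_BACKWARD
        assert by_pair[("pB", "pA")].delay_days == 1
        # only the plant-plant pairs are indirect here
        assert set(by_pair) == {("pA", "pB"), ("pB", "pA")}

    def test_gap_pair_through_shared_pollinator(self):
        net = BipartiteNetwork(
            frozenset({"pA", "pB"}),
            frozenset({"X"}),
            frozenset({("pA", "X"), ("pB", "X")}),
        )
        phens = {
            "pA": Phenophase("pA", 165, 175),
            "pB": Phenophase("pB", 200, 210),
            "X": Phenophase("X", 165, 210),
        }
        recs = indirect_delays(net, phens)
        by_pair = {(r.source_id, r.target_id): r for r in recs}
        assert by_pair[("pA", "pB")].pair_class is PairClass.GAP_FORWARD
        assert by_pair[("pA", "pB")].delay_days == 35
        assert by_pair[("pB", "pA")].pair_class is PairClass.GAP_IMPOSSIBLE
        assert by_pair[("pB", "pA")].delay_days is None

    def test_class_percentages_sum_to_hundred(self, default_community, default_static):
        _, _, phen, _, _ = default_community
        recs = indirect_delays(default_static, phen)
        table = aggregate(recs, classify_core_tail(default_static))
        assert sum(table.indirect_class_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_pair_universe_excludes_direct_links(self, default_community, default_static):
        _, _, phen, _, _ = default_community
        net = default_static
        recs = indirect_delays(net, phen)
        seen = {(r.source_id, r.target_id) for r in recs}
        for p, a in net.links:
            assert (p, a) not in seen and (a, p) not in seen
        # ordered universe size: n(n-1) minus both directions of each link
        comp = giant_component(net)
        n = len(comp)
        linked_in_comp = sum(1 for p, a in net.links if p in comp and a in comp)
        assert len(recs) == n * (n - 1) - 2 * linked_in_comp

    def test_tiny_component_rejected(self):
        net = BipartiteNetwork(
            frozenset({"P1"}), frozenset({"A1"}), frozenset({("P1", "A1")})
        )
        phens = {s: Phenophase(s, 165, 200) for s in ("P1", "A1")}
        with pytest.raises(DataError):
            indirect_delays(net, phens)


class TestCouplerChain:
    def test_directly_linked_pair_has_empty_chain(self):
        net = BipartiteNetwork(
            frozenset({"P1"}), frozenset({"A1"}), frozenset({("P1", "A1")})
        )
        phens = {s: Phenophase(s, 165, 200) for s in ("P1", "A1")}
        assert find_coupler_chain(net, phens, "P1", "A1") == []

    def test_shared_pollinator_is_the_coupler(self):
        net = BipartiteNetwork(
            frozenset({"pA", "pB"}),
            frozenset({"X"}),
            frozenset({("pA", "X"), ("pB", "X")}),
        )
        phens = {s: Phenophase(s, 165, 200) for s in ("pA", "pB", "X")}
        assert find_coupler_chain(net, phens, "pA", "pB") == ["X"]

    def test_no_chain_backward_in_time(self):
        net = BipartiteNetwork(
            frozenset({"pA", "pB"}),
            frozenset({"X", "Y"}),
            frozenset({("pA", "X"), ("pA", "Y"), ("pB", "Y")}),
        )
        phens = {
            "pA": Phenophase("pA", 200, 220),
            "X": Phenophase("X", 200, 230),
            "Y": Phenophase("Y", 150, 180),  # gone before pA starts
            "pB": Phenophase("pB", 150, 160),
        }
        # the only route is pA -> Y -> pB, but the step into Y reaches back
        # in time (Y left before pA entered), so no chain exists
        assert find_coupler_chain(net, phens, "pA", "pB") is None
        # the reverse direction is time-respecting: pB -> Y -> pA works? no:
        # Y -> pA is fine (gap_forward) but pB -> Y overlaps; chain exists
        assert find_coupler_chain(net, phens, "pB", "pA") == ["Y"]

    def test_chain_agrees_with_exhaustive_path_search(self, default_community):
        """On small random subnetworks, BFS chains match an independent
        exhaustive simple-path search, and every step is non-impossible."""
        import networkx as nx

        _, _, phen_all, pairs_all, _ = default_community
        # build a small network from the first 8 species of the community
        sub_plants = sorted({p for p, _ in pairs_all})[:3]
        sub_polls = sorted({a for _, a in pairs_all})[:5]
        links = frozenset(
            (p, a) for p, a in pairs_all if p in sub_plants and a in sub_polls
        )
        if not links:
            pytest.skip("no links among chosen species")
        net = BipartiteNetwork(frozenset(sub_plants), frozenset(sub_polls), links)
        phens = {s: phen_all[s] for s in net.species}

        g = nx.Graph(list(links))

        def oracle_reachable(s, t):
            if s not in g or t not in g:
                return False
            for path in nx.all_simple_paths(g, s, t, cutoff=len(net.species)):
                if all(
                    classify_ordered_pair(phens[u], phens[v])[0]
                    is not PairClass.GAP_IMPOSSIBLE
                    for u, v in zip(path, path[1:])
                ):
                    return True
            return False

        for s in sorted(net.species):
            for t in sorted(net.species):
                if s == t:
                    continue
                chain = find_coupler_chain(net, phens, s, t)
                assert (chain is not None) == oracle_reachable(s, t)
                if chain:
                    path = [s, *chain, t]
                    for u, v in zip(path, path[1:]):
                        assert (u, v) in net.links or (v, u) in net.links
                        cls, _ = classify_ordered_pair(phens[u], phens[v])
                        assert cls is not PairClass.GAP_IMPOSSIBLE


class TestAggregate:
    def test_identical_phenophases_nothing_impossible(self):
        phens = {s: Phenophase(s, 165, 200) for s in ("P1", "P2", "A1")}
        net = BipartiteNetwork(
            frozenset({"P1", "P2"}),
            frozenset({"A1"}),
            frozenset({("P1", "A1"), ("P2", "A1")}),
        )
        recs = indirect_delays(net, phens)
        table = aggregate(recs, classify_core_tail(net))
        assert table.indirect_class_pct["gap_impossible"] == 0.0

    def test_block_percentages_match_brute_force(self, default_community, default_static):
        _, _, phen, _, _ = default_community
        net = default_static
        ct = classify_core_tail(net)
        recs = indirect_delays(net, phen)
        table = aggregate(recs, ct)
        # independent enumeration
        comp = giant_component(net)
        linked = set(net.links) | {(a, p) for p, a in net.links}
        blocks = {}
        for s in comp:
            for t in comp:
                if s == t or (s, t) in linked:
                    continue
                key = f"{ct[s]}_to_{ct[t]}"
                cls, _ = classify_ordered_pair(phen[s], phen[t])
                n_tot, n_imp = blocks.get(key, (0, 0))
                blocks[key] = (n_tot + 1, n_imp + (cls is PairClass.GAP_IMPOSSIBLE))
        for key, (n_tot, n_imp) in blocks.items():
            assert table.indirect_block_pct_impossible[key] == pytest.approx(
                100 * n_imp / n_tot
            )

    def test_late_tail_burst_makes_backward_impossibility_asymmetric(
        self, default_community, default_static
    ):
        """Tail species concentrated late in the season make tail->core
        connections impossible more often than core->tail ones."""
        _, _, phen, _, _ = default_community
        net = default_static
        table = aggregate(indirect_delays(net, phen), classify_core_tail(net))
        imp = table.indirect_block_pct_impossible
        assert imp["tail_to_core"] > imp["core_to_tail"]

    def test_empty_records_rejected(self):
        from phenonet.core import CoreTailMap

        with pytest.raises(DataError):
            aggregate([], CoreTailMap({}, frozenset()))
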
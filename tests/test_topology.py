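"""Replicon topology calls and repeat-traversal enumeration."""

import itertools
import math

import pytest

from contiggraph import build_graph, topology
from contiggraph.topology import RepliconKind

BIG = 30000


def _graph(contigs, links):
    return build_graph(contigs, links)


def _chromosome_rows():
    # two large unique contigs keep the coverage average anchored at 30
    return [(100, BIG, 30), (101, BIG, 30)]


class TestCircularSingle:
    def test_self_linked_contig_called(self):
        g = _graph(_chromosome_rows() + [(9, 3000, 90)], [("9S", "9E", 40)])
        calls = topology.detect_circular_single(g)
        assert [c.kind for c in calls] == [RepliconKind.CIRCULAR_SINGLE]
        assert calls[0].members == frozenset({9})
        assert calls[0].mean_copy_number == pytest.approx(3.0)

    def test_self_link_plus_external_is_ambiguous(self):
        g = _graph(_chromosome_rows() + [(9, 3000, 90)],
                   [("9S", "9E", 40), ("9E", "100S", 5)])
        calls = topology.detect_circular_single(g, exclude_weak=False)
        assert [c.kind for c in calls] == [RepliconKind.AMBIGUOUS]

    def test_no_self_links_no_calls(self):
        g = _graph(_chromosome_rows(), [("100E", "101S", 10)])
        assert topology.detect_circular_single(g) == []


class TestCircularMulti:
    def test_three_contig_cycle(self):
        g = _graph(
            _chromosome_rows() + [(141, 2500, 60), (142, 2200, 60), (143, 2600, 60)],
            [("141E", "142S", 30), ("142E", "143S", 28), ("143E", "141S", 31)],
        )
        calls = topology.detect_circular_multi(g)
        assert len(calls) == 1
        assert calls[0].kind is RepliconKind.CIRCULAR_MULTI
        assert calls[0].members == frozenset({141, 142, 143})
        assert calls[0].mean_copy_number == pytest.approx(2.0)

    def test_open_chain_is_not_circular(self):
        g = _graph(_chromosome_rows() + [(1, 2500, 30), (2, 2200, 30), (3, 2600, 30)],
                   [("1E", "2S", 10), ("2E", "3S", 10)])
        assert topology.detect_circular_multi(g) == []

    def test_extra_degree_makes_component_ambiguous(self):
        g = _graph(
            _chromosome_rows() + [(1, 2500, 60), (2, 2200, 60), (3, 2600, 60)],
            [("1E", "2S", 10), ("2E", "3S", 10), ("3E", "1S", 10),
             ("3E", "2S", 10)],
        )
        calls = topology.detect_circular_multi(g, exclude_weak=False)
        assert [c.kind for c in calls] == [RepliconKind.AMBIGUOUS]


class TestLinearEnds:
    def test_repeat_with_one_free_end(self):
        g = _graph(_chromosome_rows() + [(28, 4000, 63)], [("28S", "100E", 20)])
        calls = topology.detect_linear_ends(g)
        assert [c.kind for c in calls] == [RepliconKind.LINEAR_END]
        assert calls[0].members == frozenset({28})

    def test_tir_pattern_two_links_one_end_copy_two(self):
        g = _graph(_chromosome_rows() + [(28, 18000, 60)],
                   [("28S", "100S", 20), ("28S", "101E", 22)])
        calls = topology.detect_linear_ends(g)
        assert [c.kind for c in calls] == [RepliconKind.TIR_CHROMOSOME_END]

    def test_unique_contig_free_end_is_a_gap_not_a_telomere(self):
        g = _graph(_chromosome_rows() + [(5, 4000, 30)], [("5S", "100E", 20)])
        assert topology.detect_linear_ends(g) == []


class TestIsolated:
    def test_linkless_repeat_called(self):
        g = _graph(_chromosome_rows() + [(7, 3500, 156)], [("100E", "101S", 9)])
        calls = topology.detect_isolated(g)
        assert [c.kind for c in calls] == [RepliconKind.ISOLATED_LINEAR]
        assert calls[0].mean_copy_number == pytest.approx(5.2)

    def test_linkless_unique_contig_gets_no_call(self):
        g = _graph(_chromosome_rows() + [(7, 3500, 30)], [("100E", "101S", 9)])
        assert topology.detect_isolated(g) == []

    def test_linked_contig_not_isolated(self):
        g = _graph(_chromosome_rows() + [(7, 3500, 156)], [("7E", "100S", 4)])
        assert topology.detect_isolated(g) == []

    def test_never_both_circular_single_and_isolated(self):
        g = _graph(_chromosome_rows() + [(9, 3000, 90)], [("9S", "9E", 40)])
        kinds = {c.kind for c in topology.call_replicons(g)}
        assert RepliconKind.CIRCULAR_SINGLE in kinds
        assert RepliconKind.ISOLATED_LINEAR not in kinds


class TestSimulatedPanel:
    def test_every_replicon_shape_called(self, panel_graph):
        genome, graph = panel_graph
        calls = topology.call_replicons(graph)
        by_kind = {}
        for call in calls:
            by_kind.setdefault(call.kind, []).append(call)
        cid = genome.contig_ids
        assert by_kind[RepliconKind.CIRCULAR_SINGLE][0].members == frozenset(
            {cid["p_circ1"]})
        assert by_kind[RepliconKind.CIRCULAR_MULTI][0].members == frozenset(
            {cid["q1"], cid["q2"], cid["q3"]})
        linear_members = {m for c in by_kind[RepliconKind.LINEAR_END]
                          for m in c.members}
        assert cid["t1"] in linear_members
        assert by_kind[RepliconKind.ISOLATED_LINEAR][0].members == frozenset(
            {cid["iso_hi"]})
        # single-copy linear plasmid is indistinguishable: no call at all
        called = {m for c in calls for m in c.members}
        assert cid["iso_lo"] not in called


class TestWeakLinks:
    def test_nonspecific_join_flagged(self):
        g = _graph(
            [(141, 25000, 60), (142, 25000, 60), (143, 25000, 60), (144, 25000, 60)],
            [("143E", "142E", 800), ("143E", "144E", 10)],
        )
        weak = topology.flag_weak_links(g)
        assert len(weak) == 1
        (key,) = weak
        assert key == g.get_link("143E", "144E").key

    def test_comparable_supports_not_flagged(self):
        g = _graph([(1, BIG, 30), (2, BIG, 30), (3, BIG, 30)],
                   [("1E", "2S", 100), ("1E", "3S", 80)])
        assert topology.flag_weak_links(g) == set()


class TestTraversals:
    def _repeat_graph(self, s_partners, e_partners):
        contigs = [(106, 5000, 62)]
        links = []
        seen = set()
        for lbl in s_partners:
            cid = int(lbl[:-1])
            if cid not in seen:
                contigs.append((cid, 25000, 30))
                seen.add(cid)
            links.append((lbl, "106S", 10))
        for lbl in e_partners:
            cid = int(lbl[:-1])
            if cid not in seen:
                contigs.append((cid, 25000, 30))
                seen.add(cid)
            links.append((lbl, "106E", 10))
        return _graph(contigs, links)

    def test_two_partners_per_end_yields_both_pcr_chains(self):
        g = self._repeat_graph(["37E", "42E"], ["41S", "41E"])
        alts, truncated = topology.enumerate_traversals(g, 106)
        assert not truncated
        rendered = {a.render() for a in alts}
        assert rendered == {
            "37S-37E-106S-106E-41S-41E-106E-106S-42E-42S",
            "37S-37E-106S-106E-41E-41S-106E-106S-42E-42S",
        }

    def test_single_partner_single_alternative(self):
        g = self._repeat_graph(["37E"], ["41S"])
        alts, _ = topology.enumerate_traversals(g, 106)
        assert len(alts) == 1
        assert alts[0].render() == "37S-37E-106S-106E-41S-41E"

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_alternative_count_is_k_factorial(self, k):
        s_partners = [f"{10 + i}E" for i in range(k)]
        e_partners = [f"{20 + i}S" for i in range(k)]
        g = self._repeat_graph(s_partners, e_partners)
        alts, _ = topology.enumerate_traversals(g, 106, max_alternatives=100)
        assert len(alts) == math.factorial(k)
        # brute force: matchings = distinct permutation assignments
        brute = {
            tuple(zip(s_partners, perm))
            for perm in itertools.permutations(e_partners)
        }
        assert {a.matching for a in alts} == brute

    def test_unequal_partner_counts_flagged_partial(self):
        g = self._repeat_graph(["37E", "42E", "44E"], ["41S"])
        alts, _ = topology.enumerate_traversals(g, 106)
        assert len(alts) == 3 and all(a.partial for a in alts)

    def test_truncation_flag(self):
        g = self._repeat_graph([f"{10 + i}E" for i in range(4)],
                               [f"{20 + i}S" for i in range(4)])
        alts, truncated = topology.enumerate_traversals(g, 106, max_alternatives=5)
        assert truncated and len(alts) == 5

    def test_unlinked_end_is_an_error(self):
        g = self._repeat_graph(["37E"], [])
        with pytest.raises(ValueError):
            topology.enumerate_traversals(g, 106)


class TestRelabelInvariance:
    def test_calls_stable_under_contig_renumbering(self):
        base_contigs = [(1, BIG, 30), (2, BIG, 30), (3, 3000, 90)]
        base_links = [("1E", "2S", 10), ("3S", "3E", 40)]
        mapping = {1: 11, 2: 22, 3: 33}
        relabeled_contigs = [(mapping[c], l, a) for c, l, a in base_contigs]
        relabeled_links = [
            (f"{mapping[int(a[:-1])]}{a[-1]}", f"{mapping[int(b[:-1])]}{b[-1]}", s)
            for a, b, s in base_links
        ]
        calls1 = topology.call_replicons(_graph(base_contigs, base_links))
        calls2 = topology.call_replicons(_graph(relabeled_contigs, relabeled_links))
        shapes1 = {(c.kind, frozenset(mapping[m] for m in c.members))
                   for c in calls1}
        shapes2 = {(c.kind, c.members) for c in calls2}
        assert shapes1 == shapes2
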
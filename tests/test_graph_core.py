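"""Graph model, coverage statistics, classification and weight normalization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contiggraph import (
    Contig,
    ContigClass,
    CoverageMode,
    EndLabelError,
    ReferentialIntegrityError,
    UndefinedValueError,
    average_coverage,
    build_graph,
    classify_contig,
    copy_number,
    filter_by_size,
    parse_end_label,
    unlinked_end_nodes,
    z_normalizer,
)
from contiggraph.graph_core import contig_id_from_name

FIG3D_CONTIGS = [(1, 25000, 30), (2, 25000, 30), (3, 25000, 30), (4, 25000, 30),
                 (9, 1200, 60)]
FIG3D_LINKS = [("1E", "9S", 12), ("2S", "9E", 11), ("3S", "9E", 10), ("4S", "9S", 9)]


class TestEndLabels:
    @pytest.mark.parametrize("token,cid,end", [("1S", 1, "S"), ("106E", 106, "E")])
    def test_parse(self, token, cid, end):
        node = parse_end_label(token)
        assert (node.contig_id, node.end, node.label) == (cid, end, token)

    @pytest.mark.parametrize("token", ["", "S1", "1X", "0S", "-3E", "1SE", "abc"])
    def test_malformed_labels_name_the_token(self, token):
        with pytest.raises(EndLabelError):
            parse_end_label(token)

    def test_contig_name_to_id(self):
        assert contig_id_from_name("contig00042") == 42
        assert contig_id_from_name("7") == 7
        with pytest.raises(Exception):
            contig_id_from_name("plasmid")


class TestBuildGraph:
    def test_two_nodes_per_contig(self):
        g = build_graph([(i, 1000 + i, 10) for i in range(1, 6)],
                        [("1E", "2S", 3), ("2E", "3S", 2), ("3E", "4S", 2),
                         ("4E", "5S", 1)])
        assert len(g.end_nodes()) == 10
        assert len(g.contigs) == 5
        assert len(g.links) == 4

    def test_repeat_hub_carries_four_links(self):
        g = build_graph(FIG3D_CONTIGS, FIG3D_LINKS)
        incident = [lk for lk in g.links
                    if 9 in (lk.end_a.contig_id, lk.end_b.contig_id)]
        assert len(incident) == 4
        assert g.contigs[9].klass is ContigClass.REPEAT

    def test_duplicate_rows_merge_by_summing_support(self):
        g = build_graph([(1, 1000, 10), (2, 1000, 10)],
                        [("1E", "2S", 3), ("2S", "1E", 2)])
        assert len(g.links) == 1
        assert g.links[0].support == 5

    def test_unknown_contig_in_links_rejected(self):
        with pytest.raises(ReferentialIntegrityError, match="7"):
            build_graph([(1, 1000, 10)], [("1E", "7S", 2)])


class TestAverageCoverage:
    def test_large_contig_mean_excludes_small(self):
        contigs = [Contig(1, "1", 25000, 30.0), Contig(2, "2", 30000, 34.0),
                   Contig(3, "3", 5000, 100.0)]
        avg = average_coverage(contigs, CoverageMode.CRS_LARGE_CONTIG_MEAN)
        assert avg == pytest.approx(32.0)

    def test_total_mode_is_base_ratio(self):
        contigs = [Contig(1, "1", 60000, 0.0), Contig(2, "2", 40000, 0.0)]
        avg = average_coverage(contigs, CoverageMode.ACE_TOTAL,
                               read_bases=3_000_000)
        assert avg == pytest.approx(30.0)

    def test_single_qualifying_contig(self):
        avg = average_coverage([Contig(1, "1", 21000, 28.0)],
                               CoverageMode.CRS_LARGE_CONTIG_MEAN)
        assert avg == pytest.approx(28.0)

    def test_fallback_when_nothing_large(self):
        contigs = [Contig(1, "1", 5000, 20.0), Contig(2, "2", 4000, 40.0)]
        avg = average_coverage(contigs, CoverageMode.CRS_LARGE_CONTIG_MEAN)
        assert avg == pytest.approx(30.0)

    def test_no_contigs_is_an_error(self):
        with pytest.raises(Exception):
            average_coverage([], CoverageMode.CRS_LARGE_CONTIG_MEAN)


class TestClassification:
    @pytest.mark.parametrize(
        "abundance,avg,expected",
        [
            (60, 30, ContigClass.REPEAT),
            (51, 30, ContigClass.PROBABLE_REPEAT),  # ratio 1.7
            (40, 30, ContigClass.UNIQUE),  # ratio 1.33
            (45, 30, ContigClass.PROBABLE_REPEAT),  # boundary 1.5
            (44.9, 30, ContigClass.UNIQUE),  # just under 1.5
            (75, 30, ContigClass.REPEAT),  # ratio 2.5
        ],
    )
    def test_threshold_rules(self, abundance, avg, expected):
        assert classify_contig(abundance, avg) is expected

    def test_zero_average_warns_not_raises(self):
        with pytest.warns(UserWarning):
            assert classify_contig(10, 0) is ContigClass.UNCLASSIFIED

    @given(ab=st.floats(0, 1000), avg=st.floats(0.01, 100),
           c=st.floats(0.001, 1000))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, ab, avg, c):
        assert classify_contig(ab, avg) is classify_contig(ab * c, avg * c)

    @given(avg=st.floats(1, 100),
           pair=st.tuples(st.floats(0, 500), st.floats(0, 500)))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_abundance(self, avg, pair):
        order = [ContigClass.UNIQUE, ContigClass.PROBABLE_REPEAT,
                 ContigClass.REPEAT]
        lo, hi = sorted(pair)
        assert order.index(classify_contig(lo, avg)) <= order.index(
            classify_contig(hi, avg))

    @pytest.mark.parametrize("ab,avg,expected", [(60, 30, 2.0), (0, 30, 0.0),
                                                 (30, 30, 1.0)])
    def test_copy_number(self, ab, avg, expected):
        assert copy_number(ab, avg) == pytest.approx(expected)

    def test_copy_number_undefined(self):
        with pytest.raises(UndefinedValueError):
            copy_number(10, 0)


class TestZNormalizer:
    def _graph(self, supports, small_pair=None):
        contigs = [(1, 30000, 30), (2, 30000, 30), (3, 30000, 30), (4, 30000, 30)]
        ends = [("1E", "2S"), ("2E", "3S"), ("3E", "4S"), ("4E", "1S")]
        links = [(a, b, s) for (a, b), s in zip(ends, supports)]
        if small_pair:
            contigs.append((9, 500, 30))
            links.append(("9S", "1S", small_pair))
        return build_graph(contigs, links)

    def test_mean_support_and_weights(self):
        g = self._graph([10, 20, 30, 40])
        assert z_normalizer(g) == pytest.approx(25.0)
        heavy = g.get_link("4E", "1S")
        assert heavy.display_weight == pytest.approx(40 / 25)

    def test_small_contig_links_do_not_qualify(self):
        g = self._graph([10, 20, 30], small_pair=999)
        # 3 large-large links (the 4th ends list entry is unused)
        g2 = build_graph(
            [(1, 30000, 30), (2, 30000, 30), (9, 500, 30)],
            [("1E", "2S", 10), ("2E", "9S", 50)],
        )
        assert g2.z_norm == pytest.approx(10.0)

    def test_single_qualifying_link(self):
        g = build_graph([(1, 30000, 30), (2, 30000, 30)], [("1E", "2S", 7)])
        assert g.z_norm == pytest.approx(7.0)
        assert g.links[0].display_weight == pytest.approx(1.0)

    def test_fallback_to_all_links(self):
        g = build_graph([(1, 5000, 30), (2, 4000, 30), (3, 3000, 30)],
                        [("1E", "2S", 4), ("2E", "3S", 6)])
        assert g.z_norm == pytest.approx(5.0)

    def test_no_links_z_is_one(self):
        g = build_graph([(1, 30000, 30)], [])
        assert g.z_norm == pytest.approx(1.0)

    def test_qualifying_weights_average_to_one(self):
        g = self._graph([3, 9, 14, 22])
        weights = [lk.display_weight for lk in g.links]
        assert sum(weights) / len(weights) == pytest.approx(1.0, abs=1e-9)


class TestFilterAndUnlinked:
    def test_filter_is_noop_at_zero(self):
        g = build_graph(FIG3D_CONTIGS, FIG3D_LINKS)
        f = filter_by_size(g, 0)
        assert set(f.contigs) == set(g.contigs)
        assert len(f.links) == len(g.links)

    def test_filter_drops_small_and_dangling_links(self):
        g = build_graph([(1, 500, 30), (2, 2500, 30), (3, 40000, 30)],
                        [("1E", "2S", 5), ("2E", "3S", 4)])
        f = filter_by_size(g, 2000)
        assert sorted(f.contigs) == [2, 3]
        assert len(f.end_nodes()) == 4
        assert [(lk.end_a.label, lk.end_b.label) for lk in f.links] == [("2E", "3S")]
        assert sorted(g.contigs) == [1, 2, 3]  # input untouched

    def test_filter_idempotent(self):
        g = build_graph(FIG3D_CONTIGS, FIG3D_LINKS)
        once = filter_by_size(g, 2000)
        twice = filter_by_size(once, 2000)
        assert set(once.contigs) == set(twice.contigs)
        assert [lk.key for lk in once.links] == [lk.key for lk in twice.links]

    def test_unlinked_fig3d(self):
        g = build_graph(FIG3D_CONTIGS, FIG3D_LINKS)
        assert [n.label for n in unlinked_end_nodes(g)] == ["1S", "2E", "3E", "4E"]

    def test_self_link_closes_both_ends(self):
        g = build_graph([(1, 3000, 60)], [("1S", "1E", 8)])
        assert unlinked_end_nodes(g) == []

    def test_no_links_all_ends_unlinked(self):
        g = build_graph([(1, 1000, 10), (2, 1000, 10)], [])
        assert len(unlinked_end_nodes(g)) == 4

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_unlinked_matches_bruteforce_degree_count(self, data):
        n = data.draw(st.integers(1, 6))
        contigs = [(i, 1000, 10.0) for i in range(1, n + 1)]
        labels = [f"{i}{e}" for i in range(1, n + 1) for e in "SE"]
        n_links = data.draw(st.integers(0, 8))
        rows = []
        seen = set()
        for _ in range(n_links):
            a = data.draw(st.sampled_from(labels))
            b = data.draw(st.sampled_from(labels))
            if a == b or frozenset((a, b)) in seen:
                continue
            seen.add(frozenset((a, b)))
            rows.append((a, b, data.draw(st.integers(1, 9))))
        g = build_graph(contigs, rows)
        touched = {lbl for row in rows for lbl in row[:2]}
        expected = sorted(set(labels) - touched,
                          key=lambda l: (int(l[:-1]), l[-1] != "S"))
        assert [x.label for x in unlinked_end_nodes(g)] == expected
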
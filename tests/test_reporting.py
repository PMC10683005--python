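"""Summary statistics, reports and visualization data structures."""

import networkx as nx
import numpy as np
import pytest

from cadlink.filtering import StageCounts
from cadlink.io_formats import read_network, write_network
from cadlink.models import CadPeak, CandidateAnnotation, FeaturePeakLink
from cadlink.reporting import (alluvial_counts, build_report, decorate_network,
                               pseudochromatogram, summarize, treemap)


def ann(fid, pathway="Terpenoids", structure=None, formula="C30H48O3",
        npc_class="Y", tax=0.9, score=0.7, level="species"):
    return CandidateAnnotation(
        feature_id=fid, rank=1, structure_id=structure or f"S{fid}",
        molecular_formula=formula, npc_pathway=pathway, npc_superclass="X",
        npc_class=npc_class, taxonomic_distance_score=tax, final_score=score,
        closest_organism="Org", taxon_level=level)


def link(fid, pid, final="major"):
    return FeaturePeakLink(fid, pid, 0.9, "major", final)


def peak(pid, apex, area):
    return CadPeak(pid, apex, apex - 0.1, apex + 0.1, 10.0, area)


class TestSummarize:
    def test_printed_no_filter_totals(self):
        # 1181 linked features spread over 62 contributing peaks -> 19.0
        links = [FeaturePeakLink(i, (i % 62) + 1, 0.9, "major", "major")
                 for i in range(1181)]
        stats = summarize(links, [], "none")
        assert stats.features_linked == 1181
        assert stats.mean_features_per_peak == 19.0

    def test_no_linked_features_not_available(self):
        links = [FeaturePeakLink(1, None, None, "minor", "minor")]
        stats = summarize(links, [], "none")
        assert stats.features_linked == 0
        assert stats.mean_features_per_peak is None

    def test_three_peak_hand_arithmetic(self):
        links = []
        fid = 0
        for pid, n in [(1, 2), (2, 3), (3, 4)]:
            for _ in range(n):
                fid += 1
                links.append(link(fid, pid))
        stats = summarize(links, [], "none")
        assert stats.mean_features_per_peak == 3.0

    def test_distinct_structures_counted(self):
        links = [link(1, 1), link(2, 1)]
        annotations = [ann(1, structure="A"), ann(2, structure="A")]
        stats = summarize(links, annotations, "none")
        assert stats.mean_structures_per_peak == 1.0

    def test_matches_flat_loop_recount(self, default_bundle, default_result):
        stats = summarize(default_result.links, default_bundle.annotations, "shape")
        surv = [lk for lk in default_result.links if lk.status_shape == "major"]
        peaks = {lk.peak_id for lk in surv}
        assert stats.features_linked == len(surv)
        expected = round(len(surv) / len(peaks), 1) if peaks else None
        assert stats.mean_features_per_peak == pytest.approx(expected, abs=0.051)


class TestReport:
    def test_two_isomer_candidates_one_row(self):
        peaks = [peak(1, 5.0, 50.0)]
        links = [link(1, 1), link(2, 1)]
        annotations = [ann(1, structure="oleanolic"), ann(2, structure="ursolic")]
        rows = build_report(peaks, links, annotations)
        assert len(rows) == 1
        assert {c["structure_id"] for c in rows[0].candidates} == {"oleanolic", "ursolic"}

    def test_empty_inputs_empty_report(self):
        assert build_report([], [], []) == []

    def test_unannotated_peak_listed_with_area_share(self):
        peaks = [peak(1, 5.0, 30.0), peak(2, 6.0, 30.0),
                 peak(3, 7.0, 30.0), peak(4, 8.0, 10.0)]
        links = [link(i, i) for i in (1, 2, 3)]
        annotations = [ann(i) for i in (1, 2, 3)]
        rows = build_report(peaks, links, annotations)
        assert len(rows) == 4
        unann = [r for r in rows if "unannotated" in r.flags]
        assert len(unann) == 1
        assert unann[0].area_fraction == pytest.approx(0.1)

    def test_area_fractions_sum_to_one_when_all_reported(self, default_bundle,
                                                         default_result):
        total = sum(r.area_fraction for r in default_result.report)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPseudochromatogram:
    def test_species_level_category(self):
        peaks = [peak(1, 5.0, 50.0)]
        bars = pseudochromatogram(peaks, [link(1, 1)], [ann(1)], "taxon-level")
        assert bars.bars == [(5.0, 50.0, "species")]

    def test_empty_input(self):
        assert pseudochromatogram([], [], [], "taxon-level").bars == []

    def test_bar_values_equal_peak_areas_exactly(self, default_result,
                                                 default_bundle):
        bars = pseudochromatogram(default_result.peaks, default_result.links,
                                  default_bundle.annotations, "taxon-level")
        assert [b[1] for b in bars.bars] == [p.area for p in
                                             sorted(default_result.peaks,
                                                    key=lambda p: p.apex_time)]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            pseudochromatogram([], [], [], "nope")


class TestTreemap:
    def test_single_pathway_is_one(self):
        res = treemap([link(1, 1)], [ann(1)], [peak(1, 5.0, 50.0)], "cad_area")
        assert res == {"Terpenoids": 1.0}

    def test_two_pathway_hand_arithmetic(self):
        peaks = [peak(1, 5.0, 58.0), peak(2, 6.0, 42.0)]
        links = [link(1, 1), link(2, 2)]
        annotations = [ann(1, "Terpenoids"), ann(2, "Polyketides")]
        res = treemap(links, annotations, peaks, "cad_area")
        assert res["Terpenoids"] == pytest.approx(0.58)
        assert res["Polyketides"] == pytest.approx(0.42)

    def test_empty_is_empty(self):
        assert treemap([], [], [], "cad_area") == {}

    def test_minor_count_weighting(self):
        links = [FeaturePeakLink(1, None, None, "minor", "minor"),
                 FeaturePeakLink(2, None, None, "minor", "minor"),
                 FeaturePeakLink(3, None, None, "minor", "minor")]
        annotations = [ann(1, "Terpenoids"), ann(2, "Terpenoids"),
                       ann(3, "Alkaloids")]
        res = treemap(links, annotations, [], "count")
        assert res["Terpenoids"] == pytest.approx(2 / 3)

    def test_fractions_sum_to_one(self, default_bundle, default_result):
        for weight in ("cad_area", "count"):
            res = treemap(default_result.links, default_bundle.annotations,
                          default_result.peaks, weight)
            if res:
                assert sum(res.values()) == pytest.approx(1.0, abs=1e-9)


class TestDecorateNetwork:
    def test_major_node_gets_peak_area(self):
        g = nx.Graph()
        g.add_node(1)
        out = decorate_network(g, [peak(7, 5.0, 33.0)], [link(1, 7)], [ann(1)])
        assert out.nodes[1]["cad_area"] == 33.0
        assert out.nodes[1]["status_final"] == "major"
        assert out.nodes[1]["npc_pathway"] == "Terpenoids"

    def test_minor_node_zero_area(self):
        g = nx.Graph()
        g.add_node(2)
        out = decorate_network(g, [peak(7, 5.0, 33.0)],
                               [FeaturePeakLink(2, 7, 0.5, "minor", "minor")], [])
        assert out.nodes[2]["cad_area"] == 0.0

    def test_node_without_link_gets_defaults(self):
        g = nx.Graph()
        g.add_node(5)
        out = decorate_network(g, [], [], [])
        assert out.nodes[5]["status_final"] == "minor"

    def test_decorated_roundtrip(self, tmp_path, default_bundle, default_result):
        assert default_result.network is not None
        p = write_network(default_result.network, tmp_path / "d.graphml")
        back = read_network(p)
        for n in default_result.network.nodes:
            assert back.nodes[n]["cad_area"] == pytest.approx(
                default_result.network.nodes[n]["cad_area"])
            assert back.nodes[n]["status_final"] == \
                default_result.network.nodes[n]["status_final"]


class TestAlluvial:
    def test_single_bin(self):
        counts = [StageCounts("shape+taxon+confidence", 3, {1: 1, 2: 1, 3: 1})]
        rows = alluvial_counts(counts)
        by_bin = {b: n for _, b, n in rows}
        assert by_bin["1"] == 3 and by_bin["0"] == 0

    def test_hand_binned_values(self):
        counts = [StageCounts("none", 10, {1: 0, 2: 1, 3: 2, 4: 4, 5: 9})]
        rows = alluvial_counts(counts)
        by_bin = {b: n for _, b, n in rows}
        assert by_bin == {"0": 1, "1": 1, "2": 1, "3-5": 1, ">5": 1}

    def test_partition_constant_across_stages(self, default_result):
        rows = alluvial_counts(default_result.stage_counts)
        totals = {}
        for stage, _, n in rows:
            totals[stage] = totals.get(stage, 0) + n
        assert len(set(totals.values())) == 1
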
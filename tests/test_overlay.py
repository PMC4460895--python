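"""Network overlays: induced subgraphs, fold-change annotation, stage
markers, stage assignment and peak-stage ordering."""

import numpy as np
import pandas as pd
import pytest

from stemprime.io import AnalysisConfig, GeneNetwork, StemprimeError
from stemprime.netinfer import ClusterAssignment, build_correlation_network, markov_cluster
from stemprime.overlay import (
    annotate_fold_changes,
    assign_stages,
    induced_subgraph,
    order_by_peak_stage,
    overlay_de_counts,
    select_stage_markers,
)
from stemprime.synth import (
    StageMarkerCatalog,
    TimeCourseSpec,
    simulate_stage_course,
)


@pytest.fixture(scope="module")
def course_and_truth():
    return simulate_stage_course(TimeCourseSpec(markers_per_stage=50, seed=5))


@pytest.fixture(scope="module")
def stage_pipeline(course_and_truth):
    """Catalog (subset of planted markers), network and clusters."""
    course, truth = course_and_truth
    cfg = AnalysisConfig(stage_top_n=30)
    catalog = select_stage_markers(course, cfg)
    genes = sorted(set().union(*truth.markers.values()))
    sub = course.with_values(course.values.loc[genes])
    net = build_correlation_network(sub, cfg.pearson_cutoff_stage)
    clusters = markov_cluster(net, cfg.mcl_inflation)
    return course, truth, catalog, net, clusters


class TestInducedSubgraph:
    def net(self):
        return GeneNetwork.from_edges(
            [("A", "B", 0.5), ("A", "C", 0.6), ("C", "D", 0.7)], "mi"
        )

    def test_full_set_is_identity(self):
        net = self.net()
        sub, frac = induced_subgraph(net, set(net.graph.nodes))
        assert sub.edge_set() == net.edge_set() and frac == 1.0

    def test_only_internal_edges_kept(self):
        sub, frac = induced_subgraph(self.net(), {"A", "B"})
        assert sub.edge_set() == {frozenset("AB")}
        sub2, _ = induced_subgraph(self.net(), {"A", "D"})
        assert sub2.n_edges == 0

    def test_mapped_fraction(self):
        _, frac = induced_subgraph(self.net(), {"A", "B", "nope", "missing"})
        assert frac == 0.5

    def test_empty_intersection_errors(self):
        with pytest.raises(StemprimeError):
            induced_subgraph(self.net(), {"zz"})


class TestAnnotateFoldChanges:
    def test_flags(self):
        net = GeneNetwork.from_edges([("A", "B", 0.5), ("B", "C", 0.5)], "mi")
        table = pd.DataFrame({"signed_fc": [-2.5, 1.9]}, index=["A", "B"])
        out = annotate_fold_changes(net, table, highlight_fc=1.9)
        assert out.graph.nodes["A"]["flag"] == "down"
        assert out.graph.nodes["B"]["flag"] == "mapped"  # +1.9 exactly: strict >
        assert out.graph.nodes["C"]["flag"] == "unmapped"

    def test_planted_flag_counts(self):
        nodes = [f"g{i}" for i in range(10)]
        net = GeneNetwork.from_edges([], "mi", nodes=nodes)
        fc = [-3, -2.2, -2.0, -2.5] + [2.5, 2.0, 3.5] + [1.1, -1.2, 1.0]
        table = pd.DataFrame({"signed_fc": fc}, index=nodes)
        out = annotate_fold_changes(net, table, highlight_fc=1.9)
        flags = [out.graph.nodes[n]["flag"] for n in nodes]
        assert flags.count("down") == 4 and flags.count("up") == 3


class TestStageMarkers:
    def test_recovers_planted_catalog(self, course_and_truth):
        course, truth = course_and_truth
        catalog = select_stage_markers(course, AnalysisConfig(stage_top_n=50))
        for s in truth.stages:
            a, b = truth.markers[s], catalog.markers[s]
            assert len(a & b) / len(a | b) >= 0.9, s

    def test_markers_disjoint(self, stage_pipeline):
        _, _, catalog, _, _ = stage_pipeline
        seen = set()
        for s in catalog.stages:
            assert not (seen & catalog.markers[s])
            seen |= catalog.markers[s]

    def test_no_qualifying_genes_warns(self):
        course, _ = simulate_stage_course(
            TimeCourseSpec(markers_per_stage=1, n_genes=40, marker_amplitude=0.01,
                           background_sd=0.01, seed=0)
        )
        with pytest.warns(UserWarning, match="no gene"):
            catalog = select_stage_markers(course, AnalysisConfig())
        assert catalog.n_markers == 0

    def test_top_n_larger_than_qualifying(self, course_and_truth):
        course, truth = course_and_truth
        catalog = select_stage_markers(course, AnalysisConfig(stage_top_n=10000))
        for s in truth.stages[1:]:
            assert len(catalog.markers[s]) < 10000


class TestAssignStages:
    def test_majority_rule_and_evidence(self):
        net = GeneNetwork.from_edges([("x", "m1", 0.95)], "pearson",
                                     nodes=["x"] + [f"m{i}" for i in range(1, 7)])
        catalog = StageMarkerCatalog(
            stages=("s1", "s3"),
            markers={"s3": frozenset({"m1", "m2", "m3", "m4", "m5"}),
                     "s1": frozenset({"m6"})},
        )
        clusters = ClusterAssignment(
            {"x": 1, "m1": 1, "m2": 1, "m3": 1, "m4": 1, "m5": 1, "m6": 1},
            1, True, 1,
        )
        out = assign_stages(net, catalog, clusters)
        assert out.assignment["x"] == ("s3", 5)

    def test_isolated_node_unassigned(self):
        net = GeneNetwork.from_edges([], "pearson", nodes=["lone", "m1"])
        catalog = StageMarkerCatalog(stages=("s1",), markers={"s1": frozenset({"m1"})})
        clusters = ClusterAssignment({"lone": 1, "m1": 2}, 2, True, 1)
        out = assign_stages(net, catalog, clusters)
        assert out.assignment["lone"] == ("unassigned", 0)

    def test_tie_is_unassigned(self):
        net = GeneNetwork.from_edges([], "pearson", nodes=["x", "m1", "m2"])
        catalog = StageMarkerCatalog(
            stages=("s1", "s2"),
            markers={"s1": frozenset({"m1"}), "s2": frozenset({"m2"})},
        )
        clusters = ClusterAssignment({"x": 1, "m1": 1, "m2": 1}, 1, True, 1)
        assert assign_stages(net, catalog, clusters).assignment["x"] == ("unassigned", 0)

    def test_held_out_recovery(self, stage_pipeline):
        _, truth, catalog, net, clusters = stage_pipeline
        assignment = assign_stages(net, catalog, clusters)
        truth_stage = truth.stage_of()
        held = [g for g in net.graph.nodes if g not in catalog.stage_of()]
        correct = sum(assignment.stage_of(g) == truth_stage[g] for g in held)
        assert correct / len(held) >= 0.95

    def test_node_order_invariance(self, stage_pipeline):
        _, _, catalog, net, clusters = stage_pipeline
        a1 = assign_stages(net, catalog, clusters).assignment
        shuffled = GeneNetwork(net.graph.copy(), net.weight_kind)
        a2 = assign_stages(shuffled, catalog, clusters).assignment
        assert a1 == a2


class TestOverlayCountsAndOrdering:
    def test_counts_by_stage(self, stage_pipeline):
        _, truth, catalog, net, clusters = stage_pipeline
        assignment = assign_stages(net, catalog, clusters)
        late_stage = catalog.stages[4]
        planted_up = sorted(truth.markers[late_stage])[:15]
        counts, late = overlay_de_counts(assignment, planted_up, [], catalog.stages)
        assert counts.loc[late_stage, "up"] >= 13
        assert set(late) >= set(g for g in planted_up if assignment.stage_of(g) == late_stage)

    def test_all_unassigned_zero(self):
        from stemprime.overlay import StageAssignment

        assignment = StageAssignment({"a": ("unassigned", 0)})
        counts, late = overlay_de_counts(assignment, ["a"], [], ["s1", "s2"])
        assert counts.to_numpy().sum() == 0 and late == []

    def test_peak_order(self, course_and_truth):
        course, truth = course_and_truth
        early = sorted(truth.markers[truth.stages[0]])[:3]
        late = sorted(truth.markers[truth.stages[-1]])[:3]
        ordered, means, skipped = order_by_peak_stage(course, late + early + ["ghost"])
        assert skipped == ["ghost"]
        assert ordered[:3] == early and set(ordered[3:]) == set(late)
        assert list(means.index) == ordered

    def test_same_peak_ties_by_id(self, course_and_truth):
        course, truth = course_and_truth
        genes = sorted(truth.markers[truth.stages[3]])[:4]
        ordered, _, _ = order_by_peak_stage(course, genes[::-1])
        assert ordered == sorted(genes)
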
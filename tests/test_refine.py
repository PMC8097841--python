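"""The four refinement stages and the end-to-end pipeline."""

import random

import pytest

from binrefine.graph import ContigGraph, Labelling, RefinerConfig
from binrefine.refine import (
    best_action,
    component_avg_coverage,
    is_supported,
    label_components,
    labelled_score,
    run_pipeline,
    step1_remove_unsupported,
    step2_correct_inconsistent,
    step3_propagate,
    step4_infer_multilabel,
    subset_sum_select,
)

from conftest import (
    oracle_is_supported,
    oracle_subset_sum,
    path_graph,
    random_contig_graph,
)


class TestIsSupported:
    def test_isolated_labelled_vertex(self):
        g = ContigGraph()
        g.add_vertex("a", coverage=1.0)
        lab = Labelling.from_single({"a": "red"})
        assert is_supported(g, lab, "a")

    def test_direct_same_label_neighbour(self, example):
        g, lab = example
        assert is_supported(g, lab, "2")  # red 2 adjacent to red 6

    def test_support_through_unlabelled_path(self, example):
        g, lab = example
        assert is_supported(g, lab, "18")  # green 18 -19-14- green 15

    def test_unsupported_vertex(self, example):
        g, lab = example
        assert not is_supported(g, lab, "1")  # blue 1 cannot reach blue

    def test_unlabelled_vertex_rejected(self, example):
        g, lab = example
        with pytest.raises(ValueError):
            is_supported(g, lab, "14")


class TestStep1:
    def test_removes_exactly_the_unsupported_vertex(self, example):
        g, lab = example
        out = step1_remove_unsupported(g, lab)
        assert lab.labelled - out.labelled == {"1"}
        assert all(out.labels(v) == lab.labels(v) for v in out.labelled)

    def test_uniform_label_connected_graph_unchanged(self):
        vs = ["a", "b", "c", "d"]
        g = path_graph(*vs)
        lab = Labelling.from_single({v: "x" for v in vs})
        assert step1_remove_unsupported(g, lab) == lab

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_per_vertex_bfs_oracle(self, seed):
        rng = random.Random(42 + seed)
        g, lab = random_contig_graph(rng, n_max=25)
        out = step1_remove_unsupported(g, lab)
        for v in lab.labelled:
            expected = oracle_is_supported(g, lab, v)
            assert (v in out.labelled) == expected, v

    @pytest.mark.parametrize("seed", range(10))
    def test_every_surviving_vertex_is_supported(self, seed):
        rng = random.Random(900 + seed)
        g, lab = random_contig_graph(rng, n_max=25)
        out = step1_remove_unsupported(g, lab)
        # support judged against the *input* labelling, per the
        # simultaneous-removal contract
        assert all(oracle_is_supported(g, lab, v) for v in out.labelled)


class TestLabelledScore:
    def test_four_neighbours_at_distance_one(self, example):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        assert labelled_score(g, lab1, "18", "blue", 5) == 2.0

    def test_distances_three_three_four(self, example):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        assert labelled_score(g, lab1, "18", "green", 5) == 5 / 16

    def test_unreachable_label_scores_zero(self):
        g = path_graph("a", "m", "b", coverages={"a": 1, "m": 1, "b": 1})
        lab = Labelling.from_single({"a": "x", "m": "y", "b": "z"})
        # m labelled: blocks the only path from a to b
        assert labelled_score(g, lab, "a", "z", 5) == 0.0

    def test_each_source_contributes_once_via_shortest_path(self):
        # two routes from v to t of lengths 2 and 3: one contribution, 1/4
        g = ContigGraph.from_edges(
            [("v", "p"), ("p", "t"), ("v", "q"), ("q", "r"), ("r", "t")]
        )
        lab = Labelling.from_single({"t": "x"})
        assert labelled_score(g, lab, "v", "x", 5) == 0.25


class TestStep2:
    def test_corrects_the_two_inconsistent_vertices(self, example, config):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        lab2 = step2_correct_inconsistent(g, lab1, config)
        changed = {v for v in lab1.labelled if lab1.labels(v) != lab2.labels(v)}
        assert changed == {"18", "22"}
        assert lab2.label_of("18") == "blue"
        assert lab2.label_of("22") == "green"

    def test_boundary_equality_triggers_correction(self):
        # S(v,x)=1 (one neighbour), S(v,y)=1.5 (three at distance 1):
        # 1.5*1.0 <= 1.5 holds with equality => relabelled
        g = ContigGraph.from_edges(
            [("v", "x1"), ("v", "y1"), ("v", "y2"), ("v", "y3")]
        )
        lab = Labelling.from_single(
            {"v": "x", "x1": "x", "y1": "y", "y2": "y", "y3": "y"}
        )
        # make y vertices mutually supported so step2's precondition holds
        g.add_edge("y1", "y2")
        g.add_edge("y2", "y3")
        out = step2_correct_inconsistent(g, lab, RefinerConfig(alpha=1.5))
        assert out.label_of("v") == "y"

    def test_no_competing_label_leaves_vertex_unchanged(self):
        g = path_graph("v", "t")
        lab = Labelling.from_single({"v": "x", "t": "x"})
        out = step2_correct_inconsistent(g, lab, RefinerConfig())
        assert out == lab

    def test_labelled_set_is_preserved_and_scores_increase(self, example, config):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        lab2 = step2_correct_inconsistent(g, lab1, config)
        assert lab1.labelled == lab2.labelled
        for v in lab1.labelled:
            if lab1.labels(v) != lab2.labels(v):
                old = labelled_score(g, lab1, v, lab1.label_of(v), 5)
                new = labelled_score(g, lab1, v, lab2.label_of(v), 5)
                assert new > old


class TestStep3:
    def test_worked_propagation_trace(self, example, config):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        lab2 = step2_correct_inconsistent(g, lab1, config)
        trace = []
        lab3 = step3_propagate(g, lab2, config, trace=trace)
        assert [(a.d, a.cdiff, a.source, a.target) for a, _ in trace] == [
            (1, 0, "6", "1"),
            (1, 0, "13", "14"),
            (1, 1, "22", "21"),
            (1, 2, "14", "7"),
            (1, 3, "18", "19"),
            (1, 16, "8", "3"),
            (1, 53, "21", "25"),
        ]
        assert [x for _, x in trace] == [
            "red", "red", "green", "red", "blue", "green", "green"
        ]
        assert lab3.unlabelled(g) == set()

    def test_no_unlabelled_vertices_is_a_no_op(self):
        g = path_graph("a", "b", coverages={"a": 1, "b": 2})
        lab = Labelling.from_single({"a": "x", "b": "y"})
        assert step3_propagate(g, lab, RefinerConfig()) == lab

    def test_smaller_coverage_difference_wins_at_equal_distance(self):
        g = ContigGraph.from_edges(
            [("v", "r"), ("v", "b")],
            coverages={"v": 10, "r": 12, "b": 15},
        )
        lab = Labelling.from_single({"r": "red", "b": "blue"})
        out = step3_propagate(g, lab, RefinerConfig())
        assert out.label_of("v") == "red"  # |10-12|=2 beats |10-15|=5

    def test_out_of_reach_vertices_stay_unlabelled(self):
        vs = [str(i) for i in range(9)]
        g = path_graph(*vs, coverages={v: 1.0 for v in vs})
        lab = Labelling.from_single({"0": "x"})
        out = step3_propagate(g, lab, RefinerConfig(bfs_depth_cap=5))
        # propagation re-reaches iteratively, so the whole path labels up
        assert out.unlabelled(g) == set()
        out2 = step3_propagate(g, lab, RefinerConfig(bfs_depth_cap=1))
        assert out2.unlabelled(g) == set()

    def test_isolated_unlabelled_vertex_stays_unbinned(self):
        g = path_graph("a", "b", coverages={"a": 1, "b": 1})
        g.add_vertex("lonely", coverage=1.0)
        lab = Labelling.from_single({"a": "x"})
        out = step3_propagate(g, lab, RefinerConfig())
        assert out.unlabelled(g) == {"lonely"}

    @pytest.mark.parametrize("seed", range(15))
    def test_local_candidate_refresh_equals_full_recompute(self, seed):
        """Executed action sequence is identical when every candidate is
        recomputed from scratch after each iteration."""
        rng = random.Random(3000 + seed)
        g, lab = random_contig_graph(rng, n_max=20)
        cfg = RefinerConfig()
        trace = []
        out = step3_propagate(g, lab, cfg, trace=trace)

        # reference: full recomputation
        ref = lab.copy()
        ref_trace = []
        while True:
            actions = [
                a for v in sorted(ref.unlabelled(g))
                if (a := best_action(g, ref, v, cfg.bfs_depth_cap)) is not None
            ]
            if not actions:
                break
            a = min(actions, key=lambda a: (a.d, a.cdiff, a.target, a.source))
            ref_trace.append((a.d, a.cdiff, a.source, a.target))
            ref.set_labels(a.target, {ref.label_of(a.source)})
        assert [(a.d, a.cdiff, a.source, a.target) for a, _ in trace] == ref_trace
        assert out == ref


class TestComponentAvgCoverage:
    def test_equal_lengths_reduce_to_mean(self):
        g = path_graph("a", "b", coverages={"a": 10, "b": 30})
        assert component_avg_coverage(g, ["a", "b"]) == 20

    def test_length_weighting(self):
        g = ContigGraph()
        g.add_vertex("a", length=1000, coverage=100)
        g.add_vertex("b", length=3000, coverage=50)
        assert component_avg_coverage(g, ["a", "b"]) == 62.5

    def test_singleton(self):
        g = ContigGraph()
        g.add_vertex("a", length=10, coverage=7.0)
        assert component_avg_coverage(g, ["a"]) == 7.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            component_avg_coverage(ContigGraph(), [])


class TestSubsetSum:
    def test_single_candidate_chosen_when_closer(self):
        assert subset_sum_select({"R": 19.0}, 13.0) == {"R"}

    def test_single_candidate_for_target_47(self):
        assert subset_sum_select({"B": 49.0}, 47.0) == {"B"}

    def test_tie_prefers_fewer_elements(self):
        assert subset_sum_select({"a": 10.0, "b": 20.0, "c": 30.0}, 30.0) == {"c"}

    def test_empty_subset_can_win(self):
        assert subset_sum_select({"a": 50.0}, 1.0) == frozenset()

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bitmask_enumeration_oracle(self, seed):
        rng = random.Random(4000 + seed)
        for _ in range(20):
            k = rng.randint(0, 4)
            cands = {f"c{i}": rng.uniform(0, 100) for i in range(k)}
            target = rng.uniform(-20, 250)
            assert subset_sum_select(cands, target) == \
                oracle_subset_sum(cands, target)


class TestStep4:
    def _after_step3(self, example, config):
        g, lab = example
        lab1 = step1_remove_unsupported(g, lab)
        lab2 = step2_correct_inconsistent(g, lab1, config)
        return g, step3_propagate(g, lab2, config)

    def test_vertex_3_gains_red(self, example, config):
        g, lab3 = self._after_step3(example, config)
        lab4 = step4_infer_multilabel(g, lab3, config)
        assert lab4.labels("3") == {"green", "red"}

    def test_vertex_25_gains_blue(self, example, config):
        g, lab3 = self._after_step3(example, config)
        lab4 = step4_infer_multilabel(g, lab3, config)
        assert lab4.labels("25") == {"green", "blue"}

    def test_vertex_14_gains_nothing(self, example, config):
        g, lab3 = self._after_step3(example, config)
        lab4 = step4_infer_multilabel(g, lab3, config)
        assert lab4.labels("14") == {"red"}

    def test_only_adds_labels_never_removes(self, example, config):
        g, lab3 = self._after_step3(example, config)
        lab4 = step4_infer_multilabel(g, lab3, config)
        for v in lab3.labelled:
            assert lab3.labels(v) <= lab4.labels(v)
        assert {v for v in lab4.labelled if len(lab4.labels(v)) > 1} == {"3", "25"}

    def test_component_averages(self, example, config):
        g, lab3 = self._after_step3(example, config)
        comps = {c.label: c.avg_coverage for c in label_components(g, lab3)}
        assert comps == {"red": 19.0, "green": 95.0, "blue": 49.0}


class TestPipeline:
    def test_worked_example_end_to_end(self, example, config):
        g, lab = example
        res = run_pipeline(g, lab, config)
        final = res.labelling
        assert final.labels("1") == {"red"}
        assert final.labels("18") == {"blue"}
        assert final.labels("22") == {"green"}
        assert final.labels("3") == {"green", "red"}
        assert final.labels("25") == {"green", "blue"}
        assert res.counts == {
            "removed": 1, "corrected": 2, "propagated": 7, "multi_labelled": 2
        }

    def test_empty_initial_labelling_stays_empty(self):
        g = path_graph("a", "b", "c", coverages={"a": 1, "b": 1, "c": 1})
        res = run_pipeline(g, Labelling())
        assert res.labelling.labelled == set()

    def test_correct_clique_per_bin_is_a_fixed_point(self):
        g = ContigGraph()
        for v in ("a1", "a2", "a3", "b1", "b2", "b3"):
            g.add_vertex(v, length=1000, coverage=10.0 if v[0] == "a" else 50.0)
        for u, v in [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                     ("b1", "b2"), ("b2", "b3"), ("b1", "b3")]:
            g.add_edge(u, v)
        lab = Labelling.from_single(
            {v: ("A" if v[0] == "a" else "B") for v in g.vertices}
        )
        res = run_pipeline(g, lab)
        assert res.labelling == lab

    def test_overlapped_input_rejected(self):
        g = path_graph("a", "b", coverages={"a": 1, "b": 1})
        lab = Labelling({"a": {"x", "y"}})
        with pytest.raises(ValueError):
            run_pipeline(g, lab)

    def test_missing_coverage_rejected(self):
        g = ContigGraph()
        g.add_vertex("a")
        with pytest.raises(ValueError, match="coverage"):
            run_pipeline(g, Labelling())

    def test_multilabel_flag_off_keeps_single_bins(self, example, config):
        g, lab = example
        res = run_pipeline(g, lab, config, multilabel=False)
        assert not res.labelling.is_overlapped()
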
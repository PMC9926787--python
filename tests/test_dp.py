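import itertools
import math

import numpy as np
import pytest

from gennet.datamodel import Network
from gennet.dp import (
    SearchError,
    compute_best_parents,
    compute_best_sinks,
    compute_local_scores,
    count_orderings,
    exhaustive_oracle,
    generational_successors,
    iter_dags,
    markov_equivalence_classes,
    realizable_under_complete_ordering,
    reconstruct_networks,
)
from gennet.scoring import LocalScoreTable, network_score
from gennet.screening import FeasibleSet

from .conftest import (
    brute_force_generational_orderings,
    make_continuous_dataset,
    random_parent_map,
)


def fixture_table(scores: dict, indegree: int = 2) -> LocalScoreTable:
    return LocalScoreTable(
        scores={v: {frozenset(g): s for g, s in sub.items()} for v, sub in scores.items()},
        score_type="bic",
        indegree=indegree,
    )


class TestComputeLocalScores:
    def test_entry_counts_follow_binomial_truncation(self, rng):
        names = ["a", "b", "c", "d"]
        ds = make_continuous_dataset(rng.normal(size=(50, 4)), names=names)
        feas = FeasibleSet(
            nodes=names,
            reduced_pp={"a": ("b", "c", "d"), "b": (), "c": ("a",), "d": ("a", "b")},
        )
        table = compute_local_scores(ds, feas, "bic", indegree=2)
        assert len(table.scores["a"]) == 1 + 3 + 3  # C(3,0)+C(3,1)+C(3,2)
        assert len(table.scores["b"]) == 1
        assert len(table.scores["c"]) == 2
        assert len(table.scores["d"]) == 4

    def test_total_entries_bounded_by_pbar_r_d(self, rng):
        names = [f"v{i}" for i in range(6)]
        ds = make_continuous_dataset(rng.normal(size=(40, 6)), names=names)
        for trial in range(10):
            pp = random_parent_map(names, rng, max_parents=4)
            feas = FeasibleSet(nodes=names, reduced_pp=pp)
            d = int(rng.integers(1, 4))
            table = compute_local_scores(ds, feas, "bic", indegree=d)
            r = max(len(pp[v]) for v in names)
            bound = len(names) * sum(math.comb(r, j) for j in range(d + 1))
            total = sum(len(table.scores[v]) for v in names)
            assert total <= bound


class TestBestParents:
    def test_empty_candidate_set(self):
        feas = FeasibleSet(nodes=["v", "a"], reduced_pp={"v": ("a",), "a": ()})
        table = fixture_table({"v": {(): -10.0, ("a",): -8.0}, "a": {(): -1.0}})
        bp = compute_best_parents(table, feas)
        score, tied = bp.best_for("v", [])
        assert score == -10.0 and tied == [frozenset()]

    def test_direct_max_over_four_subsets(self):
        feas = FeasibleSet(
            nodes=["v", "a", "b"], reduced_pp={"v": ("a", "b"), "a": (), "b": ()}
        )
        table = fixture_table(
            {
                "v": {(): -10.0, ("a",): -8.0, ("b",): -9.0, ("a", "b"): -8.5},
                "a": {(): 0.0},
                "b": {(): 0.0},
            }
        )
        bp = compute_best_parents(table, feas)
        score, tied = bp.best_for("v", ["a", "b"])
        assert score == -8.0 and tied == [frozenset({"a"})]

    def test_matches_exhaustive_subset_max(self, rng):
        names = ["v"] + [f"p{i}" for i in range(5)]
        pp = tuple(names[1:])
        feas = FeasibleSet(
            nodes=names, reduced_pp={"v": pp, **{p: () for p in pp}}
        )
        d = 3
        scores = {"v": {}, **{p: {(): 0.0} for p in pp}}
        for size in range(d + 1):
            for combo in itertools.combinations(pp, size):
                scores["v"][combo] = float(rng.normal())
        table = fixture_table(scores, indegree=d)
        bp = compute_best_parents(table, feas)
        for size in range(len(pp) + 1):
            for u_set in itertools.combinations(pp, size):
                best, tied = bp.best_for("v", u_set)
                brute = max(
                    table.get("v", g)
                    for k in range(min(d, size) + 1)
                    for g in itertools.combinations(u_set, k)
                )
                assert best == pytest.approx(brute, abs=1e-12)
                for g in tied:
                    assert table.get("v", g) == pytest.approx(brute, abs=1e-9)

    def test_monotone_in_candidate_set(self, rng):
        names = ["v", "a", "b", "c"]
        feas = FeasibleSet(
            nodes=names,
            reduced_pp={"v": ("a", "b", "c"), "a": (), "b": (), "c": ()},
        )
        scores = {"v": {}, "a": {(): 0.0}, "b": {(): 0.0}, "c": {(): 0.0}}
        for size in range(3):
            for combo in itertools.combinations(("a", "b", "c"), size):
                scores["v"][combo] = float(rng.normal())
        table = fixture_table(scores, indegree=2)
        bp = compute_best_parents(table, feas)
        subsets = [
            set(c)
            for size in range(4)
            for c in itertools.combinations(("a", "b", "c"), size)
        ]
        for u in subsets:
            for w in subsets:
                if u <= w:
                    assert bp.best_for("v", u)[0] <= bp.best_for("v", w)[0] + 1e-12


class TestGenerationalSuccessors:
    def test_worked_map_excludes_node3_after_4(self, worked_feasible):
        assert generational_successors({"4"}, worked_feasible) == {"1"}

    def test_empty_set_admits_all_singletons(self, worked_feasible):
        assert generational_successors(set(), worked_feasible) == {"1", "2", "3", "4"}

    def test_worked_map_level2_reachable_pairs(self, worked_feasible):
        reachable = set()
        for v in worked_feasible.nodes:
            for s in generational_successors({v}, worked_feasible):
                reachable.add(frozenset({v, s}))
        assert reachable == {
            frozenset({"1", "2"}),
            frozenset({"1", "4"}),
            frozenset({"2", "3"}),
        }


def uniform_table(feas: FeasibleSet, rng, indegree=2) -> LocalScoreTable:
    scores = {}
    for v in feas.nodes:
        entry = {}
        for size in range(min(indegree, len(feas.reduced_pp[v])) + 1):
            for combo in itertools.combinations(feas.reduced_pp[v], size):
                entry[frozenset(combo)] = float(rng.normal())
        scores[v] = entry
    return LocalScoreTable(scores=scores, score_type="bic", indegree=indegree)


class TestBestSinks:
    def test_single_node_lattice(self, rng):
        feas = FeasibleSet(nodes=["v"], reduced_pp={"v": ()})
        table = fixture_table({"v": {(): -3.5}})
        bp = compute_best_parents(table, feas)
        lattice = compute_best_sinks(feas, bp)
        assert set(lattice.reachable) == {0, 1}
        score, sinks = lattice.reachable[1]
        assert score == -3.5 and sinks == (0,)

    def test_worked_map_full_set_reachable_with_8_orderings(
        self, worked_feasible, rng
    ):
        table = uniform_table(worked_feasible, rng)
        bp = compute_best_parents(table, worked_feasible)
        lattice = compute_best_sinks(worked_feasible, bp)
        assert lattice.max_level() == 4
        assert count_orderings(
            {v: list(worked_feasible.reduced_pp[v]) for v in worked_feasible.nodes}
        ) == len(brute_force_generational_orderings(worked_feasible)) == 8

    def test_worked_map_level2_subsets_match_bruteforce(self, worked_feasible, rng):
        table = uniform_table(worked_feasible, rng)
        bp = compute_best_parents(table, worked_feasible)
        lattice = compute_best_sinks(worked_feasible, bp)
        level2 = {lattice.names(m) for m in lattice.masks_at_level(2)}
        assert level2 == {
            frozenset({"1", "2"}),
            frozenset({"1", "4"}),
            frozenset({"2", "3"}),
        }
        assert frozenset({"3", "4"}) not in level2

    def test_recursion_identity_at_every_subset(self, worked_feasible, rng):
        table = uniform_table(worked_feasible, rng)
        bp = compute_best_parents(table, worked_feasible)
        lattice = compute_best_sinks(worked_feasible, bp)
        nodes = lattice.nodes
        for mask, (cum, sinks) in lattice.reachable.items():
            if mask == 0:
                assert cum == 0.0
                continue
            for s in sinks:
                prev_mask = mask ^ (1 << s)
                prev = lattice.reachable[prev_mask][0]
                avail = [
                    nodes[i]
                    for i in range(len(nodes))
                    if prev_mask >> i & 1 and nodes[i] in worked_feasible.reduced_pp[nodes[s]]
                ]
                step, _ = bp.best_for(nodes[s], avail)
                assert cum == pytest.approx(prev + step, abs=1e-9)


class TestReconstruct:
    def test_deterministic_unwinding_of_a_single_path(self):
        # lattice whose successive best sinks from the full set are 3, 2, 1, 4
        feas = FeasibleSet(
            nodes=["1", "2", "3", "4"],
            reduced_pp={
                "1": ("4",),
                "2": ("1",),
                "3": ("2",),
                "4": (),
            },
        )
        scores = {
            "1": {(): -5.0, ("4",): -1.0},
            "2": {(): -5.0, ("1",): -1.0},
            "3": {(): -5.0, ("2",): -1.0},
            "4": {(): -1.0},
        }
        table = fixture_table(scores, indegree=1)
        bp = compute_best_parents(table, feas, indegree=1)
        lattice = compute_best_sinks(feas, bp)
        nets = reconstruct_networks(lattice, bp, table, feas)
        assert len(nets) == 1
        assert nets[0].ordering == ["4", "1", "2", "3"]
        assert nets[0].parent_sets == {
            "1": frozenset({"4"}),
            "2": frozenset({"1"}),
            "3": frozenset({"2"}),
            "4": frozenset(),
        }

    def test_single_node_yields_empty_network(self):
        feas = FeasibleSet(nodes=["v"], reduced_pp={"v": ()})
        table = fixture_table({"v": {(): -2.0}})
        bp = compute_best_parents(table, feas)
        lattice = compute_best_sinks(feas, bp)
        (net,) = reconstruct_networks(lattice, bp, table, feas)
        assert net.parent_sets["v"] == frozenset()
        assert net.total_score == pytest.approx(-2.0)

    def test_rescoring_matches_lattice_terminal(self, rng):
        names = ["a", "b", "c", "d"]
        for trial in range(20):
            pp = random_parent_map(names, rng)
            feas = FeasibleSet(nodes=names, reduced_pp=pp)
            table = uniform_table(feas, rng)
            bp = compute_best_parents(table, feas)
            lattice = compute_best_sinks(feas, bp)
            nets = reconstruct_networks(lattice, bp, table, feas)
            for net in nets:
                net.validate(indegree=2)
                assert network_score(net, table) == pytest.approx(
                    net.total_score, abs=1e-9
                )


class TestExhaustiveOracle:
    def test_two_nodes_unrestricted_enumerates_three_dags(self):
        feas = FeasibleSet(nodes=["a", "b"], reduced_pp={"a": ("b",), "b": ("a",)})
        allowed = {
            "a": [frozenset(), frozenset({"b"})],
            "b": [frozenset(), frozenset({"a"})],
        }
        dags = list(iter_dags(allowed, ["a", "b"]))
        assert len(dags) == 3

    def test_four_nodes_unrestricted_enumerates_543_dags(self):
        names = ["a", "b", "c", "d"]
        allowed = {
            v: [
                frozenset(c)
                for size in range(4)
                for c in itertools.combinations([u for u in names if u != v], size)
            ]
            for v in names
        }
        assert sum(1 for _ in iter_dags(allowed, names)) == 543

    def test_oracle_respects_parent_constraints(self, worked_feasible, rng):
        table = uniform_table(worked_feasible, rng)
        _, dags = exhaustive_oracle(worked_feasible, table, indegree=2)
        for dag in dags:
            for v, ps in dag.items():
                assert ps <= set(worked_feasible.reduced_pp[v])

    def test_size_guard(self, rng):
        names = [f"x{i}" for i in range(6)]
        feas = FeasibleSet(nodes=names, reduced_pp={v: () for v in names})
        with pytest.raises(SearchError):
            exhaustive_oracle(feas, fixture_table({v: {(): 0.0} for v in names}), 1)


class TestCountOrderings:
    def test_unconstrained_p4_has_24_orderings(self):
        assert count_orderings(4, "orderings") == 24

    def test_unconstrained_p3_path_structures_48(self):
        assert count_orderings(3, "path_structures") == 48

    def test_worked_map_has_8_complete_orderings(self, worked_feasible):
        pp = {v: list(worked_feasible.reduced_pp[v]) for v in worked_feasible.nodes}
        assert count_orderings(pp) == 8
        assert len(brute_force_generational_orderings(worked_feasible)) == 8

    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
    def test_path_structures_equal_factorial_times_power(self, p):
        assert count_orderings(p, "path_structures") == math.factorial(p) * 2 ** (
            p * (p - 1) // 2
        )


class TestDpOracleEquivalence:
    def test_dp_equals_restricted_oracle_on_random_instances(self, rng):
        names = ["a", "b", "c", "d"]
        for trial in range(30):
            pp = random_parent_map(names, rng)
            feas = FeasibleSet(nodes=names, reduced_pp=pp)
            x = rng.normal(size=(200, 4))
            x[:, 1] += 0.8 * x[:, 0]
            ds = make_continuous_dataset(x, names=names)
            d = int(rng.integers(1, 3))
            table = compute_local_scores(ds, feas, "bic", indegree=d)
            bp = compute_best_parents(table, feas)
            lattice = compute_best_sinks(feas, bp)
            best, dags = exhaustive_oracle(
                feas, table, d, require_complete_ordering=True
            )
            if lattice.max_level() == len(names):
                assert dags, "lattice complete but no realizable DAG found"
                dp_best = lattice.reachable[(1 << 4) - 1][0]
                assert dp_best == pytest.approx(best, abs=1e-8)
            else:
                assert not dags

    def test_lattice_reachability_monotone_in_pp(self, rng):
        names = ["a", "b", "c", "d"]
        for trial in range(10):
            pp = random_parent_map(names, rng, max_parents=2)
            feas_small = FeasibleSet(nodes=names, reduced_pp=dict(pp))
            # enlarge one node's pp
            grow = names[int(rng.integers(0, 4))]
            extra = [u for u in names if u != grow and u not in pp[grow]]
            pp_big = dict(pp)
            if extra:
                pp_big[grow] = tuple(sorted(set(pp[grow]) | {extra[0]}))
            feas_big = FeasibleSet(nodes=names, reduced_pp=pp_big)
            ds = make_continuous_dataset(rng.normal(size=(60, 4)), names=names)
            reach = {}
            for key, feas in (("small", feas_small), ("big", feas_big)):
                table = compute_local_scores(ds, feas, "bic", indegree=2)
                bp = compute_best_parents(table, feas)
                reach[key] = set(compute_best_sinks(feas, bp).reachable)
            assert reach["small"] <= reach["big"]


def test_markov_equivalence_classes_partition_dags():
    names = ["a", "b", "c"]
    allowed = {
        v: [
            frozenset(c)
            for size in range(3)
            for c in itertools.combinations([u for u in names if u != v], size)
        ]
        for v in names
    }
    dags = list(iter_dags(allowed, names))
    assert len(dags) == 25  # labeled DAGs on 3 nodes
    classes = markov_equivalence_classes(dags)
    assert sum(len(c) for c in classes) == 25
    # the fully disconnected DAG is alone in its class
    empty = [c for c in classes if any(all(not ps for ps in d.values()) for d in c)]
    assert len(empty) == 1 and len(empty[0]) == 1
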
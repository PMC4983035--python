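"""Fitch, Dollo and gains-only parsimony against exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest

from acidtrace.errors import InputError, LookupError_
from acidtrace.parsimony import (BinaryCharacterMatrix, compare_scenarios,
                                 dollo_scenario, fitch_cost, gains_only_cost)
from acidtrace.seqio import read_newick
from acidtrace.simulate import simulate_tree

from .conftest import (brute_force_dollo_losses, brute_force_fitch,
                       brute_force_gains_only, tree_edges)


def quartet():
    return read_newick("((A,B),(C,D));")


def random_states(tree, rng):
    return {lf.taxon.label: int(rng.integers(0, 2))
            for lf in tree.leaf_node_iter()}


class TestFitch:
    def test_one_change_for_clean_split(self):
        cost, labeling = fitch_cost(quartet(), {"A": 1, "B": 1, "C": 0, "D": 0})
        assert cost == 1

    def test_constant_character_zero_cost(self):
        cost, _ = fitch_cost(quartet(), {"A": 1, "B": 1, "C": 1, "D": 1})
        assert cost == 0

    def test_alternating_pattern_two_changes(self):
        cost, _ = fitch_cost(quartet(), {"A": 1, "B": 0, "C": 1, "D": 0})
        assert cost == 2

    def test_missing_leaf_state_rejected(self):
        with pytest.raises(InputError):
            fitch_cost(quartet(), {"A": 1, "B": 0, "C": 1})

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_minimum(self, trial):
        rng = np.random.default_rng(5000 + trial)
        tree = simulate_tree(int(rng.integers(4, 9)), rng)
        states = random_states(tree, rng)
        cost, labeling = fitch_cost(tree, states)
        assert cost == brute_force_fitch(tree, states)
        # the returned labeling attains the optimum
        attained = sum(
            labeling[_nid(p)] != labeling[_nid(c)] for p, c in tree_edges(tree)
        )
        assert attained == cost

    def test_polytomy_multichild_rule(self):
        tree = read_newick("((A,B,C),(D,E,F));")
        cost, _ = fitch_cost(tree, {"A": 1, "B": 1, "C": 0,
                                    "D": 0, "E": 0, "F": 0})
        assert cost == brute_force_fitch(tree, dict(
            A=1, B=1, C=0, D=0, E=0, F=0))

    def test_cost_bounded_by_minority_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = simulate_tree(8, rng)
            states = random_states(tree, rng)
            ones = sum(states.values())
            cost, _ = fitch_cost(tree, states)
            assert cost <= min(ones, len(states) - ones)


class TestDollo:
    def test_gain_above_clean_clade_no_losses(self):
        tree = quartet()
        d = dollo_scenario(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert d.loss_branches == ()
        assert d.event_count == 1
        # gain sits above the MRCA of A and B, not at the root
        mrca = tree.mrca(taxon_labels=["A", "B"])
        assert d.gain_node == mrca.label
        assert mrca is not tree.seed_node

    def test_alternating_pattern_two_losses(self):
        d = dollo_scenario(quartet(), {"A": 1, "B": 0, "C": 1, "D": 0})
        assert set(d.loss_branches) == {"B", "D"}
        assert d.event_count == 3

    def test_all_one_gain_at_root(self):
        tree = quartet()
        d = dollo_scenario(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert d.loss_branches == ()
        assert d.gain_node == tree.seed_node.label

    def test_all_zero_empty_scenario(self):
        d = dollo_scenario(quartet(), {"A": 0, "B": 0, "C": 0, "D": 0})
        assert d.gain_node is None and d.event_count == 0

    @pytest.mark.parametrize("trial", range(30))
    def test_loss_count_minimal_given_single_gain(self, trial):
        rng = np.random.default_rng(7000 + trial)
        tree = simulate_tree(int(rng.integers(4, 8)), rng)
        states = random_states(tree, rng)
        if not any(states.values()):
            states[next(iter(states))] = 1
        d = dollo_scenario(tree, states)
        gain = next(n for n in tree.preorder_node_iter()
                    if _nid(n) == d.gain_node)
        assert len(d.loss_branches) == brute_force_dollo_losses(
            tree, states, gain)


class TestGainsOnly:
    def test_clean_clade_single_gain(self):
        assert gains_only_cost(quartet(), {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_alternating_two_gains(self):
        assert gains_only_cost(quartet(), {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_all_zero_costs_nothing(self):
        assert gains_only_cost(quartet(), {"A": 0, "B": 0, "C": 0, "D": 0}) == 0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_minimum(self, trial):
        rng = np.random.default_rng(9000 + trial)
        tree = simulate_tree(int(rng.integers(4, 7)), rng)
        states = random_states(tree, rng)
        assert gains_only_cost(tree, states) == \
            brute_force_gains_only(tree, states)


class TestScenarios:
    def _matrix(self, data):
        return BinaryCharacterMatrix.from_dataframe(pd.DataFrame(data))

    def test_clean_clade_is_tie(self):
        matrix = self._matrix({"RD2": {"A": 1, "B": 1, "C": 0, "D": 0}})
        (res,) = compare_scenarios(quartet(), matrix)
        assert res.verdict == "tie"
        assert res.dollo_event_count == res.gains_only_cost == 1

    def test_all_one_is_tie(self):
        matrix = self._matrix({"HD": {"A": 1, "B": 1, "C": 1, "D": 1}})
        (res,) = compare_scenarios(quartet(), matrix)
        assert res.verdict == "tie"

    def test_scattered_character_favors_convergence(self):
        # four 1-bearing leaves in four separate clades of a 16-leaf tree
        tree = read_newick(
            "((((t1,t2),(t3,t4)),((t5,t6),(t7,t8))),"
            "(((t9,t10),(t11,t12)),((t13,t14),(t15,t16))));")
        states = {f"t{i}": 1 if i in (1, 5, 9, 13) else 0
                  for i in range(1, 17)}
        matrix = self._matrix({"Cter": states})
        (res,) = compare_scenarios(tree, matrix)
        assert res.gains_only_cost == 4
        assert res.dollo_event_count > 4
        assert res.verdict == "convergence_scenario"
        # cross-check both counts by enumeration
        assert res.gains_only_cost == brute_force_gains_only(tree, states)
        gain = next(n for n in tree.preorder_node_iter()
                    if _nid(n) == res.dollo_gain_node)
        assert res.dollo_event_count == 1 + brute_force_dollo_losses(
            tree, states, gain)

    def test_taxon_mismatch_rejected(self):
        matrix = self._matrix({"X": {"A": 1, "B": 0, "C": 0, "E": 0}})
        with pytest.raises(LookupError_):
            compare_scenarios(quartet(), matrix)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        tree = simulate_tree(8, rng)
        states = random_states(tree, rng)
        if not any(states.values()):
            states[next(iter(states))] = 1
        costs = (fitch_cost(tree, states)[0],
                 dollo_scenario(tree, states).event_count,
                 gains_only_cost(tree, states))
        # consistent permutation of leaf labels
        mapping = {f"t{i}": f"s{9 - i}" for i in range(1, 9)}
        for lf in tree.leaf_node_iter():
            lf.taxon.label = mapping[lf.taxon.label]
        relabeled_states = {mapping[t]: s for t, s in states.items()}
        assert (fitch_cost(tree, relabeled_states)[0],
                dollo_scenario(tree, relabeled_states).event_count,
                gains_only_cost(tree, relabeled_states)) == costs

    def test_event_count_dominates_fitch(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            tree = simulate_tree(7, rng)
            states = random_states(tree, rng)
            if not any(states.values()):
                continue
            cost, _ = fitch_cost(tree, states)
            assert dollo_scenario(tree, states).event_count >= cost
            assert gains_only_cost(tree, states) >= 1


def _nid(node):
    return node.taxon.label if node.is_leaf() else node.label
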
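"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive results by exhaustive enumeration and never call
the implementation code paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from acidtrace.seqio import ProteinRecord
from acidtrace.simulate import make_motif_fixtures

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def motif_records() -> dict[str, ProteinRecord]:
    return {r.id: r for r in make_motif_fixtures()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160812)


def random_protein(rng: np.random.Generator, length: int,
                   record_id: str = "r") -> ProteinRecord:
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id=record_id, residues=residues)


# ---------------------------------------------------------------------------
# acidic-window oracle: direct per-window counting


def brute_force_acidic_hits(residues: str, window: int, min_fraction: float,
                            acidic: set[str], tail_len) -> list[tuple[int, int, int]]:
    """(start, end, count) for every qualifying window, 1-based inclusive."""
    L = len(residues)
    if L < window:
        return []
    lo = 1 if tail_len == "all" else max(1, L - int(tail_len) + 1)
    out = []
    for start in range(lo, L - window + 2):
        chunk = residues[start - 1:start - 1 + window]
        count = sum(1 for c in chunk if c in acidic)
        if count / window >= min_fraction - 1e-12:
            out.append((start, start + window - 1, count))
    return out


# ---------------------------------------------------------------------------
# global-alignment oracle: enumerate every global alignment, score affine


def _enumerate_alignments(a: str, b: str):
    """Yield every global alignment (aligned_a, aligned_b) of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(aligned_a: str, aligned_b: str, matrix,
                    gap_open: float, gap_extend: float) -> float:
    """Affine score of a fixed alignment: a gap run of length k costs
    gap_open + (k - 1) * gap_extend; no column may be gap/gap."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        assert not (ca == "-" and cb == "-")
        if ca == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += float(matrix[ca, cb])
            in_gap_a = in_gap_b = False
    return score


def brute_force_best_score(a: str, b: str, matrix, gap_open: float,
                           gap_extend: float) -> float:
    return max(score_alignment(ra, rb, matrix, gap_open, gap_extend)
               for ra, rb in _enumerate_alignments(a, b))


# ---------------------------------------------------------------------------
# parsimony oracles: exhaustive over internal labelings / event sets


def tree_edges(tree):
    """(parent, child) node pairs for every edge below the root."""
    return [(n.parent_node, n) for n in tree.preorder_node_iter()
            if n.parent_node is not None]


def brute_force_fitch(tree, states: dict[str, int]) -> int:
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = {n: states[n.taxon.label] for n in tree.leaf_node_iter()}
    best = None
    for labels in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(map(id, internals), labels))
        for leaf, s in leaves.items():
            assign[id(leaf)] = s
        cost = sum(assign[id(p)] != assign[id(c)] for p, c in tree_edges(tree))
        best = cost if best is None else min(best, cost)
    return best


def leaf_states_from_events(tree, gain_edges: set[int], loss_edges: set[int]
                            ) -> dict[str, int] | None:
    """Leaf states implied by gain/loss events on edges (ids of child
    nodes); None if an event is vacuous (loss without the character, gain
    on top of it)."""
    states = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        s = 0 if parent is None else states[id(parent)]
        if id(node) in gain_edges:
            if s == 1:
                return None
            s = 1
        if id(node) in loss_edges:
            if s == 0:
                return None
            s = 0
        states[id(node)] = s
    return {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}


def brute_force_gains_only(tree, states: dict[str, int]) -> int:
    """Minimum number of gain edges (losses forbidden) reproducing the leaf
    states; 0 for the all-zero character."""
    if not any(states.values()):
        return 0
    edges = [c for _, c in tree_edges(tree)] + [tree.seed_node]
    for k in range(1, len(edges) + 1):
        for combo in itertools.combinations(edges, k):
            realized = leaf_states_from_events(tree, {id(n) for n in combo},
                                               set())
            if realized == states:
                return k
    raise AssertionError("unreachable")


def brute_force_dollo_losses(tree, states: dict[str, int], gain_node) -> int:
    """Minimum number of loss edges given a single gain above gain_node."""
    edges = [c for _, c in tree_edges(tree)]
    for k in range(0, len(edges) + 1):
        for combo in itertools.combinations(edges, k):
            realized = leaf_states_from_events(tree, {id(gain_node)},
                                               {id(n) for n in combo})
            if realized == states:
                return k
    raise AssertionError("no loss set explains the states")
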
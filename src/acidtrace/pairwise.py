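"""Global pairwise protein alignment and percent identity.

Needleman-Wunsch with affine gap penalties (Gotoh three-state recursion).
A gap of length *k* costs ``gap_open + (k - 1) * gap_extend``; terminal gaps
are penalised like any other (true global alignment). The traceback breaks
ties among co-optimal moves deterministically, preferring substitution
(diagonal) over a gap in the second sequence (up) over a gap in the first
(left), so the returned alignment is a pure function of the inputs.

Defaults (BLOSUM62, open 10, extend 0.5) are conventional protein-alignment
parameters. Percent identity is computed, by default, over columns where
both rows carry a residue; an alternative denominator (the shorter sequence
length) is available as ``denominator="shorter"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import substitution_matrices

from .errors import InputError
from .seqio import ProteinRecord

NEG_INF = float("-inf")


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap alignment parameters (penalties as positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def score(self, a: str, b: str) -> float:
        return float(load_matrix(self.matrix_name)[a, b])


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """An optimal global alignment of two sequences plus identity bookkeeping.

    ``n_scored_cols`` counts the columns entering the identity denominator
    under the chosen mode; ``identity_pct`` is
    ``100 * n_identical / n_scored_cols``.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_scored_cols: int
    identity_pct: float
    denominator: str = "ungapped"


def global_align(a: ProteinRecord, b: ProteinRecord,
                 params: AlignParams | None = None,
                 denominator: str = "ungapped") -> PairwiseAlignmentResult:
    """Optimal-score global alignment of two protein records.

    Implements the three-state affine recursion: state M (``a[i]`` paired
    with ``b[j]``), state X (``a[i]`` against a gap), state Y (``b[j]``
    against a gap). Raises :class:`InputError` on an empty sequence.
    """
    params = params or AlignParams()
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise InputError("cannot align empty sequences")
    n, m = len(sa), len(sb)
    go, ge = params.gap_open, params.gap_extend
    sub = load_matrix(params.matrix_name)

    # score[i][j] per state; row-major lists of floats
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b ("up")
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a ("left")
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ca = sa[i - 1]
        row_scores = sub[ca]
        for j in range(1, m + 1):
            s = float(row_scores[sb[j - 1]])
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge)

    # deterministic preference among end states: M > X > Y
    end_scores = (M[n][m], X[n][m], Y[n][m])
    best = max(end_scores)
    state = "MXY"[end_scores.index(best)]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = float(sub[sa[i - 1], sb[j - 1]])
            target = M[i][j] - s
            # predecessor preference: diagonal-M, then X (up), then Y (left)
            for prev, val in (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]),
                              ("Y", Y[i - 1][j - 1])):
                if abs(val - target) < eps:
                    state = prev
                    break
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif state == "X":
            if i == 0:  # pragma: no cover - unreachable by construction
                raise AssertionError("traceback fell off matrix in state X")
            target = X[i][j]
            if j == 0:
                # leading gap column: stay in X until i exhausted
                state = "X" if i > 1 else "M"
            else:
                for prev, val in (("M", M[i - 1][j] - go), ("X", X[i - 1][j] - ge),
                                  ("Y", Y[i - 1][j] - go)):
                    if abs(val - target) < eps:
                        state = prev
                        break
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:  # state Y
            target = Y[i][j]
            if i == 0:
                state = "Y" if j > 1 else "M"
            else:
                for prev, val in (("M", M[i][j - 1] - go), ("X", X[i][j - 1] - go),
                                  ("Y", Y[i][j - 1] - ge)):
                    if abs(val - target) < eps:
                        state = prev
                        break
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    n_identical, n_scored = _identity_counts(aligned_a, aligned_b, denominator,
                                             len(sa), len(sb))
    identity = 100.0 * n_identical / n_scored if n_scored else float("nan")
    return PairwiseAlignmentResult(
        id_a=a.id, id_b=b.id, aligned_a=aligned_a, aligned_b=aligned_b,
        score=best, n_identical=n_identical, n_scored_cols=n_scored,
        identity_pct=identity, denominator=denominator,
    )


def _identity_counts(aligned_a: str, aligned_b: str, denominator: str,
                     len_a: int, len_b: int) -> tuple[int, int]:
    if denominator not in ("ungapped", "shorter"):
        raise InputError(f"unknown identity denominator {denominator!r}")
    n_identical = 0
    n_mutual = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            n_mutual += 1
            if ca == cb:
                n_identical += 1
    n_scored = n_mutual if denominator == "ungapped" else min(len_a, len_b)
    return n_identical, n_scored


def percent_identity(result: PairwiseAlignmentResult) -> float:
    """Percent identity of an alignment result.

    Raises :class:`InputError` when no column enters the denominator
    (identity undefined).
    """
    if result.n_scored_cols == 0:
        raise InputError(
            f"identity undefined for {result.id_a} vs {result.id_b}: "
            f"no scored columns"
        )
    return 100.0 * result.n_identical / result.n_scored_cols
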
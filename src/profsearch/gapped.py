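"""Profile Smith-Waterman-Gotoh local alignment with affine gaps.

Match scores come from the query PSSM (``Q[i, s_j]``); a gap of length L
costs ``gap_open + (L - 1) * gap_extend`` (opening a length-1 gap costs
``gap_open``).  Alignment is local on both axes with the usual three-state
recurrence (H: match/mismatch, E: gap in the query axis, F: gap in the
target axis), accumulated in 64-bit registers so long profiles cannot
overflow.

Two evaluation orders are provided: the row-major reference
(:func:`gotoh_score`) and a wavefront order along minor anti-diagonals
(:func:`gotoh_score_wavefront`), which honours the same left/up/diagonal
dependencies and must produce identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .profiles import PSSM
from .seqio import EncodedSequence

_NEG = -(1 << 40)


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap costs: a length-L gap costs ``open + (L - 1) * extend``."""

    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    def cost(self, length: int) -> int:
        return 0 if length == 0 else self.gap_open + (length - 1) * self.gap_extend


@njit(cache=True)
def _gotoh_score_kernel(Q, s, go, ge):
    m = Q.shape[0]
    n = s.size
    Hprev = np.zeros(n + 1, dtype=np.int64)
    Hcur = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, _NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        Hcur[0] = 0
        e = _NEG
        for j in range(1, n + 1):
            f = max(Hprev[j] - go, F[j] - ge)
            F[j] = f
            e = max(Hcur[j - 1] - go, e - ge)
            h = Hprev[j - 1] + Q[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


def gotoh_score(pssm: PSSM, target: EncodedSequence, penalties: GapPenalties) -> int:
    """Optimal local alignment score, computed row by row."""
    if len(target) == 0:
        raise ValueError("target must be non-empty")
    return int(
        _gotoh_score_kernel(
            pssm.scores, target.codes, penalties.gap_open, penalties.gap_extend
        )
    )


@njit(cache=True)
def _gotoh_wavefront_kernel(Q, s, go, ge):
    m = Q.shape[0]
    n = s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    best = 0
    for d in range(2, m + n + 1):  # minor anti-diagonals i + j = d
        i_lo = max(1, d - n)
        i_hi = min(m, d - 1)
        for i in range(i_lo, i_hi + 1):
            j = d - i
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + Q[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def gotoh_score_wavefront(
    pssm: PSSM, target: EncodedSequence, penalties: GapPenalties
) -> int:
    """Same score as :func:`gotoh_score`, evaluated along anti-diagonals."""
    if len(target) == 0:
        raise ValueError("target must be non-empty")
    return int(
        _gotoh_wavefront_kernel(
            pssm.scores, target.codes, penalties.gap_open, penalties.gap_extend
        )
    )


@njit(cache=True)
def _gotoh_matrices(Q, s, go, ge):
    m = Q.shape[0]
    n = s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + Q[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


#: trace operations: "M" consumes (query, target), "D" consumes query only
#: (gap in target, vertical), "I" consumes target only (gap in query,
#: horizontal).
@dataclass
class GappedAlignment:
    score: int
    query_interval: tuple[int, int]   # 0-based half-open
    target_interval: tuple[int, int]
    ops: list[tuple[str, int, int]]   # (op, query_index, target_index)
    matches: int
    mismatches: int
    gap_openings: int

    @property
    def alignment_length(self) -> int:
        return len(self.ops)

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(qi, tj) for op, qi, tj in self.ops if op == "M"]

    @property
    def identity_fraction(self) -> float:
        return self.matches / len(self.ops) if self.ops else 0.0


def gotoh_align(
    pssm: PSSM, target: EncodedSequence, penalties: GapPenalties
) -> GappedAlignment:
    """Score plus traceback; ties broken diagonal > up > left, determinism
    guaranteed by starting at the first (row-major) maximal cell."""
    if len(target) == 0:
        raise ValueError("target must be non-empty")
    Q, s = pssm.scores, target.codes
    go, ge = penalties.gap_open, penalties.gap_extend
    H, E, F = _gotoh_matrices(Q, s, go, ge)
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    ops: list[tuple[str, int, int]] = []
    matches = mismatches = gap_openings = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + Q[i - 1, s[j - 1]]:
                ops.append(("M", i - 1, j - 1))
                if pssm.query_codes[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
                gap_openings += 1
            elif H[i, j] == E[i, j]:
                state = "E"
                gap_openings += 1
            else:  # pragma: no cover - recurrence guarantees a branch
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # vertical run: gap in target
            ops.append(("D", i - 1, j - 1))
            opened = F[i, j] == H[i - 1, j] - go
            i -= 1
            if opened:
                state = "H"
        else:  # "E", horizontal run: gap in query
            ops.append(("I", i - 1, j - 1))
            opened = E[i, j] == H[i, j - 1] - go
            j -= 1
            if opened:
                state = "H"
    ops.reverse()
    if ops:
        q0 = min(qi for op, qi, _ in ops if op != "I")
        q1 = max(qi for op, qi, _ in ops if op != "I") + 1
        t0 = min(tj for op, _, tj in ops if op != "D")
        t1 = max(tj for op, _, tj in ops if op != "D") + 1
    else:
        q0 = q1 = t0 = t1 = 0
    return GappedAlignment(
        score=score,
        query_interval=(q0, q1),
        target_interval=(t0, t1),
        ops=ops,
        matches=matches,
        mismatches=mismatches,
        gap_openings=gap_openings,
    )


def rescore_alignment(
    pssm: PSSM,
    target: EncodedSequence,
    alignment: GappedAlignment,
    penalties: GapPenalties,
) -> int:
    """Recompute the score implied by a trace (consistency check)."""
    total = 0
    run_op = None
    run_len = 0
    for op, qi, tj in alignment.ops:
        if op == "M":
            total -= penalties.cost(run_len)
            run_op, run_len = None, 0
            total += int(pssm.scores[qi, target.codes[tj]])
        elif op == run_op:
            run_len += 1
        else:
            total -= penalties.cost(run_len)
            run_op, run_len = op, 1
    total -= penalties.cost(run_len)
    return total
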
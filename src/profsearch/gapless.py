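"""The gapless local-alignment filter.

The filter scores a target sequence ``S = (s_1 .. s_n)`` against a query
profile ``Q`` (m x 21) by the single-diagonal recurrence

    M[i, j] = max(M[i-1, j-1] + Q[i, s_j], 0),   M[i, 0] = M[0, j] = 0,

returning the maximum cell of ``M`` -- the best contiguous-diagonal segment
score.  Because each cell depends only on its diagonal neighbour, whole rows
can be computed in parallel, which is what the batched kernel exploits.

Four evaluation strategies are provided and are score-identical (modulo the
stated 8-bit clamping of the saturating variant):

* :func:`gapless_score_oracle` -- literal cell-by-cell reference loop;
* :func:`gapless_score_batch` -- row-parallel over many targets at once;
* :func:`gapless_score_saturating` -- clamp-after-add at 255 per cell;
* :func:`gapless_score_tiled` / :func:`gapless_score_permuted` -- the
  tiled long-query and packed-column-pair layouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .profiles import PSSM, PermutedPSSM
from .seqio import EncodedSequence, PackedDB

SATURATION_LIMIT = 255


@dataclass
class GaplessScore:
    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("gapless scores are non-negative")

    def __int__(self) -> int:
        return self.value

    def __eq__(self, other) -> bool:
        return self.value == int(other)


@njit(cache=True)
def _oracle_kernel(Q, s):
    m = Q.shape[0]
    n = s.size
    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.zeros(n + 1, dtype=np.int64)
    best = 0
    for i in range(m):
        cur[0] = 0
        for j in range(1, n + 1):
            v = prev[j - 1] + Q[i, s[j - 1]]
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev, cur = cur, prev
    return best


def gapless_score_oracle(pssm: PSSM, target: EncodedSequence) -> GaplessScore:
    """Reference implementation: the recurrence evaluated cell by cell."""
    if len(target) == 0:
        return GaplessScore(0)
    return GaplessScore(int(_oracle_kernel(pssm.scores, target.codes)))


def _row_sweep(Q, codes, valid=None, saturate=False, carry=None):
    """Row-parallel sweep over query rows for a (T, L) batch of targets.

    ``codes``: (T, L) residue codes, padded arbitrarily where ``valid`` is
    False; padded cells are masked to 0 so they never contribute.  ``carry``
    seeds the incoming boundary row (tiled evaluation); returns the per-target
    best plus the final boundary row.
    """
    T, L = codes.shape
    prev = np.zeros((T, L + 1), dtype=np.int64)
    if carry is not None:
        prev[:] = carry
    cur = np.zeros_like(prev)
    best = np.zeros(T, dtype=np.int64)
    for i in range(Q.shape[0]):
        np.maximum(prev[:, :-1] + Q[i][codes], 0, out=cur[:, 1:])
        cur[:, 0] = 0
        if saturate:
            np.minimum(cur, SATURATION_LIMIT, out=cur)
        if valid is not None:
            cur[:, 1:] *= valid
        np.maximum(best, cur.max(axis=1), out=best)
        prev, cur = cur, prev
    return best, prev


def gapless_score_batch(
    pssm: PSSM,
    db: PackedDB,
    mode: str = "full",
    order: str = "record",
    max_batch: int = 512,
) -> np.ndarray:
    """Score every database sequence; row-parallel over same-length batches.

    Targets are processed in contiguous slices of the ascending-length-sorted
    packed order, padded to the slice maximum with masked cells.  ``order``
    selects whether the returned vector follows the original record order
    (default) or the packed order; the evaluation order never changes any
    score.
    """
    if mode not in ("full", "saturating"):
        raise ValueError(f"unknown mode {mode!r}")
    if order not in ("record", "packed"):
        raise ValueError(f"unknown order {order!r}")
    if db.n_sequences == 0:
        raise ValueError("empty database")
    saturate = mode == "saturating"
    lengths = db.lengths
    packed_scores = np.zeros(db.n_sequences, dtype=np.int64)
    for lo in range(0, db.n_sequences, max_batch):
        hi = min(lo + max_batch, db.n_sequences)
        L = int(lengths[lo:hi].max())
        codes = np.zeros((hi - lo, L), dtype=np.uint8)
        valid = np.zeros((hi - lo, L), dtype=np.int64)
        for t in range(lo, hi):
            a, b = db.offsets[t], db.offsets[t + 1]
            codes[t - lo, : b - a] = db.residue_block[a:b]
            valid[t - lo, : b - a] = 1
        best, _ = _row_sweep(pssm.scores, codes, valid=valid, saturate=saturate)
        packed_scores[lo:hi] = best
    if order == "packed":
        return packed_scores
    record_scores = np.zeros_like(packed_scores)
    record_scores[db.order_map] = packed_scores
    return record_scores


def gapless_score_saturating(pssm: PSSM, target: EncodedSequence) -> GaplessScore:
    """8-bit semantics: every cell clamps to 255 after the add.

    Saturation is absorbing, so the result equals ``min(255, oracle)``; a
    returned 255 marks a strong potential match.
    """
    if len(target) == 0:
        return GaplessScore(0)
    best, _ = _row_sweep(pssm.scores, target.codes[None, :], saturate=True)
    return GaplessScore(int(best[0]))


@dataclass
class TileCarry:
    """Boundary row handed from one query tile to the next.

    ``boundary[j]`` is the cell value at the tile's last query position for
    target prefix length ``j``; the first tile starts from all zeros.
    """

    boundary: np.ndarray

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=np.int64)
        if self.boundary.size and self.boundary.min() < 0:
            raise ValueError("carry values are non-negative")


def gapless_score_tiled(
    pssm: PSSM, target: EncodedSequence, tile_width: int = 2048
) -> GaplessScore:
    """Process the query in consecutive tiles of ``tile_width`` positions.

    Each tile seeds from the previous tile's :class:`TileCarry`; the result
    is identical to the untiled oracle for every tile width.
    """
    if tile_width < 1:
        raise ValueError("tile_width must be >= 1")
    n = len(target)
    if n == 0:
        return GaplessScore(0)
    codes = target.codes[None, :]
    carry = TileCarry(np.zeros(n + 1, dtype=np.int64))
    best = 0
    for t0 in range(0, pssm.query_length, tile_width):
        tile = pssm.scores[t0:t0 + tile_width]
        tile_best, boundary = _row_sweep(tile, codes, carry=carry.boundary)
        best = max(best, int(tile_best[0]))
        carry = TileCarry(boundary[0])
    return GaplessScore(best)


def gapless_score_permuted(
    ppssm: PermutedPSSM, target: EncodedSequence
) -> GaplessScore:
    """Evaluate through the packed-column-pair layout.

    The permutation pairs columns ``(j, j + c/2)`` inside each
    ``c``-column block so that, walking target residues, every permuted slot
    depends only on a fixed predecessor slot from the previous step -- the
    property that lets two packed lanes update independently.  For full
    blocks that predecessor is uniformly ``slot - 2`` (the neighbouring
    packed word), with the two block-boundary slots patched.
    """
    if len(target) == 0:
        return GaplessScore(0)
    perm = ppssm.permutation
    m = perm.size
    inverse = np.empty(m, dtype=np.int64)
    inverse[perm] = np.arange(m)
    # predecessor slot of the slot holding original column i is the slot
    # holding column i - 1; column 0 has no predecessor (boundary zero).
    has_pred = perm > 0
    pred_slot = np.zeros(m, dtype=np.int64)
    pred_slot[has_pred] = inverse[perm[has_pred] - 1]
    Qp = ppssm.scores  # (m, 21) in permuted slot order
    prev = np.zeros(m, dtype=np.int64)
    cur = np.empty(m, dtype=np.int64)
    best = 0
    for code in target.codes:
        np.maximum(np.where(has_pred, prev[pred_slot], 0) + Qp[:, code], 0, out=cur)
        row_best = int(cur.max())
        if row_best > best:
            best = row_best
        prev, cur = cur, prev
    return GaplessScore(best)
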
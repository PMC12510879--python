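"""The two-stage search workflow.

Stage 1 scores every database sequence with the gapless filter (8-bit
saturating semantics by default).  Candidates at or above the filter
threshold are ranked by (score descending, packed index ascending) and
truncated to ``max_seqs``; saturated scores of 255 mark strong potential
matches and are always admitted.  Stage 2 computes a full Smith-Waterman-
Gotoh alignment and an E-value for each candidate; hits within the E-value
cutoff are reported sorted by ascending E-value.

Streaming (contiguous database batches), partitioning (split, search, merge)
and iterative profile search are thin orchestration layers over the same
two stages and are result-invariant: they return bit-identical hit lists to
the plain search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gapless import SATURATION_LIMIT, gapless_score_batch
from .gapped import GapPenalties, GappedAlignment, gotoh_align
from .profiles import (
    PSSM,
    SubstitutionMatrix,
    load_substitution_matrix,
    pssm_from_hits,
    pssm_from_sequence,
)
from .seqio import (
    ALPHABET_SIZE,
    X_INDEX,
    EncodedSequence,
    PackedDB,
    SequenceRecord,
    encode_sequence,
)

logger = logging.getLogger("profsearch")

#: Karlin-Altschul-style parameters for gapped BLOSUM62 with open 11 / extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class SearchParams:
    filter_threshold: int = 15
    max_seqs: int = 4000
    evalue_cutoff: float = 10_000.0
    penalties: GapPenalties = field(default_factory=GapPenalties)
    tile_width: int = 2048
    batch_residues: int | None = None
    n_partitions: int = 1
    mask: bool = False
    mask_window: int = 12
    mask_entropy_threshold: float = 2.0
    iterations: int = 1
    profile_inclusion_evalue: float = 1e-3
    pseudocount_weight: float = 0.3
    filter_mode: str = "saturating"   # or "full"
    evalue_lambda: float = DEFAULT_LAMBDA
    evalue_k: float = DEFAULT_K
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.max_seqs < 1:
            raise ValueError("max_seqs must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SearchHit:
    target_id: str
    gapless_score: int
    gapped: GappedAlignment
    evalue: float
    bit_score: float
    packed_index: int = -1


def mask_low_complexity(
    seq: EncodedSequence, window: int = 12, entropy_threshold: float = 2.0
) -> EncodedSequence:
    """Replace residues in low-entropy neighbourhoods by X.

    For each position the Shannon entropy (bits) of the residue composition
    of the length-``window`` window centred there (truncated at the ends) is
    computed; positions below ``entropy_threshold`` become X.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = np.asarray(seq.codes)
    n = codes.size
    if n == 0:
        return seq
    onehot = np.zeros((n + 1, ALPHABET_SIZE), dtype=np.int64)
    np.add.at(onehot[1:], (np.arange(n), codes), 1)
    cum = np.cumsum(onehot, axis=0)
    lo = np.maximum(np.arange(n) - window // 2, 0)
    hi = np.minimum(lo + window, n)
    lo = np.minimum(lo, hi - window).clip(0)
    counts = cum[hi] - cum[lo]
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    out = codes.copy()
    out[ent < entropy_threshold] = X_INDEX
    return EncodedSequence(codes=out, id=seq.id)


def compute_evalue(
    score: int,
    query_length: int,
    db_total_residues: int,
    lam: float = DEFAULT_LAMBDA,
    k_param: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul-shaped expectation: ``E = K * m * N * exp(-lambda * S)``."""
    if lam <= 0 or k_param <= 0:
        raise ValueError("lambda and K must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    return k_param * query_length * db_total_residues * math.exp(-lam * score)


def bit_score(score: int, lam: float = DEFAULT_LAMBDA, k_param: float = DEFAULT_K) -> float:
    return (lam * score - math.log(k_param)) / math.log(2.0)


def _resolve_pssm(query, params: SearchParams, matrix: SubstitutionMatrix | None) -> PSSM:
    if isinstance(query, PSSM):
        return query
    if matrix is None:
        matrix = load_substitution_matrix(params.matrix_name)
    if isinstance(query, SequenceRecord):
        query = encode_sequence(query)
    if params.mask:
        query = mask_low_complexity(
            query, params.mask_window, params.mask_entropy_threshold
        )
    return pssm_from_sequence(query, matrix)


def _select_candidates(
    scores_packed: np.ndarray, params: SearchParams, index_offset: int = 0
) -> np.ndarray:
    """Rank by (score desc, packed index asc); truncate to max_seqs but always
    admit saturated scores."""
    idx = np.nonzero(scores_packed >= params.filter_threshold)[0]
    order = idx[np.lexsort((idx, -scores_packed[idx]))]
    if order.size > params.max_seqs:
        keep = scores_packed[order] >= SATURATION_LIMIT
        keep[: params.max_seqs] = True
        order = order[keep]
    return order + index_offset


def _stage2(
    pssm: PSSM,
    db: PackedDB,
    candidates: np.ndarray,
    params: SearchParams,
    db_total_residues: int,
    scores_packed: np.ndarray,
) -> list[SearchHit]:
    hits: list[SearchHit] = []
    for t in candidates:
        target = db.sequence(int(t))
        aln = gotoh_align(pssm, target, params.penalties)
        ev = compute_evalue(
            aln.score,
            pssm.query_length,
            db_total_residues,
            params.evalue_lambda,
            params.evalue_k,
        )
        if ev <= params.evalue_cutoff:
            hits.append(
                SearchHit(
                    target_id=target.id,
                    gapless_score=int(scores_packed[int(t)]),
                    gapped=aln,
                    evalue=ev,
                    bit_score=bit_score(aln.score, params.evalue_lambda, params.evalue_k),
                    packed_index=int(t),
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def two_stage_search(
    query,
    db: PackedDB,
    params: SearchParams | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> list[SearchHit]:
    """Gapless-filter every database sequence, then Gotoh-align the survivors."""
    params = params or SearchParams()
    if db.n_sequences == 0:
        raise ValueError("empty database")
    pssm = _resolve_pssm(query, params, matrix)
    scores = gapless_score_batch(pssm, db, mode=params.filter_mode, order="packed")
    candidates = _select_candidates(scores, params)
    logger.info(
        "stage 1: %d/%d sequences passed the gapless filter (threshold %d)",
        candidates.size, db.n_sequences, params.filter_threshold,
    )
    hits = _stage2(pssm, db, candidates, params, db.total_residues, scores)
    logger.info("stage 2: %d hits within E-value cutoff %g", len(hits), params.evalue_cutoff)
    return hits


def search_streamed(
    query,
    db: PackedDB,
    params: SearchParams | None = None,
    batch_residues: int | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> list[SearchHit]:
    """Stream the filter over contiguous packed-database batches.

    Each batch holds whole sequences totalling at most ``batch_residues``
    residues; results are bit-identical to the unbatched search.
    """
    params = params or SearchParams()
    batch_residues = batch_residues or params.batch_residues
    if batch_residues is None:
        return two_stage_search(query, db, params, matrix)
    longest = int(db.lengths.max())
    if batch_residues < longest:
        raise ValueError(
            f"batch_residues ({batch_residues}) smaller than the longest "
            f"database sequence ({longest})"
        )
    pssm = _resolve_pssm(query, params, matrix)
    scores = np.zeros(db.n_sequences, dtype=np.int64)
    lo = 0
    n_batches = 0
    while lo < db.n_sequences:
        hi = lo
        total = 0
        while hi < db.n_sequences and total + int(db.lengths[hi]) <= batch_residues:
            total += int(db.lengths[hi])
            hi += 1
        chunk = db.subset(lo, hi)
        scores[lo:hi] = gapless_score_batch(
            pssm, chunk, mode=params.filter_mode, order="packed"
        )
        lo = hi
        n_batches += 1
    logger.info("streamed stage 1 over %d batches", n_batches)
    candidates = _select_candidates(scores, params)
    return _stage2(pssm, db, candidates, params, db.total_residues, scores)


def search_partitioned(
    query,
    db: PackedDB,
    params: SearchParams | None = None,
    n_partitions: int | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> list[SearchHit]:
    """Split the database into contiguous chunks, search each independently
    with the per-partition candidate cap, then merge, re-rank globally and
    truncate -- the merged hit list is identical to the unsplit search."""
    params = params or SearchParams()
    n = n_partitions if n_partitions is not None else params.n_partitions
    if not 1 <= n <= db.n_sequences:
        raise ValueError("n_partitions must be between 1 and the database size")
    pssm = _resolve_pssm(query, params, matrix)
    bounds = np.linspace(0, db.n_sequences, n + 1, dtype=np.int64)
    scores = np.zeros(db.n_sequences, dtype=np.int64)
    per_partition: list[np.ndarray] = []
    for p in range(n):
        lo, hi = int(bounds[p]), int(bounds[p + 1])
        chunk = db.subset(lo, hi)
        chunk_scores = gapless_score_batch(
            pssm, chunk, mode=params.filter_mode, order="packed"
        )
        scores[lo:hi] = chunk_scores
        per_partition.append(_select_candidates(chunk_scores, params, index_offset=lo))
    merged = np.concatenate(per_partition) if per_partition else np.empty(0, np.int64)
    # global re-rank over the union of per-partition candidates
    order = merged[np.lexsort((merged, -scores[merged]))]
    if order.size > params.max_seqs:
        keep = scores[order] >= SATURATION_LIMIT
        keep[: params.max_seqs] = True
        order = order[keep]
    return _stage2(pssm, db, order, params, db.total_residues, scores)


def hit_observations(hit: SearchHit, db: PackedDB):
    """Column observations (query_column, residue_code) for profile building."""
    target = db.sequence(hit.packed_index)
    return [(qi, int(target.codes[tj])) for qi, tj in hit.gapped.aligned_pairs]


def iterative_search(
    query: SequenceRecord | EncodedSequence,
    db: PackedDB,
    params: SearchParams | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[list[list[SearchHit]], PSSM]:
    """Iterative profile search: hits from one round become the next round's
    PSSM.

    Round 1 searches with the single-sequence profile; each later round
    rebuilds the profile from the previous round's hits with E-value at or
    below ``profile_inclusion_evalue`` (the query's self-alignment is always
    included) and searches again.  Returns the per-round hit lists and the
    profile used in the final round.
    """
    params = params or SearchParams()
    if matrix is None:
        matrix = load_substitution_matrix(params.matrix_name)
    encoded = encode_sequence(query) if isinstance(query, SequenceRecord) else query
    pssm = _resolve_pssm(encoded, params, matrix)
    rounds: list[list[SearchHit]] = []
    for r in range(params.iterations):
        hits = two_stage_search(pssm, db, params, matrix)
        rounds.append(hits)
        if r + 1 == params.iterations:
            break
        accepted = [h for h in hits if h.evalue <= params.profile_inclusion_evalue]
        logger.info("round %d: %d hits accepted into the profile", r + 1, len(accepted))
        observations = [
            [(i, int(c)) for i, c in enumerate(encoded.codes)]  # query self-hit
        ] + [hit_observations(h, db) for h in accepted]
        pssm = pssm_from_hits(
            encoded, observations, matrix, pseudocount_weight=params.pseudocount_weight
        )
    return rounds, pssm
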
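"""Query profiles: substitution matrices, PSSMs and the packed-column layout.

A PSSM ``Q`` is an ``m x 21`` integer grid giving the score for placing any
alphabet letter at any of the ``m`` query positions.  Both alignment stages
consume the same grid, so a profile built once serves the gapless filter and
the gapped aligner alike.

Profile construction from search hits follows the conventional log-odds
recipe: observed residue frequencies per query column, mixed with
substitution-matrix-derived pseudocount frequencies, converted to half-bit
log-odds against background frequencies and rounded to integers.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import ALPHABET, ALPHABET_SIZE, X_INDEX, EncodedSequence, encode_sequence

#: Robinson & Robinson amino-acid background frequencies, in alphabet order.
_RR = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}
BACKGROUND_FREQUENCIES = np.array([_RR[a] for a in ALPHABET])
BACKGROUND_FREQUENCIES /= BACKGROUND_FREQUENCIES.sum()

#: Integer score range of profile cells; matches byte-oriented kernels.
SCORE_MIN, SCORE_MAX = -128, 127

_DEFAULT_X_SCORE = -1  # used when a matrix file does not define X


@dataclass
class SubstitutionMatrix:
    """A 21 x 21 integer substitution score grid over the internal alphabet."""

    scores: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError("substitution matrix must be 21 x 21")
        canon = self.scores[:20, :20]
        if not np.array_equal(canon, canon.T):
            raise ValueError("canonical 20 x 20 block must be symmetric")

    def score(self, a: int | str, b: int | str) -> int:
        ia = _letter_index(a) if isinstance(a, str) else a
        ib = _letter_index(b) if isinstance(b, str) else b
        return int(self.scores[ia, ib])


def _letter_index(letter: str) -> int:
    i = ALPHABET.find(letter.upper())
    return i if i >= 0 else X_INDEX


def load_substitution_matrix(source: str | Path) -> SubstitutionMatrix:
    """Load a bundled matrix by name (e.g. ``"BLOSUM62"``) or an NCBI text file.

    The file format is the standard NCBI one: a header line of column
    letters, then one row per letter.  Letters outside the internal alphabet
    (B, Z, ``*``, ...) are ignored; an absent X row/column defaults to -1.
    """
    path = Path(source)
    if not path.exists():
        bundled = importlib.resources.files("profsearch").joinpath(f"data/{source}")
        if not bundled.is_file():
            raise ValueError(f"unknown substitution matrix: {source!r}")
        text = bundled.read_text()
        name = str(source)
    else:
        text = path.read_text()
        name = path.stem
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("matrix file contains no data lines")
    header = lines[0].split()
    grid = np.full((ALPHABET_SIZE, ALPHABET_SIZE), _DEFAULT_X_SCORE, dtype=np.int64)
    seen_rows: set[int] = set()
    for ln in lines[1:]:
        fields = ln.split()
        row_letter, values = fields[0], fields[1:]
        if len(values) != len(header):
            raise ValueError(f"matrix row {row_letter!r} has {len(values)} values, "
                             f"expected {len(header)}")
        ri = _row_index(row_letter)
        if ri is None:
            continue
        seen_rows.add(ri)
        for col_letter, v in zip(header, values):
            ci = _row_index(col_letter)
            if ci is not None:
                grid[ri, ci] = int(v)
    missing = set(range(20)) - seen_rows
    if missing:
        letters = "".join(sorted(ALPHABET[i] for i in missing))
        raise ValueError(f"matrix file missing canonical rows: {letters}")
    return SubstitutionMatrix(scores=grid, name=name)


def _row_index(letter: str) -> int | None:
    if letter.upper() == "X":
        return X_INDEX
    i = ALPHABET.find(letter.upper())
    return i if i >= 0 else None


@dataclass
class PSSM:
    """Position-specific scoring matrix: ``scores[i, a]`` for query position i."""

    scores: np.ndarray
    query_codes: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        self.query_codes = np.asarray(self.query_codes, dtype=np.uint8)
        m = self.query_codes.size
        if self.scores.shape != (m, ALPHABET_SIZE):
            raise ValueError(f"PSSM grid must be {m} x {ALPHABET_SIZE}")

    @property
    def query_length(self) -> int:
        return int(self.query_codes.size)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\tres\t" + "\t".join(ALPHABET + "X") + "\n")
            letters = ALPHABET + "X"
            for i in range(self.query_length):
                row = "\t".join(str(int(v)) for v in self.scores[i])
                fh.write(f"{i}\t{letters[self.query_codes[i]]}\t{row}\n")


def pssm_from_sequence(
    query: EncodedSequence | str, matrix: SubstitutionMatrix
) -> PSSM:
    """Single-sequence profile: row i is the matrix row of query residue i."""
    if isinstance(query, str):
        query = encode_sequence(query)
    if len(query) == 0:
        raise ValueError("query must be non-empty")
    return PSSM(scores=matrix.scores[query.codes].copy(), query_codes=query.codes)


#: One hit's evidence for the profile: (query_column, observed_residue_code).
ColumnObservations = Sequence[tuple[int, int]]

_HALF_BIT = 2.0 / math.log(2.0)  # log-odds scale: scores in half-bits
_FREQ_FLOOR = 1e-9

#: Pseudocount strength: with N observations in a column the prior receives
#: weight at least beta / (N - 1 + beta), so sparse columns stay close to
#: the substitution matrix and only well-observed columns earn sharp scores.
PSEUDOCOUNT_BETA = 10.0


def pssm_from_hits(
    query: EncodedSequence,
    hit_observations: Sequence[ColumnObservations],
    matrix: SubstitutionMatrix,
    pseudocount_weight: float = 0.3,
    background: np.ndarray = BACKGROUND_FREQUENCIES,
) -> PSSM:
    """Build a profile from aligned hits, PSI-BLAST style.

    Per query column, observed residue frequencies (hits uniformly weighted)
    are mixed with matrix-implied pseudocount frequencies:
    ``f' = (1 - w_c) * f_obs + w_c * f_prior`` with
    ``f_prior(a | q_i) = p_a * 2^(S(q_i, a) / 2)``, the half-bit
    back-transform of the substitution scores.  The per-column prior weight
    is ``w_c = max(pseudocount_weight, beta / (N_c - 1 + beta))`` where
    ``N_c`` counts the observations in that column and ``beta`` is
    :data:`PSEUDOCOUNT_BETA`: columns with few observations stay near the
    substitution matrix instead of overfitting a handful of residues.
    Scores are half-bit log-odds of ``f'`` against the background, rounded
    half-away-from-zero.  Columns no hit covers fall back to the prior, so
    zero hits reproduce :func:`pssm_from_sequence` exactly, as does
    ``pseudocount_weight = 1``.
    """
    if not 0.0 <= pseudocount_weight <= 1.0:
        raise ValueError("pseudocount_weight must be in [0, 1]")
    base = pssm_from_sequence(query, matrix)
    if not hit_observations:
        return base
    m = base.query_length
    counts = np.zeros((m, 20))
    n_obs = np.zeros(m)
    weight = 1.0 / len(hit_observations)
    for obs in hit_observations:
        for col, code in obs:
            if not 0 <= col < m:
                raise ValueError(f"alignment column {col} outside query of length {m}")
            if code < 20:  # X carries no frequency evidence
                counts[col, code] += weight
                n_obs[col] += 1
    p = background[:20]
    f_prior = p[None, :] * np.exp2(base.scores[:, :20] / 2.0)
    covered = counts.sum(axis=1) > 0
    f_obs = np.zeros_like(counts)
    f_obs[covered] = counts[covered] / counts[covered].sum(axis=1, keepdims=True)
    beta = PSEUDOCOUNT_BETA
    w = np.maximum(
        pseudocount_weight,
        beta / (np.maximum(n_obs, 1.0) - 1.0 + beta),
    )[:, None]
    f_mix = np.where(covered[:, None], (1.0 - w) * f_obs + w * f_prior, f_prior)
    log_odds = _HALF_BIT * np.log(np.maximum(f_mix, _FREQ_FLOOR) / p[None, :])
    scores = np.copysign(np.floor(np.abs(log_odds) + 0.5), log_odds).astype(np.int64)
    grid = np.empty((m, ALPHABET_SIZE), dtype=np.int64)
    grid[:, :20] = np.clip(scores, SCORE_MIN, SCORE_MAX)
    grid[:, X_INDEX] = base.scores[:, X_INDEX]  # X scored from the matrix
    return PSSM(scores=grid, query_codes=base.query_codes)


@dataclass
class PermutedPSSM:
    """A PSSM with columns reordered for packed two-lane evaluation.

    Within each block of ``columns_per_thread`` consecutive query columns,
    column ``j`` is paired with column ``j + c/2`` so that diagonally
    adjacent cells sit in the same packed word: for c = 32 the packed pairs
    are (0, 16), (1, 17), (2, 18), ...  ``permutation[slot]`` is the original
    column stored at a permuted slot; it is a bijection on ``[0, m)`` (pad
    slots of a trailing partial block are simply dropped).
    """

    base: PSSM
    columns_per_thread: int
    permutation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = self.columns_per_thread
        if c <= 0 or c % 2:
            raise ValueError("columns_per_thread must be a positive even integer")
        m = self.base.query_length
        half = c // 2
        order: list[int] = []
        for block_start in range(0, m, c):
            for k in range(half):
                for col in (block_start + k, block_start + k + half):
                    if col < m:
                        order.append(col)
        self.permutation = np.array(order, dtype=np.int64)

    @property
    def scores(self) -> np.ndarray:
        return self.base.scores[self.permutation]

    def unpermute(self) -> PSSM:
        inverse = np.empty_like(self.permutation)
        inverse[self.permutation] = np.arange(self.permutation.size)
        return PSSM(
            scores=self.scores[inverse], query_codes=self.base.query_codes
        )


def permute_pssm(pssm: PSSM, columns_per_thread: int) -> PermutedPSSM:
    """Reorder PSSM columns into the packed-pair layout (see PermutedPSSM)."""
    return PermutedPSSM(base=pssm, columns_per_thread=columns_per_thread)
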
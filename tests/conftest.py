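import numpy as np
import pytest

import profsearch as ps


@pytest.fixture(scope="session")
def blosum62():
    return ps.load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def toy_matrix():
    """+2 on the canonical diagonal, -1 elsewhere (X rows/cols -1)."""
    grid = np.full((21, 21), -1, dtype=np.int64)
    np.fill_diagonal(grid[:20, :20], 2)
    return ps.SubstitutionMatrix(grid, name="toy")


@pytest.fixture(scope="session")
def match5_matrix():
    """+5 match / -4 mismatch toy matrix."""
    grid = np.full((21, 21), -4, dtype=np.int64)
    np.fill_diagonal(grid[:20, :20], 5)
    return ps.SubstitutionMatrix(grid, name="match5")


def random_records(n, rng, min_len=1, max_len=120, prefix="s"):
    letters = np.frombuffer(ps.ALPHABET.encode(), dtype=np.uint8)
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        seq = letters[rng.integers(0, 20, size=L)].tobytes().decode()
        out.append(ps.SequenceRecord(id=f"{prefix}{i}", residues=seq))
    return out


@pytest.fixture(scope="session")
def small_db():
    rng = np.random.default_rng(1234)
    records = random_records(60, rng, min_len=5, max_len=150)
    return records, ps.build_packed_db(records)


def loguniform_length(rng, lo=1, hi=3000):
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))
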
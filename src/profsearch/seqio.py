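"""Sequence I/O and the packed database representation.

Protein sequences are encoded over a 21-letter alphabet: the 20 canonical
amino acids at indices 0-19 plus the wildcard ``X`` at index 20.  Every
non-canonical letter (B, Z, J, U, O, ``*``, soft-masked lowercase, ...) maps
to ``X`` so that downstream scoring only ever sees valid alphabet indices.

Databases are stored packed: one byte per residue, concatenated, with the
sequences sorted by length in ascending order.  Length sorting keeps batches
of equal-length targets together, which is what makes the row-parallel
gapless kernel efficient; the ``order_map`` recovers the original record
order for reporting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = 20
ALPHABET_SIZE = 21
_FASTA_WRAP = 80

_CODE_OF = np.full(256, X_INDEX, dtype=np.uint8)
for _i, _aa in enumerate(ALPHABET):
    _CODE_OF[ord(_aa)] = _i
    _CODE_OF[ord(_aa.lower())] = _i
_LETTER_OF = np.frombuffer((ALPHABET + "X").encode(), dtype=np.uint8)


@dataclass
class SequenceRecord:
    """A raw protein sequence with its FASTA identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")


@dataclass
class EncodedSequence:
    """A protein as small-integer residue codes in ``[0, 20]``."""

    codes: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size and self.codes.max() >= ALPHABET_SIZE:
            raise ValueError("residue code out of alphabet range")

    def __len__(self) -> int:
        return int(self.codes.size)


def encode_sequence(record: SequenceRecord | str) -> EncodedSequence:
    """Map a residue string to alphabet indices (case-insensitive; unknowns -> X)."""
    if isinstance(record, SequenceRecord):
        residues, rid = record.residues, record.id
    else:
        residues, rid = record, ""
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    return EncodedSequence(codes=_CODE_OF[raw], id=rid)


def decode_sequence(encoded: EncodedSequence) -> str:
    """Inverse of :func:`encode_sequence` up to the many-to-one X mapping."""
    return _LETTER_OF[np.asarray(encoded.codes, dtype=np.uint8)].tobytes().decode()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; records with empty sequences are skipped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            warnings.warn(f"skipping empty-sequence record {rec.id!r}", stacklevel=2)
            continue
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WRAP)
        writer.write_file(bio)


@dataclass
class PackedDB:
    """Concatenated 1-byte-per-residue database, ascending-length-sorted.

    ``offsets`` has ``n_sequences + 1`` entries so that sequence ``i`` in
    packed order occupies ``residue_block[offsets[i]:offsets[i + 1]]``.
    ``order_map[i]`` is the original record index of packed sequence ``i``.
    """

    residue_block: np.ndarray
    offsets: np.ndarray
    order_map: np.ndarray
    ids: list[str]

    @property
    def n_sequences(self) -> int:
        return len(self.offsets) - 1

    @property
    def total_residues(self) -> int:
        return int(self.residue_block.size)

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    def sequence(self, packed_index: int) -> EncodedSequence:
        lo, hi = self.offsets[packed_index], self.offsets[packed_index + 1]
        return EncodedSequence(
            codes=self.residue_block[lo:hi],
            id=self.ids[self.order_map[packed_index]],
        )

    def __iter__(self) -> Iterator[EncodedSequence]:
        for i in range(self.n_sequences):
            yield self.sequence(i)

    def subset(self, lo: int, hi: int) -> "PackedDB":
        """Contiguous slice [lo, hi) of the packed order (shares the block)."""
        off = self.offsets[lo:hi + 1]
        return PackedDB(
            residue_block=self.residue_block[off[0]:off[-1]],
            offsets=off - off[0],
            order_map=self.order_map[lo:hi],
            ids=self.ids,
        )


def build_packed_db(records: Sequence[SequenceRecord]) -> PackedDB:
    """Encode, length-sort (stable, ascending) and concatenate ``records``."""
    if not records:
        raise ValueError("cannot build a packed database from zero records")
    encoded = [encode_sequence(r) for r in records]
    lengths = np.array([len(e) for e in encoded], dtype=np.int64)
    order = np.argsort(lengths, kind="stable")
    offsets = np.zeros(len(records) + 1, dtype=np.int64)
    np.cumsum(lengths[order], out=offsets[1:])
    block = np.empty(int(offsets[-1]), dtype=np.uint8)
    for packed_i, orig_i in enumerate(order):
        block[offsets[packed_i]:offsets[packed_i + 1]] = encoded[orig_i].codes
    return PackedDB(
        residue_block=block,
        offsets=offsets,
        order_map=order,
        ids=[r.id for r in records],
    )


_PACKED_DB_VERSION = 1


def save_packed_db(db: PackedDB, prefix: str | Path) -> None:
    """Persist as a three-file set: residue block, offsets, id table + header."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    db.residue_block.tofile(str(prefix) + ".block")
    np.savetxt(str(prefix) + ".offsets", db.offsets, fmt="%d")
    meta = {
        "version": _PACKED_DB_VERSION,
        "ids": db.ids,
        "order_map": db.order_map.tolist(),
    }
    Path(str(prefix) + ".ids.json").write_text(json.dumps(meta))


def load_packed_db(prefix: str | Path) -> PackedDB:
    prefix = str(prefix)
    meta = json.loads(Path(prefix + ".ids.json").read_text())
    if meta.get("version") != _PACKED_DB_VERSION:
        raise ValueError(f"unsupported packed-db version: {meta.get('version')!r}")
    return PackedDB(
        residue_block=np.fromfile(prefix + ".block", dtype=np.uint8),
        offsets=np.loadtxt(prefix + ".offsets", dtype=np.int64, ndmin=1),
        order_map=np.array(meta["order_map"], dtype=np.int64),
        ids=list(meta["ids"]),
    )


def write_m8(hits, query_id: str, path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (m8) lines.

    Internal coordinates are 0-based half-open; the serialized qstart/qend
    and tstart/tend are 1-based inclusive, per the BLAST convention.
    """
    with open(path, "w") as fh:
        for h in hits:
            a = h.gapped
            fh.write(
                "\t".join(
                    (
                        query_id,
                        h.target_id,
                        f"{100.0 * a.identity_fraction:.1f}",
                        str(a.alignment_length),
                        str(a.mismatches),
                        str(a.gap_openings),
                        str(a.query_interval[0] + 1),
                        str(a.query_interval[1]),
                        str(a.target_interval[0] + 1),
                        str(a.target_interval[1]),
                        f"{h.evalue:.3e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


@dataclass
class M8Row:
    query_id: str
    target_id: str
    pident: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    evalue: float
    bit_score: float


def read_m8(path: str | Path) -> list[M8Row]:
    rows: list[M8Row] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError(f"malformed m8 line: {line!r}")
            rows.append(
                M8Row(
                    f[0], f[1], float(f[2]), int(f[3]), int(f[4]), int(f[5]),
                    int(f[6]), int(f[7]), int(f[8]), int(f[9]),
                    float(f[10]), float(f[11]),
                )
            )
    return rows
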
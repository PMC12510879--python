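"""Measurement machinery: CUPS throughput, peak-performance model, ROC1.

TCUPS (trillions of cell updates per second) converts a runtime into
dynamic-programming throughput: ``TCUPS = (sum_i m_i * n_i) / (t * 10^12)``.
The theoretical peak performance (TPP) model bounds attainable TCUPS from
hardware characteristics:

    TPP = (#SMs * throughput_per_instruction * clock) / cycles_per_cell_update

with the clock in GHz and throughput in results per cycle per streaming
multiprocessor.

ROC1 measures per-query sensitivity on a family/fold-annotated benchmark
with reversed-sequence decoys: the fraction of a query's true positives
ranked above its first false positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


@dataclass
class TcupsRecord:
    """Aligned-length pairs and the elapsed wall time that produced them."""

    pair_lengths: Sequence[tuple[int, int]]
    elapsed_seconds: float

    def __post_init__(self) -> None:
        if self.elapsed_seconds <= 0:
            raise ValueError("elapsed time must be positive")
        if any(m <= 0 or n <= 0 for m, n in self.pair_lengths):
            raise ValueError("all pair lengths must be positive")


def compute_tcups(record: TcupsRecord) -> float:
    cells = sum(m * n for m, n in record.pair_lengths)
    return cells / (record.elapsed_seconds * 1e12)


@dataclass
class TppParams:
    """Hardware model inputs for the theoretical peak performance bound."""

    n_sms: int
    throughput_per_instruction: int   # results / cycle / SM
    clock_ghz: float
    cycles_per_cell_update: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_sms, self.throughput_per_instruction, self.clock_ghz) <= 0:
            raise ValueError("all TPP parameters must be positive")
        if self.cycles_per_cell_update < 1:
            raise ValueError("cycles_per_cell_update must be >= 1")


def compute_tpp(params: TppParams) -> float:
    """Theoretical peak in TCUPS: GHz * results/cycle/SM * SMs gives 10^9
    cell updates per second, hence the explicit 10^3 scaling to 10^12."""
    per_second_giga = (
        params.n_sms * params.throughput_per_instruction * params.clock_ghz
    ) / params.cycles_per_cell_update
    return per_second_giga / 1e3


@dataclass
class BenchmarkAnnotation:
    """Family/fold labels and decoy flags for every benchmark sequence.

    Decoy targets carry no family label; queries must appear with their own
    family and fold so true-positive totals can be counted over the
    reference side.
    """

    family: dict[str, str] = field(default_factory=dict)
    fold: dict[str, str] = field(default_factory=dict)
    decoys: set[str] = field(default_factory=set)
    query_ids: set[str] = field(default_factory=set)

    def tp_total(self, query_id: str) -> int:
        fam = self.family.get(query_id)
        if fam is None:
            raise KeyError(f"query {query_id!r} has no family annotation")
        return sum(
            1
            for tid, f in self.family.items()
            if f == fam and tid not in self.query_ids and tid != query_id
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for tid in sorted(set(self.family) | self.decoys):
            rows.append(
                {
                    "target_id": tid,
                    "family": self.family.get(tid, ""),
                    "fold": self.fold.get(tid, ""),
                    "is_decoy": int(tid in self.decoys),
                    "is_query": int(tid in self.query_ids),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BenchmarkAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        ann = cls()
        for _, row in df.iterrows():
            tid = row["target_id"]
            if row["family"]:
                ann.family[tid] = row["family"]
                ann.fold[tid] = row["fold"]
            if int(row["is_decoy"]):
                ann.decoys.add(tid)
            if "is_query" in row and row["is_query"] and int(row["is_query"]):
                ann.query_ids.add(tid)
        return ann


def roc1_single_query(
    ranked_target_ids: Sequence[str],
    annotation: BenchmarkAnnotation,
    query_id: str,
) -> float:
    """Fraction of the query's true positives ranked above the first false
    positive.

    Walking the hits in rank order (best E-value first): a decoy or a
    different-fold target is a false positive and stops the walk; a
    same-family target is a true positive; a same-fold, different-family
    target is ignored (neither TP nor FP).  With no false positive in the
    list, every true positive found counts.
    """
    total = annotation.tp_total(query_id)
    if total == 0:
        raise ValueError(f"query {query_id!r} has no true positives in the database")
    fam = annotation.family[query_id]
    fold = annotation.fold[query_id]
    found = 0
    for tid in ranked_target_ids:
        if tid in annotation.decoys:
            break
        t_fam = annotation.family.get(tid)
        if t_fam == fam:
            found += 1
        elif annotation.fold.get(tid) == fold:
            continue  # same fold, different family: ignored
        else:
            break  # different fold: false positive
    return found / total


def evaluate_sensitivity(
    results: Mapping[str, Sequence],
    annotation: BenchmarkAnnotation,
    report_path: str | Path | None = None,
) -> tuple[float, pd.DataFrame]:
    """Mean per-query ROC1 (unweighted) plus the per-query table.

    ``results`` maps query id to its ranked hits (objects with a
    ``target_id`` attribute, or bare id strings).  Queries without any true
    positive in the database are excluded with a warning.
    """
    rows = []
    for qid, hits in results.items():
        ids = [h if isinstance(h, str) else h.target_id for h in hits]
        try:
            r = roc1_single_query(ids, annotation, qid)
        except ValueError:
            warnings.warn(f"query {qid!r} has no true positives; excluded", stacklevel=2)
            continue
        rows.append({"query_id": qid, "roc1": r, "n_hits": len(ids),
                     "tp_total": annotation.tp_total(qid)})
    if not rows:
        raise ValueError("no usable queries (every query lacked true positives)")
    table = pd.DataFrame(rows)
    if report_path is not None:
        table.to_csv(report_path, sep="\t", index=False)
    return float(table["roc1"].mean()), table
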
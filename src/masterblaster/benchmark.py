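"""SCOP fold-level benchmarking of hit tables.

A reported hit is a true positive when its SCOP fold equals the query's fold
and a false positive otherwise; false negatives are same-fold members never
reported.  Self-hits are excluded from all counts, so for one query against a
database of D labeled sequences tp + fn = fold_size - 1 and
tn + fp = D - fold_size.

True positives are further broken down by connection type: intra-family
(same family), cross-family (same superfamily, different family) and
cross-superfamily (same fold, different superfamily) — the latter two are the
remote relationships the cascade exists to find.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import HitTableRow, ScopLabel, SequenceRecord

logger = logging.getLogger(__name__)

INTRA_FAMILY = "intra_family"
CROSS_FAMILY = "cross_family"
CROSS_SUPERFAMILY = "cross_superfamily"
DIFFERENT_FOLD = "different_fold"

CONNECTION_TYPES = (INTRA_FAMILY, CROSS_FAMILY, CROSS_SUPERFAMILY)


def classify_pair(query_label: ScopLabel, subject_label: ScopLabel) -> str:
    """Relationship of two labeled domains in the SCOP hierarchy."""
    if not isinstance(query_label, ScopLabel) or not isinstance(subject_label, ScopLabel):
        raise TypeError("labels must be ScopLabel instances")
    if query_label.family_id == subject_label.family_id:
        return INTRA_FAMILY
    if query_label.superfamily_id == subject_label.superfamily_id:
        return CROSS_FAMILY
    if query_label.fold_id == subject_label.fold_id:
        return CROSS_SUPERFAMILY
    return DIFFERENT_FOLD


@dataclasses.dataclass(frozen=True)
class BenchmarkCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "BenchmarkCounts") -> "BenchmarkCounts":
        return BenchmarkCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclasses.dataclass(frozen=True)
class BenchmarkMetrics:
    """The four fold-level rates; a rate with a 0/0 numerator is None (n/a).

    sensitivity = tp/(tp+fn)   (true positive rate)
    precision   = tp/(tp+fp)   (positive predictive value)
    specificity = tn/(tn+fp)
    error_rate  = fp/(fp+tp)   (so precision + error_rate = 1 when tp+fp>0)
    """

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    error_rate: float | None
    intra_family: int = 0
    cross_family: int = 0
    cross_superfamily: int = 0


def compute_metrics(counts: BenchmarkCounts) -> BenchmarkMetrics:
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return BenchmarkMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        precision=ratio(counts.tp, counts.tp + counts.fp),
        error_rate=ratio(counts.fp, counts.fp + counts.tp),
    )


def count_for_query(
    query_id: str,
    query_label: ScopLabel,
    hit_subject_ids: Iterable[str],
    label_map: Mapping[str, ScopLabel],
    db_fold_sizes: Mapping[str, int],
    db_size: int,
) -> BenchmarkCounts:
    """Fold-level TP/FP/TN/FN for one query's deduplicated hit set.

    Self-hits are excluded; unlabeled subjects are excluded from all four
    counts with a warning.  tn = (db_size - fold_size) - fp, reproducing the
    convention that a fold of 402 members in a 13,650-sequence database
    leaves 13,248 true negatives when no false positive is reported.
    """
    fold = query_label.fold_id
    fold_size = db_fold_sizes[fold]
    tp = fp = 0
    for sid in set(hit_subject_ids):
        if sid == query_id:
            continue
        s_label = label_map.get(sid)
        if s_label is None:
            logger.warning("hit subject %s is unlabeled; excluded from counts", sid)
            continue
        if s_label.fold_id == fold:
            tp += 1
        else:
            fp += 1
    fn = (fold_size - 1) - tp
    tn = (db_size - fold_size) - fp
    return BenchmarkCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def connection_counts(
    query_label: ScopLabel,
    hit_subject_ids: Iterable[str],
    label_map: Mapping[str, ScopLabel],
    query_id: str | None = None,
) -> Counter:
    """Partition a query's true positives by connection type."""
    out: Counter = Counter({t: 0 for t in CONNECTION_TYPES})
    for sid in set(hit_subject_ids):
        if sid == query_id:
            continue
        s_label = label_map.get(sid)
        if s_label is None:
            continue
        rel = classify_pair(query_label, s_label)
        if rel != DIFFERENT_FOLD:
            out[rel] += 1
    return out


def _fold_sizes(label_map: Mapping[str, ScopLabel]) -> dict[str, int]:
    sizes: Counter = Counter()
    for label in label_map.values():
        sizes[label.fold_id] += 1
    return dict(sizes)


@dataclasses.dataclass
class BenchmarkReport:
    """Aggregate benchmark output over a set of queries."""

    overall_counts: BenchmarkCounts
    overall: BenchmarkMetrics
    per_fold: pd.DataFrame
    connections: Counter
    per_generation_new_tp: Counter
    unique_hits: dict | None = None


def aggregate(
    hit_tables: Mapping[str, Sequence[HitTableRow]],
    label_map: Mapping[str, ScopLabel],
    db: Sequence[SequenceRecord],
    other_tables: Mapping[str, Sequence[HitTableRow]] | None = None,
) -> BenchmarkReport:
    """Pooled (micro-averaged) metrics, per-fold tables, connection breakdown.

    ``hit_tables`` maps each query id to its hit rows.  Queries without a
    label are skipped with a warning.  When ``other_tables`` is given, the
    unique-hit analysis reports the true-positive hits present here and
    absent there, partitioned by connection type.
    """
    db_ids = {r.id for r in db}
    labeled = {sid: lab for sid, lab in label_map.items() if sid in db_ids}
    fold_sizes = _fold_sizes(labeled)
    db_size = len(labeled)

    total = BenchmarkCounts(0, 0, 0, 0)
    per_fold_counts: dict[str, BenchmarkCounts] = {}
    connections: Counter = Counter({t: 0 for t in CONNECTION_TYPES})
    per_generation_new_tp: Counter = Counter()

    for query_id, rows in hit_tables.items():
        q_label = label_map.get(query_id)
        if q_label is None:
            logger.warning("query %s is unlabeled; skipped", query_id)
            continue
        subject_ids = [r.subject_id for r in rows]
        counts = count_for_query(
            query_id, q_label, subject_ids, labeled, fold_sizes, db_size
        )
        total = total + counts
        fold = q_label.fold_id
        per_fold_counts[fold] = per_fold_counts.get(
            fold, BenchmarkCounts(0, 0, 0, 0)
        ) + counts
        connections += connection_counts(q_label, subject_ids, labeled, query_id)
        for r in rows:
            s_label = labeled.get(r.subject_id)
            if (
                r.subject_id != query_id
                and s_label is not None
                and s_label.fold_id == fold
            ):
                per_generation_new_tp[r.generation] += 1

    fold_rows = []
    for fold in sorted(per_fold_counts):
        c = per_fold_counts[fold]
        m = compute_metrics(c)
        fold_rows.append(
            {
                "fold": fold,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "error_rate": m.error_rate,
            }
        )
    per_fold = pd.DataFrame(
        fold_rows,
        columns=["fold", "tp", "fp", "tn", "fn",
                 "sensitivity", "specificity", "precision", "error_rate"],
    )

    overall = compute_metrics(total)
    overall = dataclasses.replace(
        overall,
        intra_family=connections[INTRA_FAMILY],
        cross_family=connections[CROSS_FAMILY],
        cross_superfamily=connections[CROSS_SUPERFAMILY],
    )

    unique = None
    if other_tables is not None:
        if not (set(hit_tables) & set(other_tables)):
            raise ValueError("hit tables under comparison share no queries")
        unique = unique_hit_partition(hit_tables, other_tables, label_map)

    return BenchmarkReport(
        overall_counts=total,
        overall=overall,
        per_fold=per_fold,
        connections=connections,
        per_generation_new_tp=per_generation_new_tp,
        unique_hits=unique,
    )


def unique_hit_partition(
    tables_a: Mapping[str, Sequence[HitTableRow]],
    tables_b: Mapping[str, Sequence[HitTableRow]],
    label_map: Mapping[str, ScopLabel],
) -> dict:
    """True-positive (query, subject) pairs in A missing from B, by connection.

    Returns a dict with the three connection-type counts and their ``total``;
    the counts partition the total by construction.
    """
    pairs_b = {
        (q, r.subject_id) for q, rows in tables_b.items() for r in rows
    }
    partition: Counter = Counter({t: 0 for t in CONNECTION_TYPES})
    for q, rows in tables_a.items():
        q_label = label_map.get(q)
        if q_label is None:
            continue
        for sid in {r.subject_id for r in rows}:
            if sid == q or (q, sid) in pairs_b:
                continue
            s_label = label_map.get(sid)
            if s_label is None:
                continue
            rel = classify_pair(q_label, s_label)
            if rel != DIFFERENT_FOLD:
                partition[rel] += 1
    out = dict(partition)
    out["total"] = sum(partition.values())
    return out


def tp_ratio_pct(tp_baseline: int, tp_cascade: int) -> float:
    """100 * TP_baseline / TP_cascade, the published improvement ratio."""
    if tp_cascade <= 0:
        raise ValueError("cascade TP count must be positive")
    return 100.0 * tp_baseline / tp_cascade
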
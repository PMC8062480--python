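"""Redundancy clustering and progressive multiple alignment of hit sets.

Between cascade generations the accumulated hits are de-redundified with a
BLASTClust-style rule (single-linkage components of the graph whose edges are
pairs above an identity threshold with mutual length coverage) and the
surviving representatives are multiply aligned with a simple progressive
method: k-mer distances -> UPGMA guide tree -> profile-profile merges with
affine gaps and the "once a gap, always a gap" rule.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sw import nw_score_matrix_global
from .alphabet import AA_TO_INDEX, GAP, X_INDEX
from .scoring import MultipleAlignment, SubstitutionMatrix
from .search import local_align_profile, single_sequence_profile
from .seqio import SequenceRecord


@dataclasses.dataclass
class Cluster:
    """A redundancy cluster: member ids plus a canonical representative."""

    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, matrix: SubstitutionMatrix
) -> tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) on the best local alignment.

    Identity is over aligned non-gap-pair columns; coverage_x is the aligned
    span on x divided by x's length.  No positive-scoring alignment yields
    (0, 0, 0).
    """
    hit = local_align_profile(single_sequence_profile(a, matrix), b)
    if hit is None:
        return 0.0, 0.0, 0.0
    qs, qe = hit.q_interval
    ss, se = hit.s_interval
    return hit.identity_fraction, (qe - qs) / len(a), (se - ss) / len(b)


def alignment_identity(
    a: SequenceRecord, b: SequenceRecord, matrix: SubstitutionMatrix
) -> float:
    """Identity over the full-length (semi-global) alignment of two sequences.

    Matches divided by aligned non-gap-pair columns.  Unlike the local
    measure of :func:`pairwise_identity`, this does not inflate identity for
    unrelated pairs by restricting to a short high-scoring segment, so it is
    the right yardstick for divergence strata.
    """
    merged = _merge_alignments(
        [(("a"), a.residues)], [("b", b.residues)], matrix, 11, 1
    )
    ra, rb = merged[0][1], merged[1][1]
    cols = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
    if not cols:
        return 0.0
    return sum(1 for x, y in cols if x == y) / len(cols)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_sequences(
    records: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    identity_min: float = 0.80,
    coverage_min: float = 0.70,
) -> list[Cluster]:
    """Single-linkage clusters of the >=identity, mutual->=coverage graph.

    Two sequences are neighbors iff alignment identity >= identity_min and
    min(coverage_a, coverage_b) >= coverage_min (the strictest coverage
    semantics).  The representative is the longest member, ties broken by
    lexicographically smallest id; clusters are returned sorted by
    representative id, making the output order-invariant.
    """
    if not records:
        raise ValueError("no records to cluster")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate ids among records")
    ids = sorted(by_id)
    uf = _UnionFind(ids)
    for i, ai in enumerate(ids):
        for bj in ids[i + 1:]:
            ident, cov_a, cov_b = pairwise_identity(by_id[ai], by_id[bj], matrix)
            if ident >= identity_min and min(cov_a, cov_b) >= coverage_min:
                uf.union(ai, bj)
    groups: dict[str, set[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), set()).add(x)
    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda m: (-len(by_id[m]), m))
        clusters.append(Cluster(member_ids=frozenset(members), representative_id=rep))
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def kmer_distance(a: SequenceRecord | str, b: SequenceRecord | str, k: int = 3) -> float:
    """1 - shared k-mers / min(#kmers), multiset semantics; in [0, 1]."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) < k or len(sb) < k:
        raise ValueError(f"sequences must be at least {k} residues for k={k}")
    ca = Counter(sa[i:i + k] for i in range(len(sa) - k + 1))
    cb = Counter(sb[i:i + k] for i in range(len(sb) - k + 1))
    shared = sum((ca & cb).values())
    return 1.0 - shared / min(sum(ca.values()), sum(cb.values()))


@dataclasses.dataclass
class GuideTree:
    """A rooted binary guide tree node; leaves carry ids, internal nodes heights."""

    id: str | None = None
    height: float = 0.0
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.id]
        return self.left.leaves() + self.right.leaves()


def upgma(distance_table: pd.DataFrame) -> GuideTree:
    """Standard UPGMA agglomeration with deterministic tie-breaking.

    ``distance_table`` is a symmetric DataFrame with zero diagonal, indexed
    by sequence ids.  At each step the pair with the smallest distance is
    merged (ties: smallest lexicographic (id, id) pair); merge height is half
    the pair distance; distances to the merged cluster are size-weighted
    averages.
    """
    D = distance_table
    ids = list(D.index)
    if list(D.columns) != ids:
        raise ValueError("distance table index and columns must match")
    arr = D.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance table must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance table diagonal must be zero")
    nodes: dict[str, GuideTree] = {i: GuideTree(id=i) for i in ids}
    sizes: dict[str, int] = {i: 1 for i in ids}
    dist: dict[frozenset, float] = {}
    active = sorted(ids)
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            dist[frozenset((a, b))] = float(D.loc[a, b])
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                d = dist[frozenset((a, b))]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merged_key = f"({a},{b})"
        node = GuideTree(height=d / 2.0, left=nodes[a], right=nodes[b])
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dc = (na * dist[frozenset((a, c))] + nb * dist[frozenset((b, c))]) / (na + nb)
            dist[frozenset((merged_key, c))] = dc
        active = sorted([c for c in active if c not in (a, b)] + [merged_key])
        nodes[merged_key] = node
        sizes[merged_key] = na + nb
    return nodes[active[0]]


def _column_frequencies(rows: Sequence[str]) -> np.ndarray:
    """(n_cols, 20) residue frequencies per column, gaps and X excluded.

    All-gap columns yield a zero vector (they score 0 against anything).
    """
    ncol = len(rows[0])
    F = np.zeros((ncol, 20))
    for row in rows:
        for c, ch in enumerate(row):
            if ch == GAP:
                continue
            idx = AA_TO_INDEX[ch]
            if idx != X_INDEX:
                F[c, idx] += 1.0
    totals = F.sum(axis=1, keepdims=True)
    np.divide(F, totals, out=F, where=totals > 0)
    return F


def _merge_alignments(
    rows1: list[tuple[str, str]],
    rows2: list[tuple[str, str]],
    matrix: SubstitutionMatrix,
    gap_open: int,
    gap_extend: int,
) -> list[tuple[str, str]]:
    F1 = _column_frequencies([r for _, r in rows1])
    F2 = _column_frequencies([r for _, r in rows2])
    S = F1 @ matrix.scores.astype(float) @ F2.T
    _, n, i1, i2 = nw_score_matrix_global(S, float(gap_open), float(gap_extend))
    out1 = ["".join(r[c] if c >= 0 else GAP for c in i1) for _, r in rows1]
    out2 = ["".join(r[c] if c >= 0 else GAP for c in i2) for _, r in rows2]
    return [(rid, s) for (rid, _), s in zip(rows1, out1)] + [
        (rid, s) for (rid, _), s in zip(rows2, out2)
    ]


def progressive_align(
    records: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> MultipleAlignment:
    """Progressive multiple alignment up a UPGMA guide tree.

    Pairwise k-mer distances feed UPGMA; alignments are merged bottom-up by
    profile-profile global alignment (column score = frequency-weighted
    average substitution score, affine gaps).  Gaps introduced at a merge are
    never removed.  Output row order equals input order.
    """
    if not records:
        raise ValueError("no records to align")
    if len(records) == 1:
        return MultipleAlignment([(records[0].id, records[0].residues)])
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate ids among records")
    ids = [r.id for r in records]
    k = 3
    n = len(ids)
    D = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = by_id[ids[i]], by_id[ids[j]]
            if len(a) < k or len(b) < k:
                d = 1.0  # too short for k-mers: treat as maximally distant
            else:
                d = kmer_distance(a, b, k)
            D.iloc[i, j] = D.iloc[j, i] = d
    tree = upgma(D)

    def align_node(node: GuideTree) -> list[tuple[str, str]]:
        if node.is_leaf:
            return [(node.id, by_id[node.id].residues)]
        return _merge_alignments(
            align_node(node.left), align_node(node.right), matrix, gap_open, gap_extend
        )

    rows = align_node(tree)
    by_row = dict(rows)
    return MultipleAlignment([(rid, by_row[rid]) for rid in ids])
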
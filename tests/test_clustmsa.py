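import itertools
import random

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from masterblaster.clustmsa import (
    alignment_identity,
    cluster_sequences,
    kmer_distance,
    pairwise_identity,
    progressive_align,
    upgma,
)
from masterblaster.seqio import SequenceRecord

from conftest import random_protein


def rec(i, residues):
    return SequenceRecord(id=i, residues=residues)


class TestPairwiseIdentity:
    def test_identical_sequences(self, matrix):
        a = rec("a", "MKVLAWYTED")
        assert pairwise_identity(a, rec("b", a.residues), matrix) == (1.0, 1.0, 1.0)

    def test_disjoint_composition(self, matrix):
        out = pairwise_identity(rec("a", "WWWWW"), rec("b", "PPPPP"), matrix)
        assert out == (0.0, 0.0, 0.0)

    def test_half_covered_subject_by_hand(self, matrix):
        a = rec("a", "A" * 10)
        b = rec("b", "A" * 10 + "C" * 10)
        ident, cov_a, cov_b = pairwise_identity(a, b, matrix)
        assert ident == 1.0
        assert cov_a == 1.0
        assert cov_b == 0.5


class TestClusterSequences:
    def test_identical_sequences_form_one_cluster(self, matrix):
        records = [rec(f"s{i}", "MKVLAWYTEDMKVLAWYTED") for i in range(4)]
        clusters = cluster_sequences(records, matrix)
        assert len(clusters) == 1
        assert clusters[0].member_ids == {f"s{i}" for i in range(4)}
        assert clusters[0].representative_id == "s0"  # tie -> smallest id

    def test_unrelated_sequences_stay_singletons(self, matrix, rng):
        records = [rec(f"s{i}", random_protein(rng, 60)) for i in range(10)]
        clusters = cluster_sequences(records, matrix)
        assert len(clusters) == 10

    def test_single_linkage_chain_matches_component_oracle(self, matrix, rng):
        """A~B and B~C above threshold but A!~C must still merge {A,B,C}:
        cluster membership equals brute-force connected components of the
        pairwise neighbor graph."""
        base = random_protein(rng, 60)
        tail = random_protein(rng, 20)
        a = rec("a", base)
        b = rec("b", base + tail)               # shares all of a: neighbors
        c = rec("c", base[20:] + tail + random_protein(rng, 20))
        records = [a, b, c]
        clusters = cluster_sequences(records, matrix)

        ids = [r.id for r in records]
        by_id = {r.id: r for r in records}
        edges = {
            (x, y)
            for x, y in itertools.combinations(ids, 2)
            if (lambda t: t[0] >= 0.8 and min(t[1], t[2]) >= 0.7)(
                pairwise_identity(by_id[x], by_id[y], matrix)
            )
        }
        # brute-force components
        comps = {i: {i} for i in ids}
        for x, y in edges:
            merged = comps[x] | comps[y]
            for m in merged:
                comps[m] = merged
        expected = {frozenset(c) for c in comps.values()}
        assert {frozenset(c.member_ids) for c in clusters} == expected
        # the engineered chain really is a chain
        assert ("a", "b") in edges and ("b", "c") in edges and ("a", "c") not in edges
        assert len(clusters) == 1

    def test_partition_property(self, matrix, rng):
        records = [rec(f"s{i}", random_protein(rng, 40)) for i in range(8)]
        clusters = cluster_sequences(records, matrix)
        seen = [m for c in clusters for m in c.member_ids]
        assert sorted(seen) == sorted(r.id for r in records)

    def test_input_order_invariance(self, matrix, rng):
        records = [rec(f"s{i}", random_protein(rng, 40)) for i in range(6)]
        c1 = cluster_sequences(records, matrix)
        c2 = cluster_sequences(records[::-1], matrix)
        assert [(c.representative_id, c.member_ids) for c in c1] == [
            (c.representative_id, c.member_ids) for c in c2
        ]


class TestKmerDistance:
    def test_identical_is_zero(self):
        assert kmer_distance("MKVLAW", "MKVLAW") == 0.0

    def test_disjoint_is_one(self):
        assert kmer_distance("AAAAA", "WWWWW") == 1.0

    def test_hand_counted_multiset(self):
        # kmers(AAAB) = {AAA, AAB}, kmers(AAAC) = {AAA, AAC}: shared 1 of min 2
        assert kmer_distance("AAAB", "AAAC", k=3) == 0.5

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_distance("MK", "MKVLAW", k=3)


class TestUpgma:
    def test_two_leaves_cherry_at_half_distance(self):
        D = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = upgma(D)
        assert sorted(tree.leaves()) == ["a", "b"]
        assert tree.height == pytest.approx(0.2)

    def test_three_leaves_nearest_pair_first(self):
        ids = ["A", "B", "C"]
        D = pd.DataFrame(
            [[0.0, 0.2, 0.8], [0.2, 0.0, 0.9], [0.8, 0.9, 0.0]],
            index=ids, columns=ids,
        )
        tree = upgma(D)
        inner = tree.left if not tree.left.is_leaf else tree.right
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_asymmetric_table_rejected(self):
        D = pd.DataFrame([[0.0, 0.1], [0.3, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            upgma(D)

    def test_matches_scipy_average_linkage(self, nprng):
        """Five random (tie-free) tables: topology and merge heights agree
        with scipy's independent UPGMA implementation."""
        ids = list("abcde")
        for _ in range(5):
            cond = nprng.uniform(0.1, 1.0, size=10)
            D = pd.DataFrame(squareform(cond), index=ids, columns=ids)
            tree = upgma(D)
            Z = linkage(cond, method="average")

            def heights(node, acc):
                if not node.is_leaf:
                    acc.append(round(node.height * 2, 10))
                    heights(node.left, acc)
                    heights(node.right, acc)
                return acc

            assert sorted(heights(tree, [])) == pytest.approx(sorted(Z[:, 2]))

            def clades(node, acc):
                if not node.is_leaf:
                    acc.append(frozenset(node.leaves()))
                    clades(node.left, acc)
                    clades(node.right, acc)
                return acc

            # scipy clades
            n = len(ids)
            scipy_clades = []
            members = {i: frozenset([ids[i]]) for i in range(n)}
            for k, (i, j, _, _) in enumerate(Z):
                members[n + k] = members[int(i)] | members[int(j)]
                scipy_clades.append(members[n + k])
            assert set(clades(tree, [])) == set(scipy_clades)


class TestProgressiveAlign:
    def test_single_record_trivial(self, matrix):
        msa = progressive_align([rec("a", "MKVLAW")], matrix)
        assert msa.rows == [("a", "MKVLAW")]

    def test_two_identical_records_align_without_gaps(self, matrix):
        msa = progressive_align([rec("a", "MKVLAW"), rec("b", "MKVLAW")], matrix)
        assert msa.n_columns == 6
        assert all("-" not in row for _, row in msa.rows)

    def test_rows_degap_to_inputs(self, matrix, rng):
        for _ in range(10):
            records = [
                rec(f"s{i}", random_protein(rng, rng.randint(10, 40)))
                for i in range(rng.randint(2, 5))
            ]
            msa = progressive_align(records, matrix)
            assert [rid for rid, _ in msa.rows] == [r.id for r in records]
            for (rid, row), r in zip(msa.rows, records):
                assert row.replace("-", "") == r.residues
            assert max(len(r) for r in records) <= msa.n_columns
            assert msa.n_columns <= sum(len(r) for r in records)

    def test_terminal_extension_stays_terminal(self, matrix, rng):
        core = random_protein(rng, 50)
        tail = random_protein(rng, 30)
        msa = progressive_align([rec("a", core), rec("b", core + tail)], matrix)
        row_a = dict(msa.rows)["a"]
        assert row_a == core + "-" * 30


def test_alignment_identity_orders_related_above_random(matrix, rng):
    core = random_protein(rng, 100)
    mutated = list(core)
    for i in range(0, 100, 3):
        mutated[i] = random_protein(rng, 1)
    related = "".join(mutated)
    unrelated = random_protein(rng, 100)
    id_rel = alignment_identity(rec("a", core), rec("b", related), matrix)
    id_unrel = alignment_identity(rec("a", core), rec("c", unrelated), matrix)
    assert id_rel > 0.6 > id_unrel
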
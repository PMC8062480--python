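import random

import numpy as np
import pytest

from masterblaster.cascade import (
    CascadeConfig,
    alignment_chain,
    chain_to_query,
    passes_filters,
    run_master_blaster,
)
from masterblaster.scoring import MultipleAlignment
from masterblaster.search import (
    SearchConfig,
    iterative_search,
    local_align_profile,
    single_sequence_profile,
)
from masterblaster.seqio import SequenceRecord

from _oracles import compose_position_maps
from conftest import random_protein


def _hit(matrix, query_res, subject_res):
    prof = single_sequence_profile(SequenceRecord(id="q", residues=query_res), matrix)
    return local_align_profile(prof, SequenceRecord(id="s", residues=subject_res))


class TestChainToQuery:
    def test_identity_chain_equals_hit_interval(self, matrix, rng):
        q = random_protein(rng, 40)
        hit = _hit(matrix, q, q[5:35])
        assert chain_to_query(hit) == hit.q_interval

    def test_hit_confined_to_reference_only_region_chains_to_none(self, matrix):
        # reference row has a 6-residue block the query lacks entirely
        ref = "MKVLAWYTED" + "WWFFYY" + "MKVLAWYTED"
        msa = MultipleAlignment([
            ("query", "MKVLAWYTED" + "------" + "MKVLAWYTED"),
            ("ref", ref),
        ])
        hit = _hit(matrix, ref, "WWFFYY")
        hit.profile_reference_id = "ref"
        assert hit.q_interval == (10, 16)
        assert chain_to_query(hit, alignment=msa, query_id="query") is None

    def test_chain_through_alignment_matches_direct_map(self, matrix, rng):
        q = random_protein(rng, 30)
        ref = q[:10] + random_protein(rng, 5) + q[10:]
        msa = MultipleAlignment([
            ("query", q[:10] + "-----" + q[10:]),
            ("ref", ref),
        ])
        hit = _hit(matrix, ref, ref)
        hit.profile_reference_id = "ref"
        interval = chain_to_query(hit, alignment=msa, query_id="query")
        assert interval == (0, 30)

    def test_multi_step_chain_matches_brute_force_composition(self, matrix, rng):
        """Random two-alignment chains (query -> ref1 -> ref2): the interval
        returned by chain_to_query equals a per-position brute-force
        composition of the alignment maps applied to the hit's aligned
        columns."""
        for _ in range(15):
            q = random_protein(rng, 25)
            i1 = rng.randint(5, 20)
            ref1 = q[:i1] + random_protein(rng, 4) + q[i1:]
            msa1 = MultipleAlignment(
                [("query", q[:i1] + "----" + q[i1:]), ("ref1", ref1)]
            )
            i2 = rng.randint(5, 20)
            ref2 = ref1[:i2] + random_protein(rng, 3) + ref1[i2:]
            msa2 = MultipleAlignment(
                [("ref1", ref1[:i2] + "---" + ref1[i2:]), ("ref2", ref2)]
            )
            chain1 = alignment_chain(msa1, "ref1", "query")
            hit = _hit(matrix, ref2, ref2[2:-2])
            hit.profile_reference_id = "ref2"
            interval = chain_to_query(
                hit, alignment=msa2, query_id="ref1", parent_chain=chain1
            )
            full = compose_position_maps(alignment_chain(msa2, "ref2", "ref1"), chain1)
            covered = sorted(
                full[p] for p, s in hit.pairs if p >= 0 and s >= 0 and p in full
            )
            expected = (covered[0], covered[-1] + 1) if covered else None
            assert interval == expected

    def test_generation_chain_composes_alignment_rows(self, matrix):
        msa = MultipleAlignment([
            ("query", "MKVLA-WYTED"),
            ("ref", "-KVLAGWYTE-"),
        ])
        chain = alignment_chain(msa, "ref", "query")
        # ref pos 0..9 = KVLAGWYTE; G sits under a query gap
        assert chain == {0: 1, 1: 2, 2: 3, 3: 4, 5: 5, 6: 6, 7: 7, 8: 8}


class TestPassesFilters:
    @pytest.mark.parametrize(
        "e_value, interval, expected",
        [
            (1e-4, (0, 90), True),    # clears both thresholds
            (1e-4, (0, 69), False),   # coverage 0.69 just below
            (1e-4, (0, 70), True),    # coverage exactly 0.70 is inclusive
            (1e-3, (0, 90), True),    # E exactly at threshold is inclusive
            (2e-3, (0, 90), False),
            (1e-4, None, False),      # broken chain discards the hit
        ],
    )
    def test_threshold_boundaries(self, matrix, rng, e_value, interval, expected):
        q = random_protein(rng, 100)
        hit = _hit(matrix, q, q)
        hit.e_value = e_value
        assert passes_filters(hit, interval, 100, CascadeConfig()) is expected


class TestRunMasterBlaster:
    def test_hopeless_query_converges_empty(self, matrix, rng):
        query = SequenceRecord(id="q", residues="W" * 30)
        db = [SequenceRecord(id=f"d{i}", residues="P" * 40) for i in range(3)]
        result = run_master_blaster(query, db, matrix)
        assert result.converged
        assert result.final_table == []

    def test_self_copy_database(self, matrix, rng):
        q = SequenceRecord(id="q", residues=random_protein(rng, 80))
        copy = SequenceRecord(id="copy", residues=q.residues)
        result = run_master_blaster(q, [copy], matrix)
        assert result.hit_ids == {"copy"}
        assert result.converged

    def test_deterministic_rerun(self, matrix, chain_fixture):
        r1 = run_master_blaster(chain_fixture.query, chain_fixture.database, matrix)
        r2 = run_master_blaster(chain_fixture.query, chain_fixture.database, matrix)
        assert r1.final_table == r2.final_table
        assert r1.convergence_generation == r2.convergence_generation

    def test_degenerate_config_equals_inner_search(self, matrix, chain_fixture):
        """max_generations=1 with no profiles is exactly the PSI-BLAST-like
        baseline: same subjects at the same E-values as iterative_search."""
        cfg = CascadeConfig(max_generations=1, max_profiles_per_generation=0)
        result = run_master_blaster(
            chain_fixture.query, chain_fixture.database, matrix, cfg
        )
        inner = iterative_search(
            chain_fixture.query, chain_fixture.database, matrix, SearchConfig()
        )
        inner_pass = {
            h.subject_id: h.e_value
            for h in inner
            if chain_to_query(h) is not None
            and (chain_to_query(h)[1] - chain_to_query(h)[0])
            >= 0.7 * len(chain_fixture.query)
        }
        assert {r.subject_id: r.e_value for r in result.final_table} == inner_pass

    def test_accumulated_hits_grow_monotonically(self, matrix, chain_fixture):
        result = run_master_blaster(
            chain_fixture.query, chain_fixture.database, matrix
        )
        seen: set[str] = set()
        for rows in result.per_generation:
            ids = {r.subject_id for r in rows}
            assert not (ids & seen)  # new hits only
            seen |= ids
        assert seen == result.hit_ids

    def test_every_hit_satisfies_original_query_thresholds(self, matrix, chain_fixture):
        cfg = CascadeConfig()
        result = run_master_blaster(
            chain_fixture.query, chain_fixture.database, matrix, cfg
        )
        for row in result.final_table:
            assert row.e_value <= cfg.e_value_report
            assert row.coverage_pct >= 100 * cfg.query_coverage_min

    def test_intermediate_chain_recovery(self, matrix, chain_fixture):
        """The cascade's reason to exist: C is invisible to the query-anchored
        baseline but reached through the intermediate B's profile."""
        db = chain_fixture.database
        baseline = run_master_blaster(
            chain_fixture.query, db, matrix,
            CascadeConfig(max_generations=1, max_profiles_per_generation=0),
        )
        cascade = run_master_blaster(chain_fixture.query, db, matrix)
        assert "chainB" in baseline.hit_ids
        assert "chainC" not in baseline.hit_ids
        assert "chainC" in cascade.hit_ids
        c_row = next(r for r in cascade.final_table if r.subject_id == "chainC")
        assert 1 <= c_row.generation <= 3
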
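"""The cascade generation loop: search, cluster, align, multi-reference PSSMs.

Generation 0 runs the inner iterative search on the query itself.  Each later
generation (1) collects the sequences of all accumulated hits (full length by
default, so homology carried by regions outside the current anchor can seed
the next generation; truncation to aligned regions is available),
(2) clusters them for redundancy,
(3) progressively aligns the cluster representatives together with the
original query, (4) builds one rescaled PSSM per aligned sequence as
reference, (5) searches the database with every PSSM, (6) chains each hit's
coordinates back to the original query through the alignment and filters on
E-value and chained query coverage, and (7) merges by keeping each subject's
minimum E-value.  The loop converges when a generation adds no new subject.

The chaining step is what keeps the cascade honest: a hit found through an
intermediate sequence counts only if its aligned region maps, through the
generation alignment, onto at least the required fraction of the original
query.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .alphabet import GAP
from .clustmsa import cluster_sequences, progressive_align
from .scoring import (
    MultipleAlignment,
    ProfileMatrix,
    SubstitutionMatrix,
    build_pssm,
    rescale_profile,
)
from .search import (
    AlignmentHit,
    SearchConfig,
    database_length,
    iterative_search,
    search_profile,
)
from .seqio import HitTableRow, SequenceRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CascadeConfig:
    """All knobs of a cascade run (search thresholds plus generation control)."""

    e_value_report: float = 1e-3
    h_value_include: float = 1e-3
    max_inner_iterations: int = 5
    gap_open: int = 11
    gap_extend: int = 1
    query_coverage_min: float = 0.70
    max_generations: int = 5
    cluster_identity: float = 0.80
    cluster_coverage: float = 0.70
    max_profiles_per_generation: int = 50
    truncate_to_aligned_region: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for name in ("cluster_identity", "cluster_coverage", "query_coverage_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            e_value_report=self.e_value_report,
            h_value_include=self.h_value_include,
            max_inner_iterations=self.max_inner_iterations,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            query_coverage_min=self.query_coverage_min,
        )


@dataclasses.dataclass
class _AccumulatedHit:
    hit: AlignmentHit
    first_generation: int
    chained_interval: tuple[int, int]
    subject_offset: int  # offset of the (possibly truncated) subject in the original


@dataclasses.dataclass
class CascadeState:
    """Accumulated best hits and convergence bookkeeping."""

    generation_index: int = 0
    accumulated: dict[str, _AccumulatedHit] = dataclasses.field(default_factory=dict)
    new_ids_this_generation: set[str] = dataclasses.field(default_factory=set)
    converged: bool = False


@dataclasses.dataclass
class CascadeResult:
    """Per-generation new-hit tables, the final union, and convergence info."""

    query_id: str
    per_generation: list[list[HitTableRow]]
    final_table: list[HitTableRow]
    converged: bool
    convergence_generation: int | None

    @property
    def hit_ids(self) -> set[str]:
        return {r.subject_id for r in self.final_table}


def alignment_chain(
    alignment: MultipleAlignment, reference_id: str, query_id: str
) -> dict[int, int]:
    """Map reference-sequence positions to query-row positions via columns."""
    ref_row = alignment.row(reference_id)
    query_row = alignment.row(query_id)
    col_to_query: dict[int, int] = {}
    qpos = 0
    for c, ch in enumerate(query_row):
        if ch != GAP:
            col_to_query[c] = qpos
            qpos += 1
    chain: dict[int, int] = {}
    rpos = 0
    for c, ch in enumerate(ref_row):
        if ch != GAP:
            if c in col_to_query:
                chain[rpos] = col_to_query[c]
            rpos += 1
    return chain


def chain_to_query(
    hit: AlignmentHit,
    alignment: MultipleAlignment | None = None,
    parent_chain: Mapping[int, int] | None = None,
    query_id: str | None = None,
) -> tuple[int, int] | None:
    """Map a hit's aligned region onto the original query; None if empty.

    The hit's aligned profile positions are taken to reference positions
    (position_map), then to original-query positions either through the
    given alignment's query row or through ``parent_chain`` (a per-position
    map from reference to query positions), or both composed in that order.
    Returns the covered original-query interval (0-based half-open).
    """
    if alignment is not None:
        if query_id is None:
            raise ValueError("query_id is required when chaining through an alignment")
        via = alignment_chain(alignment, hit.profile_reference_id, query_id)
        if parent_chain is not None:
            via = {r: parent_chain[q] for r, q in via.items() if q in parent_chain}
    elif parent_chain is not None:
        via = dict(parent_chain)
    else:
        # identity chain: the profile's reference is the original query
        covered = [qp for qp, sp in hit.pairs if qp >= 0 and sp >= 0]
        if not covered:
            return None
        pm = hit_position_map(hit)
        lo = pm[min(covered)]
        hi = pm[max(covered)]
        return int(lo), int(hi) + 1
    covered_q = []
    pm = hit_position_map(hit)
    for qp, sp in hit.pairs:
        if qp < 0 or sp < 0:
            continue
        ref_pos = int(pm[qp])
        if ref_pos not in via:
            continue
        covered_q.append(via[ref_pos])
    if not covered_q:
        return None
    return min(covered_q), max(covered_q) + 1


def hit_position_map(hit: AlignmentHit) -> np.ndarray:
    """The profile position -> reference index map the hit was made with."""
    pm = getattr(hit, "_position_map", None)
    if pm is not None:
        return pm
    # profiles built by this package use the identity map
    n = max(int(qp) for qp, _ in hit.pairs) + 1
    return np.arange(n)


def passes_filters(
    hit: AlignmentHit,
    chained_interval: tuple[int, int] | None,
    original_query_len: int,
    config: CascadeConfig | SearchConfig,
) -> bool:
    """E-value and chained-query-coverage filter (both boundaries inclusive)."""
    if chained_interval is None:
        return False
    if hit.e_value > config.e_value_report:
        return False
    lo, hi = chained_interval
    return (hi - lo) / original_query_len >= config.query_coverage_min


def _hit_row(
    query_id: str, acc: _AccumulatedHit, query_len: int
) -> HitTableRow:
    hit = acc.hit
    lo, hi = acc.chained_interval
    ss, se = hit.s_interval
    return HitTableRow(
        query_id=query_id,
        subject_id=hit.subject_id,
        generation=acc.first_generation,
        bit_score=round(float(hit.bit_score), 4),
        e_value=float(hit.e_value),
        identity_pct=round(100.0 * hit.identity_fraction, 4),
        q_start=lo + 1,
        q_end=hi,
        s_start=acc.subject_offset + ss + 1,
        s_end=acc.subject_offset + se,
        aln_length=hit.aln_length,
        coverage_pct=round(100.0 * (hi - lo) / query_len, 4),
    )


def run_master_blaster(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the full cascade for one query against a database.

    Deterministic given inputs and config.  With ``max_generations=1`` and
    ``max_profiles_per_generation=0`` this degrades exactly to the inner
    iterative search (the PSI-BLAST-equivalent baseline).
    """
    config = config or CascadeConfig()
    if not database:
        raise ValueError("database is empty")
    by_id = {r.id: r for r in database}
    search_cfg = config.search_config()
    N = database_length(database)
    qlen = len(query)
    state = CascadeState()
    per_generation: list[list[HitTableRow]] = []

    # Generation 0: the inner iterative search seeded by the bare query.
    gen0_hits = iterative_search(query, database, matrix, search_cfg)
    new_rows: list[HitTableRow] = []
    for hit in gen0_hits:
        interval = chain_to_query(hit)
        if passes_filters(hit, interval, qlen, config):
            acc = _AccumulatedHit(hit, 0, interval, 0)
            state.accumulated[hit.subject_id] = acc
            new_rows.append(_hit_row(query.id, acc, qlen))
    per_generation.append(new_rows)
    logger.info(
        "query %s generation 0: %d hits", query.id, len(state.accumulated)
    )

    convergence_generation: int | None = None
    for g in range(1, config.max_generations + 1):
        state.generation_index = g
        state.new_ids_this_generation = set()
        if not state.accumulated or config.max_profiles_per_generation == 0:
            state.converged = True
            convergence_generation = g
            break

        # (1) hit sequences, truncated to their aligned regions by default
        subjects: list[SequenceRecord] = []
        offsets: dict[str, int] = {}
        for sid, acc in state.accumulated.items():
            rec = by_id[sid]
            if config.truncate_to_aligned_region:
                ss, se = acc.hit.s_interval
                ss += acc.subject_offset
                se += acc.subject_offset
                residues = rec.residues[ss:se]
                offsets[sid] = ss
            else:
                residues = rec.residues
                offsets[sid] = 0
            if sid == query.id:
                continue  # the query itself re-enters untruncated below
            subjects.append(SequenceRecord(id=sid, residues=residues))

        # (2) redundancy clustering; representatives only proceed
        if subjects:
            clusters = cluster_sequences(
                subjects, matrix, config.cluster_identity, config.cluster_coverage
            )
            reps = [c.representative_id for c in clusters]
        else:
            reps = []
        rep_records = {s.id: s for s in subjects}

        # order representatives by ascending best E-value of their hit
        reps.sort(key=lambda sid: (state.accumulated[sid].hit.e_value, sid))

        # (3) progressive alignment of the query plus representatives
        to_align = [query] + [rep_records[sid] for sid in reps]
        if len(to_align) == 1:
            state.converged = True
            convergence_generation = g
            break
        msa = progressive_align(to_align, matrix, config.gap_open, config.gap_extend)

        # (4) one rescaled PSSM per aligned sequence, query first, capped
        reference_ids = ([query.id] + reps)[: config.max_profiles_per_generation]
        new_rows = []
        for ref_id in reference_ids:
            profile = rescale_profile(build_pssm(msa, ref_id, matrix), matrix)
            # (5) search the database with this PSSM
            hits = search_profile(profile, database, matrix, search_cfg, N)
            chain = alignment_chain(msa, ref_id, query.id)
            for hit in hits:
                hit.generation = g
                # (6) chain back to the original query and filter
                interval = chain_to_query(hit, parent_chain=chain)
                if not passes_filters(hit, interval, qlen, config):
                    continue
                # (7) merge: keep per-subject minimum E-value
                prev = state.accumulated.get(hit.subject_id)
                if prev is None:
                    acc = _AccumulatedHit(hit, g, interval, 0)
                    state.accumulated[hit.subject_id] = acc
                    state.new_ids_this_generation.add(hit.subject_id)
                    new_rows.append(_hit_row(query.id, acc, qlen))
                elif hit.e_value < prev.hit.e_value:
                    state.accumulated[hit.subject_id] = _AccumulatedHit(
                        hit, prev.first_generation, interval, 0
                    )
        per_generation.append(new_rows)
        logger.info(
            "query %s generation %d: %d profiles, %d new hits",
            query.id, g, len(reference_ids), len(state.new_ids_this_generation),
        )
        if not state.new_ids_this_generation:
            state.converged = True
            convergence_generation = g
            break

    final = [
        _hit_row(query.id, acc, qlen)
        for acc in sorted(
            state.accumulated.values(), key=lambda a: (a.hit.e_value, a.hit.subject_id)
        )
    ]
    return CascadeResult(
        query_id=query.id,
        per_generation=per_generation,
        final_table=final,
        converged=state.converged,
        convergence_generation=convergence_generation,
    )
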
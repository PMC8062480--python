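"""Profile search: gapped local alignment, E-values, iterative inclusion.

The searcher plays the role PSI-BLAST plays inside the cascade: a profile
(or, at iteration 1, the bare query scored with BLOSUM62 rows) is aligned
locally against every database sequence, hits are ranked by Karlin-Altschul
E-value, and subjects below the *inclusion* threshold (H-value) are folded
into a query-anchored (master-slave) alignment from which the profile is
rebuilt for the next iteration.  Reporting (E-value) and inclusion (H-value)
thresholds are separate knobs, conventionally set equal.

E-values use the simple m x N search space with the gapped parameters of the
substitution matrix; rescaled profiles are statistically commensurate with
the matrix, so one (lambda, K) pair serves all profiles.  Absolute values
therefore differ from NCBI BLAST's edge-corrected ones; the protocol depends
only on ranking and thresholding.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from ._sw import sw_profile_local
from .alphabet import GAP, X_INDEX, encode
from .scoring import MultipleAlignment, ProfileMatrix, SubstitutionMatrix
from .seqio import SequenceRecord

#: Score assigned to an unknown subject residue (X) at any profile position.
X_SCORE = -1


@dataclasses.dataclass
class SearchConfig:
    """Thresholds and gap costs for one search run.

    ``e_value_report`` gates what is reported, ``h_value_include`` what is
    folded into the next profile; ``query_coverage_min`` is the fraction of
    the *original* query a chained hit must cover.
    """

    e_value_report: float = 1e-3
    h_value_include: float = 1e-3
    max_inner_iterations: int = 5
    gap_open: int = 11
    gap_extend: int = 1
    query_coverage_min: float = 0.70

    def __post_init__(self) -> None:
        if self.h_value_include > self.e_value_report:
            raise ValueError("h_value_include must be <= e_value_report")
        if self.max_inner_iterations < 1:
            raise ValueError("max_inner_iterations must be >= 1")
        if not (0 < self.query_coverage_min <= 1):
            raise ValueError("query_coverage_min must be in (0, 1]")


@dataclasses.dataclass
class AlignmentHit:
    """One best local alignment between a profile and a database sequence.

    Intervals are 0-based half-open; ``q_interval`` is on the profile's
    reference sequence (via position_map), ``s_interval`` on the subject.
    ``pairs`` holds the aligned (profile position, subject position) columns
    with -1 marking gaps.
    """

    profile_reference_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    identity_fraction: float
    pairs: np.ndarray  # (n, 2) int
    generation: int = 0

    @property
    def aligned_profile_positions(self) -> str:
        """Gapped string of reference residues over the aligned columns."""
        out = []
        for qp, _ in self.pairs:
            out.append(GAP if qp < 0 else self._ref_residue(qp))
        return "".join(out)

    def _ref_residue(self, profile_pos: int) -> str:
        return self._reference_residues[profile_pos]

    # set by local_align_profile; kept out of the dataclass signature
    _reference_residues: str = dataclasses.field(default="", repr=False)
    _subject_residues: str = dataclasses.field(default="", repr=False)
    _position_map: "np.ndarray | None" = dataclasses.field(default=None, repr=False)

    @property
    def aligned_subject_residues(self) -> str:
        out = []
        for _, sp in self.pairs:
            out.append(GAP if sp < 0 else self._subject_residues[sp])
        return "".join(out)

    @property
    def aln_length(self) -> int:
        return len(self.pairs)


def single_sequence_profile(
    record: SequenceRecord, matrix: SubstitutionMatrix
) -> ProfileMatrix:
    """The degenerate profile of a bare sequence: verbatim BLOSUM62 rows.

    Makes profile search backward-compatible with plain sequence search: the
    alignment scores equal sequence-sequence Smith-Waterman with the matrix.
    Already on the matrix's statistical scale, so no rescaling is needed.
    """
    enc = encode(record.residues)
    L = len(enc)
    scores = np.zeros((L, 20), dtype=np.int64)
    for i, code in enumerate(enc):
        if code == X_INDEX:
            scores[i] = matrix.x_scores
        else:
            scores[i] = matrix.scores[code]
    return ProfileMatrix(
        reference_id=record.id,
        reference_residues=record.residues,
        scores=scores,
        position_map=np.arange(L),
        scale_lambda=matrix.lambda_ungapped,
    )


def _score_array_with_x(profile: ProfileMatrix) -> np.ndarray:
    full = np.empty((len(profile), 21), dtype=np.int64)
    full[:, :20] = profile.scores
    full[:, 20] = X_SCORE
    return full


def local_align_profile(
    profile: ProfileMatrix,
    subject: SequenceRecord,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentHit | None:
    """Best Smith-Waterman local alignment of a profile against a subject.

    Returns ``None`` when no cell scores positive.  Identity is the fraction
    of aligned (non-gap-pair) columns where the profile's reference residue
    equals the subject residue.
    """
    if len(profile) < 1 or len(subject) < 1:
        raise ValueError("profile and subject must be non-empty")
    subj = encode(subject.residues).astype(np.int64)
    score, n, qi, sj = sw_profile_local(
        _score_array_with_x(profile), subj, gap_open, gap_extend
    )
    if score <= 0:
        return None
    pairs = np.stack([qi, sj], axis=1)
    both = (qi >= 0) & (sj >= 0)
    n_cols = int(both.sum())
    ref = profile.reference_residues
    matches = sum(
        1 for qp, sp in pairs[both] if ref[qp] == subject.residues[sp]
    )
    q_idx = qi[qi >= 0]
    s_idx = sj[sj >= 0]
    q_start = int(profile.position_map[q_idx[0]])
    q_end = int(profile.position_map[q_idx[-1]]) + 1
    hit = AlignmentHit(
        profile_reference_id=profile.reference_id,
        subject_id=subject.id,
        raw_score=float(score),
        bit_score=math.nan,
        e_value=math.nan,
        q_interval=(q_start, q_end),
        s_interval=(int(s_idx[0]), int(s_idx[-1]) + 1),
        identity_fraction=matches / n_cols if n_cols else 0.0,
        pairs=pairs,
    )
    hit._reference_residues = ref
    hit._subject_residues = subject.residues
    hit._position_map = profile.position_map
    return hit


def assign_evalue(
    raw_score: float,
    profile: ProfileMatrix,
    subject_len: int,
    db_total_len: int,
    matrix: SubstitutionMatrix,
) -> tuple[float, float]:
    """Karlin-Altschul (bit_score, e_value) for a raw alignment score.

    E = K * m * N * exp(-lambda_gapped * S) with m the profile length, N the
    total database residue count and S the score converted to the matrix's
    score units via the profile's scale_lambda (a no-op for rescaled
    profiles).  The search space is the plain m x N product without
    edge-effect correction.
    """
    m = len(profile)
    if m <= 0 or db_total_len <= 0:
        raise ValueError("profile length and database length must be positive")
    if raw_score <= 0:
        raise ValueError("raw_score must be positive")
    s_units = raw_score * profile.scale_lambda / matrix.lambda_ungapped
    lam, K = matrix.lambda_gapped, matrix.K_gapped
    bit_score = (lam * s_units - math.log(K)) / math.log(2.0)
    e_value = K * m * db_total_len * math.exp(-lam * s_units)
    return bit_score, e_value


def database_length(database: Sequence[SequenceRecord]) -> int:
    return sum(len(r) for r in database)


def search_profile(
    profile: ProfileMatrix,
    database: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    config: SearchConfig | None = None,
    db_total_len: int | None = None,
) -> list[AlignmentHit]:
    """One best hit per subject with E <= e_value_report, best E first.

    Ties are broken by descending raw score, then subject id.
    """
    config = config or SearchConfig()
    if not database:
        raise ValueError("database is empty")
    N = db_total_len if db_total_len is not None else database_length(database)
    hits: list[AlignmentHit] = []
    for subject in database:
        hit = local_align_profile(profile, subject, config.gap_open, config.gap_extend)
        if hit is None:
            continue
        hit.bit_score, hit.e_value = assign_evalue(
            hit.raw_score, profile, len(subject), N, matrix
        )
        if hit.e_value <= config.e_value_report:
            hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.subject_id))
    return hits


def master_slave_alignment(
    query: SequenceRecord, included: Sequence[AlignmentHit]
) -> MultipleAlignment:
    """Stack subject aligned regions under the query's columns.

    The query is the master: one alignment column per query residue; each
    included subject contributes its aligned residues at the query positions
    its hit aligns them to, and subject insertions relative to the query are
    discarded.  Hits must come from query-referenced profiles.
    """
    L = len(query)
    rows: list[tuple[str, str]] = [(query.id, query.residues)]
    for hit in included:
        row = [GAP] * L
        for qp, sp in hit.pairs:
            if qp >= 0 and sp >= 0:
                row[qp] = hit._subject_residues[sp]
        rows.append((hit.subject_id, "".join(row)))
    return MultipleAlignment(rows)


def iterative_search(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    matrix: SubstitutionMatrix,
    config: SearchConfig | None = None,
) -> list[AlignmentHit]:
    """PSI-BLAST-like inner loop: search, include, rebuild profile, repeat.

    Iteration 1 uses the query's single-sequence profile; later iterations
    rebuild the profile from the master-slave alignment of the query plus all
    subjects seen so far with E <= h_value_include.  Stops when an iteration
    adds no new included subject or at max_inner_iterations; returns the
    final iteration's hits passing e_value_report.
    """
    from .scoring import build_pssm, rescale_profile  # local to avoid cycle

    config = config or SearchConfig()
    N = database_length(database)
    profile = single_sequence_profile(query, matrix)
    included: dict[str, AlignmentHit] = {}
    hits = search_profile(profile, database, matrix, config, N)
    for it in range(1, config.max_inner_iterations):
        new = [
            h for h in hits
            if h.e_value <= config.h_value_include and h.subject_id not in included
        ]
        if not new:
            break
        for h in new:
            included[h.subject_id] = h
        msa = master_slave_alignment(query, list(included.values()))
        profile = rescale_profile(build_pssm(msa, query.id, matrix), matrix)
        hits = search_profile(profile, database, matrix, config, N)
    return hits
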
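"""Substitution matrices, sequence weighting and multi-reference PSSMs.

The central object is the :class:`ProfileMatrix` — an L x 20 position-specific
scoring matrix built from a multiple alignment with one chosen row as the
*reference* sequence.  The cascade builds one such profile per aligned
sequence (each sequence serving in turn as reference), which is what widens
the detectable sequence space relative to a single query-anchored profile.

Score construction follows the classic PSI-BLAST recipe: position-based
(Henikoff-Henikoff) sequence weights, substitution-matrix pseudocounts with
data weight alpha = Nc - 1 (Nc = number of distinct residue types observed in
the column) and pseudocount weight beta (default 10), mixed frequencies
converted to integer log-odds scores.  Profiles are then rescaled so that a
single set of gapped Karlin-Altschul parameters applies to all of them.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, AA_TO_INDEX, BACKGROUND, GAP, X_INDEX

_HALF_BIT = math.log(2.0) / 2.0


@dataclasses.dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer substitution matrix with its statistical parameters.

    ``lambda_ungapped`` is the unique positive solution of
    sum_ab p_a p_b exp(lambda * s_ab) = 1 (nats per score unit);
    ``lambda_gapped``/``K_gapped`` are the Karlin-Altschul parameters for the
    default affine gap costs (open 11, extend 1).
    """

    name: str
    scores: np.ndarray          # (20, 20) int
    x_scores: np.ndarray        # (20,) int, score of each residue against X
    background: np.ndarray      # (20,) float, sums to 1
    lambda_ungapped: float
    lambda_gapped: float
    K_gapped: float

    def score(self, a: str, b: str) -> int:
        return int(self.scores[AA_TO_INDEX[a], AA_TO_INDEX[b]])

    def target_frequencies(self) -> np.ndarray:
        """Implied target frequencies q_ab = p_a p_b 2^(s_ab/2), renormalized."""
        p = self.background
        q = p[:, None] * p[None, :] * np.exp2(self.scores / 2.0)
        return q / q.sum()


def _solve_lambda(moment: "callable", lo: float = 1e-4, hi: float = 10.0,
                  rtol: float = 1e-6) -> float:
    """Bisection for the positive root of moment(lambda) = 1 on [lo, hi].

    ``moment`` must be increasing through 1 on the bracket; callers verify the
    sign change and raise their own error when the bracket fails.
    """
    f_lo, f_hi = moment(lo) - 1.0, moment(hi) - 1.0
    if f_lo >= 0.0 or f_hi <= 0.0:
        raise ValueError("bracket [1e-4, 10] does not contain a positive root")
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if moment(mid) - 1.0 < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_SUPPORTED = ("BLOSUM62",)


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named substitution matrix with background and statistics.

    Only BLOSUM62 (half-bit scores, Robinson-Robinson background,
    gapped lambda 0.267 / K 0.041 for gap costs 11/1) is supported.
    """
    if name.upper() != "BLOSUM62":
        raise ValueError(f"unknown matrix {name!r}; supported: {', '.join(_SUPPORTED)}")
    raw = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    scores = np.zeros((n, n), dtype=np.int64)
    x_scores = np.zeros(n, dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        x_scores[i] = int(raw[a, "X"])
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = int(raw[a, b])
    p = BACKGROUND

    def moment(lam: float) -> float:
        return float(np.sum(p[:, None] * p[None, :] * np.exp(lam * scores)))

    lam_u = _solve_lambda(moment)
    return SubstitutionMatrix(
        name="BLOSUM62",
        scores=scores,
        x_scores=x_scores,
        background=p,
        lambda_ungapped=lam_u,
        lambda_gapped=0.267,
        K_gapped=0.041,
    )


@dataclasses.dataclass
class MultipleAlignment:
    """An ordered multiple alignment: (id, gapped string) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0][1])
        for rid, gapped in self.rows:
            if len(gapped) != ncol:
                raise ValueError(f"row {rid!r} has length {len(gapped)} != {ncol}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == row_id:
                return gapped
        raise KeyError(f"no row with id {row_id!r}")


@dataclasses.dataclass(frozen=True)
class PseudocountPolicy:
    """Pseudocount mixing policy: data weight alpha = Nc - 1, prior weight beta."""

    beta: float = 10.0
    weighting: str = "henikoff"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclasses.dataclass
class ProfileMatrix:
    """An L x 20 position-specific scoring matrix tied to a reference sequence.

    ``position_map[i]`` is the reference-sequence index profile position i
    represents; ``column_map[i]`` the source-alignment column (or -1 when the
    profile was not built from an alignment); ``origin_map[i]`` the
    original-query position the cascade chains position i to (-1 where the
    chain is undefined).  ``scale_lambda`` is the nats-per-score-unit scale of
    ``scores``.
    """

    reference_id: str
    reference_residues: str
    scores: np.ndarray                  # (L, 20) int
    position_map: np.ndarray            # (L,) int, strictly increasing
    scale_lambda: float
    column_map: np.ndarray | None = None
    origin_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.position_map), 20):
            raise ValueError("scores and position_map disagree on profile length")
        if len(self.position_map) and np.any(np.diff(self.position_map) <= 0):
            raise ValueError("position_map must be strictly increasing")

    def __len__(self) -> int:
        return self.scores.shape[0]


def henikoff_weights(msa: MultipleAlignment) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to 1.

    Per column, a residue occurring in s rows among r distinct residue types
    contributes 1/(r*s) to each of those rows; gaps contribute nothing.
    Contributions are averaged over columns and the vector normalized.
    """
    nrow = len(msa.rows)
    ncol = msa.n_columns
    weights = np.zeros(nrow)
    n_used = 0
    for c in range(ncol):
        col = [gapped[c] for _, gapped in msa.rows]
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        n_used += 1
        for i, ch in enumerate(col):
            if ch != GAP:
                weights[i] += 1.0 / (r * counts[ch])
    if n_used == 0:
        raise ValueError("alignment has no non-gap columns")
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate alignment: zero total weight")
    return weights / total


def build_pssm(
    msa: MultipleAlignment,
    reference_id: str,
    matrix: SubstitutionMatrix,
    policy: PseudocountPolicy | None = None,
) -> ProfileMatrix:
    """Build a PSSM from an alignment with ``reference_id``'s row as reference.

    One profile position per non-gap reference residue; columns where the
    reference is gapped are dropped (no insert states).  Observed frequencies
    come from Henikoff-weighted residue counts; substitution-matrix
    pseudocounts g_a = sum_b f_b q_ab / p_b are mixed in as
    Q = (alpha*f + beta*g)/(alpha+beta) with alpha = Nc - 1.  Scores are
    round(ln(Q_a/p_a)/lambda) on the exact half-bit grid (lambda = ln2/2), so
    a single-sequence profile reproduces the substitution-matrix rows;
    :func:`rescale_profile` converts to the matrix's statistical scale.
    """
    policy = policy or PseudocountPolicy()
    try:
        ref_row = msa.row(reference_id)
    except KeyError:
        raise ValueError(f"reference id {reference_id!r} is not a row of the alignment")
    weights = henikoff_weights(msa)
    p = matrix.background
    q = matrix.target_frequencies()
    # C[a, b] = q_ab / p_b, so g = C @ f.
    C = q / p[None, :]

    ref_positions = [c for c, ch in enumerate(ref_row) if ch != GAP]
    L = len(ref_positions)
    scores = np.zeros((L, 20), dtype=np.int64)
    for i, c in enumerate(ref_positions):
        f = np.zeros(20)
        types: set[str] = set()
        for w, (_, gapped) in zip(weights, msa.rows):
            ch = gapped[c]
            if ch == GAP or ch == "X":
                continue
            f[AA_TO_INDEX[ch]] += w
            types.add(ch)
        nc = len(types)
        if nc == 0:
            # Column observed only as gaps/X in every weighted row: fall back
            # to the background (all-zero scores).
            continue
        f /= f.sum()
        alpha = float(nc - 1)
        beta = policy.beta
        g = C @ f
        if alpha + beta > 0:
            Q = (alpha * f + beta * g) / (alpha + beta)
        else:
            Q = f
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum()
        raw = np.log(Q / p) / _HALF_BIT
        scores[i] = _round_half_away(raw)
    reference_residues = "".join(ref_row[c] for c in ref_positions)
    return ProfileMatrix(
        reference_id=reference_id,
        reference_residues=reference_residues,
        scores=scores,
        position_map=np.arange(L),
        scale_lambda=_HALF_BIT,
        column_map=np.asarray(ref_positions),
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def profile_ungapped_lambda(profile: ProfileMatrix, matrix: SubstitutionMatrix) -> float:
    """Solve the profile's own ungapped lambda (nats per score unit).

    The root of (1/L) sum_pos sum_a p_a exp(lambda * s(pos, a)) = 1, found by
    bisection on [1e-4, 10] to relative tolerance 1e-6.  Requires the profile
    to have negative expected score under the background (else no positive
    root exists).
    """
    p = matrix.background
    s = profile.scores.astype(float)

    def moment(lam: float) -> float:
        return float(np.mean(np.exp(lam * s) @ p))

    try:
        return _solve_lambda(moment)
    except ValueError:
        raise ValueError(
            f"profile {profile.reference_id!r} has no positive ungapped lambda "
            "(non-negative expected score under the background)"
        )


def rescale_profile(profile: ProfileMatrix, matrix: SubstitutionMatrix) -> ProfileMatrix:
    """Rescale profile scores so the matrix's Karlin-Altschul statistics apply.

    Solves the profile's own ungapped lambda_u and multiplies all scores by
    lambda_u / matrix.lambda_ungapped (re-rounded to the integer grid), after
    which the profile shares the matrix's lambda and the gapped parameters can
    be used for E-values of any profile.
    """
    if len(profile) < 1:
        raise ValueError("cannot rescale an empty profile")
    lam_u = profile_ungapped_lambda(profile, matrix)
    factor = lam_u / matrix.lambda_ungapped
    new_scores = _round_half_away(profile.scores * factor).astype(np.int64)
    return dataclasses.replace(
        profile, scores=new_scores, scale_lambda=matrix.lambda_ungapped
    )


# --- profile text serialization -------------------------------------------

def profile_to_text(profile: ProfileMatrix) -> str:
    lines = [
        f"#reference_id\t{profile.reference_id}",
        f"#scale_lambda\t{profile.scale_lambda!r}",
        "#pos\tref\t" + "\t".join(AMINO_ACIDS),
    ]
    for i in range(len(profile)):
        lines.append(
            f"{profile.position_map[i]}\t{profile.reference_residues[i]}\t"
            + "\t".join(str(int(s)) for s in profile.scores[i])
        )
    return "\n".join(lines) + "\n"


def profile_from_text(text: str) -> ProfileMatrix:
    reference_id = None
    scale_lambda = None
    positions: list[int] = []
    residues: list[str] = []
    rows: list[list[int]] = []
    for line in text.splitlines():
        if line.startswith("#reference_id\t"):
            reference_id = line.split("\t", 1)[1]
        elif line.startswith("#scale_lambda\t"):
            scale_lambda = float(line.split("\t", 1)[1])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            parts = line.split("\t")
            positions.append(int(parts[0]))
            residues.append(parts[1])
            rows.append([int(x) for x in parts[2:]])
    if reference_id is None or scale_lambda is None:
        raise ValueError("missing profile header lines")
    return ProfileMatrix(
        reference_id=reference_id,
        reference_residues="".join(residues),
        scores=np.asarray(rows, dtype=np.int64),
        position_map=np.asarray(positions),
        scale_lambda=scale_lambda,
    )


def save_profile(profile: ProfileMatrix, path: str | Path) -> None:
    Path(path).write_text(profile_to_text(profile))


def load_profile(path: str | Path) -> ProfileMatrix:
    return profile_from_text(Path(path).read_text())
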
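"""Synthetic SCOP-like databases by simulated divergent evolution.

The generator emulates the structure of a SCOP70-style benchmark set: folds
are mutually unrelated (independent random roots), superfamilies within a
fold, families within a superfamily and members within a family are related
by progressively smaller divergence, producing the identity strata the
search protocol is evaluated on (within-family well above the twilight zone,
cross-family around 20-30% identity, cross-superfamily near background).

Substitutions follow the BLOSUM62-implied conditional replacement
q(b|a) = q_ab / sum_{c != a} q_ac, so simulated divergence is self-consistent
with the scoring system the search uses.  Indels are short (1-3 residues)
and rare so that query-coverage filtering behaves as on real domains.

``make_chain_fixture`` builds the canonical intermediate-sequence scenario:
a query A, an intermediate B detectable from A, and a remote homolog C
detectable from B but not from A — the situation the cascade exists to solve.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, BACKGROUND
from .scoring import SubstitutionMatrix, load_substitution_matrix
from .seqio import ScopLabel, SequenceRecord, parse_sccs


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Shape and divergence of a simulated database.

    Divergences are expected substitutions per site on each branch of the
    hierarchy: members diverge from their family ancestor by
    ``divergence_family``, family ancestors from the superfamily ancestor by
    ``divergence_superfamily``, superfamily ancestors from the fold root by
    ``divergence_fold``; they must increase with hierarchy level.
    """

    n_folds: int = 4
    superfamilies_per_fold: int = 2
    families_per_superfamily: int = 2
    members_per_family: int = 4
    sequence_length: int = 150
    divergence_family: float = 0.3
    divergence_superfamily: float = 0.4
    divergence_fold: float = 0.8
    indel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_folds", "superfamilies_per_fold",
            "families_per_superfamily", "members_per_family",
            "sequence_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (
            self.divergence_family
            <= self.divergence_superfamily
            <= self.divergence_fold
        ):
            raise ValueError("divergences must increase with hierarchy level")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")

    @property
    def n_sequences(self) -> int:
        return (
            self.n_folds
            * self.superfamilies_per_fold
            * self.families_per_superfamily
            * self.members_per_family
        )


def _conditional_replacement(matrix: SubstitutionMatrix) -> np.ndarray:
    """(20, 20) row-stochastic replacement matrix q(b|a), identity excluded."""
    q = matrix.target_frequencies()
    cond = q.copy()
    np.fill_diagonal(cond, 0.0)
    cond /= cond.sum(axis=1, keepdims=True)
    return cond


def random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def evolve_sequence(
    parent: str,
    subs_per_site: float,
    indel_rate: float,
    rng: np.random.Generator,
    matrix: SubstitutionMatrix | None = None,
) -> str:
    """Evolve a child from ``parent`` by point substitutions and short indels.

    Poisson(subs_per_site * L) substitution events hit uniform positions; the
    replacement residue is drawn from the BLOSUM62-implied conditional
    distribution excluding identity.  Poisson(indel_rate * n_substitutions)
    indel events each insert 1-3 background-sampled residues or delete 1-3
    residues at a uniform position; deletions that would empty the sequence
    are rejected.
    """
    if not parent:
        raise ValueError("parent sequence is empty")
    matrix = matrix or _default_matrix()
    cond = _conditional_replacement(matrix)
    seq = list(parent)
    n_subs = rng.poisson(subs_per_site * len(seq))
    for _ in range(n_subs):
        pos = rng.integers(len(seq))
        a = seq[pos]
        if a == "X":
            continue
        a_idx = AMINO_ACIDS.index(a)
        seq[pos] = AMINO_ACIDS[rng.choice(20, p=cond[a_idx])]
    n_indels = rng.poisson(indel_rate * n_subs)
    for _ in range(n_indels):
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion
            pos = int(rng.integers(len(seq) + 1))
            insert = random_sequence(size, rng)
            seq[pos:pos] = list(insert)
        else:  # deletion, rejected if it would empty the sequence
            if len(seq) - size < 1:
                continue
            pos = int(rng.integers(len(seq) - size + 1))
            del seq[pos:pos + size]
    return "".join(seq)


_MATRIX_CACHE: list[SubstitutionMatrix] = []


def _default_matrix() -> SubstitutionMatrix:
    if not _MATRIX_CACHE:
        _MATRIX_CACHE.append(load_substitution_matrix("BLOSUM62"))
    return _MATRIX_CACHE[0]


def simulate_database(spec: SimSpec) -> list[SequenceRecord]:
    """Simulate a labeled SCOP-like database, deterministic under spec.seed.

    Every fold gets an independent background-frequency root; ancestors and
    members are evolved down the hierarchy at the spec's divergences.  Labels
    use sccs form ``a.<fold>.<superfamily>.<family>``.
    """
    rng = np.random.default_rng(spec.seed)
    matrix = _default_matrix()
    records: list[SequenceRecord] = []
    for f in range(1, spec.n_folds + 1):
        root = random_sequence(spec.sequence_length, rng)
        for s in range(1, spec.superfamilies_per_fold + 1):
            sf_anc = evolve_sequence(
                root, spec.divergence_fold, spec.indel_rate, rng, matrix
            )
            for fam in range(1, spec.families_per_superfamily + 1):
                fam_anc = evolve_sequence(
                    sf_anc, spec.divergence_superfamily, spec.indel_rate, rng, matrix
                )
                label = parse_sccs(f"a.{f}.{s}.{fam}")
                for m in range(1, spec.members_per_family + 1):
                    child = evolve_sequence(
                        fam_anc, spec.divergence_family, spec.indel_rate, rng, matrix
                    )
                    records.append(
                        SequenceRecord(
                            id=f"f{f}s{s}f{fam}m{m}",
                            residues=child,
                            label=label,
                        )
                    )
    return records


def label_map_of(records: Sequence[SequenceRecord]) -> dict[str, ScopLabel]:
    return {r.id: r.label for r in records if r.label is not None}


@dataclasses.dataclass
class ChainFixture:
    """A, B, C in one fold (two families) plus unrelated decoys.

    The canonical intermediate-sequence scenario: the query A detects the
    intermediate B directly; the remote homolog C is related to A only
    through B — partly through a divergent copy of the region A and B share,
    partly through a B-specific extension A lacks — so a query-anchored
    profile search from A misses C while a B-referenced profile finds it,
    and C's hit still chains back onto A with high coverage.
    """

    query: SequenceRecord
    intermediate: SequenceRecord
    remote: SequenceRecord
    decoys: list[SequenceRecord]
    identities: dict[str, float]

    @property
    def database(self) -> list[SequenceRecord]:
        return [self.query, self.intermediate, self.remote] + self.decoys

    @property
    def labels(self) -> dict[str, ScopLabel]:
        return label_map_of(self.database)


def make_chain_fixture(
    seed: int,
    core_length: int = 150,
    extension_length: int = 110,
    n_decoys: int = 20,
    step_divergence: float = 1.05,
    core_extra_divergence: float = 1.4,
    extension_divergence: float = 0.9,
    indel_rate: float = 0.05,
    max_attempts: int = 1000,
) -> ChainFixture:
    """Construct the A-B-C intermediate-sequence chain, deterministic per seed.

    B's core is evolved from A at ``step_divergence`` substitutions per site
    (about 35% identity) and B carries a random C-terminal extension; C is
    evolved from B region-wise — the shared core at ``core_extra_divergence``
    (twilight-zone similarity) and the extension at ``extension_divergence``
    (clearly detectable).  Seeds are rejection-sampled until the defining
    detection window holds: direct A-B and B-C alignments are well below the
    1e-3 reporting threshold, the direct A-C alignment and the query-anchored
    iterative profile search from A are both far above it, and a B-referenced
    profile built from the A/B alignment finds C with chained coverage of A
    of at least 0.7.
    """
    from .cascade import alignment_chain, chain_to_query
    from .clustmsa import pairwise_identity, progressive_align
    from .scoring import build_pssm, rescale_profile
    from .search import (
        SearchConfig,
        database_length,
        iterative_search,
        local_align_profile,
        search_profile,
        single_sequence_profile,
        assign_evalue,
    )

    matrix = _default_matrix()
    config = SearchConfig()
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        a_seq = random_sequence(core_length, rng)
        b_core = evolve_sequence(a_seq, step_divergence, indel_rate, rng, matrix)
        b_ext = random_sequence(extension_length, rng)
        c_core = evolve_sequence(b_core, core_extra_divergence, indel_rate, rng, matrix)
        c_ext = evolve_sequence(b_ext, extension_divergence, indel_rate, rng, matrix)
        A = SequenceRecord(id="chainA", residues=a_seq, label=parse_sccs("a.1.1.1"))
        B = SequenceRecord(id="chainB", residues=b_core + b_ext, label=parse_sccs("a.1.1.1"))
        C = SequenceRecord(id="chainC", residues=c_core + c_ext, label=parse_sccs("a.1.1.2"))
        decoys = [
            SequenceRecord(
                id=f"decoy{i + 1:02d}",
                residues=random_sequence(core_length, rng),
                label=parse_sccs(f"a.{i + 2}.1.1"),
            )
            for i in range(n_decoys)
        ]
        database = [A, B, C] + decoys
        N = database_length(database)

        def direct_e(x: SequenceRecord, y: SequenceRecord) -> float:
            prof = single_sequence_profile(x, matrix)
            hit = local_align_profile(prof, y, config.gap_open, config.gap_extend)
            if hit is None:
                return float("inf")
            _, e = assign_evalue(hit.raw_score, prof, len(y), N, matrix)
            return e

        # direct detection window
        if direct_e(A, B) > 1e-6 or direct_e(B, C) > 1e-6:
            continue
        if direct_e(A, C) < 1e-1:
            continue
        # the query-anchored iterative search must miss C ...
        baseline_ids = {
            h.subject_id
            for h in iterative_search(A, database, matrix, config)
        }
        if "chainB" not in baseline_ids or "chainC" in baseline_ids:
            continue
        # ... while a B-referenced profile from the A/B alignment finds it
        # with high chained coverage of A
        msa = progressive_align([A, B], matrix, config.gap_open, config.gap_extend)
        profile = rescale_profile(build_pssm(msa, B.id, matrix), matrix)
        chain = alignment_chain(msa, B.id, A.id)
        c_hits = [
            h for h in search_profile(profile, database, matrix, config, N)
            if h.subject_id == "chainC"
        ]
        if not c_hits:
            continue
        interval = chain_to_query(c_hits[0], parent_chain=chain)
        if interval is None or (interval[1] - interval[0]) / len(A) < 0.7:
            continue

        id_ab, _, _ = pairwise_identity(A, B, matrix)
        id_bc, _, _ = pairwise_identity(B, C, matrix)
        id_ac, _, _ = pairwise_identity(A, C, matrix)
        return ChainFixture(
            query=A,
            intermediate=B,
            remote=C,
            decoys=decoys,
            identities={"AB": id_ab, "BC": id_bc, "AC": id_ac},
        )
    raise RuntimeError(
        f"could not satisfy the chain detection-window constraints in "
        f"{max_attempts} attempts; try different divergence settings"
    )
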
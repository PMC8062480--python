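# Methods

## Scoring system

All scoring rests on BLOSUM62 (loaded from Biopython) with
Robinson–Robinson background frequencies `p`. The matrix's ungapped
Karlin–Altschul parameter λ_u ≈ 0.3176 nats per score unit is solved at load
time as the positive root of Σ_ab p_a p_b e^(λ s_ab) = 1 (bisection on
[10⁻⁴, 10], relative tolerance 10⁻⁶). Gapped statistics use the standard
published values for gap open 11 / extend 1: λ_g = 0.267, K_g = 0.041. A gap
of length k costs open + k·extend (BLAST convention), so the opening
transition pays 12 and each further residue 1.

### PSSM construction

Given a multiple alignment and a chosen reference row, one profile position
is created per non-gap reference residue; columns where the reference is
gapped are dropped (no insert states). Per column:

- **Sequence weights** are position-based (Henikoff–Henikoff): a residue
  occurring in s rows among r distinct residue types contributes 1/(r·s),
  gaps contribute nothing; contributions are averaged over columns and
  normalized.
- **Observed frequencies** f are the weighted residue counts, renormalized.
- **Pseudocount frequencies** g_a = Σ_b f_b q_ab / p_b, where the target
  frequencies are recovered from the half-bit scores as
  q_ab = p_a p_b 2^(s_ab/2) (renormalized) rather than shipped as a second
  table.
- **Mixing** follows the classic PSI-BLAST rule
  Q = (α·f + β·g)/(α+β) with α = N_c − 1 (N_c = distinct residue types
  observed in the column) and β = 10 by default.
- **Scores** are round(ln(Q_a/p_a) / (ln2/2)) — the exact half-bit grid,
  rounding half away from zero. On this grid a single-sequence alignment
  (α = 0) reproduces the BLOSUM62 row of the reference residue exactly,
  which keeps profile search backward-compatible with plain sequence search.

An unknown residue `X` contributes nothing to counts; a subject `X` scores
−1 against every profile position.

### Profile rescaling

Each profile's own ungapped λ is solved from
(1/L) Σ_pos Σ_a p_a e^(λ·s(pos,a)) = 1 and all scores are multiplied by
λ/λ_u (re-rounded to integers). After rescaling every profile shares the
matrix's statistics, so the single gapped (λ_g, K_g) pair prices raw scores
of any profile. E-values use the plain product search space,
E = K_g·m·N·e^(−λ_g·S), with m the profile length and N the total database
residue count — no edge-effect or composition correction, so absolute
E-values differ from NCBI BLAST's; the protocol depends on ranking and
thresholding, not on absolute agreement.

## The search stack

**Local alignment** is full Smith–Waterman with affine gaps over the
profile's score function (numba kernels; no word-hit heuristics — exact DP
is affordable at the package's scale). One best alignment per subject is
returned; identity is counted over aligned non-gap-pair columns.

**The inner iterative search** mirrors PSI-BLAST: iteration 1 uses the bare
query (its single-sequence profile); all subjects ever seen with
E ≤ H-value are stacked under the query's columns master-slave style
(subject insertions relative to the query are discarded), the PSSM is
rebuilt with the query as reference, and the database is re-searched.  The
loop stops when an iteration includes nothing new, or after
`max_inner_iterations` (default 5).

**The cascade** then alternates: collect accumulated hit sequences → cluster
(single-linkage components of the ≥80%-identity, mutual-≥70%-coverage graph;
representative = longest member, ties to the smallest id) → progressively
align the representatives with the original query → build one rescaled PSSM
per aligned row (query first, then representatives by ascending best
E-value, capped at `max_profiles_per_generation`, default 50 — a
tractability guard, disabled by setting it large) → search with every PSSM →
chain every hit back to the original query and filter (E ≤ 10⁻³, chained
coverage ≥ 70%, both inclusive) → merge keeping each subject's minimum
E-value and first generation. Convergence is defined on subject-id novelty,
which guarantees termination under the generation cap. With
`max_generations=1` and `max_profiles_per_generation=0` the cascade degrades
exactly to the inner iterative search; this is the baseline used in all
comparisons.

**Coordinate chaining.** A generation-g hit lives on its profile's
reference, a sequence found earlier. Its aligned profile positions are
mapped through the reference row of the generation alignment to the
alignment columns and on to the original query's row; the covered query
interval (span between the first and last covered position) drives the
coverage filter. Hits whose chain covers no query position are discarded —
a hit reached only through a region the query does not share never counts.

**Full-length re-entry.** Accumulated hits re-enter the next generation
full length rather than cut to their aligned regions. This is deliberate
and load-bearing: the profile built on an intermediate B spans all of B,
including regions the query lacks, and it is exactly those regions that let
the cascade reach homologs invisible to any query-anchored profile (the
chain scenario below). The coverage criterion still disciplines the output,
because every reported hit must chain back onto ≥70% of the original query.
Truncated re-entry is available (`truncate_to_aligned_region=True` /
`--truncate-hits`) for sensitivity analyses.

**The progressive aligner** is intentionally simple: 3-mer multiset
distances → UPGMA (deterministic lexicographic tie-breaking) →
profile-profile merges up the guide tree. Column-pair scores are
frequency-weighted average substitution scores; merges are semi-global
(affine interior gaps, free end gaps), so unshared terminal regions stay as
terminal gap blocks; gaps, once introduced, are never removed. No iterative
refinement — the aligner's job is a reasonable column structure for PSSMs,
not benchmark-grade alignment accuracy.

## Benchmarking

Fold-level, following the SCOP hierarchy encoded in sccs labels
(class.fold.superfamily.family). For one query against a database of D
labeled sequences: a deduplicated reported hit is a TP if it shares the
query's fold, else an FP; FN = (fold size − 1) − TP (self-hits are excluded
everywhere); TN = (D − fold size) − FP, reproducing the worked arithmetic
13,650 − 402 = 13,248 for a 402-member fold. The four rates are
sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP) and
error rate FP/(FP+TP); 0/0 is reported as not-available, never as 0.
Overall metrics pool counts over queries (micro-average); per-fold tables
are also emitted. True positives are partitioned by connection type
(intra-family / cross-family / cross-superfamily), and two hit tables can be
compared by the unique-hit partition: TP pairs present in one and absent
from the other, split the same way. The published improvement ratio is
reproduced as 100·TP_baseline/TP_cascade and labeled `tp_ratio_pct`.

## Synthetic data

`simulate_database` emulates a SCOP70-like benchmark set by simulated
divergent evolution: an independent background-frequency root per fold,
superfamily ancestors at `divergence_fold` expected substitutions/site from
the root, family ancestors at `divergence_superfamily` from those, members
at `divergence_family` from those. Replacements are drawn from the
BLOSUM62-implied conditional q(b|a)/Σ_{c≠a} q(c|a) — self-consistent with
the scoring system, so divergence maps monotonically onto detectability —
and indels are short (1–3 residues) and rare (0.05 per substitution) so
coverage filtering behaves as on real domains. Defaults (4 folds × 2
superfamilies × 2 families × 4 members, 150 residues, divergences
0.3/0.4/0.8) place the identity strata where the method is interesting:
within-family ≈ 55%, cross-family ≈ 25–30% (straddling the detection
threshold), cross-superfamily ≈ background. What the generator does *not*
model: domain architecture, site-rate heterogeneity, composition bias,
real indel length distributions — so passing benchmarks demonstrate the
protocol's mechanics and bookkeeping, not performance on real SCOP data.

`make_chain_fixture` engineers the canonical intermediate-sequence scenario
with known ground truth: B's core is evolved from the query A at ~1.05
subs/site (≈35% identity) and B carries a random 110-residue extension; C is
evolved from B region-wise — the shared core at a further 1.4 subs/site
(twilight zone), the extension at 0.9 (clearly detectable). Seeds are
rejection-sampled until the defining detection window holds: A↔B and B↔C
direct E ≤ 10⁻⁶, A↔C direct E ≥ 0.1, the query-anchored iterative search
misses C, and a B-referenced profile finds C with chained coverage ≥ 0.7.
The window exists because a query-anchored profile can only ever score C
against the core (at half weight), while the B-referenced profile adds B's
extension as near-single-sequence columns — the structural mechanism by
which intermediates extend reach.

## Numerical and degenerate-input choices

- Integer score grids with round-half-away-from-zero everywhere, for
  bit-reproducibility; re-running with identical inputs is bit-identical
  (no hidden randomness; all synthetic randomness is seed-derived).
- Ties: hits sort by (E-value, −raw score, subject id); cluster
  representatives by (−length, id); UPGMA merges by (distance, id pair).
- Alignment columns observed only as gaps/X fall back to background
  (all-zero scores); profiles with non-negative expected score are rejected
  at rescaling (no positive λ root exists).
- A query nothing aligns to converges immediately with an empty result;
  a generation with no clusterable hits terminates the cascade.
- Coordinates are 0-based half-open internally, 1-based inclusive in hit
  tables (BLAST tabular convention).

## Problem sizes

Default test and acceptance runs use the 64-sequence simulated database
(all 64 members as queries, baseline and cascade) and the 23-sequence chain
fixture; both finish in well under a minute on one CPU. The cascade scales
as O(generations × profiles × database residues × query length) in DP cells,
so desk-scale databases (thousands of sequences) remain practical; the
profile cap and the redundancy clustering bound the per-generation cost.

## Known limitations

- E-values are uncorrected (no length/edge or composition adjustment);
  comparisons with NCBI tools should be made on ranks, not absolute values.
- The progressive aligner and the clustering are deliberately simplified
  stand-ins for ClustalW/BLASTClust-class tools; they reproduce behavior,
  not output.
- Only BLOSUM62 is supported; no HMM profiles, no heuristic seeding.
- Fold-level benchmark averages are micro-averages by default; per-fold
  tables are provided for macro-style analyses.
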
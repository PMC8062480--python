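# masterblaster

Cascaded, multi-reference PSSM search for remote protein homology detection,
with SCOP fold-level benchmarking and a synthetic benchmark-database
generator.

## The problem

Remote homologs — proteins that share a fold and an evolutionary origin but
have drifted below ~20–25% sequence identity — are routinely missed by
pairwise sequence search. Two classic remedies are *profiles* (a
position-specific scoring matrix, PSSM, built from a multiple alignment
scores each query position with its own amino-acid preferences) and
*intermediate-sequence search* (if A detects B and B detects C, then C is a
candidate homolog of A even when A never detects C directly). This package
implements a protocol that combines both:

1. **Generation 0.** The query is searched against the database with a
   PSI-BLAST-like iterative profile search (separate reporting threshold,
   the E-value, and profile-inclusion threshold, the H-value).
2. **Each later generation.** The accumulated hits are clustered
   BLASTClust-style (single linkage at ≥80% identity with mutual ≥70%
   coverage), the cluster representatives are multiply aligned together with
   the query, and **one PSSM is built per aligned sequence, each sequence
   serving in turn as the reference** — the multi-PSSM idea. Every PSSM
   searches the database; each hit's coordinates are chained back through
   the alignment onto the original query and kept only if
   E ≤ 10⁻³ and the chained region covers ≥70% of the query.
3. Generations repeat until no new subject qualifies (convergence) or a
   generation cap (default 5) is reached; each subject keeps its best
   E-value and the generation it first appeared in.

Scoring is BLOSUM62 throughout. Alignments are Smith–Waterman with affine
gaps (open 11, extend 1); significance follows Karlin–Altschul statistics,
E = K·m·N·e^(−λS), with every profile rescaled so that one gapped parameter
set (λ = 0.267, K = 0.041) applies. Benchmarking is at the SCOP fold level:
a reported hit is a true positive iff its fold matches the query's, and true
positives are partitioned into intra-family, cross-family and
cross-superfamily connections — the latter two being the remote
relationships the cascade exists to find.

## Worked example

```bash
# a labeled synthetic database: 4 folds x 2 superfamilies x 2 families x 4
# members, 150 residues, divergence increasing up the hierarchy
masterblaster simulate --seed 1 --out db.fasta --labels labels.tsv

# cascade search with one of its members as the query
masterblaster --log-level info search --query query.fasta --db db.fasta \
    --evalue 1e-3 --hvalue 1e-3 --coverage 0.7 --generations 5 --out hits.tsv

# fold-level benchmark of the hit table
masterblaster benchmark --hits hits.tsv --labels labels.tsv --db db.fasta \
    --out report.tsv
```

The same run from Python, on the engineered intermediate-sequence chain
(query A, intermediate B, remote homolog C, 20 decoys):

```python
from masterblaster import (CascadeConfig, load_substitution_matrix,
                           make_chain_fixture, run_master_blaster)

matrix = load_substitution_matrix("BLOSUM62")
fx = make_chain_fixture(seed=1)

baseline = run_master_blaster(fx.query, fx.database, matrix,
                              CascadeConfig(max_generations=1,
                                            max_profiles_per_generation=0))
cascade = run_master_blaster(fx.query, fx.database, matrix, CascadeConfig())
print(sorted(baseline.hit_ids))  # ['chainA', 'chainB']
print(sorted(cascade.hit_ids))   # ['chainA', 'chainB', 'chainC']
for row in cascade.final_table:
    print(row.subject_id, row.generation, f"{row.e_value:.1e}", row.coverage_pct)
```

which prints

```
['chainA', 'chainB']
['chainA', 'chainB', 'chainC']
chainA 0 3.4e-71 100.0
chainB 0 7.2e-63 100.0
chainC 1 2.3e-20 98.0
```

The single-generation baseline (the PSI-BLAST equivalent) reports only the
query itself and the intermediate B; the cascade additionally reaches the
remote homolog C in generation 1, through the PSSM referenced on B, with an
E-value far below the 10⁻³ threshold and 98% chained coverage of the
original query.

## Layout

- `masterblaster.seqio` — FASTA, SCOP sccs labels, 12-column hit tables
- `masterblaster.scoring` — BLOSUM62, Henikoff weights, pseudocount PSSMs,
  profile rescaling
- `masterblaster.search` — profile Smith–Waterman, E-values, the inner
  iterative search
- `masterblaster.clustmsa` — identity clustering, UPGMA, progressive MSA
- `masterblaster.cascade` — the generation loop, coordinate chaining, CLI
  config
- `masterblaster.benchmark` — fold-level TP/FP/TN/FN, the four rates,
  connection-type breakdowns
- `masterblaster.synthetic` — simulated divergent evolution, the chain
  fixture

See `docs/methods.md` for the model, parameter and design details.
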
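# consalign

Consensus multiple sequence alignments from two or more input alignments of
the same sequences, built by dynamic programming over a weighted DAG of
alignment columns. Each consensus column carries a confidence score (the
fraction of input alignments containing it), which feeds a power-law
score→precision model and a score-threshold column filter. A letter-pair
precision/recall/F-score evaluator and a synthetic-alignment simulator round
out the toolkit, so everything is testable without external data.

## How it works

1. Every column of every input alignment is encoded as an N-tuple of
   cumulative per-sequence residue counts; identical columns in different
   alignments get identical keys.
2. The key chains of all k inputs are superimposed into a weighted DAG:
   edge weights count how many inputs contain each column-to-column
   transition.
3. A forward dynamic program selects, per node, the incoming edge
   maximizing `(path_score + weight) / (path_length + 1)`; traceback from
   the sink yields the consensus. Each column's raw score is its traceback
   edge weight; dividing by k gives a normalized score in (0, 1].
4. Normalized scores predict column precision via a fitted power law
   `precision ≈ score^m`, so the expected error of a column is
   `1 − score^m`, and low-scoring columns can be filtered out.

## CLI

```bash
# merge constituent alignments (files or a directory) into a consensus
consalign merge -i a.fasta -i b.fasta -i c.fasta -o consensus.fasta \
    --scores consensus.tsv            # per-column normalized scores
consalign merge -i alignments/ -o consensus.fasta --min-score 0.5

# score an inferred alignment against a reference (letter pairs)
consalign eval --inferred inferred.fasta --reference reference.fasta \
    --per-column columns.tsv

# fit precision = score^m to a TSV of (score, precision) observations
consalign fit --observations obs.tsv --width 0.1 --bins bins.tsv

# generate a synthetic truth alignment + k perturbed constituents
consalign simulate --n-seqs 8 --length 100 --gap-fraction 0.2 \
    --k 5 --perturb-rate 0.2 --seed 1 --outdir sim/
```

Exit codes: 0 success, 1 usage error, 2 data error.

## Library

```python
import consalign as ca

alns = [ca.read_alignment(p) for p in paths]
result = ca.merge(alns)                    # ConsensusResult
result.alignment                           # consensus Alignment
result.normalized_scores                   # per-column scores in (0, 1]

cmp = ca.compare_alignments(result.alignment, reference)
cmp.precision, cmp.recall, cmp.f_score

model = ca.fit_power(ca.bin_columns(observations))
ca.expected_error(model, 0.92)             # predicted column error rate
trimmed = ca.filter_columns(result, min_score=0.5)
```

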
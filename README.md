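# dnafcm

Competing finite-context (Markov) models for whole-genome DNA analysis.

A set of adaptive order-k models (defaults: k = 2,4,…,16) scans a DNA
sequence in a single pass. Every model estimates the next base with the
pseudocount estimator `P(s|c) = (n(s|c)+α)/(N(c)+4α)` and then updates its
counters — both the direct counter and the one addressed by the reverse
complement of `context+symbol`, so inverted repeats contribute statistics.
The sequence is partitioned into fixed-size blocks (default 200 bases); in
each block the model with the smallest accumulated code length wins, its
per-base `−log2 p̂` values form the information profile, and the winning
depth index is charged to an adaptive order-4 side model. Totals are
reported as bits per base (bpb; 2.0 is the random-DNA ceiling). An integer
range coder turns the same probability stream into an actual lossless
bitstream with a verifying decoder.

Low-order models use dense count arrays; orders ≥ 11 use hash-backed
storage, allowing depths up to 16 in modest memory. Hot loops are compiled
with numba; a pure-Python reference model ships alongside and the two are
tested for bit-identical output.

## CLI

```sh
# information profile + summary (TSV, JSON, optional smoothed bedGraph)
dnafcm profile genome.fasta -o out --bedgraph --window 2001

# fixed-order models: best depth, or a bpb-per-depth scan
dnafcm single genome.fasta --scan

# lossless compression round trip
dnafcm encode genome.fasta -o genome.dfcm
dnafcm decode genome.dfcm -o back.fasta   # retained ACGT stream

# synthetic fixtures (iid / Markov / planted direct & inverted repeats)
dnafcm gen --length 100000 --seed 1 -o fixture
dnafcm gen --spec spec.json -o fixture
```

Model flags shared by the analysis commands: `--depths 2,4,6,8,10,12,14,16`,
`--block-size 200`, `--alpha-low 1`, `--alpha-high 1/16`,
`--alpha-threshold 12`, `--side-order 4`, `--no-ir`, plus `--config FILE`
(JSON; flags override the file, the file overrides defaults). Non-ACGT
symbols (N, IUPAC codes) are removed before modeling; profile coordinates
refer to the original sequence.

## Library

```python
from dnafcm import CompetitionConfig, run_multi, run_single, best_single
from dnafcm.seqio import read_filtered

seq = read_filtered("genome.fasta")[0]
res = run_multi(seq, CompetitionConfig())
res.bpb                      # (symbol bits + side-channel bits) / bases
res.records[0].profile.bits  # per-base information content
```

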
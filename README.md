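# ccpalink

Missing-link prediction for undirected, unweighted networks — connectomes,
protein-interaction-style graphs, social and infrastructure networks. Given
only the observed topology, the task is to rank the candidate pairs
L = U − E (the N(N−1)/2 − M node pairs not joined by an edge) by how likely
they are to be missing or future edges.

The headline score is the parameterized common-neighbor + closeness index
(CCPA):

```
S_xy = α · |Γ(x) ∩ Γ(y)|  +  (1 − α) · N / d_xy ,      α ∈ [0, 1]
```

where Γ(x) is the neighborhood of x, k_x = |Γ(x)| its degree, N the node
count and d_xy the shortest-path hop distance. α = 1 reduces to plain
common-neighbor counting; α = 0 to the pairwise closeness term alone.
Eight classic baselines ship alongside it: common neighbors (CN),
CN-and-distance (CND), preferential attachment (PA, k_x·k_y), Adamic–Adar
(Σ 1/ln k_z), resource allocation (Σ 1/k_z), Jaccard, Sørensen and the
hub-promoted index.

Prediction quality is measured with the standard train/probe protocol: the
observed edges are split uniformly at random into a training set E^T
(default 80%) and a probe set E^P; scores are computed **on the training
network only**, and the AUC

```
AUC = (n1 + 0.5 · n2) / n
```

is the probability that a random probe edge outscores a random non-existent
link, with half credit for ties. Experiments repeat over independent splits
(default 15) and report mean ± sample SD; an α sweep reruns CCPA over the
grid {0.1, …, 0.9} on identical splits.

## Worked example

```sh
python examples/rank_missing_links.py
```

```
pair     score
A--D    1.7500
B--D    1.7500
C--E    1.7500
A--E    0.8333
B--E    0.8333
```

The graph is a triangle A–B–C with tail C–D–E. B–D shares the common
neighbor C and sits two hops apart, so at α = 0.5 its score is
0.5·1 + 0.5·(5/2) = 1.75; A–E shares no neighbor and is three hops away,
giving 0.5·(5/3) ≈ 0.83. Ties are broken lexicographically so output is
byte-stable.

Benchmarking on a planted community graph (`python
examples/benchmark_planted.py`, 15 random 80/20 splits each):

```
method   mean AUC   sd (15 runs)
ccpa     0.807      0.027
cn       0.789      0.021
ra       0.792      0.022
aa       0.792      0.022
pa       0.473      0.041
```

Held-out intra-community edges leave a strong common-neighbor signature,
so CN-family scorers beat chance (0.5) comfortably while degree-product PA
does not.

## Command line

The same operations are exposed as a thin CLI over edge-list files
(`node1<ws>node2` per line, `#` comments):

```sh
ccpalink summary graph.edges                   # N, M, <k>, <d> as JSON
ccpalink score graph.edges -m ccpa --alpha 0.8 # ranked candidate TSV
ccpalink evaluate graph.edges -m ccpa -m cn    # repeated-split AUC report
ccpalink sweep graph.edges                     # alpha grid + best alpha
ccpalink simulate --model erdos_renyi -n 100 -p 0.05 -o er.edges
```

Results go to stdout or `-o`; logs go to stderr; every command echoes its
resolved configuration into its output so runs are reproducible from the
echo alone. `--config file.yaml` supplies per-subcommand defaults (flags
win).

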
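"""Benchmark similarity indices with the repeated train/probe AUC protocol.

Generates a planted community graph (dense communities, sparse background),
then runs the full protocol — random 80/20 edge splits, scores computed on
the training network only, AUC = (n1 + 0.5*n2)/n against uniformly drawn
non-edges, repeated 15 times — for several indices. Community structure
means removed edges leave a strong common-neighbor signal, so CN-family
scorers should beat degree-product preferential attachment.
"""

from ccpalink import generate, GeneratorSpec, run_experiment

net = generate(GeneratorSpec("planted_cn", 72, seed=11))
print(f"benchmark graph: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print()
print("method   mean AUC   sd (15 runs)")
for method, params in [
    ("ccpa", {"alpha": 0.8}),
    ("cn", None),
    ("ra", None),
    ("aa", None),
    ("pa", None),
]:
    report = run_experiment(net, method, params, base_seed=42)
    print(f"{report.method:<8} {report.mean_auc:.3f}      {report.sd_auc:.3f}")
print()
print(
    "AUC is the probability that a held-out probe edge outscores a random\n"
    "non-edge (ties count half); 0.5 is chance level. Common-neighbor style\n"
    "indices exploit the planted triadic structure; preferential attachment\n"
    "cannot, because degrees are nearly uniform across communities."
)
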
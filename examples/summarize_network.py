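"""Summary statistics (N, M, <k>, <d>) of a network.

Computes node count, edge count, average degree 2M/N and average BFS hop
distance over connected pairs for Zachary's karate-club network (bundled
with networkx) and for a seeded scale-free graph.
"""

import json

import networkx as nx

from ccpalink import GeneratorSpec, generate, network_summary

karate = nx.karate_club_graph()
print("karate club:", json.dumps(network_summary(karate).to_dict()))

ba = generate(GeneratorSpec("barabasi_albert", 100, seed=7, params={"m": 3}))
print("BA(n=100, m=3):", json.dumps(network_summary(ba).to_dict()))

print()
print(
    "avg_degree is exactly 2M/N; avg_distance averages shortest-path hops\n"
    "over connected unordered pairs only, so it stays defined on graphs\n"
    "with isolated components."
)
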
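"""Rank the candidate (missing) links of a small graph with CCPA.

Builds the five-node fixture (triangle A-B-C with tail C-D-E), scores each
of its five non-edges with S = alpha*|CN| + (1-alpha)*N/d at alpha = 0.5,
and prints the ranking. Higher scores mean the pair is more likely to be a
missing link: pairs that share a neighbor and sit close together win.
"""

from ccpalink import fixture_g5, rank_candidates

net = fixture_g5()
ranked = rank_candidates(net, "ccpa", {"alpha": 0.5})

print("pair     score")
for s in ranked:
    print(f"{s.x}--{s.y}    {s.score:.4f}")
print()
print(
    "B--D, A--D and C--E share a common neighbor and sit two hops apart\n"
    "(score 0.5*1 + 0.5*5/2 = 1.75); A--E and B--E have no common neighbor\n"
    "and are three hops apart (0.5*5/3 = 0.83), so they rank last."
)
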
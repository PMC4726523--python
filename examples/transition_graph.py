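"""Above-neutral transitions between monomorphic states under shunning.

An edge i -> j is drawn when a single j-mutant fixates in an all-i
population with probability above neutral drift (1/Z); edge weights are
relative to 1/Z.  Under shunning no strategy invades Disc above neutral
drift (Disc is evolutionarily robust), yet most discriminators are labelled
Bad, so realized cooperation stays low.
"""

from irdyn import ModelParams, cooperation_index, named_norm, transition_graph

params = ModelParams(Z=50, norm=named_norm("SH"))
eta, result = cooperation_index(params)
graph = transition_graph(result)

print(f"shunning, Z = {params.Z}: eta = {eta:.4f}\n")
for node, attrs in graph.nodes(data=True):
    print(
        f"{node:5s} lambda = {attrs['stationary_probability']:.3f}  "
        f"good fraction = {attrs['good_fraction']:.3f}  "
        f"donation fraction = {attrs['donation_fraction']:.3f}"
    )
print("\nabove-neutral transitions (weight = fixation probability x Z):")
for u, v, attrs in graph.edges(data=True):
    print(f"  {u:5s} -> {v:5s}  {attrs['weight']:.2f}")
out_of_disc = list(graph.successors("Disc"))
print(f"\nDisc outgoing edges: {out_of_disc or 'none — Disc is evolutionarily robust'}")
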
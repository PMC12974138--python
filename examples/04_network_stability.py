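"""Network stability and keystone genera: natural connectivity and MCC.

Compares the robustness of a dense vs a sparse co-occurrence network under
random node removal (natural-connectivity curves) and ranks hub genera by
maximal clique centrality, printed as "rank/N" as network studies report.
"""

import networkx as nx

import microstab as ms

dense = nx.gnp_random_graph(60, 0.15, seed=1)
sparse = nx.gnp_random_graph(60, 0.05, seed=1)

for name, g in (("dense", dense), ("sparse", sparse)):
    nc = ms.natural_connectivity(g)
    curve = ms.robustness_curve(g, strategy="random", n_reps=100, seed=1)
    half = curve.curve[curve.curve["fraction"] == 0.5]["mean_nc"].iloc[0]
    print(f"{name}: intact NC = {nc:.3f}, NC after removing 50% of nodes = {half:.3f}")

print("\nHigher curves mean more redundant closed walks, i.e. a community whose")
print("connectivity survives losing members: the stability argument for the")
print("fibre-supplemented arm's microbiota.\n")

hubs = ms.mcc_scores(dense).head(5)
for _, row in hubs.iterrows():
    print(f"genus node {row['node']}: MCC = {row['mcc']:.0f}, rank {row['rank_label']}")
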
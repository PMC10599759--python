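"""Node-removal induced centrality and the ACC ranking.

Every reaction is removed in turn from the reaction projection of the
stoichiometric matrix; the log2 fold change of the mean eigenvector,
closeness and information centrality of the sensitivity set measures the
removed node's contribution. The Absolute Centrality Contribution (ACC)
aggregates the normalised contributions; the top per-cell decile defines
the "central" reactions.
"""

import warnings

from neurometnet import (
    SyntheticSpec,
    aggregate_acc,
    extract_sensitivity_set,
    generate_toy_network,
    induced_centrality_profile,
    project_reactions,
    select_central,
    solve_fba,
)

warnings.filterwarnings("ignore")

spec = SyntheticSpec(seed=1)
model = generate_toy_network(spec)
sens = extract_sensitivity_set(solve_fba(model))

graph = project_reactions(model)
print(f"reaction graph: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges")

induced = induced_centrality_profile(graph, sens)
labels = dict(zip(model.reaction_ids, model.cell_label))
acc = aggregate_acc(induced, [labels[r] for r in induced.index])
central = select_central(acc, q=90, model=model)

print("\ntop reactions by ACC (P_s, C_s, ACC, central flag):")
for _, row in acc.sort_values("acc", ascending=False).head(8).iterrows():
    print(
        f"  {row.reaction_id:10s} {row.cell_label:9s} "
        f"{row.p_s:6.3f} {row.c_s:6.3f} {row.acc:6.3f} "
        f"{'*' if row.reaction_id in central else ''}"
    )
print(f"\nplanted hub reactions recovered as central: "
      f"{sorted(set(spec.planted_hub_reactions) & central)}")
# The planted high-degree connectors surface in the top decile: the
# topology-based score finds the structural supports of the sensitive
# reactions, not merely the flux carriers.
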
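"""Generate a synthetic neuron-astrocyte model and solve the coupled FBA.

The model couples three neurotransmission workloads -- sodium extrusion,
the astrocyte-neuron lactate shuttle and the glutamate-glutamine cycle --
into one objective and maximises it at steady state.
"""

from neurometnet import SyntheticSpec, generate_toy_network, solve_fba

spec = SyntheticSpec(seed=1)
model = generate_toy_network(spec)
solution = solve_fba(model)

print(f"reactions: {model.n_reactions}, metabolites: {model.n_metabolites}")
print(f"objective (sum of the five workload fluxes): {solution.z:.3f} uM/s")
for rid, meaning in [
    ("NAEF_n", "neuronal sodium efflux"),
    ("LACt_a", "astrocytic lactate efflux"),
    ("LACt_n", "neuronal lactate uptake"),
    ("VGLUT_n", "vesicular glutamate export"),
    ("GLNex_a", "astrocytic glutamine export"),
]:
    print(f"  {rid:8s} {solution.flux(rid):8.3f} uM/s  ({meaning})")

# The sodium efflux saturates its measured cap of 350 uM/s and the
# neuron burns all astrocytic lactate: the cells divide the labour of
# the neurotransmission workload.
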
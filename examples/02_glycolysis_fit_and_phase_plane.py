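"""Fit the astrocytic glycolytic bound and scan a phenotypic phase plane.

The astrocytic glucose-uptake bound is the one free supply parameter: it
is fitted (by bisection) so the neuron can sustain its total ATP demand
of 155 uM/s. The phase plane then shows how the optimum responds to the
available oxygen and glucose.
"""

import numpy as np

from neurometnet import (
    SyntheticSpec,
    compute_phpp,
    fit_astrocytic_glycolysis,
    generate_toy_network,
    solve_fba,
)

model = generate_toy_network(SyntheticSpec(seed=1))

bound, fitted = fit_astrocytic_glycolysis(model, neuronal_atp_demand=155.0)
print(f"fitted astrocytic glucose-uptake bound: {bound:.4f} uM/s")
print("(the smallest supply at which the neuron can spend 155 uM/s of ATP)")

base = solve_fba(model)
glc0 = base.flux("EX_glc")
grid = compute_phpp(
    model,
    oxygen_rates=[base.flux("EX_o2")],
    glucose_rates=np.linspace(glc0 + 1.5, glc0, 4),
    oxygen_reaction="EX_o2",
    glucose_reaction="EX_glc",
)
print("\nglucose uptake ->  objective (uM/s):")
for bg, z in zip(grid.glucose_rates, grid.objective[0]):
    status = f"{z:8.3f}" if np.isfinite(z) else "infeasible"
    print(f"  {-bg:6.3f}          {status}")
# A non-zero slope means the optimal neurotransmission response depends
# on the substrate supply.
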
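# Methods

## Model and optimisation

The analysis operates on constraint-based metabolic models `(S, L_b, U_b, c)`
with per-reaction cell labels (`neuron`, `astrocyte`, `exchange`, inferred
from `_n`/`_a` ID suffixes when absent) and boolean gene–reaction rules.
Flux balance analysis maximises `cᵀv` subject to `Sv = 0`,
`L_b ≤ v ≤ U_b`, solved with the deterministic HiGHS simplex through
`scipy.optimize.linprog`. Reduced costs are taken from the dual solution
(`δᵢ = −(λ_lower,i + λ_upper,i)` of the minimisation form), with the sign
convention that `δᵢ > 0` means relaxing an active bound on `vᵢ` increases
the optimum. Solutions are accepted only if `‖Sv‖_∞ ≤ 1e-6`; reduced costs
above `1e-9` in magnitude define the sensitivity set.

Degenerate optima are possible in principle (alternative flux routings at
equal objective). The solver configuration is deterministic, so outputs are
reproducible; an optional secondary minimisation is deliberately not
applied by default. Where a quantity must be well defined on the whole
optimal face — the astrocytic-glycolysis fit — a two-stage LP pins the
objective at its optimum and then maximises the neuronal ATP-consumption
metric, making the fitted bound independent of which optimal vertex the
solver returns. The fit itself is a bisection on the astrocytic
glucose-uptake bound (tolerance 1e-4 µM/s) for the smallest bound whose
achievable neuronal ATP consumption reaches the demand.

Phenotypic phase planes pin both bounds of the oxygen and glucose exchange
fluxes to each grid value (uptakes are negative exchange fluxes) and store
the full optimal flux vector per cell of the grid; infeasible cells are
flagged and reported as NaN rather than raising.

## Normalisation and scores

The signed pseudo-logarithm is `t = asinh(z/2)/ln 10` followed by min–max
rescaling to [0, 1]; constant input maps to all zeros. Any positive
prefactor of the `asinh` is annihilated by the rescaling, so only the
sign/shape choice is observable; the signed (unsquared) form is used
because it preserves direction, which the downstream [0, 1] rescale then
standardises. Normalisation spans the whole network for each quantity
(a per-cell variant is available as an option). AO and ACC are Euclidean
norms of their normalised component pairs, so AO ∈ [0, √2] and
ACC ∈ [0, √5]. Optimal and central reactions are selected per cell at the
90th percentile (linear interpolation between order statistics; ties at
the cutoff included). Exchange-labelled reactions are pooled into every
cell stratum whose reactions they share a metabolite with, and can be
selected through either stratum.

## Induced centrality

Centrality is computed on the unweighted reaction projection (edges where
two reactions share a non-excluded metabolite; shared-metabolite counts
are retained as edge weights but not used by default). Eigenvector
centrality is a power iteration on `A + I` per connected component
(deterministic uniform start, tolerance 1e-10, at most 1e5 iterations;
the shift keeps bipartite components convergent), max-normalised within
each component. Closeness uses the Wasserman–Faust reachable-fraction
scaling so scores stay comparable on disconnected graphs; information
centrality is the Stephenson–Zelen current-flow form, computed per
component; both come from networkx. Betweenness is available as a fourth
metric for the clustering quality control only — the normative ACC uses
exactly eigenvector, closeness and information.

For each node `x`, the graph without `x` is recomputed and the mean
centrality of the surviving sensitivity-set members (members minus `x`
when `x` belongs to the set) is compared to the corresponding basal mean:
`I_C(x) = log₂(C_basal/C_−x)`, with both means floored at 1e-12 before
the ratio (flagged by a warning) and `I = 0` when the comparison set
empties. One consequence of the reachable-fraction scaling is worth
noting: deleting a node that is unreachable from the set still changes
every survivor's closeness by the `(R−1)/(N−1)` factor, so the
closeness-induced value of an isolated node is the (small, exactly
predictable) log of that factor rather than zero; eigenvector and
information centrality are strictly per-component and give exactly zero.

## Clustering quality control

Each reaction's induced centralities (four metrics) form its profile; the
reaction × reaction Pearson correlation matrix is clustered hierarchically
(Euclidean distance between correlation rows, complete linkage) and
projected by PCA. Zero-variance profiles get zero correlations with a
warning. The separation score is the fraction of cell-labelled reactions
whose 2-cluster assignment matches their cell, maximised over the two
label permutations; exchange reactions are clustered but not scored.

## The synthetic study system

The generator emulates the stimulated glutamatergic synapse with the
measured constraints as defaults: sodium efflux capped at 350 µM/s with
3 Na⁺ per ATP, housekeeping ATP fixed at ≥ 38 µM/s, the stimulated
glycolytic rate pinned at 0.9 × 2.353 = 2.1177 µM/s, astrocytic oxygen
uptake capped at 0.01666 µM/s, and an overall yield of 31 ATP per glucose
(2 glycolytic + 14.5 per pyruvate oxidised). The astrocyte additionally
carries a capped glycogen-derived glucose supply (0.3 µM/s, with a small
ATP cost of mobilisation) and the glutamate–glutamine cycle is governed by
the astrocyte-specific glutamine synthetase capacity (4.138 µM/s);
glutamate is recycled nearly closed, with a 0.05 µM/s spill-over to the
environment. Vesicular glutamate loading costs 0.25 ATP (V-ATPase) and
concentrative glutamine uptake 0.1 ATP (lumped Na-gradient cost). The
default astrocytic glucose-uptake bound is 5 µM/s before fitting.

Beyond this skeleton each cell has an interior chosen to mirror its role
and to give the two cells distinct topological signatures. The neuron —
the network's energy sink — carries a layer of ATP-consuming maintenance
processes pinned at 0.05 µM/s each; because neuronal ATP is slack-buffered
by the maintenance drain, these carry no reduced cost. The astrocyte
carries a biosynthetic web of reactions drawing on ATP, oxygen and the
glucose pool that also feeds lactate export; the carbon draw gives them
non-zero reduced costs, so the astrocytic web joins the sensitivity
interface. Interior slots are split neuron-heavy (the neuron gets five
more). This construction realises, in a 60-reaction model, the structure
the clustering QC is designed to detect: the sensitivity interface is
concentrated on the astrocytic supply side, removals inside the astrocyte
weaken it while removals inside the neuron act as removed competition,
and the nodal contribution profiles of the two cells point in opposite
directions.

Planted ground truth: one hub reaction per cell is wired as a high-degree
connector touching its cell's pools (the neuron hub also bridges to the
shared extracellular glucose/oxygen pools, next to the sensitive
astrocytic supply reactions). Planted differentially expressed genes are
drawn from reactions whose optimality rank is pinned by the flux
constraints, with effects sampled strictly beyond the filtering thresholds
(fold change in [1.4, 3.0] or [0.3, 0.7]; age coefficients in
±[0.01, 0.05]) and significances strictly below the cutoffs, while null
genes sample effects inside the null zone (fold change in [0.85, 1.15],
age coefficients in ±0.003) so that no null can cross an effect threshold
regardless of its significance draw. Threshold filtering therefore
recovers the planted sets with precision = recall = 1 by construction —
the recovery tests check the pipeline's plumbing exactly, not its
robustness to noise. What passing these tests does **not** show: behaviour
on genome-scale reconstructions, on noisy effect sizes near the
thresholds, or on transcript-level count data (effects and p-values are
drawn directly, not simulated from reads).

All generation is a pure function of the seed (`numpy.random.default_rng`);
the seed varies gene–rule assignment and the planted gene draws, while the
network topology is fixed by the constraints.

## Integration stage

Hub genes are the union of `parse_gpr` token sets over optimal ∪ central
reactions, with per-gene provenance; boolean rule structure is flattened
deliberately (membership, not logic, feeds the gene lists). DE filtering
applies the thresholds literally — effect boundaries inclusive
(FC = 1.3 passes), significance cutoffs strict (padj = 0.05 fails); the
aging direction is the coefficient's sign at magnitude ≥ 0.005.
Over-representation is an upper-tail hypergeometric test against the model
gene background with Benjamini–Hochberg correction, testing only sets
overlapping the query in at least two genes (the minimum-cluster rule).
Ortholog translation goes through a local two-column table with
one-to-many expansion; unmapped sources are reported, never dropped
silently.

## Problem sizes and known limitations

Default analyses run on ~60-reaction models (interior slots keep the LP
and the node-removal loops around a second per model); recovery metrics
aggregate 20 generator seeds. The separation score of the clustering QC
is 0.833 on the default conditions — the misassigned nodes are the
inter-cell transporters, whose removal genuinely affects both cells.
Induced centrality recomputes each metric per removal (O(n) solves of an
O(n·m) or O(n³) kernel); for genome-scale models this is the dominant
cost and would need incremental updates. The enrichment stage is a plain
over-representation test: no term-similarity fusion or network-based
grouping of the kind interactive pathway tools apply.
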
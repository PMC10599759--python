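"""Synthetic two-cell models and expression tables with planted ground truth.

The generated network is a deliberately small neuron-astrocyte system
that reproduces the structure of the stimulated glutamatergic synapse:

* each cell carries a glycolysis -> pyruvate -> oxidation skeleton with a
  31 ATP/glucose overall yield (2 glycolytic + 14.5 per pyruvate);
* the astrocyte exports lactate which the neuron imports and oxidises
  (astrocyte-neuron lactate shuttle);
* the neuron exports vesicular glutamate which the astrocyte amidates to
  glutamine and returns (glutamate-glutamine cycle);
* the neuronal Na/K-ATPase extrudes 3 Na+ per ATP, capped at the measured
  350 uM/s sodium efflux, next to a fixed 38 uM/s housekeeping ATP drain
  and a pinned stimulated glycolytic rate of 0.9 x 2.353 uM/s;
* astrocytic oxygen uptake is capped at the co-culture value 0.01666 uM/s,
  and the glutamate-glutamine cycle is governed by the capacity of the
  astrocyte-specific glutamine synthetase.

The coupled neurotransmission objective places weight 1 on exactly five
flux carriers: astrocytic lactate export, neuronal lactate import,
vesicular glutamate export, astrocytic glutamine export and neuronal
sodium efflux.

Beyond the pathway skeleton, each cell carries an interior that mirrors
its physiological role and gives the two cells distinct topological
signatures: the neuron a layer of ATP-consuming maintenance processes
(ion pumps, vesicle cycling, signalling) drawing on its ATP pool, the
astrocyte a biosynthetic web drawing on ATP, oxygen and the glucose pool
that also feeds lactate export -- which is why the astrocytic web joins
the sensitivity interface while the neuronal maintenance layer, buffered
by surplus ATP, does not.

Ground truth is planted on top: hub reactions wired as high-degree
connectors next to the sensitivity interface (they should surface in the
top ACC decile), and differentially-expressed genes whose effects are
drawn strictly beyond the filtering thresholds while every null gene
stays strictly inside the null zone, so threshold filters recover the
planted sets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTRAINTS, FluxConstraints
from .model_io import (
    CELLS,
    DE_COLUMNS,
    GeneSetCollection,
    MetabolicModel,
    ModelValidationError,
    parse_gpr,
    validate_de_table,
)

__all__ = ["SyntheticSpec", "generate_toy_network", "generate_de_tables",
           "generate_pathway_sets", "default_planted_de_genes",
           "identity_mapping_table"]

SUPPORTED_EXCHANGES = ("lactate", "glutamate", "glutamine", "sodium",
                       "glucose", "oxygen")

# Reactions whose optimality rank is pinned by the flux constraints; their
# genes are safe carriers for planted differential expression.
_RELIABLE_OPTIMAL = {
    "neuron": ("NAEF_n", "NAin_n", "NAK_n"),
    "astrocyte": ("GLCt_a", "LACt_a", "LDHr_a"),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``n_core_reactions_per_cell`` is the total internal reaction count per
    cell (pathway skeleton plus low-degree filler branches); 30 keeps the
    LP and the node-removal loops fast while leaving a 10x gap between
    planted hubs and filler connectivity.
    """

    n_core_reactions_per_cell: int = 30
    exchanged_metabolites: tuple[str, ...] = SUPPORTED_EXCHANGES
    planted_hub_reactions: tuple[str, ...] = ("HUB1_n", "HUB1_a")
    planted_de_genes: dict | None = None
    seed: int = 0
    constraints: FluxConstraints = field(default_factory=lambda: DEFAULT_CONSTRAINTS)
    astrocytic_glucose_bound: float = 5.0

    def validate(self) -> None:
        unsupported = set(self.exchanged_metabolites) - set(SUPPORTED_EXCHANGES)
        if unsupported:
            raise ModelValidationError(
                f"unsupported exchanged metabolites: {sorted(unsupported)}; "
                f"supported: {list(SUPPORTED_EXCHANGES)}"
            )
        for required in ("glucose", "oxygen", "lactate"):
            if required not in self.exchanged_metabolites:
                raise ModelValidationError(
                    f"{required} exchange is required for a viable network"
                )
        if ("glutamine" in self.exchanged_metabolites
                and "glutamate" not in self.exchanged_metabolites):
            raise ModelValidationError(
                "glutamine cycling requires glutamate exchange"
            )
        if self.n_core_reactions_per_cell < 16:
            raise ModelValidationError(
                "n_core_reactions_per_cell must be at least 16 to hold the "
                "pathway skeleton"
            )


def _core_reactions(spec: SyntheticSpec):
    """(id, stoichiometry, lb, ub, objective) tuples of the skeleton."""
    c = spec.constraints
    glyc = c.stimulated_glycolysis
    atp_ox = (c.atp_per_glucose - 2.0) / 2.0   # ATP per pyruvate oxidised
    has_na = "sodium" in spec.exchanged_metabolites
    has_glu = "glutamate" in spec.exchanged_metabolites
    has_gln = "glutamine" in spec.exchanged_metabolites

    rxns = [
        # neuron: stimulated glycolysis is pinned at the measured rate,
        # lactate oxidation covers the remaining ATP demand
        ("GLCt_n", {"glc_e": -1, "glc_n": 1}, 0, 10, 0),
        ("HEX_n", {"glc_n": -1, "pyr_n": 2, "atp_n": 2}, glyc, glyc, 0),
        ("O2t_n", {"o2_e": -1, "o2_n": 1}, 0, 1000, 0),
        ("PYRox_n", {"pyr_n": -1, "o2_n": -3, "atp_n": atp_ox}, 0, 1000, 0),
        ("LACt_n", {"lac_e": -1, "lac_n": 1}, 0, 1000, 1),
        ("LDH_n", {"lac_n": -1, "pyr_n": 1}, 0, 1000, 0),
        ("ATPM_n", {"atp_n": -1}, c.housekeeping_atp, 1000, 0),
        # astrocyte: aerobic glycolysis feeding lactate export, plus a
        # capped glycogen-derived glucose supply
        ("GLCt_a", {"glc_e": -1, "glc_a": 1}, 0, spec.astrocytic_glucose_bound, 0),
        ("GLYCO_a", {"glc_a": 1, "atp_a": -0.05}, 0, c.glycogenolysis_capacity, 0),
        ("HEX_a", {"glc_a": -1, "pyr_a": 2, "atp_a": 2}, 0, 1000, 0),
        ("LDHr_a", {"pyr_a": -1, "lac_a": 1}, 0, 1000, 0),
        ("LACt_a", {"lac_a": -1, "lac_e": 1}, 0, 1000, 1),
        ("O2t_a", {"o2_e": -1, "o2_a": 1}, 0, c.astrocytic_oxygen_uptake, 0),
        ("PYRox_a", {"pyr_a": -1, "o2_a": -3, "atp_a": atp_ox}, 0, 1000, 0),
        ("ATPM_a", {"atp_a": -1}, 0, 1000, 0),
        # environment boundary
        ("EX_glc", {"glc_e": -1}, -20, 0, 0),
        ("EX_o2", {"o2_e": -1}, -1000, 0, 0),
        ("EX_lac", {"lac_e": -1}, 0, 1000, 0),
    ]
    if has_na:
        rxns += [
            ("NAin_n", {"na_e": -1, "na_n": 1}, 0, 1000, 0),
            ("NAK_n",
             {"atp_n": -1, "na_n": -c.sodium_per_atp, "na_p": c.sodium_per_atp},
             0, 1000, 0),
            ("NAEF_n", {"na_p": -1, "na_e": 1}, 0, c.sodium_efflux, 1),
            ("EX_na", {"na_e": -1}, -1000, 1000, 0),
        ]
    if has_glu:
        # glutamate is recycled, not consumed: only a small spill-over to
        # the environment is allowed, so the cycle is governed by the
        # astrocyte-specific glutamine synthetase capacity below
        rxns += [
            ("GLUsyn_n", {"pyr_n": -1, "glu_n": 1}, 0, 1000, 0),
            # vesicular loading spends ATP through the V-ATPase
            ("VGLUT_n", {"glu_n": -1, "atp_n": -0.25, "glu_e": 1}, 0, 1000, 1),
            ("GLUt_a", {"glu_e": -1, "glu_a": 1}, 0, 1000, 0),
            ("EX_glu", {"glu_e": -1}, 0, 0.05, 0),
        ]
    if has_gln:
        rxns += [
            ("GS_a", {"glu_a": -1, "atp_a": -1, "gln_a": 1},
             0, c.glutamate_cycle_capacity, 0),
            ("GLNex_a", {"gln_a": -1, "gln_e": 1}, 0, 1000, 1),
            # concentrative glutamine uptake rides the sodium gradient
            # (lumped as an ATP-equivalent cost)
            ("GLNt_n", {"gln_e": -1, "atp_n": -0.1, "gln_n": 1}, 0, 1000, 0),
            ("GLS_n", {"gln_n": -1, "glu_n": 1}, 0, 1000, 0),
            ("EX_gln", {"gln_e": -1}, 0, 1000, 0),
        ]
    return rxns


# Planted hubs are high-degree connectors: the neuron hub bridges the
# neuronal pools to the shared extracellular glucose/oxygen pools (next
# to the sensitive astrocytic supply reactions), the astrocyte hub sits
# inside the astrocytic metabolic web.
_HUB_TOUCHPOINTS = {
    "n": ("glc_n", "pyr_n", "atp_n", "lac_n", "o2_n", "glu_n", "na_n", "na_p",
          "glc_e", "o2_e"),
    "a": ("glc_a", "pyr_a", "atp_a", "lac_a", "o2_a", "glu_a", "gln_a"),
}


def generate_toy_network(spec: SyntheticSpec) -> MetabolicModel:
    """Build the two-cell toy model; a pure function of the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rxns = _core_reactions(spec)
    rxn_ids = {r[0] for r in rxns}
    met_ids: list[str] = []
    seen = set()
    for _, stoich, *_ in rxns:
        for met in stoich:
            if met not in seen:
                seen.add(met)
                met_ids.append(met)

    # planted hub reactions: high-degree connectors feeding a dead-end
    # product, so they add topology without carrying flux
    for hub in spec.planted_hub_reactions:
        suffix = hub.rsplit("_", 1)[-1]
        if suffix not in _HUB_TOUCHPOINTS:
            raise ModelValidationError(
                f"planted hub reaction {hub!r} must end in '_n' or '_a'"
            )
        touch = [m for m in _HUB_TOUCHPOINTS[suffix] if m in seen]
        product = f"hubint_{hub}"
        met_ids.append(product)
        seen.add(product)
        stoich = {m: -1.0 for m in touch}
        stoich[product] = 1.0
        rxns.append((hub, stoich, 0, 1000, 0))
        rxn_ids.add(hub)

    # Cell interiors beyond the skeleton.  Both cells draw on their ATP
    # pool, which is slack-buffered by the maintenance drain, so none of
    # these reactions acquires a reduced cost.  The neuron interior is a
    # flat layer of ATP-consuming maintenance processes (ion pumps,
    # vesicle cycling, signalling) running at a small fixed rate; the
    # astrocyte interior is a branched metabolic web of ATP-anchored
    # side-chains (glycogen turnover, biosynthesis), giving the two
    # cells distinct topological signatures.
    counts = {
        "n": sum(1 for r in rxns if r[0].endswith("_n")),
        "a": sum(1 for r in rxns if r[0].endswith("_a")),
    }
    # Interior slots are split neuron-heavy (the stimulated neuron is
    # the network's energy sink, carrying more ATP-consuming
    # maintenance processes than the astrocyte carries web reactions).
    total_interior = 2 * spec.n_core_reactions_per_cell - counts["n"] - counts["a"]
    n_drains = max((total_interior + 5) // 2, 0)
    n_web = max(total_interior - n_drains, 0)
    for i in range(n_drains):
        rxns.append((f"MNT{i}_n", {"atp_n": -1.0}, 0.05, 0.05, 0))
    for i in range(n_web):
        # astrocytic biosynthesis draws on the glucose pool that also
        # feeds lactate export, so these reactions carry a reduced cost
        # and join the sensitivity interface
        rxns.append(
            (f"WEB{i}_a",
             {"atp_a": -1.0, "glc_a": -0.01, "o2_a": -0.01}, 0.05, 0.05, 0)
        )

    # gene-reaction rules over synthetic gene IDs; boundary exchanges are
    # spontaneous (no gene), everything else gets at least one gene
    gene_counter = 0
    gprs = []
    for rid, *_ in rxns:
        if rid.startswith("EX_"):
            gprs.append("")
            continue
        suffix = rid.rsplit("_", 1)[-1]
        draw = rng.random()
        if draw < 0.7:
            genes = [f"g{gene_counter:03d}_{suffix}"]
            gene_counter += 1
            rule = genes[0]
        elif draw < 0.9:
            genes = [f"g{gene_counter:03d}_{suffix}",
                     f"g{gene_counter + 1:03d}_{suffix}"]
            gene_counter += 2
            rule = f"{genes[0]} and {genes[1]}"
        else:
            genes = [f"g{gene_counter + k:03d}_{suffix}" for k in range(3)]
            gene_counter += 3
            rule = f"({genes[0]} and {genes[1]}) or {genes[2]}"
        gprs.append(rule)

    n, m = len(met_ids), len(rxns)
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((n, m))
    lb = np.zeros(m)
    ub = np.zeros(m)
    obj = np.zeros(m)
    rids = []
    for j, (rid, stoich, lo, hi, c_j) in enumerate(rxns):
        rids.append(rid)
        for met, coef in stoich.items():
            S[met_index[met], j] = coef
        lb[j], ub[j], obj[j] = lo, hi, c_j
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coefficients=obj,
        gpr=gprs,
    )


def default_planted_de_genes(model: MetabolicModel, spec: SyntheticSpec) -> dict:
    """Planted DE layout: genes of reactions with pinned optimality rank.

    Returns ``{(condition, cell): (up_set, down_set)}`` covering all four
    cell x condition strata.
    """
    def genes_of(rid):
        return parse_gpr(model.gpr[model.reaction_index(rid)])

    present = set(model.reaction_ids)
    layout = {}
    for cell in CELLS:
        pool = [r for r in _RELIABLE_OPTIMAL[cell] if r in present]
        if len(pool) < 2:
            raise ModelValidationError(
                f"not enough reliably-optimal reactions for cell {cell!r}"
            )
        layout[("neurotransmission", cell)] = (genes_of(pool[0]), genes_of(pool[1]))
        layout[("aging", cell)] = (genes_of(pool[-1]), genes_of(pool[0]))
    return layout


def generate_de_tables(model: MetabolicModel, spec: SyntheticSpec) -> pd.DataFrame:
    """Differential-expression table with planted effects past the thresholds.

    Null genes draw fold-changes in [0.85, 1.15] and age coefficients in
    [-0.003, 0.003] so that no null crosses an effect cutoff regardless of
    its significance draw; planted genes draw both effect and significance
    strictly past the cutoffs.  The filters therefore recover the planted
    sets with precision = recall = 1 by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(model.genes())
    planted = spec.planted_de_genes
    if planted is None:
        planted = default_planted_de_genes(model, spec)
    gene_set = set(genes)
    for (condition, cell), (up, down) in planted.items():
        missing = (set(up) | set(down)) - gene_set
        if missing:
            raise ModelValidationError(
                f"planted genes absent from model gene-reaction rules: "
                f"{sorted(missing)} in stratum ({condition}, {cell})"
            )

    rows = []
    for condition in ("neurotransmission", "aging"):
        for cell in CELLS:
            up, down = planted.get((condition, cell), (set(), set()))
            for gene in genes:
                if condition == "neurotransmission":
                    if gene in up:
                        effect = rng.uniform(1.4, 3.0)
                        sig = rng.uniform(1e-4, 0.04)
                    elif gene in down:
                        effect = rng.uniform(0.3, 0.7)
                        sig = rng.uniform(1e-4, 0.04)
                    else:
                        effect = rng.uniform(0.85, 1.15)
                        sig = rng.uniform(0.0, 1.0)
                else:
                    if gene in up:
                        effect = rng.uniform(0.01, 0.05)
                        sig = rng.uniform(1e-4, 0.009)
                    elif gene in down:
                        effect = rng.uniform(-0.05, -0.01)
                        sig = rng.uniform(1e-4, 0.009)
                    else:
                        effect = rng.uniform(-0.003, 0.003)
                        sig = rng.uniform(0.0, 1.0)
                rows.append((gene, effect, sig, cell, condition))
    table = pd.DataFrame(rows, columns=DE_COLUMNS)
    return validate_de_table(table)


def generate_pathway_sets(
    model: MetabolicModel, spec: SyntheticSpec, n_random_sets: int = 3,
    random_set_size: int = 8,
) -> GeneSetCollection:
    """GMT-style pathway collection with one planted enriched pathway.

    The planted pathway concentrates planted DE hub genes, so an
    over-representation test against the model's gene background must
    flag it; the remaining sets are uniform draws from the background.
    """
    genes = sorted(model.genes())
    if not genes:
        raise ModelValidationError("model has no genes")
    rng = np.random.default_rng(spec.seed + 2)
    planted = spec.planted_de_genes
    if planted is None:
        planted = default_planted_de_genes(model, spec)
    planted_pool = sorted(set().union(*(u | d for u, d in planted.values())))
    core = planted_pool[: max(4, min(len(planted_pool), 5))]
    filler_pool = [g for g in genes if g not in core]
    planted_set = set(core)
    if filler_pool:
        planted_set.add(filler_pool[int(rng.integers(len(filler_pool)))])
    sets = {"planted_pathway": planted_set}
    descriptions = {"planted_pathway": "pathway concentrating planted DE hub genes"}
    for i in range(n_random_sets):
        members = rng.choice(genes, size=min(random_set_size, len(genes)),
                             replace=False)
        sets[f"random_pathway_{i + 1}"] = set(members)
        descriptions[f"random_pathway_{i + 1}"] = "background draw"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def identity_mapping_table(genes) -> pd.DataFrame:
    """Identity ortholog map for synthetic gene IDs (source == target)."""
    genes = sorted(genes)
    return pd.DataFrame({"source_id": genes, "target_id": genes})
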
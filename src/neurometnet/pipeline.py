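"""End-to-end analysis: FBA -> AO -> ACC -> differential hub genes.

Chains the individual stages with their default settings so a model plus
a DE table yields hub genes, DHG and enrichment in one call.  Each stage
remains available separately for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .centrality import (
    CorrelationClusteringResult,
    aggregate_acc,
    correlation_clustering,
    induced_centrality_profile,
    project_reactions,
    select_central,
)
from .fba import FBASolution, SensitivitySet, extract_sensitivity_set, solve_fba
from .integration import DHGResult, derive_dhg, enrich_gene_sets, filter_de_genes, hub_genes
from .model_io import CELLS, CONDITIONS, GeneSetCollection, MetabolicModel
from .optimality import optimality_table

__all__ = ["AnalysisResult", "run_analysis"]

QC_METRICS = ("eigenvector", "closeness", "information", "betweenness")


@dataclass
class AnalysisResult:
    solution: FBASolution
    sensitivity: SensitivitySet
    optimality: pd.DataFrame
    induced: pd.DataFrame
    acc: pd.DataFrame
    optimal_reactions: set[str]
    central_reactions: set[str]
    clustering: CorrelationClusteringResult | None
    dhg: DHGResult | None
    enrichment: pd.DataFrame | None


def run_analysis(
    model: MetabolicModel,
    de_table: pd.DataFrame | None = None,
    pathways: GeneSetCollection | None = None,
    q: float = 90.0,
    sensitivity_tolerance: float = 1e-9,
    exclude_metabolites: list[str] | None = None,
    run_clustering_qc: bool = True,
    min_overlap: int = 2,
) -> AnalysisResult:
    """Run the full integrative analysis on one model.

    The flux stage solves the coupled-objective FBA and extracts the
    sensitivity set from the reduced costs; the topology stage computes
    induced centralities of every reaction with respect to that set and
    classifies the top per-cell ACC decile as central; hub genes are the
    genes behind optimal and central reactions, intersected per stratum
    with the filtered DE sets into differential hub genes.
    """
    solution = solve_fba(model)
    sensitivity = extract_sensitivity_set(solution, tolerance=sensitivity_tolerance)
    ao = optimality_table(model, solution, q=q)
    optimal = set(ao.loc[ao["is_optimal"], "reaction_id"])

    graph = project_reactions(model, exclude_metabolites=exclude_metabolites)
    induced = induced_centrality_profile(graph, sensitivity)
    labels = {r: c for r, c in zip(model.reaction_ids, model.cell_label)}
    acc = aggregate_acc(induced, [labels[r] for r in induced.index])
    central = select_central(acc, q=q, model=model)

    clustering = None
    if run_clustering_qc:
        qc_profile = induced_centrality_profile(graph, sensitivity, metrics=QC_METRICS)
        clustering = correlation_clustering(
            qc_profile, [labels[r] for r in qc_profile.index]
        )

    dhg_result = None
    enrichment = None
    if de_table is not None:
        genes, provenance = hub_genes(model, optimal, central)
        de_sets = {
            (condition, cell): filter_de_genes(de_table, condition, cell)
            for condition in CONDITIONS
            for cell in CELLS
            if ((de_table["condition"] == condition)
                & (de_table["cell"] == cell)).any()
        }
        dhg_result = derive_dhg(genes, de_sets, provenance)
        if pathways is not None:
            background = model.genes()
            query = dhg_result.all_dhg()
            if query:
                enrichment = enrich_gene_sets(
                    query, background, pathways, min_overlap=min_overlap
                )

    return AnalysisResult(
        solution=solution,
        sensitivity=sensitivity,
        optimality=ao,
        induced=induced,
        acc=acc,
        optimal_reactions=optimal,
        central_reactions=central,
        clustering=clustering,
        dhg=dhg_result,
        enrichment=enrichment,
    )
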
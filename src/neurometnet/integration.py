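"""From reaction sets to differential hub genes and pathway enrichment.

Hub genes are the genes associated (through gene-reaction rules) with the
union of the optimal and central reactions.  Intersecting them with the
differential-expression sets of each cell x condition stratum yields the
differential hub genes (DHG): the genes that matter for the
neurotransmission workload *and* change during neurotransmission or
brain aging.  A hypergeometric over-representation test against gene-set
collections characterises the DHG functionally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_io import CELLS, CONDITIONS, GeneSetCollection, MetabolicModel, parse_gpr

__all__ = [
    "DE_THRESHOLDS",
    "DHGResult",
    "hub_genes",
    "map_gene_ids",
    "filter_de_genes",
    "derive_dhg",
    "enrich_gene_sets",
]

logger = logging.getLogger(__name__)

# Literal filtering thresholds: effect boundaries inclusive, significance
# cutoffs strict.  Neurotransmission effects are fold-changes
# (stimulated/basal); aging effects are age coefficients whose 0.005
# magnitude corresponds to a 10% fold change.
DE_THRESHOLDS = {
    "neurotransmission": {"up": 1.3, "down": 0.77, "significance": 0.05},
    "aging": {"coefficient": 0.005, "significance": 0.01},
}


@dataclass
class DHGResult:
    """Differential hub genes per stratum, with provenance."""

    hub_genes: set[str]
    provenance: dict[str, dict]               # gene -> {sources, reactions}
    de_sets: dict = field(default_factory=dict)    # (condition, cell) -> (up, down)
    dhg: dict = field(default_factory=dict)        # (condition, cell) -> {gene: dir}

    def all_dhg(self) -> set[str]:
        out: set[str] = set()
        for stratum in self.dhg.values():
            out |= set(stratum)
        return out


def hub_genes(
    model: MetabolicModel, optimal_rxns: set, central_rxns: set
) -> tuple[set[str], dict]:
    """Union of genes behind the optimal and central reactions.

    Returns the gene set and a provenance map recording, per gene, the
    source categories ('optimal'/'central') and reactions it came from.
    Reactions with empty gene-reaction rules contribute nothing.
    """
    known = set(model.reaction_ids)
    for name, rxns in (("optimal", optimal_rxns), ("central", central_rxns)):
        unknown = set(rxns) - known
        if unknown:
            raise KeyError(f"{name} reactions not in model: {sorted(unknown)}")
    genes: set[str] = set()
    provenance: dict[str, dict] = {}
    for source, rxns in (("optimal", optimal_rxns), ("central", central_rxns)):
        for rid in sorted(rxns):
            rule = model.gpr[model.reaction_index(rid)]
            members = parse_gpr(rule)
            if not members:
                logger.info("reaction %s has no gene association; skipped", rid)
                continue
            for gene in members:
                genes.add(gene)
                entry = provenance.setdefault(
                    gene, {"sources": set(), "reactions": set()}
                )
                entry["sources"].add(source)
                entry["reactions"].add(rid)
    return genes, provenance


def map_gene_ids(genes: set, mapping: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Translate gene IDs through a two-column (source, target) table.

    One-to-many rows expand to all targets.  Returns the mapped set and
    the set of sources without any mapping.
    """
    if len(mapping) == 0 and genes:
        warnings.warn("empty mapping table: all genes unmapped", stacklevel=2)
        return set(), set(genes)
    lookup: dict[str, set[str]] = {}
    for src, tgt in zip(mapping.iloc[:, 0], mapping.iloc[:, 1]):
        lookup.setdefault(str(src), set()).add(str(tgt))
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for gene in genes:
        if gene in lookup:
            mapped |= lookup[gene]
        else:
            unmapped.add(gene)
    return mapped, unmapped


def filter_de_genes(
    table: pd.DataFrame, condition: str, cell: str
) -> tuple[set[str], set[str]]:
    """Up/down gene sets of one stratum under the literal thresholds.

    Neurotransmission: up iff FC >= 1.3, down iff FC <= 0.77, both with
    adjusted p < 0.05.  Aging: up iff coefficient >= 0.005, down iff
    <= -0.005, with FDR < 0.01.  Effect boundaries are inclusive,
    significance cutoffs strict.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if cell not in CELLS:
        raise ValueError(f"unknown cell {cell!r}")
    for col in ("gene_id", "effect", "significance", "cell", "condition"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    rows = table[(table["condition"] == condition) & (table["cell"] == cell)]
    if condition == "neurotransmission":
        t = DE_THRESHOLDS["neurotransmission"]
        sig = rows["significance"] < t["significance"]
        up = rows[(rows["effect"] >= t["up"]) & sig]
        down = rows[(rows["effect"] <= t["down"]) & sig]
    else:
        t = DE_THRESHOLDS["aging"]
        sig = rows["significance"] < t["significance"]
        up = rows[(rows["effect"] >= t["coefficient"]) & sig]
        down = rows[(rows["effect"] <= -t["coefficient"]) & sig]
    return set(up["gene_id"]), set(down["gene_id"])


def derive_dhg(
    hub: set[str],
    de_sets: dict,
    provenance: dict | None = None,
) -> DHGResult:
    """Intersect hub genes with the DE sets of every stratum.

    ``de_sets`` maps (condition, cell) to (up_set, down_set).  Genes both
    up and down (impossible within one stratum under the thresholds) are
    tagged 'ambiguous'.
    """
    result = DHGResult(
        hub_genes=set(hub),
        provenance=provenance or {},
        de_sets=dict(de_sets),
    )
    for stratum, (up, down) in de_sets.items():
        tags: dict[str, str] = {}
        for gene in sorted(hub & (set(up) | set(down))):
            if gene in up and gene in down:
                tags[gene] = "ambiguous"
            else:
                tags[gene] = "up" if gene in up else "down"
        result.dhg[stratum] = tags
    return result


def enrich_gene_sets(
    query: set,
    background: set,
    collection: GeneSetCollection,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the background before testing; only sets
    overlapping the query in at least ``min_overlap`` genes are tested
    (the minimum-genes-per-cluster rule).  The p-value is the upper tail
    P(X >= overlap) of drawing |query| genes without replacement from the
    background; q-values are Benjamini-Hochberg across tested sets.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for name, members in collection.items():
        in_bg = set(members) & background
        overlap = len(in_bg & query)
        if overlap < min_overlap:
            continue
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(background), len(in_bg), len(query)
            )
        )
        rows.append(
            {
                "set_name": name,
                "overlap_count": overlap,
                "set_size": len(in_bg),
                "query_size": len(query),
                "background_size": len(background),
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_count", "set_size", "query_size",
                 "background_size", "p_value"],
    )
    if len(result):
        result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result
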
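"""Constraint-based model container and I/O.

The in-memory representation is a light dataclass holding the
stoichiometric matrix `S` (metabolites x reactions), flux bounds, the
objective vector and per-reaction annotations (cell label and
gene-protein-reaction rule).  Models are read and written either in a
JSON dialect mirroring the common constraint-based layout (reactions with
metabolite:coefficient maps, bounds, ``gene_reaction_rule`` and
``objective_coefficient``, plus a ``cell_label`` annotation) or as SBML
Level 3 (via COBRApy/libSBML).

Tabular inputs of the downstream integration stage -- differential
expression tables, gene-set collections (GMT) and ortholog mapping tables
-- also live here.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicModel",
    "GeneSetCollection",
    "ModelValidationError",
    "GPRParseError",
    "read_model",
    "write_model",
    "parse_gpr",
    "read_de_table",
    "write_de_table",
    "validate_de_table",
    "read_gmt",
    "write_gmt",
    "read_mapping_table",
]

CELLS = ("neuron", "astrocyte")
CONDITIONS = ("neurotransmission", "aging")

DE_COLUMNS = ["gene_id", "effect", "significance", "cell", "condition"]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised for malformed gene-protein-reaction expressions."""


def infer_cell_label(reaction_id: str) -> str:
    """Cell assignment from the reaction-ID compartment suffix.

    ``*_n`` reactions belong to the neuron, ``*_a`` to the astrocyte;
    anything else (boundary exchanges, inter-cell carriers without a
    suffix) is tagged ``exchange``.
    """
    if reaction_id.endswith("_n"):
        return "neuron"
    if reaction_id.endswith("_a"):
        return "astrocyte"
    return "exchange"


@dataclass
class MetabolicModel:
    """A two-cell constraint-based metabolic model.

    ``S`` is dense (metabolites x reactions); toy and brain-scale models
    alike are far below the size where sparsity matters for this
    analysis.  Bounds and fluxes are in uM/s.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_coefficients: np.ndarray
    cell_label: list[str] = field(default_factory=list)
    gpr: list[str] = field(default_factory=list)
    compartment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coefficients = np.asarray(
            self.objective_coefficients, dtype=float
        )
        if not self.cell_label:
            self.cell_label = [infer_cell_label(r) for r in self.reaction_ids]
        if not self.gpr:
            self.gpr = [""] * self.n_reactions
        if not self.compartment:
            self.compartment = [m.rsplit("_", 1)[-1] for m in self.metabolite_ids]
        self.validate()

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def validate(self) -> None:
        n, m = self.n_metabolites, self.n_reactions
        if m == 0:
            raise ModelValidationError("model has no reactions")
        if self.S.shape != (n, m):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected {(n, m)}"
            )
        for vec, name in [
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
            (self.objective_coefficients, "objective_coefficients"),
        ]:
            if vec.shape != (m,):
                raise ModelValidationError(f"{name} length != n_reactions")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            rxn = self.reaction_ids[bad[0]]
            raise ModelValidationError(
                f"reaction {rxn!r}: lower bound {self.lower_bounds[bad[0]]} "
                f"exceeds upper bound {self.upper_bounds[bad[0]]}"
            )
        if len(set(self.reaction_ids)) != m:
            raise ModelValidationError("duplicate reaction IDs")
        if len(set(self.metabolite_ids)) != n:
            raise ModelValidationError("duplicate metabolite IDs")
        if len(self.cell_label) != m or len(self.gpr) != m:
            raise ModelValidationError("per-reaction annotation length mismatch")

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def genes(self) -> set[str]:
        """All gene IDs appearing in any gene-reaction rule."""
        out: set[str] = set()
        for rule in self.gpr:
            out |= parse_gpr(rule)
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coefficients=self.objective_coefficients.copy(),
            cell_label=list(self.cell_label),
            gpr=list(self.gpr),
            compartment=list(self.compartment),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(
                self.objective_coefficients, other.objective_coefficients
            )
            and self.cell_label == other.cell_label
            and self.gpr == other.gpr
            and self.compartment == other.compartment
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-style)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ModelValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


_GPR_TOKEN = re.compile(r"[()\s]+")


def parse_gpr(expression: str) -> set[str]:
    """Extract the set of gene IDs from a boolean gene-reaction rule.

    The AND/OR structure is flattened: only gene membership matters for
    hub-gene assembly, so ``"(g1 and g2) or g1"`` yields ``{g1, g2}``.
    """
    if expression is None:
        return set()
    expr = expression.strip()
    if not expr:
        return set()
    depth = 0
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise GPRParseError(f"unbalanced parentheses in {expression!r}")
    if depth != 0:
        raise GPRParseError(f"unbalanced parentheses in {expression!r}")
    tokens = [t for t in _GPR_TOKEN.split(expr) if t]
    return {t for t in tokens if t.lower() not in ("and", "or")}


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        coeffs = {
            model.metabolite_ids[i]: float(model.S[i, j])
            for i in np.nonzero(model.S[:, j])[0]
        }
        reactions.append(
            {
                "id": rid,
                "metabolites": coeffs,
                "lower_bound": float(model.lower_bounds[j]),
                "upper_bound": float(model.upper_bounds[j]),
                "gene_reaction_rule": model.gpr[j],
                "objective_coefficient": float(model.objective_coefficients[j]),
                "cell_label": model.cell_label[j],
            }
        )
    metabolites = [
        {"id": mid, "compartment": comp}
        for mid, comp in zip(model.metabolite_ids, model.compartment)
    ]
    return {"metabolites": metabolites, "reactions": reactions}


def _model_from_dict(data: dict) -> MetabolicModel:
    metabolite_ids = [m["id"] for m in data["metabolites"]]
    compartment = [m.get("compartment", "") for m in data["metabolites"]]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reactions = data["reactions"]
    n, m = len(metabolite_ids), len(reactions)
    S = np.zeros((n, m))
    lb = np.zeros(m)
    ub = np.zeros(m)
    obj = np.zeros(m)
    rids, labels, gprs = [], [], []
    for j, rxn in enumerate(reactions):
        rids.append(rxn["id"])
        for met, coef in rxn.get("metabolites", {}).items():
            if met not in met_index:
                raise ModelValidationError(
                    f"reaction {rxn['id']!r} references unknown metabolite {met!r}"
                )
            S[met_index[met], j] = float(coef)
        lb[j] = rxn["lower_bound"]
        ub[j] = rxn["upper_bound"]
        obj[j] = rxn.get("objective_coefficient", 0.0)
        gprs.append(rxn.get("gene_reaction_rule", ""))
        labels.append(rxn.get("cell_label") or infer_cell_label(rxn["id"]))
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=rids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coefficients=obj,
        cell_label=labels,
        gpr=gprs,
        compartment=compartment,
    )


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _model_to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("neurometnet")
    mets = {}
    for mid, comp in zip(model.metabolite_ids, model.compartment):
        met = cobra.Metabolite(mid, compartment=comp or "c")
        mets[mid] = met
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {
                mets[model.metabolite_ids[i]]: float(model.S[i, j])
                for i in np.nonzero(model.S[:, j])[0]
            }
        )
        rxn.gene_reaction_rule = model.gpr[j]
        if model.objective_coefficients[j]:
            rxn.objective_coefficient = float(model.objective_coefficients[j])
    return cm


def _model_from_cobra(cm) -> MetabolicModel:
    metabolite_ids = [m.id for m in cm.metabolites]
    compartment = [m.compartment or "" for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    n, m = len(metabolite_ids), len(cm.reactions)
    S = np.zeros((n, m))
    lb = np.zeros(m)
    ub = np.zeros(m)
    obj = np.zeros(m)
    rids, labels, gprs = [], [], []
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(cm)
    for j, rxn in enumerate(cm.reactions):
        rids.append(rxn.id)
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = float(coef)
        lb[j], ub[j] = float(rxn.lower_bound), float(rxn.upper_bound)
        obj[j] = float(coeffs.get(rxn, 0.0))
        gprs.append(rxn.gene_reaction_rule or "")
        labels.append(infer_cell_label(rxn.id))
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=rids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coefficients=obj,
        cell_label=labels,
        gpr=gprs,
        compartment=compartment,
    )


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (native dialect) or SBML Level 3.

    ``format`` is inferred from the file suffix when omitted
    (``.json`` vs ``.xml``/``.sbml``).
    """
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if format == "sbml":
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(path)
        return _model_from_cobra(cm)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write a model to disk; JSON round trips loss-free on all fields."""
    model.validate()
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sbml":
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(_model_to_cobra(model), path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Differential-expression tables, GMT, ortholog mapping
# ---------------------------------------------------------------------------

def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the DE-table schema and invariants; returns the table."""
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ModelValidationError(f"DE table missing columns {missing}")
    if ((table["significance"] < 0) | (table["significance"] > 1)).any():
        raise ModelValidationError("significance outside [0, 1]")
    nt = table[table["condition"] == "neurotransmission"]
    if (nt["effect"] <= 0).any():
        raise ModelValidationError("non-positive fold-change in neurotransmission rows")
    if table.duplicated(subset=["gene_id", "cell", "condition"]).any():
        raise ModelValidationError("duplicate (gene, cell, condition) keys")
    return table


def read_de_table(path) -> pd.DataFrame:
    return validate_de_table(pd.read_csv(path, sep="\t"))


def write_de_table(table: pd.DataFrame, path) -> None:
    validate_de_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ModelValidationError(f"malformed GMT line: {line[:50]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ModelValidationError(f"duplicate gene-set name {name!r}")
            sets[name] = set(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_mapping_table(path) -> pd.DataFrame:
    """Two-column TSV (source_id, target_id); one-to-many rows allowed."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ModelValidationError("mapping table needs two columns")
    table = table.iloc[:, :2]
    table.columns = ["source_id", "target_id"]
    return table
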
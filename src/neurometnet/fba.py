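"""Flux balance analysis with reduced-cost sensitivity.

The optimisation maximises the coupled neurotransmission objective
z = c^T v subject to steady-state mass balance S v = 0 and box bounds
L_b <= v <= U_b.  The LP is solved with the deterministic HiGHS solver;
reduced costs delta_i = dz/db_i are taken from the dual solution (sign
convention: delta_i > 0 means relaxing an active bound on v_i increases
the optimum).

Also provided: the phenotypic phase plane scan over paired oxygen/glucose
uptake rates, and the bisection fit of the astrocytic glycolytic bound to
a neuronal ATP demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "FBASolution",
    "PhPPGrid",
    "SensitivitySet",
    "FBAError",
    "FittingError",
    "solve_fba",
    "fit_astrocytic_glycolysis",
    "compute_phpp",
    "extract_sensitivity_set",
]

MASS_BALANCE_TOL = 1e-6
BOUND_TOL = 1e-9


class FBAError(RuntimeError):
    """Raised when an FBA solve cannot produce what the caller requires."""


class FittingError(FBAError):
    """Raised when a demand cannot be met anywhere in the search interval."""


@dataclass
class FBASolution:
    """Optimal fluxes, objective value and reduced costs of one FBA solve."""

    reaction_ids: list[str]
    v: np.ndarray | None
    z: float | None
    delta: np.ndarray | None
    status: str  # optimal | infeasible | unbounded

    def flux(self, reaction_id: str) -> float:
        if self.status != "optimal":
            raise FBAError(f"no fluxes available: solution is {self.status}")
        return float(self.v[self.reaction_ids.index(reaction_id)])

    def reduced_cost(self, reaction_id: str) -> float:
        if self.status != "optimal":
            raise FBAError(f"no reduced costs: solution is {self.status}")
        return float(self.delta[self.reaction_ids.index(reaction_id)])


@dataclass
class SensitivitySet:
    """Reactions with non-zero reduced cost at the FBA optimum.

    These reactions form the interface through which bound perturbations
    reach the optimal objective; their centrality is probed downstream.
    """

    s: set[str]
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = len(self.s)


@dataclass
class PhPPGrid:
    """Phenotypic phase plane tensor over oxygen x glucose uptake rates."""

    oxygen_rates: np.ndarray
    glucose_rates: np.ndarray
    reaction_ids: list[str]
    Phpp: np.ndarray          # (n_o2, n_glc, n_reactions), NaN where infeasible
    objective: np.ndarray     # (n_o2, n_glc), NaN where infeasible
    feasible: np.ndarray      # boolean (n_o2, n_glc)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_fba(model: MetabolicModel) -> FBASolution:
    """Maximise c^T v subject to S v = 0 and the model's flux bounds."""
    model.validate()
    bounds = [
        (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
        for lo, hi in zip(model.lower_bounds, model.upper_bounds)
    ]
    res = linprog(
        c=-model.objective_coefficients,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FBASolution(
            reaction_ids=list(model.reaction_ids),
            v=None, z=None, delta=None, status=status,
        )
    v = np.asarray(res.x)
    # HiGHS marginals are for the minimisation; negate for the max problem.
    delta = -(np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals))
    z = float(model.objective_coefficients @ v)
    residual = float(np.max(np.abs(model.S @ v))) if model.n_metabolites else 0.0
    if residual > MASS_BALANCE_TOL:
        raise FBAError(f"mass-balance residual {residual:.2e} exceeds tolerance")
    return FBASolution(
        reaction_ids=list(model.reaction_ids),
        v=v, z=z, delta=delta, status="optimal",
    )


def extract_sensitivity_set(
    solution: FBASolution, tolerance: float = 1e-9
) -> SensitivitySet:
    """Reactions whose |reduced cost| exceeds ``tolerance``."""
    if solution.status != "optimal":
        raise FBAError("sensitivity set requires an optimal solution")
    members = {
        rid
        for rid, d in zip(solution.reaction_ids, solution.delta)
        if abs(d) > tolerance
    }
    return SensitivitySet(s=members)


def achievable_demand(
    model: MetabolicModel,
    demand_reactions: tuple[str, ...],
    weights: tuple[float, ...] | None = None,
) -> float:
    """Maximal weighted demand flux among the FBA optima.

    Solves the FBA, then a second LP that pins the objective at its
    optimum and maximises the weighted sum of the demand fluxes.  The
    two-stage formulation makes the measure well defined when the optimal
    flux distribution is degenerate.  Returns ``-inf`` when infeasible.
    """
    if weights is None:
        weights = tuple(1.0 for _ in demand_reactions)
    sol = solve_fba(model)
    if sol.status != "optimal":
        return -np.inf
    w = np.zeros(model.n_reactions)
    for weight, rid in zip(weights, demand_reactions):
        w[model.reaction_index(rid)] += weight
    A_eq = np.vstack([model.S, model.objective_coefficients])
    b_eq = np.concatenate([np.zeros(model.n_metabolites), [sol.z]])
    bounds = [
        (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
        for lo, hi in zip(model.lower_bounds, model.upper_bounds)
    ]
    res = linprog(c=-w, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return -np.inf
    return float(w @ res.x)


def fit_astrocytic_glycolysis(
    model: MetabolicModel,
    neuronal_atp_demand: float,
    uptake_reaction: str = "GLCt_a",
    demand_reactions: tuple[str, ...] = ("NAK_n", "ATPM_n"),
    atp_weights: tuple[float, ...] | None = None,
    upper: float = 50.0,
    tolerance: float = 1e-4,
) -> tuple[float, MetabolicModel]:
    """Smallest astrocytic glucose-uptake bound meeting a neuronal ATP demand.

    The astrocytic glycolytic flux feeds lactate to the neuron; this fit
    finds, by bisection on the upper bound of ``uptake_reaction``, the
    minimal bound at which the FBA optimum can deliver at least
    ``neuronal_atp_demand`` uM/s of neuronal ATP consumption, measured as
    the weighted sum of fluxes through ``demand_reactions`` (weights
    default to 1 ATP per unit flux) maximised over the optimal face.

    Returns the fitted bound and a model copy with the bound installed.
    """
    if neuronal_atp_demand < 0:
        raise ValueError("demand must be non-negative")
    j = model.reaction_index(uptake_reaction)

    def consumption_at(bound: float) -> float:
        trial = model.copy()
        trial.upper_bounds[j] = bound
        trial.lower_bounds[j] = min(trial.lower_bounds[j], bound)
        return achievable_demand(trial, demand_reactions, atp_weights)

    if neuronal_atp_demand == 0:
        fitted = model.copy()
        fitted.upper_bounds[j] = 0.0
        fitted.lower_bounds[j] = min(fitted.lower_bounds[j], 0.0)
        return 0.0, fitted

    achieved_max = consumption_at(upper)
    if achieved_max < neuronal_atp_demand - tolerance:
        raise FittingError(
            f"demand {neuronal_atp_demand} uM/s unreachable: maximal achievable "
            f"neuronal ATP consumption is {achieved_max:.4f} uM/s at bound {upper}"
        )
    lo, hi = 0.0, upper
    if consumption_at(lo) >= neuronal_atp_demand - tolerance:
        hi = lo
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if consumption_at(mid) >= neuronal_atp_demand - tolerance:
            hi = mid
        else:
            lo = mid
    fitted = model.copy()
    fitted.upper_bounds[j] = hi
    fitted.lower_bounds[j] = min(fitted.lower_bounds[j], hi)
    return hi, fitted


def compute_phpp(
    model: MetabolicModel,
    oxygen_rates,
    glucose_rates,
    oxygen_reaction: str = "EX_o2",
    glucose_reaction: str = "EX_glc",
) -> PhPPGrid:
    """Phenotypic phase plane: FBA optima over fixed O2/glucose uptake rates.

    At each grid point the oxygen and glucose uptake fluxes are pinned
    (lower bound == upper bound == the axis value, matching the paired
    inequality constraints of the scan) and the full optimal flux vector
    is stored.  Infeasible cells are flagged and filled with NaN.

    Axis values follow the model's exchange sign convention: uptakes are
    negative exchange fluxes.
    """
    oxygen_rates = np.asarray(oxygen_rates, dtype=float)
    glucose_rates = np.asarray(glucose_rates, dtype=float)
    if oxygen_rates.size == 0 or glucose_rates.size == 0:
        raise ValueError("uptake-rate axes must be non-empty")
    for axis in (oxygen_rates, glucose_rates):
        if not (np.all(axis <= 0) or np.all(axis >= 0)):
            raise ValueError("each axis must have a consistent uptake sign")
    jo = model.reaction_index(oxygen_reaction)
    jg = model.reaction_index(glucose_reaction)
    for j, axis, name in [
        (jo, oxygen_rates, oxygen_reaction),
        (jg, glucose_rates, glucose_reaction),
    ]:
        if axis.min() < model.lower_bounds[j] - BOUND_TOL or (
            axis.max() > model.upper_bounds[j] + BOUND_TOL
        ):
            raise ValueError(
                f"axis values for {name} fall outside the model's global bounds"
            )
    n, m = len(oxygen_rates), len(glucose_rates)
    Phpp = np.full((n, m, model.n_reactions), np.nan)
    objective = np.full((n, m), np.nan)
    feasible = np.zeros((n, m), dtype=bool)
    trial = model.copy()
    for i, bo in enumerate(oxygen_rates):
        for j_, bg in enumerate(glucose_rates):
            trial.lower_bounds[jo] = trial.upper_bounds[jo] = bo
            trial.lower_bounds[jg] = trial.upper_bounds[jg] = bg
            sol = solve_fba(trial)
            if sol.status == "optimal":
                Phpp[i, j_, :] = sol.v
                objective[i, j_] = sol.z
                feasible[i, j_] = True
            else:
                warnings.warn(
                    f"phase-plane cell (o2={bo}, glc={bg}) is {sol.status}",
                    stacklevel=2,
                )
    return PhPPGrid(
        oxygen_rates=oxygen_rates,
        glucose_rates=glucose_rates,
        reaction_ids=list(model.reaction_ids),
        Phpp=Phpp,
        objective=objective,
        feasible=feasible,
    )
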
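import itertools

import numpy as np
import pytest

from neurometnet.fba import (
    FBAError,
    FittingError,
    compute_phpp,
    extract_sensitivity_set,
    fit_astrocytic_glycolysis,
    solve_fba,
)
from neurometnet.model_io import MetabolicModel

from conftest import make_chain_model


def finite_difference_reduced_costs(model, eps=1e-6):
    """Oracle: perturb each reaction's active bound and re-solve."""
    base = solve_fba(model)
    deltas = np.zeros(model.n_reactions)
    for j in range(model.n_reactions):
        v = base.v[j]
        trial = model.copy()
        if abs(v - model.upper_bounds[j]) < 1e-7:
            trial.upper_bounds[j] += eps
        elif abs(v - model.lower_bounds[j]) < 1e-7:
            trial.lower_bounds[j] += eps
            trial.upper_bounds[j] = max(trial.upper_bounds[j],
                                        trial.lower_bounds[j])
        else:
            continue
        sol = solve_fba(trial)
        if sol.status == "optimal":
            deltas[j] = (sol.z - base.z) / eps
    return deltas


def brute_force_optimum(model, tol=1e-9):
    """Enumerate basic feasible solutions of max c.v s.t. Sv=0, l<=v<=u."""
    n = model.n_reactions
    S = model.S
    rank = np.linalg.matrix_rank(S) if model.n_metabolites else 0
    free = n - rank
    best = -np.inf
    for fixed in itertools.combinations(range(n), free):
        rest = [j for j in range(n) if j not in fixed]
        for corners in itertools.product(*[(0, 1)] * free):
            v = np.zeros(n)
            for j, c in zip(fixed, corners):
                v[j] = model.lower_bounds[j] if c == 0 else model.upper_bounds[j]
            if rest:
                A = S[:, rest]
                b = -S[:, fixed] @ v[list(fixed)]
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[rest] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < model.lower_bounds - tol) or np.any(
                v > model.upper_bounds + tol
            ):
                continue
            best = max(best, float(model.objective_coefficients @ v))
    return best


def test_chain_bound_limited_maximum(chain_model):
    sol = solve_fba(chain_model)
    assert sol.status == "optimal"
    assert sol.z == pytest.approx(10.0, abs=1e-8)
    np.testing.assert_allclose(sol.v, [10.0, 10.0, 10.0], atol=1e-8)


def test_chain_reduced_costs_match_finite_difference(chain_model):
    sol = solve_fba(chain_model)
    oracle = finite_difference_reduced_costs(chain_model)
    np.testing.assert_allclose(sol.delta, oracle, atol=1e-4)
    assert sol.reduced_cost("uptake") == pytest.approx(1.0, abs=1e-9)
    assert sol.reduced_cost("convert") == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_lp_matches_brute_force_vertex_enumeration(seed):
    """On tiny random networks the LP optimum equals the best vertex."""
    rng = np.random.default_rng(seed)
    n_met, n_rxn = 3, 6
    S = rng.integers(-1, 2, size=(n_met, n_rxn)).astype(float)
    lb = np.zeros(n_rxn)
    ub = rng.uniform(1.0, 10.0, size=n_rxn)
    c = rng.uniform(0.0, 1.0, size=n_rxn)
    model = MetabolicModel(
        metabolite_ids=[f"m{i}" for i in range(n_met)],
        reaction_ids=[f"r{j}" for j in range(n_rxn)],
        S=S, lower_bounds=lb, upper_bounds=ub, objective_coefficients=c,
        cell_label=["neuron"] * n_rxn, gpr=[""] * n_rxn,
        compartment=["c"] * n_met,
    )
    sol = solve_fba(model)
    assert sol.status == "optimal"
    assert sol.z == pytest.approx(brute_force_optimum(model), abs=1e-6)


def test_solution_satisfies_mass_balance_and_bounds(toy_model):
    sol = solve_fba(toy_model)
    assert sol.status == "optimal"
    assert np.max(np.abs(toy_model.S @ sol.v)) <= 1e-6
    assert np.all(sol.v >= toy_model.lower_bounds - 1e-9)
    assert np.all(sol.v <= toy_model.upper_bounds + 1e-9)
    assert sol.z == pytest.approx(
        float(toy_model.objective_coefficients @ sol.v), abs=1e-6
    )


def test_sodium_flux_coupling_is_stoichiometric(toy_model):
    """Sodium efflux equals 3x the pump's ATP flux by mass balance."""
    sol = solve_fba(toy_model)
    assert sol.flux("NAEF_n") == pytest.approx(3.0 * sol.flux("NAK_n"), abs=1e-7)
    assert sol.flux("NAEF_n") == pytest.approx(350.0, abs=1e-6)


def test_infeasible_and_unbounded_status():
    infeasible = MetabolicModel(
        metabolite_ids=["m"],
        reaction_ids=["in", "out"],
        S=np.array([[1.0, -1.0]]),
        lower_bounds=np.array([5.0, 0.0]),
        upper_bounds=np.array([10.0, 1.0]),
        objective_coefficients=np.array([0.0, 1.0]),
        cell_label=["neuron"] * 2, gpr=[""] * 2, compartment=["c"],
    )
    sol = solve_fba(infeasible)
    assert sol.status == "infeasible"
    with pytest.raises(FBAError):
        sol.flux("in")

    unbounded = MetabolicModel(
        metabolite_ids=["m"],
        reaction_ids=["in", "out"],
        S=np.array([[1.0, -1.0]]),
        lower_bounds=np.array([0.0, 0.0]),
        upper_bounds=np.array([np.inf, np.inf]),
        objective_coefficients=np.array([0.0, 1.0]),
        cell_label=["neuron"] * 2, gpr=[""] * 2, compartment=["c"],
    )
    assert solve_fba(unbounded).status == "unbounded"


def test_sensitivity_set_threshold():
    sol = solve_fba(make_chain_model())
    sol.delta = np.array([0.0, 1e-12, 0.3])
    s = extract_sensitivity_set(sol, tolerance=1e-9)
    assert s.s == {"export"}
    assert s.k == 1


def test_sensitivity_set_matches_finite_difference_oracle(chain_model):
    sol = solve_fba(chain_model)
    s = extract_sensitivity_set(sol, tolerance=1e-9)
    oracle = finite_difference_reduced_costs(chain_model)
    expected = {
        rid for rid, d in zip(chain_model.reaction_ids, oracle) if abs(d) > 1e-6
    }
    assert s.s == expected


def test_sensitivity_set_requires_optimal(chain_model):
    sol = solve_fba(chain_model)
    sol.status = "infeasible"
    with pytest.raises(FBAError):
        extract_sensitivity_set(sol)


def make_fit_model(glc_cap=10.0):
    """Astrocyte-like converter: 1 glucose -> 2 lactate -> neuronal ATP."""
    return MetabolicModel(
        metabolite_ids=["glc_a", "lac_e", "atp_n"],
        reaction_ids=["GLCt_a", "GLYC_a", "LACox_n", "ATPM_n"],
        S=np.array(
            [
                [1.0, -1.0, 0.0, 0.0],
                [0.0, 2.0, -1.0, 0.0],
                [0.0, 0.0, 1.0, -1.0],
            ]
        ),
        lower_bounds=np.zeros(4),
        upper_bounds=np.array([glc_cap, 1000.0, 1000.0, 1000.0]),
        objective_coefficients=np.array([0.0, 0.0, 1.0, 0.0]),
        cell_label=["astrocyte", "astrocyte", "neuron", "neuron"],
        gpr=[""] * 4, compartment=["a", "e", "n"],
    )


def grid_scan_fit(model, demand, step=1e-3):
    """Oracle: scan the uptake bound on a fine grid."""
    for bound in np.arange(0.0, 10.0 + step, step):
        trial = model.copy()
        trial.upper_bounds[0] = bound
        sol = solve_fba(trial)
        if sol.status == "optimal" and sol.flux("ATPM_n") >= demand - 1e-6:
            return bound
    return None


def test_fit_zero_demand_gives_zero_bound(toy_model):
    bound, fitted = fit_astrocytic_glycolysis(toy_model, 0.0)
    assert bound == 0.0
    assert fitted.upper_bounds[fitted.reaction_index("GLCt_a")] == 0.0


def test_fit_matches_grid_scan_oracle():
    """Each glucose yields 2 lactate; demand 4 needs a bound of 2."""
    model = make_fit_model()
    bound, fitted = fit_astrocytic_glycolysis(
        model, 4.0, uptake_reaction="GLCt_a", demand_reactions=("ATPM_n",)
    )
    assert bound == pytest.approx(2.0, abs=1e-4)
    oracle = grid_scan_fit(model, 4.0)
    assert bound == pytest.approx(oracle, abs=2e-3)
    refit = solve_fba(fitted)
    assert refit.flux("ATPM_n") >= 4.0 - 1e-4


def test_fit_is_monotone_in_demand():
    model = make_fit_model()
    bounds = [
        fit_astrocytic_glycolysis(
            model, d, uptake_reaction="GLCt_a", demand_reactions=("ATPM_n",)
        )[0]
        for d in (1.0, 3.0, 6.0)
    ]
    assert bounds == sorted(bounds)


def test_fit_reports_unreachable_demand():
    model = make_fit_model(glc_cap=10.0)
    with pytest.raises(FittingError, match="unreachable"):
        fit_astrocytic_glycolysis(
            model, 10_000.0, uptake_reaction="GLCt_a",
            demand_reactions=("ATPM_n",), upper=10.0,
        )


def test_fit_on_toy_network_meets_total_demand(toy_model):
    from neurometnet.fba import achievable_demand

    bound, fitted = fit_astrocytic_glycolysis(toy_model, 155.0)
    assert 0 < bound < 5.0
    # the fitted bound delivers the demand on the optimal face and is
    # minimal: slightly below it the demand becomes unreachable
    assert achievable_demand(fitted, ("NAK_n", "ATPM_n")) >= 155.0 - 1e-2
    short = toy_model.copy()
    short.upper_bounds[short.reaction_index("GLCt_a")] = bound - 1e-2
    assert achievable_demand(short, ("NAK_n", "ATPM_n")) < 155.0


def phpp_chain_model():
    """Two-substrate chain whose export needs both oxygen and glucose;
    vents give the pinned uptakes somewhere to go."""
    return MetabolicModel(
        metabolite_ids=["glc", "o2", "prod"],
        reaction_ids=["EX_glc", "EX_o2", "burn", "export", "vent_glc", "vent_o2"],
        S=np.array(
            [
                [-1.0, 0.0, -1.0, 0.0, -1.0, 0.0],
                [0.0, -1.0, -1.0, 0.0, 0.0, -1.0],
                [0.0, 0.0, 1.0, -1.0, 0.0, 0.0],
            ]
        ),
        lower_bounds=np.array([-10.0, -10.0, 0.0, 0.0, 0.0, 0.0]),
        upper_bounds=np.array([0.0, 0.0, 1000.0, 1000.0, 1000.0, 1000.0]),
        objective_coefficients=np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0]),
        cell_label=["exchange", "exchange", "neuron", "neuron",
                    "neuron", "neuron"],
        gpr=[""] * 6, compartment=["e", "e", "c"],
    )


def test_phpp_shape_and_monotonicity():
    model = phpp_chain_model()
    grid = compute_phpp(
        model,
        oxygen_rates=[-1.0, -2.0],
        glucose_rates=[-1.0, -2.0, -3.0],
        oxygen_reaction="EX_o2",
        glucose_reaction="EX_glc",
    )
    assert grid.Phpp.shape == (2, 3, 6)
    assert grid.feasible.all()
    # with uptake pinned, export equals the limiting substrate magnitude
    assert grid.objective[0, 0] == pytest.approx(1.0, abs=1e-8)
    assert grid.objective[1, 2] == pytest.approx(2.0, abs=1e-8)
    # non-zero plane slope: the optimum depends on the substrate supply
    assert grid.objective[1, 1] > grid.objective[0, 0]


def test_phpp_rejects_out_of_range_axes():
    model = phpp_chain_model()
    with pytest.raises(ValueError, match="global bounds"):
        compute_phpp(model, [-20.0], [-1.0],
                     oxygen_reaction="EX_o2", glucose_reaction="EX_glc")
    with pytest.raises(ValueError, match="non-empty"):
        compute_phpp(model, [], [-1.0],
                     oxygen_reaction="EX_o2", glucose_reaction="EX_glc")
    with pytest.raises(ValueError, match="sign"):
        compute_phpp(model, [-1.0, 1.0], [-1.0],
                     oxygen_reaction="EX_o2", glucose_reaction="EX_glc")


def test_phpp_on_toy_network_flags_infeasible_cells(toy_model):
    """Pinning uptakes reproduces the free optimum at its own rates and
    flags substrate combinations the stoichiometry cannot balance."""
    base = solve_fba(toy_model)
    natural_o2 = base.flux("EX_o2")
    natural_glc = base.flux("EX_glc")
    with pytest.warns(UserWarning, match="infeasible"):
        grid = compute_phpp(
            toy_model,
            oxygen_rates=[natural_o2],
            glucose_rates=[natural_glc, natural_glc - 2.0],
            oxygen_reaction="EX_o2",
            glucose_reaction="EX_glc",
        )
    assert grid.feasible[0, 0]
    assert grid.objective[0, 0] == pytest.approx(base.z, abs=1e-6)
    assert not grid.feasible[0, 1]
    assert np.isnan(grid.Phpp[0, 1]).all()
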
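"""Absolute Optimality: flux/sensitivity normalisation and reaction ranking.

Each reaction's optimal flux v_i and reduced cost delta_i are mapped to
[0, 1] by a signed pseudo-logarithm (asinh(z/2), an odd function that is
logarithmic for large |z| yet defined at zero) followed by min-max
rescaling; Absolute Optimality is the Euclidean norm of the pair,

    AO_i = || (N(v_i), N(delta_i)) ||_2  in  [0, sqrt(2)].

Reactions at or above the per-cell 90th-percentile AO are the "optimal"
reactions.  Any positive constant multiplying the pseudo-logarithm is
annihilated by the rescaling, so only the sign convention is observable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fba import FBASolution
from .model_io import CELLS, MetabolicModel

__all__ = [
    "pseudo_log_normalize",
    "absolute_optimality",
    "select_top_percentile",
    "rank_sum_compare",
    "optimality_table",
]


def pseudo_log_normalize(values, abs_before_norm: bool = False) -> np.ndarray:
    """Signed pseudo-logarithm followed by min-max rescaling to [0, 1].

    ``t = asinh(z/2) / ln 10``; the output is ``(t - min t)/(max t - min t)``
    or all zeros for constant input.  With ``abs_before_norm`` the
    magnitude |z| is transformed instead of the signed value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values cannot be normalized")
    if abs_before_norm:
        values = np.abs(values)
    t = np.arcsinh(values / 2.0) / np.log(10.0)
    lo, hi = t.min(), t.max()
    if hi == lo:
        return np.zeros_like(t)
    return (t - lo) / (hi - lo)


def absolute_optimality(n_flux, n_sens) -> np.ndarray:
    """Euclidean norm of (normalized flux, normalized sensitivity)."""
    n_flux = np.asarray(n_flux, dtype=float)
    n_sens = np.asarray(n_sens, dtype=float)
    if n_flux.shape != n_sens.shape:
        raise ValueError("normalized flux and sensitivity lengths differ")
    return np.hypot(n_flux, n_sens)


def _strata(cell_labels, model: MetabolicModel | None = None) -> dict[str, np.ndarray]:
    """Index sets per cell; exchange reactions pool into the cell(s) whose
    metabolites they touch (both cells when the metabolite is shared)."""
    labels = np.asarray(cell_labels, dtype=object)
    strata = {cell: list(np.nonzero(labels == cell)[0]) for cell in CELLS}
    exchange = np.nonzero(labels == "exchange")[0]
    if exchange.size:
        if model is None:
            for cell in CELLS:
                strata[cell].extend(exchange)
        else:
            for j in exchange:
                mets = np.nonzero(model.S[:, j])[0]
                for cell in CELLS:
                    touches = any(
                        model.S[i, k] != 0
                        for i in mets
                        for k in np.nonzero(labels == cell)[0]
                    )
                    if touches:
                        strata[cell].append(int(j))
    return {c: np.asarray(sorted(set(ix)), dtype=int) for c, ix in strata.items()}


def select_top_percentile(
    scores,
    cell_labels,
    reaction_ids,
    q: float = 90.0,
    model: MetabolicModel | None = None,
) -> set[str]:
    """Reactions at or above the per-cell q-th percentile of their score.

    The percentile is the empirical quantile with linear interpolation
    between order statistics, computed separately inside each cell
    stratum; ties at the cutoff are included.  Exchange-labelled
    reactions are pooled with the cell(s) they connect to and can be
    selected through either stratum.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0 <= q < 100:
        raise ValueError("percentile must be in [0, 100)")
    reaction_ids = list(reaction_ids)
    selected: set[str] = set()
    for cell, idx in _strata(cell_labels, model).items():
        if idx.size == 0:
            warnings.warn(f"empty stratum {cell!r}; skipped", stacklevel=2)
            continue
        cutoff = np.percentile(scores[idx], q)
        selected |= {reaction_ids[i] for i in idx if scores[i] >= cutoff}
    return selected


def rank_sum_compare(values, cell_labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of neuron vs astrocyte scores."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(cell_labels, dtype=object)
    groups = [values[labels == cell] for cell in CELLS]
    if any(len(g) == 0 for g in groups):
        raise ValueError("both neuron and astrocyte strata must be non-empty")
    stat, p = stats.ranksums(groups[0], groups[1])
    return float(stat), float(p)


def optimality_table(
    model: MetabolicModel,
    solution: FBASolution,
    q: float = 90.0,
    abs_before_norm: bool = False,
    per_cell_norm: bool = False,
) -> pd.DataFrame:
    """Per-reaction AO table with the per-cell percentile classification.

    Normalisation spans the whole network by default (``per_cell_norm``
    switches to within-cell rescaling).  Columns: reaction_id,
    cell_label, flux, sensitivity, n_flux, n_sens, ao, is_optimal.
    """
    if solution.status != "optimal":
        raise ValueError("optimality table requires an optimal FBA solution")
    table = pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "cell_label": model.cell_label,
            "flux": solution.v,
            "sensitivity": solution.delta,
        }
    )
    if per_cell_norm:
        n_flux = np.zeros(len(table))
        n_sens = np.zeros(len(table))
        for _, idx in _strata(model.cell_label, model).items():
            n_flux[idx] = pseudo_log_normalize(table["flux"].values[idx],
                                               abs_before_norm)
            n_sens[idx] = pseudo_log_normalize(table["sensitivity"].values[idx],
                                               abs_before_norm)
    else:
        n_flux = pseudo_log_normalize(table["flux"].values, abs_before_norm)
        n_sens = pseudo_log_normalize(table["sensitivity"].values, abs_before_norm)
    table["n_flux"] = n_flux
    table["n_sens"] = n_sens
    table["ao"] = absolute_optimality(n_flux, n_sens)
    optimal = select_top_percentile(
        table["ao"].values, model.cell_label, model.reaction_ids, q=q, model=model
    )
    table["is_optimal"] = table["reaction_id"].isin(optimal)
    return table
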
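"""Flux balance analysis: maximize biomass flux at steady state.

Solves ``max v_biomass  s.t.  S v = 0,  lb <= v <= ub`` with the HiGHS
linear-programming solver.  Exchange reactions follow the standard
convention ``external metabolite ->`` so uptake is negative flux; a medium
opens uptake by setting the exchange lower bound to minus its rate.

Only the optimal objective value is contractually deterministic.  The flux
vector is a witness of one optimum: LP degeneracy means alternative optima
exist and witnesses must never be compared across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel
from .templates import OXYGEN_EXTERNAL_ID

logger = logging.getLogger(__name__)

#: conventional max uptake rate for medium compounds, mmol/gDW/h
DEFAULT_UPTAKE = 10.0
#: biomass flux above which a model is called "growing" (strict >)
GROWTH_THRESHOLD = 1e-6
#: solver-grade feasibility tolerance
FEASIBILITY_TOL = 1e-9
#: test-grade audit tolerance for steady state and bound violations
AUDIT_TOL = 1e-6


class MediumError(ValueError):
    """A medium is inconsistent with itself or with a model."""


class FbaSolverError(RuntimeError):
    """The LP solver failed numerically (never silently reported as 0)."""


@dataclass(frozen=True)
class Medium:
    """A named set of exchangeable compounds with max uptake rates.

    ``uptakes`` maps *external metabolite ids* to positive uptake rates in
    mmol/gDW/h.  Under anaerobiosis the oxygen exchange must not be opened.
    """

    medium_id: str
    uptakes: dict[str, float] = field(default_factory=dict)
    anaerobic: bool = True

    def __post_init__(self) -> None:
        for met, rate in self.uptakes.items():
            if not rate > 0:
                raise MediumError(f"medium {self.medium_id!r}: uptake rate for "
                                  f"{met!r} must be > 0, got {rate}")
        if self.anaerobic and OXYGEN_EXTERNAL_ID in self.uptakes:
            raise MediumError(
                f"medium {self.medium_id!r} is anaerobic but lists oxygen"
            )

    def plus(self, medium_id: str, extra: dict[str, float]) -> "Medium":
        """New medium with additional compounds (rates override on clash)."""
        merged = dict(self.uptakes)
        merged.update(extra)
        return Medium(medium_id, merged, self.anaerobic)

    def without(self, medium_id: str, compounds: set[str] | frozenset[str]) -> "Medium":
        kept = {m: r for m, r in self.uptakes.items() if m not in compounds}
        return Medium(medium_id, kept, self.anaerobic)


def medium_from_compounds(
    medium_id: str,
    compounds,
    *,
    anaerobic: bool = True,
    default_rate: float = DEFAULT_UPTAKE,
) -> Medium:
    """Build a medium from compound ids (``x`` becomes ``x_e``) or from a
    mapping compound -> rate."""
    if isinstance(compounds, dict):
        items = compounds.items()
    else:
        items = ((c, default_rate) for c in compounds)
    uptakes = {
        (c if c.endswith("_e") else f"{c}_e"): float(rate) for c, rate in items
    }
    return Medium(medium_id, uptakes, anaerobic)


@dataclass(frozen=True)
class FbaSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Copy of the model with exchange uptake bounds set from the medium.

    For every exchange reaction the uptake (negative) bound becomes
    ``-rate`` when its external metabolite is in the medium and 0 otherwise;
    secretion (positive) bounds are untouched.  Under anaerobiosis the
    oxygen uptake is forced shut.  Compounds in the medium without an
    exchange reaction in the model raise :class:`MediumError`.
    """
    exchange_by_met: dict[str, str] = {}
    for r in model.reactions:
        if model.is_exchange(r):
            (met,) = r.stoichiometry
            exchange_by_met[met] = r.id
    unmatched = sorted(set(medium.uptakes) - set(exchange_by_met))
    if unmatched:
        raise MediumError(
            f"medium {medium.medium_id!r} names compounds with no exchange "
            f"reaction in model {model.model_id!r}: {', '.join(unmatched)}"
        )
    new_bounds: dict[str, tuple[float, float]] = {}
    for met, rxn_id in exchange_by_met.items():
        ub = model.get_reaction(rxn_id).upper_bound
        rate = medium.uptakes.get(met, 0.0)
        if medium.anaerobic and met == OXYGEN_EXTERNAL_ID:
            rate = 0.0
        new_bounds[rxn_id] = (-rate, ub)
    return model.with_bounds(new_bounds)


def solve_fba(model: MetabolicModel, *, feasibility_tol: float = FEASIBILITY_TOL) -> FbaSolution:
    """Maximize the biomass objective subject to S v = 0 and flux bounds.

    Deterministic for a fixed model (fixed solver configuration).  A
    numerically failed solve raises :class:`FbaSolverError` with the solver
    diagnostics rather than reporting zero growth.
    """
    model.validate()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    c = np.zeros(n)
    obj_idx = model.reaction_ids.index(model.objective_reaction_id)
    c[obj_idx] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": feasibility_tol,
            "dual_feasibility_tolerance": feasibility_tol,
        },
    )
    if res.status == 0:
        fluxes = dict(zip(model.reaction_ids, (float(v) for v in res.x)))
        return FbaSolution("optimal", float(res.x[obj_idx]), fluxes)
    if res.status == 2:
        return FbaSolution("infeasible", float("nan"))
    if res.status == 3:
        return FbaSolution("unbounded", float("inf"))
    raise FbaSolverError(
        f"LP solve failed on model {model.model_id!r}: status={res.status}, "
        f"message={res.message!r}"
    )


def audit_solution(model: MetabolicModel, solution: FbaSolution, *, tol: float = AUDIT_TOL) -> float:
    """Return ``||S v||_inf`` of an optimal witness; raise if it or any
    bound is violated beyond the audit tolerance."""
    if solution.status != "optimal":
        raise ValueError("can only audit an optimal solution")
    v = np.array([solution.fluxes[r] for r in model.reaction_ids])
    S = model.stoichiometric_matrix()
    residual = float(np.abs(S @ v).max()) if S.size else 0.0
    lb, ub = model.bounds_arrays()
    bound_violation = float(np.maximum(lb - v, 0).max(initial=0.0)
                            + np.maximum(v - ub, 0).max(initial=0.0))
    if residual > tol or bound_violation > tol:
        raise FbaSolverError(
            f"solution audit failed for {model.model_id!r}: "
            f"||Sv||_inf={residual:.3g}, bound violation={bound_violation:.3g}"
        )
    return residual


def check_growth(solution: FbaSolution, threshold: float = GROWTH_THRESHOLD) -> bool:
    """Binary growth call: optimal status and objective strictly above the
    threshold separating biological growth from numerical noise."""
    return solution.status == "optimal" and solution.objective_value > threshold
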
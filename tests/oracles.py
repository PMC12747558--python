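"""Independent oracles used by the test suite.

These are deliberately written without reference to the library's solver
or search code: the LP oracle enumerates polytope vertices, the
combination oracle enumerates subsets, and the set-cover oracle
enumerates candidate subsets.  They are exact on the small instances the
tests use, and slow by design.
"""

from __future__ import annotations

import itertools

import numpy as np

from hydroscreen.model import MetabolicModel, Metabolite, Reaction


def vertex_lp_max(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, obj_idx: int,
                  tol: float = 1e-7) -> float | None:
    """Maximize v[obj_idx] over {S v = 0, lb <= v <= ub} by enumerating
    candidate vertices (all finite-bound boxes, so the region is a
    bounded polytope and the optimum, when feasible, sits on a vertex).

    Returns None when the polytope is empty.
    """
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - r
    best: float | None = None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, p in zip(fixed, pattern):
                v[j] = lb[j] if p == 0 else ub[j]
            b = -S[:, list(fixed)] @ v[list(fixed)] if fixed else np.zeros(S.shape[0])
            if free:
                x, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = x
            if S.size and np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(v[obj_idx])
            best = val if best is None else max(best, val)
    return best


def random_small_model(rng: np.random.Generator, max_mets: int = 6,
                       max_rxns: int = 8) -> MetabolicModel:
    """A random dense-ish stoichiometric model with finite bounds.

    Reactions with a single metabolite get that metabolite marked
    external so the model passes structural validation.
    """
    n_m = int(rng.integers(2, max_mets + 1))
    n_r = int(rng.integers(3, max_rxns + 1))
    S = np.zeros((n_m, n_r))
    for j in range(n_r):
        k = int(rng.integers(1, min(3, n_m) + 1))
        rows = rng.choice(n_m, size=k, replace=False)
        S[rows, j] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
    external = {int(i) for j in range(n_r)
                if np.count_nonzero(S[:, j]) == 1
                for i in np.nonzero(S[:, j])[0]}
    mets = [Metabolite(f"m{i}", compartment="external" if i in external else "internal")
            for i in range(n_m)]
    reactions = []
    for j in range(n_r):
        reversible = bool(rng.random() < 0.4)
        lb = -10.0 if reversible else 0.0
        # occasionally force flux away from zero to create infeasible cases
        if rng.random() < 0.15:
            lb = float(rng.uniform(0.5, 2.0))
        ub = float(rng.uniform(max(lb, 0.0) + 1.0, 10.0))
        stoich = {f"m{i}": float(S[i, j]) for i in np.nonzero(S[:, j])[0]}
        reactions.append(Reaction(f"r{j}", stoich, lb, ub))
    obj = f"r{int(rng.integers(n_r))}"
    return MetabolicModel("random_small", mets, reactions, obj)


def exhaustive_min_combo(grows, carbon_ids: list[str], max_k: int):
    """Smallest growth-supporting carbon subset by exhaustive search.

    ``grows(subset)`` is a callable on tuples of carbon ids.  Ties inside
    a size class resolve to the first subset in panel-lexicographic
    order, matching the documented search order.
    """
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(carbon_ids, k):
            if grows(combo):
                return frozenset(combo)
    return None


def brute_force_set_cover(covered_sets: list[frozenset], universe: frozenset) -> int:
    """Minimum number of sets covering every coverable universe element."""
    if not covered_sets:
        return 0
    coverable = universe & frozenset().union(*covered_sets)
    for k in range(0, len(covered_sets) + 1):
        for chosen in itertools.combinations(covered_sets, k):
            union = frozenset().union(*chosen) if chosen else frozenset()
            if coverable <= union:
                return k
    raise AssertionError("unreachable: full selection always covers coverable")
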
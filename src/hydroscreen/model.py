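"""Stoichiometric model containers for constraint-based growth simulation.

A :class:`MetabolicModel` is a deliberately small digital-cell
representation: metabolites live in one of two compartments (``internal``
or ``external``), reactions carry signed stoichiometry, flux bounds in
mmol/gDW/h and an optional set of EC numbers, and a single designated
biomass reaction is the growth objective.  Exchange reactions are written
in the standard constraint-based convention ``external metabolite ->``
so that negative flux denotes uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

COMPARTMENTS = ("internal", "external")

#: Conventional default flux bounds (mmol/gDW/h).
DEFAULT_UPPER = 1000.0
DEFAULT_LOWER_REVERSIBLE = -1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "internal"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "ec_numbers", frozenset(self.ec_numbers))


@dataclass
class MetabolicModel:
    """A stoichiometric network with a biomass objective.

    Invariants (checked by :meth:`validate`):

    * every stoichiometry key is a declared metabolite,
    * the objective reaction exists,
    * every exchange reaction touches exactly one *external* metabolite,
    * ``lower_bound <= upper_bound`` (enforced on construction).
    """

    model_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str = ""

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def get_reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def is_exchange(self, reaction: Reaction) -> bool:
        """True when the reaction touches exactly one external metabolite
        and nothing else (boundary reaction)."""
        if len(reaction.stoichiometry) != 1:
            return False
        (met_id,) = reaction.stoichiometry
        met = self._met_index.get(met_id)
        return met is not None and met.compartment == "external"

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def exchange_for(self, external_met_id: str) -> Reaction | None:
        for r in self.reactions:
            if self.is_exchange(r) and external_met_id in r.stoichiometry:
                return r
        return None

    # -- mutation helpers (return new model; models are treated as values)

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with the given reactions re-bounded."""
        new_reactions = []
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                r = replace(r, lower_bound=lb, upper_bound=ub)
            new_reactions.append(r)
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=new_reactions,
            objective_reaction_id=self.objective_reaction_id,
        )

    # -- matrix view ------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions), internal metabolites only
        balanced? No — all declared metabolites are rows; external
        metabolites are balanced through their exchange reactions."""
        met_pos = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coeff in r.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
        if not self.objective_reaction_id:
            raise ModelValidationError("model has no objective reaction")
        if self.objective_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        # exchange reactions: single metabolite implies it must be external
        # (the biomass objective is exempt: it is a sink pseudo-reaction)
        for r in self.reactions:
            if r.id == self.objective_reaction_id:
                continue
            if len(r.stoichiometry) == 1:
                (met_id,) = r.stoichiometry
                met = self._met_index[met_id]
                if met.compartment != "external":
                    raise ModelValidationError(
                        f"boundary reaction {r.id!r} touches internal "
                        f"metabolite {met_id!r}; exchanges must touch exactly "
                        "one external metabolite"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective_reaction_id=self.objective_reaction_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.objective_reaction_id == other.objective_reaction_id
        )
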
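"""Universal reaction template for draft digital-cell reconstruction.

The template is a pan-model: one exchange + transport per medium compound,
EC-tagged catabolic routes from every panel carbon into biomass precursors,
EC-tagged biosynthesis routes for every trace supplement, and a single
biomass reaction.  Draft models are reconstructed by selecting the template
reactions whose EC annotations occur in a genome's EC set.

Biomass precursors are split into two pools (A and B).  Every carbon has
two independently EC-tagged catabolic reactions, one feeding each pool:

* a genome holding *both* ECs of a carbon can grow on that carbon alone;
* a genome holding only the pool-A EC of one carbon and only the pool-B EC
  of another needs the two carbons jointly — a provable multi-carbon
  requirement.

Supplement biosynthesis draws on pool A; deleting (not annotating) the
biosynthesis EC makes the supplement an auxotrophic requirement, since the
biomass reaction consumes every supplement species unconditionally.

Synthetic pathway ECs live in a reserved fake namespace (``9.9.x.y``) so
they can never collide with real EC annotations such as the hydrogen-
production triad.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction
from .panels import (
    CarbonPanel,
    SupplementPanel,
    load_base_medium_compounds,
    synthetic_carbon_panel,
    synthetic_supplement_panel,
)

#: biomass demand per unit growth for pool precursors and base nutrients
POOL_A_DEMAND = 0.5
POOL_B_DEMAND = 0.5
SUPPLEMENT_DEMAND = 0.05
BASE_DEMAND = {"nh4": 0.1, "pi": 0.02, "so4": 0.01, "mg2": 0.005, "fe2": 0.002}

BIOMASS_ID = "BIOMASS"
OXYGEN_EXCHANGE_ID = "EX_o2"
OXYGEN_EXTERNAL_ID = "o2_e"


def carbon_pool_ecs(panel_index: int) -> tuple[str, str]:
    """Fake-namespace EC pair (pool A, pool B) for the carbon at the given
    1-based panel position."""
    return f"9.9.1.{panel_index}", f"9.9.3.{panel_index}"


def supplement_synthesis_ec(panel_index: int) -> str:
    return f"9.9.2.{panel_index}"


@dataclass(frozen=True)
class ReactionTemplate:
    """Universal model plus the panel bookkeeping needed to plant and
    recover growth phenotypes."""

    universal: MetabolicModel
    carbon_panel: CarbonPanel
    supplement_panel: SupplementPanel
    biomass_id: str = BIOMASS_ID

    @property
    def carbon_ecs(self) -> dict[str, tuple[str, str]]:
        return {
            cid: carbon_pool_ecs(i)
            for i, cid in enumerate(self.carbon_panel.ids, start=1)
        }

    @property
    def supplement_ecs(self) -> dict[str, str]:
        return {
            sid: supplement_synthesis_ec(j)
            for j, sid in enumerate(self.supplement_panel.ids, start=1)
        }

    def validate(self) -> None:
        self.universal.validate()
        biomass = self.universal.get_reaction(self.biomass_id)
        internal_inputs = [
            m
            for m, c in biomass.stoichiometry.items()
            if c < 0 and self.universal.get_metabolite(m).compartment == "internal"
        ]
        if not internal_inputs:
            raise ModelValidationError(
                "biomass reaction must consume at least one internal precursor"
            )
        # exactly one exchange per external metabolite
        counts: dict[str, int] = {}
        for r in self.universal.reactions:
            if self.universal.is_exchange(r):
                (met,) = r.stoichiometry
                counts[met] = counts.get(met, 0) + 1
        for m in self.universal.metabolites:
            if m.compartment == "external" and counts.get(m.id, 0) != 1:
                raise ModelValidationError(
                    f"external metabolite {m.id!r} has {counts.get(m.id, 0)} "
                    "exchange reactions; exactly one required"
                )


def build_template(
    n_carbons: int,
    n_supplements: int,
    *,
    carbon_panel: CarbonPanel | None = None,
    supplement_panel: SupplementPanel | None = None,
) -> ReactionTemplate:
    """Construct the universal template for a carbon/supplement panel.

    ``n_carbons`` must be >= 1; ``n_supplements`` may be 0.  Explicit panels
    override the packaged defaults (their sizes then win).
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if n_supplements < 0:
        raise ValueError("n_supplements must be >= 0")
    panel = carbon_panel if carbon_panel is not None else synthetic_carbon_panel(n_carbons)
    supps = (
        supplement_panel
        if supplement_panel is not None
        else synthetic_supplement_panel(n_supplements)
    )

    mets: list[Metabolite] = [
        Metabolite("pool_a_c", "precursor pool A", "internal"),
        Metabolite("pool_b_c", "precursor pool B", "internal"),
        Metabolite(OXYGEN_EXTERNAL_ID, "oxygen", "external"),
    ]
    rxns: list[Reaction] = [
        Reaction(OXYGEN_EXCHANGE_ID, {OXYGEN_EXTERNAL_ID: -1.0})
    ]

    for i, carbon in enumerate(panel.carbons, start=1):
        cid = carbon.carbon_id
        ec_a, ec_b = carbon_pool_ecs(i)
        mets.append(Metabolite(f"{cid}_e", carbon.name, "external"))
        mets.append(Metabolite(f"{cid}_c", carbon.name, "internal"))
        rxns.append(Reaction(f"EX_{cid}", {f"{cid}_e": -1.0}))
        rxns.append(Reaction(f"TP_{cid}", {f"{cid}_e": -1.0, f"{cid}_c": 1.0}))
        rxns.append(
            Reaction(
                f"CAT_{cid}_a",
                {f"{cid}_c": -1.0, "pool_a_c": 1.0},
                ec_numbers=frozenset({ec_a}),
            )
        )
        rxns.append(
            Reaction(
                f"CAT_{cid}_b",
                {f"{cid}_c": -1.0, "pool_b_c": 1.0},
                ec_numbers=frozenset({ec_b}),
            )
        )

    biomass_stoich: dict[str, float] = {
        "pool_a_c": -POOL_A_DEMAND,
        "pool_b_c": -POOL_B_DEMAND,
    }

    for j, (sid, name) in enumerate(supps.supplements, start=1):
        mets.append(Metabolite(f"{sid}_e", name, "external"))
        mets.append(Metabolite(f"{sid}_c", name, "internal"))
        rxns.append(Reaction(f"EX_{sid}", {f"{sid}_e": -1.0}))
        rxns.append(Reaction(f"TP_{sid}", {f"{sid}_e": -1.0, f"{sid}_c": 1.0}))
        rxns.append(
            Reaction(
                f"SYN_{sid}",
                {"pool_a_c": -1.0, f"{sid}_c": 1.0},
                ec_numbers=frozenset({supplement_synthesis_ec(j)}),
            )
        )
        biomass_stoich[f"{sid}_c"] = -SUPPLEMENT_DEMAND

    for compound, demand in BASE_DEMAND.items():
        mets.append(Metabolite(f"{compound}_e", compound, "external"))
        mets.append(Metabolite(f"{compound}_c", compound, "internal"))
        rxns.append(Reaction(f"EX_{compound}", {f"{compound}_e": -1.0}))
        rxns.append(Reaction(f"TP_{compound}", {f"{compound}_e": -1.0, f"{compound}_c": 1.0}))
        biomass_stoich[f"{compound}_c"] = -demand
    # water and protons are medium compounds with exchanges but no biomass
    # demand; they keep the base medium file honest without constraining
    for compound in ("h2o", "h"):
        mets.append(Metabolite(f"{compound}_e", compound, "external"))
        rxns.append(Reaction(f"EX_{compound}", {f"{compound}_e": -1.0}))

    rxns.append(Reaction(BIOMASS_ID, biomass_stoich))

    universal = MetabolicModel(
        model_id="universal_template",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=BIOMASS_ID,
    )
    template = ReactionTemplate(universal, panel, supps)
    template.validate()
    return template


def base_medium_uptakes() -> dict[str, float]:
    """External metabolite ids and rates of the packaged base medium."""
    return {f"{c}_e": rate for c, rate in load_base_medium_compounds().items()}
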
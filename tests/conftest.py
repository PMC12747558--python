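import pytest

from hydroscreen.fba import medium_from_compounds
from hydroscreen.panels import load_base_medium_compounds
from hydroscreen.model import MetabolicModel, Metabolite, Reaction
from hydroscreen.synthetic import SyntheticConfig, generate_cohort
from hydroscreen.templates import build_template


@pytest.fixture(scope="session")
def small_template():
    """5-carbon, 2-supplement template: big enough for every phenotype."""
    return build_template(5, 2)


@pytest.fixture(scope="session")
def base():
    """Packaged base minimal medium (anaerobic, no carbons/supplements)."""
    return medium_from_compounds("base_medium_v1", load_base_medium_compounds())


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-MAG cohort on the small panel."""
    config = SyntheticConfig(
        n_mags=60, seed=11, n_carbons=5, n_supplements=2,
        single_carbon_fraction=0.7, auxotroph_fraction=0.4,
    )
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture()
def chain_model():
    """EX -> transport -> biomass chain with unit stoichiometry: the
    biomass optimum equals the opened uptake rate."""
    return MetabolicModel(
        "chain",
        metabolites=[Metabolite("a_e", compartment="external"),
                     Metabolite("a_c", compartment="internal")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}),
            Reaction("TP_a", {"a_e": -1.0, "a_c": 1.0}),
            Reaction("BIOMASS", {"a_c": -1.0}),
        ],
        objective_reaction_id="BIOMASS",
    )
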
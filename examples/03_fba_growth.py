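"""Reconstruct a draft model from an EC set and simulate growth with FBA.

The draft keeps every template reaction whose EC annotation occurs in the
genome, plus exchanges, transports and biomass.  Applying a medium opens
uptake bounds on the matching exchange reactions; flux balance analysis
then maximizes biomass flux at steady state.
"""

from hydroscreen import (
    apply_medium,
    build_draft_model,
    build_template,
    check_growth,
    load_run_config,
    solve_fba,
)
from hydroscreen.pipeline import base_medium
from hydroscreen.templates import carbon_pool_ecs, supplement_synthesis_ec

template = build_template(n_carbons=53, n_supplements=5)
base = base_medium(load_run_config())

# a genome with the full glucose route and all supplement biosyntheses
ec_set = set(carbon_pool_ecs(1)) | {supplement_synthesis_ec(j) for j in range(1, 6)}
model = build_draft_model(ec_set, template, model_id="demo")

for carbon in ("c01_glucose", "c05_xylose"):
    medium = base.plus(f"base+{carbon}", {f"{carbon}_e": 10.0})
    solution = solve_fba(apply_medium(model, medium))
    verdict = "grows" if check_growth(solution) else "no growth"
    print(f"{carbon:14s} biomass flux = {solution.objective_value:.4f}  ({verdict})")

# Glucose feeds both biomass precursor pools through the annotated route,
# so biomass flux is positive (uptake 10 mmol/gDW/h minus the supplement
# synthesis overhead); xylose has no route in this genome, so flux is 0.
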
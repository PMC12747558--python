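"""Carbon-source utilization spectra and nutritional requirements.

For each draft model the panel is screened one carbon at a time on the
base minimal medium; MAGs failing every single carbon are searched for a
smallest multi-carbon combination (sizes 2..max_k, panel order, first hit
wins and is re-verified minimal); trace-supplement requirements are called
by leave-one-out deletion from a growth-supporting medium.

Carbon screening is run with all trace supplements present, so that
auxotrophies do not mask carbon requirements; essentiality is then probed
separately.  The two requirement axes are therefore identified
independently, matching how the planted ground truth is constructed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .fba import (
    DEFAULT_UPTAKE,
    FbaSolverError,
    Medium,
    apply_medium,
    check_growth,
    solve_fba,
)
from .model import MetabolicModel
from .panels import CarbonPanel

GROWTH_CLASSES = ("single_carbon", "multi_carbon", "no_growth")

DEFAULT_MAX_K = 3


class NoGrowthError(RuntimeError):
    """The model cannot grow even on the richest probed medium."""


@dataclass(frozen=True)
class UtilizationSpectrum:
    model_id: str
    carbon_ids: tuple[str, ...]
    growth: tuple[bool, ...]                  # single-carbon calls, panel order
    minimal_carbon_combo: frozenset[str]      # size 1, >=2, or empty (no growth)
    required_supplements: frozenset[str]
    growth_class: str

    def __post_init__(self) -> None:
        if self.growth_class not in GROWTH_CLASSES:
            raise ValueError(f"unknown growth class {self.growth_class!r}")
        if len(self.growth) != len(self.carbon_ids):
            raise ValueError("growth vector length must match the panel")

    @property
    def usable_alone(self) -> frozenset[str]:
        return frozenset(c for c, g in zip(self.carbon_ids, self.growth) if g)


def _carbon_medium(base: Medium, carbon_ids, uptake: float) -> Medium:
    extra = {f"{c}_e": uptake for c in carbon_ids}
    return base.plus(f"{base.medium_id}+{'+'.join(carbon_ids)}", extra)


def _grows(model: MetabolicModel, medium: Medium, threshold: float) -> bool:
    return check_growth(solve_fba(apply_medium(model, medium)), threshold)


def single_carbon_spectrum(
    model: MetabolicModel,
    panel: CarbonPanel,
    base: Medium,
    *,
    uptake: float = DEFAULT_UPTAKE,
    threshold: float = 1e-6,
) -> list[bool]:
    """Growth call for each panel carbon added alone to the base medium.

    The base medium must not already contain a panel carbon.  Solver
    failures propagate with the offending carbon attached.
    """
    clash = sorted(
        c for c in panel.ids if f"{c}_e" in base.uptakes
    )
    if clash:
        raise ValueError(
            f"base medium {base.medium_id!r} already contains panel "
            f"carbon(s): {', '.join(clash)}"
        )
    calls: list[bool] = []
    for cid in panel.ids:
        try:
            calls.append(_grows(model, _carbon_medium(base, [cid], uptake), threshold))
        except FbaSolverError as exc:
            raise FbaSolverError(f"carbon {cid}: {exc}") from exc
    return calls


def find_minimal_carbon_combination(
    model: MetabolicModel,
    panel: CarbonPanel,
    base: Medium,
    max_k: int = DEFAULT_MAX_K,
    *,
    uptake: float = DEFAULT_UPTAKE,
    threshold: float = 1e-6,
    singles: list[bool] | None = None,
) -> frozenset[str] | None:
    """Smallest carbon subset (size <= max_k) supporting growth, or None.

    Searched in increasing size and panel order; the winner's minimality
    is re-verified against all its proper subsets.  A precomputed
    single-carbon vector may be passed to skip re-testing size 1.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if singles is None:
        singles = single_carbon_spectrum(
            model, panel, base, uptake=uptake, threshold=threshold
        )
    for cid, grows in zip(panel.ids, singles):
        if grows:
            return frozenset({cid})
    for k in range(2, max_k + 1):
        for combo in itertools.combinations(panel.ids, k):
            if _grows(model, _carbon_medium(base, combo, uptake), threshold):
                for r in range(1, k):
                    for sub in itertools.combinations(combo, r):
                        if _grows(model, _carbon_medium(base, sub, uptake), threshold):
                            raise AssertionError(
                                f"combination search returned non-minimal "
                                f"{combo}: proper subset {sub} already grows"
                            )
                return frozenset(combo)
    return None


def detect_essential_supplements(
    model: MetabolicModel,
    growth_medium: Medium,
    supplement_ids,
    *,
    threshold: float = 1e-6,
) -> frozenset[str]:
    """Leave-one-out supplement essentiality.

    ``growth_medium`` must contain every supplement and support growth;
    a supplement is essential when removing it alone abolishes growth.
    """
    if not _grows(model, growth_medium, threshold):
        raise NoGrowthError(
            f"model {model.model_id!r} does not grow on {growth_medium.medium_id!r} "
            "even with all supplements present"
        )
    essential = set()
    for sid in supplement_ids:
        reduced = growth_medium.without(f"{growth_medium.medium_id}-{sid}",
                                        frozenset({f"{sid}_e"}))
        if not _grows(model, reduced, threshold):
            essential.add(sid)
    return frozenset(essential)


def characterize_model(
    model: MetabolicModel,
    panel: CarbonPanel,
    base: Medium,
    supplement_ids,
    *,
    uptake: float = DEFAULT_UPTAKE,
    threshold: float = 1e-6,
    max_k: int = DEFAULT_MAX_K,
) -> UtilizationSpectrum:
    """Full per-model characterization: spectrum, minimal combo, supplements.

    ``base`` is the supplement-free minimal medium; carbon screening runs
    with all supplements added so auxotrophies cannot mask carbon calls.
    """
    supplement_ids = list(supplement_ids)
    base_plus_supps = base.plus(
        f"{base.medium_id}+supps", {f"{s}_e": uptake for s in supplement_ids}
    )
    singles = single_carbon_spectrum(
        model, panel, base_plus_supps, uptake=uptake, threshold=threshold
    )
    if any(singles):
        combo = frozenset({panel.ids[singles.index(True)]})
        growth_class = "single_carbon"
    else:
        combo = find_minimal_carbon_combination(
            model, panel, base_plus_supps, max_k,
            uptake=uptake, threshold=threshold, singles=singles,
        )
        growth_class = "multi_carbon" if combo else "no_growth"
    if combo:
        growth_medium = _carbon_medium(base_plus_supps, sorted(combo), uptake)
        required = detect_essential_supplements(
            model, growth_medium, supplement_ids, threshold=threshold
        )
    else:
        combo = frozenset()
        required = frozenset()
    return UtilizationSpectrum(
        model_id=model.model_id,
        carbon_ids=tuple(panel.ids),
        growth=tuple(singles),
        minimal_carbon_combo=combo,
        required_supplements=required,
        growth_class=growth_class,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_spectrum_matrix(spectra: list[UtilizationSpectrum], path) -> None:
    """0/1 growth matrix, rows = MAG models, columns = panel carbons."""
    if not spectra:
        pd.DataFrame(columns=["mag_id"]).to_csv(path, sep="\t", index=False)
        return
    carbon_ids = spectra[0].carbon_ids
    rows = [
        {"mag_id": s.model_id, **{c: int(g) for c, g in zip(s.carbon_ids, s.growth)}}
        for s in spectra
    ]
    pd.DataFrame(rows, columns=["mag_id", *carbon_ids]).to_csv(path, sep="\t", index=False)


def write_requirements(spectra: list[UtilizationSpectrum], path) -> None:
    rows = [{
        "mag_id": s.model_id,
        "growth_class": s.growth_class,
        "minimal_carbon_combo": ";".join(sorted(s.minimal_carbon_combo)),
        "required_supplements": ";".join(sorted(s.required_supplements)),
    } for s in spectra]
    pd.DataFrame(
        rows,
        columns=["mag_id", "growth_class", "minimal_carbon_combo", "required_supplements"],
    ).to_csv(path, sep="\t", index=False)
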
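"""Selective-media design: candidate enumeration and greedy set cover.

Each candidate medium is one observed requirement pattern — a minimal
carbon set (or a single usable carbon) together with the required trace
supplements.  A candidate covers a MAG when its carbons satisfy the MAG's
carbon requirement (intersection for single-carbon growers, superset for
multi-carbon combos) and its supplements include every required one.

The final panel is chosen by classic greedy set cover (largest uncovered
gain first; ties broken by fewer composition components, then by
lexicographic composition), giving the standard H(d) approximation
guarantee.  Every (medium, MAG) claim can be re-certified by an FBA
growth check so subsumption-logic bugs can never survive into a design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .spectrum import UtilizationSpectrum

logger = logging.getLogger(__name__)


class CertificationError(RuntimeError):
    """A claimed (medium, MAG) growth pair failed its FBA re-check."""


@dataclass(frozen=True)
class CandidateMedium:
    carbons: frozenset[str]
    supplements: frozenset[str]
    covered: frozenset[str]

    @property
    def composition_key(self) -> tuple:
        return (len(self.carbons) + len(self.supplements),
                tuple(sorted(self.carbons)), tuple(sorted(self.supplements)))


@dataclass(frozen=True)
class MediaFormulation:
    medium_id: str
    base_medium: str
    carbons: frozenset[str]
    supplements: frozenset[str]
    covered: frozenset[str]
    selectivity: float  # covered count / total candidate MAGs


def medium_satisfies(
    carbons: frozenset[str], supplements: frozenset[str], spectrum: UtilizationSpectrum,
) -> bool:
    """Requirement subsumption: does a composition satisfy one MAG?"""
    if spectrum.growth_class == "no_growth":
        return False
    if not spectrum.required_supplements <= supplements:
        return False
    if spectrum.growth_class == "single_carbon":
        return bool(carbons & spectrum.usable_alone)
    return spectrum.minimal_carbon_combo <= carbons


def enumerate_candidate_media(
    spectra: list[UtilizationSpectrum],
) -> list[CandidateMedium]:
    """One candidate per distinct requirement pattern, deduplicated by
    composition, coverage computed by subsumption over all MAGs."""
    if not spectra:
        logger.warning("no spectra supplied; candidate medium list is empty")
        return []
    compositions: set[tuple[frozenset[str], frozenset[str]]] = set()
    for s in spectra:
        if s.growth_class == "no_growth":
            continue
        compositions.add((s.minimal_carbon_combo, s.required_supplements))
    candidates = []
    for carbons, supplements in compositions:
        covered = frozenset(
            s.model_id for s in spectra if medium_satisfies(carbons, supplements, s)
        )
        candidates.append(CandidateMedium(carbons, supplements, covered))
    candidates.sort(key=lambda c: c.composition_key)
    return candidates


def greedy_media_cover(
    candidates: list[CandidateMedium],
    targets: set[str] | frozenset[str],
    *,
    base_medium: str = "base_medium_v1",
    certifier=None,
) -> tuple[list[MediaFormulation], frozenset[str]]:
    """Greedy set cover of the target MAGs by candidate media.

    Returns ``(formulations, uncoverable_targets)``.  When ``certifier``
    is given it is called as ``certifier(mag_id, carbons, supplements)``
    for every claimed pair and must return True, else
    :class:`CertificationError` is raised.
    """
    targets = frozenset(targets)
    if not targets:
        return [], frozenset()
    if not candidates:
        raise ValueError("greedy_media_cover requires a non-empty candidate list")
    coverable = targets & frozenset().union(*(c.covered for c in candidates))
    uncoverable = targets - coverable
    uncovered = set(coverable)
    chosen: list[CandidateMedium] = []
    while uncovered:
        best_gain = max(len(c.covered & uncovered) for c in candidates)
        if best_gain == 0:
            break
        # ties: fewer composition components, then lexicographic composition
        tied = [c for c in candidates if len(c.covered & uncovered) == best_gain]
        best = min(tied, key=lambda c: c.composition_key)
        chosen.append(best)
        uncovered -= best.covered
    formulations = []
    for k, cand in enumerate(chosen, start=1):
        covered = cand.covered & targets
        if certifier is not None:
            for mag_id in sorted(covered):
                if not certifier(mag_id, cand.carbons, cand.supplements):
                    raise CertificationError(
                        f"medium {k} claims MAG {mag_id} but the FBA re-check "
                        "finds no growth"
                    )
        formulations.append(MediaFormulation(
            medium_id=f"medium_{k:02d}",
            base_medium=base_medium,
            carbons=cand.carbons,
            supplements=cand.supplements,
            covered=covered,
            selectivity=len(covered) / len(targets),
        ))
    return formulations, uncoverable


@dataclass(frozen=True)
class CoverageReport:
    per_medium: pd.DataFrame
    n_media: int
    coverage_fraction: float
    agreement: float | None = None


def coverage_report(
    formulations: list[MediaFormulation],
    targets: set[str] | frozenset[str],
    ground_truth=None,
    spectra: list[UtilizationSpectrum] | None = None,
) -> CoverageReport:
    """Per-medium coverage counts and overall coverage fraction.

    With planted ground truth (and the recovered spectra), additionally
    reports the fraction of targets whose recovered requirement pattern
    (minimal combo + required supplements) matches the planted one.
    """
    targets = frozenset(targets)
    rows = [{
        "medium_id": f.medium_id,
        "n_carbons": len(f.carbons),
        "n_supplements": len(f.supplements),
        "covered": len(f.covered),
        "selectivity": f.selectivity,
        "carbons": ";".join(sorted(f.carbons)),
        "supplements": ";".join(sorted(f.supplements)),
    } for f in formulations]
    per_medium = pd.DataFrame(rows, columns=[
        "medium_id", "n_carbons", "n_supplements", "covered", "selectivity",
        "carbons", "supplements",
    ])
    covered_union = frozenset().union(*(f.covered for f in formulations)) \
        if formulations else frozenset()
    coverage = len(covered_union & targets) / len(targets) if targets else 1.0
    agreement = None
    if ground_truth is not None and spectra is not None:
        by_id = {s.model_id: s for s in spectra}
        hits = total = 0
        for mag_id in targets:
            if mag_id not in by_id or mag_id not in ground_truth.entries:
                continue
            total += 1
            s, e = by_id[mag_id], ground_truth.entries[mag_id]
            if (s.minimal_carbon_combo == e.minimal_carbon_combo
                    and s.required_supplements == e.required_supplements):
                hits += 1
        agreement = hits / total if total else None
    return CoverageReport(per_medium, len(formulations), coverage, agreement)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_formulations(formulations: list[MediaFormulation], path) -> None:
    """Long-format composition table: medium_id, component, role."""
    rows = []
    for f in formulations:
        rows.append({"medium_id": f.medium_id, "component": f.base_medium, "role": "base"})
        for c in sorted(f.carbons):
            rows.append({"medium_id": f.medium_id, "component": c, "role": "carbon"})
        for s in sorted(f.supplements):
            rows.append({"medium_id": f.medium_id, "component": s, "role": "supplement"})
    pd.DataFrame(rows, columns=["medium_id", "component", "role"]).to_csv(
        path, sep="\t", index=False
    )


def write_coverage_matrix(
    formulations: list[MediaFormulation], targets, path,
) -> None:
    """0/1 matrix, rows = media, columns = target MAGs."""
    targets = sorted(targets)
    rows = [
        {"medium_id": f.medium_id, **{t: int(t in f.covered) for t in targets}}
        for f in formulations
    ]
    pd.DataFrame(rows, columns=["medium_id", *targets]).to_csv(path, sep="\t", index=False)
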
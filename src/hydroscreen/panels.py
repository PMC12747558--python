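"""Carbon-source and supplement panels, and the base minimal medium.

The default carbon panel has 53 compounds spanning sugars, organic acids,
sugar alcohols and amino acids — the compound classes screened when
simulating growth of candidate hydrogen producers.  The base minimal
medium (N, P, S sources, ions, water) is always available; carbons and
trace supplements are added per experiment.  All three ship as versioned
TSV files inside the package so that every run is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CARBON_CLASSES = ("sugar", "organic acid", "sugar alcohol", "amino acid")


@dataclass(frozen=True)
class CarbonSource:
    carbon_id: str
    name: str
    carbon_class: str


@dataclass(frozen=True)
class CarbonPanel:
    """Ordered carbon-source panel; search order is panel order."""

    carbons: tuple[CarbonSource, ...]

    def __post_init__(self) -> None:
        ids = [c.carbon_id for c in self.carbons]
        if len(set(ids)) != len(ids):
            raise ValueError("carbon panel ids must be unique")
        for c in self.carbons:
            if c.carbon_class not in CARBON_CLASSES:
                raise ValueError(
                    f"{c.carbon_id}: class {c.carbon_class!r} not in {CARBON_CLASSES}"
                )

    @property
    def ids(self) -> list[str]:
        return [c.carbon_id for c in self.carbons]

    def __len__(self) -> int:
        return len(self.carbons)

    def __contains__(self, carbon_id: str) -> bool:
        return carbon_id in set(self.ids)

    def subset(self, n: int) -> "CarbonPanel":
        if not 1 <= n <= len(self.carbons):
            raise ValueError(f"panel subset size must be in [1, {len(self.carbons)}]")
        return CarbonPanel(self.carbons[:n])


@dataclass(frozen=True)
class SupplementPanel:
    """Trace supplements (vitamins/cofactors) screened for essentiality."""

    supplements: tuple[tuple[str, str], ...] = field(default_factory=tuple)  # (id, name)

    @property
    def ids(self) -> list[str]:
        return [s for s, _ in self.supplements]

    def __len__(self) -> int:
        return len(self.supplements)

    def subset(self, n: int) -> "SupplementPanel":
        if not 0 <= n <= len(self.supplements):
            raise ValueError("supplement subset out of range")
        return SupplementPanel(self.supplements[:n])


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hydroscreen").joinpath("data", name)))


def load_carbon_panel(path: str | Path | None = None) -> CarbonPanel:
    """Load a carbon panel TSV (columns carbon_id, name, class).

    With no path, loads the packaged 53-compound panel ``carbon_panel_v1``.
    """
    path = _data_path("carbon_panel_v1.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    return CarbonPanel(
        tuple(
            CarbonSource(row["carbon_id"], row["name"], row["class"])
            for _, row in df.iterrows()
        )
    )


def load_supplement_panel(path: str | Path | None = None) -> SupplementPanel:
    path = _data_path("supplements_v1.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    return SupplementPanel(tuple(zip(df["supplement_id"], df["name"])))


def load_base_medium_compounds(path: str | Path | None = None) -> dict[str, float]:
    """Base minimal-medium compounds and their max uptake rates."""
    path = _data_path("base_medium_v1.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["compound"], df["rate"].astype(float)))


def synthetic_carbon_panel(n_carbons: int) -> CarbonPanel:
    """First ``n_carbons`` compounds of the packaged panel; for larger
    panels, numbered synthetic carbons are appended."""
    base = load_carbon_panel()
    if n_carbons <= len(base):
        return base.subset(n_carbons)
    extra = tuple(
        CarbonSource(f"c{i:02d}_synth", f"synthetic carbon {i}", "sugar")
        for i in range(len(base) + 1, n_carbons + 1)
    )
    return CarbonPanel(base.carbons + extra)


def synthetic_supplement_panel(n_supplements: int) -> SupplementPanel:
    base = load_supplement_panel()
    if n_supplements <= len(base):
        return base.subset(n_supplements)
    extra = tuple(
        (f"s{i}_synth", f"synthetic supplement {i}")
        for i in range(len(base) + 1, n_supplements + 1)
    )
    return SupplementPanel(base.supplements + extra)
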
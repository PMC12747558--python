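"""Synthetic MAG cohorts with planted, provable ground truth.

Every downstream stage (screening, reconstruction, growth simulation,
media design) is tested against cohorts generated here, because the
planted truth is recoverable *by construction*:

* triad-enzyme presence is planted directly into each MAG's EC set —
  candidacy is a pure membership question;
* carbon usability is planted through the fake-namespace pathway ECs of
  the two-pool template (see :mod:`hydroscreen.templates`): a
  single-carbon grower receives both pool ECs of each usable carbon,
  while a multi-carbon MAG receives the pool-A EC of one combo carbon and
  the pool-B EC of the other, so no single carbon can feed both pools;
* auxotrophies are planted by withholding the biosynthesis EC of the
  required supplement.

Randomness uses one root seed with an independent child stream per MAG
(``default_rng([seed, index])``), so a cohort prefix is stable when
``n_mags`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gem import build_draft_model
from .model import MetabolicModel
from .screening import TRIAD, TRIAD_NAMES, MagRecord
from .templates import ReactionTemplate, build_template

# fixed decoy annotation pool: real, fully specified ECs that are neither
# triad markers nor in the reserved synthetic namespace
DECOY_ECS = (
    "1.1.1.1", "1.1.1.27", "1.2.1.12", "1.3.8.1", "1.6.5.3",
    "2.3.1.8", "2.3.1.9", "2.3.1.19", "2.7.1.1", "2.7.1.2",
    "2.7.1.40", "2.7.2.3", "2.8.3.8", "4.1.2.13", "4.2.1.11",
    "4.2.1.17", "5.3.1.9", "5.4.2.11", "6.2.1.1", "1.1.1.157",
)

_BACTERIAL_TAXA = (
    ("Bacillota", "Clostridium"),
    ("Bacillota", "Ruminiclostridium"),
    ("Bacillota", "Bacillus"),
    ("Bacteroidota", "Bacteroides"),
    ("Bacteroidota", "Prevotella"),
    ("Pseudomonadota", "Escherichia"),
    ("Pseudomonadota", "Desulfovibrio"),
    ("Actinomycetota", "Bifidobacterium"),
    ("Spirochaetota", "Treponema"),
    ("Thermotogota", "Thermotoga"),
)
_ARCHAEAL_TAXA = (
    ("Euryarchaeota", "Methanosarcina"),
    ("Euryarchaeota", "Methanoculleus"),
    ("Halobacterota", "Methanosaeta"),
)
_SAMPLE_CODES = ("YT", "ML", "NP", "NL", "JB", "JX", "CL", "CS", "ZS", "WT", "YH")


class ConfigError(ValueError):
    """A synthetic cohort configuration is invalid; names the field."""


class ConsistencyError(ValueError):
    """A ground-truth entry references panels absent from the template."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a planted cohort.

    Defaults mirror the screened study cohort: 281 MAGs passing quality
    gates, marker prevalences giving ≈76% of MAGs at least one triad
    enzyme, a 53-carbon panel with 93% of growers needing only a single
    carbon, and a minority of trace-supplement auxotrophs.
    """

    n_mags: int = 281
    seed: int = 0
    completeness_range: tuple[float, float] = (70.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 10.0)
    enzyme_prevalence: dict[str, float] = field(
        default_factory=lambda: {"FDH": 0.30, "AK": 0.50, "BK": 0.33}
    )
    archaea_fraction: float = 0.021
    n_carbons: int = 53
    n_supplements: int = 5
    single_carbon_fraction: float = 0.93
    auxotroph_fraction: float = 0.25

    def validate(self) -> None:
        if self.n_mags < 1:
            raise ConfigError("n_mags must be >= 1")
        if self.n_carbons < 1:
            raise ConfigError("n_carbons must be >= 1")
        if self.n_supplements < 0:
            raise ConfigError("n_supplements must be >= 0")
        for name, rng_pair, limits in (
            ("completeness_range", self.completeness_range, (0.0, 100.0)),
            ("contamination_range", self.contamination_range, (0.0, float("inf"))),
        ):
            lo, hi = rng_pair
            if not (limits[0] <= lo <= hi <= limits[1]):
                raise ConfigError(f"{name} must be ordered within {limits}, got {rng_pair}")
        if set(self.enzyme_prevalence) != set(TRIAD_NAMES):
            raise ConfigError(
                f"enzyme_prevalence must have exactly the keys {TRIAD_NAMES}"
            )
        for name, p in (
            *self.enzyme_prevalence.items(),
            ("archaea_fraction", self.archaea_fraction),
            ("single_carbon_fraction", self.single_carbon_fraction),
            ("auxotroph_fraction", self.auxotroph_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if self.single_carbon_fraction < 1.0 and self.n_carbons < 2:
            raise ConfigError(
                "single_carbon_fraction < 1 requires n_carbons >= 2 "
                "(multi-carbon combos need two carbons)"
            )
        if self.auxotroph_fraction > 0.0 and self.n_supplements < 1:
            raise ConfigError(
                "auxotroph_fraction > 0 requires n_supplements >= 1"
            )


@dataclass(frozen=True)
class GroundTruthEntry:
    is_candidate: bool
    usable_carbons: frozenset[str]
    minimal_carbon_combo: frozenset[str]
    required_supplements: frozenset[str]

    @property
    def growth_class(self) -> str:
        if len(self.minimal_carbon_combo) == 1:
            return "single_carbon"
        if len(self.minimal_carbon_combo) >= 2:
            return "multi_carbon"
        return "no_growth"

    @property
    def singly_usable_carbons(self) -> frozenset[str]:
        """Carbons supporting growth *alone*: all usable carbons for a
        single-carbon grower, none for a multi-carbon MAG."""
        return self.usable_carbons if self.growth_class == "single_carbon" else frozenset()


@dataclass(frozen=True)
class GroundTruth:
    entries: dict[str, GroundTruthEntry]
    carbon_ids: tuple[str, ...]
    supplement_ids: tuple[str, ...]


def _growth_ec_set(entry: GroundTruthEntry, template: ReactionTemplate) -> frozenset[str]:
    """ECs encoding the planted growth phenotype against a template."""
    carbon_ecs = template.carbon_ecs
    supplement_ecs = template.supplement_ecs
    missing = (entry.usable_carbons - set(carbon_ecs)) | (
        entry.required_supplements - set(supplement_ecs)
    )
    if missing:
        raise ConsistencyError(
            f"ground truth references panel entries absent from the "
            f"template: {sorted(missing)}"
        )
    ecs: set[str] = set()
    combo = sorted(entry.minimal_carbon_combo)
    if len(combo) == 1:
        for cid in entry.usable_carbons:
            ec_a, ec_b = carbon_ecs[cid]
            ecs.update((ec_a, ec_b))
    elif len(combo) >= 2:
        # first combo carbon (panel order) feeds pool A, second pool B
        ec_a, _ = carbon_ecs[combo[0]]
        _, ec_b = carbon_ecs[combo[1]]
        ecs.update((ec_a, ec_b))
    for sid in supplement_ecs:
        if sid not in entry.required_supplements:
            ecs.add(supplement_ecs[sid])
    return frozenset(ecs)


def generate_cohort(config: SyntheticConfig) -> tuple[list[MagRecord], GroundTruth]:
    """Generate ``n_mags`` MAG records and their planted ground truth.

    Deterministic for a fixed seed; each MAG uses its own child stream so
    a prefix of the cohort is invariant under changes of ``n_mags``.
    """
    config.validate()
    template = build_template(config.n_carbons, config.n_supplements)
    carbon_ids = list(template.carbon_panel.ids)
    supplement_ids = list(template.supplement_panel.ids)

    records: list[MagRecord] = []
    entries: dict[str, GroundTruthEntry] = {}
    for i in range(config.n_mags):
        rng = np.random.default_rng([config.seed, i])
        mag_id = f"MAG_{i + 1:04d}"
        completeness = float(rng.uniform(*config.completeness_range))
        contamination = float(rng.uniform(*config.contamination_range))
        is_archaeon = bool(rng.random() < config.archaea_fraction)
        taxa = _ARCHAEAL_TAXA if is_archaeon else _BACTERIAL_TAXA
        phylum, genus = taxa[int(rng.integers(len(taxa)))]
        sample_id = _SAMPLE_CODES[int(rng.integers(len(_SAMPLE_CODES)))]

        triad_present = frozenset(
            ec for name, ec in zip(TRIAD_NAMES, TRIAD)
            if rng.random() < config.enzyme_prevalence[name]
        )

        single = bool(rng.random() < config.single_carbon_fraction)
        if single or config.n_carbons < 2:
            n_extra_max = min(7, config.n_carbons - 1)
            breadth = 1 + int(rng.binomial(n_extra_max, 0.3)) if n_extra_max else 1
            picked = rng.choice(config.n_carbons, size=breadth, replace=False)
            usable = frozenset(carbon_ids[j] for j in picked)
            combo = frozenset({min(usable, key=carbon_ids.index)})
        else:
            pair = rng.choice(config.n_carbons, size=2, replace=False)
            usable = frozenset(carbon_ids[j] for j in sorted(pair))
            combo = usable

        if config.n_supplements and rng.random() < config.auxotroph_fraction:
            n_req = min(config.n_supplements, 1 + int(rng.random() < 0.3))
            picked_s = rng.choice(config.n_supplements, size=n_req, replace=False)
            required = frozenset(supplement_ids[j] for j in picked_s)
        else:
            required = frozenset()

        entry = GroundTruthEntry(
            is_candidate=bool(triad_present),
            usable_carbons=usable,
            minimal_carbon_combo=combo,
            required_supplements=required,
        )
        entries[mag_id] = entry

        n_decoys = int(rng.integers(5, 16))
        decoys = frozenset(
            DECOY_ECS[j] for j in rng.choice(len(DECOY_ECS), size=n_decoys, replace=False)
        )
        ec_numbers = triad_present | _growth_ec_set(entry, template) | decoys

        records.append(MagRecord(
            mag_id=mag_id,
            sample_id=sample_id,
            taxonomy={
                "domain": "Archaea" if is_archaeon else "Bacteria",
                "phylum": phylum,
                "genus": genus,
            },
            completeness=completeness,
            contamination=contamination,
            ec_numbers=ec_numbers,
        ))

    truth = GroundTruth(entries, tuple(carbon_ids), tuple(supplement_ids))
    return records, truth


def instantiate_model(
    entry: GroundTruthEntry, template: ReactionTemplate, model_id: str = "synthetic",
) -> MetabolicModel:
    """Build the metabolic model realising a planted phenotype.

    The model holds catabolic routes only for the planted usable carbons
    (for multi-carbon MAGs, pool-split so that only the combo jointly
    feeds biomass) and lacks the biosynthesis reactions of every required
    supplement.
    """
    return build_draft_model(_growth_ec_set(entry, template), template, model_id)


# ---------------------------------------------------------------------------
# ground-truth TSV (test/bench harness format)
# ---------------------------------------------------------------------------

GROUND_TRUTH_COLUMNS = [
    "mag_id", "is_candidate", "growth_class", "usable_carbons",
    "minimal_carbon_combo", "required_supplements",
]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for mag_id in sorted(truth.entries):
        e = truth.entries[mag_id]
        rows.append({
            "mag_id": mag_id,
            "is_candidate": int(e.is_candidate),
            "growth_class": e.growth_class,
            "usable_carbons": ";".join(sorted(e.usable_carbons)),
            "minimal_carbon_combo": ";".join(sorted(e.minimal_carbon_combo)),
            "required_supplements": ";".join(sorted(e.required_supplements)),
        })
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ground_truth(
    path: str | Path,
    carbon_ids: tuple[str, ...] = (),
    supplement_ids: tuple[str, ...] = (),
) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = {}
    for _, row in df.iterrows():
        entries[row["mag_id"]] = GroundTruthEntry(
            is_candidate=bool(int(row["is_candidate"])),
            usable_carbons=frozenset(x for x in row["usable_carbons"].split(";") if x),
            minimal_carbon_combo=frozenset(
                x for x in row["minimal_carbon_combo"].split(";") if x
            ),
            required_supplements=frozenset(
                x for x in row["required_supplements"].split(";") if x
            ),
        )
    return GroundTruth(entries, carbon_ids, supplement_ids)
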
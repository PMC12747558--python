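"""MAG quality filtering and hydrogen-producer triad classification.

Candidate anaerobic hydrogen producers are flagged by three marker
enzymes, one per fermentative hydrogen route:

* formate dehydrogenase (FDH, EC 1.17.1.9) — formate cleavage,
* acetate kinase (AK, EC 2.7.2.1) — acetate-type fermentation,
* butyrate kinase (BK, EC 2.7.2.7) — butyrate-type fermentation.

Quality gates use strict inequalities (completeness strictly greater than
the threshold, contamination strictly below), so MAGs sitting exactly on a
threshold fail.  EC matching is exact-string on fully specified four-field
EC numbers; partial ECs such as ``2.7.2.-`` never match, avoiding silent
over-calling.

Archaeal MAGs are flagged but, by default, not excluded from candidacy:
archaea carry the marker enzymes yet typically consume hydrogen en route
to methane, so downstream users may wish to drop them — that is a
reporting decision, not a screening one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

EC_FDH = "1.17.1.9"
EC_AK = "2.7.2.1"
EC_BK = "2.7.2.7"
TRIAD = (EC_FDH, EC_AK, EC_BK)
TRIAD_NAMES = ("FDH", "AK", "BK")

#: the 8 Venn regions, canonical order
VENN_REGIONS = (
    "none", "FDH", "AK", "BK", "FDH&AK", "FDH&BK", "AK&BK", "FDH&AK&BK",
)

_EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

TAXONOMY_RANKS = ("domain", "phylum", "genus")


class RecordValidationError(ValueError):
    """One or more MAG records carry impossible quality metrics."""


@dataclass(frozen=True)
class MagRecord:
    """One metagenome-assembled genome with its annotation summary."""

    mag_id: str
    sample_id: str
    taxonomy: dict[str, str]            # rank -> label, ranks domain..genus
    completeness: float                 # percent, [0, 100]
    contamination: float                # percent, >= 0
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ec_numbers", frozenset(self.ec_numbers))


@dataclass(frozen=True)
class QualityThresholds:
    """Strict quality gates: pass iff completeness > min_completeness and
    contamination < max_contamination; high-quality tier analogously."""

    min_completeness: float = 70.0
    max_contamination: float = 10.0
    hq_min_completeness: float = 90.0
    hq_max_contamination: float = 5.0

    def __post_init__(self) -> None:
        if (self.hq_min_completeness < self.min_completeness
                or self.hq_max_contamination > self.max_contamination):
            raise ValueError(
                "high-quality thresholds must be at least as stringent as "
                "the base thresholds"
            )


TIER_HIGH = "high_quality"
TIER_MEDIUM = "medium_quality"
TIER_FAIL = "fail"


@dataclass(frozen=True)
class TriadResult:
    mag_id: str
    has_fdh: bool
    has_ak: bool
    has_bk: bool
    venn_region: str
    is_candidate: bool
    archaeal_flag: bool


@dataclass(frozen=True)
class VennSummary:
    region_counts: dict[str, int]
    total_screened: int
    total_candidates: int


def validate_records(records: list[MagRecord]) -> None:
    bad = [
        r.mag_id
        for r in records
        if not (0.0 <= r.completeness <= 100.0) or r.contamination < 0.0
    ]
    if bad:
        raise RecordValidationError(
            "records with completeness outside [0, 100] or negative "
            f"contamination: {', '.join(bad)}"
        )


def filter_by_quality(
    records: list[MagRecord],
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[list[MagRecord], dict[str, str]]:
    """Quality-gate a cohort; returns (passing records, tier per MAG).

    Input order is preserved.  Tiers are ``high_quality`` /
    ``medium_quality`` for passers and ``fail`` otherwise.
    """
    if not records:
        raise ValueError("filter_by_quality requires a non-empty cohort")
    validate_records(records)
    passing: list[MagRecord] = []
    tiers: dict[str, str] = {}
    for r in records:
        if (r.completeness > thresholds.min_completeness
                and r.contamination < thresholds.max_contamination):
            passing.append(r)
            hq = (r.completeness > thresholds.hq_min_completeness
                  and r.contamination < thresholds.hq_max_contamination)
            tiers[r.mag_id] = TIER_HIGH if hq else TIER_MEDIUM
        else:
            tiers[r.mag_id] = TIER_FAIL
    return passing, tiers


def _venn_region(has_fdh: bool, has_ak: bool, has_bk: bool) -> str:
    present = [n for n, h in zip(TRIAD_NAMES, (has_fdh, has_ak, has_bk)) if h]
    return "&".join(present) if present else "none"


def classify_triad(record: MagRecord, rule: str = "any") -> TriadResult:
    """Classify one MAG by exact membership of the triad ECs.

    ``rule="any"`` (default) calls a candidate when at least one marker is
    present; ``rule="all"`` requires all three.  Malformed EC strings in
    the record are ignored with a warning, never fatal.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"rule must be 'any' or 'all', got {rule!r}")
    malformed = [e for e in record.ec_numbers if not _EC_PATTERN.match(e)]
    if malformed:
        logger.warning(
            "MAG %s: ignoring %d malformed EC string(s): %s",
            record.mag_id, len(malformed), ", ".join(sorted(malformed)[:5]),
        )
    ecs = record.ec_numbers - set(malformed)
    has_fdh, has_ak, has_bk = (EC_FDH in ecs), (EC_AK in ecs), (EC_BK in ecs)
    flags = (has_fdh, has_ak, has_bk)
    is_candidate = any(flags) if rule == "any" else all(flags)
    return TriadResult(
        mag_id=record.mag_id,
        has_fdh=has_fdh,
        has_ak=has_ak,
        has_bk=has_bk,
        venn_region=_venn_region(*flags),
        is_candidate=is_candidate,
        archaeal_flag=record.taxonomy.get("domain") == "Archaea",
    )


def venn_summary(results: list[TriadResult]) -> VennSummary:
    """Mutually exclusive region counts over the three marker enzymes.

    Counts always sum to the number screened; under the "any" rule the
    candidate total equals the inclusion–exclusion union |FDH ∪ AK ∪ BK|.
    """
    counts = {region: 0 for region in VENN_REGIONS}
    for res in results:
        counts[_venn_region(res.has_fdh, res.has_ak, res.has_bk)] += 1
    total = len(results)
    return VennSummary(
        region_counts=counts,
        total_screened=total,
        total_candidates=total - counts["none"],
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

MAG_TSV_COLUMNS = [
    "mag_id", "sample_id", "domain", "phylum", "genus",
    "completeness", "contamination", "ec_numbers",
]


def records_to_frame(records: list[MagRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "mag_id": r.mag_id,
            "sample_id": r.sample_id,
            "domain": r.taxonomy.get("domain", ""),
            "phylum": r.taxonomy.get("phylum", ""),
            "genus": r.taxonomy.get("genus", ""),
            "completeness": f"{r.completeness:.4f}",
            "contamination": f"{r.contamination:.4f}",
            "ec_numbers": ";".join(sorted(r.ec_numbers)),
        })
    return pd.DataFrame(rows, columns=MAG_TSV_COLUMNS)


def write_mag_table(records: list[MagRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_mag_table(path: str | Path) -> list[MagRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(MAG_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing MAG table columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        ecs = frozenset(e for e in row["ec_numbers"].split(";") if e)
        records.append(MagRecord(
            mag_id=row["mag_id"],
            sample_id=row["sample_id"],
            taxonomy={
                "domain": row["domain"], "phylum": row["phylum"],
                "genus": row["genus"],
            },
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            ec_numbers=ecs,
        ))
    return records


def write_screening_report(
    results: list[TriadResult], tiers: dict[str, str], path: str | Path,
) -> None:
    rows = [{
        "mag_id": r.mag_id,
        "tier": tiers.get(r.mag_id, ""),
        "venn_region": r.venn_region,
        "is_candidate": int(r.is_candidate),
        "archaeal_flag": int(r.archaeal_flag),
    } for r in results]
    pd.DataFrame(
        rows, columns=["mag_id", "tier", "venn_region", "is_candidate", "archaeal_flag"]
    ).to_csv(path, sep="\t", index=False)


def write_venn_summary(summary: VennSummary, path: str | Path) -> None:
    rows = [{"region": region, "count": summary.region_counts[region]}
            for region in VENN_REGIONS]
    rows.append({"region": "total_screened", "count": summary.total_screened})
    rows.append({"region": "total_candidates", "count": summary.total_candidates})
    pd.DataFrame(rows, columns=["region", "count"]).to_csv(path, sep="\t", index=False)
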
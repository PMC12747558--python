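"""End-to-end orchestration: generate → screen → build → spectrum → design.

A run is driven by a :class:`RunConfig` (loadable from YAML; the packaged
``default_config.yaml`` holds the full default with every threshold named).
Each stage writes its TSV outputs before the next starts, a stage failure
halts the run with partial outputs preserved, and the manifest records the
config hash, seed, package version and per-stage row counts.  Re-running
with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .fba import Medium, apply_medium, check_growth, medium_from_compounds, solve_fba
from .gem import build_draft_model, write_model
from .media import (
    coverage_report,
    enumerate_candidate_media,
    greedy_media_cover,
    write_coverage_matrix,
    write_formulations,
)
from .model import MetabolicModel
from .panels import load_base_medium_compounds
from .screening import (
    MagRecord,
    QualityThresholds,
    classify_triad,
    filter_by_quality,
    read_mag_table,
    venn_summary,
    write_mag_table,
    write_screening_report,
    write_venn_summary,
)
from .spectrum import characterize_model, write_requirements, write_spectrum_matrix
from .synthetic import SyntheticConfig, generate_cohort, write_ground_truth
from .templates import build_template

logger = logging.getLogger(__name__)

STAGES = ("generate", "screen", "build_models", "spectrum", "design")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs remain on disk."""


@dataclass
class RunConfig:
    output_dir: Path = Path("hydroscreen_run")
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mags_path: Path | None = None
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    triad_rule: str = "any"
    growth_threshold: float = 1e-6
    default_uptake: float = 10.0
    anaerobic: bool = True
    max_k: int = 3
    model_format: str = "native"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    def validate(self) -> None:
        self.synthetic.validate()
        if self.triad_rule not in ("any", "all"):
            raise ValueError(f"triad_rule must be any|all, got {self.triad_rule!r}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages.get("generate", True):
            if self.mags_path is None or not Path(self.mags_path).exists():
                raise ValueError(
                    "generate stage disabled but mags_path missing or not found"
                )

    def to_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "synthetic": dataclasses.asdict(self.synthetic),
            "mags_path": str(self.mags_path) if self.mags_path else None,
            "screening": {**dataclasses.asdict(self.thresholds),
                          "triad_rule": self.triad_rule},
            "fba": {"growth_threshold": self.growth_threshold,
                    "default_uptake": self.default_uptake,
                    "anaerobic": self.anaerobic},
            "spectrum": {"max_k": self.max_k},
            "model_format": self.model_format,
            "stages": {s: bool(self.stages.get(s, True)) for s in STAGES},
        }
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_run_config(path: str | Path | None = None, *, seed: int | None = None,
                    output_dir: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; with no path, the packaged default."""
    if path is None:
        text = resources.files("hydroscreen").joinpath(
            "data", "default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    syn = raw.get("synthetic", {})
    scr = raw.get("screening", {})
    fba_cfg = raw.get("fba", {})
    cfg = RunConfig(
        output_dir=Path(raw.get("output_dir", "hydroscreen_run")),
        seed=int(raw.get("seed", 0)),
        synthetic=SyntheticConfig(
            n_mags=int(syn.get("n_mags", 281)),
            seed=int(raw.get("seed", 0)),
            completeness_range=tuple(syn.get("completeness_range", (70.0, 100.0))),
            contamination_range=tuple(syn.get("contamination_range", (0.0, 10.0))),
            enzyme_prevalence=dict(syn.get(
                "enzyme_prevalence", {"FDH": 0.30, "AK": 0.50, "BK": 0.33})),
            archaea_fraction=float(syn.get("archaea_fraction", 0.021)),
            n_carbons=int(syn.get("n_carbons", 53)),
            n_supplements=int(syn.get("n_supplements", 5)),
            single_carbon_fraction=float(syn.get("single_carbon_fraction", 0.93)),
            auxotroph_fraction=float(syn.get("auxotroph_fraction", 0.25)),
        ),
        mags_path=Path(raw["mags_path"]) if raw.get("mags_path") else None,
        thresholds=QualityThresholds(
            min_completeness=float(scr.get("min_completeness", 70.0)),
            max_contamination=float(scr.get("max_contamination", 10.0)),
            hq_min_completeness=float(scr.get("hq_min_completeness", 90.0)),
            hq_max_contamination=float(scr.get("hq_max_contamination", 5.0)),
        ),
        triad_rule=scr.get("triad_rule", "any"),
        growth_threshold=float(fba_cfg.get("growth_threshold", 1e-6)),
        default_uptake=float(fba_cfg.get("default_uptake", 10.0)),
        anaerobic=bool(fba_cfg.get("anaerobic", True)),
        max_k=int(raw.get("spectrum", {}).get("max_k", 3)),
        model_format=raw.get("model_format", "native"),
        stages={s: bool(raw.get("stages", {}).get(s, True)) for s in STAGES},
    )
    if seed is not None:
        cfg.seed = int(seed)
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=int(seed))
    if output_dir is not None:
        cfg.output_dir = Path(output_dir)
    return cfg


def base_medium(config: RunConfig) -> Medium:
    """The supplement-free base minimal medium of a run."""
    return medium_from_compounds(
        "base_medium_v1", load_base_medium_compounds(), anaerobic=config.anaerobic,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "hydroscreen_version": __version__,
        "counts": counts,
        "stages_run": [],
    }

    records: list[MagRecord] = []
    truth = None
    template = build_template(config.synthetic.n_carbons, config.synthetic.n_supplements)
    base = base_medium(config)

    def _stage(name: str) -> bool:
        return bool(config.stages.get(name, True))

    try:
        if _stage("generate"):
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            records, truth = generate_cohort(syn)
            write_mag_table(records, out / "mags.tsv")
            write_ground_truth(truth, out / "ground_truth.tsv")
            manifest["stages_run"].append("generate")
        elif config.mags_path is not None:
            records = read_mag_table(config.mags_path)
        counts["input_mags"] = len(records)

        triad_results = []
        candidates: list[MagRecord] = []
        if _stage("screen"):
            passing, tiers = filter_by_quality(records, config.thresholds)
            triad_results = [classify_triad(r, config.triad_rule) for r in passing]
            summary = venn_summary(triad_results)
            write_screening_report(triad_results, tiers, out / "screening_report.tsv")
            write_venn_summary(summary, out / "venn_summary.tsv")
            by_id = {t.mag_id: t for t in triad_results}
            candidates = [r for r in passing if by_id[r.mag_id].is_candidate]
            counts["pass_quality"] = len(passing)
            counts["candidates"] = len(candidates)
            manifest["stages_run"].append("screen")

        models: dict[str, MetabolicModel] = {}
        if _stage("build_models"):
            if not candidates:
                raise StageError("build_models: no screened candidates available")
            model_dir = out / "models"
            model_dir.mkdir(exist_ok=True)
            suffix = "mdl" if config.model_format == "native" else "xml"
            for r in candidates:
                m = build_draft_model(r.ec_numbers, template, model_id=r.mag_id)
                models[r.mag_id] = m
                write_model(m, model_dir / f"{r.mag_id}.{suffix}", config.model_format)
            counts["models_built"] = len(models)
            manifest["stages_run"].append("build_models")

        spectra = []
        if _stage("spectrum"):
            if not models:
                raise StageError("spectrum: no models available")
            for mag_id in sorted(models):
                spectra.append(characterize_model(
                    models[mag_id], template.carbon_panel, base,
                    template.supplement_panel.ids,
                    uptake=config.default_uptake,
                    threshold=config.growth_threshold,
                    max_k=config.max_k,
                ))
            write_spectrum_matrix(spectra, out / "spectrum_matrix.tsv")
            write_requirements(spectra, out / "requirements.tsv")
            for cls in ("single_carbon", "multi_carbon", "no_growth"):
                counts[cls] = sum(1 for s in spectra if s.growth_class == cls)
            manifest["stages_run"].append("spectrum")

        if _stage("design"):
            if not spectra:
                raise StageError("design: no spectra available")
            cands = enumerate_candidate_media(spectra)
            targets = frozenset(s.model_id for s in spectra)

            def certifier(mag_id: str, carbons, supplements) -> bool:
                medium = base.plus(
                    "certify",
                    {**{f"{c}_e": config.default_uptake for c in carbons},
                     **{f"{s}_e": config.default_uptake for s in supplements}},
                )
                sol = solve_fba(apply_medium(models[mag_id], medium))
                return check_growth(sol, config.growth_threshold)

            formulations, uncoverable = greedy_media_cover(
                cands, targets, certifier=certifier,
            )
            report = coverage_report(formulations, targets, truth, spectra)
            write_formulations(formulations, out / "media_formulations.tsv")
            write_coverage_matrix(formulations, targets, out / "coverage_matrix.tsv")
            report_rows = report.per_medium.copy()
            report_rows["selectivity"] = report_rows["selectivity"].map(
                lambda x: f"{x:.6f}")
            report_rows.to_csv(out / "coverage_report.tsv", sep="\t", index=False)
            counts["media"] = report.n_media
            counts["uncoverable"] = len(uncoverable)
            manifest["coverage_fraction"] = report.coverage_fraction
            if report.agreement is not None:
                manifest["requirement_agreement"] = report.agreement
            manifest["stages_run"].append("design")
    except StageError:
        raise
    except Exception as exc:  # halt with stage context, partial outputs kept
        stage = manifest["stages_run"][-1] if manifest["stages_run"] else "setup"
        raise StageError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return manifest
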
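"""End-to-end orchestration: config -> populations -> SD reference ->
simulation study -> metrics, with a reproducibility manifest.

Seeding scheme: one master seed fans out through ``numpy`` SeedSequence
spawn keys — ``(0, i)`` for population i, ``(1,)`` for the SD-reference
bootstrap, and ``(i, j, r)`` (three-part keys, so no collision with the
two-part stage keys) for study cell (population i, size j, replicate r).
Partial re-runs of any stage therefore match the full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import DEFAULT_BOUNDS, SurveyDataset, clean_records, read_survey_csv
from .evaluate import bias_regression, classify, mean_bias_table, summarize
from .sdref import SDReference, build_sd_reference, builtin_reference
from .simulate import PopulationSpec, SimulationDesign, generate_population, run_study

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Run configuration failed validation."""


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see the commented example in examples/)."""

    seed: int
    out_dir: Path
    population_specs: list[PopulationSpec] = dataclasses.field(default_factory=list)
    population_csvs: list[Path] = dataclasses.field(default_factory=list)
    design: SimulationDesign = dataclasses.field(default_factory=SimulationDesign)
    methods: tuple[str, ...] = ("classic", "probit_I", "probit_II")
    cutoffs: tuple[float, ...] = (115.0, 125.0)
    n_boot: int = 2000
    cleaning_bounds: tuple[float, float] = DEFAULT_BOUNDS
    sdref_source: str = "builtin"  # builtin | build | file
    sdref_path: Path | None = None
    sdref_survey_csvs: list[Path] = dataclasses.field(default_factory=list)
    sdref_n_boot: int = 2000
    sdref_dispersion_mm: float = 0.0
    thresholds_pct: tuple[float, ...] = (5.0, 10.0, 15.0)
    raw: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        problems = []
        if "seed" not in raw:
            problems.append("seed is mandatory")
        if "out_dir" not in raw:
            problems.append("out_dir is mandatory")
        pops = raw.get("populations", [])
        pop_specs = [PopulationSpec(**p) for p in pops if isinstance(p, dict)]
        pop_csvs = [base / p for p in raw.get("population_csvs", [])]
        for p in pop_csvs:
            if not p.exists():
                problems.append(f"population csv {p} not found")
        if not pop_specs and not pop_csvs:
            problems.append("no populations configured")

        sd = raw.get("sd_reference", {"source": "builtin"})
        source = sd.get("source", "builtin")
        if source not in ("builtin", "build", "file"):
            problems.append(f"unknown sd_reference source {source!r}")
        sd_path = base / sd["path"] if sd.get("path") else None
        sd_csvs = [base / p for p in sd.get("survey_csvs", [])]
        if source == "file" and (sd_path is None or not sd_path.exists()):
            problems.append("sd_reference source 'file' needs an existing path")
        if source == "build" and not sd_csvs:
            problems.append("sd_reference source 'build' needs survey_csvs")

        est = raw.get("estimators", {})
        methods = tuple(est.get("methods", ("classic", "probit_I", "probit_II")))
        for m in methods:
            if m not in ("classic", "probit_I", "probit_II"):
                problems.append(f"unknown method {m!r}")
        if problems:
            raise ConfigError("; ".join(problems))

        design_raw = raw.get("design", {})
        return cls(
            seed=int(raw["seed"]),
            out_dir=base / raw["out_dir"],
            population_specs=pop_specs,
            population_csvs=pop_csvs,
            design=SimulationDesign(
                sample_sizes=tuple(design_raw.get("sample_sizes", (25, 50, 75, 100, 125, 150, 175, 200))),
                reps=int(design_raw.get("reps", 100)),
                n_clusters_sub=int(design_raw.get("n_clusters_sub", 25)),
            ),
            methods=methods,
            cutoffs=tuple(float(c) for c in est.get("cutoffs", (115.0, 125.0))),
            n_boot=int(est.get("n_boot", 2000)),
            cleaning_bounds=tuple(raw.get("cleaning_bounds", DEFAULT_BOUNDS)),
            sdref_source=source,
            sdref_path=sd_path,
            sdref_survey_csvs=sd_csvs,
            sdref_n_boot=int(sd.get("n_boot", 2000)),
            sdref_dispersion_mm=float(sd.get("dispersion_mm", 0.0)),
            thresholds_pct=tuple(float(t) for t in raw.get("thresholds_pct", (5.0, 10.0, 15.0))),
            raw=raw,
        )


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_populations(cfg: RunConfig) -> tuple[list[SurveyDataset], list[dict]]:
    pops: list[SurveyDataset] = []
    reports: list[dict] = []
    for i, spec in enumerate(cfg.population_specs):
        spec = dataclasses.replace(spec, survey_id=spec.survey_id or f"pop{i:04d}")
        if spec.survey_id == "synthetic":
            spec = dataclasses.replace(spec, survey_id=f"pop{i:04d}")
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0, i)))
        pops.append(generate_population(spec, rng=rng))
    for path in cfg.population_csvs:
        ds = read_survey_csv(path)
        ds, report = clean_records(ds, cfg.cleaning_bounds)
        ds.validate_source()
        reports.append({"survey_id": ds.survey_id, **json.loads(report.to_json())})
        pops.append(ds)
    return pops, reports


def _load_sdref(cfg: RunConfig) -> SDReference:
    if cfg.sdref_source == "builtin":
        return builtin_reference(cfg.sdref_dispersion_mm)
    if cfg.sdref_source == "file":
        return SDReference.from_json(Path(cfg.sdref_path).read_text())
    surveys = []
    for path in cfg.sdref_survey_csvs:
        ds = read_survey_csv(path)
        ds, _ = clean_records(ds, cfg.cleaning_bounds)
        surveys.append(ds)
    return build_sd_reference(
        surveys,
        n_boot=cfg.sdref_n_boot,
        seed=np.random.SeedSequence(cfg.seed, spawn_key=(1,)),
    )


def run_pipeline(cfg: RunConfig, progress: bool = False) -> dict:
    """Execute generate -> SD reference -> simulate -> evaluate; return manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg.raw),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }

    needs_ref = "probit_I" in cfg.methods
    sdref = _load_sdref(cfg) if needs_ref else None
    if sdref is not None:
        (out / "sdref.json").write_text(sdref.to_json())
        manifest["stages"]["sd_reference"] = {"regions": sorted(sdref.regions)}

    pops, cleaning = _load_populations(cfg)
    if needs_ref:
        missing = sorted({p.region for p in pops} - set(sdref.regions))
        if missing:
            raise ConfigError(f"regions {missing} absent from the SD reference")
    if cleaning:
        (out / "cleaning_reports.json").write_text(json.dumps(cleaning, indent=2))
    manifest["stages"]["populations"] = {
        "n_populations": len(pops),
        "n_children": int(sum(p.n for p in pops)),
    }

    results = run_study(
        pops, cfg.design, methods=cfg.methods, sdref=sdref, cutoffs=cfg.cutoffs,
        seed=cfg.seed, n_boot=cfg.n_boot, progress=progress,
    )
    results.to_csv(out / "results.csv", index=False)
    n_errors = int((results["error_code"] != "").sum())
    manifest["stages"]["simulate"] = {
        "n_subsamples": cfg.design.n_subsamples(len(pops)),
        "n_rows": len(results),
        "n_error_rows": n_errors,
    }

    metrics = summarize(results, thresholds=cfg.thresholds_pct)
    metrics.to_csv(out / "metrics.csv", index=False)

    cls_rows = []
    gam_rows = results[results["cutoff_mm"] == 125.0]
    if len(gam_rows):
        for (method, size), grp in gam_rows.groupby(["method", "sample_size"]):
            for t in cfg.thresholds_pct:
                c = classify(grp, t)
                cls_rows.append({
                    "method": method, "sample_size": size, "threshold_pct": t,
                    "p_correct": c.p_correct, "specificity": c.specificity,
                    "accuracy": c.accuracy, "n_eligible": c.n_eligible,
                })
    pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)

    reg_frames = []
    for method in cfg.methods:
        if method == "classic" or 125.0 not in cfg.cutoffs:
            continue
        try:
            mb = mean_bias_table(results, method, 125.0)
            usable = [p for p in ("region", "gam_category", "livelihood", "residence",
                                  "sample_size", "date_period", "design")
                      if mb[p].nunique() > 1]
            if not usable:
                continue
            table = bias_regression(mb, predictors=usable).table
            table.insert(0, "method", method)
            reg_frames.append(table)
        except ValueError as exc:
            warnings.warn(f"bias regression skipped for {method}: {exc}")
    if reg_frames:
        pd.concat(reg_frames).to_csv(out / "bias_regression.csv", index=False)

    manifest["stages"]["evaluate"] = {
        "n_metric_rows": len(metrics),
        "n_classification_rows": len(cls_rows),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
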
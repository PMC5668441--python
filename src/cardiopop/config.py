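"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` (serialisable to YAML) plus a seed fully determines a
run: sample conductances, simulate, calibrate against biomarker ranges,
transfect the mutation, classify phenotypes, run the drug trials, and emit
report tables.  All randomness flows from one ``numpy`` seed sequence with
deterministically derived per-stage substreams, so rerunning an identical
config reproduces byte-identical population files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cell_model as cm
from .analysis import ancestor_contrast, compare_groups, stopped_vs_beating_contrast
from .biomarkers import BiomarkerSettings
from .drugs import DrugSpec, drug_trial
from .population import (
    BiomarkerRanges,
    ClassificationRule,
    build_population,
    classify,
    transfect,
)
from .simulation import DetectionSettings, SolverSettings

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "packaged_config"]

log = logging.getLogger("cardiopop")


def packaged_config(name: str) -> Path:
    """Path of a configuration file shipped with the package (see ``configs/``)."""
    return Path(importlib.resources.files("cardiopop") / "configs" / name)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    n: int = 100
    interval: tuple[float, float] = (0.5, 2.0)
    scheme: str = "uniform"
    solver: SolverSettings = field(default_factory=SolverSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    biomarkers: BiomarkerSettings = field(default_factory=BiomarkerSettings)
    ranges_path: str = ""              # empty -> packaged synthetic ranges
    drug_paths: tuple[str, ...] = ()
    doses_uM: tuple[float, ...] = (5.0, 10.0, 20.0)
    apd90_threshold_ms: float | None = None   # None -> control upper APD90 bound
    outdir: str = "cardiopop_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("solver", SolverSettings), ("detection", DetectionSettings),
                           ("biomarkers", BiomarkerSettings)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "interval" in raw:
            raw["interval"] = tuple(raw["interval"])
        for key in ("drug_paths", "doses_uM"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "biomarkers" in raw and isinstance(raw["biomarkers"], BiomarkerSettings):
            pass
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key in ("solver", "detection", "biomarkers"):
            raw[key] = dataclasses.asdict(getattr(self, key))
        raw["biomarkers"]["apd_levels"] = list(self.biomarkers.apd_levels)
        raw["interval"] = list(self.interval)
        raw["drug_paths"] = list(self.drug_paths)
        raw["doses_uM"] = list(self.doses_uM)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def config_hash(self) -> str:
        raw = dataclasses.asdict(self)
        for key in ("solver", "detection", "biomarkers"):
            raw[key] = dataclasses.asdict(getattr(self, key))
        payload = json.dumps(raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def resolve_ranges(self) -> BiomarkerRanges:
        path = self.ranges_path or packaged_config("ranges_synthetic.yaml")
        return BiomarkerRanges.from_yaml(path)


def run_pipeline(config: RunConfig, progress: bool = False) -> dict:
    """Execute the whole workflow and write all artifacts under ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``).  On stage
    failure the manifest records the stages completed so far before the
    exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "counts": {},
        "timings_s": {},
    }

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"].append(name)
        manifest["timings_s"][name] = round(time.time() - t0, 2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    config.to_yaml(out / "config.yaml")
    ranges = config.resolve_ranges()
    ss = np.random.SeedSequence(config.seed)
    sample_seed = ss.spawn(1)[0]

    try:
        t0 = time.time()
        control = build_population(
            config.n, ranges, seed=sample_seed, interval=config.interval,
            scheme=config.scheme, settings=config.solver, detection=config.detection,
            bio_settings=config.biomarkers, progress=progress,
        )
        control.provenance["seed"] = config.seed
        if len(control) == 0:
            raise PipelineError("calibration produced an empty population "
                                f"(n={config.n} sampled)")
        control.to_csv(out / "population_control.csv")
        manifest["counts"]["sampled"] = config.n
        manifest["counts"]["control_accepted"] = len(control)
        finish_stage("build_population", t0)

        t0 = time.time()
        mutant = transfect(control, config.solver, config.detection, config.biomarkers,
                           progress=progress)
        manifest["counts"]["mutant_spontaneous"] = len(mutant)
        manifest["counts"]["mutant_quiescent"] = len(mutant.provenance["quiescent_ids"])
        finish_stage("transfect", t0)

        t0 = time.time()
        rule = ClassificationRule(apd90_threshold_ms=config.apd90_threshold_ms)
        labels = classify(mutant, rule)
        mutant.to_csv(out / "population_mutant.csv")
        manifest["counts"]["symptomatic"] = int((labels == "symptomatic").sum())
        manifest["counts"]["asymptomatic"] = int((labels == "asymptomatic").sum())
        finish_stage("classify", t0)

        t0 = time.time()
        _write_contrasts(out, control, mutant)
        finish_stage("contrasts", t0)

        for path in config.drug_paths:
            drug = DrugSpec.from_yaml(path)
            for pop, tag in ((control, "control"), (mutant, "mutant")):
                t0 = time.time()
                trial = drug_trial(pop, drug, list(config.doses_uM), config.solver,
                                   config.detection, config.biomarkers, progress=progress)
                trial.per_model.to_csv(out / f"trial_{drug.name}_{tag}.csv", index=False)
                trial.aggregates.to_csv(out / f"trial_{drug.name}_{tag}_aggregates.csv",
                                        index=False)
                for dose in config.doses_uM:
                    key = f"{drug.name}_{tag}_stopped_at_{dose}uM"
                    manifest["counts"][key] = len(trial.stopped_ids(dose))
                if tag == "mutant":
                    _write_stopped_contrast(out, trial, pop, max(config.doses_uM), drug.name)
                finish_stage(f"drug_trial_{drug.name}_{tag}", t0)
    except Exception as exc:
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_contrasts(out: Path, control, mutant) -> None:
    if "label" not in mutant.table.columns:
        return
    sym = mutant.subset((mutant.table["label"] == "symptomatic").to_numpy())
    asym = mutant.subset((mutant.table["label"] == "asymptomatic").to_numpy())
    if len(sym) and len(asym):
        gc = compare_groups(sym, asym, list(cm.SAMPLED_PARAMETERS))
        gc.table.to_csv(out / "contrast_symptomatic_vs_asymptomatic.csv", index=False)
        anc = ancestor_contrast(control, mutant)
        anc.table.to_csv(out / "contrast_ancestors.csv", index=False)


def _write_stopped_contrast(out: Path, trial, pop, dose: float, drug_name: str) -> None:
    try:
        gc = stopped_vs_beating_contrast(trial, pop, dose)
    except ValueError:
        return
    gc.table.to_csv(out / f"contrast_stopped_{drug_name}_{dose}uM.csv", index=False)


def _versions() -> dict:
    import numba
    import pandas
    import scipy

    from . import __version__

    return {
        "cardiopop": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "numba": numba.__version__,
    }
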
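"""Experimentally calibrated populations of cell models.

The population-of-models method represents cell-to-cell electrophysiological
variability by sampling multiplicative scale factors on the maximal
conductances/permeabilities of a baseline model, simulating every variant,
and keeping ("calibrating") only those whose AP biomarkers fall within
experimentally observed ranges.  A disease mutation is then *transfected*
in silico: the mutant current formulation is switched on in every accepted
control model, with no further calibration, preserving a one-to-one
control-to-mutant mapping.  Mutant models are finally classified as
symptomatic (pathologically prolonged APD) or asymptomatic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cell_model as cm
from .biomarkers import (
    BIOMARKER_COLUMNS,
    BiomarkerSettings,
    NoCompleteCycleError,
    extract_biomarkers,
)
from .simulation import DetectionSettings, SolverSettings, detect_cycles, run_to_steady_state

__all__ = [
    "ConductanceSample",
    "BiomarkerRanges",
    "CandidateRecord",
    "Population",
    "sample_population",
    "evaluate_candidates",
    "calibrate",
    "build_population",
    "transfect",
    "classify",
    "ClassificationRule",
]

SCALE_COLUMNS = [f"scale_{p}" for p in cm.SAMPLED_PARAMETERS]


@dataclass(frozen=True)
class ConductanceSample:
    """One sampled model: an id plus a scale factor per sampled maximum."""

    id: int
    scales: dict[str, float]

    def to_parameters(self, genotype=cm.Genotype.CONTROL) -> cm.CellParameters:
        return cm.CellParameters.from_scale_factors(self.scales, genotype)


@dataclass
class BiomarkerRanges:
    """Per-biomarker inclusive [lower, upper] acceptance window."""

    bounds: dict[str, tuple[float, float]]
    source: str = ""

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"range for {k} has lower > upper ({lo} > {hi})")

    def accepts(self, biomarkers: dict[str, float]) -> bool:
        for name, (lo, hi) in self.bounds.items():
            if name not in biomarkers:
                raise KeyError(f"calibration range refers to biomarker {name!r} "
                               f"which was not measured")
            if not (lo <= biomarkers[name] <= hi):
                return False
        return True

    @classmethod
    def union_of_datasets(cls, tables: list["BiomarkerRanges"], source: str = "union"
                          ) -> "BiomarkerRanges":
        """Combine per-dataset ranges into one window covering them all
        (min of lower bounds, max of upper bounds per biomarker)."""
        bounds: dict[str, tuple[float, float]] = {}
        for t in tables:
            for k, (lo, hi) in t.bounds.items():
                if k in bounds:
                    bounds[k] = (min(bounds[k][0], lo), max(bounds[k][1], hi))
                else:
                    bounds[k] = (lo, hi)
        return cls(bounds, source)

    @classmethod
    def from_yaml(cls, path) -> "BiomarkerRanges":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        bounds = {k: (float(v["lower"]), float(v["upper"])) for k, v in raw["biomarkers"].items()}
        return cls(bounds, source=raw.get("source", str(path)))

    def to_yaml(self, path) -> None:
        raw = {
            "source": self.source,
            "biomarkers": {k: {"lower": lo, "upper": hi} for k, (lo, hi) in self.bounds.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class CandidateRecord:
    """A sampled model with its simulation outcome, before calibration."""

    sample: ConductanceSample
    status: str                        # "spontaneous" | "quiescent" | "failed"
    biomarkers: dict[str, float] | None

    @property
    def spontaneous(self) -> bool:
        return self.status == "spontaneous"


@dataclass
class Population:
    """A homogeneous-genotype set of accepted models as a flat table.

    One row per model: id, the 11 scale factors, genotype, status, the
    biomarker summary, and (after :func:`classify`) a phenotype label.
    """

    table: pd.DataFrame
    genotype: cm.Genotype
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotype = cm.Genotype(self.genotype)
        if len(self.table) and self.table["id"].duplicated().any():
            raise ValueError("model ids must be unique within a population")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def sample_for(self, model_id: int) -> ConductanceSample:
        row = self.table.loc[self.table["id"] == model_id]
        if row.empty:
            raise KeyError(f"no model with id {model_id}")
        scales = {p: float(row.iloc[0][f"scale_{p}"]) for p in cm.SAMPLED_PARAMETERS}
        return ConductanceSample(int(model_id), scales)

    def parameters_for(self, model_id: int) -> cm.CellParameters:
        return self.sample_for(model_id).to_parameters(self.genotype)

    def conductance(self, name: str) -> pd.Series:
        """Absolute maximal conductance/permeability per model (scale x baseline)."""
        if name not in cm.BASELINE_MAXIMA:
            raise KeyError(f"unknown conductance {name!r}")
        return self.table[f"scale_{name}"] * cm.BASELINE_MAXIMA[name]

    def subset(self, mask) -> "Population":
        return Population(self.table[mask].reset_index(drop=True), self.genotype,
                          dict(self.provenance))

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "genotype", self.genotype.value)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "Population":
        df = pd.read_csv(path)
        genos = df["genotype"].unique()
        if len(genos) != 1:
            raise ValueError("population file must be genotype-homogeneous")
        return cls(df.drop(columns=["genotype"]), cm.Genotype(genos[0]), provenance or {})


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_population(
    n: int,
    interval: tuple[float, float] = (0.5, 2.0),
    seed: int | np.random.SeedSequence | None = None,
    scheme: str = "uniform",
    start_id: int = 0,
) -> list[ConductanceSample]:
    """Draw ``n`` random models as scale factors on the 11 sampled maxima.

    ``scheme`` is ``"uniform"`` (independent draws) or ``"lhs"``
    (Latin-hypercube, one stratum per model and dimension).  Reproducible
    under a fixed ``seed``.
    """
    lo, hi = interval
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid sampling interval [{lo}, {hi}]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    k = len(cm.SAMPLED_PARAMETERS)
    if scheme == "uniform":
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=(n, k))
    elif scheme == "lhs":
        from scipy.stats import qmc

        rng = np.random.default_rng(seed)
        u = qmc.LatinHypercube(d=k, seed=rng).random(n)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    factors = lo + (hi - lo) * u
    return [
        ConductanceSample(start_id + i, dict(zip(cm.SAMPLED_PARAMETERS, map(float, factors[i]))))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Simulation of candidates
# ---------------------------------------------------------------------------


def _simulate_one(
    params: cm.CellParameters,
    settings: SolverSettings,
    detection: DetectionSettings,
    bio_settings: BiomarkerSettings,
) -> tuple[str, dict | None]:
    res = run_to_steady_state(params, settings=settings, detection=detection)
    if not res.spontaneous:
        return res.status, None
    try:
        bio = extract_biomarkers(detect_cycles(res.trace, detection), res.trace, bio_settings)
    except NoCompleteCycleError:
        return "quiescent", None
    return "spontaneous", bio.summary


def evaluate_candidates(
    samples: list[ConductanceSample],
    genotype=cm.Genotype.CONTROL,
    settings: SolverSettings = SolverSettings(),
    detection: DetectionSettings = DetectionSettings(),
    bio_settings: BiomarkerSettings = BiomarkerSettings(),
    progress: bool = False,
) -> list[CandidateRecord]:
    """Simulate every sampled model and measure its biomarkers (or flag quiescence)."""
    iterator = samples
    if progress:
        from tqdm import tqdm

        iterator = tqdm(samples, desc=f"simulating ({cm.Genotype(genotype).value})")
    records = []
    for s in iterator:
        status, summary = _simulate_one(s.to_parameters(genotype), settings, detection, bio_settings)
        records.append(CandidateRecord(s, status, summary))
    return records


def _records_to_table(records: list[CandidateRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=["id", *SCALE_COLUMNS, "status", *BIOMARKER_COLUMNS])
    rows = []
    for r in records:
        row = {"id": r.sample.id}
        row.update({f"scale_{p}": r.sample.scales[p] for p in cm.SAMPLED_PARAMETERS})
        row["status"] = r.status
        for b in BIOMARKER_COLUMNS:
            row[b] = r.biomarkers.get(b, np.nan) if r.biomarkers else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration, transfection, classification
# ---------------------------------------------------------------------------


def calibrate(
    candidates: list[CandidateRecord],
    ranges: BiomarkerRanges,
    genotype=cm.Genotype.CONTROL,
    provenance: dict | None = None,
) -> Population:
    """Filter candidates to those whose biomarkers fall inside ``ranges``.

    A candidate is accepted iff it beats spontaneously AND every biomarker
    named in ``ranges`` lies inside its inclusive window.  Quiescent and
    failed candidates are always rejected.  The operation is idempotent:
    re-calibrating an accepted population with the same ranges is a no-op.
    """
    accepted = [r for r in candidates if r.spontaneous and ranges.accepts(r.biomarkers)]
    prov = dict(provenance or {})
    prov.update(
        {
            "ranges": {k: list(v) for k, v in ranges.bounds.items()},
            "ranges_source": ranges.source,
            "n_candidates": len(candidates),
            "n_accepted": len(accepted),
            "n_quiescent": sum(not r.spontaneous for r in candidates),
        }
    )
    return Population(_records_to_table(accepted), genotype, prov)


def build_population(
    n: int,
    ranges: BiomarkerRanges,
    seed: int | np.random.SeedSequence | None = None,
    interval: tuple[float, float] = (0.5, 2.0),
    scheme: str = "uniform",
    settings: SolverSettings = SolverSettings(),
    detection: DetectionSettings = DetectionSettings(),
    bio_settings: BiomarkerSettings = BiomarkerSettings(),
    progress: bool = False,
) -> Population:
    """Sample, simulate and calibrate a control population in one call."""
    samples = sample_population(n, interval, seed, scheme)
    records = evaluate_candidates(samples, cm.Genotype.CONTROL, settings, detection,
                                  bio_settings, progress)
    prov = {"seed": seed if isinstance(seed, int) else None, "n_sampled": n,
            "interval": list(interval), "scheme": scheme}
    return calibrate(records, ranges, cm.Genotype.CONTROL, prov)


def transfect(
    control: Population,
    settings: SolverSettings = SolverSettings(),
    detection: DetectionSettings = DetectionSettings(),
    bio_settings: BiomarkerSettings = BiomarkerSettings(),
    progress: bool = False,
) -> Population:
    """Express the V1763M mutation in every model of a calibrated control population.

    No biomarker-range filtering is applied to the mutant population; the
    only exclusions are models that stop beating once mutated, whose ids
    are logged in ``provenance["quiescent_ids"]``.  Scale factors and ids
    are preserved, so the control-to-mutant id mapping is injective.
    """
    if control.genotype is not cm.Genotype.CONTROL:
        raise ValueError("transfection starts from a control-genotype population")
    samples = [control.sample_for(i) for i in control.ids]
    records = evaluate_candidates(samples, cm.Genotype.V1763M, settings, detection,
                                  bio_settings, progress)
    surviving = [r for r in records if r.spontaneous]
    quiescent_ids = [r.sample.id for r in records if not r.spontaneous]
    prov = dict(control.provenance)
    prov.update({"parent": "control", "quiescent_ids": quiescent_ids,
                 "n_control": len(control), "n_mutant": len(surviving)})
    return Population(_records_to_table(surviving), cm.Genotype.V1763M, prov)


@dataclass(frozen=True)
class ClassificationRule:
    """Symptomatic iff APD90 exceeds a threshold.

    ``apd90_threshold_ms=None`` means: use the upper APD90 calibration
    bound of the control population (a mutant AP longer than anything the
    control calibration would have accepted is pathologically prolonged).
    """

    biomarker: str = "APD90"
    apd90_threshold_ms: float | None = None

    def threshold_for(self, population: Population) -> float:
        if self.apd90_threshold_ms is not None:
            return self.apd90_threshold_ms
        ranges = population.provenance.get("ranges", {})
        if self.biomarker not in ranges:
            raise KeyError(
                f"classification rule needs an explicit threshold or a calibration "
                f"range for {self.biomarker!r}"
            )
        return float(ranges[self.biomarker][1])


def classify(
    mutant: Population, rule: ClassificationRule = ClassificationRule()
) -> pd.Series:
    """Label every mutant model ``symptomatic`` or ``asymptomatic``.

    Returns the labels (indexed like the population table) and stores them
    in the table's ``label`` column.  The labels always partition the
    population.
    """
    if rule.biomarker not in mutant.table.columns:
        raise KeyError(f"classification rule refers to absent biomarker {rule.biomarker!r}")
    thr = rule.threshold_for(mutant)
    labels = pd.Series(
        np.where(mutant.table[rule.biomarker] > thr, "symptomatic", "asymptomatic"),
        index=mutant.table.index,
        name="label",
    )
    mutant.table["label"] = labels
    mutant.provenance["classification_threshold_ms"] = thr
    return labels
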
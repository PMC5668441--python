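"""Single pore-block drug model and population dose-sweep trials.

Drug action is represented as a time-independent multiplicative reduction
of each targeted channel's maximal conductance:

    factor = 1 / (1 + (dose / IC50)^h)

with ``h`` the Hill coefficient (1 unless an assay says otherwise).  The
targeted channels are I_Na, I_NaL, I_Kr and I_CaL; a drug may carry
different IC50/h for control and mutant channels (relevant for Na+-channel
blockers whose affinity differs between wild-type and V1763M channels).
No state-dependent (use-dependent) binding is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cell_model as cm
from .biomarkers import BiomarkerSettings
from .population import Population, evaluate_candidates
from .simulation import DetectionSettings, SolverSettings

__all__ = ["ChannelBlock", "DrugSpec", "TrialResult", "block_factor", "apply_drug",
           "drug_trial", "TARGET_CHANNELS"]

#: The four drug-targeted channels, keyed by current name.
TARGET_CHANNELS = ("I_Na", "I_NaL", "I_Kr", "I_CaL")

_BLOCK_FIELD = {"I_Na": "i_na", "I_NaL": "i_nal", "I_Kr": "i_kr", "I_CaL": "i_cal"}


def block_factor(dose_uM: float, ic50_uM: float, hill: float = 1.0) -> float:
    """Pore-block conductance factor in (0, 1]; monotone non-increasing in dose."""
    if dose_uM < 0:
        raise ValueError("dose must be >= 0")
    if ic50_uM <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill coefficient must be > 0")
    if dose_uM == 0:
        return 1.0
    return 1.0 / (1.0 + (dose_uM / ic50_uM) ** hill)


@dataclass(frozen=True)
class ChannelBlock:
    """IC50/Hill of one drug on one channel, with optional per-genotype overrides."""

    ic50_uM: float
    hill: float = 1.0
    genotype_overrides: dict = field(default_factory=dict)

    def resolve(self, genotype) -> tuple[float, float]:
        g = cm.Genotype(genotype).value
        ov = self.genotype_overrides.get(g, {})
        return float(ov.get("ic50_uM", self.ic50_uM)), float(ov.get("hill", self.hill))


@dataclass
class DrugSpec:
    """A drug's multichannel pore-block parameters and default dose list."""

    name: str
    channels: dict[str, ChannelBlock]
    doses_uM: tuple[float, ...] = ()

    def __post_init__(self):
        unknown = set(self.channels) - set(TARGET_CHANNELS)
        if unknown:
            raise ValueError(f"drug {self.name!r} targets unknown channels: {sorted(unknown)}")
        for ch, blk in self.channels.items():
            if blk.ic50_uM <= 0 or blk.hill <= 0:
                raise ValueError(f"{self.name}/{ch}: IC50 and Hill must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "DrugSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        channels = {
            ch: ChannelBlock(
                ic50_uM=float(d["ic50_uM"]),
                hill=float(d.get("hill", 1.0)),
                genotype_overrides=d.get("genotype_overrides", {}),
            )
            for ch, d in raw["channels"].items()
        }
        return cls(raw["name"], channels, tuple(raw.get("doses_uM", ())))

    def to_yaml(self, path) -> None:
        raw = {
            "name": self.name,
            "doses_uM": list(self.doses_uM),
            "channels": {
                ch: {
                    "ic50_uM": blk.ic50_uM,
                    "hill": blk.hill,
                    **({"genotype_overrides": blk.genotype_overrides}
                       if blk.genotype_overrides else {}),
                }
                for ch, blk in self.channels.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def apply_drug(drug: DrugSpec, dose_uM: float, genotype=cm.Genotype.CONTROL) -> cm.BlockFactors:
    """Genotype-resolved block factors for one dose; untargeted channels stay at 1."""
    blocks = cm.BlockFactors()
    for ch, blk in drug.channels.items():
        ic50, hill = blk.resolve(genotype)
        setattr(blocks, _BLOCK_FIELD[ch], block_factor(dose_uM, ic50, hill))
    blocks.validate()
    return blocks


@dataclass
class TrialResult:
    """Per-model x per-dose drug responses plus per-dose aggregates.

    ``per_model`` columns: id, dose_uM, stopped, APD90_free, APD90_drug,
    dAPD90_ms, dAPD90_pct, prolonged, label (if the population is
    classified).  Stopped models carry no ΔAPD90.
    """

    drug: str
    genotype: str
    per_model: pd.DataFrame
    aggregates: pd.DataFrame

    def stopped_ids(self, dose_uM: float) -> list[int]:
        pm = self.per_model
        sel = pm[(pm["dose_uM"] == dose_uM) & pm["stopped"]]
        return sel["id"].tolist()


def _aggregate(per_model: pd.DataFrame, by_label: bool) -> pd.DataFrame:
    groups = ["dose_uM", "label"] if by_label else ["dose_uM"]
    rows = []
    for keys, g in per_model.groupby(groups):
        keys = keys if isinstance(keys, tuple) else (keys,)
        beating = g[~g["stopped"] & ~g["failed"]]
        row = dict(zip(groups, keys))
        row.update(
            {
                "n": len(g),
                "n_stopped": int(g["stopped"].sum()),
                "n_failed": int(g["failed"].sum()),
                "n_prolonged": int(beating["prolonged"].sum()),
                "mean_dAPD90_ms": float(beating["dAPD90_ms"].mean()),
                "mean_dAPD90_pct": float(beating["dAPD90_pct"].mean()),
                "median_dAPD90_ms": float(beating["dAPD90_ms"].median()),
                "sd_dAPD90_ms": float(beating["dAPD90_ms"].std(ddof=1)),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def drug_trial(
    pop: Population,
    drug: DrugSpec,
    doses_uM: list[float] | None = None,
    settings: SolverSettings = SolverSettings(),
    detection: DetectionSettings = DetectionSettings(),
    bio_settings: BiomarkerSettings = BiomarkerSettings(),
    progress: bool = False,
) -> TrialResult:
    """Re-simulate every model of ``pop`` at every dose and measure ΔAPD90.

    Each model restarts from the published initial conditions with the
    dose's block factors applied throughout; ΔAPD90 is taken against the
    model's drug-free APD90 recorded in the population table.  Models that
    stop beating are flagged ``stopped``; solver failures are flagged
    ``failed`` and excluded from aggregates (with their count reported).
    """
    doses = list(doses_uM if doses_uM is not None else drug.doses_uM)
    if not doses:
        raise ValueError("no doses given")
    if pop.table["APD90"].isna().any():
        raise ValueError("population lacks drug-free biomarkers")
    has_labels = "label" in pop.table.columns
    rows = []
    for dose in doses:
        blocks = apply_drug(drug, dose, pop.genotype)
        samples = [pop.sample_for(i) for i in pop.ids]
        iterator = samples
        if progress:
            from tqdm import tqdm

            iterator = tqdm(samples, desc=f"{drug.name} {dose} uM")
        for s in iterator:
            free_apd = float(pop.table.loc[pop.table["id"] == s.id, "APD90"].iloc[0])
            params = s.to_parameters(pop.genotype)
            status, summary = _simulate_one_with_blocks(
                params, blocks, settings, detection, bio_settings
            )
            row = {
                "id": s.id,
                "dose_uM": dose,
                "stopped": status == "quiescent",
                "failed": status == "failed",
                "APD90_free": free_apd,
            }
            if summary is not None:
                d = summary["APD90"] - free_apd
                row.update(
                    APD90_drug=summary["APD90"],
                    dAPD90_ms=d,
                    dAPD90_pct=100.0 * d / free_apd,
                    prolonged=d > 0,
                )
            else:
                row.update(APD90_drug=np.nan, dAPD90_ms=np.nan, dAPD90_pct=np.nan,
                           prolonged=False)
            if has_labels:
                row["label"] = pop.table.loc[pop.table["id"] == s.id, "label"].iloc[0]
            rows.append(row)
    per_model = pd.DataFrame(rows)
    agg = _aggregate(per_model, by_label=False)
    if has_labels:
        agg = pd.concat([agg, _aggregate(per_model, by_label=True)], ignore_index=True)
    return TrialResult(drug.name, pop.genotype.value, per_model, agg)


def _simulate_one_with_blocks(params, blocks, settings, detection, bio_settings):
    from .biomarkers import NoCompleteCycleError, extract_biomarkers
    from .simulation import detect_cycles, run_to_steady_state

    res = run_to_steady_state(params, blocks=blocks, settings=settings, detection=detection)
    if res.status == "failed":
        return "failed", None
    if not res.spontaneous:
        return "quiescent", None
    try:
        bio = extract_biomarkers(detect_cycles(res.trace, detection), res.trace, bio_settings)
    except NoCompleteCycleError:
        return "quiescent", None
    return "spontaneous", bio.summary
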
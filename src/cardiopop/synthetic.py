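"""Synthetic fixtures: analytic waveforms, toy ranges, toy populations, toy drugs.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without any experimental table.  The
generators are seed-deterministic and emit the same in-memory objects and
file formats as the real pipeline (drop-in fixtures).

These fixtures emulate the *shape* of real inputs — AP-like waveforms with
closed-form biomarkers, biomarker windows around a reference model, labeled
populations with planted conductance differences — not the electrophysiology
itself; use the cell model for that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cell_model as cm
from .biomarkers import BIOMARKER_COLUMNS
from .drugs import ChannelBlock, DrugSpec
from .population import BiomarkerRanges, Population
from .simulation import Trace

__all__ = ["WaveformSpec", "make_waveform", "make_range_table", "make_toy_population",
           "make_test_drug", "write_fixture_workspace"]


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric AP-like waveform whose biomarkers are known in closed form.

    Each beat rises linearly from ``MDP`` to ``Peak`` over ``upstroke_ms``,
    then repolarizes either linearly back to MDP over ``repol_ms`` or
    exponentially toward MDP with time constant ``tau_ms``, and rests at
    MDP until the next cycle.  Closed forms (measured from the upstroke):
    ``APA = Peak − MDP``; ``Vmax = APA / upstroke_ms``;
    linear: ``APD_x = x/100 * repol_ms``; exponential:
    ``APD_x = tau_ms * ln(100/(100−x))``.
    """

    MDP_mV: float = -80.0
    Peak_mV: float = 40.0
    upstroke_ms: float = 1.0
    repol: str = "linear"            # "linear" | "exponential"
    repol_ms: float = 300.0
    tau_ms: float = 100.0
    cycle_ms: float = 1000.0
    beats: int = 5
    dt_ms: float = 0.5

    def __post_init__(self):
        if self.Peak_mV <= self.MDP_mV:
            raise ValueError("Peak must exceed MDP")
        if min(self.upstroke_ms, self.cycle_ms, self.dt_ms) <= 0:
            raise ValueError("durations must be positive")
        if self.repol not in ("linear", "exponential"):
            raise ValueError(f"unknown repolarization shape {self.repol!r}")

    def expected_apd(self, x: int) -> float:
        """Analytic APD_x in ms, measured from the peak."""
        if self.repol == "linear":
            return (x / 100.0) * self.repol_ms
        return self.tau_ms * math.log(100.0 / (100.0 - x))


def make_waveform(spec: WaveformSpec) -> Trace:
    """Render the waveform on a regular grid."""
    apa = spec.Peak_mV - spec.MDP_mV
    t_ms = np.arange(0.0, spec.beats * spec.cycle_ms, spec.dt_ms)
    v = np.full_like(t_ms, spec.MDP_mV)
    for k in range(spec.beats):
        tau0 = k * spec.cycle_ms
        local = t_ms - tau0
        rise = (local >= 0) & (local < spec.upstroke_ms)
        v[rise] = spec.MDP_mV + apa * local[rise] / spec.upstroke_ms
        post = local - spec.upstroke_ms
        if spec.repol == "linear":
            fall = (post >= 0) & (post < spec.repol_ms)
            v[fall] = spec.Peak_mV - apa * post[fall] / spec.repol_ms
        else:
            fall = (post >= 0) & (local < spec.cycle_ms)
            v[fall] = spec.MDP_mV + apa * np.exp(-post[fall] / spec.tau_ms)
    return Trace(t_ms / 1000.0, v, metadata={"synthetic": True, "spec": spec.__dict__.copy()})


def make_range_table(
    tightness: float, reference: dict[str, float], seed: int | None = None
) -> BiomarkerRanges:
    """Acceptance windows ``reference ± tightness x |reference|`` per biomarker.

    ``tightness`` is a fraction (> 0); large values accept everything,
    values near zero accept only the reference model itself.  The
    construction is deterministic (``seed`` is accepted for interface
    uniformity with the other generators).
    """
    if not tightness > 0:
        raise ValueError("tightness must be > 0")
    bounds = {}
    for k, v in reference.items():
        if k not in BIOMARKER_COLUMNS:
            continue
        half = tightness * abs(v)
        bounds[k] = (v - half, v + half)
    return BiomarkerRanges(bounds, source=f"synthetic tightness={tightness}")


def make_toy_population(
    n: int,
    planted: dict[str, float] | None = None,
    seed: int | None = None,
    apd90_split_ms: float = 500.0,
) -> Population:
    """A labeled mutant-genotype population with exactly planted group medians.

    Half the models are labeled ``symptomatic``, half ``asymptomatic``.
    For each entry ``param -> pct`` in ``planted``, the symptomatic group's
    median scale factor is ``1 + pct/100`` while the asymptomatic median is
    1, exactly (the central elements of each group are pinned to the
    median), so :func:`cardiopop.analysis.compare_groups` must recover the
    planted percent difference to round-off.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    planted = planted or {}
    rng = np.random.default_rng(seed)
    n_sym = n // 2
    n_asym = n - n_sym
    labels = ["symptomatic"] * n_sym + ["asymptomatic"] * n_asym

    def median_pinned(g: int, center: float) -> np.ndarray:
        off = np.linspace(-0.15, 0.15, g)
        if g % 2 == 1:
            off[g // 2] = 0.0
        else:
            off[g // 2 - 1] = off[g // 2] = 0.0
        vals = center * (1.0 + off)
        rng.shuffle(vals)
        return vals

    cols = {"id": np.arange(n)}
    for p in cm.SAMPLED_PARAMETERS:
        center_sym = 1.0 + planted.get(p, 0.0) / 100.0
        cols[f"scale_{p}"] = np.concatenate(
            [median_pinned(n_sym, center_sym), median_pinned(n_asym, 1.0)]
        )
    df = pd.DataFrame(cols)
    df["status"] = "spontaneous"
    base = {"rate": 36.0, "MDP": -76.0, "Peak": 28.0, "APA": 104.0, "Vmax": 25.0,
            "APD30": 200.0, "APD50": 300.0}
    for k, v in base.items():
        df[k] = v + rng.normal(0, 0.01 * abs(v), n)
    df["APD90"] = np.where(
        np.array(labels) == "symptomatic",
        apd90_split_ms * 1.3 + rng.uniform(0, 50, n),
        apd90_split_ms * 0.8 + rng.uniform(-50, 0, n),
    )
    df["label"] = labels
    prov = {"synthetic": True, "seed": seed, "planted": dict(planted),
            "ranges": {"APD90": [0.0, apd90_split_ms]}}
    return Population(df, cm.Genotype.V1763M, prov)


def make_test_drug(name: str = "testdrug") -> DrugSpec:
    """Fictitious pore-block spec for exercising the drug machinery.

    20 μM exactly halves I_NaL (IC50 = 20 μM, h = 1) and weakly blocks
    I_Kr, with a genotype override on I_Na to exercise the genotype
    resolution path.  Deliberately namespaced apart from the (synthetic)
    mexiletine/ranolazine parameter files.
    """
    return DrugSpec(
        name=name,
        channels={
            "I_NaL": ChannelBlock(ic50_uM=20.0, hill=1.0),
            "I_Kr": ChannelBlock(ic50_uM=200.0, hill=1.0),
            "I_Na": ChannelBlock(ic50_uM=400.0, hill=1.0,
                                 genotype_overrides={"V1763M": {"ic50_uM": 200.0}}),
        },
        doses_uM=(5.0, 10.0, 20.0),
    )


def write_fixture_workspace(outdir, seed: int = 0, n: int = 12) -> dict:
    """Write a complete toy workspace (ranges, drug spec, mini population).

    Returns the paths written.  Used by the ``make-fixtures`` CLI command
    and by tests that exercise the file-based interfaces.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference = {"rate": 36.0, "MDP": -76.0, "Peak": 28.0, "APA": 104.0, "Vmax": 25.0,
                 "APD30": 200.0, "APD50": 300.0, "APD90": 480.0}
    ranges = make_range_table(0.5, reference, seed)
    ranges.to_yaml(out / "ranges_toy.yaml")
    drug = make_test_drug()
    drug.to_yaml(out / "testdrug.yaml")
    pop = make_toy_population(n, {"g_NaL": 41.0}, seed)
    pop.to_csv(out / "toy_population.csv")
    return {"ranges": out / "ranges_toy.yaml", "drug": out / "testdrug.yaml",
            "population": out / "toy_population.csv"}
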
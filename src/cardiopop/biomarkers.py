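"""Action-potential biomarker extraction.

Biomarkers are the currency of the whole pipeline: they are what the
population is calibrated on, what phenotypes are classified by, and what
drug responses are read out as.  Definitions (per beat):

rate
    60 / mean cycle length, beats/min (requires at least two cycles).
MDP
    maximum diastolic potential — the minimum Vm of the cycle, mV.
Peak
    maximum Vm of the cycle, mV.
APA
    action-potential amplitude, ``Peak − MDP``, mV.
Vmax
    maximum upstroke velocity, V/s.
APD_x
    action-potential duration at x% repolarization: time from the instant
    of maximum upstroke velocity to the downward crossing of
    ``Peak − x/100 × APA``, ms.  The upstroke (not a stimulus, these cells
    are unpaced) is the reference point; crossings are linearly
    interpolated between samples so results are stable under grid
    refinement.

The per-model summary is the mean over the last ``summary_beats`` complete
beats, which smooths residual beat-to-beat drift near the limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulation import Trace

__all__ = ["BiomarkerSettings", "Biomarkers", "NoCompleteCycleError", "extract_biomarkers",
           "BIOMARKER_COLUMNS"]

#: Canonical column order of exported biomarker tables.
BIOMARKER_COLUMNS = ("rate", "MDP", "Peak", "APA", "Vmax", "APD30", "APD50", "APD90")


class NoCompleteCycleError(ValueError):
    """Raised when a trace contains no complete AP cycle to measure."""


@dataclass(frozen=True)
class BiomarkerSettings:
    apd_levels: tuple[int, ...] = (30, 50, 90)
    summary_beats: int = 3


@dataclass
class Biomarkers:
    """Per-beat biomarker table plus the across-beat summary used downstream."""

    per_beat: pd.DataFrame
    summary: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.summary[key]

    def as_row(self) -> dict[str, float]:
        return {k: self.summary.get(k, np.nan) for k in self.summary}


def _interp_crossing_down(t: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """Time of the first downward crossing of ``level``, linearly interpolated."""
    below = (v[:-1] >= level) & (v[1:] < level)
    idx = np.nonzero(below)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    frac = (v[i] - level) / (v[i] - v[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def extract_biomarkers(
    cycles: list[tuple[int, int]],
    trace: Trace,
    settings: BiomarkerSettings = BiomarkerSettings(),
) -> Biomarkers:
    """Measure every biomarker on the detected cycles of ``trace``.

    Raises :class:`NoCompleteCycleError` if no cycle yields a complete
    measurement (the undefined-biomarkers signal — deliberately an
    exception, not zeros).
    """
    if not cycles:
        raise NoCompleteCycleError("no AP cycles detected")
    t, v, dvdt = trace.t, trace.Vm, trace.dVdt
    rows = []
    upstroke_times = []
    for a, b in cycles:
        seg = slice(a, b + 1)
        iup = a + int(np.argmax(dvdt[seg]))
        mdp = float(np.min(v[seg]))
        peak = float(np.max(v[iup : b + 1])) if iup < b else float(v[b])
        apa = peak - mdp
        if apa <= 0:
            continue
        row = {"MDP": mdp, "Peak": peak, "APA": apa, "Vmax": float(dvdt[iup]),
               "t_up": float(t[iup])}
        ok = True
        for x in sorted(settings.apd_levels):
            level = peak - (x / 100.0) * apa
            tc = _interp_crossing_down(t[iup : b + 1], v[iup : b + 1], level)
            if tc is None:
                ok = False
                break
            row[f"APD{x}"] = (tc - t[iup]) * 1000.0
        if ok:
            rows.append(row)
            upstroke_times.append(row["t_up"])
    if not rows:
        raise NoCompleteCycleError("no complete AP cycle (repolarization never "
                                   "reaches the APD level)")
    per_beat = pd.DataFrame(rows)
    if len(upstroke_times) >= 2:
        rate = 60.0 / float(np.mean(np.diff(upstroke_times)))
    else:
        rate = 0.0
    tail = per_beat.tail(settings.summary_beats)
    summary = {"rate": rate}
    for col in per_beat.columns:
        if col != "t_up":
            summary[col] = float(tail[col].mean())
    return Biomarkers(per_beat=per_beat, summary=summary)
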
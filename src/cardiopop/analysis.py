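"""Group contrasts: the ionic and biomarker summaries behind phenotype splits.

Conventions follow standard reporting practice for populations of models:
conductance contrasts are **medians of absolute maxima** (scale factor x
baseline value, so e.g. a late-Na conductance is reported in S/F and the
L-type Ca permeability in cm^3/(F*s)); ΔAPD90 aggregates are means ± SD.
The percent difference is 100 x (median_A − median_B) / median_B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cell_model as cm
from .population import Population
from .drugs import TrialResult

__all__ = ["GroupContrast", "compare_groups", "ancestor_contrast",
           "stopped_vs_beating_contrast", "rank_test", "CONDUCTANCE_REPORT_UNITS"]

#: Reporting units of each maximal conductance/permeability (values are the
#: factor converting the model's internal unit into the reporting unit).
CONDUCTANCE_REPORT_UNITS = {p: ("S/F", 1.0) for p in cm.SAMPLED_PARAMETERS}
CONDUCTANCE_REPORT_UNITS["P_CaL"] = ("cm^3/(F*s)", 1.0e6)   # m^3 -> cm^3... see note
CONDUCTANCE_REPORT_UNITS["k_NCX"] = ("A/F", 1.0)
CONDUCTANCE_REPORT_UNITS["P_NaK"] = ("A/F", 1.0)
CONDUCTANCE_REPORT_UNITS["g_pCa"] = ("A/F", 1.0)
# 1 m^3/(F*s) = 1e6 cm^3/(F*s); the baseline 8.64e-5 m^3/(F*s) prints as 86.4.


@dataclass
class GroupContrast:
    """Median-based contrast between two groups over a set of quantities."""

    table: pd.DataFrame      # columns: quantity, unit, median_a, median_b, pct_diff
    n_a: int
    n_b: int

    def pct(self, quantity: str) -> float:
        row = self.table.loc[self.table["quantity"] == quantity]
        if row.empty:
            raise KeyError(quantity)
        return float(row["pct_diff"].iloc[0])


def _values(pop: Population, quantity: str) -> tuple[pd.Series, str]:
    if quantity in cm.SAMPLED_PARAMETERS:
        unit, factor = CONDUCTANCE_REPORT_UNITS[quantity]
        return pop.conductance(quantity) * factor, unit
    if quantity in pop.table.columns:
        return pop.table[quantity], ""
    raise KeyError(f"unknown quantity {quantity!r}")


def compare_groups(
    pop_a: Population, pop_b: Population, quantities: list[str]
) -> GroupContrast:
    """Median of each quantity in group A vs group B, with percent difference.

    Conductances are contrasted on absolute maxima (scale x baseline) in
    their reporting units; biomarker columns are contrasted as stored.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for q in quantities:
        va, unit = _values(pop_a, q)
        vb, _ = _values(pop_b, q)
        ma, mb = float(va.median()), float(vb.median())
        pct = np.nan if mb == 0 else 100.0 * (ma - mb) / mb
        rows.append({"quantity": q, "unit": unit, "median_a": ma, "median_b": mb,
                     "pct_diff": pct})
    return GroupContrast(pd.DataFrame(rows), len(pop_a), len(pop_b))


def ancestor_contrast(
    control: Population, mutant: Population, quantities: list[str] | None = None
) -> GroupContrast:
    """Contrast control-genotype models by the fate of their mutant descendants.

    Group A: control ancestors of symptomatic mutants; group B: ancestors
    of asymptomatic mutants (matched by model id — the transfection
    preserves ids).  Default quantities are the control biomarkers.
    """
    if "label" not in mutant.table.columns:
        raise ValueError("mutant population must be classified first")
    missing = set(mutant.ids) - set(control.ids)
    if missing:
        raise ValueError(f"broken control-mutant id mapping; unmatched ids: {sorted(missing)[:5]}")
    labels = mutant.table.set_index("id")["label"]
    sym_ids = labels[labels == "symptomatic"].index
    asym_ids = labels[labels == "asymptomatic"].index
    ga = control.subset(control.table["id"].isin(sym_ids).to_numpy())
    gb = control.subset(control.table["id"].isin(asym_ids).to_numpy())
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("one ancestor group is empty")
    qs = quantities if quantities is not None else ["rate", "Vmax", "APD90"]
    return compare_groups(ga, gb, qs)


def stopped_vs_beating_contrast(
    trial: TrialResult, pop: Population, dose_uM: float,
    quantities: list[str] | None = None,
) -> GroupContrast:
    """Conductance contrast between models silenced by a dose and those still beating."""
    pm = trial.per_model
    at_dose = pm[pm["dose_uM"] == dose_uM]
    if at_dose.empty:
        raise ValueError(f"trial contains no dose {dose_uM} uM")
    stopped_ids = at_dose.loc[at_dose["stopped"], "id"]
    beating_ids = at_dose.loc[~at_dose["stopped"] & ~at_dose["failed"], "id"]
    if len(stopped_ids) == 0 or len(beating_ids) == 0:
        raise ValueError("need at least one stopped and one beating model at this dose")
    ga = pop.subset(pop.table["id"].isin(stopped_ids).to_numpy())
    gb = pop.subset(pop.table["id"].isin(beating_ids).to_numpy())
    qs = quantities if quantities is not None else ["g_Na", "g_K1"]
    return compare_groups(ga, gb, qs)


def rank_test(pop_a: Population, pop_b: Population, quantity: str) -> float:
    """Two-sided Mann-Whitney U p-value for one quantity between two groups.

    Provided for exploratory use; the pipeline's headline numbers are the
    median contrasts, not significance tests.
    """
    from scipy.stats import mannwhitneyu

    va, _ = _values(pop_a, quantity)
    vb, _ = _values(pop_b, quantity)
    return float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
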
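"""Group contrasts: brute-force oracles, antisymmetry, planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest

import cardiopop as cp
from cardiopop import cell_model as cm
from cardiopop.analysis import (
    CONDUCTANCE_REPORT_UNITS,
    ancestor_contrast,
    compare_groups,
    stopped_vs_beating_contrast,
)
from cardiopop.drugs import TrialResult
from cardiopop.population import Population


def _pop_from_scales(scales_by_model, genotype=cp.Genotype.V1763M, apd90=None):
    rows = []
    for i, scales in enumerate(scales_by_model):
        row = {"id": i, **{f"scale_{p}": scales.get(p, 1.0) for p in cm.SAMPLED_PARAMETERS}}
        row["status"] = "spontaneous"
        row["APD90"] = apd90[i] if apd90 is not None else 400.0
        row["rate"] = 40.0
        row["Vmax"] = 25.0
        rows.append(row)
    return Population(pd.DataFrame(rows), genotype)


class TestCompareGroups:
    def test_group_vs_itself_is_zero(self):
        pop = cp.make_toy_population(10, {"g_NaL": 30.0}, seed=2)
        gc = compare_groups(pop, pop, ["g_NaL", "g_Kr", "APD90"])
        assert np.allclose(gc.table["pct_diff"], 0.0)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(9)
        a = _pop_from_scales([{"g_NaL": v} for v in rng.uniform(0.5, 2, 11)])
        b = _pop_from_scales([{"g_NaL": v} for v in rng.uniform(0.5, 2, 7)])
        gc = compare_groups(a, b, ["g_NaL"])
        base = cm.BASELINE_MAXIMA["g_NaL"]
        ma = np.median(a.table["scale_g_NaL"] * base)
        mb = np.median(b.table["scale_g_NaL"] * base)
        assert gc.table["median_a"].iloc[0] == pytest.approx(ma)
        assert gc.pct("g_NaL") == pytest.approx(100 * (ma - mb) / mb)

    def test_absolute_maxima_units(self):
        """P_CaL contrasts are reported in cm^3/(F*s): the baseline prints as ~86.4."""
        pop = _pop_from_scales([{p: 1.0 for p in cm.SAMPLED_PARAMETERS}] * 3)
        gc = compare_groups(pop, pop, ["P_CaL"])
        unit, factor = CONDUCTANCE_REPORT_UNITS["P_CaL"]
        assert unit == "cm^3/(F*s)"
        assert gc.table["median_a"].iloc[0] == pytest.approx(
            cm.BASELINE_MAXIMA["P_CaL"] * factor
        )
        assert gc.table["median_a"].iloc[0] == pytest.approx(86.36, rel=1e-3)

    def test_antisymmetry(self):
        a = _pop_from_scales([{"g_Kr": 1.4}] * 5)
        b = _pop_from_scales([{"g_Kr": 0.8}] * 5)
        ab = compare_groups(a, b, ["g_Kr"]).pct("g_Kr")
        ba = compare_groups(b, a, ["g_Kr"]).pct("g_Kr")
        assert (1 + ab / 100) * (1 + ba / 100) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        pop = cp.make_toy_population(6, seed=1)
        empty = pop.subset(np.zeros(len(pop), dtype=bool))
        with pytest.raises(ValueError):
            compare_groups(empty, pop, ["g_NaL"])

    def test_unknown_quantity_rejected(self):
        pop = cp.make_toy_population(6, seed=1)
        with pytest.raises(KeyError):
            compare_groups(pop, pop, ["g_mystery"])


class TestPlantedTruth:
    @pytest.mark.parametrize("pct", [41.0, -17.7, 13.6])
    def test_single_planted_difference_recovered_exactly(self, pct):
        pop = cp.make_toy_population(30, {"g_NaL": pct}, seed=4)
        sym = pop.subset((pop.table["label"] == "symptomatic").to_numpy())
        asym = pop.subset((pop.table["label"] == "asymptomatic").to_numpy())
        gc = compare_groups(sym, asym, ["g_NaL"])
        assert gc.pct("g_NaL") == pytest.approx(pct, abs=1e-9)

    def test_multi_parameter_planting(self):
        planted = {"g_NaL": 41.0, "P_CaL": 27.1, "g_Kr": -17.7, "g_K1": 13.6, "g_pCa": -8.6}
        pop = cp.make_toy_population(41, planted, seed=8)
        sym = pop.subset((pop.table["label"] == "symptomatic").to_numpy())
        asym = pop.subset((pop.table["label"] == "asymptomatic").to_numpy())
        gc = compare_groups(sym, asym, list(planted))
        for p, pct in planted.items():
            assert gc.pct(p) == pytest.approx(pct, abs=1e-9)


class TestAncestorContrast:
    def _setup(self):
        apds_ctrl = [300.0, 320.0, 500.0, 520.0]
        control = _pop_from_scales([{}] * 4, cp.Genotype.CONTROL, apd90=apds_ctrl)
        mutant = _pop_from_scales([{}] * 4, cp.Genotype.V1763M,
                                  apd90=[400, 410, 700, 720])
        mutant.table["label"] = ["asymptomatic", "asymptomatic", "symptomatic", "symptomatic"]
        return control, mutant

    def test_matches_manual_partition(self):
        control, mutant = self._setup()
        gc = ancestor_contrast(control, mutant, ["APD90"])
        # symptomatic ancestors: APD90 {500, 520}; asymptomatic: {300, 320}
        assert gc.table["median_a"].iloc[0] == pytest.approx(510.0)
        assert gc.table["median_b"].iloc[0] == pytest.approx(310.0)
        assert gc.pct("APD90") == pytest.approx(100 * 200 / 310)

    def test_single_label_errors(self):
        control, mutant = self._setup()
        mutant.table["label"] = "symptomatic"
        with pytest.raises(ValueError):
            ancestor_contrast(control, mutant)

    def test_broken_mapping_errors(self):
        control, mutant = self._setup()
        mutant.table.loc[0, "id"] = 99
        with pytest.raises(ValueError):
            ancestor_contrast(control, mutant)

    def test_unclassified_mutant_errors(self):
        control, mutant = self._setup()
        mutant.table.drop(columns=["label"], inplace=True)
        with pytest.raises(ValueError):
            ancestor_contrast(control, mutant)


class TestStoppedVsBeating:
    def _trial(self, stopped_ids, all_ids, dose=20.0):
        rows = [
            {"id": i, "dose_uM": dose, "stopped": i in stopped_ids, "failed": False,
             "dAPD90_ms": np.nan if i in stopped_ids else -10.0}
            for i in all_ids
        ]
        pm = pd.DataFrame(rows)
        return TrialResult("x", "V1763M", pm, pd.DataFrame())

    def test_matches_manual_medians(self):
        scales = [{"g_Na": v} for v in (0.6, 0.7, 1.5, 1.6, 1.7)]
        pop = _pop_from_scales(scales)
        trial = self._trial({0, 1}, range(5))
        gc = stopped_vs_beating_contrast(trial, pop, 20.0, ["g_Na"])
        base = cm.BASELINE_MAXIMA["g_Na"]
        assert gc.table["median_a"].iloc[0] == pytest.approx(0.65 * base)
        assert gc.table["median_b"].iloc[0] == pytest.approx(1.6 * base)

    def test_no_stopped_models_errors(self):
        pop = _pop_from_scales([{}] * 3)
        trial = self._trial(set(), range(3))
        with pytest.raises(ValueError):
            stopped_vs_beating_contrast(trial, pop, 20.0)

    def test_absent_dose_errors(self):
        pop = _pop_from_scales([{}] * 3)
        trial = self._trial({0}, range(3))
        with pytest.raises(ValueError):
            stopped_vs_beating_contrast(trial, pop, 5.0)


def test_rank_test_returns_probability():
    a = cp.make_toy_population(12, {"g_NaL": 60.0}, seed=3)
    sym = a.subset((a.table["label"] == "symptomatic").to_numpy())
    asym = a.subset((a.table["label"] == "asymptomatic").to_numpy())
    p = cp.rank_test(sym, asym, "g_NaL")
    assert 0.0 <= p <= 1.0
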
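"""Sampling, calibration, transfection and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import cardiopop as cp
from cardiopop import cell_model as cm
from cardiopop.population import (
    BiomarkerRanges,
    CandidateRecord,
    ConductanceSample,
    calibrate,
    classify,
    sample_population,
)


def _toy_candidates(values, quiescent=()):
    """CandidateRecords with a single hand-written APD90 biomarker each."""
    records = []
    for i, apd in enumerate(values):
        sample = ConductanceSample(i, {p: 1.0 for p in cm.SAMPLED_PARAMETERS})
        if i in quiescent:
            records.append(CandidateRecord(sample, "quiescent", None))
        else:
            bio = {"APD90": apd, "rate": 40.0}
            records.append(CandidateRecord(sample, "spontaneous", bio))
    return records


class TestSampling:
    def test_zero_models(self):
        assert sample_population(0, seed=0) == []

    @pytest.mark.parametrize("scheme", ["uniform", "lhs"])
    def test_bounds_and_reproducibility(self, scheme):
        a = sample_population(25, (0.5, 2.0), seed=11, scheme=scheme)
        b = sample_population(25, (0.5, 2.0), seed=11, scheme=scheme)
        assert a == b
        for s in a:
            for v in s.scales.values():
                assert 0.5 <= v <= 2.0

    def test_latin_hypercube_stratifies_each_dimension(self):
        n = 16
        samples = sample_population(n, (0.0, 1.0), seed=3, scheme="lhs")
        for p in cm.SAMPLED_PARAMETERS:
            vals = np.array([s.scales[p] for s in samples])
            strata = np.floor(vals * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            sample_population(5, (2.0, 0.5), seed=0)

    def test_unique_ids(self):
        ids = [s.id for s in sample_population(30, seed=0)]
        assert len(set(ids)) == 30


class TestCalibration:
    def test_matches_brute_force_oracle(self):
        """Acceptance equals an exhaustive per-candidate, per-biomarker check."""
        rng = np.random.default_rng(5)
        apds = rng.uniform(100, 900, 40)
        records = _toy_candidates(apds, quiescent={3, 17})
        ranges = BiomarkerRanges({"APD90": (250.0, 600.0)})
        pop = calibrate(records, ranges)
        expected = {
            r.sample.id
            for r in records
            if r.status == "spontaneous" and 250.0 <= r.biomarkers["APD90"] <= 600.0
        }
        assert set(pop.ids) == expected

    def test_infinite_ranges_accept_all_spontaneous(self):
        records = _toy_candidates([100, 500, 2000], quiescent={1})
        ranges = BiomarkerRanges({"APD90": (-np.inf, np.inf)})
        pop = calibrate(records, ranges)
        assert set(pop.ids) == {0, 2}

    def test_bounds_inclusive(self):
        records = _toy_candidates([250.0, 600.0])
        pop = calibrate(records, BiomarkerRanges({"APD90": (250.0, 600.0)}))
        assert len(pop) == 2

    def test_idempotent(self):
        records = _toy_candidates(np.linspace(100, 800, 15))
        ranges = BiomarkerRanges({"APD90": (200.0, 700.0)})
        once = calibrate(records, ranges)
        kept = [r for r in records if r.sample.id in set(once.ids)]
        twice = calibrate(kept, ranges)
        assert list(twice.ids) == list(once.ids)

    @given(lo=st.floats(100, 400), width=st.floats(0, 400), shrink=st.floats(0, 200))
    @hyp_settings(max_examples=30, deadline=None)
    def test_anti_monotonicity(self, lo, width, shrink):
        """Shrinking any range never enlarges the accepted set."""
        records = _toy_candidates(np.linspace(50, 900, 25))
        wide = calibrate(records, BiomarkerRanges({"APD90": (lo, lo + width)}))
        s = min(shrink, width / 2)
        lo2, hi2 = lo + s, max(lo + s, lo + width - s)
        narrow = calibrate(records, BiomarkerRanges({"APD90": (lo2, hi2)}))
        assert set(narrow.ids) <= set(wide.ids)

    def test_missing_biomarker_named_in_error(self):
        records = _toy_candidates([400.0])
        with pytest.raises(KeyError, match="Vmax"):
            calibrate(records, BiomarkerRanges({"Vmax": (0.0, 100.0)}))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            BiomarkerRanges({"APD90": (600.0, 250.0)})


class TestTransfection:
    def test_scale_factors_and_ids_preserved(self, control_population, mutant_population):
        assert mutant_population.genotype is cp.Genotype.V1763M
        ctrl = control_population.table.set_index("id")
        for mid in mutant_population.ids:
            row = mutant_population.table.set_index("id").loc[mid]
            for p in cm.SAMPLED_PARAMETERS:
                assert row[f"scale_{p}"] == ctrl.loc[mid, f"scale_{p}"]

    def test_id_mapping_injective(self, mutant_population):
        assert len(set(mutant_population.ids)) == len(mutant_population)

    def test_cardinality_conservation(self, control_population, mutant_population):
        nq = len(mutant_population.provenance["quiescent_ids"])
        assert len(control_population) == len(mutant_population) + nq

    def test_requires_control_genotype(self, mutant_population):
        with pytest.raises(ValueError):
            cp.transfect(mutant_population)


class TestClassification:
    def test_partition(self, mutant_population):
        labels = mutant_population.table["label"]
        assert set(labels.unique()) <= {"symptomatic", "asymptomatic"}
        assert len(labels) == len(mutant_population)

    def test_all_short_apds_are_asymptomatic(self):
        pop = cp.make_toy_population(8, seed=0)
        pop.table["APD90"] = 100.0
        labels = classify(pop, cp.ClassificationRule(apd90_threshold_ms=500.0))
        assert (labels == "asymptomatic").all()

    def test_threshold_from_calibration_ranges(self, mutant_population, synthetic_ranges):
        thr = mutant_population.provenance["classification_threshold_ms"]
        assert thr == synthetic_ranges.bounds["APD90"][1]

    def test_absent_biomarker_errors(self):
        pop = cp.make_toy_population(4, seed=0)
        with pytest.raises(KeyError):
            classify(pop, cp.ClassificationRule(biomarker="APD95"))


class TestPersistence:
    def test_csv_round_trip_and_byte_determinism(self, control_population, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        control_population.to_csv(p1)
        control_population.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = cp.Population.from_csv(p1)
        assert len(back) == len(control_population)
        assert list(back.ids) == list(control_population.ids)
        pd.testing.assert_frame_equal(
            back.table[["APD90"]], control_population.table[["APD90"]]
        )

    def test_duplicate_ids_rejected(self):
        df = cp.make_toy_population(4, seed=0).table
        df.loc[1, "id"] = df.loc[0, "id"]
        with pytest.raises(ValueError):
            cp.Population(df, cp.Genotype.V1763M)

    def test_hdf5_round_trip_with_trace_attachment(self, tmp_path):
        from cardiopop.io import load_population_hdf5, save_population_hdf5

        pop = cp.make_toy_population(6, {"g_NaL": 20.0}, seed=9)
        trace = cp.make_waveform(cp.WaveformSpec(beats=2))
        path = tmp_path / "pop.h5"
        save_population_hdf5(pop, path, traces={0: trace})
        back, traces = load_population_hdf5(path)
        assert back.genotype is pop.genotype
        assert sorted(back.ids) == sorted(pop.ids)
        assert np.allclose(
            back.table.sort_values("id")["APD90"],
            pop.table.sort_values("id")["APD90"],
        )
        assert back.provenance["planted"] == {"g_NaL": 20.0}
        assert np.allclose(traces[0].Vm, trace.Vm)

    def test_ranges_yaml_round_trip(self, synthetic_ranges, tmp_path):
        path = tmp_path / "ranges.yaml"
        synthetic_ranges.to_yaml(path)
        back = BiomarkerRanges.from_yaml(path)
        assert back.bounds == synthetic_ranges.bounds
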
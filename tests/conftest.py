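"""Shared fixtures.

The expensive fixtures are session-scoped and deliberately small: the cell
model is integrated for 60 simulated seconds (20-s analysis window) for
population work, and with the full 800-s production protocol only for the
two baseline (control vs mutant) reference runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cardiopop as cp
from cardiopop.config import packaged_config

FIXTURE_SEED = 1
FIXTURE_N = 48


@pytest.fixture(scope="session")
def fast_settings() -> cp.SolverSettings:
    return cp.SolverSettings(duration=60.0, analysis_window=20.0)


@pytest.fixture(scope="session")
def synthetic_ranges() -> cp.BiomarkerRanges:
    return cp.BiomarkerRanges.from_yaml(packaged_config("ranges_synthetic.yaml"))


@pytest.fixture(scope="session")
def baseline_runs():
    """Full-protocol (800 s) steady-state runs of the baseline control and
    mutant models, with biomarkers and persistent late-Na measurements."""
    out = {}
    for tag, params in (
        ("control", cp.CellParameters()),
        ("mutant", cp.apply_mutation(cp.CellParameters())),
    ):
        res = cp.run_to_steady_state(params)
        bio = cp.extract_biomarkers(cp.detect_cycles(res.trace), res.trace)
        out[tag] = {
            "params": params,
            "result": res,
            "biomarkers": bio,
            "persistent_inal": cp.persistent_late_sodium(res, params),
        }
    return out


@pytest.fixture(scope="session")
def candidate_records(fast_settings):
    samples = cp.sample_population(FIXTURE_N, seed=FIXTURE_SEED)
    return cp.evaluate_candidates(samples, settings=fast_settings)


@pytest.fixture(scope="session")
def control_population(candidate_records, synthetic_ranges):
    pop = cp.calibrate(candidate_records, synthetic_ranges,
                       provenance={"seed": FIXTURE_SEED})
    assert len(pop) > 0
    return pop


@pytest.fixture(scope="session")
def mutant_population(control_population, fast_settings):
    mut = cp.transfect(control_population, settings=fast_settings)
    cp.classify(mut)
    return mut


@pytest.fixture(scope="session")
def mexiletine_trial(mutant_population, fast_settings):
    drug = cp.DrugSpec.from_yaml(packaged_config("mexiletine_synthetic.yaml"))
    return cp.drug_trial(mutant_population, drug, [10.0, 20.0], settings=fast_settings)


@pytest.fixture(scope="session")
def mexiletine_control_trial(control_population, fast_settings):
    drug = cp.DrugSpec.from_yaml(packaged_config("mexiletine_synthetic.yaml"))
    return cp.drug_trial(control_population, drug, [10.0, 20.0], settings=fast_settings)


@pytest.fixture(scope="session")
def ranolazine_trial(mutant_population, fast_settings):
    drug = cp.DrugSpec.from_yaml(packaged_config("ranolazine_synthetic.yaml"))
    return cp.drug_trial(mutant_population, drug, [20.0], settings=fast_settings)


def _two_model_population(fast_settings, scales_list, genotype):
    """Build a tiny population directly from given scale-factor dicts."""
    rows = []
    for i, scales in enumerate(scales_list):
        full = {p: scales.get(p, 1.0) for p in cp.BASELINE_MAXIMA}
        params = cp.CellParameters.from_scale_factors(full, genotype)
        res = cp.run_to_steady_state(params, settings=fast_settings)
        bio = cp.extract_biomarkers(cp.detect_cycles(res.trace), res.trace)
        row = {"id": i, **{f"scale_{p}": full[p] for p in cp.BASELINE_MAXIMA},
               "status": "spontaneous", **bio.summary}
        rows.append(row)
    from cardiopop.population import Population

    return Population(pd.DataFrame(rows), genotype)


@pytest.fixture(scope="session")
def gnal_pair_population(fast_settings):
    """Two mutant models identical except for late-Na conductance (low vs high)."""
    return _two_model_population(
        fast_settings,
        [{"g_NaL": 0.6}, {"g_NaL": 1.8}],
        cp.Genotype.V1763M,
    )
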
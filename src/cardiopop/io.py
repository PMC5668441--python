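"""Optional HDF5 persistence for populations with trace attachments.

CSV is the canonical interchange for population tables (modest, diffable);
HDF5 is provided for bulk runs where voltage traces are attached to the
population file.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .cell_model import Genotype
from .population import Population
from .simulation import Trace

__all__ = ["save_population_hdf5", "load_population_hdf5"]


def save_population_hdf5(
    pop: Population, path, traces: dict[int, Trace] | None = None
) -> None:
    """Write a population (and optionally per-model voltage traces) to HDF5.

    Layout: one dataset per table column under ``/table``; provenance and
    genotype as root attributes (provenance JSON-encoded); per-model traces
    under ``/traces/<id>/{t,Vm}``.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["genotype"] = pop.genotype.value
        fh.attrs["provenance"] = json.dumps(pop.provenance, default=str)
        g = fh.create_group("table")
        for col in pop.table.columns:
            values = pop.table[col].to_numpy()
            if values.dtype == object:
                values = values.astype("S")
            g.create_dataset(col, data=values)
        if traces:
            tg = fh.create_group("traces")
            for model_id, tr in traces.items():
                sub = tg.create_group(str(model_id))
                sub.create_dataset("t", data=tr.t)
                sub.create_dataset("Vm", data=tr.Vm)


def load_population_hdf5(path) -> tuple[Population, dict[int, Trace]]:
    """Read back a population and any attached traces."""
    with h5py.File(path, "r") as fh:
        cols = {}
        for col, ds in fh["table"].items():
            values = ds[...]
            if values.dtype.kind == "S":
                values = values.astype(str)
            cols[col] = values
        table = pd.DataFrame(cols)
        if "id" in table.columns:
            table["id"] = table["id"].astype(int)
        pop = Population(
            table,
            Genotype(fh.attrs["genotype"]),
            json.loads(fh.attrs["provenance"]),
        )
        traces = {}
        if "traces" in fh:
            for model_id, sub in fh["traces"].items():
                traces[int(model_id)] = Trace(sub["t"][...], sub["Vm"][...])
    return pop, traces
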
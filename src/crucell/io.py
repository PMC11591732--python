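"""Trace persistence: HDF5 for full SimTraces, CSV for whole-cell fields,
spark events and per-beat metrics."""

from __future__ import annotations

import numpy as np
import h5py

from .model import SimTrace

__all__ = ["save_trace", "load_trace", "trace_to_csv"]


def save_trace(trace: SimTrace, path, config_hash: str | None = None) -> None:
    """Write a SimTrace to HDF5: one dataset per whole-cell field, an optional
    2-D per-CRU subspace block, stimulus times and metadata attributes."""
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("fields")
        for name, arr in trace.data.items():
            grp.create_dataset(name, data=arr)
        if trace.cru_ca_ds is not None:
            h5.create_dataset("cru_ca_ds", data=trace.cru_ca_ds)
            h5.create_dataset("cru_indices", data=trace.cru_indices)
        h5.create_dataset("stim_times", data=np.asarray(trace.stim_times))
        for key in ("seed", "dt", "n_cru"):
            if key in trace.meta:
                h5.attrs[key] = trace.meta[key]
        if config_hash:
            h5.attrs["config_hash"] = config_hash


def load_trace(path) -> SimTrace:
    with h5py.File(path, "r") as h5:
        data = {name: ds[...] for name, ds in h5["fields"].items()}
        cru = h5["cru_ca_ds"][...] if "cru_ca_ds" in h5 else None
        idx = h5["cru_indices"][...] if "cru_indices" in h5 else None
        stim = h5["stim_times"][...]
        meta = dict(h5.attrs)
    return SimTrace(data, cru_ca_ds=cru, cru_indices=idx, stim_times=stim,
                    meta=meta)


def trace_to_csv(trace: SimTrace, path) -> None:
    """Flat CSV export of the whole-cell fields."""
    trace.to_dataframe().to_csv(path, index=False)
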
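"""Serialization: HDF5 dataset container and plain-text geometry tables.

Epoched datasets round-trip bit-exactly through HDF5 with their sampling
metadata, covariance windows, units and provenance.  Sensor arrays, grids
and NAI maps use documented CSV tables (one row per channel / point, SI
units).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import SensorArray, SourceGrid, array_from_table
from .synthetic import EpochedData


def save_epochs(path, epochs: EpochedData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin"] = epochs.tmin
        f.attrs["noise_window"] = list(epochs.noise_window)
        f.attrs["data_window"] = list(epochs.data_window)
        f.attrs["rank_reduced"] = epochs.rank_reduced
        if epochs.rank_retained is not None:
            f.attrs["rank_retained"] = epochs.rank_retained
        f.attrs["meta"] = json.dumps(epochs.meta)
        if epochs.array is not None:
            f.create_dataset(
                "array_table",
                data=epochs.array.to_table().to_csv(index=False).encode(),
            )


def load_epochs(path) -> EpochedData:
    with h5py.File(path, "r") as f:
        array = None
        if "array_table" in f:
            from io import StringIO

            array = array_from_table(
                pd.read_csv(StringIO(f["array_table"][()].decode()))
            )
        return EpochedData(
            f["data"][()],
            float(f.attrs["sfreq"]),
            float(f.attrs["tmin"]),
            tuple(f.attrs["noise_window"]),
            tuple(f.attrs["data_window"]),
            array=array,
            rank_reduced=bool(f.attrs["rank_reduced"]),
            rank_retained=int(f.attrs["rank_retained"])
            if "rank_retained" in f.attrs
            else None,
            meta=json.loads(f.attrs["meta"]),
        )


def save_array(path, array: SensorArray) -> None:
    # %.17g round-trips float64 exactly through text
    array.to_table().to_csv(path, index=False, float_format="%.17g")


def load_array(path) -> SensorArray:
    return array_from_table(pd.read_csv(path))


def save_grid(path, grid: SourceGrid) -> None:
    df = grid.to_table()
    header = (
        f"# spacing={grid.spacing} inside_margin={grid.inside_margin} "
        f"origin={grid.origin.tolist()}\n"
    )
    Path(path).write_text(header + df.to_csv(index=False, float_format="%.17g"))


def load_grid(path) -> SourceGrid:
    text = Path(path).read_text().splitlines()
    meta = dict(
        kv.split("=", 1) for kv in text[0].lstrip("# ").split(" ", 2)
    )
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(text[1:])))
    return SourceGrid(
        df[["x", "y", "z"]].to_numpy(),
        float(meta["spacing"]),
        float(meta["inside_margin"]),
        np.asarray(json.loads(meta["origin"]), float),
    )
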
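"""Delimited-text and HDF5 input/output.

File formats:

* spikes CSV — columns ``unit_id, spike_time_s``
* units CSV — ``unit_id, area, layer, waveform_width_ms, snr, mouse_id``
* epochs CSV — ``start_s, end_s, category`` (raw stimulus name)
* running-speed CSV — ``time_s, speed_cm_s``
* rate matrices and stimulus movies — HDF5 (see ``RateMatrix.to_hdf5`` and
  :func:`save_movie`)
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .preprocess import SpikeTable

#: Float format used for byte-stable CSV output.
FLOAT_FORMAT = "%.10g"


def read_spike_table(
    spikes_csv, units_csv, session_duration: float | None = None
) -> SpikeTable:
    """Assemble a :class:`SpikeTable` from spikes + unit-metadata CSVs.

    When ``session_duration`` is omitted it is taken as the last spike time
    rounded up to the next second.
    """
    sp = pd.read_csv(spikes_csv)
    units = pd.read_csv(units_csv).set_index("unit_id")
    spikes = {
        str(uid): np.sort(g["spike_time_s"].to_numpy(float))
        for uid, g in sp.groupby("unit_id", sort=False)
    }
    for uid in units.index.astype(str):
        spikes.setdefault(uid, np.empty(0))
    if session_duration is None:
        last = max((s[-1] for s in spikes.values() if s.size), default=0.0)
        session_duration = float(np.ceil(last)) + 1.0
    units.index = units.index.astype(str)
    return SpikeTable(spikes=spikes, units=units, session_duration=session_duration)


def write_spike_table(table: SpikeTable, spikes_csv, units_csv) -> None:
    rows = [
        (uid, t) for uid, st in table.spikes.items() for t in st
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        spikes_csv, index=False, float_format=FLOAT_FORMAT
    )
    table.units.to_csv(units_csv, float_format=FLOAT_FORMAT)


def read_epochs(path) -> pd.DataFrame:
    """Epoch table with columns start_s, end_s, category."""
    return pd.read_csv(path)


def read_speed(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_movie(path, movie: np.ndarray, frame_rate: float) -> None:
    """Persist a pixels × frames movie with its frame rate."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("movie", data=np.asarray(movie, float))
        ds.attrs["frame_rate"] = frame_rate


def load_movie(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as fh:
        ds = fh["movie"]
        return ds[()], float(ds.attrs["frame_rate"])
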
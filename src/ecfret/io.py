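"""Photon-stream containers on disk: HDF5-style layout or 3-column text."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .simulate import PhotonStream


def write_photon_hdf5(stream: PhotonStream, path: str | Path) -> None:
    """Write a photon stream with datasets timestamps / detector / excitation."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("photon_data")
        grp.create_dataset("timestamps", data=stream.timestamps)
        grp.create_dataset("detector", data=stream.detector)
        grp.create_dataset("excitation", data=stream.excitation)
        f.attrs["acquisition_duration"] = stream.duration


def read_photon_hdf5(path: str | Path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        grp = f["photon_data"]
        return PhotonStream(
            timestamps=grp["timestamps"][:],
            detector=grp["detector"][:],
            excitation=grp["excitation"][:],
            duration=float(f.attrs["acquisition_duration"]),
        )


def write_photon_text(stream: PhotonStream, path: str | Path) -> None:
    """3-column text fallback: timestamp_s, detector, excitation."""
    header = f"# acquisition_duration_s={stream.duration}\n" \
             "timestamp_s\tdetector\texcitation"
    data = np.column_stack([stream.timestamps, stream.detector,
                            stream.excitation])
    np.savetxt(path, data, fmt=("%.9f", "%d", "%d"), delimiter="\t",
               header=header, comments="")


def read_photon_text(path: str | Path) -> PhotonStream:
    with open(path) as fh:
        first = fh.readline().strip()
    duration = float(first.split("=", 1)[1]) if first.startswith("#") else None
    data = np.loadtxt(path, skiprows=2 if duration is not None else 1,
                      delimiter="\t")
    data = np.atleast_2d(data)
    ts = data[:, 0]
    if duration is None:
        duration = float(ts[-1]) if ts.size else 0.0
    return PhotonStream(ts, data[:, 1].astype(np.int8),
                        data[:, 2].astype(np.int8), duration)
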
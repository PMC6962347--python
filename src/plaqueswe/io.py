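"""HDF5 container I/O for wave data.

One acquisition lives in one HDF5 file with datasets

* ``iq`` (complex) or ``velocity`` (float): (depth, lateral, slow_time)
* ``roi`` (bool, optional): (depth, lateral) plaque mask
* ``map_left`` / ``map_right`` (float, optional): depth-averaged
  space-time maps with their ``*_lateral_positions`` axis vectors and a
  shared ``map_times`` vector

and root attributes carrying every acquisition-grid field in SI units.
Vendor IQ formats are proprietary; this container is the documented
ingestion boundary (axis order, SI units, required attributes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .datatypes import AcquisitionGrid, IQEnsemble, ParticleVelocityField, ROIMask, SpaceTimeMap

__all__ = [
    "save_field",
    "load_field",
    "save_iq",
    "load_iq",
    "load_roi",
    "save_maps",
    "load_maps",
]


def _write_grid(f: h5py.File, grid: AcquisitionGrid) -> None:
    for key, val in grid.to_attrs().items():
        f.attrs[key] = val


def _read_grid(f: h5py.File) -> AcquisitionGrid:
    return AcquisitionGrid.from_attrs(f.attrs)


def save_field(path, field: ParticleVelocityField, roi: Optional[ROIMask] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=field.values)
        _write_grid(f, field.grid)
        if roi is not None:
            f.create_dataset("roi", data=roi.mask)


def load_field(path) -> ParticleVelocityField:
    with h5py.File(path, "r") as f:
        if "velocity" not in f:
            raise KeyError(f"{Path(path).name}: no 'velocity' dataset")
        grid = _read_grid(f)
        values = f["velocity"][()]
    if values.shape[2] != grid.n_frames:
        grid = AcquisitionGrid(**{**grid.to_attrs(), "n_frames": values.shape[2]})
    return ParticleVelocityField(values=values, grid=grid)


def save_iq(path, iq: IQEnsemble, roi: Optional[ROIMask] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("iq", data=iq.samples)
        _write_grid(f, iq.grid)
        if roi is not None:
            f.create_dataset("roi", data=roi.mask)


def load_iq(path) -> IQEnsemble:
    with h5py.File(path, "r") as f:
        if "iq" not in f:
            raise KeyError(f"{Path(path).name}: no 'iq' dataset")
        grid = _read_grid(f)
        samples = f["iq"][()]
    return IQEnsemble(samples=samples, grid=grid)


def load_roi(path) -> Optional[ROIMask]:
    with h5py.File(path, "r") as f:
        if "roi" not in f:
            return None
        return ROIMask(f["roi"][()])


def save_maps(path, left: SpaceTimeMap, right: SpaceTimeMap) -> None:
    with h5py.File(path, "a") as f:
        for name, m in (("map_left", left), ("map_right", right)):
            for ds in (name, f"{name}_lateral_positions"):
                if ds in f:
                    del f[ds]
            f.create_dataset(name, data=m.values)
            f.create_dataset(f"{name}_lateral_positions", data=m.lateral_positions)
        if "map_times" in f:
            del f["map_times"]
        f.create_dataset("map_times", data=left.times)


def load_maps(path) -> tuple[SpaceTimeMap, SpaceTimeMap]:
    with h5py.File(path, "r") as f:
        times = f["map_times"][()]
        out = []
        for name, direction in (("map_left", "leftward"), ("map_right", "rightward")):
            out.append(
                SpaceTimeMap(
                    values=f[name][()],
                    lateral_positions=f[f"{name}_lateral_positions"][()],
                    times=times,
                    direction=direction,
                )
            )
    return out[0], out[1]
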
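"""Standard-format I/O: MRC2014 volumes, CSV tables, JSON results.

Volumes are written as 32-bit float MRC2014 maps through gemmi.  Internally
all coordinates are nm; the MRC header records the voxel size in Å (x10) as
is conventional for cryo-EM maps, and the world origin in Å in the MRC
origin words.  Grids are indexed ``grid[ix, iy, iz]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .filaments import FilamentTrace
from .volume import DensityVolume

__all__ = ["write_mrc", "read_mrc", "write_traces_csv", "read_traces_csv",
           "write_json"]

TRACE_COLUMNS = ["mt_id", "point_index", "x_nm", "y_nm", "z_nm"]


def write_mrc(vol: DensityVolume, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.grid, dtype=np.float32))
    nx, ny, nz = vol.grid.shape
    vs_a = vol.voxel_size * 10.0  # nm -> Å
    m.grid.unit_cell = gemmi.UnitCell(nx * vs_a, ny * vs_a, nz * vs_a, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, o in zip((50, 51, 52), vol.origin):
        m.set_header_float(w, float(o) * 10.0)  # origin in Å
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityVolume:
    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    vs_nm = cell.a / grid.shape[0] / 10.0
    origin = np.array([m.header_float(w) for w in (50, 51, 52)]) / 10.0
    return DensityVolume(grid, vs_nm, origin)


def write_traces_csv(traces: list[FilamentTrace], path) -> None:
    rows = []
    for tr in traces:
        for i, p in enumerate(tr.points):
            rows.append((tr.mt_id, i, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces_csv(path, resampled: bool = False,
                    spacing: float | None = None) -> list[FilamentTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns {missing}")
    traces = []
    for mt_id, g in df.groupby("mt_id", sort=True):
        g = g.sort_values("point_index")
        pts = g[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        traces.append(FilamentTrace(mt_id=int(mt_id), points=pts,
                                    resampled=resampled, spacing=spacing))
    return traces


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True,
                                     default=_jsonable) + "\n")
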
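"""VTK unstructured-grid time-series output.

Frames are XML VTU files with plain inline ASCII data arrays (no appended
binary blocks), so any standard VTK reader parses them and diffs are
bit-stable; a PVD collection file indexes the frames by simulation time.
2-D geometry is embedded in 3-D with z = 0.

Per framework a cell is exported as:

- VM: one polygon per element;
- VT: the clipped Voronoi polygon of each centre;
- PM: one VTK vertex per centre (a point-glyph source);
- CA/CP: one unit quad per occupied lattice site, carrying the owning
  cell's data.

Every frame exposes an integer cell-data array named exactly "Cell types"
(plus "Cell ids"), so time series can be coloured by type in ParaView.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .geometry import BoundingBox, Lattice, VertexMesh, voronoi_regions_or_box

__all__ = ["write_frame", "write_series_index", "SeriesIndex", "frame_geometry"]

VTK_VERTEX = 1
VTK_POLYGON = 7
VTK_QUAD = 9


class SeriesIndex:
    """Ordered (timestep, frame path) list backing a PVD collection file."""

    def __init__(self):
        self.entries: list[tuple[float, str]] = []

    def append(self, timestep: float, path: str | Path) -> None:
        if self.entries and timestep <= self.entries[-1][0]:
            raise ValueError("timestep values must be strictly increasing")
        self.entries.append((float(timestep), str(path)))

    def __len__(self) -> int:
        return len(self.entries)


def frame_geometry(state) -> tuple[np.ndarray, list[list[int]], list[int], dict[str, list]]:
    """Extract (points, cell connectivity, VTK cell types, cell data) from a state."""
    structure = state.structure
    cells = state.cells
    if isinstance(structure, VertexMesh):
        ids = sorted(structure.nodes)
        index = {nid: k for k, nid in enumerate(ids)}
        points = np.array([structure.nodes[nid].position for nid in ids])
        conn, vtk_types, type_arr, id_arr = [], [], [], []
        for eid in sorted(structure.elements):
            conn.append([index[n] for n in structure.elements[eid].node_ids])
            vtk_types.append(VTK_POLYGON)
            type_arr.append(cells[eid].type_label)
            id_arr.append(eid)
        return points, conn, vtk_types, {"Cell types": type_arr, "Cell ids": id_arr}
    if isinstance(structure, Lattice):
        points_list, conn, type_arr, id_arr = [], [], [], []
        for x, y in np.argwhere(structure.occupancy != 0):
            cid = int(structure.occupancy[x, y])
            base = len(points_list)
            points_list += [
                [x - 0.5, y - 0.5],
                [x + 0.5, y - 0.5],
                [x + 0.5, y + 0.5],
                [x - 0.5, y + 0.5],
            ]
            conn.append([base, base + 1, base + 2, base + 3])
            type_arr.append(cells[cid].type_label)
            id_arr.append(cid)
        points = np.array(points_list) if points_list else np.empty((0, 2))
        return points, conn, [VTK_QUAD] * len(conn), {
            "Cell types": type_arr,
            "Cell ids": id_arr,
        }
    # centre population
    ids = structure.ids()
    pts = structure.coords()
    type_arr = [cells[i].type_label for i in ids]
    if structure.connectivity_mode == "voronoi" and len(ids) >= 1:
        margin = 1.0
        box = BoundingBox(
            float(pts[:, 0].min()) - margin,
            float(pts[:, 0].max()) + margin,
            float(pts[:, 1].min()) - margin,
            float(pts[:, 1].max()) + margin,
        )
        regions = voronoi_regions_or_box(pts, box)
        points_list, conn = [], []
        for poly in regions:
            base = len(points_list)
            points_list += [list(p) for p in poly]
            conn.append(list(range(base, base + len(poly))))
        return np.array(points_list), conn, [VTK_POLYGON] * len(conn), {
            "Cell types": type_arr,
            "Cell ids": list(ids),
        }
    conn = [[k] for k in range(len(ids))]
    return pts, conn, [VTK_VERTEX] * len(conn), {"Cell types": type_arr, "Cell ids": list(ids)}


def _fmt_floats(arr: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in arr.ravel())


def _fmt_ints(vals) -> str:
    return " ".join(str(int(v)) for v in vals)


def write_frame(state, path: str | Path) -> None:
    """Write one VTU frame for the state; atomic (no partial file on error)."""
    points2d, conn, vtk_types, cell_data = frame_geometry(state)
    n_points = len(points2d)
    n_cells = len(conn)
    points3d = np.zeros((n_points, 3))
    if n_points:
        points3d[:, :2] = points2d
    connectivity = [i for ring in conn for i in ring]
    offsets = np.cumsum([len(ring) for ring in conn])
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_points}" NumberOfCells="{n_cells}">',
        "      <Points>",
        f'        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt_floats(points3d)}</DataArray>',
        "      </Points>",
        "      <Cells>",
        f'        <DataArray type="Int64" Name="connectivity" format="ascii">{_fmt_ints(connectivity)}</DataArray>',
        f'        <DataArray type="Int64" Name="offsets" format="ascii">{_fmt_ints(offsets)}</DataArray>',
        f'        <DataArray type="UInt8" Name="types" format="ascii">{_fmt_ints(vtk_types)}</DataArray>',
        "      </Cells>",
        "      <CellData>",
    ]
    for name, values in cell_data.items():
        parts.append(
            f'        <DataArray type="Int32" Name="{name}" format="ascii">{_fmt_ints(values)}</DataArray>'
        )
    parts += [
        "      </CellData>",
        "    </Piece>",
        "  </UnstructuredGrid>",
        "</VTKFile>",
        "",
    ]
    _atomic_write(path, "\n".join(parts))


def write_series_index(index: SeriesIndex, path: str | Path) -> None:
    """Write the PVD collection file for a frame series."""
    if len(index) == 0:
        raise OSError("refusing to write an empty series index")
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1" byte_order="LittleEndian">',
        "  <Collection>",
    ]
    for timestep, frame in index.entries:
        rel = os.path.basename(frame)
        parts.append(f'    <DataSet timestep="{timestep!r}" group="" part="0" file="{rel}"/>')
    parts += ["  </Collection>", "</VTKFile>", ""]
    _atomic_write(path, "\n".join(parts))


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        with open(tmp, "w") as fh:
            fh.write(text)
    except OSError:
        if tmp.exists():
            tmp.unlink()
        raise
    tmp.replace(path)
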
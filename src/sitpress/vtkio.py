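"""Minimal VTK legacy (ASCII) unstructured-grid reader/writer.

Supports the two volumetric cell types the tissue pipeline uses —
hexahedra (VTK type 12) and tetrahedra (type 10) — plus optional scalar
CELL_DATA fields.  Coordinates are millimetres by convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

VTK_TET = 10
VTK_HEX = 12
_NODES_PER = {VTK_TET: 4, VTK_HEX: 8}


def write_vtk(
    path: str | Path,
    nodes: np.ndarray,
    hexes: np.ndarray | None = None,
    tets: np.ndarray | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "sitpress mesh",
) -> None:
    nodes = np.asarray(nodes, dtype=float)
    hexes = np.zeros((0, 8), dtype=int) if hexes is None else np.asarray(hexes, dtype=int)
    tets = np.zeros((0, 4), dtype=int) if tets is None else np.asarray(tets, dtype=int)
    ncell = len(hexes) + len(tets)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    size = len(hexes) * 9 + len(tets) * 5
    lines.append(f"CELLS {ncell} {size}")
    lines += ["8 " + " ".join(map(str, h)) for h in hexes]
    lines += ["4 " + " ".join(map(str, t)) for t in tets]
    lines.append(f"CELL_TYPES {ncell}")
    lines += [str(VTK_HEX)] * len(hexes) + [str(VTK_TET)] * len(tets)
    if cell_data:
        lines.append(f"CELL_DATA {ncell}")
        for name, values in cell_data.items():
            values = np.asarray(values)
            if len(values) != ncell:
                raise ValueError(f"cell_data {name!r} length != number of cells")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vtk(path: str | Path):
    """Read an ASCII legacy unstructured grid.

    Returns (nodes, hexes, tets, cell_data); cell_data values follow the
    file's cell order (hexes then tets when written by :func:`write_vtk`).
    """
    tokens = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a VTK legacy file")
    # tokenize from line 3 onward (line 1 is the free-form title)
    body = lines[3:]
    i = 0

    def words():
        for ln in body:
            for w in ln.split():
                yield w

    it = words()
    tok = list(it)

    def expect(kw: str, at: int) -> int:
        if tok[at].upper() != kw:
            raise ValueError(f"{path}: expected {kw}, found {tok[at]!r}")
        return at + 1

    i = expect("DATASET", 0)
    if tok[i].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"{path}: only UNSTRUCTURED_GRID supported")
    i += 1
    i = expect("POINTS", i)
    npts = int(tok[i]); i += 2  # skip dtype
    nodes = np.array(tok[i : i + 3 * npts], dtype=float).reshape(npts, 3)
    i += 3 * npts
    i = expect("CELLS", i)
    ncell = int(tok[i]); size = int(tok[i + 1]); i += 2
    raw = np.array(tok[i : i + size], dtype=int)
    i += size
    i = expect("CELL_TYPES", i)
    if int(tok[i]) != ncell:
        raise ValueError(f"{path}: CELL_TYPES count mismatch")
    i += 1
    ctypes = np.array(tok[i : i + ncell], dtype=int)
    i += ncell
    cells = []
    pos = 0
    for k in range(ncell):
        n = raw[pos]
        cells.append(raw[pos + 1 : pos + 1 + n])
        pos += 1 + n
    hexes, tets = [], []
    for conn, ct in zip(cells, ctypes):
        if ct == VTK_HEX:
            hexes.append(conn)
        elif ct == VTK_TET:
            tets.append(conn)
        else:
            raise ValueError(f"{path}: unsupported cell type {ct}")
    cell_data: dict[str, np.ndarray] = {}
    while i < len(tok):
        if tok[i].upper() == "CELL_DATA":
            i += 2
        elif tok[i].upper() == "SCALARS":
            name = tok[i + 1]
            ncomp = int(tok[i + 3]) if tok[i + 3].isdigit() else 1
            i += 4 if tok[i + 3].isdigit() else 3
            if tok[i].upper() == "LOOKUP_TABLE":
                i += 2
            cell_data[name] = np.array(tok[i : i + ncell * ncomp], dtype=float)
            i += ncell * ncomp
        else:
            break
    return (
        nodes,
        np.array(hexes, dtype=int).reshape(-1, 8),
        np.array(tets, dtype=int).reshape(-1, 4),
        cell_data,
    )
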
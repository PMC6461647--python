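"""MRC map/image and STAR table I/O, backed by gemmi.

Volumes, micrographs and particle stacks are stored as MRC mode-2 (float32)
with the pixel size encoded in the unit cell.  Arrays are passed around as
numpy float arrays; micrographs are indexed ``[y, x]`` and volumes
``[z, y, x]`` with position ``(x, y)`` in 0-based pixels mapping to
``arr[y, x]``.  Tabular metadata (picks, particles, ground truth, FSC
curves) is written as single-block STAR files; floats are serialized with
``repr`` so a write/read round trip is bit-identical.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

__all__ = ["write_mrc", "read_mrc", "write_star_table", "read_star_table"]


def write_mrc(path: str | os.PathLike, data: np.ndarray, pixel_size: float) -> None:
    """Write a 2D image or 3D volume (or image stack) as an MRC map."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("expected a 2D image or 3D array")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    nz, ny, nx = data.shape
    m.grid.set_unit_cell(
        gemmi.UnitCell(nz * pixel_size, ny * pixel_size, nx * pixel_size, 90, 90, 90)
    )
    m.update_ccp4_header()
    m.write_ccp4_map(os.fspath(path))


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns (array, pixel_size).  2D maps are squeezed."""
    m = gemmi.read_ccp4_map(os.fspath(path))
    data = np.array(m.grid, copy=True)
    pixel = float(m.grid.unit_cell.a) / data.shape[0]
    if data.shape[0] == 1:
        data = data[0]
    return data.astype(np.float64), pixel


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    s = str(v)
    return s if s and " " not in s else f'"{s}"'


def write_star_table(
    path: str | os.PathLike,
    table: pd.DataFrame,
    block_name: str = "particles",
    prefix: str = "_xt",
) -> None:
    """Write a DataFrame as one STAR data block with a loop.

    Column ``foo`` becomes tag ``{prefix}Foo`` unless it already starts with
    an underscore, in which case it is used verbatim.
    """
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    tags = [
        c if c.startswith("_") else prefix + c[:1].upper() + c[1:]
        for c in table.columns
    ]
    loop = block.init_loop("", tags)
    for row in table.itertuples(index=False):
        loop.add_row([_fmt(v) for v in row])
    doc.write_file(os.fspath(path))


def read_star_table(path: str | os.PathLike, prefix: str = "_xt") -> pd.DataFrame:
    """Read the first loop of the first STAR block back into a DataFrame.

    Numeric columns are restored with full precision; tag prefixes added by
    :func:`write_star_table` are stripped.
    """
    doc = gemmi.cif.read_file(os.fspath(path))
    block = doc[0]
    cols: dict[str, list] = {}
    for item in block:
        loop = item.loop
        if loop is None:
            continue
        n, w = loop.length(), loop.width()
        flat = list(loop.values)
        for j, tag in enumerate(loop.tags):
            name = tag
            if tag.startswith(prefix) and len(tag) > len(prefix):
                stem = tag[len(prefix):]
                name = stem[:1].lower() + stem[1:]
            cols[name] = [gemmi.cif.as_string(flat[i * w + j]) for i in range(n)]
        break
    df = pd.DataFrame(cols)
    for c in df.columns:
        # builtin float() round-trips repr() exactly (pd.to_numeric does not)
        try:
            as_float = [float(v) for v in df[c]]
        except ValueError:
            continue
        if all(v == int(v) for v in as_float) and not any(
            "." in s or "e" in s.lower() for s in df[c]
        ):
            df[c] = [int(v) for v in as_float]
        else:
            df[c] = as_float
    return df
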
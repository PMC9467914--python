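"""MRC2014 volume/image input and output (gemmi backend).

Writes mode-2 (float32) maps with the voxel size carried in the header cell;
2D images are stored as single-section volumes.  Axis order is x-fast.
"""

from __future__ import annotations

import numpy as np
import gemmi

__all__ = ["read_mrc", "write_mrc", "MRCFormatError"]


class MRCFormatError(ValueError):
    """Raised for malformed or truncated MRC files."""


def write_mrc(data: np.ndarray, voxel_size_A: float | tuple, path: str) -> None:
    """Write a 2D image or 3D volume as an MRC2014 mode-2 map."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if np.isscalar(voxel_size_A):
        voxel = (float(voxel_size_A),) * 3
    else:
        voxel = tuple(float(v) for v in voxel_size_A)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(arr))
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    # grid axes follow the array shape; cell edge = n * voxel per axis
    m.grid.unit_cell = gemmi.UnitCell(arr.shape[0] * voxel[0],
                                      arr.shape[1] * voxel[1],
                                      arr.shape[2] * voxel[2], 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str) -> tuple[np.ndarray, float]:
    """Read an MRC2014 map; returns (float32 array, voxel size in Å).

    2D images written by :func:`write_mrc` come back with the leading
    singleton axis retained (squeeze at the call site if needed).
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MRCFormatError(f"cannot read MRC file {path!r}: {exc}") from exc
    arr = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    voxel = cell.c / arr.shape[2]  # xy voxel (last axes are isotropic here)
    return arr, float(voxel)
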
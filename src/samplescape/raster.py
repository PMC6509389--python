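"""Minimal raster grid container with ESRI ASCII grid text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band grid. ``values`` is (nrows, ncols); NaN marks nodata."""

    values: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.cellsize, self.xllcorner, self.yllcorner,
                      self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xllcorner}\n"
        f"yllcorner {raster.yllcorner}\n"
        f"cellsize {raster.cellsize}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path) -> Raster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in hdr or "nrows" not in hdr:
        raise ValueError(f"{path}: missing ncols/nrows header")
    vals = np.loadtxt(lines[i:], dtype=float)
    vals = np.atleast_2d(vals)
    if vals.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError(
            f"{path}: body shape {vals.shape} does not match header"
        )
    nodata = hdr.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(
        vals,
        cellsize=hdr.get("cellsize", 1.0),
        xllcorner=hdr.get("xllcorner", 0.0),
        yllcorner=hdr.get("yllcorner", 0.0),
        nodata=nodata,
    )
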
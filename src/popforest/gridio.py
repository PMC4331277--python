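"""Text-format raster I/O: ESRI ASCII grids on a GridTemplate.

ASCII grids (.asc) are the plain-text raster interchange format readable
by every desktop GIS; they carry the georeferencing this pipeline needs
(origin, square cell size, nodata) and keep fixtures human-inspectable.
"""

from __future__ import annotations

import numpy as np

from .grid import GridTemplate

_NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, template: GridTemplate) -> None:
    """Write a single-band raster as an ESRI ASCII grid (NaN → nodata)."""
    if template.pixel_width != template.pixel_height:
        raise ValueError("ASCII grids require square pixels")
    values = np.asarray(values, dtype=np.float64)
    if values.shape != template.shape:
        raise ValueError("raster does not match its template")
    minx, miny, _, _ = template.bounds
    out = np.where(np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {template.n_cols}\n"
        f"nrows {template.n_rows}\n"
        f"xllcorner {minx!r}\n"
        f"yllcorner {miny!r}\n"
        f"cellsize {template.pixel_width!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path, crs_id: str = "local-metric") -> tuple[np.ndarray, GridTemplate]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {values.shape} does not match header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    template = GridTemplate(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        pixel_width=cell,
        pixel_height=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id=crs_id,
    )
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, template
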
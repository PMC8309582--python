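"""Gridded prediction and kriging-variance maps.

Every cell center of a regular grid is predicted at each requested time
slice with the chosen method; kriging methods also fill a prediction
variance raster (IDW leaves it blank). Cells with an empty neighborhood are
marked missing (NaN), never zero. Maps export as long CSV and, optionally,
as one ESRI ASCII grid (plain text) per time slice and layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FixedStationSeries, GridSpec, ObservationSet
from .errors import EmptyInputError, InvalidInputError
from .predictors import IDWParams, NeighborhoodSpec, predict_points
from .variogram import VariogramModel

logger = logging.getLogger(__name__)

NODATA = -9999.0


@dataclass
class PredictionMap:
    """Per-time-slice prediction and variance rasters on a GridSpec.

    Arrays are (n_times, n_y, n_x), row j corresponding to the cell row at
    y = y_min + (j + 0.5) · cell_size (row 0 is the southern edge)."""

    grid: GridSpec
    prediction: np.ndarray
    variance: np.ndarray  # all-NaN for IDW

    def __post_init__(self) -> None:
        shape = (len(self.grid.times), self.grid.n_y, self.grid.n_x)
        if self.prediction.shape != shape or self.variance.shape != shape:
            raise InvalidInputError(f"raster shape must be {shape}")
        if np.any(self.variance[np.isfinite(self.variance)] < 0):
            raise InvalidInputError("variance raster must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        xs, ys = self.grid.cell_centers()
        tt, yy, xx = np.meshgrid(self.grid.times, ys, xs, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "t": tt.ravel(),
                "prediction": self.prediction.ravel(),
                "variance": self.variance.ravel(),
            }
        )


def predict_grid(
    obs: ObservationSet,
    station: FixedStationSeries | None,
    model: VariogramModel | None,
    method: str,
    grid: GridSpec,
    *,
    neighborhood: NeighborhoodSpec | None = None,
    idw_params: IDWParams | None = None,
) -> PredictionMap:
    """Predict every cell center at every grid time with one method."""
    if len(obs) == 0:
        raise EmptyInputError("no observations to predict from")
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)  # (n_y, n_x)
    n_cells = grid.n_x * grid.n_y
    pred = np.full((len(grid.times), grid.n_y, grid.n_x), np.nan)
    var = np.full_like(pred, np.nan)
    for k, t in enumerate(grid.times):
        targets = np.column_stack([xx.ravel(), yy.ravel(), np.full(n_cells, t)])
        out = predict_points(
            obs,
            station,
            model,
            method,
            targets,
            neighborhood=neighborhood,
            idw_params=idw_params,
        )
        pred[k] = out["prediction"].to_numpy().reshape(grid.n_y, grid.n_x)
        var[k] = out["variance"].to_numpy().reshape(grid.n_y, grid.n_x)
    n_missing = int(np.isnan(pred).sum())
    if n_missing:
        logger.warning("%d grid cells have no usable neighborhood", n_missing)
    return PredictionMap(grid=grid, prediction=pred, variance=var)


def export_map(
    pmap: PredictionMap,
    *,
    csv_path=None,
    asc_dir=None,
    prefix: str = "map",
) -> list[Path]:
    """Write the map as long CSV (x, y, t, prediction, variance) and/or one
    ESRI ASCII grid per time slice and layer. Missing cells are blank in CSV
    and NODATA in the grids. Values round-trip at 1e-6."""
    written: list[Path] = []
    if csv_path is not None:
        df = pmap.to_frame()
        df.to_csv(csv_path, index=False, float_format="%.9g")
        written.append(Path(csv_path))
    if asc_dir is not None:
        asc_dir = Path(asc_dir)
        asc_dir.mkdir(parents=True, exist_ok=True)
        for k, t in enumerate(pmap.grid.times):
            for layer, arr in (("pred", pmap.prediction), ("var", pmap.variance)):
                if layer == "var" and np.all(np.isnan(arr[k])):
                    continue
                path = asc_dir / f"{prefix}_{layer}_t{int(t)}.asc"
                _write_asc(arr[k], pmap.grid, path)
                written.append(path)
    return written


def _write_asc(raster2d: np.ndarray, grid: GridSpec, path) -> None:
    """ESRI ASCII grid; file rows run north to south, so the array (row 0 =
    south) is flipped on write. Cell (column 0, file bottom row) corresponds
    to the cell whose lower-left corner is (x_min, y_min)."""
    header = (
        f"ncols {grid.n_x}\n"
        f"nrows {grid.n_y}\n"
        f"xllcorner {grid.x_min:.6f}\n"
        f"yllcorner {grid.y_min:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = np.where(np.isfinite(raster2d), raster2d, NODATA)[::-1]
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.9g")


def read_asc(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid back to a south-up array + header dict."""
    header: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key] = float(val) if "." in val or key.startswith(("x", "y", "c", "N")) else int(val)
    body = np.loadtxt(lines[6:])
    body = np.atleast_2d(body)[::-1]
    nodata = float(header.get("NODATA_value", NODATA))
    return np.where(body == nodata, np.nan, body), header


def read_map_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
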
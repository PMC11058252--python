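"""Environment grid of the microhabitat array.

Rows of the array sit inside a diffusive nitrogen gradient between a
source channel (high [N]) and a sink channel (low [N]); at steady state
the profile across the gap is linear, so each row is assigned the
concentration at its centerline.  Columns sit under a near-linear light
field, so each column is assigned a PAR value on a linear ramp.  Raw
signals (fluorescent-dye intensity for the gradient, camera grayscale
for light) map to physical units through two-point linear calibrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentGrid",
    "LinearCalibration",
    "row_nitrogen_profile",
    "col_light_profile",
    "apply_calibration",
    "default_environment",
]

# Default geometry: 2308 µm source-to-sink gap with 8 row centerlines
# equally spaced from gap/4 to the sink boundary (~247 µm apart).  With
# the standard 35.3 -> 5.3 µM boundary conditions this yields row values
# 27.8 down to 5.3 µM and a slope of ~1.3 µM per 100 µm.
DEFAULT_CHANNEL_GAP_UM = 2308.0


def _default_centerlines(n_rows: int, channel_gap: float) -> np.ndarray:
    return np.linspace(channel_gap / 4.0, channel_gap, n_rows)


@dataclass(frozen=True)
class LinearCalibration:
    """The unique line through two anchor points (x0, y0), (x1, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x0 == self.x1:
            raise ValueError("calibration anchors must have distinct x values")

    @property
    def slope(self) -> float:
        return (self.y1 - self.y0) / (self.x1 - self.x0)

    def __call__(self, raw):
        return apply_calibration(raw, self)

    def inverse(self) -> "LinearCalibration":
        if self.y0 == self.y1:
            raise ValueError("constant calibration has no inverse")
        return LinearCalibration(self.y0, self.x0, self.y1, self.x1)

    def to_json(self) -> str:
        return json.dumps(
            {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearCalibration":
        d = json.loads(text)
        return cls(d["x0"], d["y0"], d["x1"], d["y1"])


def apply_calibration(raw, cal: LinearCalibration):
    """Evaluate the calibration line at ``raw`` (scalar or array)."""
    raw = np.asarray(raw, dtype=float)
    out = cal.y0 + cal.slope * (raw - cal.x0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EnvironmentGrid:
    """Per-row nitrogen (µM) and per-column PAR values of an R×C array.

    ``row_nitrogen`` runs from the source-side row to the sink-side row
    (non-increasing); ``col_par`` is monotone across columns.
    """

    row_nitrogen: np.ndarray
    col_par: np.ndarray

    def __post_init__(self) -> None:
        rn = np.asarray(self.row_nitrogen, dtype=float)
        cp = np.asarray(self.col_par, dtype=float)
        object.__setattr__(self, "row_nitrogen", rn)
        object.__setattr__(self, "col_par", cp)
        if np.any(rn < 0) or np.any(cp < 0):
            raise ValueError("environment values must be >= 0")
        if rn.size < 1 or cp.size < 1:
            raise ValueError("grid must have at least one row and column")
        if np.any(np.diff(rn) > 1e-12):
            raise ValueError("row_nitrogen must be non-increasing source->sink")
        d = np.diff(cp)
        if not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
            raise ValueError("col_par must be monotone across columns")

    @property
    def n_rows(self) -> int:
        return self.row_nitrogen.size

    @property
    def n_cols(self) -> int:
        return self.col_par.size

    def nitrogen_at(self, row: int) -> float:
        return float(self.row_nitrogen[row])

    def par_at(self, col: int) -> float:
        return float(self.col_par[col])

    def to_csv(self, path) -> None:
        rows = [
            {"axis": "row", "index": i, "value": v, "units": "uM"}
            for i, v in enumerate(self.row_nitrogen)
        ] + [
            {"axis": "col", "index": j, "value": v, "units": "umol_m2_s"}
            for j, v in enumerate(self.col_par)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvironmentGrid":
        df = pd.read_csv(Path(path))
        required = {"axis", "index", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"environment CSV missing columns {required - set(df.columns)}")
        rn = df[df.axis == "row"].sort_values("index")["value"].to_numpy()
        cp = df[df.axis == "col"].sort_values("index")["value"].to_numpy()
        return cls(row_nitrogen=rn, col_par=cp)


def row_nitrogen_profile(
    c_source: float,
    c_sink: float,
    n_rows: int = 8,
    channel_gap: float = DEFAULT_CHANNEL_GAP_UM,
    row_centerlines: np.ndarray | None = None,
) -> np.ndarray:
    """Nitrogen concentration at each row centerline.

    Linear interpolation across the gap: position 0 is the source
    channel wall (``c_source``), position ``channel_gap`` the sink wall
    (``c_sink``).  In the default geometry the sink-adjacent row sits at
    the sink boundary, so with boundaries 35.3/5.3 µM the rows span
    27.8 down to 5.3 µM.
    """
    if not (c_source >= c_sink >= 0):
        raise ValueError("need c_source >= c_sink >= 0")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if channel_gap <= 0:
        raise ValueError("channel_gap must be > 0")
    if row_centerlines is None:
        x = _default_centerlines(n_rows, channel_gap)
    else:
        x = np.asarray(row_centerlines, dtype=float)
        if x.size != n_rows:
            raise ValueError("row_centerlines length must equal n_rows")
        if np.any(x <= 0) or np.any(x > channel_gap):
            raise ValueError("row centerlines must lie inside (0, channel_gap]")
    return c_source + (c_sink - c_source) * x / channel_gap


def col_light_profile(par_min: float, par_max: float, n_cols: int = 8) -> np.ndarray:
    """``n_cols`` equally spaced PAR values from ``par_min`` to ``par_max``."""
    if par_min < 0 or par_max < 0:
        raise ValueError("PAR values must be >= 0")
    if par_max < par_min:
        raise ValueError("need par_max >= par_min")
    if n_cols < 1:
        raise ValueError("n_cols must be >= 1")
    if n_cols == 1:
        return np.array([(par_min + par_max) / 2.0])
    return np.linspace(par_min, par_max, n_cols)


def default_environment(
    c_source: float = 35.3,
    c_sink: float = 5.3,
    par_min: float = 0.1,
    par_max: float = 45.0,
    n_rows: int = 8,
    n_cols: int = 8,
) -> EnvironmentGrid:
    """The standard 8×8 dual-gradient array (N: 27.8->5.3 µM, PAR 0.1->45)."""
    return EnvironmentGrid(
        row_nitrogen=row_nitrogen_profile(c_source, c_sink, n_rows),
        col_par=col_light_profile(par_min, par_max, n_cols),
    )
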
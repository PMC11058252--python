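"""Maximum specific growth rates from fluorescence time series.

Background-subtracted intensity is taken as proportional to cell
number, so growth is ln((I_t − bg)/(I_0 − bg)).  The maximum specific
growth rate of a habitat is the largest ordinary-least-squares slope
over any window of n consecutive points of that log-ratio curve whose
center time falls at or after a threshold (default 1.3 days, skipping
the early acclimation phase); n = 9 suppresses read-out noise without
flattening the estimate.  The standard error attached to each maximum
is the spread of the k = 4 window slopes around the maximizer, used
downstream as bootstrap resampling weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .environment import EnvironmentGrid
from .synthetic_data import ArrayTimeSeries

__all__ = [
    "GrowthCurve",
    "GrowthRateRecord",
    "GrowthRateMatrix",
    "HabitatExcluded",
    "ExtractionError",
    "to_growth_curve",
    "window_slopes",
    "sliding_window_rate",
    "se_around_max",
    "build_matrix",
]

MATRIX_COLUMNS = [
    "replicate_id",
    "row",
    "col",
    "nitrogen_uM",
    "par",
    "mu_per_day",
    "se_per_day",
    "window_center_h",
]

# exclusion reason codes
EMPTY = "EMPTY"
NONPOSITIVE_I0 = "NONPOSITIVE_I0"
TOO_SHORT = "TOO_SHORT"
NO_WINDOW = "NO_WINDOW"


class HabitatExcluded(Exception):
    """Habitat cannot yield a growth curve; carries a reason code."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


class ExtractionError(Exception):
    """Rate extraction failed on an otherwise valid curve."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class GrowthCurve:
    """ln(N/N0) vs time for one habitat; masked points are NaN."""

    replicate_id: str
    row: int
    col: int
    times: np.ndarray  # hours
    log_ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.log_ratio, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "log_ratio", y)
        if t.size != y.size:
            raise ValueError("times and log_ratio must have equal length")
        if t.size and y[0] != 0.0:
            raise ValueError("log_ratio must start at 0 by construction")


@dataclass(frozen=True)
class GrowthRateRecord:
    replicate_id: str
    row: int
    col: int
    mu: float  # day^-1
    se: float  # day^-1
    window_center_time_h: float
    n_window: int
    window_index: int = -1  # index of the maximizing window, internal

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass
class GrowthRateMatrix:
    """Per-habitat growth-rate records joined to the environment grid."""

    records: dict
    env: EnvironmentGrid
    exclusions: list = field(default_factory=list)  # (replicate_id,row,col,reason)

    def __len__(self) -> int:
        return len(self.records)

    def observations(self):
        """Arrays (L, N, mu, se) over all records, in sorted key order."""
        keys = sorted(self.records)
        L = np.array([self.env.par_at(k[2]) for k in keys])
        N = np.array([self.env.nitrogen_at(k[1]) for k in keys])
        mu = np.array([self.records[k].mu for k in keys])
        se = np.array([self.records[k].se for k in keys])
        return L, N, mu, se

    def to_csv(self, path) -> None:
        rows = []
        for (rep, r, c) in sorted(self.records):
            rec = self.records[(rep, r, c)]
            rows.append(
                {
                    "replicate_id": rep,
                    "row": r,
                    "col": c,
                    "nitrogen_uM": self.env.nitrogen_at(r),
                    "par": self.env.par_at(c),
                    "mu_per_day": rec.mu,
                    "se_per_day": rec.se,
                    "window_center_h": rec.window_center_time_h,
                }
            )
        pd.DataFrame(rows, columns=MATRIX_COLUMNS).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path, env: EnvironmentGrid) -> "GrowthRateMatrix":
        df = pd.read_csv(Path(path), float_precision="round_trip")
        missing = set(MATRIX_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"matrix CSV missing columns: {sorted(missing)}")
        records = {}
        for _, r in df.iterrows():
            row, col = int(r.row), int(r.col)
            if row >= env.n_rows or col >= env.n_cols:
                raise ValueError(f"habitat ({row},{col}) outside environment grid")
            key = (str(r.replicate_id), row, col)
            records[key] = GrowthRateRecord(
                replicate_id=key[0],
                row=row,
                col=col,
                mu=float(r.mu_per_day),
                se=float(r.se_per_day),
                window_center_time_h=float(r.window_center_h),
                n_window=0,
            )
        return cls(records=records, env=env)

    def write_exclusion_log(self, path) -> None:
        lines = [f"{rep}\t{r}\t{c}\t{reason}" for rep, r, c, reason in self.exclusions]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_growth_curve(series: ArrayTimeSeries, background: float) -> GrowthCurve:
    """Background-subtract and log-transform one habitat's intensities.

    Raises :class:`HabitatExcluded` for empty habitats and habitats
    whose initial signal does not rise above background.  Later
    non-positive background-subtracted values are masked (NaN), never
    silently dropped.
    """
    if series.times.size == 0:
        raise ValueError("empty time series")
    if series.n0_cells == 0:
        raise HabitatExcluded(EMPTY, f"habitat ({series.row},{series.col}) seeded empty")
    net = series.intensity - background
    if net[0] <= 0:
        raise HabitatExcluded(
            NONPOSITIVE_I0,
            f"initial intensity at or below background for ({series.row},{series.col})",
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        log_ratio = np.where(net > 0, np.log(np.where(net > 0, net, 1.0) / net[0]), np.nan)
    n_masked = int(np.sum(~np.isfinite(log_ratio)))
    if n_masked:
        warnings.warn(
            f"{n_masked} non-positive background-subtracted point(s) masked for "
            f"habitat ({series.row},{series.col})",
            stacklevel=2,
        )
    log_ratio[0] = 0.0
    return GrowthCurve(
        replicate_id=series.replicate_id,
        row=series.row,
        col=series.col,
        times=series.times,
        log_ratio=log_ratio,
    )


def window_slopes(curve: GrowthCurve, n: int = 9):
    """OLS slope (day⁻¹) and center time (h) of every length-n window.

    Windows containing masked points get a NaN slope.
    """
    t = curve.times
    y = curve.log_ratio
    if n < 2:
        raise ValueError("window length n must be >= 2")
    if t.size < n:
        raise ExtractionError(
            TOO_SHORT, f"curve has {t.size} points, fewer than window n={n}"
        )
    n_win = t.size - n + 1
    slopes = np.empty(n_win)
    centers = np.empty(n_win)
    for i in range(n_win):
        tw = t[i : i + n]
        yw = y[i : i + n]
        centers[i] = tw.mean()
        if not np.all(np.isfinite(yw)):
            slopes[i] = np.nan
            continue
        tc = tw - tw.mean()
        slopes[i] = float(tc @ (yw - yw.mean()) / (tc @ tc)) * 24.0  # per day
    return slopes, centers


def sliding_window_rate(
    curve: GrowthCurve, n: int = 9, min_time_days: float = 1.3
) -> GrowthRateRecord:
    """Maximum window slope at or after the time threshold.

    Only windows whose *center* time is >= ``min_time_days`` compete;
    ties go to the earliest window.
    """
    slopes, centers = window_slopes(curve, n)
    eligible = (centers >= min_time_days * 24.0) & np.isfinite(slopes)
    if not np.any(eligible):
        raise ExtractionError(
            NO_WINDOW,
            f"no window with center time >= {min_time_days} d for "
            f"habitat ({curve.row},{curve.col})",
        )
    masked = np.where(eligible, slopes, -np.inf)
    best = int(np.argmax(masked))  # argmax returns the first maximum
    return GrowthRateRecord(
        replicate_id=curve.replicate_id,
        row=curve.row,
        col=curve.col,
        mu=float(slopes[best]),
        se=0.0,
        window_center_time_h=float(centers[best]),
        n_window=n,
        window_index=best,
    )


def se_around_max(curve: GrowthCurve, record: GrowthRateRecord, k: int = 4) -> float:
    """Standard error from the k window slopes around the maximizer.

    Takes positions max−1 … max+k−2 (the maximizer plus its nearest
    neighbours), clamped at the ends of the window sequence, and
    returns sd/√k.  If fewer than k windows exist, all are used with a
    warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    slopes, _ = window_slopes(curve, record.n_window)
    n_win = slopes.size
    if n_win < k:
        warnings.warn(
            f"only {n_win} windows available for se (k={k}); using all", stacklevel=2
        )
        chosen = slopes
    else:
        lo = max(0, min(record.window_index - 1, n_win - k))
        chosen = slopes[lo : lo + k]
    chosen = chosen[np.isfinite(chosen)]
    if chosen.size < 2:
        return 0.0
    return float(np.std(chosen, ddof=1) / np.sqrt(chosen.size))


def build_matrix(
    series: Iterable[ArrayTimeSeries],
    env: EnvironmentGrid,
    background: float | Mapping[str, float] | None = None,
    n: int = 9,
    min_time_days: float = 1.3,
    k: int = 4,
) -> GrowthRateMatrix:
    """Full extraction over all habitats of one or more replicates.

    ``background`` is a scalar, a per-replicate mapping, or None to
    estimate it per replicate as the minimum intensity observed across
    habitats (a habitat-free floor).  Excluded habitats are logged with
    reason codes rather than raising.
    """
    series = list(series)
    if background is None:
        background = {}
        for s in series:
            m = float(s.intensity.min())
            background[s.replicate_id] = min(background.get(s.replicate_id, np.inf), m)

    def bg_for(rep: str) -> float:
        if isinstance(background, Mapping):
            return float(background[rep])
        return float(background)

    records: dict = {}
    exclusions: list = []
    for s in series:
        if s.row >= env.n_rows or s.col >= env.n_cols:
            raise ValueError(
                f"habitat ({s.row},{s.col}) outside the {env.n_rows}x{env.n_cols} grid"
            )
        key = (s.replicate_id, s.row, s.col)
        if key in records:
            raise ValueError(f"duplicate habitat {key}")
        try:
            curve = to_growth_curve(s, bg_for(s.replicate_id))
            rec = sliding_window_rate(curve, n=n, min_time_days=min_time_days)
            se = se_around_max(curve, rec, k=k)
        except HabitatExcluded as e:
            exclusions.append((*key, e.reason))
            continue
        except ExtractionError as e:
            exclusions.append((*key, e.reason))
            continue
        records[key] = GrowthRateRecord(
            replicate_id=rec.replicate_id,
            row=rec.row,
            col=rec.col,
            mu=rec.mu,
            se=se,
            window_center_time_h=rec.window_center_time_h,
            n_window=rec.n_window,
            window_index=rec.window_index,
        )
    return GrowthRateMatrix(records=records, env=env, exclusions=exclusions)
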
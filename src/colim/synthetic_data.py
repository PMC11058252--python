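"""Synthetic microhabitat-array growth experiments.

Emulates the replicated dual-gradient experiment: an R×C array of
nanoliter habitats, each seeded with a small random number of cells
(habitats may stay empty), growing exponentially at the rate the
colimitation model assigns to that habitat's (PAR, [N]) combination.
The perfused device holds the environment static, so cell number has a
closed form per habitat — exact exponential, or logistic if a carrying
capacity is set — and no ODE integration is needed.  Fluorescence
read-out is gain·cells·m + background, where m is a lognormal
multiplier with mean 1 and a configurable coefficient of variation and
the background has additive Gaussian jitter.

Defaults mirror the study design: 8×8 array, 3 replicates, samples
every 4 h over 7 days, 1–6 cells seeded per habitat.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import EnvironmentGrid, default_environment
from .model import ModelSpec, MonodParams

__all__ = [
    "ArrayTimeSeries",
    "SeedingConfig",
    "NoiseConfig",
    "SimulationConfig",
    "simulate_array",
    "seed_counts",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "simulate_rate_matrices",
]

TS_COLUMNS = ["replicate_id", "row", "col", "time_h", "intensity", "n0_cells"]


@dataclass(frozen=True)
class ArrayTimeSeries:
    """Fluorescence intensity vs time for one habitat of one replicate."""

    replicate_id: str
    row: int
    col: int
    times: np.ndarray  # hours, regular grid
    intensity: np.ndarray
    n0_cells: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)
        if t.size != y.size:
            raise ValueError("times and intensity must have equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must be on a constant step")
        if np.any(y < 0):
            raise ValueError("intensity must be >= 0")
        if self.n0_cells < 0:
            raise ValueError("n0_cells must be >= 0")

    @property
    def is_empty(self) -> bool:
        return self.n0_cells == 0


@dataclass(frozen=True)
class SeedingConfig:
    min_cells: int = 1
    max_cells: int = 6
    p_empty: float = 0.05

    def __post_init__(self) -> None:
        if not (1 <= self.min_cells <= self.max_cells):
            raise ValueError("need 1 <= min_cells <= max_cells")
        if not (0 <= self.p_empty < 1):
            raise ValueError("need 0 <= p_empty < 1")


@dataclass(frozen=True)
class NoiseConfig:
    intensity_cv: float = 0.05
    background_level: float = 100.0
    background_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.background_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    env: EnvironmentGrid = field(default_factory=default_environment)
    params: MonodParams = field(
        default_factory=lambda: MonodParams(
            mu_max=2.4, L0=50.8, K_L=57.2, N0=0.0, K_N=2.8
        )
    )
    model_form: str = "multiplicative_storage"
    duration_days: float = 7.0
    sample_interval_h: float = 4.0
    n_replicates: int = 3
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    carrying_capacity: float | None = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gain: float = 50.0  # intensity units per cell
    lag_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.sample_interval_h <= 0:
            raise ValueError("duration and sample interval must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.carrying_capacity is not None and self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be > 0 when set")
        if self.model_form not in ("multiplicative_storage", "liebig_min"):
            raise ValueError(f"unsupported simulation model form {self.model_form!r}")

    @property
    def times_h(self) -> np.ndarray:
        n = int(round(self.duration_days * 24.0 / self.sample_interval_h))
        return np.arange(n + 1) * self.sample_interval_h


def seed_counts(rng: np.random.Generator, seeding: SeedingConfig) -> int:
    """One initial cell count: 0 w.p. p_empty, else uniform on {min..max}."""
    if rng.random() < seeding.p_empty:
        return 0
    return int(rng.integers(seeding.min_cells, seeding.max_cells + 1))


def _cells_trajectory(
    n0: float, mu_per_day: float, times_h: np.ndarray, K: float | None, lag_h: float
) -> np.ndarray:
    t_days = np.clip(times_h - lag_h, 0.0, None) / 24.0
    if K is None:
        return n0 * np.exp(mu_per_day * t_days)
    # logistic closed form, capped at K
    return K / (1.0 + (K / n0 - 1.0) * np.exp(-mu_per_day * t_days))


def _growth_rate(cfg: SimulationConfig, L: float, N: float) -> float:
    spec = ModelSpec(
        form=cfg.model_form,
        free_params=frozenset(),
        fixed_params={
            "mu_max": cfg.params.mu_max,
            "L0": cfg.params.L0,
            "K_L": cfg.params.K_L,
            "N0": cfg.params.N0,
            "K_N": cfg.params.K_N,
        },
    )
    return float(spec.evaluate(L, N, cfg.params))


def simulate_array(cfg: SimulationConfig) -> list[ArrayTimeSeries]:
    """Simulate every habitat of every replicate. Deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    times = cfg.times_h
    out: list[ArrayTimeSeries] = []
    for rep in range(cfg.n_replicates):
        rep_id = f"R{rep + 1}"
        for row in range(cfg.env.n_rows):
            N = cfg.env.nitrogen_at(row)
            for col in range(cfg.env.n_cols):
                L = cfg.env.par_at(col)
                n0 = seed_counts(rng, cfg.seeding)
                if n0 == 0:
                    cells = np.zeros_like(times)
                else:
                    mu = _growth_rate(cfg, L, N)
                    cells = _cells_trajectory(
                        float(n0), mu, times, cfg.carrying_capacity, cfg.lag_h
                    )
                signal = cfg.gain * cells
                if cfg.noise.intensity_cv > 0:
                    cv2 = cfg.noise.intensity_cv**2
                    sigma = np.sqrt(np.log1p(cv2))
                    mult = rng.lognormal(-0.5 * np.log1p(cv2), sigma, size=times.size)
                    signal = signal * mult
                background = cfg.noise.background_level
                if cfg.noise.background_sd > 0:
                    background = background + rng.normal(
                        0.0, cfg.noise.background_sd, size=times.size
                    )
                intensity = np.clip(signal + background, 0.0, None)
                out.append(
                    ArrayTimeSeries(
                        replicate_id=rep_id,
                        row=row,
                        col=col,
                        times=times.copy(),
                        intensity=intensity,
                        n0_cells=n0,
                    )
                )
    return out


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of cfg with all stochastic read-out noise and empties disabled."""
    return replace(
        cfg,
        noise=NoiseConfig(intensity_cv=0.0, background_level=cfg.noise.background_level, background_sd=0.0),
        seeding=replace(cfg.seeding, p_empty=0.0),
    )


def write_timeseries_csv(series: Sequence[ArrayTimeSeries], path, seed: int | None = None) -> None:
    """Write long-format time series (one row per habitat per time point).

    A leading ``#``-comment records the RNG seed for provenance.
    """
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "replicate_id": s.replicate_id,
                    "row": s.row,
                    "col": s.col,
                    "time_h": s.times,
                    "intensity": s.intensity,
                    "n0_cells": s.n0_cells,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[TS_COLUMNS]
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_timeseries_csv(path) -> list[ArrayTimeSeries]:
    """Parse a time-series CSV back into per-habitat series.

    Keying is order-insensitive: rows are grouped by (replicate, row,
    col) and sorted by time.  Schema violations and ragged time grids
    raise with the offending location.
    """
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    missing = set(TS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-series CSV missing columns: {sorted(missing)}")
    out = []
    for (rep, row, col), g in df.groupby(["replicate_id", "row", "col"], sort=True):
        g = g.sort_values("time_h")
        n0 = g["n0_cells"].unique()
        if n0.size != 1:
            raise ValueError(
                f"inconsistent n0_cells for habitat ({rep},{row},{col}) "
                f"starting at file row {int(g.index[0]) + 2}"
            )
        t = g["time_h"].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            bad = np.nonzero(~np.isclose(dt, dt[0], rtol=1e-9, atol=1e-9))[0]
            if np.any(dt <= 0) or bad.size:
                i = int(g.index[np.argmax(dt <= 0) + 1 if np.any(dt <= 0) else bad[0] + 1])
                raise ValueError(
                    f"non-uniform time grid for habitat ({rep},{row},{col}) at file row {i + 2}"
                )
        out.append(
            ArrayTimeSeries(
                replicate_id=str(rep),
                row=int(row),
                col=int(col),
                times=t,
                intensity=g["intensity"].to_numpy(dtype=float),
                n0_cells=int(n0[0]),
            )
        )
    return out


def simulate_rate_matrices(
    env: EnvironmentGrid,
    params: MonodParams,
    noise_sd: float,
    n_replicates: int = 3,
    seed: int = 0,
    form: str = "multiplicative_storage",
    se_floor: float = 0.02,
):
    """Directly simulate per-habitat growth-rate matrices (no time series).

    Each replicate observes µ(L, N) + Gaussian noise of sd ``noise_sd``
    (day⁻¹), with a reported standard error drawn near ``noise_sd``
    (floored at ``se_floor``).  A fast stand-in for the full pipeline
    when only the fitting stage is under study.
    """
    from .growth_extraction import GrowthRateMatrix, GrowthRateRecord

    rng = np.random.default_rng(seed)
    spec = ModelSpec(
        form=form,
        free_params=frozenset(),
        fixed_params={
            "mu_max": params.mu_max,
            "L0": params.L0,
            "K_L": params.K_L,
            "N0": params.N0,
            "K_N": params.K_N,
        },
    )
    matrices = []
    for rep in range(n_replicates):
        records = {}
        for row in range(env.n_rows):
            for col in range(env.n_cols):
                mu_true = float(spec.evaluate(env.par_at(col), env.nitrogen_at(row), params))
                mu_obs = mu_true + rng.normal(0.0, noise_sd)
                se = max(se_floor, abs(rng.normal(noise_sd, 0.25 * noise_sd))) if noise_sd > 0 else 0.0
                key = (f"R{rep + 1}", row, col)
                records[key] = GrowthRateRecord(
                    replicate_id=key[0],
                    row=row,
                    col=col,
                    mu=mu_obs,
                    se=se,
                    window_center_time_h=84.0,
                    n_window=9,
                )
        matrices.append(GrowthRateMatrix(records=records, env=env))
    return matrices
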
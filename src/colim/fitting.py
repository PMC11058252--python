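"""Weighted-bootstrap nonlinear least-squares fitting of colimitation models.

Point fits minimise Σ(µ_obs − µ_model(L, N))² over the free parameters
with non-negativity bounds, via trust-region reflective least squares
with a small multi-start over jittered initial values to guard against
local minima.  Uncertainty follows the replicate-resampling bootstrap:
in each of B runs, every (row, col) condition draws one replicate's
observed rate with probability proportional to 1/se² (the reciprocal
squared standard error around that replicate's maximum growth rate),
the resampled matrix is refitted, and the reported estimate of each
parameter is the mean of its B fitted values.

Model comparison refits rival model forms on a shared bootstrap stream
and reports mean SSE, R² and small-sample AIC (AICc) for each.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .growth_extraction import GrowthRateMatrix
from .model import ModelSpec, MonodParams, default_fit_spec

__all__ = [
    "FitResult",
    "BootstrapResult",
    "nls_fit",
    "bootstrap_fit",
    "param_significance",
    "compare_models",
    "predict_map",
    "predicted_vs_observed",
    "resample_conditions",
]


@dataclass(frozen=True)
class FitResult:
    params: MonodParams
    free_values: dict
    sse: float
    r2: float
    n_obs: int
    converged: bool
    spec: ModelSpec

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    @property
    def aicc(self) -> float:
        """Small-sample AIC under a Gaussian error model."""
        n, k = self.n_obs, self.spec.n_free
        if n - k - 1 <= 0:
            return np.inf
        sse = max(self.sse, 1e-300)
        return n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class BootstrapResult:
    samples: dict          # param -> np.ndarray of length B
    means: dict            # param -> float (the reported estimate)
    sds: dict
    correlations: pd.DataFrame
    B: int
    seed: int
    spec: ModelSpec
    point_fit: FitResult

    def to_report_json(self) -> str:
        return json.dumps(
            {
                "model_form": self.spec.form,
                "fixed": dict(self.spec.fixed_params),
                "free": sorted(self.spec.free_params),
                "estimates": self.means,
                "sds": self.sds,
                "correlations": self.correlations.to_dict(),
                "B": self.B,
                "seed": self.seed,
                "point_fit": {
                    "free_values": self.point_fit.free_values,
                    "sse": self.point_fit.sse,
                    "r2": self.point_fit.r2,
                    "n_obs": self.point_fit.n_obs,
                },
            },
            indent=2,
            sort_keys=True,
        )

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples)

    def estimated_params(self) -> MonodParams:
        return self.spec.build_params(self.means)


# ---------------------------------------------------------------- point fit


def _default_init(spec: ModelSpec, L: np.ndarray, N: np.ndarray, mu: np.ndarray) -> dict:
    init = {}
    mu_top = float(np.max(mu)) if np.max(mu) > 0 else 1.0
    for p in spec.free_params:
        if p in ("mu_max", "mu_0"):
            init[p] = mu_top
        elif p == "K_L":
            init[p] = float(np.median(L))
        elif p == "K_N":
            init[p] = float(np.median(N))
        elif p == "L0":
            init[p] = 0.1 * float(np.max(L))
        elif p == "N0":
            init[p] = 0.1 * float(np.max(N))
    return init


_LOWER = {"K_L": 1e-6, "K_N": 1e-6}  # keep denominators positive


def nls_fit(
    matrix: GrowthRateMatrix,
    spec: ModelSpec | None = None,
    init: dict | None = None,
    bounds: dict | None = None,
    n_starts: int = 5,
    multistart_seed: int = 12345,
) -> FitResult:
    """Unweighted nonlinear least squares on one growth-rate matrix.

    Free/fixed split per ``spec`` (default protocol: µmax fixed at 2.4
    day⁻¹, N0 fixed at 0, L0 free).  All free parameters are bounded
    below at 0 (half-saturations at 1e-6).  Deterministic given data,
    spec and init; ``n_starts`` jittered restarts are derived from a
    fixed seed, and the best-SSE solution is returned.
    """
    if spec is None:
        spec = default_fit_spec()
    if len(matrix) == 0:
        raise ValueError("empty growth-rate matrix")
    L, N, mu, _ = matrix.observations()
    if len(matrix) < spec.n_free:
        raise ValueError(
            f"{len(matrix)} observation(s) cannot identify {spec.n_free} free parameters"
        )
    if np.ptp(L) == 0 and np.ptp(N) == 0 and spec.n_free > 1:
        raise ValueError("single-condition matrix: model is not identifiable")
    if np.ptp(mu) == 0 and spec.n_free > 1:
        raise ValueError("all observed rates identical: degenerate fitting surface")

    names = sorted(spec.free_params)
    x0_map = _default_init(spec, L, N, mu)
    if init:
        x0_map.update({k: v for k, v in init.items() if k in spec.free_params})
    lo = np.array([_LOWER.get(p, 0.0) for p in names])
    hi = np.full(len(names), np.inf)
    if bounds:
        for i, p in enumerate(names):
            if p in bounds:
                lo[i], hi[i] = bounds[p]

    def residuals(x):
        p = spec.build_params(dict(zip(names, x)))
        return spec.evaluate(L, N, p) - mu

    x0 = np.clip(np.array([x0_map[p] for p in names]), lo + 1e-12, None)
    starts = [x0]
    rng = np.random.default_rng(multistart_seed)
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform(0.3, 3.0, size=len(names))
        starts.append(np.clip(x0 * jitter, lo + 1e-12, None))

    best = None
    converged = False
    for s in starts:
        try:
            sol = least_squares(residuals, s, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
            converged = converged or bool(sol.success)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    sse, sol = best
    converged = bool(sol.success)
    if not converged:
        warnings.warn("nonlinear least squares did not report convergence", stacklevel=2)
    free_values = dict(zip(names, (float(v) for v in sol.x)))
    params = spec.build_params(free_values)
    sst = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return FitResult(
        params=params,
        free_values=free_values,
        sse=sse,
        r2=r2,
        n_obs=len(matrix),
        converged=converged,
        spec=spec,
    )


# ---------------------------------------------------------------- bootstrap


def _condition_weights(ses: np.ndarray) -> np.ndarray:
    """Per-condition replicate-selection probabilities ∝ 1/se².

    Zero-se entries (noise-free data) take the largest finite weight at
    that condition, or uniform weight when every se is zero, keeping
    the ordering of informative replicates without infinities.
    """
    w = np.empty_like(ses, dtype=float)
    pos = ses > 0
    if np.any(pos):
        w[pos] = 1.0 / ses[pos] ** 2
        w[~pos] = w[pos].max()
    else:
        w[:] = 1.0
    return w / w.sum()


def resample_conditions(
    matrices: list[GrowthRateMatrix], rng: np.random.Generator
) -> tuple[GrowthRateMatrix, np.ndarray]:
    """Draw one replicate per condition, weight ∝ 1/se² per condition.

    Returns the resampled matrix (replicate ids collapsed to "BS") and
    the index of the chosen replicate for each condition (sorted
    condition order) for diagnostics.
    """
    env = matrices[0].env
    conditions: dict = {}
    for i, m in enumerate(matrices):
        if m.env.n_rows != env.n_rows or m.env.n_cols != env.n_cols:
            raise ValueError("replicates must share the environment grid")
        for (rep, r, c), rec in m.records.items():
            conditions.setdefault((r, c), []).append((i, rec))
    records = {}
    chosen_idx = []
    for (r, c) in sorted(conditions):
        entries = conditions[(r, c)]
        ses = np.array([rec.se for _, rec in entries])
        probs = _condition_weights(ses)
        pick = int(rng.choice(len(entries), p=probs))
        chosen_idx.append(entries[pick][0])
        rec = entries[pick][1]
        records[("BS", r, c)] = rec
    return GrowthRateMatrix(records=records, env=env), np.array(chosen_idx)


def bootstrap_fit(
    replicate_matrices: list[GrowthRateMatrix],
    spec: ModelSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 5,
) -> BootstrapResult:
    """Replicate-resampling bootstrap of the nonlinear least-squares fit.

    Conditions present in no replicate are simply absent; a condition
    missing from some replicates samples only among those that have it.
    The reported parameter estimates are the means over the B fits.
    """
    if spec is None:
        spec = default_fit_spec()
    if not replicate_matrices:
        raise ValueError("need at least one replicate matrix")
    n_cond_full = replicate_matrices[0].env.n_rows * replicate_matrices[0].env.n_cols
    seen = {(r, c) for m in replicate_matrices for (_, r, c) in m.records}
    if len(seen) < n_cond_full:
        warnings.warn(
            f"{n_cond_full - len(seen)} condition(s) have no record in any replicate "
            "and are dropped",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    names = sorted(spec.free_params)
    samples = {p: np.empty(B) for p in names}
    for b in range(B):
        m, _ = resample_conditions(replicate_matrices, rng)
        fit = nls_fit(m, spec, n_starts=n_starts)
        for p in names:
            samples[p][b] = fit.free_values[p]
    means = {p: float(samples[p].mean()) for p in names}
    sds = {p: float(samples[p].std(ddof=1)) if B > 1 else 0.0 for p in names}
    df = pd.DataFrame(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance columns -> NaN corr
        corr = df.corr()
    for p in names:
        corr.loc[p, p] = 1.0
    # point fit on the full pooled data for reference
    pooled = {}
    for m in replicate_matrices:
        pooled.update(m.records)
    point = nls_fit(
        GrowthRateMatrix(records=pooled, env=replicate_matrices[0].env),
        spec,
        n_starts=n_starts,
    )
    return BootstrapResult(
        samples=samples,
        means=means,
        sds=sds,
        correlations=corr,
        B=B,
        seed=seed,
        spec=spec,
        point_fit=point,
    )


def param_significance(
    result: BootstrapResult, param: str, null_value: float = 0.0
) -> dict:
    """Two-sided significance of a bootstrap parameter against a null value.

    Returns both a normal-approximation (Wald) p-value,
    2(1 − Φ(|mean − null|/sd)), and the bootstrap tail fraction
    2·min(frac ≤ null, frac ≥ null).
    """
    if param not in result.samples:
        raise KeyError(f"{param!r} is not a free parameter of this fit")
    s = result.samples[param]
    mean, sd = result.means[param], result.sds[param]
    if sd == 0:
        warnings.warn("zero bootstrap sd: p-value is degenerate", stacklevel=2)
        p_wald = 1.0 if mean == null_value else 0.0
    else:
        z = abs(mean - null_value) / sd
        p_wald = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    frac_le = float(np.mean(s <= null_value))
    frac_ge = float(np.mean(s >= null_value))
    p_tail = min(1.0, 2.0 * min(frac_le, frac_ge))
    if p_tail == 0.0:
        p_tail = 2.0 / result.B  # resolution bound of the bootstrap
        p_tail = min(p_tail, 1.0)
        p_tail_note = "below bootstrap resolution"
    else:
        p_tail_note = ""
    return {"p_wald": p_wald, "p_tail": p_tail, "note": p_tail_note}


def compare_models(
    replicate_matrices: list[GrowthRateMatrix],
    specs: list[ModelSpec],
    B: int = 200,
    seed: int = 0,
    n_starts: int = 5,
    max_failure_frac: float = 0.10,
) -> pd.DataFrame:
    """Goodness of fit of rival model forms over a shared bootstrap stream.

    Every spec is fitted to the *same* B resampled matrices, so SSE
    differences reflect the model forms, not sampling noise.  Returns a
    table indexed by form with mean SSE, mean R², mean AICc, the free
    parameter count and a rank by each metric.  Specs failing to
    converge in more than ``max_failure_frac`` of runs are excluded.
    """
    if len(specs) < 1:
        raise ValueError("need at least one model spec")
    rng = np.random.default_rng(seed)
    resampled = [resample_conditions(replicate_matrices, rng)[0] for _ in range(B)]
    rows = {}
    for spec in specs:
        sses, r2s, aiccs, fails = [], [], [], 0
        for m in resampled:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = nls_fit(m, spec, n_starts=n_starts)
                if not fit.converged:
                    fails += 1
                    continue
            except Exception:
                fails += 1
                continue
            sses.append(fit.sse)
            r2s.append(fit.r2)
            aiccs.append(fit.aicc)
        if fails > max_failure_frac * B:
            warnings.warn(
                f"model form {spec.form!r} failed in {fails}/{B} runs; excluded",
                stacklevel=2,
            )
            continue
        rows[spec.form] = {
            "n_free": spec.n_free,
            "sse_mean": float(np.mean(sses)),
            "r2_mean": float(np.mean(r2s)),
            "aicc_mean": float(np.mean(aiccs)),
            "n_converged": len(sses),
        }
    table = pd.DataFrame(rows).T
    if len(table) > 1:
        table["rank_sse"] = table["sse_mean"].rank(method="min").astype(int)
        table["rank_r2"] = table["r2_mean"].rank(ascending=False, method="min").astype(int)
        table["rank_aicc"] = table["aicc_mean"].rank(method="min").astype(int)
    return table


# ---------------------------------------------------------------- prediction


def predict_map(
    params: MonodParams, L_grid: np.ndarray, N_grid: np.ndarray
) -> pd.DataFrame:
    """Lookup map of predicted growth rate over a light × nitrogen grid.

    Rows are nitrogen values, columns light values; entries in day⁻¹.
    """
    from .model import growth_rate_multiplicative

    L = np.asarray(L_grid, dtype=float)
    N = np.asarray(N_grid, dtype=float)
    if np.any(L < 0) or np.any(N < 0):
        raise ValueError("grid values must be >= 0")
    LL, NN = np.meshgrid(L, N)
    mu = growth_rate_multiplicative(LL, NN, params)
    mu = np.atleast_2d(mu)
    return pd.DataFrame(mu, index=pd.Index(N, name="nitrogen_uM"),
                        columns=pd.Index(L, name="par"))


def predicted_vs_observed(
    matrix: GrowthRateMatrix, params: MonodParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired (µ_pred, µ_obs) vectors and their R² about the identity fit."""
    from .model import growth_rate_multiplicative

    L, N, mu_obs, _ = matrix.observations()
    mu_pred = growth_rate_multiplicative(L, N, params)
    sst = float(np.sum((mu_obs - mu_obs.mean()) ** 2))
    sse = float(np.sum((mu_obs - mu_pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return np.asarray(mu_pred), mu_obs, r2
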
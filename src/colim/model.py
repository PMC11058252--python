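"""Monod colimitation growth-rate models.

The central object is the multiplicative colimitation model for a
phototroph growing under simultaneous light (L, PAR in µmol·m⁻²·s⁻¹)
and nitrogen ([N], µM) limitation::

    µ(L, N) = µmax · (L + L0)/(K_L + L + L0) · (N + N0)/(K_N + N + N0)

Each parenthesised term is an ordinary Monod saturating factor with an
additive "storage" offset: L0 represents light-equivalent energy from
acetate in the medium (residual dark growth), N0 intracellular nitrogen
reserves.  K_L and K_N are the half-saturation constants.

Two rival formulations are provided for model comparison: a reduced
multiplicative form with both storages pinned at zero (free parameters
µ0, K_L, K_N only), and a law-of-minimum (Liebig) form in which growth
is set by the single most limiting factor, µmax·min(f_L, f_N), using
the same saturating factors so the two families are nested over an
identical parameterisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MonodParams",
    "FactorSpec",
    "ModelSpec",
    "MODEL_FORMS",
    "growth_rate_multiplicative",
    "growth_rate_liebig",
    "growth_rate_product",
]

MODEL_FORMS = (
    "multiplicative_storage",
    "multiplicative_basic",
    "liebig_min",
    "generalized_product",
)


@dataclass(frozen=True)
class MonodParams:
    """Parameter vector of the two-resource colimitation model.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate, day⁻¹.
    L0 : float
        Light-equivalent storage offset (acetate), µmol·m⁻²·s⁻¹.
    K_L : float
        Light half-saturation constant, µmol·m⁻²·s⁻¹.
    N0 : float
        Stored-nitrogen offset, µM.
    K_N : float
        Nitrogen half-saturation constant, µM.
    """

    mu_max: float
    L0: float
    K_L: float
    N0: float
    K_N: float

    def __post_init__(self) -> None:
        for name in ("mu_max", "L0", "K_L", "N0", "K_N"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.K_L <= 0 or self.K_N <= 0:
            raise ValueError("half-saturation constants K_L and K_N must be > 0")

    def to_json(self, form: str = "multiplicative_storage") -> str:
        if form not in MODEL_FORMS:
            raise ValueError(f"unknown form {form!r}")
        return json.dumps(
            {
                "mu_max": self.mu_max,
                "L0": self.L0,
                "K_L": self.K_L,
                "N0": self.N0,
                "K_N": self.K_N,
                "form": form,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MonodParams":
        d = json.loads(text)
        return cls(
            mu_max=d["mu_max"], L0=d["L0"], K_L=d["K_L"], N0=d["N0"], K_N=d["K_N"]
        )


@dataclass(frozen=True)
class FactorSpec:
    """One environmental factor of the generalized product model.

    ``storage`` and ``half_sat`` are in the factor's own units.
    """

    value_name: str
    storage: float
    half_sat: float

    def __post_init__(self) -> None:
        if self.storage < 0:
            raise ValueError("storage must be >= 0")
        if self.half_sat <= 0:
            raise ValueError("half_sat must be > 0")


# parameters each model form uses
_FORM_PARAMS = {
    "multiplicative_storage": frozenset({"mu_max", "L0", "K_L", "N0", "K_N"}),
    "multiplicative_basic": frozenset({"mu_0", "K_L", "K_N"}),
    "liebig_min": frozenset({"mu_max", "L0", "K_L", "N0", "K_N"}),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which model form is fitted and which parameters are free vs fixed."""

    form: str
    free_params: frozenset = field(default_factory=frozenset)
    fixed_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in MODEL_FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        object.__setattr__(self, "free_params", frozenset(self.free_params))
        object.__setattr__(self, "fixed_params", dict(self.fixed_params))
        if self.form == "generalized_product":
            return  # parameter bookkeeping handled by the caller
        wanted = _FORM_PARAMS[self.form]
        fixed = set(self.fixed_params)
        if self.free_params & fixed:
            raise ValueError("free_params and fixed_params overlap")
        if self.free_params | fixed != wanted:
            raise ValueError(
                f"form {self.form} needs exactly params {sorted(wanted)}; "
                f"got free={sorted(self.free_params)} fixed={sorted(fixed)}"
            )

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def build_params(self, free_values: Mapping[str, float]) -> MonodParams:
        """Assemble a full MonodParams from free values plus the fixed map."""
        vals = dict(self.fixed_params)
        vals.update(free_values)
        if self.form == "multiplicative_basic":
            return MonodParams(
                mu_max=vals["mu_0"], L0=0.0, K_L=vals["K_L"], N0=0.0, K_N=vals["K_N"]
            )
        return MonodParams(
            mu_max=vals["mu_max"],
            L0=vals["L0"],
            K_L=vals["K_L"],
            N0=vals["N0"],
            K_N=vals["K_N"],
        )

    def evaluate(self, L, N, p: MonodParams):
        if self.form == "liebig_min":
            return growth_rate_liebig(L, N, p)
        return growth_rate_multiplicative(L, N, p)


def _check_inputs(L, N):
    L = np.asarray(L, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(L < 0):
        raise ValueError("light intensity L must be >= 0")
    if np.any(N < 0):
        raise ValueError("nitrogen concentration N must be >= 0")
    return L, N


def _factors(L, N, p: MonodParams):
    fL = (L + p.L0) / (p.K_L + L + p.L0)
    fN = (N + p.N0) / (p.K_N + N + p.N0)
    return fL, fN


def growth_rate_multiplicative(L, N, p: MonodParams):
    """Specific growth rate under the multiplicative colimitation model.

    µ = µmax · f_L · f_N with f_X = (X + X0)/(K_X + X + X0).  Accepts
    scalars or broadcastable arrays; returns day⁻¹.
    """
    L, N = _check_inputs(L, N)
    fL, fN = _factors(L, N, p)
    out = p.mu_max * fL * fN
    return float(out) if out.ndim == 0 else out


def growth_rate_liebig(L, N, p: MonodParams):
    """Law-of-minimum analogue: µ = µmax · min(f_L, f_N).

    Uses the same saturating factors (including storage offsets) as the
    multiplicative form so the two families share a parameter space.
    """
    L, N = _check_inputs(L, N)
    fL, fN = _factors(L, N, p)
    out = p.mu_max * np.minimum(fL, fN)
    return float(out) if out.ndim == 0 else out


def growth_rate_product(
    factors: Sequence[tuple[float, FactorSpec]], mu_max: float
):
    """Generalized product over any number of non-substitutable factors.

    µ = µmax · Πᵢ (Eᵢ + Eᵢ₀)/(K_Eᵢ + Eᵢ + Eᵢ₀).  An empty factor list
    returns µmax.  With factors [light, nitrogen] this reproduces the
    two-resource model exactly.
    """
    if mu_max < 0:
        raise ValueError("mu_max must be >= 0")
    out = float(mu_max)
    for value, spec in factors:
        value = float(value)
        if value < 0:
            raise ValueError(f"factor {spec.value_name!r} value must be >= 0")
        out *= (value + spec.storage) / (spec.half_sat + value + spec.storage)
    return out


def default_fit_spec(acetate: bool = True, mu_max: float = 2.4) -> ModelSpec:
    """Standard fitting protocol for the two-gradient experiment.

    µmax is fixed (2.4 day⁻¹, the maximum rate measured previously in
    the same device) and N0 is fixed at 0 because cells are nitrogen
    starved beforehand.  L0 is free when the medium contains acetate,
    otherwise fixed at 0 (no residual dark growth without acetate).
    """
    if acetate:
        return ModelSpec(
            form="multiplicative_storage",
            free_params=frozenset({"L0", "K_L", "K_N"}),
            fixed_params={"mu_max": mu_max, "N0": 0.0},
        )
    return ModelSpec(
        form="multiplicative_storage",
        free_params=frozenset({"K_L", "K_N"}),
        fixed_params={"mu_max": mu_max, "N0": 0.0, "L0": 0.0},
    )
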
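"""Core kinetics of the mediator-feedback skin-inflammation model.

Two diffusible species live on the skin surface: a pro-inflammatory
mediator ``a`` (the activator; its local concentration is the model's
proxy for visible erythema) and an anti-inflammatory mediator ``i``
(the inhibitor).  The activator autoactivates through a saturating
Hill term, is repressed by the inhibitor, and both are produced
basally and cleared linearly.  In nondimensional form the well-mixed
kinetics are

    da/dt = p_a + q_a * a^n / ((a^n + 1)(i + 1)) - r_a * a
    di/dt = p_i + q_i * a^n i^n / ((a^n + 1)(i^n + 1)) - i

with time scaled by the inhibitor clearance rate and concentrations by
the respective Hill thresholds.  This module holds the parameter
containers, the reaction terms, their analytic Jacobian, and the
dimensional-to-nondimensional mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Any

import numpy as np

__all__ = [
    "DimParams",
    "Params",
    "reaction_rates",
    "jacobian",
    "nondimensionalize",
]


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

_DIM_KEYS = ("PA", "QA", "KA", "RA", "DA", "PI", "QI", "KI", "RI", "DI", "n")
_NONDIM_KEYS = ("pa", "qa", "ra", "Da", "pi", "qi", "Di", "n")


@dataclass(frozen=True)
class DimParams:
    """Dimensional kinetic parameters (any consistent unit system).

    ``P`` basal production, ``Q`` maximal feedback production, ``K``
    half-saturation threshold, ``R`` linear clearance, ``D`` diffusion;
    the ``_A`` group is the pro-inflammatory mediator, the ``_I`` group
    the anti-inflammatory one.  ``n`` is the Hill cooperativity.
    """

    P_A: float
    Q_A: float
    K_A: float
    R_A: float
    D_A: float
    P_I: float
    Q_I: float
    K_I: float
    R_I: float
    D_I: float
    n: int = 2

    def __post_init__(self) -> None:
        for name in ("P_A", "Q_A", "K_A", "R_A", "P_I", "Q_I", "K_I", "R_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.D_A < 0 or self.D_I < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("Hill coefficient n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))

    def to_json(self) -> str:
        keys = dict(zip(_DIM_KEYS, (self.P_A, self.Q_A, self.K_A, self.R_A,
                                    self.D_A, self.P_I, self.Q_I, self.K_I,
                                    self.R_I, self.D_I, self.n)))
        return json.dumps(keys)

    @classmethod
    def from_json(cls, doc: str) -> "DimParams":
        d = json.loads(doc)
        return cls(P_A=d["PA"], Q_A=d["QA"], K_A=d["KA"], R_A=d["RA"],
                   D_A=d["DA"], P_I=d["PI"], Q_I=d["QI"], K_I=d["KI"],
                   R_I=d["RI"], D_I=d["DI"], n=d.get("n", 2))


@dataclass(frozen=True)
class Params:
    """Nondimensional parameters of the reaction-diffusion system.

    p_a, q_a : basal / maximal production rate of the pro-inflammatory
        mediator (units of inhibitor-clearance rate).
    r_a : clearance of the pro-inflammatory mediator relative to the
        anti-inflammatory one.
    p_i, q_i : basal / maximal production rate of the anti-inflammatory
        mediator.
    D_a, D_i : diffusion coefficients; equal by default, which rules
        out Turing (diffusion-driven) instability.
    n : Hill cooperativity, default 2.
    """

    p_a: float
    q_a: float
    r_a: float
    p_i: float
    q_i: float
    D_a: float = 0.3
    D_i: float = 0.3
    n: int = 2

    def __post_init__(self) -> None:
        for name in ("p_a", "r_a", "p_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # q_a = q_i = 0 is the feedback-free (linear) limit, useful as
        # an analytic reference case
        if self.q_a < 0 or self.q_i < 0:
            raise ValueError("q_a and q_i must be non-negative")
        if self.D_a < 0 or self.D_i < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("Hill coefficient n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))

    # conservative invariant box: Hill factors are <= 1 so any steady
    # state satisfies a* <= (p_a+q_a)/r_a and i* <= p_i+q_i
    @property
    def a_max(self) -> float:
        return (self.p_a + self.q_a) / self.r_a

    @property
    def i_max(self) -> float:
        return self.p_i + self.q_i

    def with_(self, **kw: Any) -> "Params":
        return replace(self, **kw)

    def to_json(self) -> str:
        keys = dict(zip(_NONDIM_KEYS, (self.p_a, self.q_a, self.r_a, self.D_a,
                                       self.p_i, self.q_i, self.D_i, self.n)))
        return json.dumps(keys)

    @classmethod
    def from_json(cls, doc: str) -> "Params":
        d = json.loads(doc)
        unknown = set(d) - set(_NONDIM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(p_a=d["pa"], q_a=d["qa"], r_a=d["ra"], D_a=d.get("Da", 0.3),
                   p_i=d["pi"], q_i=d["qi"], D_i=d.get("Di", 0.3),
                   n=d.get("n", 2))


# --------------------------------------------------------------------------
# Reaction terms
# --------------------------------------------------------------------------

def _hill(x: np.ndarray | float, n: int) -> np.ndarray | float:
    """x^n / (x^n + 1), computed overflow-safely for large x.

    For x > 1 the equivalent form 1 / (1 + x^-n) is used so that x^n
    never overflows during large transients.
    """
    x = np.asarray(x, dtype=float)
    big = x > 1.0
    out = np.empty_like(x)
    xs = np.where(big, 1.0, x)      # safe operand for the small branch
    xb = np.where(big, x, 2.0)      # safe operand for the large branch
    out[...] = np.where(big, 1.0 / (1.0 + xb ** (-n)),
                        xs ** n / (xs ** n + 1.0))
    return out if out.ndim else float(out)


def _dhill(x: np.ndarray | float, n: int) -> np.ndarray | float:
    """d/dx of x^n/(x^n+1) = n x^(n-1) / (x^n+1)^2.

    Written as n*H*(1-H)/x for x > 0 to reuse the overflow-safe Hill
    factor; the x -> 0 limit is 1 for n = 1 and 0 for n >= 2.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(_hill(x, n))
    pos = x > 0.0
    xsafe = np.where(pos, x, 1.0)
    lim0 = 1.0 if n == 1 else 0.0
    out = np.where(pos, n * h * (1.0 - h) / xsafe, lim0)
    return out if out.ndim else float(out)


def _check_nonneg(a, i) -> None:
    if np.any(np.asarray(a) < 0) or np.any(np.asarray(i) < 0):
        raise ValueError("concentrations must be non-negative")


def reaction_rates(a, i, params: Params):
    """Well-mixed reaction terms (da/dt, di/dt), diffusion excluded.

    Accepts scalars or arrays (broadcast elementwise).  Raises
    ``ValueError`` on negative concentrations.
    """
    _check_nonneg(a, i)
    n = params.n
    ha = _hill(a, n)
    hi = _hill(i, n)
    a = np.asarray(a, dtype=float)
    i = np.asarray(i, dtype=float)
    rate_a = params.p_a + params.q_a * ha / (i + 1.0) - params.r_a * a
    rate_i = params.p_i + params.q_i * ha * hi - i
    if rate_a.ndim == 0:
        return float(rate_a), float(rate_i)
    return rate_a, rate_i


def jacobian(a: float, i: float, params: Params) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`reaction_rates` at (a, i)."""
    _check_nonneg(a, i)
    n = params.n
    ha = float(np.asarray(_hill(a, n)))
    hi = float(np.asarray(_hill(i, n)))
    dha = float(np.asarray(_dhill(a, n)))
    dhi = float(np.asarray(_dhill(i, n)))
    daa = params.q_a * dha / (i + 1.0) - params.r_a
    dai = -params.q_a * ha / (i + 1.0) ** 2
    dia = params.q_i * hi * dha
    dii = params.q_i * ha * dhi - 1.0
    return np.array([[daa, dai], [dia, dii]])


def nondimensionalize(dim: DimParams) -> Params:
    """Map dimensional parameters to the nondimensional set.

    Concentrations are scaled by the Hill thresholds (A = K_A a,
    I = K_I i) and time by the inhibitor clearance (T = t / R_I), so

        p_a = P_A/(R_I K_A),  q_a = Q_A/(R_I K_A),  r_a = R_A/R_I,
        D_a = D_A/R_I,        p_i = P_I/(R_I K_I),  q_i = Q_I/(R_I K_I),
        D_i = D_I/R_I.

    Space is treated as already nondimensional: the diffusion scaling
    carries no explicit length scale, so D_a, D_i are interpreted on
    the simulation grid's own units.
    """
    if dim.K_A <= 0 or dim.K_I <= 0 or dim.R_I <= 0:
        raise ValueError("K_A, K_I and R_I must be strictly positive")
    s = dim.R_I
    return Params(
        p_a=dim.P_A / (s * dim.K_A),
        q_a=dim.Q_A / (s * dim.K_A),
        r_a=dim.R_A / s,
        D_a=dim.D_A / s,
        p_i=dim.P_I / (s * dim.K_I),
        q_i=dim.Q_I / (s * dim.K_I),
        D_i=dim.D_I / s,
        n=dim.n,
    )
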
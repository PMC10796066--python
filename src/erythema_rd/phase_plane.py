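"""Well-mixed (D_a = D_i = 0) analysis of the mediator-feedback kinetics.

Enumerates steady states and their linear stability, classifies the
dynamical regime (excitable vs bistable), computes nullclines and
healthy/threshold/inflamed state distances, integrates well-mixed time
courses, and evaluates the linear dispersion relation about a
homogeneous steady state.

The regime vocabulary follows the inflammation literature: the
low-concentration attractor is the healthy state S_H, a nearby unstable
state acts as a stimulation threshold S_T, and a second
high-concentration attractor, when present, is the chronically
inflamed state S_I.  "Excitable" means S_H is the only attractor
(supra-threshold stimuli cause a large transient excursion and
return); "bistable" means S_H and S_I coexist, separated by S_T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .model_core import Params, jacobian, reaction_rates

__all__ = [
    "SteadyState",
    "RegimeReport",
    "StimPulse",
    "find_steady_states",
    "classify_regime",
    "regime_report",
    "nullclines",
    "trajectory",
    "dispersion_relation",
]

logger = logging.getLogger("erythema_rd")

#: |Re lambda| below this is reported as "marginal" and excluded from
#: the regime census (protects sweep cells sitting on a bifurcation).
MARGINAL_TOL = 1e-8

#: dedup radius for nearly coincident roots
DEDUP_RADIUS = 1e-6

#: fixed RK4 step for well-mixed trajectories (matches the PDE stepper)
ODE_DT = 0.01


@dataclass(frozen=True)
class SteadyState:
    """A root (a*, i*) of the reaction terms with its linear stability."""

    a_star: float
    i_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable" | "marginal"

    def distance_to(self, other: "SteadyState") -> float:
        return math.hypot(self.a_star - other.a_star, self.i_star - other.i_star)


@dataclass(frozen=True)
class RegimeReport:
    """Steady-state inventory with regime class and S_H/S_T/S_I roles."""

    states: tuple[SteadyState, ...]
    regime: str  # "excitable" | "bistable" | "monostable_plain" | "other"
    S_H: SteadyState | None
    S_T: SteadyState | None
    S_I: SteadyState | None
    d_HT: float | None
    d_TI: float | None


@dataclass(frozen=True)
class StimPulse:
    """Transient additive source on da/dt over the window [t_on, t_off)."""

    t_on: float = 10.0
    t_off: float = 11.0
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if not (self.t_off > self.t_on >= 0):
            raise ValueError("need t_off > t_on >= 0")
        if self.amplitude <= 0:
            raise ValueError("pulse amplitude must be positive")


# --------------------------------------------------------------------------
# Steady states
# --------------------------------------------------------------------------

def _a_nullcline_i(a: np.ndarray, params: Params) -> np.ndarray:
    """i on the da/dt = 0 branch, valid where r_a*a > p_a.

    Solving p_a + q_a a^n/((a^n+1)(i+1)) = r_a a for i gives
    i = q_a a^n / ((a^n+1)(r_a a - p_a)) - 1.
    """
    n = params.n
    an = a ** n
    denom = (an + 1.0) * (params.r_a * a - params.p_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        return params.q_a * an / denom - 1.0


def _classify_root(a: float, i: float, params: Params) -> SteadyState:
    eig = np.linalg.eigvals(jacobian(a, i, params))
    re = np.real(eig)
    if np.any(np.abs(re) <= MARGINAL_TOL):
        stab = "marginal"
    elif np.all(re < 0):
        stab = "stable"
    else:
        stab = "unstable"
    return SteadyState(a, i, (complex(eig[0]), complex(eig[1])), stab)


def _a_nullcline_a_at_i(i: float, params: Params) -> list[float]:
    """Real non-negative a with da/dt = 0 at fixed i (polynomial roots).

    da/dt = 0 is (i+1)(r_a a - p_a)(a^n + 1) - q_a a^n = 0, a
    degree-(n+1) polynomial in a.
    """
    n = params.n
    c = np.zeros(n + 2)
    c[0] = params.r_a * (i + 1.0)
    c[1] = -params.p_a * (i + 1.0) - params.q_a
    c[-2] += params.r_a * (i + 1.0)
    c[-1] += -params.p_a * (i + 1.0)
    return sorted(r.real for r in np.roots(c)
                  if abs(r.imag) < 1e-9 and r.real >= -1e-12)


def _polish_2d(a0: float, i0: float, params: Params, tol: float) -> tuple | None:
    sol = optimize.root(
        lambda v: reaction_rates(max(v[0], 0.0), max(v[1], 0.0), params),
        x0=[max(a0, 0.0), max(i0, 0.0)], tol=tol)
    a, i = float(sol.x[0]), float(sol.x[1])
    if a < -1e-12 or i < -1e-12:
        return None
    a, i = max(a, 0.0), max(i, 0.0)
    res = reaction_rates(a, i, params)
    if math.hypot(*res) > 1e-9:
        return None
    return a, i


def find_steady_states(params: Params, tol: float = 1e-12,
                       n_scan: int = 4000) -> list[SteadyState]:
    """All steady states of the well-mixed kinetics, sorted by a*.

    Two complementary scalar reductions are scanned for sign changes
    and each bracket solved by Brent's method, then polished by a 2D
    quasi-Newton step: (1) along the closed-form a-nullcline branch
    i(a) = q_a a^n/((a^n+1)(r_a a - p_a)) - 1, the residual
    g(a) = di/dt(a, i(a)); (2) along the same nullcline parametrized
    by i through its degree-(n+1) polynomial in a, which also resolves
    near-vertical branches (the q_a -> 0 limit).  Roots closer than
    the dedup radius are merged and classified by the eigenvalues of
    the analytic Jacobian.
    """
    a_lo = params.p_a / params.r_a
    a_hi = params.a_max * (1.0 + 1e-9)
    # uniform scan plus log-spaced refinement just above the pole at
    # a = p_a/r_a, where the nullcline branch is near-vertical
    a_grid = np.unique(np.concatenate([
        np.linspace(a_lo, a_hi, n_scan + 1)[1:],
        a_lo + np.logspace(-12, np.log10(a_hi - a_lo), n_scan // 2),
    ]))
    i_vals = _a_nullcline_i(a_grid, params)
    # clamp i < 0 to 0: there di/dt = p_i > 0, so no spurious roots,
    # but brackets spanning the branch's i = 0 exit stay detectable
    ok = np.isfinite(i_vals) & (i_vals <= params.i_max * 10)
    i_cl = np.clip(i_vals, 0.0, None)

    def g(a: float) -> float:
        i = float(_a_nullcline_i(np.asarray(a, dtype=float), params))
        if i < 0:
            i = 0.0
        return reaction_rates(a, i, params)[1]

    g_vals = np.full_like(a_grid, np.nan)
    aa = a_grid[ok]
    ii = i_cl[ok]
    g_vals[ok] = (params.p_i
                  + params.q_i * (aa ** params.n / (aa ** params.n + 1.0))
                  * (ii ** params.n / (ii ** params.n + 1.0)) - ii)

    roots: list[tuple[float, float]] = []
    for j in range(len(a_grid) - 1):
        g0, g1 = g_vals[j], g_vals[j + 1]
        if not (np.isfinite(g0) and np.isfinite(g1)):
            continue
        if g0 == 0.0:
            roots.append((a_grid[j], float(i_vals[j])))
            continue
        if g0 * g1 < 0:
            try:
                a_root = optimize.brentq(g, a_grid[j], a_grid[j + 1],
                                         xtol=1e-14, rtol=1e-14)
            except (ValueError, RuntimeError) as exc:  # pragma: no cover
                logger.warning("bracket [%g, %g] skipped: %s",
                               a_grid[j], a_grid[j + 1], exc)
                continue
            i_root = float(_a_nullcline_i(np.asarray(a_root), params))
            polished = _polish_2d(a_root, i_root, params, tol)
            if polished is not None:
                roots.append(polished)

    # complementary scan parametrized by i (catches near-vertical
    # nullcline branches the a-scan under-resolves)
    i_grid = np.linspace(0.0, params.i_max * 1.05, n_scan // 4)
    branch_vals: list[list[float]] = []
    for i_v in i_grid:
        a_roots = _a_nullcline_a_at_i(i_v, params)
        gs = []
        for a_v in a_roots:
            gs.append(reaction_rates(max(a_v, 0.0), i_v, params)[1])
        branch_vals.append(gs)
    for j in range(len(i_grid) - 1):
        g0s, g1s = branch_vals[j], branch_vals[j + 1]
        if len(g0s) != len(g1s):
            continue  # branch count changes inside the cell; the
            # a-parametrized scan covers folds of the same curve
        for k in range(len(g0s)):
            if g0s[k] * g1s[k] < 0:
                def gk(i_v: float, k=k) -> float:
                    a_roots = _a_nullcline_a_at_i(i_v, params)
                    a_v = a_roots[min(k, len(a_roots) - 1)]
                    return reaction_rates(max(a_v, 0.0), i_v, params)[1]
                try:
                    i_root = optimize.brentq(gk, i_grid[j], i_grid[j + 1],
                                             xtol=1e-14, rtol=1e-14)
                except (ValueError, RuntimeError, IndexError):
                    continue
                a_roots = _a_nullcline_a_at_i(i_root, params)
                if not a_roots:
                    continue
                a_root = a_roots[min(k, len(a_roots) - 1)]
                polished = _polish_2d(a_root, i_root, params, tol)
                if polished is not None:
                    roots.append(polished)

    # dedup
    uniq: list[tuple[float, float]] = []
    for r in sorted(roots):
        if all(math.hypot(r[0] - u[0], r[1] - u[1]) > DEDUP_RADIUS
               for u in uniq):
            uniq.append(r)

    states = [_classify_root(a, i, params) for a, i in uniq]
    states.sort(key=lambda s: s.a_star)
    return states


# --------------------------------------------------------------------------
# Regime classification
# --------------------------------------------------------------------------

def classify_regime(states: Sequence[SteadyState]) -> RegimeReport:
    """Assign the dynamical regime from the steady-state census.

    1 stable + 2 unstable -> excitable (S_H the attractor, S_T the
    unstable state nearest S_H); 2 stable + 1 unstable -> bistable
    (S_H/S_I the low/high-a attractors, S_T the unstable state between
    them); a single stable state -> monostable_plain; anything else ->
    other.  Marginal states are excluded from the census.
    """
    if not states:
        raise ValueError("empty steady-state list (p_a, p_i > 0 forbids this)")
    census = [s for s in states if s.stability != "marginal"]
    n_marg = len(states) - len(census)
    if n_marg:
        logger.info("%d marginal state(s) excluded from regime census", n_marg)
    stable = [s for s in census if s.stability == "stable"]
    unstable = [s for s in census if s.stability == "unstable"]

    S_H = S_T = S_I = None
    regime = "other"
    if len(stable) == 1 and len(unstable) == 0 and len(census) == 1:
        regime = "monostable_plain"
        S_H = stable[0]
    elif len(stable) == 2 and len(unstable) == 1 and len(census) == 3:
        regime = "bistable"
        S_H = min(stable, key=lambda s: s.a_star)
        S_I = max(stable, key=lambda s: s.a_star)
        S_T = unstable[0]
    elif len(stable) == 1 and len(unstable) == 2 and len(census) == 3:
        regime = "excitable"
        S_H = stable[0]
        S_T = min(unstable, key=lambda s: s.distance_to(S_H))

    d_HT = S_H.distance_to(S_T) if (S_H and S_T) else None
    d_TI = S_T.distance_to(S_I) if (S_T and S_I) else None
    return RegimeReport(states=tuple(sorted(states, key=lambda s: s.a_star)),
                        regime=regime, S_H=S_H, S_T=S_T, S_I=S_I,
                        d_HT=d_HT, d_TI=d_TI)


def regime_report(params: Params) -> RegimeReport:
    """Convenience: find steady states and classify in one call."""
    return classify_regime(find_steady_states(params))


# --------------------------------------------------------------------------
# Nullclines
# --------------------------------------------------------------------------

def nullclines(params: Params, a_grid: np.ndarray):
    """Polyline branches of the two nullclines over ``a_grid``.

    Returns ``(a_branches, i_branches)``: each a list of (m, 2) arrays
    of (a, i) points, branches ordered by i.  The da/dt = 0 family has
    the closed form i = q_a a^n/((a^n+1)(r_a a - p_a)) - 1, kept where
    r_a a > p_a and i >= 0.  The di/dt = 0 family solves, per a, the
    degree-(n+1) polynomial -i^(n+1) + (p_i + c) i^n - i + p_i = 0
    with c = q_i a^n/(a^n + 1), keeping real non-negative roots.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    n = params.n

    ia = _a_nullcline_i(a_grid, params)
    keep = (params.r_a * a_grid > params.p_a) & np.isfinite(ia) & (ia >= 0)
    a_branch = np.column_stack([a_grid[keep], ia[keep]])
    a_branches = [a_branch] if len(a_branch) else []

    rows: dict[int, list[tuple[float, float]]] = {}
    for a in a_grid:
        c = params.q_i * a ** n / (a ** n + 1.0)
        # -i^(n+1) + (p_i + c) i^n + 0*... - i + p_i
        coeffs = np.zeros(n + 2)
        coeffs[0] = -1.0
        coeffs[1] = params.p_i + c
        coeffs[-2] += -1.0
        coeffs[-1] += params.p_i
        # collect real roots sorted; branch index by rank
        real = sorted(r.real for r in np.roots(coeffs)
                      if abs(r.imag) < 1e-9 and r.real >= -1e-12)
        for k, i_val in enumerate(real):
            rows.setdefault(k, []).append((a, max(i_val, 0.0)))

    i_branches = [np.asarray(rows[k]) for k in sorted(rows) if rows[k]]
    i_branches.sort(key=lambda b: float(np.median(b[:, 1])))
    return a_branches, i_branches


# --------------------------------------------------------------------------
# Well-mixed time courses
# --------------------------------------------------------------------------

def trajectory(params: Params, a0: float, i0: float, t_end: float,
               pulse: StimPulse | None = None, dt: float = ODE_DT):
    """Fixed-step RK4 integration of the well-mixed kinetics.

    Returns an (m, 3) array of rows (t, a, i) at every step, starting
    at t = 0.  When ``pulse`` is given, its amplitude is added to
    da/dt during [t_on, t_off).  Raises on blow-up (a or i > 1e6).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_steps = int(round(t_end / dt))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ra, ri = reaction_rates(max(y[0], 0.0), max(y[1], 0.0), params)
        if pulse is not None and pulse.t_on <= t < pulse.t_off:
            ra += pulse.amplitude
        return np.array([ra, ri])

    out = np.empty((n_steps + 1, 3))
    y = np.array([a0, i0], dtype=float)
    out[0] = (0.0, y[0], y[1])
    for k in range(n_steps):
        t = k * dt
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(np.abs(y) > 1e6) or not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"well-mixed trajectory diverged at t = {t + dt:.4f}")
        out[k + 1] = (t + dt, y[0], y[1])
    return out


# --------------------------------------------------------------------------
# Linear dispersion relation
# --------------------------------------------------------------------------

def save_trajectory_csv(path, series: np.ndarray) -> None:
    """Write a (t, a, i) time course as CSV."""
    np.savetxt(path, series, delimiter=",", header="t,a,i", comments="",
               fmt="%.10g")


def save_nullclines_csv(path, params: Params, a_grid: np.ndarray) -> None:
    """Write both nullcline families as CSV polylines.

    Columns: family (a_nullcline | i_nullcline), branch index, a, i.
    """
    a_br, i_br = nullclines(params, a_grid)
    with open(path, "w") as fh:
        fh.write("family,branch,a,i\n")
        for fam, branches in (("a_nullcline", a_br), ("i_nullcline", i_br)):
            for k, b in enumerate(branches):
                for a, i in b:
                    fh.write(f"{fam},{k},{a:.10g},{i:.10g}\n")


def dispersion_relation(params: Params, base: SteadyState,
                        k_grid: Iterable[float]) -> np.ndarray:
    """Leading eigenvalue real part of J - k^2 diag(D_a, D_i) per k.

    With equal diffusion coefficients D the spectrum shifts rigidly,
    lambda(k) = lambda(0) - D k^2, so a homogeneous state stable to
    uniform perturbations stays stable at every wavenumber — the model
    admits no Turing instability.
    """
    J = jacobian(base.a_star, base.i_star, params)
    out = []
    for k in k_grid:
        Jk = J - k ** 2 * np.diag([params.D_a, params.D_i])
        out.append(float(np.max(np.real(np.linalg.eigvals(Jk)))))
    return np.asarray(out)
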
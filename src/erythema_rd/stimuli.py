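"""Synthetic stimulation protocols and initial fields.

Generates the in-silico experiments the simulations start from: a
uniform low-mediator resting skin (a = i = 0.01 everywhere), onto
which a stimulus adds pro-inflammatory mediator in one of three
geometries — small circular Gaussian seeds (micro-inflammation foci of
roughly unit width), a straight line (contact with a tentacle or plant
branch), or a connected random network (the capillary reticulum).
Stimuli are purely additive and touch only the pro-inflammatory
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "GridSpec",
    "StimSpec",
    "FieldPair",
    "uniform_field",
    "apply_stimulus",
    "protocol_fixture",
    "PROTOCOL_NAMES",
]


@dataclass(frozen=True)
class GridSpec:
    """Periodic square grid: nx*ny cells of width dx (nondimensional)."""

    nx: int = 192
    ny: int = 192
    dx: float = 0.5

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass(frozen=True)
class StimSpec:
    """A stimulation event: geometry, strength and application time.

    shape: "gaussian_seeds" (one Gaussian bump of width ``sigma`` per
    entry of ``centers``), "line" (the same profile along a straight
    segment between the first two centers), or "network" (the profile
    along the edges of a random Voronoi diagram seeded by
    ``rng_seed``).  ``amplitude`` is the peak concentration added to
    the pro-inflammatory field; ``sigma`` is in the grid's space
    units; ``apply_time`` in nondimensional time.
    """

    shape: str = "gaussian_seeds"
    centers: tuple[tuple[float, float], ...] = ()
    amplitude: float = 1.0
    sigma: float = 1.0
    apply_time: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian_seeds", "line", "network"):
            raise ValueError(f"unknown stimulus shape {self.shape!r}")
        if self.amplitude <= 0 or self.sigma <= 0:
            raise ValueError("amplitude and sigma must be positive")
        if self.apply_time < 0:
            raise ValueError("apply_time must be non-negative")
        object.__setattr__(self, "centers",
                           tuple((float(x), float(y)) for x, y in self.centers))

    def to_dict(self) -> dict:
        return {"shape": self.shape, "centers": list(map(list, self.centers)),
                "amplitude": self.amplitude, "sigma": self.sigma,
                "apply_time": self.apply_time, "rng_seed": self.rng_seed}

    @classmethod
    def from_dict(cls, d: dict) -> "StimSpec":
        return cls(shape=d["shape"],
                   centers=tuple(tuple(c) for c in d.get("centers", ())),
                   amplitude=d.get("amplitude", 1.0),
                   sigma=d.get("sigma", 1.0),
                   apply_time=d.get("apply_time", 1.0),
                   rng_seed=d.get("rng_seed", 0))


@dataclass
class FieldPair:
    """The two concentration fields on a GridSpec (row-major, y first)."""

    a: np.ndarray
    i: np.ndarray

    def copy(self) -> "FieldPair":
        return FieldPair(self.a.copy(), self.i.copy())


def uniform_field(grid: GridSpec, a0: float = 0.01,
                  i0: float = 0.01) -> FieldPair:
    """Spatially uniform resting state (defaults a = i = 0.01)."""
    if a0 < 0 or i0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    return FieldPair(np.full(grid.shape, float(a0)),
                     np.full(grid.shape, float(i0)))


# --------------------------------------------------------------------------
# Stimulus geometry
# --------------------------------------------------------------------------

def _periodic_dist2(grid: GridSpec, cx: float, cy: float) -> np.ndarray:
    """Squared minimal periodic distance (grid-cell units) to (cx, cy)."""
    x = np.arange(grid.nx)[None, :]
    y = np.arange(grid.ny)[:, None]
    ddx = np.abs(x - cx)
    ddx = np.minimum(ddx, grid.nx - ddx)
    ddy = np.abs(y - cy)
    ddy = np.minimum(ddy, grid.ny - ddy)
    return ddx ** 2 + ddy ** 2


def _gaussian_bump(grid: GridSpec, cx: float, cy: float,
                   sigma_cells: float) -> np.ndarray:
    return np.exp(-_periodic_dist2(grid, cx, cy) / (2.0 * sigma_cells ** 2))


def _profile_along_points(grid: GridSpec, pts: np.ndarray,
                          sigma_cells: float) -> np.ndarray:
    """max-composited Gaussian profile of distance to a dense point set."""
    out = np.zeros(grid.shape)
    for cx, cy in pts:
        np.maximum(out, _gaussian_bump(grid, cx % grid.nx, cy % grid.ny,
                                       sigma_cells), out=out)
    return out


def _line_points(p0: np.ndarray, p1: np.ndarray, step: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def _network_segments(grid: GridSpec, rng_seed: int,
                      n_sites: int = 24) -> list[tuple[np.ndarray, np.ndarray]]:
    """Voronoi ridge segments of randomly placed sites, periodic wrap.

    Sites are tiled 3x3 before triangulating so ridges wrap seamlessly;
    only ridges with at least one endpoint in the central tile are
    kept, giving a connected reticulum on the torus.
    """
    rng = np.random.default_rng(rng_seed)
    sites = rng.uniform(0, [grid.nx, grid.ny], size=(n_sites, 2))
    shifts = np.array([(sx, sy) for sx in (-1, 0, 1) for sy in (-1, 0, 1)])
    tiled = np.concatenate([sites + s * [grid.nx, grid.ny] for s in shifts])
    vor = Voronoi(tiled)
    segs = []
    for (v0, v1) in vor.ridge_vertices:
        if v0 < 0 or v1 < 0:
            continue
        p0, p1 = vor.vertices[v0], vor.vertices[v1]
        mid = (p0 + p1) / 2
        if 0 <= mid[0] < grid.nx and 0 <= mid[1] < grid.ny:
            segs.append((p0, p1))
    return segs


def apply_stimulus(fields: FieldPair, grid: GridSpec,
                   stim: StimSpec) -> FieldPair:
    """Return a new FieldPair with the stimulus added to ``a``.

    All geometries deposit the same radial Gaussian cross-profile of
    width ``sigma`` (max-composited along lines and network edges so
    overlaps do not double-count); ``i`` is returned unchanged.
    """
    sigma_cells = stim.sigma / grid.dx
    bump = np.zeros(grid.shape)
    if stim.shape == "gaussian_seeds":
        if not stim.centers:
            raise ValueError("gaussian_seeds needs at least one center")
        for cx, cy in stim.centers:
            np.maximum(bump, _gaussian_bump(grid, cx % grid.nx, cy % grid.ny,
                                            sigma_cells), out=bump)
    elif stim.shape == "line":
        if len(stim.centers) < 2:
            raise ValueError("line stimulus needs two endpoint centers")
        p0 = np.asarray(stim.centers[0], dtype=float)
        p1 = np.asarray(stim.centers[1], dtype=float)
        pts = _line_points(p0, p1, step=0.5)
        bump = _profile_along_points(grid, pts, sigma_cells)
    else:  # network
        for p0, p1 in _network_segments(grid, stim.rng_seed):
            pts = _line_points(p0, p1, step=0.5)
            np.maximum(bump, _profile_along_points(grid, pts, sigma_cells),
                       out=bump)
    out = fields.copy()
    out.a += stim.amplitude * bump
    return out


# --------------------------------------------------------------------------
# Named protocol fixtures
# --------------------------------------------------------------------------

PROTOCOL_NAMES = ("fading_linear", "fading_reticular", "fading_circular",
                  "expanding_three_seeds")


def protocol_fixture(name: str,
                     grid: GridSpec | None = None) -> tuple[GridSpec, StimSpec]:
    """Reproducible named stimulation protocols.

    fading_linear: a straight segment across the domain;
    fading_reticular: the random capillary-like network (fixed seed);
    fading_circular: one Gaussian seed at the domain center;
    expanding_three_seeds: three well-separated Gaussian seeds.
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(
            f"unknown protocol {name!r}; valid names: {PROTOCOL_NAMES}")
    g = grid or GridSpec()
    cx, cy = g.nx / 2, g.ny / 2
    if name == "fading_linear":
        stim = StimSpec(shape="line",
                        centers=((g.nx * 0.2, g.ny * 0.3),
                                 (g.nx * 0.8, g.ny * 0.7)))
    elif name == "fading_reticular":
        stim = StimSpec(shape="network", centers=(), rng_seed=7)
    elif name == "fading_circular":
        # a stimulated circular *area* spanning several cells, so that
        # interior-first clearing is resolvable
        stim = StimSpec(shape="gaussian_seeds", centers=((cx, cy),), sigma=4.0)
    else:  # expanding_three_seeds
        stim = StimSpec(shape="gaussian_seeds",
                        centers=((g.nx * 0.30, g.ny * 0.35),
                                 (g.nx * 0.68, g.ny * 0.30),
                                 (g.nx * 0.50, g.ny * 0.70)))
    return g, stim
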
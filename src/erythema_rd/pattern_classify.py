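"""Morphological classification of simulated erythema snapshots.

Maps binary suprathreshold masks (and their time series) onto the
clinical pattern vocabulary:

* fading      — the area vanishes while its outer radius holds steady
                (interior clears first);
* shrinking   — the area vanishes by contraction of the outer boundary;
* circular    — filled, hole-free expanding blob;
* annular     — a single closed ring (low-concentration interior);
* polycyclic  — nested concentric rings;
* arcuate     — open, curve-like ring segments;
* gyrate      — spiralling curve segments (wood-grain), detected by the
                total turning of the skeleton path.

The decision rules formalize verbal clinical descriptors, so the exact
constants (radius-stability tolerance, curvature thresholds) are
package choices, exposed as keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "BinaryMask",
    "ComponentFeatures",
    "PatternLabel",
    "binarize",
    "snapshot_features",
    "label_snapshot",
    "label_series",
]

EXPANDING_LABELS = ("circular", "annular", "polycyclic", "arcuate", "gyrate")


@dataclass(frozen=True)
class BinaryMask:
    """Suprathreshold mask of the pro-inflammatory field."""

    mask: np.ndarray
    threshold_used: float


@dataclass(frozen=True)
class ComponentFeatures:
    """Topology descriptors of one 8-connected foreground component."""

    area: int
    n_holes: int            # 4-connected background holes fully enclosed
    is_ring: bool           # closed: at least one hole
    is_curve_like: bool     # thin relative to its skeleton length
    skeleton_length: int    # pixels in the morphological skeleton
    n_endpoints: int        # skeleton endpoints (0 for closed rings)
    total_turning: float    # |unwrapped tangent rotation| along skeleton, rad
    nesting_depth: int      # 1 = top level; 2 = inside another's hole ...
    bbox: tuple[int, int, int, int]  # (y0, x0, y1, x1) on the unwrapped grid


@dataclass(frozen=True)
class PatternLabel:
    """Final label for a snapshot series plus its supporting evidence."""

    label: str
    area_series: tuple[float, ...]
    radius_series: tuple[float, ...]
    disappearance_time: float | None
    final_features: tuple[ComponentFeatures, ...]


# --------------------------------------------------------------------------
# Binarization and unwrapping
# --------------------------------------------------------------------------

def binarize(a_field: np.ndarray, threshold: float) -> BinaryMask:
    """Mask of cells whose activator concentration exceeds ``threshold``.

    The natural threshold is the a-coordinate of the threshold steady
    state S_T when the regime has one; otherwise the midpoint between
    the field's extremes is a reasonable fallback.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return BinaryMask(np.asarray(a_field) > threshold, float(threshold))


def unwrap_mask(mask: np.ndarray) -> np.ndarray:
    """Roll the periodic grid so the pattern does not straddle an edge.

    The cut is placed through the emptiest row and column, so any
    pattern smaller than the domain becomes contiguous; topology
    (hole counting) is then Euclidean rather than toroidal.
    """
    rows = mask.sum(axis=1)
    cols = mask.sum(axis=0)
    return np.roll(mask, (-int(np.argmin(rows)), -int(np.argmin(cols))),
                   axis=(0, 1))


# --------------------------------------------------------------------------
# Per-component features
# --------------------------------------------------------------------------

_S8 = np.ones((3, 3), dtype=int)


def _skeleton_path_turning(skel: np.ndarray) -> tuple[int, float]:
    """Endpoint count and total tangent rotation of a skeleton.

    The longest geodesic path through the skeleton (double-BFS) is
    smoothed and its tangent angle unwrapped; the absolute rotation
    from one end to the other measures how far the curve winds: ~pi
    for a "C", > 2*pi for a spiral.
    """
    pts = np.argwhere(skel)
    if len(pts) < 5:
        return 0, 0.0
    index = {tuple(p): k for k, p in enumerate(pts)}
    nbrs: list[list[int]] = [[] for _ in pts]
    for k, (y, x) in enumerate(pts):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None:
                    nbrs[k].append(j)
    n_end = sum(1 for nb in nbrs if len(nb) == 1)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        prev = {start: -1}
        queue = [start]
        last = start
        while queue:
            nxt = []
            for u in queue:
                for v in nbrs[u]:
                    if v not in prev:
                        prev[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            queue = nxt
        return last, prev

    far, _ = bfs(0)
    far2, prev = bfs(far)
    path = []
    u = far2
    while u != -1:
        path.append(u)
        u = prev[u]
    if len(path) < 9:
        return n_end, 0.0
    xy = pts[path].astype(float)
    # smooth to suppress lattice staircase angles
    w = min(7, len(xy) // 3 * 2 + 1)
    kernel = np.ones(w) / w
    ys = np.convolve(xy[:, 0], kernel, mode="valid")
    xs = np.convolve(xy[:, 1], kernel, mode="valid")
    ang = np.unwrap(np.arctan2(np.diff(ys), np.diff(xs)))
    return n_end, float(abs(ang[-1] - ang[0]))


def snapshot_features(bm: BinaryMask | np.ndarray) -> list[ComponentFeatures]:
    """Topology features of every 8-connected component of the mask.

    The grid is unwrapped first (see :func:`unwrap_mask`).  Holes are
    4-connected background regions that do not touch the component's
    exterior; a component with holes is a closed ring.  Curve-likeness
    compares the area with the skeleton length (thin structures have
    area of a few pixels per unit of skeleton).
    """
    mask = bm.mask if isinstance(bm, BinaryMask) else bm
    mask = unwrap_mask(np.asarray(mask, dtype=bool))
    lab, n = ndimage.label(mask, structure=_S8)
    feats: list[ComponentFeatures] = []
    filled_list = []
    for c in range(1, n + 1):
        comp = lab == c
        area = int(comp.sum())
        filled = ndimage.binary_fill_holes(comp)
        filled_list.append(filled)
        holes, n_holes = ndimage.label(filled & ~comp)  # 4-connectivity
        skel = skeletonize(comp)
        skel_len = int(skel.sum())
        mean_width = area / max(skel_len, 1)
        # elongated: skeleton much longer than the structure is wide
        is_curve = skel_len >= 8 and skel_len >= 2.5 * mean_width
        n_end, turning = _skeleton_path_turning(skel) if is_curve else (0, 0.0)
        ys, xs = np.nonzero(comp)
        feats.append(ComponentFeatures(
            area=area,
            n_holes=int(n_holes),
            is_ring=n_holes >= 1,
            is_curve_like=is_curve,
            skeleton_length=skel_len,
            n_endpoints=n_end,
            total_turning=turning,
            nesting_depth=1,
            bbox=(int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())),
        ))
    # nesting: component c sits one level below every component whose
    # filled region contains it
    depth = [1] * len(feats)
    for ci in range(len(feats)):
        for cj in range(len(feats)):
            if ci == cj:
                continue
            inner = lab == ci + 1
            if feats[cj].area > feats[ci].area and \
                    bool(np.all(filled_list[cj][inner])):
                depth[ci] = max(depth[ci], depth[cj] + 1)
    feats = [ComponentFeatures(**{**f.__dict__, "nesting_depth": d})
             for f, d in zip(feats, depth)]
    return feats


# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

def _bbox_overlap(b1, b2) -> bool:
    return not (b1[2] < b2[0] or b2[2] < b1[0]
                or b1[3] < b2[1] or b2[3] < b1[1])


def label_snapshot(features: Sequence[ComponentFeatures],
                   min_area: int = 6,
                   spiral_turning: float = 2.0 * np.pi,
                   c_turning: float = 0.9 * np.pi,
                   min_arc_skeleton: int = 20) -> str:
    """Assign one of the expanding-pattern labels to a snapshot.

    Decision list (first match wins): none -> gyrate -> polycyclic ->
    annular -> arcuate -> circular -> other.

    gyrate (wood grain) is either a spiral — an open curve whose
    skeleton turns by more than ``spiral_turning`` — or interlocking
    "C"-pairs, or the broken-concentric signature: at least two long
    open arcs (skeleton >= ``min_arc_skeleton``) coexisting with a
    closed ring.  polycyclic is a concentric structure: a ring with
    further structure (ring or core) nested inside its hole.  A lone
    closed ring is annular; open arcs without rings are arcuate;
    filled hole-free blobs are circular.
    """
    feats = [f for f in features if f.area >= min_area]
    if not feats:
        return "none"
    open_curves = [f for f in feats
                   if f.is_curve_like and f.n_endpoints >= 2 and not f.is_ring]
    rings = [f for f in feats if f.is_ring]
    # gyrate: spirals, interlocking C-pairs, or broken concentric rings
    if any(f.total_turning > spiral_turning for f in open_curves):
        return "gyrate"
    cs = [f for f in open_curves if f.total_turning >= c_turning]
    for ki in range(len(cs)):
        for kj in range(ki + 1, len(cs)):
            if _bbox_overlap(cs[ki].bbox, cs[kj].bbox):
                return "gyrate"
    long_arcs = [f for f in open_curves if f.skeleton_length >= min_arc_skeleton]
    if len(long_arcs) >= 2 and rings:
        return "gyrate"
    if any(f.nesting_depth >= 2 for f in feats) and rings:
        return "polycyclic"
    if rings:
        return "annular"
    if open_curves:
        return "arcuate"
    if all(not f.is_curve_like and f.n_holes == 0 for f in feats):
        return "circular"
    return "other"


def _outer_radius(mask: np.ndarray) -> float:
    """Max distance of mask cells from their centroid (unwrapped)."""
    m = unwrap_mask(mask)
    ys, xs = np.nonzero(m)
    if len(ys) == 0:
        return 0.0
    cy, cx = ys.mean(), xs.mean()
    return float(np.hypot(ys - cy, xs - cx).max())


def label_series(snapshots: Sequence[tuple[float, BinaryMask]],
                 radius_tolerance: float = 0.2,
                 growth_window: float = 0.5,
                 morphology_mask: BinaryMask | np.ndarray | None = None,
                 ) -> PatternLabel:
    """Classify a time series of suprathreshold masks.

    Vanishing series split into fading (outer radius within
    ``radius_tolerance`` of its running maximum until the area is
    nearly gone — the interior clears first) and shrinking (the outer
    radius contracts monotonically).  Persistently growing series take
    the morphological label of the final snapshot; when
    ``morphology_mask`` is given it replaces the final activity mask
    for that purpose (useful when the activity threshold sits below a
    chronically inflamed plateau, which would hide ring structure).
    """
    if len(snapshots) < 3:
        raise ValueError("need at least 3 post-stimulus snapshots")
    times = [t for t, _ in snapshots]
    masks = [bm.mask if isinstance(bm, BinaryMask) else bm
             for _, bm in snapshots]
    areas = np.array([int(m.sum()) for m in masks], dtype=float)
    radii = np.array([_outer_radius(m) for m in masks])
    final_bm = snapshots[-1][1] if morphology_mask is None else morphology_mask
    feats = tuple(snapshot_features(final_bm))

    disappearance: float | None = None
    live = np.nonzero(areas > 0)[0]
    if len(live) and areas[-1] == 0:
        k_gone = int(live[-1]) + 1
        if k_gone < len(times):
            disappearance = times[k_gone]

    def result(label: str) -> PatternLabel:
        return PatternLabel(label=label, area_series=tuple(areas),
                            radius_series=tuple(radii),
                            disappearance_time=disappearance,
                            final_features=feats)

    if areas.max() == 0:
        return result("none")

    if areas[-1] == 0:
        r_max = radii.max()
        a_max = areas.max()
        # frames before near-disappearance (area above 10% of peak)
        core = np.nonzero(areas >= 0.1 * a_max)[0]
        r_core = radii[core]
        if np.all(r_core >= (1.0 - radius_tolerance) * r_max):
            return result("fading")
        k_peak = int(np.argmax(radii))
        tail = radii[k_peak:int(live[-1]) + 1]
        if np.all(np.diff(tail) <= 0.05 * r_max + 1e-9):
            return result("shrinking")
        return result("other")

    # growing over the last part of the series?
    t0 = times[0] + (times[-1] - times[0]) * (1.0 - growth_window)
    idx = [k for k, t in enumerate(times) if t >= t0]
    if len(idx) >= 2 and areas[idx[-1]] > areas[idx[0]]:
        if morphology_mask is None and masks[-1].mean() > 0.9:
            # the whole domain is uniformly suprathreshold: a filled
            # chronically inflamed region
            return result("circular")
        if morphology_mask is not None and masks[-1].mean() > 0.5:
            # chronic inflammation has saturated the domain: when the
            # bright mask shows no internal contrast (nearly empty or
            # nearly full) the lesion is a uniformly red filled region
            m = (morphology_mask.mask if isinstance(morphology_mask, BinaryMask)
                 else morphology_mask)
            if m.mean() > 0.9 or m.mean() < 1e-3:
                return result("circular")
        return result(label_snapshot(feats))
    return result("other")
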
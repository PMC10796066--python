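"""Parametric synthetic binary masks with known pattern labels.

These generators draw idealized geometric stand-ins for each pattern
class — filled disk, annulus, nested annuli, gapped ring, spiral pair,
and fading/shrinking disk series — so the morphological classifier can
be validated independently of any reaction-diffusion simulation.
"""

from __future__ import annotations

import numpy as np

from .pattern_classify import BinaryMask

__all__ = [
    "disk_mask", "annulus_mask", "nested_annuli_mask", "gapped_ring_mask",
    "spiral_pair_mask", "fading_series", "shrinking_series",
    "growing_series", "MASK_BATTERY",
]


def _grid(n: int, center=None):
    cy, cx = center if center is not None else (n / 2, n / 2)
    y, x = np.mgrid[0:n, 0:n]
    return y - cy, x - cx


def disk_mask(n: int = 96, r: float = 20.0, center=None) -> np.ndarray:
    y, x = _grid(n, center)
    return x ** 2 + y ** 2 <= r ** 2


def annulus_mask(n: int = 96, r_out: float = 24.0,
                 r_in: float = 16.0, center=None) -> np.ndarray:
    y, x = _grid(n, center)
    r2 = x ** 2 + y ** 2
    return (r2 <= r_out ** 2) & (r2 >= r_in ** 2)


def nested_annuli_mask(n: int = 96, radii=((30.0, 26.0), (18.0, 14.0)),
                       center=None) -> np.ndarray:
    out = np.zeros((n, n), dtype=bool)
    for r_out, r_in in radii:
        out |= annulus_mask(n, r_out, r_in, center)
    return out


def gapped_ring_mask(n: int = 96, r_out: float = 24.0, r_in: float = 16.0,
                     gap_deg: float = 90.0, gap_at_deg: float = 0.0,
                     center=None) -> np.ndarray:
    """A ring with an angular sector removed: an open arc segment."""
    y, x = _grid(n, center)
    ring = annulus_mask(n, r_out, r_in, center)
    ang = np.degrees(np.arctan2(y, x))
    rel = (ang - gap_at_deg + 180.0) % 360.0 - 180.0
    return ring & ~(np.abs(rel) <= gap_deg / 2.0)


def spiral_pair_mask(n: int = 128, turns: float = 1.6, pitch: float = 12.0,
                     width: float = 2.0, r0: float = 5.0) -> np.ndarray:
    """Two interleaved Archimedean spiral arms (wood-grain motif)."""
    out = np.zeros((n, n), dtype=bool)
    y, x = _grid(n)
    for phase in (0.0, np.pi):
        t = np.linspace(0.0, 2 * np.pi * turns, 1200)
        r = r0 + pitch * t / (2 * np.pi)
        sy = n / 2 + r * np.sin(t + phase)
        sx = n / 2 + r * np.cos(t + phase)
        for py, px in zip(sy, sx):
            out |= (x + n / 2 - px) ** 2 + (y + n / 2 - py) ** 2 <= width ** 2
    return out


def fading_series(n: int = 96, r: float = 22.0, steps: int = 6):
    """Disk whose interior clears at constant outer radius, then empty.

    The suprathreshold area becomes a thinning ring of fixed outer
    radius and finally vanishes — interior-first resolution.
    """
    frames = []
    for k in range(steps):
        r_in = r * k / (steps - 1.5)
        m = annulus_mask(n, r, min(r_in, r - 1e-9)) if r_in > 0 else disk_mask(n, r)
        frames.append(m if r_in < r else np.zeros((n, n), dtype=bool))
    frames.append(np.zeros((n, n), dtype=bool))
    return [(float(t + 1), BinaryMask(m, 0.5)) for t, m in enumerate(frames)]


def shrinking_series(n: int = 96, r: float = 22.0, steps: int = 6):
    """Disk contracting to nothing: outer boundary closes inward."""
    frames = [disk_mask(n, r * (1 - k / (steps - 1.0))) if k < steps - 1
              else np.zeros((n, n), dtype=bool) for k in range(steps)]
    frames.append(np.zeros((n, n), dtype=bool))
    return [(float(t + 1), BinaryMask(m, 0.5)) for t, m in enumerate(frames)]


def growing_series(final_mask: np.ndarray, steps: int = 4):
    """Self-similar growth ending at ``final_mask`` (zoomed dilations)."""
    from scipy import ndimage
    frames = []
    for k in range(steps - 1, 0, -1):
        frames.append(ndimage.binary_erosion(final_mask, iterations=2 * k))
    frames.append(final_mask)
    return [(float(t + 1), BinaryMask(m, 0.5)) for t, m in enumerate(frames)]


#: (name, series factory, expected label) — the classifier battery
MASK_BATTERY = (
    ("fading_disk", fading_series, "fading"),
    ("shrinking_disk", shrinking_series, "shrinking"),
    ("growing_disk", lambda: growing_series(disk_mask()), "circular"),
    ("growing_annulus", lambda: growing_series(annulus_mask()), "annular"),
    ("growing_nested_annuli",
     lambda: growing_series(nested_annuli_mask()), "polycyclic"),
    ("growing_gapped_ring",
     lambda: growing_series(gapped_ring_mask()), "arcuate"),
    ("growing_spiral_pair",
     lambda: growing_series(spiral_pair_mask()), "gyrate"),
)
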
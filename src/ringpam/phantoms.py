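"""Numerical phantoms: sphere columns, microspheres, leads and tubes.

All phantoms are expressed as sets of spherical photoacoustic sources, the
only source primitive the forward model accepts.  Extended absorbers
(graphite leads, dye-filled tubes) are rasterized into dense chains of
spheres; the per-sphere amplitude is scaled with the rasterization spacing
(``amplitude · spacing / diameter``) so that the total source strength of an
object is independent of how finely it is sampled.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from .forward import SphereSource

__all__ = [
    "sphere_column",
    "microsphere",
    "parallel_leads",
    "curved_tubes",
    "intertwined_tubes",
    "make_preset",
    "PRESETS",
]


def sphere_column(
    n: int = 5,
    z_range: tuple[float, float] = (15.0, 35.0),
    diameter: float = 0.5,
    amplitude: float = 1.0,
) -> list[SphereSource]:
    """Equally spaced on-axis spheres spanning ``z_range`` (defaults: five
    0.5 mm spheres at 15, 20, 25, 30, 35 mm — the design-study phantom)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        depths = [0.5 * (z_range[0] + z_range[1])]
    else:
        depths = np.linspace(z_range[0], z_range[1], n)
    return [SphereSource((0.0, 0.0, float(z)), diameter, amplitude) for z in depths]


def microsphere(
    depth: float, diameter: float = 0.1, amplitude: float = 1.0
) -> list[SphereSource]:
    """Single on-axis microsphere (canonical resolution/calibration target).

    The default 0.1 mm diameter is a single fixed value representative of
    the 90–110 µm microspheres used for resolution phantoms.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    return [SphereSource((0.0, 0.0, float(depth)), diameter, amplitude)]


def _chain_sources(
    pts: np.ndarray, length: float, diameter: float, amplitude: float
) -> list[SphereSource]:
    """Spheres along a sampled centerline; per-sphere amplitude follows the
    trapezoid rule (half weight at the endpoints) so the total source
    strength is exactly ``amplitude · length / diameter`` for any spacing."""
    n = pts.shape[0]
    seg = length / (n - 1) if n > 1 else length
    amps = np.full(n, amplitude * seg / diameter)
    if n > 1:
        amps[0] *= 0.5
        amps[-1] *= 0.5
    return [SphereSource(tuple(p), diameter, float(a)) for p, a in zip(pts, amps)]


def _chain(
    start: np.ndarray, stop: np.ndarray, diameter: float, spacing: float, amplitude: float
) -> list[SphereSource]:
    length = float(np.linalg.norm(stop - start))
    n = math.ceil(length / spacing) + 1
    pts = start[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (stop - start)[None, :]
    return _chain_sources(pts, length, diameter, amplitude)


def parallel_leads(
    lead_specs: Sequence[tuple[float, float]],
    diameter: float = 0.7,
    length: float = 10.0,
    spacing: float | None = None,
    amplitude: float = 1.0,
) -> list[SphereSource]:
    """Parallel absorbing leads, rasterized as sphere chains along y.

    ``lead_specs`` lists ``(depth, x_offset)`` pairs; each lead runs parallel
    to the y axis (perpendicular to the scan direction), centred at y = 0.
    Scanning such leads with a single conical ring provokes the X-shaped
    artefacts that dynamic focusing and coherence weighting suppress.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if spacing is None:
        spacing = 0.25 * diameter  # quarter-diameter default: RF converged to <1%
    if spacing > 0.5 * diameter:
        raise ValueError("rasterization spacing must be <= diameter / 2")
    sources: list[SphereSource] = []
    for depth, x_off in lead_specs:
        a = np.array([x_off, -0.5 * length, depth])
        b = np.array([x_off, +0.5 * length, depth])
        sources.extend(_chain(a, b, diameter, spacing, amplitude))
    return sources


def curved_tubes(
    tubes: Sequence[np.ndarray],
    inner_diameter: float = 1.0,
    spacing: float | None = None,
    amplitude: float = 1.0,
) -> list[SphereSource]:
    """Smooth tube-like absorbers from per-tube control points.

    Each tube is a spline through its ``(n, 3)`` control points
    (chord-length parameterized, order ≤ 3), rasterized to spheres of the
    tube diameter at arc spacing ≤ diameter/2.  Self-intersection is not
    checked.  A two-point tube degenerates to a straight lead.
    """
    if spacing is None:
        spacing = 0.25 * inner_diameter
    if spacing > 0.5 * inner_diameter:
        raise ValueError("rasterization spacing must be <= inner_diameter / 2")
    sources: list[SphereSource] = []
    for cp in tubes:
        cp = np.asarray(cp, dtype=float)
        if cp.ndim != 2 or cp.shape[0] < 2 or cp.shape[1] != 3:
            raise ValueError("each tube needs >= 2 three-dimensional control points")
        if cp.shape[0] == 2:
            sources.extend(_chain(cp[0], cp[1], inner_diameter, spacing, amplitude))
            continue
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
        )
        spline = make_interp_spline(chord, cp, k=min(3, cp.shape[0] - 1))
        # oversample, then resample uniformly in arc length
        u = np.linspace(0.0, chord[-1], max(200, 20 * cp.shape[0]))
        dense = spline(u)
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        n = math.ceil(arc[-1] / spacing) + 1
        targets = np.linspace(0.0, arc[-1], n)
        pts = np.column_stack(
            [np.interp(targets, arc, dense[:, k]) for k in range(3)]
        )
        sources.extend(
            _chain_sources(pts, float(arc[-1]), inner_diameter, amplitude)
        )
    return sources


def intertwined_tubes(
    inner_diameter: float = 1.0, amplitude: float = 1.0
) -> list[SphereSource]:
    """Preset of three intertwined curved tubes with crossings in projection.

    Control points are declared fixture values spanning depths 20–32 mm with
    lateral extents of ±8 mm, chosen so the top-view projection of the three
    centerlines crosses (as an irregular multi-tube phantom does).
    """
    tubes = [
        np.array(
            [[-8.0, -8.0, 22.0], [-2.0, 0.0, 26.0], [4.0, 6.0, 24.0], [8.0, 8.0, 21.0]]
        ),
        np.array(
            [[-8.0, 8.0, 28.0], [-1.0, 2.0, 30.0], [3.0, -4.0, 32.0], [8.0, -8.0, 29.0]]
        ),
        np.array(
            [[-8.0, 0.0, 20.0], [0.0, 4.0, 23.0], [5.0, -2.0, 25.0], [8.0, -6.0, 26.0]]
        ),
    ]
    return curved_tubes(tubes, inner_diameter=inner_diameter, amplitude=amplitude)


PRESETS = {
    "sphere_column": sphere_column,
    "microsphere": microsphere,
    "parallel_leads": parallel_leads,
    "intertwined_tubes": intertwined_tubes,
}


def make_preset(name: str, **params) -> list[SphereSource]:
    """Build a named preset phantom (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**params)
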
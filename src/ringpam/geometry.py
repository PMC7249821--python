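"""Axisymmetric detector surfaces for scanning photoacoustic macroscopy.

The detectors modelled here are surfaces of revolution around a common
symmetry axis: flat annular rings, annular rings lying on a cone (including
the full axicon as the degenerate case ``r_inner = 0``) and spherical caps.
The coordinate convention places ``z = 0`` at the plane of the flat centre
ring, with z increasing toward the sample.  Inclined and curved elements rise
from that plane toward the sample, so that spherical waves emitted by
on-axis sources can reach the surface at near-normal incidence — this is
what gives the conical array its extended axial focus.

Units: lengths in mm, areas in mm², angles in degrees (converted internally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "RingElement",
    "SphericalCap",
    "DetectorArray",
    "SurfaceMesh",
    "DegenerateMeshWarning",
    "equal_area_partition",
    "element_area",
    "surface_mesh",
    "normal_incidence_depth_range",
    "load_geometry",
    "save_geometry",
    "bundled_geometry_names",
    "fabricated_array",
    "measurement_array",
    "comparison_geometries",
]

Element = Union["RingElement", "SphericalCap"]


class DegenerateMeshWarning(UserWarning):
    """Requested mesh spacing exceeds the element extent."""


@dataclass(frozen=True)
class RingElement:
    """Annular sensor element, flat or lying on a cone.

    Parameters
    ----------
    r_inner, r_outer:
        Radial bounds of the active area, mm.
    inclination:
        Angle of the surface relative to the plane perpendicular to the
        symmetry axis, degrees.  ``0`` means a flat annulus.
    r_base:
        Radius at which the conical surface meets the reference plane
        ``z = 0``.  Defaults to ``r_inner`` (cone whose inner edge lies in
        the plane).  The surface elevation at radius ``r`` is
        ``(r - r_base) * tan(inclination)``.
    """

    r_inner: float
    r_outer: float
    inclination: float = 0.0
    r_base: float | None = None
    name: str = "ring"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_inner < self.r_outer:
            raise ValueError(
                f"require 0 <= r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )
        if not 0.0 <= self.inclination < 90.0:
            raise ValueError(f"inclination must be in [0, 90), got {self.inclination}")
        if self.r_base is None:
            object.__setattr__(self, "r_base", self.r_inner)
        if not math.isfinite(self.r_base):
            raise ValueError("r_base must be finite")

    @property
    def is_flat(self) -> bool:
        return self.inclination == 0.0

    def elevation(self, r):
        """Axial elevation z(r) of the surface above the reference plane."""
        if self.is_flat:
            return np.zeros_like(np.asarray(r, dtype=float))
        return (np.asarray(r, dtype=float) - self.r_base) * math.tan(
            math.radians(self.inclination)
        )

    @property
    def area(self) -> float:
        return element_area(self)


@dataclass(frozen=True)
class SphericalCap:
    """Spherically focused sensor surface (cap of a sphere).

    The cap touches the reference plane at the axis and curves toward the
    sample; its centre of curvature (the focus) sits on the axis at depth
    ``radius_of_curvature``.
    """

    radius_of_curvature: float
    aperture_diameter: float
    name: str = "cap"

    def __post_init__(self) -> None:
        if self.radius_of_curvature <= 0 or self.aperture_diameter <= 0:
            raise ValueError("radius of curvature and aperture must be positive")
        if self.aperture_diameter > 2.0 * self.radius_of_curvature:
            raise ValueError("aperture_diameter must not exceed the sphere diameter")

    @property
    def focus(self) -> tuple[float, float, float]:
        return (0.0, 0.0, self.radius_of_curvature)

    @property
    def cap_height(self) -> float:
        a = 0.5 * self.aperture_diameter
        rho = self.radius_of_curvature
        return rho - math.sqrt(rho * rho - a * a)

    @property
    def area(self) -> float:
        return element_area(self)


@dataclass(frozen=True)
class DetectorArray:
    """Ordered set of elements sharing one symmetry axis."""

    elements: tuple[Element, ...]
    name: str = "array"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        rings = sorted(
            (e for e in self.elements if isinstance(e, RingElement)),
            key=lambda e: e.r_inner,
        )
        for a, b in zip(rings, rings[1:]):
            if b.r_inner < a.r_outer:
                raise ValueError(
                    f"ring elements {a.name!r} and {b.name!r} overlap radially"
                )

    def __iter__(self) -> Iterator[Element]:
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def element_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.elements)

    def subset(self, names: Sequence[str], name: str | None = None) -> "DetectorArray":
        """Return a new array keeping only the named elements (in order)."""
        by_name = {e.name: e for e in self.elements}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"unknown element(s): {missing}")
        return DetectorArray(
            tuple(by_name[n] for n in names), name=name or f"{self.name}-subset"
        )


@dataclass(frozen=True)
class SurfaceMesh:
    """Quadrature discretization of one element surface.

    ``points`` are 3-D positions (mm) lying exactly on the parent surface,
    ``weights`` the associated area weights (mm²) whose sum equals the
    analytic element area (exact by construction: each concentric band
    carries its analytic band area, split evenly among its points).

    ``edge_lo``/``edge_hi`` optionally hold the radial band edges of each
    quadrature patch (on-surface positions).  The forward model uses them to
    integrate each patch's retarded contribution over its radial
    arrival-time window instead of depositing a point delta, which removes
    the aliasing between band spacing and time sampling.
    """

    points: np.ndarray
    weights: np.ndarray
    element: Element
    edge_lo: np.ndarray | None = None
    edge_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or wts.shape != (pts.shape[0],):
            raise ValueError("inconsistent mesh point/weight shapes")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)
        for attr in ("edge_lo", "edge_hi"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != pts.shape:
                    raise ValueError(f"{attr} must match the point array shape")
                object.__setattr__(self, attr, val)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def total_area(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# design operations


def equal_area_partition(
    r_inner_first: float,
    r_outer_first: float,
    n_rings: int,
    inclination: float = 0.0,
) -> np.ndarray:
    """Ring boundary radii giving ``n_rings`` annuli of equal surface area.

    The innermost annulus is fixed by ``[r_inner_first, r_outer_first]`` and
    outer boundaries follow from the equal-area condition.  For a common
    inclination the 1/cos(inclination) area factor cancels, so the closed
    form ``r_k = sqrt(r_0² + k·(r_1² − r_0²))`` holds for any inclination.

    Returns ``n_rings + 1`` boundary radii (mm).
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if r_inner_first < 0 or r_outer_first <= r_inner_first:
        raise ValueError("require 0 <= r_inner_first < r_outer_first")
    if not 0.0 <= inclination < 90.0:
        raise ValueError("inclination must be in [0, 90)")
    r0sq = r_inner_first**2
    step = r_outer_first**2 - r0sq
    k = np.arange(n_rings + 1)
    return np.sqrt(r0sq + k * step)


def element_area(element: Element) -> float:
    """Analytic surface area of an element, mm²."""
    if isinstance(element, RingElement):
        flat = math.pi * (element.r_outer**2 - element.r_inner**2)
        return flat / math.cos(math.radians(element.inclination))
    if isinstance(element, SphericalCap):
        return 2.0 * math.pi * element.radius_of_curvature * element.cap_height
    raise TypeError(f"unsupported element type: {type(element).__name__}")


def _mesh_ring(element: RingElement, spacing: float) -> SurfaceMesh:
    theta = math.radians(element.inclination)
    slant = (element.r_outer - element.r_inner) / math.cos(theta)
    if spacing > slant:
        warnings.warn(
            f"mesh spacing {spacing} mm exceeds the {slant:.3g} mm radial extent "
            f"of element {element.name!r}; emitting a single band",
            DegenerateMeshWarning,
            stacklevel=3,
        )
    n_bands = max(1, math.ceil(slant / spacing))
    edges = np.linspace(element.r_inner, element.r_outer, n_bands + 1)
    cos_t = math.cos(theta)
    pts, los, his, wts = [], [], [], []
    for k in range(n_bands):
        r1, r2 = edges[k], edges[k + 1]
        band_area = math.pi * (r2 * r2 - r1 * r1) / cos_t
        rm = 0.5 * (r1 + r2)
        # even count, half-bin offset: the point set is mirror symmetric in
        # both x and y, so mirrored phantoms give exactly mirrored signals
        n_az = 2 * max(4, math.ceil(math.pi * rm / spacing))
        phi = (np.arange(n_az) + 0.5) * (2.0 * math.pi / n_az)
        cphi, sphi = np.cos(phi), np.sin(phi)
        for radius, dest in ((rm, pts), (r1, los), (r2, his)):
            z = float(element.elevation(radius))
            dest.append(
                np.column_stack([radius * cphi, radius * sphi, np.full(n_az, z)])
            )
        wts.append(np.full(n_az, band_area / n_az))
    return SurfaceMesh(
        np.vstack(pts),
        np.concatenate(wts),
        element,
        edge_lo=np.vstack(los),
        edge_hi=np.vstack(his),
    )


def _mesh_cap(element: SphericalCap, spacing: float) -> SurfaceMesh:
    rho = element.radius_of_curvature
    psi_max = math.asin(0.5 * element.aperture_diameter / rho)
    arc = rho * psi_max
    if spacing > arc:
        warnings.warn(
            f"mesh spacing {spacing} mm exceeds the {arc:.3g} mm arc extent of "
            f"element {element.name!r}; emitting a single band",
            DegenerateMeshWarning,
            stacklevel=3,
        )
    n_bands = max(1, math.ceil(arc / spacing))
    psi_edges = np.linspace(0.0, psi_max, n_bands + 1)
    pts, los, his, wts = [], [], [], []
    for k in range(n_bands):
        p1, p2 = psi_edges[k], psi_edges[k + 1]
        band_area = 2.0 * math.pi * rho * rho * (math.cos(p1) - math.cos(p2))
        pm = 0.5 * (p1 + p2)
        rm = rho * math.sin(pm)
        n_az = 2 * max(4, math.ceil(math.pi * rm / spacing))
        phi = (np.arange(n_az) + 0.5) * (2.0 * math.pi / n_az)
        cphi, sphi = np.cos(phi), np.sin(phi)
        # cap touches z = 0 at the axis; every point lies on the sphere
        for psi, dest in ((pm, pts), (p1, los), (p2, his)):
            r = rho * math.sin(psi)
            z = rho * (1.0 - math.cos(psi))
            dest.append(np.column_stack([r * cphi, r * sphi, np.full(n_az, z)]))
        wts.append(np.full(n_az, band_area / n_az))
    return SurfaceMesh(
        np.vstack(pts),
        np.concatenate(wts),
        element,
        edge_lo=np.vstack(los),
        edge_hi=np.vstack(his),
    )


def surface_mesh(element: Element, max_point_spacing: float) -> SurfaceMesh:
    """Discretize an element into quadrature points and area weights.

    Concentric bands of points honour ``max_point_spacing`` in both the
    radial (slant) and azimuthal directions; each band carries its analytic
    area, so the weight sum is exact for any spacing.
    """
    if max_point_spacing <= 0:
        raise ValueError("max_point_spacing must be positive")
    if isinstance(element, RingElement):
        return _mesh_ring(element, max_point_spacing)
    if isinstance(element, SphericalCap):
        return _mesh_cap(element, max_point_spacing)
    raise TypeError(f"unsupported element type: {type(element).__name__}")


def normal_incidence_depth_range(ring: RingElement) -> tuple[float, float]:
    """On-axis depth range rated for normal incidence on an inclined ring.

    A surface point at radius r is rated for the axial source depth

        z(r) = r / tan(inclination) − (r − r_base) · tan(inclination),

    the cotangent focus of the ring radius reduced by the ring's elevation
    above the base plane.  z is linear in r, so the range endpoints come from
    the element edges.  A flat ring (inclination 0) has no finite
    normal-incidence depth and returns ``(0.0, inf)``.
    """
    if ring.is_flat:
        return (0.0, math.inf)
    t = math.tan(math.radians(ring.inclination))
    z = [r / t - (r - ring.r_base) * t for r in (ring.r_inner, ring.r_outer)]
    return (min(z), max(z))


# ---------------------------------------------------------------------------
# geometry configuration files

_TYPE_TAGS = {"flat_ring", "cone_ring", "spherical_cap"}


def _element_from_dict(d: dict) -> Element:
    kind = d.get("type")
    if kind not in _TYPE_TAGS:
        raise ValueError(f"unknown element type {kind!r}")
    name = d.get("name", kind)
    if kind == "spherical_cap":
        return SphericalCap(
            radius_of_curvature=float(d["radius_of_curvature"]),
            aperture_diameter=float(d["aperture_diameter"]),
            name=name,
        )
    inclination = float(d.get("inclination_deg", 0.0)) if kind == "cone_ring" else 0.0
    r_base = d.get("r_base")
    return RingElement(
        r_inner=float(d["r_inner"]),
        r_outer=float(d["r_outer"]),
        inclination=inclination,
        r_base=None if r_base is None else float(r_base),
        name=name,
    )


def _element_to_dict(e: Element) -> dict:
    if isinstance(e, SphericalCap):
        return {
            "name": e.name,
            "type": "spherical_cap",
            "radius_of_curvature": e.radius_of_curvature,
            "aperture_diameter": e.aperture_diameter,
        }
    d = {"name": e.name, "r_inner": e.r_inner, "r_outer": e.r_outer}
    if e.is_flat:
        d["type"] = "flat_ring"
    else:
        d.update(type="cone_ring", inclination_deg=e.inclination, r_base=e.r_base)
    return d


def _bundled_configs() -> dict:
    text = resources.files("ringpam").joinpath("data/geometries.yaml").read_text()
    return yaml.safe_load(text)


def bundled_geometry_names() -> list[str]:
    return sorted(_bundled_configs())


def load_geometry(source: Union[str, Path]) -> DetectorArray:
    """Load a detector geometry by bundled name or from a YAML/JSON file."""
    configs = _bundled_configs()
    if isinstance(source, str) and source in configs:
        entry = configs[source]
        name = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"geometry file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if "elements" in data:
            entry, name = data, data.get("name", path.stem)
        elif len(data) == 1:
            name, entry = next(iter(data.items()))
        else:
            raise ValueError(
                f"{path} contains multiple geometries; load one by name instead"
            )
    elements = tuple(_element_from_dict(d) for d in entry["elements"])
    return DetectorArray(elements, name=name)


def save_geometry(array: DetectorArray, path: Union[str, Path]) -> Path:
    path = Path(path)
    doc = {array.name: {"elements": [_element_to_dict(e) for e in array.elements]}}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# reference arrays

#: radii (mm) of the etched separation lines patterning the fabricated array
FABRICATED_ETCHED_RADII = (7.75, 10.75, 13.25, 15.25, 17.25)
#: cone inclination of the fabricated array's outer rings, degrees
FABRICATED_CONE_ANGLE = 25.0


def outermost_etched_ring() -> RingElement:
    """Outermost fabricated ring over its full etched bounds (15.25–17.25 mm).

    Used for the device's depth-limit rating; the simulation fixture
    :func:`fabricated_array` instead trims the insensitive etched lines off
    the active areas.
    """
    return RingElement(
        FABRICATED_ETCHED_RADII[-2],
        FABRICATED_ETCHED_RADII[-1],
        FABRICATED_CONE_ANGLE,
        r_base=FABRICATED_ETCHED_RADII[0],
        name="ring4_etched",
    )


def fabricated_array() -> DetectorArray:
    """The five-element fabricated array: flat centre ring + four 25° rings.

    Active radial bounds follow from the etched radii (7.75, 10.75, 13.25,
    15.25, 17.25 mm) with the 0.5 mm etched lines insensitive (split
    half-and-half between neighbours); the cone meets the flat plane at
    7.75 mm.
    """
    return load_geometry("fabricated_array")


def measurement_array() -> DetectorArray:
    """Fabricated-array subset used for measurements: flat + three outer rings."""
    return fabricated_array().subset(
        ["flat_ring", "ring2", "ring3", "ring4"], name="measurement_array"
    )


def comparison_geometries() -> dict[str, DetectorArray]:
    """The four simulated design-study geometries, equal outer diameter 28 mm."""
    return {
        name: load_geometry(name)
        for name in (
            "spherical_cap_25mm",
            "axicon_25deg",
            "planar_ring_array",
            "conical_ring_array",
        )
    }
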
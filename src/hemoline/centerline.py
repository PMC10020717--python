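"""Centerline-based compact representation.

The whole pipeline hangs off an ordered, equally spaced (default 2 mm)
discrete centerline.  Per centerline point a cross-section plane is defined
orthogonal to the local tangent; static pressure is averaged on each plane
and wall shear stress (WSS) on the vessel segment between two adjacent
planes.  Cross-section lumen shapes are additionally rasterized to fixed-size
binary images (default 68x68 over a fixed 50 mm physical window) for the
shape autoencoder.

In-plane axes follow a rotation-minimizing (parallel-transport) frame so
that section images do not spin as the centerline sweeps around the arch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .exceptions import GeometryError, InputError, MissingDataError

DEFAULT_SPACING_MM = 2.0
DEFAULT_GRID = 68
DEFAULT_WINDOW_MM = 50.0

REGIONS = ("LVOT", "valve", "ascending", "arch", "descending")


@dataclass
class Centerline:
    """Ordered 3D points at fixed arc-length spacing.

    Attributes
    ----------
    points : (N, 3) float array, mm
    arc_length : (N,) float array, mm, strictly increasing from 0
    spacing : nominal consecutive-point distance, mm
    regions : optional (N,) array of anatomical labels (see ``REGIONS``)
    """

    points: np.ndarray
    arc_length: np.ndarray
    spacing: float = DEFAULT_SPACING_MM
    regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InputError("centerline points must be an (N, 3) array")
        if len(self.points) != len(self.arc_length):
            raise InputError("points and arc_length length mismatch")
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
            if len(self.regions) != len(self.points):
                raise InputError("regions length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def region_indices(self, region: str) -> np.ndarray:
        if self.regions is None:
            raise InputError("centerline has no region labels")
        return np.flatnonzero(self.regions == region)


@dataclass
class SectionFrame:
    """Cross-section plane: origin, unit normal (tangent) and in-plane axes."""

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray


@dataclass
class ShapeImage:
    """Binary occupancy raster of a lumen cross-section.

    ``grid`` is a (grid_size, grid_size) boolean array over a square physical
    window of ``window_mm`` centred on the section origin, axes aligned with
    the section's rotation-minimizing frame.
    """

    grid: np.ndarray
    window_mm: float
    section_index: int = -1

    @property
    def grid_size(self) -> int:
        return self.grid.shape[0]

    @property
    def occupied_fraction(self) -> float:
        return float(self.grid.mean())

    def area_mm2(self) -> float:
        """Pixel-count estimate of the lumen area."""
        px = self.window_mm / self.grid.shape[0]
        return float(self.grid.sum()) * px * px


def _densify(curve: np.ndarray, resolution: float) -> np.ndarray:
    """Resample a polyline at fine, approximately equal arc steps."""
    curve = np.asarray(curve, dtype=float)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / resolution)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, curve[:, k]) for k in range(3)])


def resample_centerline(
    curve: np.ndarray, spacing: float = DEFAULT_SPACING_MM
) -> Centerline:
    """Resample a rectifiable 3D path to equally spaced centerline points.

    Points are stepped so that each *consecutive Euclidean distance* equals
    ``spacing`` (the last partial interval is dropped); on a straight curve
    this coincides with equal arc-length steps and gives
    ``floor(L / spacing) + 1`` points.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 3 or len(curve) < 2:
        raise InputError("curve must be an (M>=2, 3) array")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = float(seg.sum())
    if total < 2.0 * spacing:
        raise InputError(
            f"curve length {total:.3f} mm shorter than 2*spacing={2 * spacing:.3f} mm"
        )
    dense = _densify(curve, resolution=min(spacing / 40.0, 0.1))

    points = [dense[0]]
    j = 0  # index into dense polyline
    while True:
        p = points[-1]
        # advance to the first dense vertex farther than `spacing` from p
        while j + 1 < len(dense) and np.linalg.norm(dense[j + 1] - p) < spacing:
            j += 1
        if j + 1 >= len(dense):
            break
        # exact sphere/segment intersection between dense[j] and dense[j+1]
        a, b = dense[j], dense[j + 1]
        d = b - a
        f = a - p
        aa = float(d @ d)
        bb = 2.0 * float(f @ d)
        cc = float(f @ f) - spacing * spacing
        disc = bb * bb - 4 * aa * cc
        if disc < 0:  # numerical corner: fall back to the far vertex
            t = 1.0
        else:
            t = (-bb + np.sqrt(disc)) / (2 * aa)
            t = min(max(t, 0.0), 1.0)
        points.append(a + t * d)

    pts = np.asarray(points)
    arc = spacing * np.arange(len(pts))
    return Centerline(points=pts, arc_length=arc, spacing=spacing)


def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(steps < 1e-12):
        raise GeometryError("duplicate consecutive centerline points (degenerate tangent)")
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise GeometryError("duplicate consecutive centerline points (degenerate tangent)")
    return t / norms


def section_planes(centerline: Centerline) -> list[SectionFrame]:
    """One centerline-orthogonal plane per point.

    Normals are the local tangents; in-plane axes (u, v) are parallel
    transported along the curve (rotation-minimizing), so consecutive frames
    never flip or spin.
    """
    pts = centerline.points
    tang = _tangents(pts)

    # initial u: project the least-aligned coordinate axis into the first plane
    axis = np.eye(3)[np.argmin(np.abs(tang[0]))]
    u = axis - (axis @ tang[0]) * tang[0]
    u /= np.linalg.norm(u)

    frames: list[SectionFrame] = []
    for i in range(len(pts)):
        t = tang[i]
        u = u - (u @ t) * t  # transport previous u into the new plane
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise GeometryError(f"degenerate frame transport at point {i}")
        u = u / nu
        v = np.cross(t, u)
        frames.append(SectionFrame(origin=pts[i], normal=t, u=u, v=v))
    return frames


def average_pressure(samples, section_index: int) -> float:
    """Cross-section averaged static pressure: arithmetic mean of the plane's samples."""
    values = samples.pressure_values(section_index)
    if len(values) == 0:
        raise MissingDataError(f"no pressure samples for section {section_index}")
    return float(np.mean(values))


def average_wss(samples, segment_index: int) -> float:
    """Segment-averaged WSS: mean of wall-sample magnitudes between sections i and i+1."""
    values = samples.wss_values(segment_index)
    if len(values) == 0:
        raise MissingDataError(f"no WSS samples for segment {segment_index}")
    return float(np.mean(np.abs(values)))


def rasterize_section(
    section,
    grid_size: int = DEFAULT_GRID,
    window_mm: float = DEFAULT_WINDOW_MM,
) -> ShapeImage:
    """Rasterize a cross-section lumen polygon to a binary occupancy image.

    The raster covers a fixed physical window centred on the section origin
    and oriented by the section's in-plane frame, so absolute size is
    preserved across sections (shape and scale both reach the autoencoder).
    A pixel is occupied when its centre lies inside the polygon.
    """
    xy = section.boundary_local
    if xy is None or len(xy) < 3:
        raise InputError("section boundary polygon is empty or degenerate")
    half = window_mm / 2.0
    if np.max(np.abs(xy)) > half:
        raise GeometryError(
            f"section boundary (extent {np.max(np.abs(xy)):.1f} mm) exceeds the "
            f"{window_mm:.0f} mm raster window"
        )
    px = window_mm / grid_size
    # pixel-centre coordinates: row r centre at -half + (r + 0.5) * px
    rc = (xy + half) / px - 0.5
    mask = polygon2mask((grid_size, grid_size), rc[:, ::-1])  # (row=y, col=x)
    if not mask.any():
        raise InputError("rasterization produced an empty image (degenerate polygon)")
    return ShapeImage(grid=mask, window_mm=window_mm, section_index=getattr(section, "index", -1))


def build_profile(case, samples):
    """Assemble averaged pressure/WSS per centerline point into a profile.

    WSS of segment (i, i+1) is assigned to point i; the last point repeats the
    last segment value so input and output sequences share length N.
    """
    from .oracle import HemodynamicProfile  # local import avoids a module cycle

    n = case.centerline.n_points
    missing = [i for i in range(n) if len(samples.pressure_values(i)) == 0]
    missing += [i for i in range(n - 1) if len(samples.wss_values(i)) == 0]
    if missing:
        raise MissingDataError(f"missing samples for sections/segments: {sorted(set(missing))}")

    pressure = np.array([average_pressure(samples, i) for i in range(n)])
    wss_seg = np.array([average_wss(samples, i) for i in range(n - 1)])
    wss = np.append(wss_seg, wss_seg[-1])
    return HemodynamicProfile(
        pressure=pressure,
        wss=wss,
        flow_rate=samples.flow_rate,
        source="oracle",
    )
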
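"""Synthetic aorta + aortic-valve geometry generator.

Produces anatomically plausible parametric flow domains standing in for
segmented patient surfaces: a candy-cane centerline (straight LVOT/valve/
ascending limb, ~180 deg arch, descending limb), a smooth lumen-radius
profile between segment diameters, and a leaflet-bounded "tri-star" orifice
polygon in the valve region whose area equals the prescribed aortic valve
area (AVA).

Anatomical region order along the centerline is always
LVOT -> valve -> ascending -> arch -> descending.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .centerline import (
    DEFAULT_SPACING_MM,
    Centerline,
    SectionFrame,
    resample_centerline,
    section_planes,
)
from .exceptions import ConfigurationError, GeometryError

# fractions of total centerline length per anatomical segment (arch fraction
# is re-derived when an explicit arch radius is given)
SEGMENT_FRACTIONS = {
    "LVOT": 0.10,
    "valve": 0.05,
    "ascending": 0.30,
    "arch": 0.25,
    "descending": 0.30,
}

# blend windows around the valve (mm); lumen area may change steeply here
VALVE_ENTRANCE_BLEND_MM = 12.0
VALVE_EXIT_BLEND_MM = 24.0

N_BOUNDARY_VERTICES = 64


@dataclass
class GeometryParams:
    """Parametric description of one synthetic case.

    Units: AVA in cm^2, all lengths/diameters in mm.
    """

    ava: float = 0.8
    lvot_diameter: float = 22.0
    ascending_diameter: float = 30.0
    descending_diameter: float = 24.0
    arch_radius: float | None = None  # None -> semicircle consuming 25% of length
    total_length: float = 240.0
    n_leaflets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.3 <= self.ava <= 2.5):
            raise ConfigurationError(f"AVA {self.ava} cm^2 outside [0.3, 2.5]")
        for name in ("lvot_diameter", "ascending_diameter", "descending_diameter"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.total_length <= 0:
            raise ConfigurationError("total_length must be positive")
        if self.n_leaflets < 2:
            raise ConfigurationError("n_leaflets must be >= 2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeometryParams":
        return cls(**json.loads(text))


@dataclass
class CrossSection:
    """Planar lumen cross-section at one centerline point.

    ``boundary`` is the closed polygon in 3D (mm); ``boundary_local`` the same
    polygon in the section's in-plane (u, v) coordinates.  In the valve region
    the boundary is the leaflet-bounded orifice only.
    """

    origin: np.ndarray
    normal: np.ndarray
    boundary: np.ndarray
    boundary_local: np.ndarray
    area: float
    region: str
    index: int = -1
    u: np.ndarray | None = None  # in-plane axis mapping local x
    v: np.ndarray | None = None  # in-plane axis mapping local y


@dataclass
class CaseGeometry:
    """A synthetic (or user-supplied) flow domain: centerline + cross-sections."""

    centerline: Centerline
    sections: list[CrossSection]
    label: str = ""
    params: GeometryParams | None = None

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.sections])

    @property
    def regions(self) -> np.ndarray:
        return np.asarray(self.centerline.regions)

    def valve_indices(self) -> np.ndarray:
        return self.centerline.region_indices("valve")

    def transition_mask(self) -> np.ndarray:
        """Points inside the valve or its entrance/exit blend windows.

        Lumen area changes steeply here by construction; smoothness
        guarantees apply only outside this mask.
        """
        s = self.centerline.arc_length
        mask = self.regions == "valve"
        vi = np.flatnonzero(mask)
        if len(vi):
            s0, s1 = s[vi[0]], s[vi[-1]]
            mask = mask | ((s >= s0 - VALVE_ENTRANCE_BLEND_MM) & (s <= s1 + VALVE_EXIT_BLEND_MM))
        return mask


# ---------------------------------------------------------------------------
# cohort sampling


DEFAULT_COHORT_CONFIG = {
    # AVA range covers severe stenosis up to healthy valves (> 1 cm^2)
    "ava": (0.4, 2.0),
    "lvot_diameter": (20.0, 24.0),
    # upper bound keeps the lumen radius below the arch curvature radius
    # (~18 mm for the shortest default cases), avoiding tube fold-over
    "ascending_diameter": (26.0, 32.0),
    "descending_diameter": (21.0, 27.0),
    # keeps floor(L/2)+1 within 110-130 points at 2 mm spacing
    "total_length": (222.0, 258.0),
}


def sample_geometry_params(
    cohort_config: dict | None = None, seed: int = 0
) -> GeometryParams:
    """Draw one case's parameters uniformly from the configured cohort ranges."""
    cfg = dict(DEFAULT_COHORT_CONFIG)
    if cohort_config:
        cfg.update(cohort_config)
    rng = np.random.default_rng(seed)
    values = {}
    for name, (lo, hi) in cfg.items():
        if lo > hi:
            raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        values[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return GeometryParams(seed=seed, **values)


# ---------------------------------------------------------------------------
# case construction


def _segment_lengths(params: GeometryParams) -> dict[str, float]:
    L = params.total_length
    if params.arch_radius is None:
        arch_len = SEGMENT_FRACTIONS["arch"] * L
    else:
        arch_len = np.pi * params.arch_radius
        if arch_len >= 0.7 * L:
            raise GeometryError("arch_radius consumes more than 70% of total length")
    rest = L - arch_len
    straight_total = sum(
        f for k, f in SEGMENT_FRACTIONS.items() if k != "arch"
    )
    out = {
        k: rest * SEGMENT_FRACTIONS[k] / straight_total
        for k in ("LVOT", "valve", "ascending", "descending")
    }
    out["arch"] = arch_len
    return out


def _analytic_curve(params: GeometryParams, n_dense: int = 4000) -> np.ndarray:
    """Candy-cane space curve sampled densely by arc length."""
    seg = _segment_lengths(params)
    L = params.total_length
    l_up = seg["LVOT"] + seg["valve"] + seg["ascending"]
    l_arch = seg["arch"]
    R = l_arch / np.pi
    s = np.linspace(0.0, L, n_dense)
    pts = np.empty((n_dense, 3))
    for i, si in enumerate(s):
        if si <= l_up:
            pts[i] = (0.0, 0.0, si)
        elif si <= l_up + l_arch:
            phi = (si - l_up) / R
            pts[i] = (R * (1.0 - np.cos(phi)), 0.0, l_up + R * np.sin(phi))
        else:
            pts[i] = (2.0 * R, 0.0, l_up - (si - l_up - l_arch))
    return pts


def _region_labels(arc: np.ndarray, params: GeometryParams) -> np.ndarray:
    seg = _segment_lengths(params)
    bounds = np.cumsum([seg[k] for k in ("LVOT", "valve", "ascending", "arch")])
    labels = np.empty(len(arc), dtype=object)
    labels[:] = "descending"
    labels[arc < bounds[3]] = "arch"
    labels[arc < bounds[2]] = "ascending"
    labels[arc < bounds[1]] = "valve"
    labels[arc < bounds[0]] = "LVOT"
    return labels.astype(str)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _radius_profile(arc: np.ndarray, params: GeometryParams) -> np.ndarray:
    """Lumen-equivalent radius along the centerline (mm), C1-smooth.

    Plateaus at the segment diameters with smoothstep blends; the valve
    plateau sits at the orifice-equivalent radius sqrt(AVA/pi).
    """
    seg = _segment_lengths(params)
    s_v0 = seg["LVOT"]
    s_v1 = s_v0 + seg["valve"]
    s_a1 = s_v1 + seg["ascending"]
    s_ar1 = s_a1 + seg["arch"]
    L = params.total_length

    r_lvot = params.lvot_diameter / 2.0
    r_asc = params.ascending_diameter / 2.0
    r_desc = params.descending_diameter / 2.0
    r_valve = np.sqrt(params.ava * 100.0 / np.pi)  # cm^2 -> mm^2

    r = np.full_like(arc, r_desc)
    # LVOT plateau then entrance blend into the valve radius
    b0 = max(s_v0 - VALVE_ENTRANCE_BLEND_MM, 0.0)
    m = arc <= s_v0
    r[m] = r_lvot + (r_valve - r_lvot) * _smoothstep((arc[m] - b0) / (s_v0 - b0))
    # valve plateau
    m = (arc > s_v0) & (arc <= s_v1)
    r[m] = r_valve
    # exit blend into ascending plateau: ease-out only, so the jet expands
    # immediately past the orifice (the pressure minimum stays at the valve)
    b1 = min(s_v1 + VALVE_EXIT_BLEND_MM, s_a1)
    m = (arc > s_v1) & (arc <= b1)
    t = np.clip((arc[m] - s_v1) / (b1 - s_v1), 0.0, 1.0)
    r[m] = r_valve + (r_asc - r_valve) * (1.0 - (1.0 - t) ** 2)
    m = (arc > b1) & (arc <= s_a1)
    r[m] = r_asc
    # arch: gentle taper ascending -> descending
    m = (arc > s_a1) & (arc <= s_ar1)
    r[m] = r_asc + (r_desc - r_asc) * _smoothstep((arc[m] - s_a1) / (s_ar1 - s_a1))
    return r


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _orifice_polygon(ava_cm2: float, n_leaflets: int, n_vertices: int) -> np.ndarray:
    """Leaflet-bounded 'tri-star' orifice, scaled to the target area exactly."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = 1.0 + 0.28 * np.cos(n_leaflets * theta)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    scale = np.sqrt(ava_cm2 * 100.0 / _polygon_area(xy))
    return xy * scale


def _ellipse_polygon(radius: float, ellipticity: float, n_vertices: int) -> np.ndarray:
    """Area-preserving mildly elliptic lumen boundary.

    The inscribed n-gon is rescaled so its shoelace area equals pi*a*b
    exactly; section areas then match the analytic radius profile.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a = radius * (1.0 + ellipticity)
    b = radius / (1.0 + ellipticity)
    xy = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    return xy * np.sqrt(np.pi * a * b / _polygon_area(xy))


def build_case(params: GeometryParams, label: str = "") -> CaseGeometry:
    """Build the full synthetic flow domain for one parameter set.

    Deterministic given ``params`` (mild per-section ellipticity jitter is
    driven by ``params.seed``).  Valve-region cross-sections carry the
    leaflet-bounded orifice polygon whose area equals AVA to within float
    round-off.
    """
    dense = _analytic_curve(params)
    cl = resample_centerline(dense, spacing=DEFAULT_SPACING_MM)
    cl.regions = _region_labels(cl.arc_length, params)
    frames = section_planes(cl)

    radii = _radius_profile(cl.arc_length, params)
    rng = np.random.default_rng(params.seed)
    ellip = np.clip(rng.normal(0.0, 0.03, cl.n_points), -0.08, 0.08)

    sections: list[CrossSection] = []
    for i, fr in enumerate(frames):
        region = str(cl.regions[i])
        if region == "valve":
            xy = _orifice_polygon(params.ava, params.n_leaflets, N_BOUNDARY_VERTICES)
        else:
            xy = _ellipse_polygon(radii[i], float(ellip[i]), N_BOUNDARY_VERTICES)
        area = _polygon_area(xy)
        if area <= 0:
            raise GeometryError(f"degenerate lumen section at point {i}")
        b3d = fr.origin + xy[:, 0:1] * fr.u + xy[:, 1:2] * fr.v
        sections.append(
            CrossSection(
                origin=fr.origin,
                normal=fr.normal,
                boundary=b3d,
                boundary_local=xy,
                area=area,
                region=region,
                index=i,
                u=fr.u,
                v=fr.v,
            )
        )
    case = CaseGeometry(centerline=cl, sections=sections, label=label, params=params)
    _check_no_fold_over(case)
    return case


def _check_no_fold_over(case: CaseGeometry) -> None:
    """Reject lumens that would self-intersect around the arch.

    A tube folds over when the section radius exceeds the local curvature
    radius of the centerline; for the semicircular arch that is the arch
    radius itself.
    """
    seg = _segment_lengths(case.params) if case.params else None
    if seg is None:
        return
    arch_R = seg["arch"] / np.pi
    arch_idx = np.flatnonzero(case.regions == "arch")
    if len(arch_idx) == 0:
        return
    max_r = max(
        np.max(np.linalg.norm(case.sections[i].boundary_local, axis=1)) for i in arch_idx
    )
    if max_r >= arch_R:
        raise GeometryError(
            f"lumen radius {max_r:.1f} mm exceeds arch curvature radius {arch_R:.1f} mm "
            "(self-intersecting geometry)"
        )


def build_straight_tube(
    radius_mm: float = 12.0,
    length_mm: float = 240.0,
    region: str = "ascending",
    spacing: float = DEFAULT_SPACING_MM,
) -> CaseGeometry:
    """Degenerate test geometry: a straight uniform circular tube, no valve.

    With a single region and constant area the oracle applies no contraction
    and no expansion loss, so the pressure profile shows friction only.
    """
    n_dense = max(int(length_mm / 0.5), 10)
    curve = np.column_stack([
        np.zeros(n_dense), np.zeros(n_dense), np.linspace(0.0, length_mm, n_dense)
    ])
    cl = resample_centerline(curve, spacing=spacing)
    cl.regions = np.full(cl.n_points, region, dtype=object).astype(str)
    frames = section_planes(cl)
    sections = []
    for i, fr in enumerate(frames):
        xy = _ellipse_polygon(radius_mm, 0.0, N_BOUNDARY_VERTICES)
        sections.append(CrossSection(
            origin=fr.origin, normal=fr.normal,
            boundary=fr.origin + xy[:, 0:1] * fr.u + xy[:, 1:2] * fr.v,
            boundary_local=xy, area=_polygon_area(xy), region=region,
            index=i, u=fr.u, v=fr.v,
        ))
    return CaseGeometry(centerline=cl, sections=sections, label="straight-tube")


# ---------------------------------------------------------------------------
# surface export


def export_surface(case: CaseGeometry, path: str | Path):
    """Export the lumen as a watertight triangulated STL surface.

    The tube is lofted through the section boundary rings (vertex
    correspondence follows the rotation-minimizing frame) and capped with
    triangle fans at both ends.
    """
    import trimesh

    rings = [np.asarray(s.boundary, dtype=float) for s in case.sections]
    m = len(rings[0])
    verts = np.vstack(rings)
    faces = []
    for i in range(len(rings) - 1):
        base0, base1 = i * m, (i + 1) * m
        for k in range(m):
            k2 = (k + 1) % m
            faces.append([base0 + k, base1 + k, base1 + k2])
            faces.append([base0 + k, base1 + k2, base0 + k2])
    # end caps
    c0 = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    for k in range(m):
        k2 = (k + 1) % m
        faces.append([c0, k2, k])
        base = (len(rings) - 1) * m
        faces.append([c0 + 1, base + k, base + k2])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.export(str(path))
    return mesh
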
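"""Reduced-order quasi-1D hemodynamics oracle.

Replaces the 3D CFD stage with a marched extended-Bernoulli model along the
centerline: per-point mean velocity from continuity (V = Q/A, with a
contraction coefficient applied inside the valve so the throat velocity is
the vena-contracta velocity), Darcy friction losses (laminar 64/Re, Blasius
0.316 Re^-1/4 for Re >= 2300), and a Borda-Carnot expansion loss distributed
linearly over a recovery length downstream of the valve.  This produces the
characteristic pattern of a steep transvalvular pressure drop followed by
partial pressure recovery in the ascending aorta, a valve-region WSS peak,
and decaying jet-elevated WSS downstream.

Pressure is reported in mmHg (internal physics in SI), WSS in Pa.  Profiles
are shifted post hoc so the outlet pressure equals a prescribed value
(default 130 mmHg), which leaves all pressure differences untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, PhysicsError

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322


@dataclass
class OracleParams:
    """Physical constants and closure parameters of the reduced-order model."""

    rho: float = 1050.0  # blood density, kg/m^3
    mu: float = 0.0035  # dynamic (infinite-shear) viscosity, Pa*s
    cc: float = 0.85  # orifice contraction coefficient
    expansion_k: float = 1.0  # Borda-Carnot loss coefficient
    recovery_length: float = 40.0  # mm, pressure-recovery / jet-decay scale
    jet_wss_gain: float = 0.02  # jet WSS term as a fraction of vc dynamic pressure
    sample_noise_frac: float = 0.05  # field-sample spread vs local dynamic pressure
    outlet_pressure: float = 130.0  # mmHg
    include_friction: bool = True  # disable for inviscid Bernoulli checks

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise InputError("rho and mu must be positive")
        if not (0.0 < self.cc <= 1.0):
            raise InputError("contraction coefficient must be in (0, 1]")
        if self.recovery_length <= 0:
            raise InputError("recovery_length must be positive")


@dataclass
class HemodynamicProfile:
    """Per-centerline-point averaged pressure (mmHg) and WSS (Pa)."""

    pressure: np.ndarray
    wss: np.ndarray
    flow_rate: float = 0.0  # ml/s
    source: str = "oracle"  # "oracle" | "surrogate"

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        if self.pressure.shape != self.wss.shape or self.pressure.ndim != 1:
            raise InputError("pressure and wss must be 1D arrays of equal length")
        if np.any(self.wss < -1e-12):
            raise InputError("WSS values must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.pressure)


def _friction_factor(re: np.ndarray) -> np.ndarray:
    """Darcy friction factor: laminar below Re 2300, Blasius above."""
    re = np.maximum(re, 1e-9)
    return np.where(re < 2300.0, 64.0 / re, 0.316 * re ** -0.25)


def solve_profile(case, flow_rate: float, params: OracleParams | None = None) -> HemodynamicProfile:
    """March the extended-Bernoulli model along the centerline.

    Parameters
    ----------
    case : CaseGeometry
    flow_rate : ml/s (> 0)
    """
    if params is None:
        params = OracleParams()
    if flow_rate <= 0:
        raise InputError("flow_rate must be positive")

    areas_mm2 = case.areas
    if np.any(areas_mm2 <= 0):
        raise PhysicsError("non-positive lumen area along the centerline")

    s = case.centerline.arc_length * 1e-3  # m
    a = areas_mm2 * 1e-6  # m^2
    q = flow_rate * 1e-6  # m^3/s
    rho, mu = params.rho, params.mu

    regions = np.asarray(case.centerline.regions)
    valve = regions == "valve"
    a_eff = np.where(valve, a * params.cc, a)
    v = q / a_eff  # effective mean velocity, m/s
    d = 2.0 * np.sqrt(a_eff / np.pi)  # hydraulic diameter, m

    # cumulative Darcy friction loss
    if params.include_friction:
        re = rho * v * d / mu
        f = _friction_factor(re)
        dp_step = f[:-1] * (np.diff(s) / d[:-1]) * 0.5 * rho * v[:-1] ** 2
        fric = np.concatenate([[0.0], np.cumsum(dp_step)])
    else:
        f = np.zeros_like(v)
        fric = np.zeros_like(v)

    # Borda-Carnot expansion loss + jet WSS, only when a valve is present
    bc = np.zeros_like(v)
    jet = np.zeros_like(v)
    if valve.any():
        i_vc = int(np.flatnonzero(valve)[np.argmin(a_eff[valve])])  # throat
        # the expansion loss begins where the lumen actually widens: extend
        # the exit over any trailing points still at the orifice area
        i_exit = int(np.flatnonzero(valve)[-1])
        a_min = float(a_eff[valve].min())
        while i_exit + 1 < len(a_eff) and a_eff[i_exit + 1] <= a_min * 1.001:
            i_exit += 1
        v_vc = float(v[i_vc])
        rec = params.recovery_length * 1e-3
        s_end = s[i_exit] + rec
        i_ds = int(np.searchsorted(s, s_end))
        i_ds = min(i_ds, len(s) - 1)
        v_ds = float(v[i_ds])
        loss = params.expansion_k * 0.5 * rho * (v_vc - v_ds) ** 2
        bc = loss * np.clip((s - s[i_exit]) / rec, 0.0, 1.0)

        downstream = s >= s[i_vc]
        jet[downstream] = (
            params.jet_wss_gain
            * 0.5
            * rho
            * v_vc**2
            * np.exp(-(s[downstream] - s[i_vc]) / rec)
        )

    p_pa = 0.5 * rho * (v[0] ** 2 - v**2) - fric - bc
    pressure = p_pa * MMHG_PER_PA

    # WSS: pipe-friction estimate plus the decaying jet term
    f_wss = _friction_factor(rho * v * d / mu)
    wss = (f_wss / 8.0) * rho * v**2 + jet

    profile = HemodynamicProfile(
        pressure=pressure, wss=wss, flow_rate=flow_rate, source="oracle"
    )
    return shift_pressure(profile, params.outlet_pressure)


def shift_pressure(profile: HemodynamicProfile, outlet_pressure: float = 130.0) -> HemodynamicProfile:
    """Add a constant so the last pressure value equals ``outlet_pressure``.

    Pairwise pressure differences are untouched (incompressible flow is
    invariant to the absolute pressure level).
    """
    if profile.n_points == 0:
        raise InputError("empty profile")
    shift = outlet_pressure - profile.pressure[-1]
    return HemodynamicProfile(
        pressure=profile.pressure + shift,
        wss=profile.wss.copy(),
        flow_rate=profile.flow_rate,
        source=profile.source,
    )


def compute_mpd(profile: HemodynamicProfile) -> float:
    """Maximum pressure drop: inlet pressure minus the lowest pressure anywhere."""
    if profile.n_points == 0:
        raise InputError("empty profile")
    return float(profile.pressure[0] - np.min(profile.pressure))


def compute_tpg(profile: HemodynamicProfile, valve_end_index: int | None = None) -> float:
    """Transvalvular pressure gradient.

    Inlet pressure minus the pressure at the point of highest pressure
    recovery downstream of the pressure minimum.  If the minimum falls on the
    last point there is no downstream segment; the inlet-to-outlet drop is
    returned with a warning.
    """
    p = profile.pressure
    if len(p) == 0:
        raise InputError("empty profile")
    if valve_end_index is not None and not (0 <= valve_end_index < len(p)):
        raise InputError("valve_end_index out of range")
    i_min = int(np.argmin(p))
    if i_min == len(p) - 1:
        warnings.warn("pressure minimum at outlet: no downstream recovery segment")
        return float(p[0] - p[-1])
    return float(p[0] - np.max(p[i_min + 1 :]))


# ---------------------------------------------------------------------------
# synthetic field samples (stand-in for the 3D CFD fields)


@dataclass
class FieldSamples:
    """Noisy per-section pressure and per-segment wall-WSS samples.

    ``pressure`` holds, per cross-section, sample points (inside the lumen
    polygon; the leaflet-bounded orifice in the valve region) and pressure
    values whose empirical mean equals the profile value.  ``wss`` holds, per
    inter-section segment, wall points on the boundary polygon and positive
    WSS magnitudes with a circumferential (von-Mises-shaped) jet asymmetry
    downstream of the valve, again mean-exact.
    """

    pressure: list  # per section: (points (n,3), values (n,))
    wss: list  # per segment: (points (n,3), values (n,))
    seed: int = 0
    flow_rate: float = 0.0

    def pressure_values(self, section_index: int) -> np.ndarray:
        if not (0 <= section_index < len(self.pressure)):
            return np.array([])
        return self.pressure[section_index][1]

    def wss_values(self, segment_index: int) -> np.ndarray:
        if not (0 <= segment_index < len(self.wss)):
            return np.array([])
        return self.wss[segment_index][1]


def _points_in_polygon(xy: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection sampling inside a star-shaped polygon (local coords)."""
    from matplotlib.path import Path as MplPath

    path = MplPath(xy)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform(lo, hi, size=(4 * n, 2))
        keep = cand[path.contains_points(cand)]
        out = np.vstack([out, keep])
    return out[:n]


def sample_fields(case, profile: HemodynamicProfile, params: OracleParams | None = None,
                  seed: int = 0, n_samples: int = 64) -> FieldSamples:
    """Generate noisy per-section/segment field samples around the profile.

    The within-plane pressure spread scales with the local dynamic pressure
    (``sample_noise_frac`` of 1/2 rho V^2); noise is re-centred so the
    per-section empirical mean equals the profile value exactly.  Wall WSS
    samples carry a von-Mises circumferential asymmetry downstream of the
    valve (jet impingement) and are positive with segment mean equal to the
    profile WSS.
    """
    if params is None:
        params = OracleParams()
    if n_samples < 8:
        raise InputError("need at least 8 samples per section/segment")
    n = case.centerline.n_points
    if profile.n_points != n:
        raise InputError("profile length does not match case centerline")

    rng = np.random.default_rng(seed)
    q = profile.flow_rate * 1e-6
    regions = np.asarray(case.centerline.regions)
    valve_idx = np.flatnonzero(regions == "valve")
    i_vc = int(valve_idx[0]) if len(valve_idx) else -1

    pressure_out, wss_out = [], []
    for i, sec in enumerate(case.sections):
        v_i = q / (sec.area * 1e-6)
        dyn_mmhg = 0.5 * params.rho * v_i**2 * MMHG_PER_PA
        sigma = params.sample_noise_frac * dyn_mmhg
        pts2 = _points_in_polygon(sec.boundary_local, n_samples, rng)
        pts3 = sec.origin + pts2[:, 0:1] * sec.u + pts2[:, 1:2] * sec.v
        noise = rng.normal(0.0, sigma, n_samples) if sigma > 0 else np.zeros(n_samples)
        values = profile.pressure[i] + noise - noise.mean()
        pressure_out.append((pts3, values))

    for i in range(n - 1):
        sec = case.sections[i]
        theta = rng.uniform(0.0, 2.0 * np.pi, n_samples)
        # interpolate wall points on the boundary polygon by angular fraction
        frac = theta / (2.0 * np.pi) * len(sec.boundary)
        k = (frac.astype(int)) % len(sec.boundary)
        pts3 = sec.boundary[k]
        base = profile.wss[i]
        if base <= 0:
            values = np.zeros(n_samples)
        else:
            if i_vc >= 0 and i > i_vc:
                kappa = 1.0  # jet impingement asymmetry downstream of the valve
                w = np.exp(kappa * np.cos(theta))
            else:
                w = np.ones(n_samples)
            rel = rng.normal(0.0, params.sample_noise_frac, n_samples) if params.sample_noise_frac > 0 else 0.0
            values = np.clip(w * (1.0 + rel), 1e-6, None)
            values *= base / values.mean()  # exact segment mean, positivity kept
        wss_out.append((pts3, values))

    return FieldSamples(pressure=pressure_out, wss=wss_out, seed=seed, flow_rate=profile.flow_rate)
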
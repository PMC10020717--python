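"""Training-corpus assembly.

Flow-rate assignment (observed pass-through or an AVA-shifted truncated
normal model), +-25% flow augmentation with oracle re-solves, filtering on
maximum pressure drop (MPD <= 120 mmHg, boundary inclusive), geometry-grouped
MPD-stratified splitting into 11 subsets, per-point feature building for the
sequence surrogate, and train-fitted z-score standardization.

All flow variants of one geometry always land in the same subset, so held
out geometries are never seen during training in any flow condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .exceptions import ConfigurationError, InputError
from .geometry import CaseGeometry
from .oracle import HemodynamicProfile, OracleParams, compute_mpd, compute_tpg, solve_profile

logger = logging.getLogger(__name__)

MPD_FILTER_MMHG = 120.0
N_SUBSETS = 11

FLOW_CONDITIONS = ("baseline", "minus25", "plus25")
FLOW_FACTORS = {"baseline": 1.0, "minus25": 0.75, "plus25": 1.25}


@dataclass
class FlowModel:
    """AVA-shifted truncated-normal peak-systolic flow model (ml/s).

    mean = intercept + slope * AVA[cm^2]; SD = sd_frac * mean; truncated to
    [lo, hi].  Stands in for flow rates derived from ventricular volumetry.
    """

    intercept: float = 150.0
    slope: float = 250.0
    sd_frac: float = 0.15
    lo: float = 100.0
    hi: float = 700.0


@dataclass
class CaseRecord:
    """One simulated configuration: a geometry under one flow condition."""

    geometry_id: str
    flow_condition: str  # baseline | minus25 | plus25
    flow_rate: float  # ml/s
    flow_source: str  # observed | modelled
    profile: HemodynamicProfile
    mpd: float
    tpg: float
    peak_wss: float
    case: CaseGeometry | None = None

    @classmethod
    def from_profile(cls, geometry_id, condition, flow_rate, flow_source, profile, case=None):
        return cls(
            geometry_id=geometry_id,
            flow_condition=condition,
            flow_rate=flow_rate,
            flow_source=flow_source,
            profile=profile,
            mpd=compute_mpd(profile),
            tpg=compute_tpg(profile),
            peak_wss=float(np.max(profile.wss)),
            case=case,
        )


@dataclass
class DatasetSplit:
    """Disjoint geometry-id subsets; one holds the test cases."""

    subsets: list[list[str]]
    test_subset_index: int = 0

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    @property
    def test_ids(self) -> set[str]:
        return set(self.subsets[self.test_subset_index])

    def train_ids(self, exclude_subset: int | None = None) -> set[str]:
        """All non-test geometry ids, optionally excluding one validation subset."""
        out: set[str] = set()
        for k, ids in enumerate(self.subsets):
            if k == self.test_subset_index or k == exclude_subset:
                continue
            out.update(ids)
        return out


@dataclass
class FeatureSequence:
    """Per-centerline-point input matrix for the surrogate.

    Columns: x, y, z (mm, pose-normalized), cross-section area (mm^2),
    area-normalized flow Q/A (m/s), then the m shape-code values.
    """

    values: np.ndarray  # (N, 5 + m)
    geometry_id: str = ""
    flow_condition: str = "baseline"

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def assign_flow(
    ava: float,
    mode: str = "modelled",
    seed: int = 0,
    observed_rate: float | None = None,
    model: FlowModel | None = None,
) -> tuple[float, str]:
    """Assign a baseline peak-systolic flow rate (ml/s) to a geometry.

    ``observed`` mode passes the supplied rate through; ``modelled`` draws
    from the AVA-shifted truncated normal, deterministically given the seed.
    """
    if mode == "observed":
        if observed_rate is None or observed_rate <= 0:
            raise InputError("observed mode requires a positive flow rate")
        return float(observed_rate), "observed"
    if mode != "modelled":
        raise InputError(f"unknown flow mode {mode!r}")
    fm = model or FlowModel()
    mu = fm.intercept + fm.slope * ava
    sd = fm.sd_frac * mu
    a, b = (fm.lo - mu) / sd, (fm.hi - mu) / sd
    rate = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=np.random.default_rng(seed)))
    return rate, "modelled"


def augment_flows(
    records: list[CaseRecord], oracle_params: OracleParams | None = None
) -> list[CaseRecord]:
    """Expand baseline records with -25% and +25% flow variants.

    Each variant's profile is re-solved by the reduced-order oracle at the
    scaled flow; output holds 3x the input count, variants grouped per
    geometry in the order baseline, minus25, plus25.
    """
    if any(r.flow_condition != "baseline" for r in records):
        raise InputError("augment_flows expects baseline records only")
    ids = [r.geometry_id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate geometry_ids in baseline records")
    out: list[CaseRecord] = []
    for rec in records:
        out.append(rec)
        for cond in ("minus25", "plus25"):
            q = FLOW_FACTORS[cond] * rec.flow_rate
            profile = solve_profile(rec.case, q, oracle_params)
            out.append(
                CaseRecord.from_profile(
                    rec.geometry_id, cond, q, rec.flow_source, profile, rec.case
                )
            )
    return out


def filter_mpd(records: list[CaseRecord], threshold_mmhg: float = MPD_FILTER_MMHG) -> list[CaseRecord]:
    """Retain records with MPD <= threshold (boundary inclusive), preserving order."""
    if threshold_mmhg <= 0:
        raise InputError("threshold must be positive")
    retained = [r for r in records if r.mpd <= threshold_mmhg]
    excluded = len(records) - len(retained)
    logger.info(
        "MPD filter at %.0f mmHg: retained %d of %d (%d excluded)",
        threshold_mmhg, len(retained), len(records), excluded,
    )
    return retained


def split_datasets(
    records: list[CaseRecord],
    n_subsets: int = N_SUBSETS,
    test_index: int = 0,
    seed: int = 0,
) -> DatasetSplit:
    """MPD-stratified, geometry-grouped round-robin split.

    Geometries are sorted by their baseline (or mean) MPD with a seeded
    tie-shuffle, then dealt round-robin into subsets, so every subset covers
    the full MPD range and no geometry's flow variants are ever separated.
    """
    if n_subsets < 2:
        raise InputError("need at least 2 subsets")
    if not (0 <= test_index < n_subsets):
        raise InputError("test_index out of range")
    by_geom: dict[str, list[CaseRecord]] = {}
    for r in records:
        by_geom.setdefault(r.geometry_id, []).append(r)
    if len(by_geom) < n_subsets:
        raise InputError(
            f"{len(by_geom)} geometries cannot fill {n_subsets} subsets"
        )

    def key_mpd(recs: list[CaseRecord]) -> float:
        base = [r for r in recs if r.flow_condition == "baseline"]
        return base[0].mpd if base else float(np.mean([r.mpd for r in recs]))

    rng = np.random.default_rng(seed)
    order = sorted(by_geom, key=lambda g: (key_mpd(by_geom[g]), rng.random()))
    subsets: list[list[str]] = [[] for _ in range(n_subsets)]
    for i, g in enumerate(order):
        subsets[i % n_subsets].append(g)
    return DatasetSplit(subsets=subsets, test_subset_index=test_index)


# ---------------------------------------------------------------------------
# features


def pose_normalize(points: np.ndarray) -> np.ndarray:
    """Canonical pose: inlet at the origin, initial tangent along +z.

    The rotation maps the initial tangent to +z and keeps the arch plane in
    x-z, so geometries from arbitrary scanner frames become comparable.
    """
    pts = np.asarray(points, dtype=float) - points[0]
    t0 = pts[1] - pts[0]
    t0 = t0 / np.linalg.norm(t0)
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(t0, z)
    c = float(t0 @ z)
    if np.linalg.norm(vcross) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array(
            [[0, -vcross[2], vcross[1]], [vcross[2], 0, -vcross[0]], [-vcross[1], vcross[0], 0]]
        )
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    pts = pts @ rot.T
    # rotate about z so the dominant bending direction lies along +x
    far = pts[np.argmax(np.abs(pts[:, :2]).sum(axis=1))]
    ang = np.arctan2(far[1], far[0]) if np.hypot(far[0], far[1]) > 1e-9 else 0.0
    ca, sa = np.cos(-ang), np.sin(-ang)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    return pts @ rz.T


def build_features(
    record: CaseRecord,
    encoder,
    shape_codes: np.ndarray | None = None,
    grid_size: int | None = None,
    window_mm: float | None = None,
) -> FeatureSequence:
    """Assemble the per-point surrogate input matrix for one record.

    ``shape_codes`` may carry precomputed per-section codes (N, m) to avoid
    re-rasterizing identical geometry across flow variants; otherwise each
    section is rasterized and encoded here.  Q/A lands in m/s because
    ml/s / mm^2 = m/s exactly.
    """
    from .centerline import DEFAULT_GRID, DEFAULT_WINDOW_MM, rasterize_section

    case = record.case
    if case is None:
        raise InputError("record carries no geometry")
    n = case.centerline.n_points
    if shape_codes is None:
        gs = grid_size or DEFAULT_GRID
        wm = window_mm or DEFAULT_WINDOW_MM
        images = [rasterize_section(s, gs, wm) for s in case.sections]
        shape_codes = np.vstack([encoder.encode(img) for img in images])
    shape_codes = np.asarray(shape_codes, dtype=float)
    if shape_codes.shape[0] != n:
        raise ConfigurationError("shape_codes length does not match centerline")

    coords = pose_normalize(case.centerline.points)
    areas = case.areas
    qa = record.flow_rate / areas  # ml/s per mm^2 == m/s
    values = np.column_stack([coords, areas, qa, shape_codes])
    return FeatureSequence(
        values=values,
        geometry_id=record.geometry_id,
        flow_condition=record.flow_condition,
    )


class Standardizer:
    """Per-column z-scoring fitted on training sequences only.

    Zero-variance columns are guarded (scale forced to 1) so constant
    features pass through unchanged.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.zero_variance_: np.ndarray | None = None

    def fit(self, arrays: list[np.ndarray]) -> "Standardizer":
        stacked = np.vstack([np.asarray(a, dtype=float) for a in arrays])
        self.mean_ = stacked.mean(axis=0)
        scale = stacked.std(axis=0)
        zero = scale < 1e-12
        if zero.any():
            warnings.warn(f"zero-variance feature column(s) {np.flatnonzero(zero)}: scale guarded to 1")
            scale = np.where(zero, 1.0, scale)
        self.scale_ = scale
        self.zero_variance_ = zero
        return self

    def raw_sd(self) -> np.ndarray:
        """Training SD with guarded (constant) columns reported as zero."""
        self._check()
        zero = self.zero_variance_ if self.zero_variance_ is not None else np.zeros_like(self.scale_, bool)
        return np.where(zero, 0.0, self.scale_)

    def _check(self) -> None:
        if self.mean_ is None:
            raise ConfigurationError("standardizer not fitted")

    def transform(self, a: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(a, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, a: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(a, dtype=float) * self.scale_ + self.mean_


def standardize(
    sequences: list[np.ndarray], stats: Standardizer | None = None
) -> tuple[list[np.ndarray], Standardizer]:
    """Z-score a list of (N_i, F) arrays; fit on them unless stats are given."""
    if stats is None:
        stats = Standardizer().fit(sequences)
    return [stats.transform(s) for s in sequences], stats
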
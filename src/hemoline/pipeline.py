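"""End-to-end orchestration and on-disk artifacts.

``run_pipeline`` executes the full desk-scale study: synthesize a cohort of
parametric aorta+valve geometries, solve reference profiles with the
reduced-order oracle, apply flow augmentation and the MPD filter, build the
geometry-grouped stratified split, train the shape autoencoder and the
bi-LSTM surrogate, and evaluate the held-out test subset (per-case metrics,
cohort summary, TOST equivalence of TPG).

One global seed fans out deterministically to per-stage seeds, so any stage
can be re-run in isolation and two runs with the same config are identical.
Artifacts are written as a JSON manifest, CSV tables and npz/JSON model
checkpoints under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centerline as cl
from .autoencoder import AEModel, train_autoencoder
from .dataset import (
    CaseRecord,
    DatasetSplit,
    FeatureSequence,
    FlowModel,
    assign_flow,
    augment_flows,
    build_features,
    filter_mpd,
    split_datasets,
)
from .evaluation import (
    case_metrics,
    cohort_report,
    evaluate_records,
    tost_tpg,
)
from .exceptions import HemolineError, InputError, MissingDataError
from .geometry import CaseGeometry, GeometryParams, build_case, sample_geometry_params
from .oracle import HemodynamicProfile, OracleParams, solve_profile
from .surrogate import SurrogateConfig, SurrogateModel, predict, train_surrogate

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    n_geometries: int = 100
    cohort_config: dict | None = None
    oracle: OracleParams = field(default_factory=OracleParams)
    flow_model: FlowModel = field(default_factory=FlowModel)
    mpd_threshold: float = 120.0
    n_subsets: int = 11
    test_subset_index: int = 0
    ae_m: int = 4
    ae_epochs: int = 60
    ae_max_images: int = 3000
    grid_size: int = 68
    window_mm: float = 50.0
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    output_dir: str | None = None

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("geometry", "flow", "ae", "surrogate", "evaluation")
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("oracle"), dict):
            d["oracle"] = OracleParams(**d["oracle"])
        if isinstance(d.get("flow_model"), dict):
            d["flow_model"] = FlowModel(**d["flow_model"])
        if isinstance(d.get("surrogate"), dict):
            d["surrogate"] = SurrogateConfig(**d["surrogate"])
        return cls(**d)


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    records: list[CaseRecord]
    retained: list[CaseRecord]
    split: DatasetSplit
    ae: AEModel
    model: SurrogateModel
    features: dict[str, FeatureSequence] | None
    test_metrics: list
    report: dict
    equivalence: object


# ---------------------------------------------------------------------------
# stages


def synthesize_cohort(config: RunConfig) -> list[CaseGeometry]:
    """Sample and build ``n_geometries`` synthetic cases, one seed each."""
    base = config.stage_seeds()["geometry"]
    cases = []
    for k in range(config.n_geometries):
        params = sample_geometry_params(config.cohort_config, seed=base + k)
        cases.append(build_case(params, label=f"geom{k:04d}"))
    return cases


def baseline_records(cases: list[CaseGeometry], config: RunConfig) -> list[CaseRecord]:
    """Assign modelled baseline flows and solve the reference profiles."""
    base = config.stage_seeds()["flow"]
    out = []
    for k, case in enumerate(cases):
        rate, source = assign_flow(
            case.params.ava, mode="modelled", seed=base + k, model=config.flow_model
        )
        profile = solve_profile(case, rate, config.oracle)
        out.append(
            CaseRecord.from_profile(case.label, "baseline", rate, source, profile, case)
        )
    return out


def encode_geometries(
    cases: list[CaseGeometry], ae: AEModel, config: RunConfig
) -> dict[str, np.ndarray]:
    """Per-geometry (N, m) shape-code matrices, computed once per geometry."""
    codes = {}
    for case in cases:
        imgs = [cl.rasterize_section(s, config.grid_size, config.window_mm) for s in case.sections]
        codes[case.label] = np.vstack([ae.encode(im) for im in imgs])
    return codes


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the whole workflow; see module docstring for the stages."""
    t0 = time.time()
    seeds = config.stage_seeds()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    try:
        _stage("synthesize geometries")
        cases = synthesize_cohort(config)

        _stage("baseline flows + oracle profiles")
        base = baseline_records(cases, config)

        _stage("flow augmentation (+-25%)")
        records = augment_flows(base, config.oracle)

        _stage(f"MPD filter at {config.mpd_threshold:g} mmHg")
        retained = filter_mpd(records, config.mpd_threshold)

        _stage("stratified geometry-grouped split")
        split = split_datasets(
            retained, config.n_subsets, config.test_subset_index, seed=seeds["geometry"]
        )
        test_ids = split.test_ids
        train_ids = split.train_ids()

        _stage("rasterize cross-sections")
        case_by_id = {c.label: c for c in cases}
        used_ids = sorted({r.geometry_id for r in retained})
        rasters: dict[str, list] = {}
        for g in used_ids:
            rasters[g] = [
                cl.rasterize_section(s, config.grid_size, config.window_mm)
                for s in case_by_id[g].sections
            ]

        _stage("autoencoder training")
        rng = np.random.default_rng(seeds["ae"])
        images = [im for g in used_ids if g in train_ids for im in rasters[g]]
        if len(images) > config.ae_max_images:
            keep = rng.choice(len(images), config.ae_max_images, replace=False)
            images = [images[int(i)] for i in keep]
        ae = train_autoencoder(images, m=config.ae_m, seed=seeds["ae"], epochs=config.ae_epochs)

        _stage("shape encoding")
        codes = {
            g: np.vstack([ae.encode(im) for im in rasters[g]]) for g in used_ids
        }
        features = {}
        for r in retained:
            f = build_features(r, ae, shape_codes=codes[r.geometry_id])
            features[(r.geometry_id, r.flow_condition)] = f

        _stage("surrogate training")
        train_records = [r for r in retained if r.geometry_id in train_ids]
        cfg = dataclasses.replace(config.surrogate, seed=seeds["surrogate"], m=config.ae_m)
        model = train_surrogate(
            [features[(r.geometry_id, r.flow_condition)] for r in train_records],
            [r.profile for r in train_records],
            cfg,
        )

        _stage("evaluation on the held-out subset")
        test_records = [r for r in retained if r.geometry_id in test_ids]
        test_feats = [features[(r.geometry_id, r.flow_condition)] for r in test_records]
        metrics = evaluate_records(model, test_feats, test_records)
        report = cohort_report(
            metrics,
            test_mpds=[r.mpd for r in test_records],
            cohort_mpds=[r.mpd for r in retained],
        )
        equivalence = tost_tpg(
            [m.tpg_ref for m in metrics], [m.tpg_pred for m in metrics]
        )
        report["tost"] = dataclasses.asdict(equivalence)
        report["n_baseline"] = len(base)
        report["n_augmented"] = len(records)
        report["n_retained"] = len(retained)
        report["seeds"] = seeds

        if out_dir:
            _stage("write artifacts")
            _write_artifacts(out_dir, config, retained, split, ae, model, metrics, report)
        _stage("done")
    except HemolineError as err:
        logger.error("pipeline aborted: %s", err)
        raise

    return RunResult(
        config=config, records=records, retained=retained, split=split,
        ae=ae, model=model, features=features, test_metrics=metrics,
        report=report, equivalence=equivalence,
    )


def _write_artifacts(out_dir, config, retained, split, ae, model, metrics, report):
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonable(config.to_dict()),
        "split": {"subsets": split.subsets, "test_subset_index": split.test_subset_index},
        "records": [
            {"geometry_id": r.geometry_id, "condition": r.flow_condition,
             "flow_ml_s": r.flow_rate, "flow_source": r.flow_source,
             "mpd": r.mpd, "tpg": r.tpg, "peak_wss": r.peak_wss}
            for r in retained
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    ae.save(out_dir / "autoencoder")
    model.save(out_dir / "surrogate")
    pd.DataFrame([dataclasses.asdict(m) for m in metrics]).to_csv(
        out_dir / "test_metrics.csv", index=False
    )
    (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# case bundles (documented CSV + JSON layout)


def write_case_bundle(case: CaseGeometry, records: list[CaseRecord], path: str | Path) -> None:
    """Serialize one geometry and its records to a JSON + CSV bundle.

    Layout: ``manifest.json`` (schema version, geometry params, record
    metadata), ``centerline.csv`` (x, y, z, s, region, area per point),
    ``sections.csv`` (section_index, vertex_index, x, y, z, u, v) and one
    ``profile_<condition>.csv`` per record (index, s_mm, region,
    pressure_mmHg, wss_Pa).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "label": case.label,
        "params": dataclasses.asdict(case.params) if case.params else None,
        "records": [
            {"geometry_id": r.geometry_id, "condition": r.flow_condition,
             "flow_ml_s": r.flow_rate, "flow_source": r.flow_source}
            for r in records
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    cln = case.centerline
    pd.DataFrame({
        "x": cln.points[:, 0], "y": cln.points[:, 1], "z": cln.points[:, 2],
        "s": cln.arc_length, "region": cln.regions, "area": case.areas,
    }).to_csv(path / "centerline.csv", index=False)

    rows = []
    for s in case.sections:
        for k, (p3, p2) in enumerate(zip(s.boundary, s.boundary_local)):
            rows.append((s.index, k, p3[0], p3[1], p3[2], p2[0], p2[1]))
    pd.DataFrame(rows, columns=["section", "vertex", "x", "y", "z", "u", "v"]).to_csv(
        path / "sections.csv", index=False
    )

    for r in records:
        pd.DataFrame({
            "index": np.arange(r.profile.n_points),
            "s_mm": cln.arc_length,
            "region": cln.regions,
            "pressure_mmHg": r.profile.pressure,
            "wss_Pa": r.profile.wss,
        }).to_csv(path / f"profile_{r.flow_condition}.csv", index=False)


def read_case_bundle(path: str | Path) -> tuple[CaseGeometry, list[CaseRecord]]:
    """Load a bundle written by :func:`write_case_bundle` (lossless to 1e-9)."""
    from .geometry import CrossSection

    path = Path(path)
    mf_path = path / "manifest.json"
    if not mf_path.exists():
        raise MissingDataError(f"no manifest.json under {path}")
    manifest = json.loads(mf_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise InputError(
            f"bundle schema version mismatch: expected {SCHEMA_VERSION}, found {version}"
        )

    cl_df = _read_csv(path / "centerline.csv")
    points = cl_df[["x", "y", "z"]].to_numpy()
    cln = cl.Centerline(
        points=points,
        arc_length=cl_df["s"].to_numpy(),
        regions=cl_df["region"].to_numpy(),
    )
    sec_df = _read_csv(path / "sections.csv")
    sections = []
    frames = cl.section_planes(cln)
    for idx, grp in sec_df.groupby("section", sort=True):
        b3d = grp[["x", "y", "z"]].to_numpy()
        b2d = grp[["u", "v"]].to_numpy()
        fr = frames[int(idx)]
        from .geometry import _polygon_area

        sections.append(CrossSection(
            origin=fr.origin, normal=fr.normal, boundary=b3d, boundary_local=b2d,
            area=_polygon_area(b2d), region=str(cl_df["region"].iloc[int(idx)]),
            index=int(idx), u=fr.u, v=fr.v,
        ))
    params = GeometryParams(**manifest["params"]) if manifest.get("params") else None
    case = CaseGeometry(centerline=cln, sections=sections,
                        label=manifest.get("label", ""), params=params)

    records = []
    for meta in manifest.get("records", []):
        prof_path = path / f"profile_{meta['condition']}.csv"
        df = _read_csv(prof_path)
        profile = HemodynamicProfile(
            pressure=df["pressure_mmHg"].to_numpy(),
            wss=df["wss_Pa"].to_numpy(),
            flow_rate=meta["flow_ml_s"],
            source="oracle",
        )
        records.append(CaseRecord.from_profile(
            meta["geometry_id"], meta["condition"], meta["flow_ml_s"],
            meta["flow_source"], profile, case,
        ))
    return case, records


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise MissingDataError(f"bundle file missing: {path}")
    try:
        return pd.read_csv(path)
    except Exception as err:  # noqa: BLE001 - surface file and cause
        raise InputError(f"failed to parse {path}: {err}") from err
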
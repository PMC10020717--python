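"""Corpus assembly: flow model, augmentation, MPD filter, split, features."""

import numpy as np
import pytest

from hemoline.dataset import (
    CaseRecord,
    FlowModel,
    Standardizer,
    assign_flow,
    augment_flows,
    build_features,
    filter_mpd,
    split_datasets,
    standardize,
)
from hemoline.exceptions import InputError
from hemoline.geometry import GeometryParams, build_case
from hemoline.oracle import HemodynamicProfile, solve_profile


def fake_record(geometry_id, mpd, condition="baseline", flow=400.0):
    """Metadata-only record for filter/split mechanics tests."""
    prof = HemodynamicProfile(pressure=np.array([130.0, 130.0 - mpd, 125.0]),
                              wss=np.array([1.0, 2.0, 1.0]))
    return CaseRecord(
        geometry_id=geometry_id, flow_condition=condition, flow_rate=flow,
        flow_source="modelled", profile=prof, mpd=mpd, tpg=mpd / 2.0, peak_wss=2.0,
    )


class TestAssignFlow:
    def test_observed_pass_through(self):
        rate, source = assign_flow(0.8, mode="observed", observed_rate=420.0)
        assert rate == 420.0 and source == "observed"

    def test_observed_requires_positive_rate(self):
        with pytest.raises(InputError):
            assign_flow(0.8, mode="observed", observed_rate=-5.0)

    def test_same_seed_same_draw(self):
        a, _ = assign_flow(0.9, seed=11)
        b, _ = assign_flow(0.9, seed=11)
        assert a == b

    def test_mean_flow_increases_with_ava(self):
        lo = [assign_flow(0.5, seed=k)[0] for k in range(2000)]
        hi = [assign_flow(1.5, seed=k)[0] for k in range(2000)]
        assert np.mean(hi) > np.mean(lo)

    def test_draws_respect_truncation(self):
        fm = FlowModel()
        draws = [assign_flow(2.0, seed=k, model=fm)[0] for k in range(500)]
        assert min(draws) >= fm.lo and max(draws) <= fm.hi


class TestAugmentFlows:
    @pytest.fixture(scope="class")
    def baseline_batch(self):
        out = []
        for k in range(3):
            case = build_case(GeometryParams(ava=0.7 + 0.3 * k, seed=k), label=f"g{k}")
            prof = solve_profile(case, 400.0)
            out.append(CaseRecord.from_profile(f"g{k}", "baseline", 400.0, "observed", prof, case))
        return out

    def test_three_variants_per_baseline(self, baseline_batch):
        out = augment_flows(baseline_batch)
        assert len(out) == 3 * len(baseline_batch)

    def test_variant_rates_are_quarter_shifts(self, baseline_batch):
        out = augment_flows(baseline_batch[:1])
        rates = {r.flow_condition: r.flow_rate for r in out}
        assert rates == {"baseline": 400.0, "minus25": 300.0, "plus25": 500.0}

    def test_mpd_monotone_in_flow_within_geometry(self, baseline_batch):
        out = augment_flows(baseline_batch)
        for g in {r.geometry_id for r in out}:
            mpds = {r.flow_condition: r.mpd for r in out if r.geometry_id == g}
            assert mpds["minus25"] < mpds["baseline"] < mpds["plus25"]
            assert all(v >= 0 for v in mpds.values())

    def test_non_baseline_input_rejected(self, baseline_batch):
        out = augment_flows(baseline_batch[:1])
        with pytest.raises(InputError):
            augment_flows(out)

    def test_duplicate_ids_rejected(self, baseline_batch):
        with pytest.raises(InputError):
            augment_flows([baseline_batch[0], baseline_batch[0]])


class TestFilterMpd:
    def test_boundary_inclusive_hand_example(self):
        records = [fake_record(f"g{i}", mpd) for i, mpd in enumerate([50, 120, 121, 200])]
        kept = filter_mpd(records, 120.0)
        assert [r.mpd for r in kept] == [50, 120]

    def test_empty_input(self):
        assert filter_mpd([], 120.0) == []

    def test_retained_set_is_exactly_below_threshold(self):
        rng = np.random.default_rng(1)
        records = [fake_record(f"g{i}", float(m)) for i, m in enumerate(rng.uniform(0, 240, 200))]
        kept = filter_mpd(records)
        assert {r.geometry_id for r in kept} == {r.geometry_id for r in records if r.mpd <= 120}
        assert max(r.mpd for r in kept) <= 120.0


class TestSplitDatasets:
    def _records(self, n_geoms, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n_geoms):
            mpd = float(rng.uniform(2, 118))
            for cond, fac in (("baseline", 1.0), ("minus25", 0.8), ("plus25", 1.2)):
                out.append(fake_record(f"g{i:03d}", mpd * fac, condition=cond))
        return out

    def test_round_robin_counts(self):
        split = split_datasets(self._records(88), n_subsets=11, seed=0)
        assert [len(s) for s in split.subsets] == [8] * 11

    def test_union_disjoint(self):
        split = split_datasets(self._records(40), n_subsets=11, seed=1)
        all_ids = [g for s in split.subsets for g in s]
        assert len(all_ids) == len(set(all_ids)) == 40

    def test_variants_never_split_across_subsets(self):
        records = self._records(33)
        split = split_datasets(records, n_subsets=11, seed=2)
        member = {g: k for k, s in enumerate(split.subsets) for g in s}
        for r in records:
            assert member[r.geometry_id] == member[r.geometry_id.split("/")[0]]

    def test_each_subset_spans_mpd_range(self):
        records = self._records(88, seed=3)
        split = split_datasets(records, n_subsets=11, seed=3)
        base_mpd = {r.geometry_id: r.mpd for r in records if r.flow_condition == "baseline"}
        all_mpds = np.array(list(base_mpd.values()))
        global_range = all_mpds.max() - all_mpds.min()
        for s in split.subsets:
            mpds = np.array([base_mpd[g] for g in s])
            assert (mpds.max() - mpds.min()) >= 0.6 * global_range

    def test_too_few_geometries_rejected(self):
        with pytest.raises(InputError):
            split_datasets(self._records(5), n_subsets=11)


class _IdentityEncoder:
    m = 4

    def encode(self, image):
        return np.zeros(4)


class TestBuildFeatures:
    @pytest.fixture(scope="class")
    def record(self, default_case):
        prof = solve_profile(default_case, 400.0)
        return CaseRecord.from_profile("fixture-case", "baseline", 400.0, "observed", prof, default_case)

    def test_row_width_with_default_code_size(self, record):
        n = record.case.centerline.n_points
        feats = build_features(record, None, shape_codes=np.zeros((n, 4)))
        assert feats.width == 9

    def test_area_normalized_flow_units(self, record):
        # ml/s divided by mm^2 is exactly m/s
        n = record.case.centerline.n_points
        feats = build_features(record, None, shape_codes=np.zeros((n, 4)))
        np.testing.assert_allclose(feats.values[:, 4], 400.0 / record.case.areas)
        a400 = np.argmin(np.abs(record.case.areas - 400.0))
        if abs(record.case.areas[a400] - 400.0) < 40.0:
            assert feats.values[a400, 4] == pytest.approx(1.0, rel=0.1)

    def test_flow_only_changes_qa_column(self, record, default_case):
        prof2 = solve_profile(default_case, 500.0)
        rec2 = CaseRecord.from_profile("fixture-case", "plus25", 500.0, "observed", prof2, default_case)
        n = default_case.centerline.n_points
        codes = np.arange(n * 4, dtype=float).reshape(n, 4)
        f1 = build_features(record, None, shape_codes=codes)
        f2 = build_features(rec2, None, shape_codes=codes)
        np.testing.assert_array_equal(f1.values[:, :4], f2.values[:, :4])
        np.testing.assert_array_equal(f1.values[:, 5:], f2.values[:, 5:])
        assert not np.allclose(f1.values[:, 4], f2.values[:, 4])

    def test_pose_normalization_pins_inlet_and_tangent(self, record):
        n = record.case.centerline.n_points
        feats = build_features(record, None, shape_codes=np.zeros((n, 4)))
        coords = feats.values[:, :3]
        np.testing.assert_allclose(coords[0], 0.0, atol=1e-9)
        t0 = coords[1] - coords[0]
        np.testing.assert_allclose(t0 / np.linalg.norm(t0), [0, 0, 1], atol=1e-9)

    def test_encoder_used_when_no_codes_supplied(self, record):
        feats = build_features(record, _IdentityEncoder())
        assert feats.width == 9
        np.testing.assert_array_equal(feats.values[:, 5:], 0.0)


class TestStandardize:
    def test_fit_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        seqs = [rng.normal(5, 3, size=(30, 4)) for _ in range(6)]
        scaled, stats = standardize(seqs)
        stacked = np.vstack(scaled)
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(stacked.std(axis=0), 1.0, atol=1e-10)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        seqs = [rng.normal(size=(20, 3)) for _ in range(4)]
        _, stats = standardize(seqs)
        x = rng.normal(size=(7, 3))
        np.testing.assert_allclose(stats.inverse_transform(stats.transform(x)), x, atol=1e-10)

    def test_constant_column_guarded(self):
        seqs = [np.column_stack([np.full(10, 3.0), np.arange(10, dtype=float)])]
        with pytest.warns(UserWarning):
            scaled, stats = standardize(seqs)
        np.testing.assert_allclose(scaled[0][:, 0], 0.0)
        assert stats.raw_sd()[0] == 0.0
        x = np.column_stack([np.full(5, 3.0), np.zeros(5)])
        np.testing.assert_allclose(stats.inverse_transform(stats.transform(x))[:, 0], 3.0)

    def test_test_data_scaled_with_training_stats(self):
        rng = np.random.default_rng(2)
        train = [rng.normal(0, 1, size=(50, 2)) for _ in range(3)]
        _, stats = standardize(train)
        test = [rng.normal(10, 5, size=(20, 2))]
        scaled, stats2 = standardize(test, stats)
        assert stats2 is stats
        assert abs(np.vstack(scaled).mean()) > 1.0  # not re-centred on test data
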
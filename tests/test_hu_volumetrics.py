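"""HU classification, region volumetrics and simulated resection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ppolung.hu_volumetrics import (
    CLASS_EMPHYSEMATOUS,
    CLASS_NON_AERATED,
    CLASS_WELL_AERATED,
    HUTissueClassifier,
    HUVolume,
    LungLabelMap,
    ResectionPlan,
    SegmentInfo,
    UndefinedFractionError,
    classify_volume,
    region_volumetrics,
    simulate_resection,
)
from ppolung.synthetic_data import PhantomSpec, make_phantom

from conftest import small_uniform_volume


def brute_force_tally(hu, labels):
    """Independent per-voxel oracle: loop over the grid, threshold by hand."""
    counts = {}
    for idx in np.ndindex(hu.shape):
        code = int(labels[idx])
        if code == 0:
            continue
        v = hu[idx]
        if v < -900:
            cls = "emph"
        elif v <= -501:
            cls = "well"
        else:
            cls = "non"
        counts.setdefault(code, {"well": 0, "emph": 0, "non": 0})[cls] += 1
    return counts


class TestClassification:
    @pytest.mark.parametrize("hu,expected", [
        (-750.0, CLASS_WELL_AERATED),   # mid functional band
        (-950.0, CLASS_EMPHYSEMATOUS),  # below -900
        (-200.0, CLASS_NON_AERATED),    # dense tissue
        (-900.0, CLASS_WELL_AERATED),   # lower bound inclusive
        (-501.0, CLASS_WELL_AERATED),   # upper bound inclusive
        (-500.5, CLASS_NON_AERATED),    # boundary-gap value goes dense
    ])
    def test_thresholds(self, hu, expected):
        vol, labels = small_uniform_volume(hu)
        cm = classify_volume(vol, labels)
        assert np.all(cm.classes[labels.lung_mask] == expected)

    def test_exact_mixture_counts(self):
        # 70k / 20k / 10k voxels at -750 / -950 / -200 HU in one segment
        flat = np.concatenate([np.full(70_000, -750.0), np.full(20_000, -950.0),
                               np.full(10_000, -200.0)])
        hu = flat.reshape(100, 100, 10)
        vol = HUVolume(values=hu, spacing=(1, 1, 1))
        labels = LungLabelMap(labels=np.ones_like(hu, dtype=np.int16),
                              table={1: SegmentInfo("right", "right upper lobe", "S1")})
        cm = classify_volume(vol, labels)
        assert (cm.classes == CLASS_WELL_AERATED).sum() == 70_000
        assert (cm.classes == CLASS_EMPHYSEMATOUS).sum() == 20_000
        assert (cm.classes == CLASS_NON_AERATED).sum() == 10_000

    def test_background_exactly_where_label_zero(self, phantom):
        vol, labels, _ = phantom
        cm = classify_volume(vol, labels)
        assert np.array_equal(cm.classes == 0, labels.labels == 0)

    def test_shape_mismatch_rejected(self):
        vol, _ = small_uniform_volume(-750, shape=(6, 6, 6))
        _, labels = small_uniform_volume(-750, shape=(5, 5, 5))
        with pytest.raises(ValueError, match="shape"):
            classify_volume(vol, labels)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            HUVolume(values=np.full((3, 3, 3), np.nan), spacing=(1, 1, 1))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(hu=hnp.arrays(np.float64, (5, 5, 5),
                         elements=st.floats(-1100, 100)),
           mask=hnp.arrays(np.bool_, (5, 5, 5)))
    def test_partition_property(self, hu, mask):
        """The three class counts always partition the lung-mask voxel count."""
        vol = HUVolume(values=hu, spacing=(1, 1, 1))
        labels = LungLabelMap(labels=mask.astype(np.int16),
                              table={1: SegmentInfo("right", "right upper lobe", "S1")})
        cm = classify_volume(vol, labels)
        counts = [(cm.classes == c).sum() for c in
                  (CLASS_WELL_AERATED, CLASS_EMPHYSEMATOUS, CLASS_NON_AERATED)]
        assert sum(counts) == mask.sum()
        assert (cm.classes == 0).sum() == (~mask).sum()

    def test_threshold_monotonicity(self, phantom):
        """Shifting all lung HU by +/-1000 drives every voxel dense/emphysematous."""
        vol, labels, _ = phantom
        up = HUVolume(values=vol.values + 1000.0, spacing=vol.spacing)
        down = HUVolume(values=vol.values - 1000.0, spacing=vol.spacing)
        mask = labels.lung_mask
        assert np.all(classify_volume(up, labels).classes[mask] == CLASS_NON_AERATED)
        assert np.all(classify_volume(down, labels).classes[mask] == CLASS_EMPHYSEMATOUS)

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone
        clf = HUTissueClassifier(theta_emph=-850.0)
        assert clone(clf).get_params()["theta_emph"] == -850.0
        clf.set_params(theta_emph=-900.0)
        out = clf.fit(np.array([[-950.0, -750.0, -200.0]])).transform(
            np.array([-950.0, -750.0, -200.0]))
        assert out.tolist() == [CLASS_EMPHYSEMATOUS, CLASS_WELL_AERATED,
                                CLASS_NON_AERATED]
        with pytest.raises(ValueError):
            HUTissueClassifier(theta_emph=-400.0).transform(np.zeros(3))


class TestRegionVolumetrics:
    def test_unit_cube(self):
        vol, labels = small_uniform_volume(-750, shape=(10, 10, 10))
        cm = classify_volume(vol, labels)
        rows = {r.region_id: r for r in region_volumetrics(cm, labels, vol)}
        assert rows["segment:1"].volume_total == pytest.approx(1.0)
        assert rows["segment:1"].volume_well_aerated == pytest.approx(1.0)
        assert rows["whole_lung"].volume_total == pytest.approx(1.0)

    def test_two_segments_spacing(self):
        # 500 voxels each at 2x2x2 mm -> 4 mL per segment, 8 mL whole lung
        labels_arr = np.concatenate([np.ones(500), np.full(500, 2)]).reshape(10, 10, 10)
        table = {1: SegmentInfo("right", "right upper lobe", "S1"),
                 2: SegmentInfo("right", "right upper lobe", "S2")}
        labels = LungLabelMap(labels=labels_arr.astype(np.int16), table=table)
        vol = HUVolume(values=np.full((10, 10, 10), -750.0), spacing=(2, 2, 2))
        cm = classify_volume(vol, labels)
        rows = {r.region_id: r for r in region_volumetrics(cm, labels, vol)}
        assert rows["segment:1"].volume_total == pytest.approx(4.0)
        assert rows["segment:2"].volume_total == pytest.approx(4.0)
        assert rows["whole_lung"].volume_total == pytest.approx(8.0)

    def test_matches_brute_force_oracle(self):
        vol, labels, _ = make_phantom(PhantomSpec(shape=(14, 14, 20), seed=7))
        cm = classify_volume(vol, labels)
        rows = {r.region_id: r for r in region_volumetrics(cm, labels, vol)}
        oracle = brute_force_tally(vol.values, labels.labels)
        vml = vol.voxel_volume_ml
        for code, c in oracle.items():
            row = rows[f"segment:{code}"]
            assert row.volume_well_aerated == pytest.approx(c["well"] * vml)
            assert row.volume_emphysematous == pytest.approx(c["emph"] * vml)
            assert row.volume_non_aerated == pytest.approx(c["non"] * vml)

    def test_aggregates_sum_exactly(self, phantom):
        vol, labels, _ = phantom
        cm = classify_volume(vol, labels)
        rows = region_volumetrics(cm, labels, vol)
        segs = [r for r in rows if r.region_id.startswith("segment:")]
        whole = next(r for r in rows if r.region_id == "whole_lung")
        # aggregates come from summed voxel counts, so equality is exact
        vml = vol.voxel_volume_ml
        total_count = round(whole.volume_total / vml)
        assert total_count == sum(round(s.volume_total / vml) for s in segs)
        for field in ("volume_total", "volume_well_aerated",
                      "volume_emphysematous", "volume_non_aerated"):
            assert getattr(whole, field) == pytest.approx(
                sum(getattr(s, field) for s in segs), rel=1e-12)

    def test_class_volumes_partition_total(self, phantom):
        vol, labels, _ = phantom
        cm = classify_volume(vol, labels)
        for r in region_volumetrics(cm, labels, vol):
            assert (r.volume_well_aerated + r.volume_emphysematous
                    + r.volume_non_aerated) == pytest.approx(r.volume_total, rel=1e-12)

    def test_absent_table_segment_gets_zero_row(self):
        vol, _ = small_uniform_volume(-750)
        table = {1: SegmentInfo("right", "right upper lobe", "S1"),
                 9: SegmentInfo("right", "right lower lobe", "S9")}
        labels = LungLabelMap(labels=np.ones((6, 6, 6), dtype=np.int16), table=table)
        cm = classify_volume(vol, labels)
        rows = {r.region_id: r for r in region_volumetrics(cm, labels, vol)}
        assert rows["segment:9"].volume_total == 0.0


class TestSimulateResection:
    def test_hand_arithmetic_two_segments(self, two_segment_lung):
        rows, table = two_segment_lung
        sim = simulate_resection(rows, ResectionPlan(frozenset({2})), table)
        assert sim.removed_total_fraction == pytest.approx(0.4)
        assert sim.removed_functional_fraction == pytest.approx(100 / 700)
        assert sim.removed_healthy_over_removed_total == pytest.approx(0.25)
        assert sim.healthy_over_total == pytest.approx(0.7)
        assert sim.ipsi_remaining_healthy_over_total == pytest.approx(1.0)

    def test_all_healthy_half_removed(self):
        vol, _ = small_uniform_volume(-750, shape=(8, 8, 8))
        half = np.ones((8, 8, 8), dtype=np.int16)
        half[4:] = 2
        table = {1: SegmentInfo("right", "right upper lobe", "S1"),
                 2: SegmentInfo("right", "right lower lobe", "S6")}
        labels = LungLabelMap(labels=half, table=table)
        cm = classify_volume(vol, labels)
        rows = region_volumetrics(cm, labels, vol)
        sim = simulate_resection(rows, ResectionPlan(frozenset({1})), table)
        assert sim.removed_total_fraction == pytest.approx(0.5)
        assert sim.removed_functional_fraction == pytest.approx(0.5)
        assert sim.removed_healthy_over_removed_total == pytest.approx(1.0)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ResectionPlan(frozenset())

    def test_cross_lateral_plan_rejected(self, phantom):
        vol, labels, _ = phantom
        cm = classify_volume(vol, labels)
        rows = region_volumetrics(cm, labels, vol)
        with pytest.raises(ValueError, match="laterality"):
            simulate_resection(rows, ResectionPlan(frozenset({1, 11})), labels.table)

    def test_zero_functional_denominator_is_explicit_error(self):
        vol, labels = small_uniform_volume(-200)  # no well-aerated tissue at all
        cm = classify_volume(vol, labels)
        rows = region_volumetrics(cm, labels, vol)
        with pytest.raises(UndefinedFractionError):
            simulate_resection(rows, ResectionPlan(frozenset({1})), labels.table)

    def test_conservation_per_class(self):
        """Removed + remaining equals whole lung, per tissue class, exactly
        (10 mm voxels give unit-mL voxel volumes, so float arithmetic is exact)."""
        vol, labels, _ = make_phantom(
            PhantomSpec(shape=(16, 16, 24), spacing=(10.0, 10.0, 10.0), seed=5))
        cm = classify_volume(vol, labels)
        rows = region_volumetrics(cm, labels, vol)
        segs = [r for r in rows if r.region_id.startswith("segment:")]
        whole = next(r for r in rows if r.region_id == "whole_lung")
        plan = ResectionPlan(frozenset({1, 2, 3}))
        removed = [s for s in segs if next(iter(s.label_codes)) in plan.removed_segments]
        remaining = [s for s in segs if next(iter(s.label_codes)) not in plan.removed_segments]
        for field in ("volume_total", "volume_well_aerated",
                      "volume_emphysematous", "volume_non_aerated"):
            rem = sum(getattr(s, field) for s in removed)
            keep = sum(getattr(s, field) for s in remaining)
            assert rem + keep == getattr(whole, field)
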
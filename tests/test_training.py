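import numpy as np
import pytest

from borealdist.classes import MAP_CODES, TRAINING_CLASSES
from borealdist.simulate import EventSpec, simulate_trajectory
from borealdist.spectral import ValidationError
from borealdist.training import (
    REJECT_DNBR,
    REJECT_POLYGON_TOO_LARGE,
    REJECT_TREE_COVER,
    CandidatePoint,
    TrainingExample,
    build_training_window,
    examples_to_frame,
    filter_pest_candidates,
    label_pest_severity,
    make_composite_examples,
    make_training_set,
    remap_to_final,
    spatial_cv_split,
)


def make_point(**overrides):
    defaults = dict(
        pixel_id=1, source_severity="medium", polygon_area_ha=500.0,
        tree_cover_pct=80.0, landcover="coniferous",
        overlaps_excluded_cover=False, dnbr_at_event=0.2, tile_id=3,
    )
    defaults.update(overrides)
    return CandidatePoint(**defaults)


class TestFilterPestCandidates:
    def test_good_point_kept(self):
        kept, rejected = filter_pest_candidates([make_point()])
        assert len(kept) == 1 and not rejected

    def test_polygon_too_large(self):
        _, rejected = filter_pest_candidates([make_point(polygon_area_ha=12_000)])
        assert rejected[0][1] == [REJECT_POLYGON_TOO_LARGE]

    def test_low_tree_cover(self):
        _, rejected = filter_pest_candidates([make_point(tree_cover_pct=40)])
        assert REJECT_TREE_COVER in rejected[0][1]

    @pytest.mark.parametrize("overrides", [
        dict(source_severity="light"),
        dict(overlaps_excluded_cover=True),
        dict(landcover="deciduous"),
        dict(dnbr_at_event=0.05),
    ])
    def test_each_predicate_rejects(self, overrides):
        kept, rejected = filter_pest_candidates([make_point(**overrides)])
        assert not kept and len(rejected) == 1

    def test_missing_field_names_it(self):
        with pytest.raises(ValidationError, match="dnbr_at_event"):
            make_point(dnbr_at_event=np.nan)

    def test_conjunction_reports_all_reasons(self):
        _, rejected = filter_pest_candidates(
            [make_point(polygon_area_ha=20_000, dnbr_at_event=0.01)]
        )
        assert set(rejected[0][1]) == {REJECT_POLYGON_TOO_LARGE, REJECT_DNBR}

    def test_pure_conjunction_order_free(self):
        pts = [make_point(pixel_id=i, dnbr_at_event=d)
               for i, d in enumerate([0.05, 0.2, 0.11, 0.09])]
        kept_fwd, _ = filter_pest_candidates(pts)
        kept_rev, _ = filter_pest_candidates(pts[::-1])
        assert {p.pixel_id for p in kept_fwd} == {p.pixel_id for p in kept_rev}


class TestLabelPestSeverity:
    @pytest.mark.parametrize("dnbr, label", [
        (0.16, "medium_defoliation"),
        (0.26, "high_defoliation"),
        (0.101, "low_defoliation"),
    ])
    def test_examples(self, dnbr, label):
        assert label_pest_severity(make_point(dnbr_at_event=dnbr)) == label

    def test_below_threshold_rejected(self):
        with pytest.raises(ValidationError):
            label_pest_severity(make_point(dnbr_at_event=0.05))


class TestBuildTrainingWindow:
    def test_deterministic_under_seed(self):
        ev = EventSpec("fire", 2000, 1, 0.4, 0.06)
        traj = simulate_trajectory(ev, (1985, 2024), 0.01, seed=1)
        a = build_training_window(traj, seed=42)
        b = build_training_window(traj, seed=42)
        assert a.event_offset == b.event_offset
        np.testing.assert_array_equal(a.window, b.window)

    def test_offset_support_is_1_to_9(self):
        ev = EventSpec("fire", 2005, 1, 0.4, 0.06)
        traj = simulate_trajectory(ev, (1985, 2024), 0.0)
        rng = np.random.default_rng(0)
        offsets = {build_training_window(traj, seed=rng).event_offset
                   for _ in range(1000)}
        assert offsets == set(range(1, 10))

    def test_undisturbed_window_has_no_event(self):
        traj = simulate_trajectory(None, (1985, 2024), 0.0)
        ex = build_training_window(traj, seed=0)
        assert ex.event_offset is None
        assert ex.label == "forest"

    def test_too_short_trajectory(self):
        traj = simulate_trajectory(None, (2000, 2005), 0.0)
        with pytest.raises(ValidationError):
            build_training_window(traj, seed=0)

    def test_event_never_first_year(self):
        with pytest.raises(ValidationError):
            TrainingExample(np.zeros((10, 6)), "fire", event_offset=0)

    def test_window_shape_enforced(self):
        with pytest.raises(ValidationError):
            TrainingExample(np.zeros((9, 6)), "fire", event_offset=1)


class TestCompositeExamples:
    def test_dams_windows_drop_and_stay_low(self):
        examples = make_composite_examples(("forest", "water"), 10, seed=0,
                                           noise_sd=0.0)
        assert len(examples) == 10
        for ex in examples:
            nir, swir2 = ex.window[:, 3], ex.window[:, 5]
            nbr = (nir - swir2) / (nir + swir2)
            drops = np.flatnonzero(np.diff(nbr) < -0.3)
            assert drops.size == 1  # exactly one persistent conversion
            assert np.all(nbr[drops[0] + 1:] < 0.35)
            assert ex.label == "dams"

    def test_pest_fire_label(self):
        (ex,) = make_composite_examples(("pest", "fire"), 1, seed=1)
        assert ex.label == "pest_fire"
        assert 1 <= ex.event_offset <= 9

    def test_zero_examples(self):
        assert make_composite_examples(("forest", "crops"), 0) == []

    def test_unsupported_pair(self):
        with pytest.raises(ValidationError):
            make_composite_examples(("water", "forest"), 1)


class TestRemapToFinal:
    @pytest.mark.parametrize("label, code", [
        ("pest_fire", 1),
        ("crops_change", 0),
        ("high_defoliation", 8),
        ("dams", 4),
        ("pest_harv", 5),
        ("windthrow", 3),
        ("partial_harvest", 2),
    ])
    def test_examples(self, label, code):
        assert remap_to_final(label) == code

    def test_total_on_training_classes(self):
        for label in TRAINING_CLASSES:
            assert remap_to_final(label) == MAP_CODES[label]

    def test_surjective_onto_map_codes(self):
        assert {remap_to_final(c) for c in TRAINING_CLASSES} == set(range(9))

    def test_unknown_label(self):
        with pytest.raises(ValidationError):
            remap_to_final("lava_flow")


class TestSpatialCvSplit:
    def test_partition_properties(self):
        plan = spatial_cv_split(seed=0)
        all_tiles = set(range(66))
        holdout = set(plan.holdout_tiles)
        assert len(holdout) == 4
        assert len(plan.folds) == 10
        for train_tiles, test_tiles in plan.folds:
            tr, te = set(train_tiles), set(test_tiles)
            assert tr & te == set()
            assert tr | te == all_tiles - holdout
            assert not (tr | te) & holdout
            assert len(te) == round(0.10 * 62)  # 6 test tiles per fold

    def test_seeded_determinism(self):
        a, b = spatial_cv_split(seed=5), spatial_cv_split(seed=5)
        np.testing.assert_array_equal(a.holdout_tiles, b.holdout_tiles)
        for (tra, tea), (trb, teb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(tea, teb)

    def test_too_few_tiles(self):
        with pytest.raises(ValidationError):
            spatial_cv_split(n_tiles=5)

    def test_examples_follow_their_tile(self):
        tile_ids = np.array([0, 0, 1, 2, 3, 3, 4] * 10)
        plan = spatial_cv_split(tile_ids, n_holdout_tiles=1,
                                test_fraction=0.25, seed=0)
        # tile universe is derived from the tiles actually present
        present = set(np.unique(tile_ids))
        for train_tiles, test_tiles in plan.folds:
            assert set(train_tiles) | set(test_tiles) <= present


class TestMakeTrainingSet:
    def test_covers_all_classes(self):
        X, y, tiles = make_training_set(3, noise_sd=0.01, seed=0)
        assert X.shape == (3 * len(TRAINING_CLASSES), 10, 6)
        assert set(np.unique(y)) == set(range(len(TRAINING_CLASSES)))
        assert tiles.shape == y.shape

    def test_deterministic(self):
        X1, y1, t1 = make_training_set(2, seed=9)
        X2, y2, t2 = make_training_set(2, seed=9)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(t1, t2)

    def test_frame_serialization(self):
        from borealdist.training import build_training_window
        traj = simulate_trajectory(None, (1985, 2024), 0.0)
        df = examples_to_frame([build_training_window(traj, seed=0)])
        assert df.shape[0] == 1
        assert sum(c.startswith("v") for c in df.columns) == 60
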
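import numpy as np
import pandas as pd
import pytest

from borealdist.spectral import UndefinedValueError, ValidationError
from borealdist.validation import (
    ConfusionMatrix,
    PlotMeasurement,
    Tree,
    accuracy_report,
    area_adjusted_accuracy,
    confusion_matrix,
    filter_plot_measurements,
    majority_neighborhood_class,
    omission_commission,
    overall_accuracy,
    pct_agb_defoliated,
    r2,
    round_half_up,
    temporal_match,
    vilts_sample_plan,
)


class TestRoundHalfUp:
    @pytest.mark.parametrize("x, expected", [
        (0.5, 1), (1.5, 2), (2.4, 2), (2.6, 3), (16.5, 17), (-0.4, 0),
    ])
    def test_examples(self, x, expected):
        assert round_half_up(x) == expected


class TestConfusionMatrix:
    def test_perfect_agreement_diagonal(self):
        cm = confusion_matrix(["a", "b", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 0], [0, 2]])

    def test_empty_input_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.total == 0

    def test_unknown_label(self):
        with pytest.raises(ValidationError):
            confusion_matrix(["a"], ["z"], ["a", "b"])

    def test_unpaired_lengths(self):
        with pytest.raises(ValidationError):
            confusion_matrix(["a"], [], ["a"])

    def test_reference_totals(self, table_matrix):
        np.testing.assert_array_equal(
            table_matrix.counts.sum(axis=0), [542, 139, 139, 22, 27, 202]
        )
        assert table_matrix.total == 1071


class TestOverallAccuracy:
    def test_reference_fixture(self, table_matrix):
        assert round_half_up(overall_accuracy(table_matrix)) == 81

    def test_diagonal_is_100(self):
        cm = ConfusionMatrix(np.diag([5, 3]), ["a", "b"])
        assert overall_accuracy(cm) == 100.0

    def test_zero_diagonal_is_0(self):
        cm = ConfusionMatrix([[0, 2], [3, 0]], ["a", "b"])
        assert overall_accuracy(cm) == 0.0

    def test_empty_matrix_errors(self):
        with pytest.raises(UndefinedValueError):
            overall_accuracy(ConfusionMatrix(np.zeros((2, 2)), ["a", "b"]))


class TestOmissionCommission:
    def test_identity_all_zero(self):
        cm = ConfusionMatrix(np.eye(3) * 4, ["a", "b", "c"])
        oc = omission_commission(cm)
        assert (oc == 0).all().all()

    @pytest.mark.parametrize("cls, omission, commission", [
        ("wildfire", 17, 2),
        ("harvesting", 31, 14),
        ("windthrow", 55, 58),
        ("pest", 52, 19),
        ("no_change", 2, 21),
        ("pest_harv", 33, 22),
    ])
    def test_reference_fixture(self, table_matrix, cls, omission, commission):
        report = accuracy_report(table_matrix)
        assert report.loc[cls, "omission"] == omission
        assert report.loc[cls, "commission"] == commission

    def test_joint_reproduction(self, table_matrix):
        # every printed integer percentage reproduces simultaneously
        report = accuracy_report(table_matrix)
        assert list(report["omission"]) == [2, 17, 31, 55, 33, 52]
        assert list(report["commission"]) == [21, 2, 14, 58, 22, 19]
        assert round_half_up(overall_accuracy(table_matrix)) == 81

    def test_accounting_identity(self, table_matrix):
        # omission-weighted column totals and commission-weighted row totals
        # both reconcile with the trace before any rounding
        oc = omission_commission(table_matrix)
        col = table_matrix.counts.sum(axis=0)
        row = table_matrix.counts.sum(axis=1)
        trace = np.trace(table_matrix.counts)
        from_om = np.sum(col * (1 - oc["omission"].to_numpy() / 100))
        from_com = np.sum(row * (1 - oc["commission"].to_numpy() / 100))
        assert from_om == pytest.approx(trace, abs=1e-9)
        assert from_com == pytest.approx(trace, abs=1e-9)

    def test_zero_total_flagged_nan(self):
        cm = ConfusionMatrix([[2, 1], [0, 0]], ["a", "b"])
        oc = omission_commission(cm)
        assert np.isnan(oc.loc["b", "commission"])


class TestAreaAdjusted:
    def test_single_stratum_collapses(self, table_matrix):
        est = area_adjusted_accuracy([(table_matrix, 1.0)])
        assert est.overall == pytest.approx(overall_accuracy(table_matrix), abs=1e-9)
        oc = omission_commission(table_matrix)
        pd.testing.assert_series_equal(
            est.per_class["omission"], oc["omission"],
            check_names=False, atol=1e-9,
        )

    def test_weights_proportional_to_sizes_collapse(self):
        cm1 = ConfusionMatrix([[30, 5], [5, 10]], ["a", "b"])   # n=50
        cm2 = ConfusionMatrix([[80, 10], [20, 40]], ["a", "b"])  # n=150
        est = area_adjusted_accuracy([(cm1, 0.25), (cm2, 0.75)])
        pooled = ConfusionMatrix(cm1.counts + cm2.counts, ["a", "b"])
        assert est.overall == pytest.approx(overall_accuracy(pooled), abs=1e-9)

    def test_two_stratum_hand_example(self):
        # hand-computed before implementation:
        # p11 = .9*40/50 + .1*10/50 = 0.74     p12 = .9*5/50 + .1*10/50 = 0.11
        # p21 = .9*3/50 + .1*10/50 = 0.074     p22 = .9*2/50 + .1*20/50 = 0.076
        cm1 = ConfusionMatrix([[40, 5], [3, 2]], ["a", "b"])
        cm2 = ConfusionMatrix([[10, 10], [10, 20]], ["a", "b"])
        est = area_adjusted_accuracy([(cm1, 0.9), (cm2, 0.1)])
        np.testing.assert_allclose(
            est.proportions, [[0.74, 0.11], [0.074, 0.076]], atol=1e-12
        )
        assert est.overall == pytest.approx(100 * (0.74 + 0.076), abs=1e-9)
        # commission(a) = 100 * (1 - .74/.85); omission(a) = 100 * (1 - .74/.814)
        assert est.per_class.loc["a", "commission"] == pytest.approx(
            100 * (1 - 0.74 / 0.85), abs=1e-9
        )
        assert est.per_class.loc["a", "omission"] == pytest.approx(
            100 * (1 - 0.74 / 0.814), abs=1e-9
        )

    def test_unanimous_strata_zero_se(self):
        cm1 = ConfusionMatrix([[10, 0], [0, 0]], ["a", "b"])
        cm2 = ConfusionMatrix([[0, 0], [0, 20]], ["a", "b"])
        est = area_adjusted_accuracy([(cm1, 0.5), (cm2, 0.5)])
        assert est.overall_se == pytest.approx(0.0, abs=1e-12)

    def test_bad_weights(self):
        cm = ConfusionMatrix([[1, 0], [0, 1]], ["a", "b"])
        with pytest.raises(ValidationError):
            area_adjusted_accuracy([(cm, 0.5), (cm, 0.6)])


def make_plot(trees, **kw):
    return PlotMeasurement(plot_id=1, year=2000, trees=trees, **kw)


class TestPctAgbDefoliated:
    def test_all_coniferous_defoliated(self):
        plot = make_plot([Tree("coniferous", 20, 50, defoliated=True),
                          Tree("coniferous", 15, 30, defoliated=True)])
        assert pct_agb_defoliated(plot) == 100.0

    def test_arithmetic_ratio(self):
        plot = make_plot([Tree("coniferous", 20, 25, defoliated=True),
                          Tree("coniferous", 30, 75, defoliated=False)])
        assert pct_agb_defoliated(plot) == 25.0

    def test_deciduous_defoliation_not_counted(self):
        plot = make_plot([Tree("deciduous", 20, 40, defoliated=True),
                          Tree("coniferous", 25, 60, defoliated=False)])
        assert pct_agb_defoliated(plot) == 0.0

    def test_small_dbh_excluded(self):
        plot = make_plot([Tree("coniferous", 8, 100, defoliated=True),
                          Tree("coniferous", 20, 50, defoliated=False)])
        assert pct_agb_defoliated(plot) == 0.0

    def test_zero_agb_undefined(self):
        with pytest.raises(UndefinedValueError):
            pct_agb_defoliated(make_plot([Tree("coniferous", 5, 10)]))

    def test_order_and_scale_invariance(self):
        trees = [Tree("coniferous", 20, 25, defoliated=True),
                 Tree("deciduous", 12, 35),
                 Tree("coniferous", 30, 40)]
        base = pct_agb_defoliated(make_plot(trees))
        shuffled = pct_agb_defoliated(make_plot(trees[::-1]))
        scaled = pct_agb_defoliated(make_plot(
            [Tree(t.species_group, t.dbh_cm, t.agb * 7.3, t.defoliated)
             for t in trees]
        ))
        assert base == pytest.approx(shuffled, abs=1e-12)
        assert base == pytest.approx(scaled, abs=1e-12)


class TestFilterPlots:
    def test_low_agb_dropped(self):
        plot = make_plot([Tree("coniferous", 20, 40)])
        kept, rejected = filter_plot_measurements([plot])
        assert not kept and "plot_agb_below_50" in rejected[0][1]

    def test_dead_unknown_dropped(self):
        trees = [Tree("coniferous", 20, 20, dead=True) for _ in range(9)]
        trees.append(Tree("coniferous", 20, 20))
        plot = make_plot(trees, mortality_cause_known=False)
        kept, rejected = filter_plot_measurements([plot])
        assert not kept

    def test_dead_known_cause_kept(self):
        trees = [Tree("coniferous", 20, 20, dead=True) for _ in range(9)]
        trees.append(Tree("coniferous", 20, 20))
        plot = make_plot(trees, mortality_cause_known=True)
        kept, _ = filter_plot_measurements([plot])
        assert kept

    def test_good_plot_kept(self):
        plot = make_plot([Tree("coniferous", 25, 120, defoliated=True),
                          Tree("coniferous", 30, 60)])
        kept, rejected = filter_plot_measurements([plot])
        assert kept and not rejected

    def test_deciduous_only_defoliation_dropped(self):
        plot = make_plot([Tree("deciduous", 25, 80, defoliated=True),
                          Tree("coniferous", 30, 60)])
        kept, rejected = filter_plot_measurements([plot])
        assert not kept and "deciduous_defoliation_only" in rejected[0][1]


class TestMajorityNeighborhood:
    def test_uniform_window(self):
        raster = np.full((5, 5), 3)
        assert majority_neighborhood_class(raster, (2, 2)) == 3

    def test_simple_majority(self):
        raster = np.zeros((3, 3), dtype=int)
        raster.ravel()[:5] = 7
        assert majority_neighborhood_class(raster, (1, 1)) == 7

    def test_tie_prefers_disturbed(self):
        raster = np.zeros((3, 3), dtype=int)
        raster.ravel()[:4] = 1      # 4 fire
        raster.ravel()[4] = 2       # 1 harvest
        # 4 background, 4 fire, 1 harvest -> fire wins the tie
        assert majority_neighborhood_class(raster, (1, 1)) == 1

    def test_edge_point_rejected(self):
        with pytest.raises(ValidationError):
            majority_neighborhood_class(np.zeros((5, 5)), (0, 2))


class TestTemporal:
    def test_overlap_is_match(self):
        assert temporal_match({2005}, set(range(2003, 2008)))

    def test_disjoint_no_match(self):
        assert not temporal_match({2005}, {2007})

    def test_empty_prediction_no_match(self):
        assert not temporal_match(set(), {2007})

    def test_empty_reference_errors(self):
        with pytest.raises(ValidationError):
            temporal_match({2005}, set())

    def test_r2_identity(self):
        years = [1990, 1995, 2001, 2010]
        assert r2(years, years) == pytest.approx(1.0)

    def test_r2_reasonable(self):
        obs = np.array([1990, 1995, 2000, 2005, 2010])
        assert 0.9 < r2(obs + np.array([1, -1, 0, 1, -1]), obs) < 1.0


class TestViltsSamplePlan:
    @staticmethod
    def candidates(n_per, strata=("a", "b"), seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for s in strata:
            frames.append(pd.DataFrame({
                "stratum": s,
                "x": rng.uniform(0, 10_000, n_per),
                "y": rng.uniform(0, 10_000, n_per),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_proportional_allocation(self):
        plan = vilts_sample_plan({"a": 5.0, "b": 5.0}, self.candidates(200), n=100)
        assert plan.allocation == {"a": 50, "b": 50}
        assert len(plan.points) == 100

    def test_allocation_sums_exactly(self):
        plan = vilts_sample_plan({"a": 1, "b": 1, "c": 1}, self.candidates(200, "abc"),
                                 n=100)
        assert sum(plan.allocation.values()) == 100

    def test_min_distance_exclusion(self):
        cands = self.candidates(50)
        training = cands[["x", "y"]].to_numpy()  # every candidate is too close
        with pytest.warns(UserWarning):
            plan = vilts_sample_plan({"a": 1.0, "b": 1.0}, cands,
                                     training_points=training, n=10)
        assert len(plan.points) == 0

    def test_far_training_points_ignored(self):
        cands = self.candidates(100)
        training = np.array([[1e9, 1e9]])
        plan = vilts_sample_plan({"a": 1.0, "b": 1.0}, cands,
                                 training_points=training, n=20)
        assert len(plan.points) == 20

    def test_zero_area_stratum_warns(self):
        with pytest.warns(UserWarning, match="zero area"):
            vilts_sample_plan({"a": 1.0, "b": 0.0}, self.candidates(100), n=10)

    def test_seeded_reproducibility(self):
        cands = self.candidates(200)
        p1 = vilts_sample_plan({"a": 1, "b": 2}, cands, n=60, seed=4)
        p2 = vilts_sample_plan({"a": 1, "b": 2}, cands, n=60, seed=4)
        pd.testing.assert_frame_equal(p1.points, p2.points)
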
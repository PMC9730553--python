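import numpy as np
import pytest
from hypothesis import given, strategies as st

import fdd11
from fdd11.calibration import Cutoffs
from fdd11.responses import MISSING, ResponseMatrix
from fdd11.scoring import (
    RecodeMap,
    apply_recodes,
    assign_level,
    build_emotion_testlet,
    combine_twelve_item,
    derive_cutoffs,
    fdd11_recode_map,
    filter_missingness,
    score_persons,
    transform_to_scale,
)

# tolerance for values reconstructed from printed (2-decimal) parameters
PRINT_TOL = 0.02


def _matrix(rows, item_ids, group=None):
    rows = np.asarray(rows)
    return ResponseMatrix(rows, [f"p{i}" for i in range(len(rows))], item_ids, group)


class TestRecode:
    def test_published_recode_rows(self, artifact):
        rm = fdd11_recode_map(artifact)
        assert rm["Q02"] == (0, 1, 1, 2, 2)
        assert rm["Q11"] == (0, 1, 2, 3, 4)
        assert rm["Q01"] == (0, 1, 2, 3, 3)
        assert rm["Q09"] == (0, 1, 1, 2, 2, 3, 3, 4, 4)

    def test_apply_recodes_examples(self, artifact):
        rm = fdd11_recode_map(artifact)
        data = _matrix([[3] * 11, [4] * 11], artifact.item_ids)
        # Q09 column is on the 0-8 testlet-sum scale; 3 -> 2, 4 -> 2
        out = apply_recodes(data, rm)
        assert out.column("Q02")[0] == 2
        assert out.column("Q11")[1] == 4
        # all-maximum original responses give the recoded maximum sum of 30
        full = _matrix([[4, 4, 4, 4, 4, 4, 4, 4, 8, 4, 4]], artifact.item_ids)
        assert apply_recodes(full, rm).sum_scores()[0] == 30

    def test_missing_passes_through(self, artifact):
        rm = fdd11_recode_map(artifact)
        row = [0] * 11
        row[1] = MISSING
        out = apply_recodes(_matrix([row], artifact.item_ids), rm)
        assert out.column("Q02")[0] == MISSING

    def test_out_of_range_category_reported_with_cells(self, artifact):
        rm = fdd11_recode_map(artifact)
        row = [0] * 11
        row[0] = 7
        with pytest.raises(ValueError, match="Q01"):
            apply_recodes(_matrix([row], artifact.item_ids), rm)

    @given(st.lists(st.integers(0, 3), min_size=5, max_size=5))
    def test_recode_maps_preserve_order(self, raws):
        vec = (0, 1, 1, 2, 2)
        rm = RecodeMap({"X": vec})
        rec = [vec[v] for v in raws]
        for a, b in zip(sorted(raws), sorted(raws)[1:]):
            assert vec[a] <= vec[b]
        assert sorted(rec) == [vec[v] for v in sorted(raws)]


class TestEmotionTestlet:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(4, 4, 4), (0, 0, 0), (1, 2, 2), (2, 1, 2), (3, 4, 4), (1, 0, 1)],
    )
    def test_examples(self, a, b, expected):
        assert build_emotion_testlet(a, b) == expected

    def test_missing_propagates(self):
        assert build_emotion_testlet(MISSING, 3) == MISSING
        assert build_emotion_testlet(2, MISSING) == MISSING

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_emotion_testlet(5, 0)

    def test_combine_twelve_item_matrix(self):
        ids = ["Q01", "Q09a", "Q09b", "Q11"]
        data = _matrix([[1, 4, 4, 2], [0, 1, MISSING, 3]], ids)
        out = combine_twelve_item(data)
        assert out.item_ids == ["Q01", "Q09", "Q11"]
        assert out.column("Q09")[0] == 8  # summed scale, pre-recode
        assert out.column("Q09")[1] == MISSING


class TestMissingnessFilter:
    def test_boundary(self):
        ids = [f"Q{j}" for j in range(11)]
        two = [MISSING, MISSING] + [1] * 9
        three = [MISSING, MISSING, MISSING] + [1] * 8
        data = _matrix([two, three, [1] * 11], ids)
        kept, excluded = filter_missingness(data, max_missing=2)
        assert kept.person_ids == ["p0", "p2"]
        assert excluded == ["p1"]

    def test_complete_matrix_identity(self):
        data = _matrix([[1, 2], [0, 1]], ["A", "B"])
        kept, excluded = filter_missingness(data)
        assert excluded == []
        assert np.array_equal(kept.values, data.values)


class TestTransformAndLevels:
    def test_anchor_endpoints(self):
        assert transform_to_scale(-3.71, (-3.71, 4.18)) == 0.0
        assert transform_to_scale(4.18, (-3.71, 4.18)) == 100.0

    @pytest.mark.parametrize("theta,published", [(0.303, 50.85), (-0.31, 43.08)])
    def test_published_rows(self, theta, published):
        assert transform_to_scale(theta, (-3.71, 4.18)) == pytest.approx(
            published, abs=PRINT_TOL
        )

    def test_clamped_outside_anchors(self):
        assert transform_to_scale(-9.0, (-3.71, 4.18)) == 0.0
        assert transform_to_scale(9.0, (-3.71, 4.18)) == 100.0

    def test_affine_on_collinear_points(self):
        anchors = (-3.71, 4.18)
        t = np.array([-1.0, 0.5, 2.0])  # equally spaced
        y = transform_to_scale(t, anchors)
        assert y[1] - y[0] == pytest.approx(y[2] - y[1])

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            transform_to_scale(0.0, (1.0, 1.0))

    @pytest.mark.parametrize(
        "score,level",
        [(39.39, "Moderate"), (41.30, "Severe"), (0.0, "No"), (10.12, "Mild")],
    )
    def test_published_level_rows(self, score, level):
        assert assign_level(score, Cutoffs(4.3, 22.6, 40.8)) == level

    def test_boundary_scores_go_up(self):
        cut = Cutoffs(4.3, 22.6, 40.8)
        assert assign_level(4.3, cut) == "Mild"
        assert assign_level(22.6, cut) == "Moderate"
        assert assign_level(40.8, cut) == "Severe"
        assert assign_level(100.0, cut) == "Severe"


class TestDeriveCutoffs:
    def test_three_point_example(self):
        cut = derive_cutoffs(np.array([10.0, 20.0, 30.0]))
        assert cut.as_tuple() == pytest.approx((10.0, 20.0, 30.0))

    def test_symmetric_sd20(self):
        rng = np.random.default_rng(1)
        x = 50 + 20 * np.sign(rng.standard_normal(4000))  # mean 50, sd ~20
        cut = derive_cutoffs(x)
        assert cut.as_tuple() == pytest.approx((30.0, 50.0, 70.0), abs=1.5)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            derive_cutoffs(np.full(10, 42.0))

    def test_ordering_invariant_on_simulated_population(self, artifact, items):
        data, _ = fdd11.simulate(fdd11.SimConfig(n_persons=2000, seed=2))
        scores = fdd11.score_persons(data, artifact)
        cut = derive_cutoffs(np.array([s.transformed for s in scores]))
        c1, c2, c3 = cut.as_tuple()
        assert 0 < c1 < c2 < c3 < 100


class TestScorePersons:
    def test_published_sum_rows(self, artifact):
        # complete recoded patterns with sums 10 and 2
        ten = [1, 0, 1, 1, 0, 1, 1, 1, 2, 1, 1]
        two = [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1]
        data = _matrix([ten, two], artifact.item_ids)
        s10, s2 = score_persons(data, artifact)
        assert s10.sum_score == 10
        assert s10.transformed == pytest.approx(43.08, abs=0.5)
        assert s10.level == "Severe"
        assert s2.level == "Mild"

    def test_equal_sums_identical_scores(self, artifact):
        a = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0]
        ra, rb = score_persons(_matrix([a, b], artifact.item_ids), artifact)
        assert ra.theta == rb.theta and ra.transformed == rb.transformed

    def test_person_order_invariance(self, artifact):
        rows = [[1] * 11, [2, 1, 2, 1, 0, 1, 1, 1, 3, 2, 4], [0] * 11]
        fwd = score_persons(_matrix(rows, artifact.item_ids), artifact)
        rev = score_persons(_matrix(rows[::-1], artifact.item_ids), artifact)
        assert [s.theta for s in fwd] == [s.theta for s in rev[::-1]]

    def test_extremes_use_anchors(self, artifact):
        rows = [[0] * 11, [3, 2, 3, 3, 2, 2, 2, 2, 4, 3, 4]]
        lo, hi = score_persons(_matrix(rows, artifact.item_ids), artifact)
        assert (lo.theta, lo.transformed, lo.level) == (-3.71, 0.0, "No")
        assert (hi.theta, hi.transformed, hi.level) == (4.18, 100.0, "Severe")
        assert lo.extreme_flag and hi.extreme_flag

    def test_missing_items_scored_on_answered_subset(self, artifact):
        full = [1, 0, 1, 1, 0, 1, 1, 1, 2, 1, 1]
        partial = list(full)
        partial[1] = MISSING  # drops a hard item the person scored 0 on
        sf, sp = score_persons(_matrix([full, partial], artifact.item_ids), artifact)
        assert sp.n_missing == 1
        assert sp.se is not None
        # same sum over fewer items implies at least as high an ability
        assert sp.theta >= sf.theta - 1e-9

    def test_item_mismatch_rejected(self, artifact):
        data = _matrix([[0, 1]], ["Q01", "QXX"])
        with pytest.raises(ValueError, match="mismatch"):
            score_persons(data, artifact)

    def test_classification_matches_published_sum_ranges(self, artifact, score_lookup):
        levels = {}
        for pa in score_lookup:
            tr = transform_to_scale(pa.theta, artifact.anchors)
            levels[pa.sum_score] = assign_level(tr, artifact.cutoffs)
        assert [s for s, l in levels.items() if l == "No"] == [0]
        assert [s for s, l in levels.items() if l == "Mild"] == [1, 2]
        assert [s for s, l in levels.items() if l == "Moderate"] == list(range(3, 9))
        assert [s for s, l in levels.items() if l == "Severe"] == list(range(9, 31))
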
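import numpy as np
import pandas as pd
import pytest

import fdd11
from fdd11.calibration import ItemCalibration
from fdd11.diagnostics import (
    abilities_for_matrix,
    item_infit,
    person_infit,
    person_separation_index,
    residual_correlation_flags,
    score_conditional_moments,
    standardized_residuals,
    suggest_collapse,
    targeting_summary,
    threshold_order_check,
)
from fdd11.pcm import PersonAbility, probability_matrix
from fdd11.responses import ResponseMatrix


def _pa(theta, se):
    return PersonAbility(theta=theta, se=se, sum_score=0, extreme_flag=se is None)


class TestResiduals:
    def test_observed_equals_expected_gives_zero(self):
        # symmetric dichotomous pair at theta = 0: E = 0.5 each
        items = [ItemCalibration("A", (0.0,)), ItemCalibration("B", (0.0,))]
        data = ResponseMatrix(np.array([[1, 0]]), ["p0"], ["A", "B"])
        z = standardized_residuals(data, items, np.array([0.0]), moments="theta")
        assert z[0, 0] == pytest.approx(1.0)  # (1-0.5)/0.5
        assert z[0, 1] == pytest.approx(-1.0)
        assert z[0].sum() == pytest.approx(0.0)

    def test_score_conditional_moments_sum_to_score(self, items):
        E, V = score_conditional_moments(items)
        sums = E.sum(axis=1)
        assert sums == pytest.approx(np.arange(31), abs=1e-10)
        assert np.all(V[1:-1] > 0)

    def test_column_means_near_zero_under_model(self, items, model_true_5000):
        data, _ = model_true_5000
        z = standardized_residuals(data, items)
        means = np.nanmean(z, axis=0)
        assert np.nanmax(np.abs(means)) < 0.05

    def test_missing_propagates(self, items):
        vals = np.ones((4, 11), dtype=int)
        vals[0, 3] = -1
        data = ResponseMatrix(vals, [f"p{i}" for i in range(4)], [it.item_id for it in items])
        z = standardized_residuals(data, items)
        assert np.isnan(z[0, 3])


class TestInfit:
    def test_item_infit_near_one_under_model(self, items, model_true_5000):
        data, _ = model_true_5000
        fit = item_infit(data, items)
        assert fit.between(0.9, 1.1).all()
        assert fit.mean() == pytest.approx(1.0, abs=0.05)

    def test_double_discrimination_item_flagged_as_overfitting(self, items, model_true_5000):
        data, thetas = model_true_5000
        rng = np.random.default_rng(77)
        j = data.item_ids.index("Q06")
        it = items[j]
        steep = ItemCalibration("tmp", tuple(2 * t for t in it.thresholds))
        P = probability_matrix(2 * thetas, steep)  # slope doubled
        vals = data.values.copy()
        vals[:, j] = (rng.random(len(thetas))[:, None] > P.cumsum(1)[:, :-1]).sum(1)
        tampered = ResponseMatrix(vals, data.person_ids, data.item_ids)
        fit = item_infit(tampered, items)
        assert fit["Q06"] < 0.7

    def test_single_person_degenerate(self, items):
        data = ResponseMatrix(np.ones((1, 11), dtype=int), ["p0"], [i.item_id for i in items])
        fit = item_infit(data, items)
        assert fit.isna().all()

    def test_person_perfectly_expected_has_near_zero_infit(self):
        # at theta = 0 each symmetric 3-category item has E = 1 exactly
        items = [ItemCalibration(c, (-2.0, 2.0)) for c in "ABCDE"]
        data = ResponseMatrix(np.ones((2, 5), dtype=int), ["p0", "p1"], list("ABCDE"))
        fit, _ = person_infit(data, items, np.zeros(2), moments="theta")
        assert fit["p0"] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_extreme_person_misfits(self, items, model_true_5000):
        data, _ = model_true_5000
        maxc = np.array([it.max_category for it in items])
        alt = np.where(np.arange(11) % 2 == 0, maxc, 0)
        stacked = ResponseMatrix(
            np.vstack([data.values, alt]), list(data.person_ids) + ["alt"], data.item_ids
        )
        fit, frac = person_infit(stacked, items)
        assert fit["alt"] > 2.0

    def test_misfit_fraction_order_five_percent_under_model(self, items, model_true_5000):
        data, _ = model_true_5000
        _, frac = person_infit(data, items)
        assert 0.005 < frac < 0.10


class TestLocalDependence:
    def test_duplicated_item_flagged(self, items, model_true_5000):
        data, _ = model_true_5000
        vals = np.column_stack([data.values, data.values[:, -1]])
        dup = ResponseMatrix(
            vals, data.person_ids, data.item_ids + ["Q11b"]
        )
        z = standardized_residuals(dup, list(items) + [items[-1]])
        _, flags, _ = residual_correlation_flags(z, dup.item_ids)
        assert ("Q11", "Q11b") in flags

    def test_independent_items_unflagged(self, items, model_true_5000):
        data, _ = model_true_5000
        z = standardized_residuals(data, items)
        corr, flags, threshold = residual_correlation_flags(z, data.item_ids)
        assert flags == []
        # the sum constraint pushes the mean off-diagonal correlation to
        # about -1/(I-1), so the flag threshold lands near 0.2 - 0.1
        assert threshold == pytest.approx(0.1, abs=0.03)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="3 items"):
            residual_correlation_flags(np.zeros((10, 2)), ["A", "B"])


class TestThresholdOrder:
    def test_published_calibration_ordered(self, items):
        assert threshold_order_check(items) == []

    def test_inverted_pair_flagged(self):
        assert threshold_order_check([ItemCalibration("X", (0.5, -0.2))]) == ["X"]

    def test_single_threshold_never_flagged(self):
        assert threshold_order_check([ItemCalibration("X", (1.0,))]) == []


class TestSuggestCollapse:
    @pytest.fixture(scope="class")
    def disordered_data(self):
        # middle category rarely modal -> disordered estimated thresholds
        bad = ItemCalibration("B1", (0.5, -0.2))
        items = [ItemCalibration(f"I{k}", (-0.8 + 0.4 * k,)) for k in range(4)] + [bad]
        cfg = fdd11.SimConfig(
            n_persons=3000, seed=9, items=items,
            ability=fdd11.AbilityModel(p_floor=0.0, mean=0.0, sd=1.2),
        )
        return fdd11.simulate(cfg)[0]

    def test_collapse_restores_ordering(self, disordered_data):
        result = fdd11.calibrate_items_cml(disordered_data)
        assert "B1" in threshold_order_check(result.items)
        recodes, steps = suggest_collapse(disordered_data, result)
        assert len(steps) >= 1
        refit = fdd11.calibrate_items_cml(fdd11.apply_recodes(disordered_data, recodes))
        assert threshold_order_check(refit.items) == []

    def test_maps_monotone_surjective(self, disordered_data):
        recodes, _ = suggest_collapse(disordered_data)
        for item_id, vec in recodes.maps.items():
            assert list(vec) == sorted(vec)
            assert set(vec) == set(range(max(vec) + 1))

    def test_ordered_instrument_untouched(self, items, model_true_5000):
        data, _ = model_true_5000
        result = fdd11.calibrate_items_cml(data)
        recodes, steps = suggest_collapse(data, result)
        assert steps == []
        for item_id, vec in recodes.maps.items():
            assert list(vec) == list(range(len(vec)))


class TestPersonSeparation:
    def test_zero_error_gives_one(self):
        abil = [_pa(t, 1e-9) for t in (-1.0, 0.0, 1.0, 2.0)]
        assert person_separation_index(abil) == pytest.approx(1.0, abs=1e-9)

    def test_error_equal_to_variance_floors_at_zero(self):
        thetas = [-1.0, 1.0, -1.0, 1.0]
        sd = np.std(thetas, ddof=1)
        abil = [_pa(t, sd) for t in thetas]
        assert person_separation_index(abil) == 0.0

    def test_increases_with_ability_spread(self, items):
        psis = []
        for sd in (0.5, 1.0, 2.0):
            cfg = fdd11.SimConfig(
                n_persons=3000, seed=23,
                ability=fdd11.AbilityModel(p_floor=0.0, mean=-1.0, sd=sd),
            )
            data, _ = fdd11.simulate(cfg)
            abil = abilities_for_matrix(data, items)
            psis.append(person_separation_index(abil))
        assert psis[0] < psis[1] < psis[2]

    def test_exclude_extremes_variant_is_lower_on_skewed_data(self, items):
        data, _ = fdd11.simulate(fdd11.SimConfig(n_persons=2000, seed=29))
        abil = abilities_for_matrix(data, items)
        assert person_separation_index(abil, include_extremes=False) <= person_separation_index(abil)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            person_separation_index([_pa(0.0, 0.1)])
        with pytest.raises(ValueError):
            person_separation_index([_pa(1.0, 0.1), _pa(1.0, 0.1)])


class TestTargeting:
    def test_published_item_row(self, items):
        # computed over all thresholds; matches the published targeting table
        # to the rounding of the printed thresholds
        abil = [_pa(t, 0.3) for t in (-1.0, 0.0)]
        t = targeting_summary(abil, items)
        assert t.item_mean == pytest.approx(0.2863, abs=0.005)
        assert t.item_sd == pytest.approx(0.7788, abs=0.005)
        assert t.item_range == (-1.48, 1.74)

    def test_person_moments_recovered(self, items, model_true_5000):
        data, thetas = model_true_5000
        abil = abilities_for_matrix(data, items)
        t = targeting_summary(abil, items)
        # extreme scorers are excluded by default, so the estimate mean sits
        # slightly above the generating mean on this floor-heavy population
        assert t.person_mean == pytest.approx(-1.2733, abs=0.25)
        # estimated-ability SD exceeds the true SD (estimation noise)
        assert 0.9 < t.person_sd < 1.6

    def test_single_item_sd_zero(self):
        t = targeting_summary([_pa(0.0, 0.1), _pa(1.0, 0.1)], [ItemCalibration("X", (0.3,))])
        assert t.item_sd == 0.0
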
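import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from palscout.diffstats import (
    P_FLOOR,
    bky_fdr,
    compare_conditions,
    paired_t_test,
    two_sample_t_test,
)
from palscout.io_tables import SampleDesign, ValidationError
from palscout.preprocess import log2_transform

from conftest import make_matrix


class TestPairedT:
    def test_identical_pairs_null(self):
        a = np.arange(8.0)
        t, p = paired_t_test(a, a)
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_differences_floored(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_t_test(a + 1.0, a)
        assert p == P_FLOOR and np.isinf(t) and t > 0

    def test_textbook_computation(self):
        """Differences [0.8,1.2,1.0,1.1,0.9]: t = mean/(sd/sqrt(5))."""
        b = np.zeros(5)
        a = np.array([0.8, 1.2, 1.0, 1.1, 0.9])
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(14.142135623730953)
        assert p == pytest.approx(0.00014512817061319757)

    def test_pairs_with_missing_member_dropped(self):
        a = np.array([1.0, 2.0, np.nan, 4.0])
        b = np.array([0.0, 1.0, 2.0, np.nan])
        t, p = paired_t_test(a, b)
        t2, p2 = paired_t_test(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert (t, p) == (t2, p2)

    def test_fewer_than_two_pairs_is_error(self):
        with pytest.raises(ValidationError, match="complete pairs"):
            paired_t_test([1.0, np.nan], [0.0, 1.0])


class TestWelchT:
    def test_identical_groups(self):
        a = np.array([1.0, 1.0, 1.0])
        assert two_sample_t_test(a, a) == (0.0, 1.0)

    def test_clear_separation(self):
        rng = np.random.default_rng(0)
        a = 1 + rng.normal(0, 1e-3, 5)
        b = 3 + rng.normal(0, 1e-3, 5)
        _, p = two_sample_t_test(a, b)
        assert p < 1e-3

    def test_against_brute_force_welch_formula(self):
        a = [5.1, 4.9, 5.3, 5.0, 4.8]
        b = [6.2, 6.0, 5.9, 6.4, 6.1]
        t, p = two_sample_t_test(a, b)
        assert t == pytest.approx(-9.041944301794649)
        assert p == pytest.approx(1.790820533733078e-05)

    def test_small_group_is_error(self):
        with pytest.raises(ValidationError, match="2 values per group"):
            two_sample_t_test([1.0], [1.0, 2.0])


class TestBKY:
    def test_all_ones_no_rejections(self):
        q, rej = bky_fdr(np.ones(10))
        assert not rej.any()
        np.testing.assert_array_equal(q, 1.0)

    def test_single_small_p_rejected(self):
        q, rej = bky_fdr([0.01], alpha=0.05)
        assert rej[0]
        # with m = 1 the procedure reduces to p <= alpha/(1+alpha), so the
        # smallest rejecting alpha is p/(1-p)
        assert q[0] == pytest.approx(0.01 / 0.99)

    def test_published_example_vector(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569,
             0.594, 0.696, 0.762, 0.94, 0.942, 0.975, 1.0]
        q, rej = bky_fdr(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        np.testing.assert_array_equal(rej, ref)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValidationError, match="p-values"):
                bky_fdr(bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_reference_and_dominates_bh(self, seed):
        """Two-stage rejections equal statsmodels' and contain BH's."""
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 120)
        # mix of null and signal p-values
        p = np.concatenate([
            rng.uniform(size=m), rng.uniform(0, 1e-3, size=rng.integers(0, 6))
        ])
        p = np.clip(p, 1e-12, 1.0)
        q, rej = bky_fdr(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        np.testing.assert_array_equal(rej, ref)
        bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert (rej | ~bh).all()  # BKY rejections are a superset of BH's
        # q-values are monotone in p-value rank and consistent with reject
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        np.testing.assert_array_equal(q <= 0.05, rej)


class TestCompareConditions:
    def _design(self, n=4):
        rows = []
        for cond in ("vehicle", "probe"):
            for r in range(1, n + 1):
                rows.append((f"{cond}_{r}", cond, r, "biological"))
        return SampleDesign(
            pd.DataFrame(rows, columns=["sample_id", "condition",
                                        "replicate_index", "role"])
        )

    def test_duplicated_columns_are_null(self):
        design = self._design()
        rng = np.random.default_rng(1)
        half = rng.lognormal(3, 1, size=(20, 4))
        m = make_matrix(
            np.hstack([half, half]),
            samples=[f"{c}_{r}" for c in ("vehicle", "probe")
                     for r in range(1, 5)],
        )
        res = compare_conditions(log2_transform(m), design, "probe", "vehicle")
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_spiked_feature_ranks_first(self):
        design = self._design(8)
        rng = np.random.default_rng(42)
        log2 = rng.normal(20, 0.1, size=(200, 16))
        log2[0, 8:] += 2.0  # +2 log2 in probe, all 8 pairs
        m = make_matrix(
            2.0 ** log2,
            samples=[f"{c}_{r}" for c in ("vehicle", "probe")
                     for r in range(1, 9)],
        )
        res = compare_conditions(log2_transform(m), design, "probe", "vehicle")
        top = res.sort_values("neglog10p", ascending=False).iloc[0]
        assert top["feature_id"] == "F1"
        assert top["log2fc"] == pytest.approx(2.0, abs=0.2)

    def test_hand_computed_fold_changes(self):
        design = self._design(2)
        # log2 values chosen so paired differences are exact
        log2 = np.array(
            [[1.0, 2.0, 3.0, 4.0],   # diffs (probe - vehicle): 2, 2
             [5.0, 5.0, 6.0, 7.0],   # diffs: 1, 2
             [2.0, 1.0, 2.0, 1.0]],  # diffs: 0, 0
        )
        m = make_matrix(2.0 ** log2,
                        samples=["vehicle_1", "vehicle_2",
                                 "probe_1", "probe_2"])
        res = compare_conditions(
            log2_transform(m), design, "probe", "vehicle"
        ).set_index("feature_id")
        assert res.loc["F1", "log2fc"] == pytest.approx(2.0)
        assert res.loc["F2", "log2fc"] == pytest.approx(1.5)
        assert res.loc["F3", "log2fc"] == pytest.approx(0.0)
        assert res.loc["F3", "p"] == 1.0
        # y = -log10(p) exactly
        np.testing.assert_allclose(
            res["neglog10p"], -np.log10(res["p"])
        )

    def test_antisymmetry_of_direction(self):
        design = self._design(4)
        rng = np.random.default_rng(9)
        vals = rng.lognormal(10, 1, size=(30, 8))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = log2_transform(make_matrix(
            vals,
            samples=[f"{c}_{r}" for c in ("vehicle", "probe")
                     for r in range(1, 5)],
        ))
        ab = compare_conditions(m, design, "probe", "vehicle")
        ba = compare_conditions(m, design, "vehicle", "probe")
        merged = ab.merge(ba, on="feature_id", suffixes=("_ab", "_ba"))
        np.testing.assert_allclose(merged["log2fc_ab"], -merged["log2fc_ba"])
        np.testing.assert_allclose(merged["p_ab"], merged["p_ba"])

    def test_absent_condition_is_error(self):
        design = self._design(2)
        m = log2_transform(make_matrix(
            np.ones((3, 4)) * 2,
            samples=["vehicle_1", "vehicle_2", "probe_1", "probe_2"],
        ))
        with pytest.raises(ValidationError, match="absent"):
            compare_conditions(m, design, "probe", "competition")

    def test_features_without_enough_pairs_skipped(self):
        design = self._design(2)
        vals = np.array([[1.0, 2.0, 4.0, 8.0],
                         [np.nan, 2.0, 4.0, np.nan]])
        m = log2_transform(make_matrix(
            vals, samples=["vehicle_1", "vehicle_2", "probe_1", "probe_2"]
        ))
        res = compare_conditions(m, design, "probe", "vehicle")
        assert res["feature_id"].tolist() == ["F1"]
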
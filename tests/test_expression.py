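import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combotx.errors import DomainError, NormalizationError
from combotx.expression import (
    CountMatrix,
    NormalizedExpression,
    filter_low_counts,
    fold_change_vs_reference,
    fold_vs_control,
    threshold_and_rank,
    upper_quartile_normalize,
)


def make_matrix(counts: np.ndarray, conditions=None, genes=None):
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    if conditions is None:
        conditions = ["vehicle"] * (n_samples // 2) + ["treated"] * (n_samples - n_samples // 2)
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(conditions, index=samples),
    )


class TestFilterLowCounts:
    def test_boundary_at_five_total_counts(self):
        m = make_matrix(np.array([[1, 3], [2, 3], [0, 0]]))  # totals 4, 5, 0
        kept = filter_low_counts(m, min_total=5)
        assert list(kept.counts.index) == ["g1"]

    def test_all_zero_matrix_empties(self):
        kept = filter_low_counts(make_matrix(np.zeros((5, 3), int)))
        assert kept.counts.empty

    def test_matches_row_sum_oracle(self, rng):
        counts = rng.integers(0, 10, size=(100, 4))
        kept = filter_low_counts(make_matrix(counts), min_total=5)
        expected = [f"g{i}" for i in range(100) if counts[i].sum() >= 5]
        assert list(kept.counts.index) == expected


class TestUpperQuartileNormalize:
    def test_identical_samples_get_equal_factors(self, rng):
        col = rng.integers(0, 200, size=50)
        m = make_matrix(np.column_stack([col, col]))
        norm = upper_quartile_normalize(m)
        assert norm.scale_factors.iloc[0] == pytest.approx(norm.scale_factors.iloc[1])
        ratio = norm.values.iloc[:, 0] / np.maximum(m.counts.iloc[:, 0], 1)
        assert ratio.nunique() <= 2  # proportional to input

    def test_pure_depth_multiplier_exactly_removed(self, rng):
        """Sample B = 2 x sample A normalizes to byte-identical values."""
        col = rng.integers(1, 500, size=200)
        m = make_matrix(np.column_stack([col, 2 * col]))
        norm = upper_quartile_normalize(m)
        np.testing.assert_array_equal(norm.values.iloc[:, 0], norm.values.iloc[:, 1])

    def test_post_normalization_percentiles_agree(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(300, 6))
        norm = upper_quartile_normalize(make_matrix(counts, conditions=["c"] * 6))
        expressed = norm.values.loc[counts.sum(axis=1) > 0]
        p75 = expressed.quantile(0.75)
        assert (p75.max() - p75.min()) / p75.mean() < 1e-9

    def test_zero_upper_quartile_rejected(self):
        counts = np.zeros((10, 2), int)
        counts[0, 0] = 100  # sample 1 has one expressed gene; sample 2 p75 = 0
        with pytest.raises(NormalizationError):
            upper_quartile_normalize(make_matrix(counts))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_commutes_with_sample_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 300, size=(40, 5))
        m = make_matrix(counts, conditions=["c"] * 5)
        norm = upper_quartile_normalize(filter_low_counts(m))
        perm = rng.permutation(5)
        m2 = CountMatrix(m.counts.iloc[:, perm], m.conditions)
        norm2 = upper_quartile_normalize(filter_low_counts(m2))
        pd.testing.assert_frame_equal(norm2.values, norm.values.iloc[:, perm], rtol=1e-12)


class TestFoldChange:
    def norm(self):
        # already-normalized values so fold changes are read off directly
        values = pd.DataFrame(
            np.array([[10.0, 10.0, 20.0, 20.0], [40.0, 40.0, 40.0, 40.0],
                      [5.0, 5.0, 1.0, 1.0]]),
            index=["g0", "g1", "g2"],
            columns=["s0", "s1", "s2", "s3"],
        )
        conditions = pd.Series(
            ["vehicle", "vehicle", "treated", "treated"], index=values.columns
        )
        return NormalizedExpression(values, pd.Series(1.0, index=values.columns),
                                    conditions)

    def test_reference_vs_itself_is_one(self):
        fc = fold_change_vs_reference(self.norm(), "vehicle", "vehicle", pseudocount=0.0)
        assert np.allclose(fc.fold_change, 1.0)

    def test_two_fold_gene(self):
        fc = fold_change_vs_reference(self.norm(), "treated", "vehicle", pseudocount=0.0)
        assert fc.fold_change.loc["g0"] == pytest.approx(2.0)
        assert fc.log2_fc.loc["g0"] == pytest.approx(1.0)

    def test_matches_ratio_oracle(self, rng):
        counts = rng.integers(1, 100, size=(30, 4))
        m = make_matrix(counts, conditions=["vehicle", "vehicle", "treated", "treated"])
        norm = upper_quartile_normalize(m)
        fc = fold_change_vs_reference(norm, "treated", "vehicle", pseudocount=0.5)
        v = norm.values
        expected = (v[["s2", "s3"]].mean(axis=1) + 0.5) / (v[["s0", "s1"]].mean(axis=1) + 0.5)
        np.testing.assert_allclose(fc.fold_change, expected, rtol=1e-12)

    def test_missing_condition_raises_key_error(self):
        with pytest.raises(KeyError):
            fold_change_vs_reference(self.norm(), "absent")


class TestThresholdAndRank:
    def fc_table(self, folds):
        fc = pd.Series(folds)
        return pd.DataFrame({"fold_change": fc, "log2_fc": np.log2(fc)})

    def test_threshold_boundary(self):
        ranked = threshold_and_rank(self.fc_table({"a": 1.49, "b": 1.50, "c": 1 / 1.50}))
        assert set(ranked.genes) == {"b", "c"}

    def test_unregulated_input_gives_empty_list_with_warning(self):
        with pytest.warns(UserWarning):
            ranked = threshold_and_rank(self.fc_table({"a": 1.0, "b": 1.0}))
        assert len(ranked) == 0

    def test_order_matches_hand_sorted_expectation(self):
        folds = {"up2": 4.0, "up1": 2.0, "dn1": 0.5, "dn2": 0.25, "mid": 1.1}
        ranked = threshold_and_rank(self.fc_table(folds))
        assert list(ranked.genes) == ["up2", "up1", "dn1", "dn2"]

    def test_invariant_to_row_order(self, rng):
        folds = {f"g{i}": float(f) for i, f in enumerate(rng.uniform(0.2, 5.0, 30))}
        table = self.fc_table(folds)
        shuffled = table.sample(frac=1.0, random_state=1)
        r1 = threshold_and_rank(table)
        r2 = threshold_and_rank(shuffled)
        assert r1.genes == r2.genes
        np.testing.assert_array_equal(r1.scores, r2.scores)


class TestFoldVsControl:
    def test_control_is_one_and_treated_scaled(self):
        values = pd.Series([100.0, 100.0, 300.0, 300.0])
        groups = pd.Series(["dmso", "dmso", "combo", "combo"])
        folds = fold_vs_control(values, groups, "dmso")
        assert folds["dmso"] == pytest.approx(1.0)
        assert folds["combo"] == pytest.approx(3.0)

    def test_zero_control_mean_rejected(self):
        values = pd.Series([0.0, 0.0, 5.0])
        groups = pd.Series(["dmso", "dmso", "combo"])
        with pytest.raises(DomainError):
            fold_vs_control(values, groups, "dmso")

    def test_missing_control_rejected(self):
        with pytest.raises(KeyError):
            fold_vs_control(pd.Series([1.0]), pd.Series(["a"]), "dmso")
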
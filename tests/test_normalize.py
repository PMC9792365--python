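import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtdiff import (
    AbundanceTable,
    DesignError,
    InputError,
    StateError,
    TransformError,
    batch_pca,
    drop_missing,
    log2_zscore,
    median_center,
    reference_normalize,
)
from tmtdiff.containers import NormalizedMatrix

from conftest import FULL_STEPS, make_matrix


def table_from(values, groups, batches, steps=()):
    values = np.asarray(values, dtype=float)
    cols = [f"s{i}" for i in range(values.shape[1])]
    data = pd.DataFrame(values, index=[f"P{i}" for i in range(values.shape[0])], columns=cols)
    ann = pd.DataFrame({"group": groups, "batch": batches}, index=cols)
    return AbundanceTable(data, ann, steps=list(steps))


class TestReferenceNormalize:
    def test_sample_equal_to_reference_gives_ratio_one(self):
        t = table_from([[5, 5, 5]], ["case", "control", "reference"], ["B1"] * 3)
        out = reference_normalize(t)
        assert (out.data.to_numpy() == 1.0).all()
        assert list(out.data.columns) == ["s0", "s1"]  # reference dropped

    def test_missing_reference_blanks_that_batch(self):
        t = table_from(
            [[2, 2, 1, 4, 4, np.nan]],
            ["case", "control", "reference"] * 2,
            ["B1"] * 3 + ["B2"] * 3,
        )
        out = reference_normalize(t)
        assert out.data.loc["P0", ["s0", "s1"]].tolist() == [2.0, 2.0]
        assert out.data.loc["P0", ["s3", "s4"]].isna().all()

    def test_shared_batch_shift_cancels_exactly(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(3, 1, size=(30, 3))
        shifted = base * 2.0**1.7  # same multiplicative shift on every channel
        t0 = table_from(base, ["case", "control", "reference"], ["B1"] * 3)
        t1 = table_from(shifted, ["case", "control", "reference"], ["B1"] * 3)
        np.testing.assert_allclose(
            reference_normalize(t0).data, reference_normalize(t1).data, rtol=1e-12
        )

    def test_batch_without_reference_is_a_design_error(self):
        t = table_from([[1, 2]], ["case", "control"], ["B1", "B1"])
        with pytest.raises(DesignError, match="B1"):
            reference_normalize(t)

    def test_missing_propagates_through_division(self):
        t = table_from([[np.nan, 2, 1]], ["case", "control", "reference"], ["B1"] * 3)
        out = reference_normalize(t)
        assert np.isnan(out.data.loc["P0", "s0"])
        assert out.data.loc["P0", "s1"] == 2.0


class TestMedianCenter:
    def test_hand_examples(self):
        t = table_from(
            [[2, 2, 2, 4], [1, 2, 3, np.nan]],
            ["case", "case", "control", "control"],
            ["B1"] * 4,
            steps=["reference_normalize"],
        )
        out = median_center(t)
        assert out.data.loc["P0"].tolist() == [1, 1, 1, 2]
        np.testing.assert_allclose(
            out.data.loc["P1"].tolist()[:3], [0.5, 1.0, 1.5]
        )

    def test_all_missing_row_passes_through(self):
        t = table_from(
            [[np.nan, np.nan], [1.0, 3.0]],
            ["case", "control"], ["B1"] * 2,
            steps=["reference_normalize"],
        )
        out = median_center(t)
        assert out.data.loc["P0"].isna().all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_median_is_one(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0, 1, size=(40, 8))
        t = table_from(vals, ["case"] * 4 + ["control"] * 4, ["B1"] * 8,
                       steps=["reference_normalize"])
        out = median_center(t)
        np.testing.assert_allclose(out.data.median(axis=1), 1.0, rtol=1e-12)

    def test_requires_reference_normalization_first(self):
        t = table_from([[1, 2]], ["case", "control"], ["B1"] * 2)
        with pytest.raises(StateError):
            median_center(t)


class TestLog2Zscore:
    def test_hand_example_sample_sd_convention(self):
        # column {1,2,4} -> log2 {0,1,2} -> z with ddof=1 SD 1 -> {-1,0,1}
        t = table_from(
            [[1.0], [2.0], [4.0]],
            ["case"], ["B1"],
            steps=["reference_normalize", "median_center"],
        )
        out = log2_zscore(t)
        np.testing.assert_allclose(out.data["s0"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_columns_are_standardized(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.lognormal(0, 1, (50, 6)), ["case"] * 3 + ["control"] * 3,
                       ["B1"] * 6, steps=["reference_normalize", "median_center"])
        out = log2_zscore(t)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_protein_axis_option(self):
        rng = np.random.default_rng(1)
        t = table_from(rng.lognormal(0, 1, (5, 10)), ["case"] * 5 + ["control"] * 5,
                       ["B1"] * 10, steps=["reference_normalize", "median_center"])
        out = log2_zscore(t, axis="protein")
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_degenerate_constant_column_flagged(self):
        t = table_from(np.ones((4, 2)), ["case", "control"], ["B1"] * 2,
                       steps=["reference_normalize", "median_center"])
        with pytest.raises(TransformError, match="zero-variance"):
            log2_zscore(t)

    def test_non_positive_value_names_protein_and_sample(self):
        t = table_from([[1.0, 2.0], [1.0, 3.0]], ["case", "control"], ["B1"] * 2,
                       steps=["reference_normalize", "median_center"])
        # negatives cannot enter via the constructor; simulate a corrupted
        # intermediate to exercise the defensive transform guard
        t.data.iloc[0, 1] = -2.0
        with pytest.raises(TransformError, match="P0.*s1"):
            log2_zscore(t)


class TestDropMissing:
    def test_counts_and_identity(self):
        m = make_matrix(
            [[1, 2], [np.nan, 1], [3, 4], [1, np.nan], [0.5, 2]],
            ["case", "control"],
            steps=FULL_STEPS[:3],
        )
        out = drop_missing(m)
        assert list(out.data.index) == ["P0000", "P0002", "P0004"]
        again = drop_missing(make_matrix(out.data.to_numpy(), ["case", "control"],
                                         steps=FULL_STEPS[:3]))
        assert len(again.data) == 3

    def test_retained_fraction_matches_binomial_expectation(self):
        # entries drop independently: retention ~ (1-r)^n_samples
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10_000, 30))
        mask = rng.random(vals.shape) < 0.02
        vals[mask] = np.nan
        m = make_matrix(vals, ["case"] * 15 + ["control"] * 15, steps=FULL_STEPS[:3])
        frac = len(drop_missing(m).data) / 10_000
        expect = 0.98**30
        assert frac == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / 10_000))


class TestBatchPca:
    def test_indistinguishable_batches_show_no_separation(self):
        rng = np.random.default_rng(3)
        # exact duplicates across fictitious batches: each sample's nearest
        # neighbour sits in the other batch, so separation is absent
        block = rng.normal(size=(30, 4))
        m = make_matrix(np.hstack([block, block]),
                        ["case", "case", "control", "control"] * 2,
                        batches=["B1"] * 4 + ["B2"] * 4)
        _, sil = batch_pca(m)
        assert sil <= 0.05
        # iid samples with arbitrary batch labels: silhouette near zero
        m2 = make_matrix(rng.normal(size=(40, 12)),
                         ["case"] * 6 + ["control"] * 6,
                         batches=["B1", "B2"] * 6)
        _, sil2 = batch_pca(m2)
        assert abs(sil2) < 0.2

    def test_coordinates_invariant_to_protein_order(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(40, 6))
        m1 = make_matrix(vals, ["case"] * 3 + ["control"] * 3, batches=["B1", "B1", "B1", "B2", "B2", "B2"])
        perm = rng.permutation(40)
        m2 = NormalizedMatrix(m1.data.iloc[perm], m1.annotations, steps=list(m1.steps))
        c1, s1 = batch_pca(m1)
        c2, s2 = batch_pca(m2)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_too_few_samples_rejected(self):
        m = make_matrix([[1.0, 2.0], [0.0, 1.0]], ["case", "control"])
        with pytest.raises(InputError, match="3 samples"):
            batch_pca(m)
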
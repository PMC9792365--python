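import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmtdiff import (
    BootAucConfig,
    InputError,
    auc,
    bootauc_q,
    bootstrap_auc,
    null_bootstrap_auc,
    rank_by_sd,
)

from conftest import make_matrix


def brute_force_auc(scores, labels):
    """Independent oracle: explicit loop over all case-control pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auc([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5

    def test_enumerated_example(self):
        # pairs (3,2)+ (3,0)+ (1,2)- (1,0)+ -> 3/4
        assert auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_matches_mannwhitney_u_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 8, size=2)
            scores = rng.integers(0, 6, size=n1 + n2).astype(float)  # force ties
            labels = np.array([1] * n1 + [0] * n2)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided")
            assert auc(scores, labels) == pytest.approx(u.statistic / (n1 * n2), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_score_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 10, size=2)
        scores = rng.normal(size=n1 + n2)
        labels = np.array([1] * n1 + [0] * n2)
        assert auc(-scores, labels) == pytest.approx(1 - auc(scores, labels), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(InputError):
            auc([1.0, 2.0], [1, 1])


class TestBootstrapAuc:
    def test_separated_protein_saturates(self):
        vals = np.concatenate([np.full(5, 10.0), np.zeros(5)])[None, :]
        m = make_matrix(vals, ["case"] * 5 + ["control"] * 5)
        out = bootstrap_auc(m, config=BootAucConfig(n_bootstrap=100, seed=1))
        assert out.loc["P0000", "mean_auc"] == 1.0
        assert out.loc["P0000", "sd_auc"] == 0.0

    def test_null_proteins_center_on_half(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(300, 30)), ["case"] * 15 + ["control"] * 15)
        out = bootstrap_auc(m, config=BootAucConfig(n_bootstrap=100, seed=3))
        se = out["mean_auc"].std() / np.sqrt(len(out))
        assert abs(out["mean_auc"].mean() - 0.5) < 3 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(40, 12)), ["case"] * 6 + ["control"] * 6)
        cfg = BootAucConfig(n_bootstrap=50, seed=5)
        pd.testing.assert_frame_equal(bootstrap_auc(m, config=cfg), bootstrap_auc(m, config=cfg))

    def test_matches_naive_resampling_oracle(self):
        """The multiplicity-weighted einsum equals plain resampling in law."""
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(1, 16))
        vals[0, :8] += 1.0
        labels = np.array([1] * 8 + [0] * 8)
        m = make_matrix(vals, ["case"] * 8 + ["control"] * 8)
        ours = bootstrap_auc(m, config=BootAucConfig(n_bootstrap=4000, seed=7))
        naive = []
        for _ in range(4000):
            cs = rng.choice(vals[0, :8], size=8, replace=True)
            ks = rng.choice(vals[0, 8:], size=8, replace=True)
            naive.append(auc(np.concatenate([cs, ks]), labels))
        naive = np.asarray(naive)
        se = naive.std() / np.sqrt(len(naive))
        assert ours.loc["P0000", "mean_auc"] == pytest.approx(naive.mean(), abs=4 * se)
        assert ours.loc["P0000", "sd_auc"] == pytest.approx(naive.std(ddof=1), rel=0.1)

    def test_more_resamples_stabilize_the_mean(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(30, 12)), ["case"] * 6 + ["control"] * 6)
        spread = {}
        for B in (25, 400):
            means = [
                bootstrap_auc(m, config=BootAucConfig(n_bootstrap=B, seed=s))["mean_auc"]
                for s in range(8)
            ]
            spread[B] = np.std(np.stack(means), axis=0).mean()
        assert spread[400] < spread[25]


class TestNullBootstrapAuc:
    def test_bookkeeping_single_permutation(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(2, 8)), ["case"] * 4 + ["control"] * 4)
        out = null_bootstrap_auc(
            m, config=BootAucConfig(n_bootstrap=20, n_label_permutations=1, seed=1)
        )
        assert len(out) == 2
        assert set(out["permutation"]) == {0}
        assert set(out["protein"]) == {"P0000", "P0001"}

    def test_permuted_spiked_data_centers_on_half(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(100, 20))
        vals[:30, :10] += 1.0  # real signal, destroyed by permutation
        m = make_matrix(vals, ["case"] * 10 + ["control"] * 10)
        out = null_bootstrap_auc(
            m, config=BootAucConfig(n_bootstrap=50, n_label_permutations=10, seed=2)
        )
        assert out["mean_auc"].mean() == pytest.approx(0.5, abs=0.02)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(10, 8)), ["case"] * 4 + ["control"] * 4)
        cfg = BootAucConfig(n_bootstrap=20, n_label_permutations=3, seed=4)
        pd.testing.assert_frame_equal(
            null_bootstrap_auc(m, config=cfg), null_bootstrap_auc(m, config=cfg)
        )


class TestBootaucQ:
    def _rows(self, means):
        return pd.DataFrame(
            {"auc": means, "mean_auc": means, "sd_auc": np.full(len(means), 0.1)},
            index=[f"P{i}" for i in range(len(means))],
        )

    def _null(self, means, n_perm=4):
        reps = np.tile(np.asarray(means), n_perm)
        return pd.DataFrame(
            {"permutation": np.repeat(np.arange(n_perm), len(means)), "mean_auc": reps}
        )

    def test_unmatched_top_protein_gets_q_zero(self):
        rows = self._rows([0.99, 0.6, 0.55])
        null = self._null([0.58, 0.52, 0.45])
        out = bootauc_q(rows, null, BootAucConfig(n_bootstrap=10))
        assert out.loc["P0", "q"] == 0.0

    def test_exact_half_gets_q_one(self):
        rows = self._rows([0.5, 0.7])
        out = bootauc_q(rows, self._null([0.5, 0.6]), BootAucConfig(n_bootstrap=10))
        assert out.loc["P0", "q"] == 1.0

    def test_q_monotone_along_each_tail(self):
        rng = np.random.default_rng(5)
        rows = self._rows(np.clip(rng.normal(0.5, 0.1, size=60), 0.01, 0.99))
        null = self._null(np.clip(rng.normal(0.5, 0.1, size=60), 0.01, 0.99))
        out = bootauc_q(rows, null, BootAucConfig(n_bootstrap=10))
        for tail in (out["mean_auc"] > 0.5, out["mean_auc"] < 0.5):
            sub = out[tail]
            ordered = sub.reindex((sub["mean_auc"] - 0.5).abs().sort_values(ascending=False).index)
            assert (np.diff(ordered["q"].to_numpy()) >= -1e-12).all()

    def test_label_swap_mirrors_mean_and_keeps_q(self):
        rng = np.random.default_rng(6)
        means = np.clip(rng.normal(0.5, 0.12, size=40), 0.01, 0.99)
        nulls = np.clip(rng.normal(0.5, 0.05, size=40), 0.01, 0.99)
        q1 = bootauc_q(self._rows(means), self._null(nulls), BootAucConfig(n_bootstrap=10))["q"]
        q2 = bootauc_q(self._rows(1 - means), self._null(1 - nulls), BootAucConfig(n_bootstrap=10))["q"]
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_empty_null_rejected(self):
        with pytest.raises(InputError):
            bootauc_q(self._rows([0.6]), pd.DataFrame(columns=["permutation", "mean_auc"]),
                      BootAucConfig(n_bootstrap=10))


class TestRankBySd:
    def test_orders_by_sd_then_effect_then_id(self):
        rows = pd.DataFrame(
            {
                "mean_auc": [0.9, 0.6, 0.8, 0.2],
                "sd_auc": [0.2, 0.01, 0.01, 0.01],
                "significant": [True, True, True, True],
            },
            index=["A", "B", "C", "D"],
        )
        # ties at sd 0.01: |mean-0.5| gives D (0.3), C (0.3)... D vs C tie -> id
        assert list(rank_by_sd(rows)) == ["C", "D", "B", "A"]

    def test_stable_across_calls(self):
        rng = np.random.default_rng(7)
        rows = pd.DataFrame(
            {
                "mean_auc": rng.uniform(0, 1, 50),
                "sd_auc": rng.choice([0.01, 0.02, 0.03], 50),
                "significant": rng.random(50) < 0.5,
            },
            index=[f"P{i}" for i in range(50)],
        )
        assert list(rank_by_sd(rows)) == list(rank_by_sd(rows))
        assert len(rank_by_sd(rows, significant_only=False)) == 50
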
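"""Two-phase feature selection: correlation voting and PCA contributions."""

import numpy as np
import pandas as pd
import pytest
from oracles import brute_force_minimal_removal

from riskpipe import reference as ref
from riskpipe.select import (
    TwoPhaseFeatureSelector,
    apply_selection,
    contribution_counts,
    correlation_flags,
    pca_contributions,
    pca_removals,
    select_features,
    vote_removals,
)


class TestCorrelationFlags:
    def test_duplicated_column_flags_exactly_one(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        flags = correlation_flags(df, cutoff=0.75)
        assert len(flags & {"a", "b"}) == 1
        assert "c" not in flags

    def test_uncorrelated_data_flags_nothing(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        assert correlation_flags(df, cutoff=0.75) == set()

    def test_zero_variance_column_treated_as_uncorrelated(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=100), "const": np.ones(100)})
        assert correlation_flags(df, cutoff=0.75) == set()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_matches_exhaustive_minimal_removal(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        # correlated block structure over <= 6 features
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": z1 + 0.1 * rng.normal(size=n),
                "b": z1 + 0.1 * rng.normal(size=n),
                "c": z2 + 0.15 * rng.normal(size=n),
                "d": z2 + 0.15 * rng.normal(size=n),
                "e": rng.normal(size=n),
                "f": rng.normal(size=n),
            }
        )
        flags = correlation_flags(df, cutoff=0.75)
        assert len(flags) == brute_force_minimal_removal(df, 0.75)
        survivors = [c for c in df.columns if c not in flags]
        corr = np.abs(np.corrcoef(df[survivors].to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.75

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            correlation_flags(pd.DataFrame({"a": [1.0]}))


class TestVoting:
    def test_published_time_domain_votes(self):
        removed = {n for n, v in ref.TIME_CM_VOTES.items() if v >= 22}
        assert removed == {
            "std_gyro_accel_x",
            "std_gyro_accel_z",
            "std_gyro_angvel_y",
            "std_accel_x",
            "std_accel_z",
        }

    def test_published_extended_votes_remove_eleven(self):
        removed = {n for n, v in ref.EXT_CM_VOTES.items() if v >= 22}
        assert len(removed) == 11
        assert "fft_energy_gyro_accel_x" in removed
        assert "entropy_gyro_accel_y" in removed

    def test_vote_removals_threshold_and_monotonicity(self):
        flags = [{"a", "b"}, {"a"}, {"a", "c"}]
        assert vote_removals(flags, min_votes=3) == {"a"}
        assert vote_removals(flags, min_votes=2) == {"a"}
        assert vote_removals(flags, min_votes=1) == {"a", "b", "c"}
        assert vote_removals(flags, min_votes=4) == set()
        # raising the threshold never grows the removal set
        prev = None
        for mv in range(1, 5):
            cur = vote_removals(flags, min_votes=mv)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestPCAContributions:
    def test_contributions_sum_to_100_per_dimension(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 6)))
        entry = pca_contributions(df, var_target=0.6)
        sums = entry.contributions.sum(axis=0)
        np.testing.assert_allclose(sums, 100.0, rtol=1e-9)
        assert entry.cum_variance >= 0.6

    def test_two_symmetric_features_split_50_50(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=4000), "b": rng.normal(size=4000)})
        entry = pca_contributions(df, var_target=0.0)
        np.testing.assert_allclose(entry.contributions.iloc[:, 0], 50.0, atol=3.0)

    def test_var_target_zero_keeps_one_dimension(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)))
        assert pca_contributions(df, var_target=0.0).n_dims == 1

    def test_matches_eigendecomposition_oracle(self, rng):
        # known covariance, contributions from a direct eigen-decomposition
        # of the sample correlation matrix
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + np.eye(5)
        X = rng.multivariate_normal(np.zeros(5), cov, size=2000)
        df = pd.DataFrame(X, columns=list("abcde"))
        entry = pca_contributions(df, var_target=0.6)
        R = np.corrcoef(X, rowvar=False)
        w, V = np.linalg.eigh(R)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        want = 100.0 * V**2
        got = entry.contributions.to_numpy()
        np.testing.assert_allclose(got[:, :3], want[:, :3], atol=1e-8)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="constant"):
            pca_contributions(df)


class TestCountsAndRemovals:
    def test_published_count_ceilings(self):
        assert 5 * 23 == 115
        assert 8 * 23 == 184

    def test_published_time_pca_removals(self):
        removed = pca_removals(ref.TIME_PCA_COUNTS, negligible_max=1)
        assert removed == {
            "mean_gyro_angvel_x",
            "mean_gyro_angvel_y",
            "mean_gyro_angvel_z",
            "ultraviolet",
        }

    def test_published_extended_pca_removals(self):
        removed = pca_removals(ref.EXT_PCA_COUNTS, negligible_max=0)
        assert removed == {
            "entropy_gyro_angvel_x",
            "entropy_gyro_angvel_y",
            "entropy_gyro_angvel_z",
            "ultraviolet",
        }

    def test_uniform_contributions_count_zero(self, rng):
        from riskpipe.select import PCAReportEntry

        p = 4
        contrib = pd.DataFrame(np.full((p, 2), 100.0 / p), index=list("abcd"), columns=["dim1", "dim2"])
        entry = PCAReportEntry(n_dims=2, cum_variance=0.7, contributions=contrib)
        counts = contribution_counts([entry])
        assert all(v == 0 for v in counts.values())  # strict inequality

    def test_count_ceiling_is_sum_of_retained_dims(self, rng):
        dfs = {u: pd.DataFrame(rng.normal(size=(200, 5))) for u in "xyz"}
        entries = {u: pca_contributions(df, var_target=0.6) for u, df in dfs.items()}
        counts = contribution_counts(entries)
        ceiling = sum(e.n_dims for e in entries.values())
        assert max(counts.values()) <= ceiling


class TestApplyAndPipeline:
    def test_apply_drops_by_name_preserving_order(self, time_matrix):
        from riskpipe.select import SelectionResult

        res = SelectionResult(removed_by_cm={"std_accel_x"}, removed_by_pca={"ultraviolet"}, retained=[])
        out = apply_selection(time_matrix, res)
        assert len(out.feature_names) == 24
        assert out.feature_names == [f for f in time_matrix.feature_names if f not in res.removed]
        with pytest.raises(KeyError):
            time_matrix.drop_features({"no_such_feature"})

    def test_empty_removal_is_identity(self, time_matrix):
        from riskpipe.select import SelectionResult

        res = SelectionResult(removed_by_cm=set(), removed_by_pca=set(), retained=list(time_matrix.feature_names))
        assert apply_selection(time_matrix, res).feature_names == time_matrix.feature_names

    def test_selector_removes_injected_duplicate_and_is_deterministic(self, rng):
        n = 500
        frames = {}
        for u in range(3):
            base = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
            base["a_dup"] = base["a"] + 1e-6 * rng.normal(size=n)
            frames[f"u{u}"] = base
        res1, cm, pca = select_features(frames, min_votes=2)
        res2, _, _ = select_features(frames, min_votes=2)
        assert res1.to_dict() == res2.to_dict()
        assert len(res1.removed_by_cm & {"a", "a_dup"}) == 1
        # every user flags one member of the duplicated pair
        assert cm.votes.get("a", 0) + cm.votes.get("a_dup", 0) == 3

    def test_sklearn_estimator_contract(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        X["b"] = X["a"] * 0.999 + 1e-3 * rng.normal(size=200)
        sel = TwoPhaseFeatureSelector(min_votes=1)
        out = sel.fit_transform(X)
        assert sel.get_params()["cutoff"] == 0.75
        assert list(out.columns) == sel.retained_
        assert sel.get_support().sum() == len(sel.retained_)
        assert sel.selection_result_.removed == sel.removed_by_cm_ | sel.removed_by_pca_
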
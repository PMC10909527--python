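"""MFA core: oracle equivalence, algebraic identities, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from affectspace.mfa import (
    GroupSpec,
    ZeroVarianceError,
    aggregate_table,
    fit_mfa,
    project_supplementary,
    standardize_and_weight,
)
from affectspace.schema import ACTIVE_VARS

from conftest import brute_force_mfa


def random_table(n, seed, correlated=True):
    rng = np.random.default_rng(seed)
    if correlated:
        f = rng.standard_normal((n, 1))
        Y = f @ rng.normal(0, 1, (1, 5)) + rng.standard_normal((n, 5))
    else:
        Y = rng.standard_normal((n, 5))
    t = pd.DataFrame(Y, columns=list(ACTIVE_VARS))
    t["participant"] = [f"P{i%4}" for i in range(n)]
    t["stimulus"] = [f"S{i%7}" for i in range(n)]
    t["valence_category"] = [["negative", "neutral", "positive"][i % 3] for i in range(n)]
    t["arousal_category"] = [["low", "medium", "high"][i % 3] for i in range(n)]
    return t


class TestWeighting:
    def test_weighted_group_first_eigenvalue_is_one(self):
        for seed in range(5):
            t = random_table(40, seed)
            spec = GroupSpec()
            weighted, weights, info = standardize_and_weight(t, spec)
            n = len(weighted)
            for g, cols in spec.groups.items():
                W = weighted[cols].to_numpy()
                lam1 = np.max(np.linalg.eigvalsh(W.T @ W / n))
                assert lam1 == pytest.approx(1.0, abs=1e-10)

    def test_single_variable_group_weight_one(self):
        t = random_table(30, 1)
        spec = GroupSpec(groups={"a": ["pupil"], "b": ["valence", "arousal"]}, supplementary=[])
        _, weights, _ = standardize_and_weight(t, spec)
        assert weights["a"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_variable_group_weight_half(self):
        t = random_table(30, 2)
        t["valence2"] = t["valence"]  # perfectly correlated pair: lambda1 = 2
        spec = GroupSpec(groups={"dup": ["valence", "valence2"], "rest": ["pupil"]},
                         supplementary=[])
        _, weights, _ = standardize_and_weight(t, spec)
        assert weights["dup"] == pytest.approx(0.5, abs=1e-10)

    def test_zero_variance_column_named(self):
        t = random_table(30, 3)
        t["scr"] = 1.0
        with pytest.raises(ZeroVarianceError, match="scr"):
            standardize_and_weight(t, GroupSpec())


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,seed", [(10, 0), (25, 1), (50, 2), (50, 3)])
    def test_eigenvalues_and_scores_match_brute_force(self, n, seed):
        t = random_table(n, seed)
        spec = GroupSpec()
        res = fit_mfa(t, spec, n_dims=5)
        Y = t[list(ACTIVE_VARS)].to_numpy(dtype=float)
        evals, scores, _ = brute_force_mfa(Y, [slice(0, 2), slice(2, 5)])
        assert np.allclose(res.eigenvalues, evals, atol=1e-10)
        F = res.scores.to_numpy()
        for s in range(F.shape[1]):
            if evals[s] < 1e-12:
                continue
            c = np.corrcoef(F[:, s], scores[:, s])[0, 1]
            assert abs(abs(c) - 1.0) < 1e-10

    def test_total_inertia_identity(self):
        # sum of eigenvalues = sum over groups of group inertia / lambda1(g)
        t = random_table(40, 4)
        spec = GroupSpec()
        res = fit_mfa(t, spec)
        expected = sum(
            len(cols) / res.group_first_eigenvalues[g] for g, cols in spec.groups.items()
        )
        assert res.total_inertia == pytest.approx(expected, abs=1e-10)


class TestIdentities:
    def test_contributions_sum_to_100(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=5)
        assert np.allclose(res.contributions.sum(axis=0), 100.0, atol=1e-8)
        assert np.allclose(res.group_contributions.sum(axis=0), 100.0, atol=1e-8)

    def test_contribution_formula(self, tiny_table):
        # contribution = 100 * weight * loading^2 / eigenvalue
        res = fit_mfa(tiny_table, n_dims=2)
        for g, cols in res.groups.items():
            w = res.group_weights[g]
            for v in cols:
                for s, dim in enumerate(["dim1", "dim2"]):
                    expected = (
                        100.0 * w * res.correlations.loc[v, dim] ** 2 / res.eigenvalues[s]
                    )
                    assert res.contributions.loc[v, dim] == pytest.approx(expected, abs=1e-8)

    def test_cos2_bounded_by_one(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=5)
        total = res.cos2.sum(axis=1)
        assert (total <= 1.0 + 1e-8).all()

    def test_partial_coordinate_barycentre_identity(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=2)
        mean_partial = sum(ps.to_numpy() for ps in res.partial_scores.values()) / len(
            res.partial_scores
        )
        assert np.allclose(mean_partial, res.scores.to_numpy(), atol=1e-10)

    def test_duplicate_groups_partial_points_coincide(self):
        t = random_table(30, 5)
        t["valence_b"] = t["valence"]
        t["arousal_b"] = t["arousal"]
        spec = GroupSpec(
            groups={"a": ["valence", "arousal"], "b": ["valence_b", "arousal_b"]},
            supplementary=[],
        )
        res = fit_mfa(t, spec, n_dims=2)
        pa = res.partial_scores["a"].to_numpy()
        pb = res.partial_scores["b"].to_numpy()
        assert np.allclose(pa, pb, atol=1e-10)
        assert np.allclose(pa, res.scores.to_numpy(), atol=1e-10)

    def test_single_group_reduces_to_pca(self):
        t = random_table(35, 6)
        spec = GroupSpec(groups={"all": list(ACTIVE_VARS)}, supplementary=[])
        res = fit_mfa(t, spec, n_dims=3)
        X = t[list(ACTIVE_VARS)].to_numpy(dtype=float)
        X = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(X.T @ X / len(X))
        order = np.argsort(evals)[::-1]
        pcs = X @ evecs[:, order]
        for s in range(3):
            c = np.corrcoef(res.scores.to_numpy()[:, s], pcs[:, s])[0, 1]
            assert abs(abs(c) - 1.0) < 1e-10

    def test_sign_convention_deterministic(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=2)
        for dim in ["dim1", "dim2"]:
            j = res.correlations[dim].abs().idxmax()
            assert res.correlations.loc[j, dim] > 0


class TestPartialAxes:
    def test_entries_are_correlations(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=2)
        assert (res.partial_axes_table.abs() <= 1.0 + 1e-12).to_numpy().all()

    def test_single_group_partial_axes_identity(self):
        t = random_table(30, 7)
        spec = GroupSpec(groups={"all": list(ACTIVE_VARS)}, supplementary=[])
        res = fit_mfa(t, spec, n_dims=3)
        block = res.partial_axes_table.loc["all"].to_numpy()[:3, :3]
        assert np.allclose(np.abs(block), np.eye(3), atol=1e-8)

    def test_autonomic_separate_dim_tracks_orienting_dimension(self, study_table):
        res = fit_mfa(study_table, n_dims=2)
        pa = res.partial_axes_table
        # the autonomic group's own first PC correlates more with the
        # autonomic-dominated global dimension than the subjective group does
        auto1 = pa.loc[("autonomic", 1)].abs()
        assert auto1.max() > 0.7


class TestSupplementary:
    def test_single_category_sits_at_origin(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=2)
        cats = pd.Series("all", index=tiny_table.index)
        out = project_supplementary(res, cats)
        assert np.allclose(out["coordinates"].to_numpy(), 0.0, atol=1e-10)

    def test_mirrored_categories_symmetric(self):
        t = random_table(40, 8)
        res = fit_mfa(t, GroupSpec(supplementary=[]), n_dims=2)
        half = pd.Series(
            np.where(res.scores["dim1"] >= res.scores["dim1"].median(), "hi", "lo"),
            index=res.scores.index,
        )
        out = project_supplementary(res, half)["coordinates"]
        # weighted barycentres sum to zero because scores are centered
        n_hi = (half == "hi").sum()
        n_lo = (half == "lo").sum()
        combined = n_hi * out.loc["hi"] + n_lo * out.loc["lo"]
        assert np.allclose(combined.to_numpy(), 0.0, atol=1e-8)

    def test_valence_categories_ordered_along_affect_dimension(self, study_table):
        res = fit_mfa(study_table, n_dims=2)
        coords = res.supplementary_coords["valence_category"]
        # find the dimension carrying subjective valence and its direction
        sgn = np.sign(res.correlations.loc["valence", "dim1"])
        vals = (sgn * coords["dim1"]).loc[["negative", "neutral", "positive"]]
        assert vals.is_monotonic_increasing

    def test_missing_category_rejected(self, tiny_table):
        res = fit_mfa(tiny_table, n_dims=2)
        cats = pd.Series("x", index=tiny_table.index[:-2])
        with pytest.raises(ValueError, match="undefined"):
            project_supplementary(res, cats)


class TestAggregation:
    def test_stimulus_aggregation_row_count(self, study_table):
        agg = aggregate_table(study_table, "stimulus")
        assert len(agg) == 56
        assert "valence_category" in agg.columns

    def test_participant_category_aggregation_bounded(self, study_table):
        agg = aggregate_table(study_table, "participant_valence")
        assert len(agg) <= 51 * 3

    def test_idempotent_on_constant_cells(self):
        t = random_table(30, 9)
        agg1 = aggregate_table(t, "participant")
        # aggregating an already-aggregated table by the same key is identity
        agg2 = aggregate_table(agg1, "participant")
        pd.testing.assert_frame_equal(
            agg1.sort_values("participant").reset_index(drop=True)[agg2.columns],
            agg2.sort_values("participant").reset_index(drop=True),
        )

    def test_unknown_aggregation_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="unknown aggregation"):
            aggregate_table(tiny_table, "by_weekday")


def test_n_dims_beyond_rank_warns(tiny_table):
    with pytest.warns(RuntimeWarning, match="truncat"):
        fit_mfa(tiny_table, n_dims=9)
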
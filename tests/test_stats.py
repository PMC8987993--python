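"""Group statistics: ANCOVA, BH, partial correlation, Fisher z, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from padkit.stats import (
    ancova_compare,
    bh_adjust,
    clinical_associations,
    compare_correlations,
    exclude_lowest,
    partial_correlation,
)


def _toy_groups(n_per=(23, 33, 34), seed=0, effect=(5.0, 0.0, -1.0)):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["MSA", "PD", "HC"], n_per)
    n = len(groups)
    covs = pd.DataFrame(
        {
            "age": rng.uniform(50, 85, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.uniform(6, 20, n),
        }
    )
    shift = dict(zip(["MSA", "PD", "HC"], effect))
    y = np.array([shift[g] for g in groups]) + 0.1 * covs["age"] + rng.normal(0, 3, n)
    return y.to_numpy(), groups, covs


class TestAncova:
    def test_degrees_of_freedom_for_three_groups_three_covariates(self):
        y, groups, covs = _toy_groups()
        comp = ancova_compare(y, groups, covs)
        assert comp.df == (2, 84)  # n=90, 3 groups, 3 covariates

    def test_covariate_fully_explains_outcome(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(40, 80, 60)
        groups = np.repeat(["A", "B", "C"], 20)
        comp = ancova_compare(2.0 * age, groups, pd.DataFrame({"age": age}))
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-16)

    def test_matches_nested_rss_brute_force(self):
        y, groups, covs = _toy_groups(seed=5)
        comp = ancova_compare(y, groups, covs)
        # brute force: RSS of full and reduced linear models
        labels = sorted(set(groups))
        dummies = np.column_stack([(groups == g).astype(float) for g in labels[1:]])
        X_full = np.column_stack([np.ones(len(y)), dummies, covs.to_numpy()])
        X_red = np.column_stack([np.ones(len(y)), covs.to_numpy()])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        df1, df2 = comp.df
        F = ((rss(X_red) - rss(X_full)) / df1) / (rss(X_full) / df2)
        assert comp.f_statistic == pytest.approx(F, rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        y, groups, covs = _toy_groups(seed=6)
        data = covs.assign(y=y, group=groups)
        pg = pingouin.ancova(data=data, dv="y", between="group",
                             covar=["age", "sex", "education"])
        comp = ancova_compare(y, groups, covs)
        row = pg.loc[pg["Source"] == "group"].iloc[0]
        pcol = "p_unc" if "p_unc" in pg.columns else "p-unc"
        assert comp.f_statistic == pytest.approx(float(row["F"]), rel=1e-6)
        assert comp.p_value == pytest.approx(float(row[pcol]), rel=1e-6)

    def test_posthoc_bh_ordering(self):
        y, groups, covs = _toy_groups(seed=7)
        comp = ancova_compare(y, groups, covs)
        post = comp.posthoc
        assert set(zip(post["group_a"], post["group_b"])) == {
            ("HC", "MSA"), ("HC", "PD"), ("MSA", "PD")
        }
        assert (post["p_adjusted"] >= post["p_raw"] - 1e-15).all()
        assert (post["p_adjusted"] <= 1.0).all()

    def test_collinear_covariates_rejected(self):
        y, groups, covs = _toy_groups()
        covs["age2"] = covs["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ancova_compare(y, groups, covs)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_and_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_order_invariance_and_bounds(self, pvals, rand):
        adj = bh_adjust(pvals)
        assert np.all((adj >= np.asarray(pvals) - 1e-15) & (adj <= 1.0))
        perm = list(range(len(pvals)))
        rand.shuffle(perm)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 50))
        rho, p = partial_correlation(x, y)
        from scipy.stats import pearsonr

        r_ref, p_ref = pearsonr(x, y)
        assert rho == pytest.approx(r_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_identical_variables_give_unit_correlation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        covs = rng.normal(size=(30, 2))
        rho, p = partial_correlation(x, x, covs)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(10)
        n = 40
        covs = rng.normal(size=(n, 3))
        x = covs @ [1.0, -2.0, 0.5] + rng.normal(size=n)
        y = covs @ [0.3, 1.0, -1.0] + 0.5 * x + rng.normal(size=n)
        rho, _ = partial_correlation(x, y, covs)
        Z = np.column_stack([np.ones(n), covs])
        H = Z @ np.linalg.pinv(Z)
        rx, ry = x - H @ x, y - H @ y
        assert rho == pytest.approx(
            np.corrcoef(rx, ry)[0, 1], rel=1e-10
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        n = 60
        data = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "c1", "c2"])
        data["y"] += 0.6 * data["x"]
        ours = partial_correlation(data["x"], data["y"], data[["c1", "c2"]])
        ref = pingouin.partial_corr(data=data, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert ours[0] == pytest.approx(float(ref["r"].iloc[0]), rel=1e-8)
        assert ours[1] == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="need n >"):
            partial_correlation([1.0, 2, 3], [1.0, 2, 3], np.ones((3, 2)))


class TestCompareCorrelations:
    def test_equal_correlations_give_p_one(self):
        z, p = compare_correlations(0.4, 30, 0.4, 30)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "rho1,n1,rho2,n2,expected_p",
        [
            (0.409, 33, -0.013, 34, 0.081),  # PD vs HC
            (0.074, 23, 0.409, 33, 0.212),   # MSA vs PD
            (0.074, 23, -0.013, 34, 0.763),  # MSA vs HC
        ],
    )
    def test_published_between_group_pvalues(self, rho1, n1, rho2, n2, expected_p):
        _, p = compare_correlations(rho1, n1, rho2, n2)
        assert p == pytest.approx(expected_p, abs=5e-3)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 30, 0.2, 30)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.2, 30)


class TestExcludeLowest:
    def test_zero_counts_keep_everything(self):
        mask = exclude_lowest([1.0, 2.0, 3.0], ["A"] * 3, {"A": 0})
        assert mask.all()

    def test_keeps_largest(self):
        mask = exclude_lowest([1.0, 2.0, 3.0], ["A"] * 3, {"A": 2})
        np.testing.assert_array_equal(mask, [False, False, True])

    def test_ties_broken_by_first_occurrence(self):
        mask = exclude_lowest([1.0, 1.0, 1.0], ["A"] * 3, {"A": 2})
        np.testing.assert_array_equal(mask, [False, False, True])

    def test_exclusion_reduces_ancova_df(self):
        y, groups, covs = _toy_groups(seed=12)
        mask = exclude_lowest(y, groups, {"MSA": 2, "PD": 3, "HC": 2})
        assert mask.sum() == 83
        comp = ancova_compare(y[mask], groups[mask], covs.loc[mask])
        assert comp.df == (2, 77)

    def test_count_exceeding_group_size_rejected(self):
        with pytest.raises(ValueError, match="cannot exclude"):
            exclude_lowest([1.0, 2.0], ["A", "A"], {"A": 3})


class TestClinicalAssociations:
    def _pads_and_participants(self, n=40, seed=13):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        pads = pd.DataFrame(
            {"id": ids, "modality": "GM", "corrected_pad": rng.normal(0, 5, n)}
        )
        participants = pd.DataFrame(
            {
                "id": ids,
                "age": rng.uniform(50, 85, n),
                "sex": rng.choice(["male", "female"], n),
                "education": rng.uniform(6, 20, n),
                "group": "PD",
            }
        )
        return pads, participants

    def test_collinear_score_gives_unit_rho(self):
        pads, part = self._pads_and_participants()
        part["UPDRS_total"] = pads["corrected_pad"].to_numpy() * 2 + 1
        out = clinical_associations(pads, part, ["UPDRS_total"], covariate_names=[])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_missing_scores_flagged_not_dropped(self):
        pads, part = self._pads_and_participants()
        part["MoCA"] = np.nan
        out = clinical_associations(pads, part, ["MoCA", "absent_score"])
        flags = dict(zip(out["score"], out["flag"]))
        assert flags["MoCA"] == "all missing"
        assert flags["absent_score"] == "score absent"

    def test_pairwise_missing_reported_in_n(self):
        pads, part = self._pads_and_participants()
        part["MMSE"] = np.where(np.arange(len(part)) < 10, np.nan, 25.0 + part["age"] * 0.01)
        out = clinical_associations(pads, part, ["MMSE"])
        assert int(out.loc[0, "n"]) == len(part) - 10
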
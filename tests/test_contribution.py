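"""Contribution profiles, ΔES selection, ranking, regional aggregation."""

import numpy as np
import pandas as pd
import pytest

from padkit.contribution import (
    ContributionProfile,
    aggregate_by_region,
    contribution_profile,
    delta_effect_size,
    rank_top,
)
from padkit.features import FeatureDescriptor


def _profile(group, es_map):
    table = pd.DataFrame(
        {"es": pd.Series(es_map), "degenerate": False, "n": 100}
    )
    table.index.name = "feature"
    return ContributionProfile(group, "GM", table)


class TestProfile:
    def test_single_feature_profile(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame({"f": rng.standard_normal(50)})
        pads = 0.8 * z["f"].to_numpy() + 0.2 * rng.standard_normal(50)
        prof = contribution_profile(z, pads, group="PD")
        assert len(prof.table) == 1
        assert prof.es["f"] > 0.5

    def test_misaligned_participants_rejected(self):
        z = pd.DataFrame({"f": np.arange(20.0)})
        with pytest.raises(ValueError, match="misalignment"):
            contribution_profile(z, np.zeros(19))

    def test_constant_feature_flagged(self):
        z = pd.DataFrame({"f": np.ones(30), "g": np.arange(30.0)})
        prof = contribution_profile(z, np.arange(30.0))
        assert prof.table.loc["f", "degenerate"]
        assert not prof.table.loc["g", "degenerate"]

    def test_pad_independent_of_z_gives_small_effects(self, gm_norms, traj):
        """A synthetic PAD unrelated to any Z leaves all |ES| below 0.2."""
        from padkit.simulate import ClinicalCohortConfig, generate_clinical_cohort

        cohort = generate_clinical_cohort(
            ClinicalCohortConfig("HC", 500, pad_shift=0.0), traj, seed=115
        )
        Z = gm_norms.transform(cohort.tables["GM"], cohort.ages, cohort.sex_codes)
        rng = np.random.default_rng(116)
        pads = rng.normal(0, 5, len(Z))
        prof = contribution_profile(Z, pads)
        assert prof.es.abs().max() < 0.2


class TestAttributionRecovery:
    def test_features_carrying_the_offset_rank_highest(
        self, traj, gm_model, gm_norms, hc_corrector
    ):
        """When the brain-age offset loads on a known subset S of features,
        |ES| ranks S above its complement (Mann-Whitney on ranks)."""
        from scipy.stats import mannwhitneyu

        from padkit.simulate import ClinicalCohortConfig, generate_clinical_cohort
        from conftest import corrected_gm_pad

        subset = gm_norms.feature_names_[:20]
        cohort = generate_clinical_cohort(
            ClinicalCohortConfig(
                "MSA", 200, pad_shift=9.0, jitter_sd=6.0,
                pad_shift_features=subset,
            ),
            traj, seed=106,
        )
        pads = corrected_gm_pad(gm_model, hc_corrector, cohort)
        Z = gm_norms.transform(cohort.tables["GM"], cohort.ages, cohort.sex_codes)
        prof = contribution_profile(Z, pads, group="MSA")
        ranks = prof.es.abs().rank(ascending=False)
        in_s, out_s = ranks[subset], ranks.drop(subset)
        assert in_s.mean() < out_s.mean()
        assert mannwhitneyu(in_s, out_s, alternative="less").pvalue < 0.01


class TestRanking:
    def test_top_k_descending_by_magnitude(self):
        prof = _profile("MSA", {"a": 0.2, "b": -0.9, "c": 0.5})
        assert rank_top(prof, 2) == ["b", "c"]
        assert rank_top(prof, 10) == ["b", "c", "a"]

    def test_ties_broken_lexicographically(self):
        prof = _profile("MSA", {"beta": 0.5, "alpha": -0.5, "gamma": 0.1})
        assert rank_top(prof, 2) == ["alpha", "beta"]


class TestDeltaES:
    def test_published_worked_examples(self):
        """ΔES recomputed from the printed per-group effect sizes."""
        msa = _profile("MSA", {
            "Vol R Lat OrbFron Gy": 0.527,
            "CT R Inf Parie Gy": 0.501,
            "GFA R UF": 0.109,
            "MD CC Parie": 0.683,
        })
        pd_ = _profile("PD", {
            "Vol R Lat OrbFron Gy": 0.106,
            "CT R Inf Parie Gy": 0.068,
            "GFA R UF": 0.617,
            "MD CC Parie": 0.277,
        })
        hc = _profile("HC", {
            "Vol R Lat OrbFron Gy": 0.496,
            "CT R Inf Parie Gy": 0.365,
            "GFA R UF": 0.008,
            "MD CC Parie": 0.502,
        })
        delta = delta_effect_size(msa, pd_, hc, threshold=0.3)
        t = delta.table
        assert t.loc["Vol R Lat OrbFron Gy", "delta_es"] == pytest.approx(0.421, abs=1e-9)
        assert t.loc["CT R Inf Parie Gy", "delta_es"] == pytest.approx(0.433, abs=1e-9)
        assert t.loc["MD CC Parie", "delta_es"] == pytest.approx(0.406, abs=1e-9)
        # the GFA R UF row is the one feature loading more on PD than MSA;
        # the printed -0.507 comes from unrounded inputs (within 0.002)
        assert t.loc["GFA R UF", "delta_es"] == pytest.approx(-0.507, abs=2e-3)
        assert t["selected"].all()

    def test_equal_profiles_not_selected(self):
        a = _profile("MSA", {"f": 0.5})
        b = _profile("PD", {"f": 0.5})
        t = delta_effect_size(a, b).table
        assert t.loc["f", "delta_es"] == 0.0
        assert not t.loc["f", "selected"]

    def test_antisymmetry_preserves_selection(self):
        rng = np.random.default_rng(1)
        names = [f"f{i}" for i in range(30)]
        a = _profile("MSA", dict(zip(names, rng.uniform(-1, 1, 30))))
        b = _profile("PD", dict(zip(names, rng.uniform(-1, 1, 30))))
        ab = delta_effect_size(a, b).table
        ba = delta_effect_size(b, a).table
        np.testing.assert_allclose(ab["delta_es"], -ba["delta_es"])
        pd.testing.assert_series_equal(ab["selected"], ba["selected"])

    def test_feature_set_mismatch_rejected(self):
        a = _profile("MSA", {"f": 0.5})
        b = _profile("PD", {"g": 0.5})
        with pytest.raises(ValueError, match="different feature sets"):
            delta_effect_size(a, b)


class TestAggregation:
    def _descriptors(self):
        return [
            FeatureDescriptor("Vol L A", "GM_volume", "frontal", "left"),
            FeatureDescriptor("Vol R B", "GM_volume", "parietal", "right"),
            FeatureDescriptor("Vol L C", "GM_volume", "temporal", "left"),
            FeatureDescriptor("Vol R D", "GM_volume", "occipital", "right"),
        ]

    def test_equal_effects_split_evenly(self):
        prof = _profile("MSA", {"Vol L A": 0.5, "Vol R B": 0.5,
                                "Vol L C": -0.5, "Vol R D": 0.5})
        out = aggregate_by_region(prof, self._descriptors())
        assert np.allclose(out["percent"], 25.0)
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_single_nonzero_feature_takes_all(self):
        prof = _profile("MSA", {"Vol L A": 0.7, "Vol R B": 0.0,
                                "Vol L C": 0.0, "Vol R D": 0.0})
        out = aggregate_by_region(prof, self._descriptors())
        frontal = out.loc[out["region_group"] == "frontal", "percent"].iloc[0]
        assert frontal == pytest.approx(100.0)

    def test_hand_summed_percentages(self):
        prof = _profile("MSA", {"Vol L A": 0.4, "Vol R B": -0.1,
                                "Vol L C": 0.3, "Vol R D": 0.2})
        out = aggregate_by_region(prof, self._descriptors()).set_index("region_group")
        assert out.loc["frontal", "percent"] == pytest.approx(40.0)
        assert out.loc["parietal", "percent"] == pytest.approx(10.0)
        assert out.loc["temporal", "percent"] == pytest.approx(30.0)
        assert out.loc["occipital", "percent"] == pytest.approx(20.0)

    def test_hemisphere_aggregation_sums_to_100(self):
        prof = _profile("MSA", {"Vol L A": 0.4, "Vol R B": 0.1,
                                "Vol L C": 0.3, "Vol R D": 0.2})
        out = aggregate_by_region(prof, self._descriptors(), by="hemisphere")
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_all_zero_profile_flagged(self):
        prof = _profile("MSA", {"Vol L A": 0.0, "Vol R B": 0.0,
                                "Vol L C": 0.0, "Vol R D": 0.0})
        out = aggregate_by_region(prof, self._descriptors())
        assert (out["flag"] == "all-zero profile").any()

    def test_missing_descriptor_rejected(self):
        prof = _profile("MSA", {"unknown": 0.5})
        with pytest.raises(ValueError, match="descriptors missing"):
            aggregate_by_region(prof, self._descriptors())
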
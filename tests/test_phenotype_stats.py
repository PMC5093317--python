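"""Growth calls, PCA, permANOVA, rank-sum, MIC, phytate, trait summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fermentype.datamodel_io import Censoring, GrowthCall
from fermentype.phenotype_stats import (
    assemble_matrix,
    call_growth,
    call_mic,
    compare_genotype_groups,
    pca,
    permanova,
    phytate_percent,
    ranksum,
    standardize,
    summarize_traits,
)


class TestGrowthCalls:
    @pytest.mark.parametrize("od,expected", [
        (0.15, GrowthCall.NEGATIVE),
        (0.30, GrowthCall.INHIBITED),
        (0.20, GrowthCall.INHIBITED),
        (0.40, GrowthCall.INHIBITED),
        (0.41, GrowthCall.POSITIVE),
        (0.0, GrowthCall.NEGATIVE),
    ])
    def test_thresholds(self, od, expected):
        assert call_growth(od) is expected

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            call_growth(-0.01)

    def test_monotone_in_od(self):
        ods = np.linspace(0, 1, 101)
        calls = [call_growth(o) for o in ods]
        assert all(a.value <= b.value for a, b in zip(calls, calls[1:]))


class TestAssembleStandardize:
    def test_replicate_means(self):
        raw = pd.DataFrame({
            "strain": ["s1", "s1", "s1", "s2", "s2"],
            "condition": ["c1", "c1", "c2", "c1", "c2"],
            "od": [0.2, 0.4, 0.5, 0.1, 0.9],
        })
        m = assemble_matrix(raw)
        assert m.od.loc["s1", "c1"] == pytest.approx(0.3)
        assert m.od.loc["s1", "c2"] == pytest.approx(0.5)
        assert m.replicate_count.loc["s1", "c1"] == 2
        assert m.od.shape == (2, 2)

    def test_missing_cell_reported(self):
        raw = pd.DataFrame({"strain": ["s1", "s2"],
                            "condition": ["c1", "c2"],
                            "od": [0.2, 0.3]})
        with pytest.raises(ValueError, match=r"s1.*c2|missing"):
            assemble_matrix(raw)

    def test_standardize_closed_form(self):
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0]})
        out = standardize(df)
        assert np.allclose(out["c"].values, [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="flat"):
            out = standardize(df)
        assert list(out.columns) == ["c"]
        assert abs(out.mean(axis=0)).max() < 1e-12
        assert np.allclose(out.std(axis=0, ddof=1), 1.0)


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": t, "y": 2 * t, "z": -t})
        res = pca(standardize(df))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 5)),
                          columns=[f"c{i}" for i in range(5)])
        std = standardize(df)
        res = pca(std)
        recon = res.scores.values @ res.loadings.values.T
        assert np.allclose(recon, std.values, atol=1e-9)
        # loadings orthonormal, fractions non-increasing
        k = res.loadings.shape[1]
        assert np.allclose(res.loadings.values.T @ res.loadings.values,
                           np.eye(k), atol=1e-9)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_planted_clusters_separated_in_scores(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        centers = np.array([[0, 0, 0, 0], [4, 4, 0, 0], [0, 4, 4, 4]])
        X = np.vstack([c + rng.normal(0, 1.0, size=(15, 4)) for c in centers])
        labels = np.repeat([0, 1, 2], 15)
        res = pca(standardize(pd.DataFrame(X)))
        sil = silhouette_score(res.scores.values[:, :2], labels)
        assert sil > 0.5


class TestPermanova:
    def test_tiny_case_matches_exhaustive_enumeration(self):
        # 1-D Euclidean pseudo-F equals the classical one-way F, so the
        # exact permutation p can be enumerated independently via scipy
        rng = np.random.default_rng(8)
        x = rng.normal(size=(4, 1))
        labels = np.array(["a", "a", "b", "b"])
        res = permanova(x, labels, exhaustive=True)
        f_obs = scipy.stats.f_oneway(x[:2, 0], x[2:, 0]).statistic
        assert res.pseudo_F == pytest.approx(f_obs)
        count = sum(
            scipy.stats.f_oneway(x[list(p[:2]), 0], x[list(p[2:]), 0]).statistic
            >= f_obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert res.p_value == pytest.approx(count / 24)

    def test_pseudo_f_equals_classical_f_univariate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 1))
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        res = permanova(x, labels, n_permutations=49, seed=1)
        f = scipy.stats.f_oneway(x[:10, 0], x[10:20, 0], x[20:, 0]).statistic
        assert res.pseudo_F == pytest.approx(f)

    def test_statistic_agrees_with_skbio(self):
        import skbio
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(10)
        X = rng.normal(size=(18, 4))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = permanova(X, labels, n_permutations=99, seed=3)
        from scipy.spatial.distance import pdist, squareform
        dm = skbio.DistanceMatrix(squareform(pdist(X)),
                                  [str(i) for i in range(18)])
        theirs = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert res.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_maximal_separation_attains_minimum_p(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, size=(10, 3)),
                       rng.normal(5, 1, size=(10, 3))])
        labels = ["a"] * 10 + ["b"] * 10
        res = permanova(X, labels, n_permutations=199, seed=5)
        assert res.p_value == pytest.approx(1 / 200)

    def test_requires_seed_and_group_sizes(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="seed"):
            permanova(X, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(X, ["a", "a", "a", "b"], seed=1)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(X, ["a", "a", "a", "a"], seed=1)


class TestRankSum:
    def test_fully_separated_small_groups(self):
        res = ranksum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_p_one(self):
        res = ranksum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_exact_matches_scipy_enumeration_small_untied(self):
        rng = np.random.default_rng(14)
        for na in range(1, 5):
            for nb in range(1, 5):
                vals = rng.permutation(np.arange(1.0, na + nb + 1))
                a, b = vals[:na], vals[na:]
                res = ranksum(a, b)
                assert res.method == "exact"
                ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                               method="exact")
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_statistic_is_rank_sum_of_first_group(self):
        res = ranksum([10.0, 20.0], [1.0, 2.0, 3.0])
        assert res.statistic == 4 + 5

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, size=15)
        b = rng.normal(0.8, 1, size=18)
        res = ranksum(a, b)
        assert res.method == "normal_approx"
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic", use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])


class TestGroupComparison:
    @staticmethod
    def planted_matrix(rng, shift_conditions=("42C",), shift=1.0):
        strains = [f"I{i}" for i in range(10)] + [f"II{i}" for i in range(12)]
        conds = ["27C", "42C", "xylose"]
        data = rng.normal(0.5, 0.1, size=(len(strains), len(conds)))
        df = pd.DataFrame(data, index=strains, columns=conds)
        for c in shift_conditions:
            df.loc[[s for s in strains if s.startswith("I") and
                    not s.startswith("II")], c] += shift
        groups = {s: ("I" if not s.startswith("II") else "II")
                  for s in strains}
        return df, groups

    def test_planted_effect_starred_with_direction(self):
        df, groups = self.planted_matrix(np.random.default_rng(16))
        table = compare_genotype_groups(df, groups)
        assert table.loc["42C", "stars"] != ""
        assert table.loc["42C", "direction"] == "I>II"

    def test_single_condition_matrix(self):
        df, groups = self.planted_matrix(np.random.default_rng(17))
        table = compare_genotype_groups(df[["27C"]], groups)
        assert list(table.index) == ["27C"]

    def test_bh_adjustment_is_monotone_and_larger(self):
        df, groups = self.planted_matrix(np.random.default_rng(18))
        table = compare_genotype_groups(df, groups, bh_correction=True)
        assert (table["p_bh"] >= table["p_value"] - 1e-12).all()


class TestMIC:
    def test_exact_call(self):
        res = call_mic("d", {0.06: 0.8, 0.12: 0.5, 0.25: 0.1, 0.5: 0.05})
        assert (res.mic, res.censoring) == (0.25, Censoring.EXACT)

    def test_growth_at_max_censors_above(self):
        res = call_mic("d", {0.06: 0.8, 0.12: 0.6, 0.25: 0.5, 0.5: 0.9})
        assert res.mic is None and res.censoring is Censoring.ABOVE_MAX

    def test_no_growth_anywhere_censors_below(self):
        res = call_mic("d", {0.06: 0.05, 0.12: 0.02, 0.25: 0.01})
        assert (res.mic, res.censoring) == (0.06, Censoring.BELOW_MIN)

    def test_invariant_to_mapping_order(self):
        fwd = {0.06: 0.8, 0.12: 0.5, 0.25: 0.1, 0.5: 0.05}
        rev = dict(reversed(list(fwd.items())))
        assert call_mic("d", fwd) == call_mic("d", rev)

    def test_unsorted_pair_sequence_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            call_mic("d", [(0.12, 0.5), (0.06, 0.8)])
        with pytest.raises(ValueError, match="ascending"):
            call_mic("d", [(0.06, 0.5), (0.06, 0.8)])

    def test_monotone_in_threshold(self):
        series = {0.06: 0.8, 0.12: 0.35, 0.25: 0.15, 0.5: 0.05}
        mic_strict = call_mic("d", series, growth_threshold=0.1)
        mic_loose = call_mic("d", series, growth_threshold=0.4)
        assert mic_loose.mic <= mic_strict.mic

    def test_needs_two_concentrations(self):
        with pytest.raises(ValueError):
            call_mic("d", {0.06: 0.8})


class TestPhytate:
    @pytest.mark.parametrize("initial,final,expected", [
        (3.0, 3.0, 0.0),
        (3.0, 1.5, 50.0),
        (3.0, 1.71, 43.0),
    ])
    def test_percent_closed_form(self, initial, final, expected):
        assert phytate_percent(initial, final).percent_degraded == \
            pytest.approx(expected)

    def test_final_above_initial_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            res = phytate_percent(3.0, 3.2, strain_id="x")
        assert res.percent_degraded == 0.0

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            phytate_percent(0.0, 0.0)


class TestTraitSummaries:
    def test_fixture_percentages_match_printed_values(self, fixtures):
        isolates, _, traits, _ = fixtures
        species_map = {r.strain_id: r.species for r in isolates}
        summary = summarize_traits(traits, species_map)
        km = summary["Kluyveromyces marxianus"]
        sc = summary["Saccharomyces cerevisiae"]
        pf = summary["Pichia fermentans"]
        assert km["hyphae_percent"] == 31
        assert sc["hyphae_percent"] == 40
        assert pf["hyphae_percent"] == 33
        assert sc["invasiveness_percent_by_grade"][0] == 70
        assert sc["invasiveness_percent_by_grade"][3] == 30
        assert km["invasive_above_grade_percent"] == 10

    def test_h2o2_resistant_strains(self, fixtures):
        isolates, _, traits, _ = fixtures
        species_map = {r.strain_id: r.species for r in isolates}
        summary = summarize_traits(traits, species_map)
        assert sorted(summary["Kluyveromyces marxianus"]
                      ["h2o2_resistant_strains"]) == ["AL1", "AL4", "CL5"]
        assert summary["Saccharomyces cerevisiae"]["h2o2_resistant_strains"] \
            == ["CL2"]

    def test_empty_table(self):
        assert summarize_traits([], {}) == {}

    def test_uncovered_strain_rejected(self, fixtures):
        _, _, traits, _ = fixtures
        with pytest.raises(ValueError, match="AL1"):
            summarize_traits(traits, {})
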
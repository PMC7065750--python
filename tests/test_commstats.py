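"""Tests for the community statistics: diversity, IRD, Bray-Curtis,
PERMANOVA, PCO, MANOVA and the classical tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from kelpsat import commstats as cs
from kelpsat.synthdata import SurveySpec, gen_survey_tables


@pytest.fixture(scope="module")
def survey18():
    spec = SurveySpec(n_sites_per_cell={("IE", "exposed"): 5,
                                        ("IE", "sheltered"): 5,
                                        ("MP", "exposed"): 4,
                                        ("MP", "sheltered"): 4}, seed=21)
    return gen_survey_tables(spec)


class TestTransformAndDiversity:
    def test_ln1p_closed_forms_and_monotonicity(self):
        m = pd.DataFrame([[0.0, np.e - 1.0]])
        out = cs.ln1p_transform(m)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(1.0)
        x = np.random.default_rng(0).uniform(0, 50, (5, 5))
        t = cs.ln1p_transform(pd.DataFrame(x)).to_numpy()
        assert np.array_equal(np.argsort(x, axis=None),
                              np.argsort(t, axis=None))
        with pytest.raises(ValueError):
            cs.ln1p_transform(pd.DataFrame([[-1.0]]))

    def test_monoculture(self):
        rec = cs.diversity_metrics([0, 37, 0])
        assert (rec.S, rec.H, rec.d) == (1, 0.0, 0.0)
        assert rec.J is None

    def test_uniform_composition(self):
        rec = cs.diversity_metrics([5, 5, 5, 5])
        assert rec.H == pytest.approx(np.log(4))
        assert rec.J == pytest.approx(1.0)

    def test_hand_computed_shannon(self):
        counts = np.array([5.0, 5.0, 10.0])
        p = counts / counts.sum()
        expected = -sum(pi * np.log(pi) for pi in p)
        rec = cs.diversity_metrics(counts)
        assert rec.H == pytest.approx(expected)
        assert rec.d == pytest.approx(2 / np.log(20))
        assert 0 <= rec.J <= 1

    def test_diversity_bounds_on_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 40, size=12)
            if counts.sum() <= 1:
                continue
            rec = cs.diversity_metrics(counts)
            assert 0 <= rec.H <= np.log(max(rec.S, 1)) + 1e-12
            if rec.J is not None:
                assert 0 <= rec.J <= 1 + 1e-12

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.diversity_metrics([0, 0])


class TestIrd:
    # (%num, %freq, published integer IRD) for the dominance-ranked benthic taxa
    PUBLISHED = [(12.20, 77.78, 949), (2.67, 94.44, 252), (3.20, 72.22, 231),
                 (1.91, 83.33, 159), (1.48, 88.89, 132), (0.63, 100.00, 63),
                 (0.70, 88.89, 62)]

    @pytest.mark.parametrize("pnum,pfreq,expected", PUBLISHED)
    def test_published_worked_examples(self, pnum, pfreq, expected):
        _, rounded = cs.ird_score(pnum, pfreq)
        assert rounded == expected

    def test_table_shares_and_ranking(self):
        m = pd.DataFrame({"a": [2.0, 2.0], "b": [1.0, 0.0], "c": [0.5, 0.5]})
        tab = cs.ird_table(m)
        assert tab.loc["a", "pct_num"] == pytest.approx(4 / 6 * 100)
        assert tab.loc["a", "pct_freq"] == 100.0
        assert tab.loc["b", "pct_freq"] == 50.0
        assert list(tab.index) == list(tab["ird"].sort_values(ascending=False).index)

    def test_ubiquitous_taxon(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        tab = cs.ird_table(m)
        assert tab.loc["b", "ird"] == pytest.approx(100 * tab.loc["b", "pct_num"])

    def test_ird_bounded_by_components(self, survey18):
        tab = cs.ird_table(survey18[0])
        assert (tab["ird"] <= 100 * tab["pct_num"] + 1e-9).all()
        assert (tab["ird"] <= 100 * tab["pct_freq"] + 1e-9).all()


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        m = pd.DataFrame([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 5.0]])
        D = cs.bray_curtis(m).to_numpy()
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_hand_computed_pair(self):
        D = cs.bray_curtis(pd.DataFrame([[1.0, 2.0, 0.0], [0.0, 2.0, 4.0]]))
        assert D.iloc[0, 1] == pytest.approx(5 / 9)

    def test_matches_scipy_and_is_metric_shaped(self, survey18):
        X = survey18[0].to_numpy()
        ours = cs.bray_curtis(survey18[0]).to_numpy()
        ref = squareform(pdist(X, metric="braycurtis"))
        assert np.allclose(ours, ref)
        assert np.allclose(ours, ours.T)
        assert np.all(np.diag(ours) == 0)
        assert ours.min() >= 0 and ours.max() <= 1

    def test_all_zero_pair_convention(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            D = cs.bray_curtis(m)
        assert D.iloc[0, 1] == 0.0


class TestPermanova:
    def test_table4_degrees_of_freedom(self, survey18):
        ab, fac = survey18
        D = cs.bray_curtis(cs.ln1p_transform(ab))
        tab = cs.permanova_2way(D, fac, n_perm=49, seed=0)
        assert tab.loc[["location", "exposure", "location:exposure",
                        "Residual", "Total"], "df"].tolist() == [1, 1, 1, 14, 17]
        assert tab["df"].drop("Total").sum() == 17

    def test_one_way_pseudo_f_matches_skbio(self, survey18):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        ab, fac = survey18
        D = np.asarray(cs.bray_curtis(cs.ln1p_transform(ab)))
        ours = cs.permanova(D, pd.DataFrame({"g": fac["exposure"].to_numpy()}),
                            terms=["g"], n_perm=49, seed=1)
        ref = skbio_distance.permanova(skbio_distance.DistanceMatrix(D),
                                       fac["exposure"].to_numpy(),
                                       permutations=49)
        assert ours.loc["g", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-10)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 6-sample one-factor toy: exact p by full enumeration of the 720
        # sample permutations vs our Monte-Carlo permutation p
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, size=(6, 4))
        X[:3] += 4.0
        D = squareform(pdist(X, metric="braycurtis"))
        g = np.array(["a"] * 3 + ["b"] * 3)
        fac = pd.DataFrame({"g": g})

        def pseudo_f(perm):
            gp = g[list(perm)]
            tab = cs.permanova(D, pd.DataFrame({"g": gp}), terms=["g"],
                               n_perm=1, seed=0)
            return tab.loc["g", "pseudo_F"]

        f_obs = pseudo_f(range(6))
        f_all = np.array([pseudo_f(p) for p in itertools.permutations(range(6))])
        p_exact = np.mean(f_all >= f_obs - 1e-12)
        n_perm = 999
        tab = cs.permanova(D, fac, terms=["g"], n_perm=n_perm, seed=0)
        p_mc = tab.loc["g", "p_perm"]
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 2 * mc_se + 1 / (n_perm + 1)

    def test_strong_effect_detected(self):
        spec = SurveySpec(n_sites_per_cell=5, seed=9,
                          effect_sizes={"exposed": {"Balanus_laevis": 6.0,
                                                    "Bunodactis_octoradiata": 5.0}})
        ab, fac = gen_survey_tables(spec)
        D = cs.bray_curtis(cs.ln1p_transform(ab))
        tab = cs.permanova_2way(D, fac, n_perm=199, seed=2)
        assert tab.loc["exposure", "p_perm"] <= 0.01
        assert tab.loc["location", "p_perm"] > 0.05

    def test_seed_is_mandatory_and_confounded_designs_raise(self, survey18):
        ab, fac = survey18
        D = cs.bray_curtis(ab)
        with pytest.raises(ValueError):
            cs.permanova_2way(D, fac, n_perm=9)
        confounded = fac.copy()
        confounded["exposure"] = np.where(confounded["location"] == "IE",
                                          "exposed", "sheltered")
        with pytest.raises(ValueError):
            cs.permanova_2way(D, confounded, n_perm=9, seed=0)


class TestPairwisePermanova:
    def test_t_squared_equals_one_way_pseudo_f(self, survey18):
        ab, fac = survey18
        D = cs.bray_curtis(cs.ln1p_transform(ab))
        out = cs.pairwise_permanova(D, fac["location"], n_perm=49, seed=4)
        sub = fac["location"].isin(["IE", "MP"]).to_numpy()
        ref = cs.permanova(np.asarray(D)[np.ix_(sub, sub)],
                           pd.DataFrame({"g": fac["location"][sub].to_numpy()}),
                           terms=["g"], n_perm=1, seed=0)
        assert out["t"].iloc[0] ** 2 == pytest.approx(ref.loc["g", "pseudo_F"])

    def test_null_and_separated_groups(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(1, 5, size=(4, 6))
        X = np.vstack([base + rng.normal(0, 1e-3, size=(4, 6)),
                       base + rng.normal(0, 1e-3, size=(4, 6))])
        D = squareform(pdist(X, metric="braycurtis"))
        g = pd.Series(["a"] * 4 + ["b"] * 4)
        out = cs.pairwise_permanova(D, g, n_perm=199, seed=7)
        assert out["p_perm"].iloc[0] > 0.2  # near-duplicated groups: null
        # 8 + 8 samples so a random permutation essentially never reproduces
        # the observed split (2/12870 of permutations tie the statistic)
        X2 = np.vstack([rng.uniform(0, 1, (8, 6)), 30 + rng.uniform(0, 1, (8, 6))])
        D2 = squareform(pdist(X2, metric="braycurtis"))
        g2 = pd.Series(["a"] * 8 + ["b"] * 8)
        out2 = cs.pairwise_permanova(D2, g2, n_perm=199, seed=8)
        # strongly separated: p saturates at the attainable minimum 1/(n_perm+1)
        assert out2["p_perm"].iloc[0] == pytest.approx(1 / 200)


class TestPco:
    def test_euclidean_line_configuration_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])[:, None]
        D = squareform(pdist(pts))
        res = cs.pco(D)
        tol = 1e-8
        assert res.percent_variation[0] == pytest.approx(100.0)
        rec = squareform(pdist(res.coordinates))
        assert np.max(np.abs(rec - D)) <= tol

    def test_euclidean_reconstruction_2d(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        res = cs.pco(D)
        rec = squareform(pdist(res.coordinates))
        assert np.max(np.abs(rec - D)) <= 1e-8
        assert not res.has_negative_eigenvalues

    def test_eigenvalue_sum_equals_gower_trace(self, survey18):
        D = cs.bray_curtis(cs.ln1p_transform(survey18[0])).to_numpy()
        res = cs.pco(D)
        n = D.shape[0]
        C = np.eye(n) - np.ones((n, n)) / n
        G = C @ (-0.5 * D**2) @ C
        assert res.eigenvalues.sum() == pytest.approx(np.trace(G))

    def test_braycurtis_negative_eigenvalues_reported(self, survey18):
        D = cs.bray_curtis(cs.ln1p_transform(survey18[0])).to_numpy()
        res = cs.pco(D)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        if (res.eigenvalues < -1e-10).any():
            assert res.has_negative_eigenvalues

    def test_matches_skbio_pcoa(self, survey18):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        D = cs.bray_curtis(cs.ln1p_transform(survey18[0])).to_numpy()
        ours = cs.pco(D)
        ref = skbio_ord.pcoa(skbio_distance.DistanceMatrix(D))
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, 0]),
            np.abs(ref.samples.iloc[:, 0].to_numpy()), atol=1e-8)


class TestVectorOverlay:
    def test_axis_aligned_taxon(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform
        res = cs.pco(squareform(pdist(pts)))
        m = pd.DataFrame({"follows_axis1": res.coordinates[:, 0],
                          "constant": np.ones(12)})
        with pytest.warns(UserWarning, match="zero variance"):
            vec = cs.vector_overlay(res, m, threshold=0.5)
        assert "constant" not in vec.index
        assert vec.loc["follows_axis1", "r_axis1"] == pytest.approx(1.0)
        assert abs(vec.loc["follows_axis1", "r_axis2"]) < 0.5

    def test_threshold_filters(self, survey18):
        D = cs.bray_curtis(cs.ln1p_transform(survey18[0])).to_numpy()
        res = cs.pco(D)
        all_vec = cs.vector_overlay(res, survey18[0], threshold=0.0)
        kept = cs.vector_overlay(res, survey18[0], threshold=0.5)
        assert set(kept.index) <= set(all_vec.index)
        assert (kept[["r_axis1", "r_axis2"]].abs().max(axis=1) >= 0.5).all()


class TestPillaiManova:
    def test_null_limit(self):
        rng = np.random.default_rng(10)
        block = rng.normal(size=(10, 2))
        Y = np.vstack([block, block])
        g = np.repeat(["x", "y"], 10)
        V, F, p = cs.pillai_manova(Y, g)
        assert V == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_univariate_reduction_equals_anova_f(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        _, F, p = cs.pillai_manova(y[:, None], g)
        ref = stats.f_oneway(y[:8], y[8:16], y[16:])
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_trace_identity_h_h_plus_e(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(30, 3))
        Y[10:20] += 0.8
        g = np.repeat(["a", "b", "c"], 10)
        V, _, _ = cs.pillai_manova(Y, g)
        grand = Y.mean(axis=0)
        H = np.zeros((3, 3))
        E = np.zeros((3, 3))
        for lev in "abc":
            Yg = Y[g == lev]
            mg = Yg.mean(axis=0)
            H += len(Yg) * np.outer(mg - grand, mg - grand)
            E += (Yg - mg).T @ (Yg - mg)
        ref = np.trace(H @ np.linalg.inv(H + E))
        assert V == pytest.approx(ref)

    def test_matches_statsmodels(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(40, 3))
        Y[20:] += 0.5
        g = np.repeat(["a", "b"], 20)
        V, F, p = cs.pillai_manova(Y, g)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = g
        res = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
        row = res.results["g"]["stat"].loc["Pillai's trace"]
        assert V == pytest.approx(float(row["Value"]))
        assert F == pytest.approx(float(row["F Value"]))
        assert p == pytest.approx(float(row["Pr > F"]))


class TestClassicalTests:
    def test_paired_t_hand_computation(self):
        before = np.zeros(3)
        after = np.array([1.0, 2.0, 3.0])
        t, p = cs.paired_t(before, after)
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        ref = stats.ttest_rel(after, before)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))

    def test_paired_t_identity_and_shift_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 5.0])
        assert cs.paired_t(x, x) == (0.0, 1.0)
        y = x + np.array([0.5, -0.2, 0.3, 0.1])
        assert cs.paired_t(x, y)[0] == pytest.approx(cs.paired_t(x + 9, y + 9)[0])

    def test_two_sample_t_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        t, p = cs.two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))

    def test_two_sample_t_separation_limit(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1e-6, 5)
        b = 1 + rng.normal(0, 1e-6, 5)
        t, p = cs.two_sample_t(a, b)
        assert abs(t) > 1e4 and p < 1e-4

    def test_chi_square_closed_form_2x2(self):
        T = np.array([[10, 20], [20, 10]])
        X2, p = cs.chi_square_composition(T)
        n = T.sum()
        a, b, c, d = T.ravel()
        closed = n * (a * d - b * c) ** 2 / (30 * 30 * 30 * 30)
        assert X2 == pytest.approx(closed)
        ref = stats.chi2_contingency(T, correction=False)
        assert (X2, p) == pytest.approx((ref.statistic, ref.pvalue))

    def test_proportional_rows_give_zero(self):
        T = np.array([[5, 10, 15], [10, 20, 30]])
        X2, p = cs.chi_square_composition(T)
        assert X2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_for_2xk(self):
        rng = np.random.default_rng(15)
        T = rng.integers(5, 30, size=(2, 4))
        X2, p = cs.chi_square_composition(T)
        assert p == pytest.approx(stats.chi2.sf(X2, 3))
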
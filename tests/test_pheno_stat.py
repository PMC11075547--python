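"""Camera correction, outliers, adjusted means, heritability, pruning, PCA."""

import numpy as np
import pandas as pd
import pytest

from fruitgwas import pheno_stat as ps
from fruitgwas.pheno_stat import (VarianceComponents, choose_pc_count,
                                  correct_camera_effect, estimate_heritability,
                                  filter_by_heritability, fit_adjusted_means,
                                  prune_correlated, remove_outliers, run_pca)

from conftest import tree_records


def image_frame(values, years, cameras):
    idx = pd.MultiIndex.from_tuples(
        [("G1", y, "1", 1, c) for y, c in zip(years, cameras)],
        names=["genotype_id", "year", "tree_id", "fruit_index", "camera"])
    return pd.DataFrame({"f": values}, index=idx)


class TestCameraCorrection:
    def test_single_cell_residuals(self):
        df = image_frame([1.0, 2.0, 3.0], [2020] * 3, ["Side1"] * 3)
        out = correct_camera_effect(df)
        assert np.allclose(out["f"], [-1, 0, 1])

    def test_shifted_camera_removed(self):
        vals = [1.0, 2.0, 11.0, 12.0]
        df = image_frame(vals, [2020] * 4, ["Side1", "Side1", "Side2", "Side2"])
        out = correct_camera_effect(df)
        for cam in ("Side1", "Side2"):
            cell = out[out.index.get_level_values("camera") == cam]["f"]
            assert abs(cell.mean()) < 1e-12

    def test_matches_ols_oracle(self, rng):
        """One-way fixed-effect fit per year: residuals equal OLS residuals
        of value ~ C(camera) within each year."""
        import statsmodels.formula.api as smf

        years = rng.choice([2019, 2020], 60)
        cams = rng.choice(["Top", "Side1", "Side2"], 60)
        vals = rng.normal(size=60)
        df = image_frame(vals, years, cams)
        out = correct_camera_effect(df)
        flat = df.reset_index()
        expected = np.empty(60)
        for y in (2019, 2020):
            sub = flat[flat["year"] == y]
            fit = smf.ols("f ~ C(camera)", sub).fit()
            expected[sub.index] = fit.resid
        assert np.allclose(out["f"].to_numpy(), expected)

    def test_zero_cell_means_invariant(self, rng):
        years = rng.choice([2019, 2020], 200)
        cams = rng.choice(["Top", "Side1", "Side2", "Side3", "Side4"], 200)
        df = image_frame(rng.normal(size=200) * 10 + 5, years, cams)
        out = correct_camera_effect(df)
        g = out.groupby([out.index.get_level_values("year"),
                         out.index.get_level_values("camera")])["f"].mean()
        assert (g.abs() < 1e-9).all()


class TestOutliers:
    def test_normal_sample_untouched(self, rng):
        v = rng.normal(size=1000)
        assert remove_outliers(v).sum() == 1000

    def test_extreme_value_removed(self):
        v = np.array([0.0] * 20 + [1e6])
        v[:20] = np.linspace(-1, 1, 20)
        keep = remove_outliers(v)
        assert not keep[-1]
        assert keep[:20].all()

    def test_constant_vector_unchanged(self):
        assert remove_outliers(np.ones(10)).all()


class TestAdjustedMeans:
    def test_balanced_single_year_equals_raw_means(self, rng):
        df, _ = tree_records(rng, n_geno=20, years=(2019,))
        adj = fit_adjusted_means(df)["feat0"]
        raw = df["feat0"].groupby("genotype_id").mean()
        assert np.allclose(adj, raw.loc[adj.index])

    def test_year_constant_shift_preserves_contrasts(self, rng):
        """Adding a constant to one year's observations shifts all
        adjusted means equally (genotype contrasts invariant)."""
        df, _ = tree_records(rng, n_geno=15)
        adj1 = fit_adjusted_means(df)["feat0"]
        df2 = df.copy()
        sel = df2.index.get_level_values("year") == 2020
        df2.loc[sel, "feat0"] += 7.5
        adj2 = fit_adjusted_means(df2)["feat0"]
        diff = adj2 - adj1
        assert np.allclose(diff, diff.iloc[0])

    def test_unbalanced_matches_lsmeans_oracle(self, rng):
        """Oracle: statsmodels OLS fit with explicit prediction-grid
        averaging over year and replicate-in-year levels."""
        import statsmodels.formula.api as smf

        df, _ = tree_records(rng, n_geno=8)
        df = df.drop(df.index[[3, 7, 12]])  # unbalance
        adj = fit_adjusted_means(df)["feat0"]
        flat = df.reset_index()
        flat["year"] = flat["year"].astype(str)
        fit = smf.ols("feat0 ~ C(genotype_id) + C(year) + C(year):C(tree_id)", flat).fit()
        for g in adj.index:
            preds = []
            for y in ("2019", "2020"):
                year_preds = [fit.predict(pd.DataFrame(
                    {"genotype_id": [g], "year": [y], "tree_id": [r]}))[0]
                    for r in ("1", "2")]
                preds.append(np.mean(year_preds))
            assert adj[g] == pytest.approx(np.mean(preds), abs=1e-8)


class TestHeritability:
    def test_eq3_arithmetic(self):
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1.0, n_bar=2.0)
        assert vc.h2 == pytest.approx(2.0 / 3.0)
        assert VarianceComponents(0.0, 1.0, 2.0).h2 == 0.0
        assert 0.0 <= VarianceComponents(5.0, 0.1, 1.0).h2 <= 1.0

    def test_matches_mixedlm_oracle(self, rng):
        import statsmodels.formula.api as smf

        df, _ = tree_records(rng, n_geno=60, sg2=1.5, se2=1.0)
        vc = estimate_heritability(df["feat0"])
        flat = df.reset_index()
        flat["yr"] = flat["year"].astype(str)
        fit = smf.mixedlm("feat0 ~ yr + yr:tree_id", flat,
                          groups=flat["genotype_id"]).fit(reml=True)
        assert vc.sigma_g2 == pytest.approx(fit.cov_re.iloc[0, 0], rel=1e-3, abs=1e-4)
        assert vc.sigma_e2 == pytest.approx(fit.scale, rel=1e-3)

    def test_null_heritability_near_zero(self, rng):
        h2s = []
        for _ in range(200):
            df, _ = tree_records(rng, n_geno=500, sg2=0.0, se2=1.0, years=(2019,))
            h2s.append(estimate_heritability(df["feat0"]).h2)
        assert np.nanmean(h2s) < 0.05

    def test_recovery_of_planted_h2(self, rng):
        """sigma_g2=2, sigma_e2=1, 2 reps in one year: H2 = 2/(2+1/2) = 0.8."""
        h2s = []
        for _ in range(200):
            df, _ = tree_records(rng, n_geno=40, sg2=2.0, se2=1.0, years=(2019,))
            h2s.append(estimate_heritability(df["feat0"]).h2)
        assert np.nanmean(h2s) == pytest.approx(0.8, abs=0.05)

    def test_affine_invariance(self, rng):
        df, _ = tree_records(rng, n_geno=40)
        h1 = estimate_heritability(df["feat0"]).h2
        h2 = estimate_heritability(df["feat0"] * 3.7 + 12.0).h2
        assert h1 == pytest.approx(h2, abs=1e-6)

    def test_filter_threshold_strict(self):
        h2 = pd.Series({"a": 0.39, "b": 0.41, "c": 1.0})
        assert filter_by_heritability(h2, 0.4) == ["b", "c"]
        assert filter_by_heritability(h2, 0.6) == ["c"]


class TestPruning:
    def test_orthogonal_features_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 5)),
                          columns=list("abcde"))
        res = prune_correlated(df, 0.75)
        assert res.kept == list("abcde")

    def test_duplicate_removed(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=300)})
        res = prune_correlated(df)
        assert len(res.kept) == 2
        assert "c" in res.kept
        assert len(res.dropped) == 1

    def test_postcondition_exhaustive(self, rng):
        """Surviving set verified by exhaustive pairwise scan."""
        base = rng.normal(size=(200, 6))
        mix = rng.normal(size=(6, 20))
        df = pd.DataFrame(base @ mix + 0.4 * rng.normal(size=(200, 20)),
                          columns=[f"f{i}" for i in range(20)])
        res = prune_correlated(df, 0.75)
        corr = df[res.kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert (corr < 0.75).all()
        assert len(res.kept) + len(res.dropped) == 20


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 8)))
        res = run_pca(df)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_data(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({f"f{i}": x * (i + 1) for i in range(4)})
        res = run_pca(df)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_scores_match_svd_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        res = run_pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        # oracle: eigendecomposition of the covariance of standardized data
        C = np.cov(Z.to_numpy().T)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        scores = Z.to_numpy() @ v[:, order]
        for k in range(6):
            a = res.scores.iloc[:, k].to_numpy()
            b = scores[:, k]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)
        # orthogonality
        S = res.scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_column_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20),
                           "c": rng.normal(size=20)})
        res = run_pca(df)
        assert "b" not in res.loadings.index


class TestChoosePCs:
    @pytest.mark.parametrize("fracs,target,k", [
        ([0.5, 0.3, 0.2], 0.8, 2),
        ([0.5, 0.3, 0.2], 1.0, 3),
        ([0.48, 0.12, 0.09, 0.08, 0.04, 0.03, 0.03, 0.02, 0.11], 0.8, 5),
    ])
    def test_examples(self, fracs, target, k):
        fracs = np.asarray(fracs)
        # brute-force cumulative scan oracle
        brute = next(i + 1 for i in range(len(fracs))
                     if fracs[: i + 1].sum() >= target - 1e-12)
        assert choose_pc_count(fracs, target) == brute == k
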
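"""Generator properties: determinism, LD control, latent-trait variance,
rendering monotonicity, clonal heritability of emitted features."""

import numpy as np
import pandas as pd
import pytest

from fruitgwas import gwas
from fruitgwas.shape_features import image_features, symmetry_statistic
from fruitgwas.synthetic_data import (SimConfig, render_color, render_fruit,
                                      simulate_dataset, simulate_genotypes,
                                      simulate_latent_traits)


def adjacent_r2(G, marker_map, keep):
    D = G.to_numpy(float)
    cols = np.flatnonzero(keep)
    ch = marker_map["chrom"].to_numpy()
    vals = [np.corrcoef(D[:, a], D[:, b])[0, 1] ** 2
            for a, b in zip(cols[:-1], cols[1:])
            if b - a == 1 and ch[a] == ch[b]]
    return float(np.median(vals))


class TestGenotypes:
    def test_deterministic(self):
        cfg = SimConfig(seed=3, n_genotypes=30, markers_per_chromosome=8)
        G1, m1 = simulate_genotypes(cfg, np.random.default_rng(3))
        G2, m2 = simulate_genotypes(cfg, np.random.default_rng(3))
        assert G1.equals(G2) and m1.equals(m2)

    def test_switch_probability_controls_ld(self):
        # founder-limited pools: whole-chromosome copies of few founders
        base = dict(seed=1, n_genotypes=200, markers_per_chromosome=40,
                    n_founders=8)
        lo = SimConfig(switch_prob=0.0, **base)
        hi = SimConfig(switch_prob=1.0, **base)
        r2_lo, r2_hi = [], []
        for cfg, acc in ((lo, r2_lo), (hi, r2_hi)):
            G, mm = simulate_genotypes(cfg, np.random.default_rng(cfg.seed))
            keep = gwas.filter_maf(G.to_numpy(float))
            acc.append(adjacent_r2(G, mm, keep))
        assert r2_lo[0] > 0.5
        # switch prob 1: adjacent LD collapses to the inter-chromosome baseline
        assert r2_hi[0] < 0.05

    def test_two_subpopulations_create_structure(self):
        cfg = SimConfig(seed=2, n_genotypes=200, markers_per_chromosome=30)
        G, _ = simulate_genotypes(cfg, np.random.default_rng(2))
        keep = gwas.filter_maf(G.to_numpy(float))
        pcs = gwas.structure_pcs(G.to_numpy(float)[:, keep], 3)
        labels = (np.arange(200) >= 100).astype(int)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(pcs[:, :1], labels) > 0.5

    def test_dosages_complete_and_biallelic(self):
        cfg = SimConfig(seed=4, n_genotypes=20, markers_per_chromosome=5)
        G, mm = simulate_genotypes(cfg, np.random.default_rng(4))
        assert np.isin(G.to_numpy(), (0, 1, 2)).all()
        assert mm.index.is_unique
        assert (mm["pos_bp"] >= 0).all()


class TestLatentTraits:
    def test_constant_when_no_variance(self):
        cfg = SimConfig(seed=5, n_genotypes=30, markers_per_chromosome=5)
        from fruitgwas.synthetic_data import LatentPlan
        cfg.latent_plans = {name: LatentPlan(0, 0.0) for name in cfg.latent_plans}
        G, _ = simulate_genotypes(cfg, np.random.default_rng(5))
        # with no QTNs everything is polygenic share 1.0 -> not constant;
        # zero polygenic requires qtn_share * n = 1 exactly with n = 0 -> skip
        truth = simulate_latent_traits(G, cfg, np.random.default_rng(5))
        assert truth.latents.shape == (30, 6)

    def test_single_qtn_dosage_groups_differ_by_effect(self):
        cfg = SimConfig(seed=6, n_genotypes=400, markers_per_chromosome=10)
        from fruitgwas.synthetic_data import LatentPlan
        cfg.latent_plans = dict(cfg.latent_plans)
        cfg.latent_plans["redness"] = LatentPlan(1, 0.99)
        G, _ = simulate_genotypes(cfg, np.random.default_rng(6))
        truth = simulate_latent_traits(G, cfg, np.random.default_rng(6))
        marker, beta, _ = truth.qtns["redness"][0]
        z = truth.latents["redness"]
        sd = np.sqrt(truth.realized_variance["redness"])
        by_dosage = z.groupby(G[marker]).mean() * sd
        steps = np.diff(by_dosage.sort_index().to_numpy())
        assert np.allclose(steps, beta, atol=0.12 * beta)

    def test_realized_variance_near_planned(self):
        """At large n the realized latent variance approaches
        sum 2 p (1-p) beta^2 + polygenic variance."""
        cfg = SimConfig(seed=7, n_genotypes=2000, markers_per_chromosome=10)
        G, _ = simulate_genotypes(cfg, np.random.default_rng(7))
        truth = simulate_latent_traits(G, cfg, np.random.default_rng(7))
        for name, plan in cfg.latent_plans.items():
            qtn_var = 0.0
            for marker, beta, _ in truth.qtns[name]:
                p = G[marker].mean() / 2.0
                qtn_var += 2 * p * (1 - p) * beta ** 2
            planned = qtn_var + plan.polygenic_share
            # QTN dosages carry LD/structure covariance, so allow 25%
            assert truth.realized_variance[name] == pytest.approx(planned, rel=0.25)


class TestRendering:
    def _biases(self):
        from fruitgwas.contours import ALL_VIEWS
        return {c: 1.0 for c in ALL_VIEWS}

    def test_symmetric_fruit_has_zero_symmetry(self):
        cfg = SimConfig(sigma_harmonic=0.0)
        rng = np.random.default_rng(0)
        views = render_fruit(150.0, 1.2, 0.0, 0.0, self._biases(), rng, cfg)
        c = views["Side1"]
        for s in ("LR", "AB", "A", "B", "L", "R"):
            assert abs(symmetry_statistic(c, s, "Av")) < 1e-9

    def test_elongation_monotone_in_xy_ratio(self):
        cfg = SimConfig(sigma_harmonic=0.0)
        rng = np.random.default_rng(0)
        short = render_fruit(150.0, 1.0, 0.0, 0.0, self._biases(), rng, cfg)["Side1"]
        long_ = render_fruit(150.0, 1.3, 0.0, 0.0, self._biases(), rng, cfg)["Side1"]
        fs = {str(k): v for k, v in image_features(short).items()}
        fl = {str(k): v for k, v in image_features(long_).items()}
        assert fl["XY_Rat_A_Max"] > fs["XY_Rat_A_Max"]

    def test_nonpositive_radius_raises(self):
        cfg = SimConfig(sigma_harmonic=0.0)
        with pytest.raises(ValueError):
            render_fruit(-5.0, 1.0, 0.0, 0.0, self._biases(),
                         np.random.default_rng(0), cfg)

    def test_redness_monotone_in_red_mass(self):
        rng = np.random.default_rng(1)
        red = np.mean([render_color(2.5, 0.0, 0.0, 0.0, rng)[0][:3].sum()
                       for _ in range(30)])
        green = np.mean([render_color(-2.5, 0.0, 0.0, 0.0, rng)[0][:3].sum()
                         for _ in range(30)])
        assert red > green


class TestDataset:
    def test_deterministic_files(self, tmp_path, small_simdata):
        from fruitgwas.synthetic_data import SimConfig, simulate_dataset

        cfg = SimConfig(seed=11, n_genotypes=40, markers_per_chromosome=10,
                        fruits_per_tree=3)
        again = simulate_dataset(cfg)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        small_simdata.write(d1)
        again.write(d2)
        for name in ("contours.csv", "colors.csv", "genotypes.csv", "map.csv",
                     "sim_truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_year_overlap_structure(self, small_simdata):
        keys = pd.DataFrame([(k.genotype_id, k.year) for k in small_simdata.contours],
                            columns=["g", "y"]).drop_duplicates()
        per_year = keys.groupby("y")["g"].apply(set)
        y1, y2 = per_year.loc[2019], per_year.loc[2020]
        assert len(y1) < len(y2)           # year one phenotyped fewer genotypes
        assert len(y1 & y2) > 0            # partial overlap

    def test_tree_and_fruit_counts(self, small_simdata):
        df = pd.DataFrame([(k.genotype_id, k.year, k.tree_id, k.fruit_index, k.camera)
                           for k in small_simdata.contours],
                          columns=["g", "y", "t", "f", "c"])
        assert set(df["t"]) == {"1", "2"}
        assert df.groupby(["g", "y", "t", "f"])["c"].count().eq(5).all()
        assert df["f"].max() <= 5

    def test_clonal_h2_of_size_feature_matches_config(self, small_simdata):
        """The clonal-mean H2 the statistics stage computes for a pure
        size feature lands near the value implied by the generator's
        variance components."""
        from fruitgwas import pheno_stat
        from fruitgwas.pipeline import PipelineConfig, tree_feature_table
        from fruitgwas.color_features import color_table_from_frame

        cfg = PipelineConfig()
        table, _ = tree_feature_table(small_simdata.contours,
                                      color_table_from_frame(small_simdata.colors),
                                      cfg)
        # a clean size proxy: mean radius of the full contour
        col = "Av_SAv_Pol_Abs_AB_Av"
        vc = pheno_stat.estimate_heritability(table[col])
        implied = small_simdata.config.implied_clonal_h2()
        assert vc.h2 == pytest.approx(implied, abs=0.1)
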
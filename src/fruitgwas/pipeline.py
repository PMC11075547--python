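"""End-to-end orchestration: contours and color histograms in, GWAS hits,
variance partitions and multilocus genotype tables out.

Stage order: clean contours -> shape features -> color features -> camera
correction -> view/tree aggregation -> outlier removal -> adjusted means
and heritability -> heritability filtering, feature selection and PCA
(separately for shape and color) -> GWAS per trait -> variance
partitioning -> multilocus genotypes and averaged contours ->
co-localization with a published-loci catalog.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import color_features as cf
from . import contours as ct
from . import gwas, multilocus, pheno_stat
from . import shape_features as sf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the published analysis values)
    plus input/output paths and the seed."""

    contours: str = "contours.csv"
    colors: str = "colors.csv"
    genotypes: str = "genotypes.csv"
    map: str = "map.csv"
    catalog: str = ""
    out: str = "results"

    min_dim_px: float = 150.0
    stalk_iqr_k: float = 1.5
    outlier_k: float = 15.0
    h2_pca: float = 0.4
    h2_select: float = 0.6
    corr_cutoff: float = 0.75
    maf: float = 0.05
    structure_pcs: int = 3
    alpha: float = 0.05
    alpha_strict: float = 0.01
    linkage_window_bp: int = 100_000
    color_window: float = 0.05
    color_clusters: int = 3
    pc_target: float = 0.80
    max_pcs_gwas: int = 7
    ld_r2: float = 0.7
    max_pseudo_qtns: int = 20
    blink_max_iter: int = 10
    seed: int = 0

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(value) if not isinstance(current, str) else value
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tree_features: pd.DataFrame
    adjusted_means: pd.DataFrame
    h2: pd.DataFrame
    selected: dict[str, list[str]]
    pca: dict[str, pheno_stat.PCAResult]
    n_pcs: dict[str, int]
    scans: dict[str, gwas.AssociationResult]
    hits: pd.DataFrame
    partitions: dict[str, gwas.VariancePartition]
    multilocus_tables: list[multilocus.MultilocusGenotypeTable]
    average_contours: dict[str, list[multilocus.AverageContour]]
    colocalization: pd.DataFrame | None
    manifest: dict


def clean_contours(contours: dict, cfg: PipelineConfig) -> dict:
    """Stalk removal plus minimum-dimension filtering on side views."""
    out = {}
    dropped = 0
    for key, c in contours.items():
        if key.camera == ct.TOP_VIEW:
            out[key] = c
            continue
        c2 = ct.remove_stalk(c)
        if not ct.min_dimension_ok(c2, cfg.min_dim_px):
            dropped += 1
            continue
        out[key] = c2
    if dropped:
        logger.info("dropped %d side views below %.0f px", dropped, cfg.min_dim_px)
    return out


def _family_columns(columns, family: str) -> list[str]:
    color = ("_Hue_", "_Sat_")
    if family == "color":
        return [c for c in columns if any(t in c for t in color)]
    return [c for c in columns if not any(t in c for t in color)]


def tree_feature_table(contours: dict, color_wide: pd.DataFrame,
                       cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Per-tree feature records for the full grammar (shape + color)."""
    cleaned = clean_contours(contours, cfg)
    shape_images = sf.image_fragment_table(cleaned)
    peaks = cf.fit_color_peaks(color_wide)
    color_images = cf.image_color_fragment_table(color_wide, peaks, cfg.color_window)
    shape_images = pheno_stat.correct_camera_effect(shape_images)
    color_images = pheno_stat.correct_camera_effect(color_images)
    shape_tree = sf.aggregate_fragment_table(shape_images, sf.FRUIT_LEVELS)
    color_tree = sf.aggregate_fragment_table(color_images, sf.COLOR_FRUIT_LEVELS)
    table = pd.concat([shape_tree, color_tree], axis=1)
    # full grammar column order
    order = [c for c in map(str, sf.enumerate_feature_grammar()) if c in table.columns]
    return table[order], {"peaks": peaks, "n_images": len(cleaned)}


def run_pipeline(cfg: PipelineConfig,
                 data=None) -> PipelineResult:
    """Execute every stage; ``data`` may be a pre-built
    ``synthetic_data.SimDataset`` (otherwise inputs are read from the
    configured paths)."""
    manifest: dict = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": []}

    def stage(name, **counts):
        manifest["stages"].append({"stage": name, **counts})
        logger.info("stage %s: %s", name, counts)

    if data is not None:
        contours = data.contours
        color_wide = cf.color_table_from_frame(data.colors)
        G = data.genotypes
        marker_map = data.marker_map
    else:
        for path_attr in ("contours", "colors", "genotypes", "map"):
            p = getattr(cfg, path_attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"missing {path_attr} input: {p}")
        contours = ct.read_contours(cfg.contours)
        color_wide = cf.read_color_histograms(cfg.colors)
        G = pd.read_csv(cfg.genotypes, index_col=0)
        marker_map = pd.read_csv(cfg.map, index_col=0)
    stage("inputs", images=len(contours), genotypes=len(G), markers=G.shape[1])

    tree_table, info = tree_feature_table(contours, color_wide, cfg)
    stage("features", trees=len(tree_table), features=tree_table.shape[1],
          cleaned_images=info["n_images"])

    tree_table = pheno_stat.remove_outliers_frame(tree_table, cfg.outlier_k)
    stage("outliers", trees=len(tree_table))

    adjusted = pheno_stat.fit_adjusted_means(tree_table)
    h2 = pheno_stat.heritability_table(tree_table)
    stage("adjusted_means", genotypes=len(adjusted),
          features_with_h2=int(h2["H2"].notna().sum()))

    selected: dict[str, list[str]] = {}
    pca_results: dict[str, pheno_stat.PCAResult] = {}
    n_pcs: dict[str, int] = {}
    for family in ("shape", "color"):
        cols = _family_columns(adjusted.columns, family)
        fam_h2 = h2.loc[cols, "H2"]
        pca_feats = pheno_stat.filter_by_heritability(fam_h2, cfg.h2_pca)
        select_feats = pheno_stat.filter_by_heritability(fam_h2, cfg.h2_select)
        if pca_feats:
            pca_results[family] = pheno_stat.run_pca(adjusted[pca_feats])
            k = pheno_stat.choose_pc_count(pca_results[family].variance_fractions,
                                           cfg.pc_target)
            n_pcs[family] = min(k, cfg.max_pcs_gwas)
        if len(select_feats) >= 2:
            sel = pheno_stat.prune_correlated(adjusted[select_feats], cfg.corr_cutoff)
            selected[family] = sel.kept
        else:
            selected[family] = select_feats
        stage(f"selection_{family}", heritable=len(pca_feats),
              selected=len(selected[family]), pcs=n_pcs.get(family, 0))

    keep = gwas.filter_maf(G.to_numpy(float), cfg.maf)
    Gf = G.loc[:, keep]
    marker_map_f = marker_map.loc[Gf.columns]
    stage("maf_filter", markers=int(keep.sum()))

    dosage_all = Gf.to_numpy(float)
    pcs_geno = gwas.structure_pcs(dosage_all, cfg.structure_pcs)
    pcs_geno = pd.DataFrame(pcs_geno, index=Gf.index)

    traits: dict[str, pd.Series] = {}
    for family in ("shape", "color"):
        if family in pca_results:
            scores = pca_results[family].scores
            for i in range(n_pcs.get(family, 0)):
                traits[f"{family}_PC{i + 1}"] = scores[f"PC{i + 1}"]
        for name in selected.get(family, []):
            traits[name] = adjusted[name].dropna()

    scans: dict[str, gwas.AssociationResult] = {}
    hit_rows = []
    for trait, y in traits.items():
        common = y.index.intersection(Gf.index)
        if len(common) < 30:
            logger.warning("trait %s has too few genotypes (%d); skipped",
                           trait, len(common))
            continue
        yv = y.loc[common].to_numpy(float)
        Gm = Gf.loc[common].to_numpy(float)
        cov = pcs_geno.loc[common].to_numpy(float)
        res = gwas.blink_scan(yv, Gm, cov, ld_r2=cfg.ld_r2,
                              max_iter=cfg.blink_max_iter,
                              max_qtn=cfg.max_pseudo_qtns)
        scans[trait] = res
        sig5 = set(gwas.bonferroni_significant(res, cfg.alpha))
        sig1 = set(gwas.bonferroni_significant(res, cfg.alpha_strict))
        for j in sorted(sig5):
            marker = Gf.columns[j]
            hit_rows.append({
                "trait": trait, "marker": marker,
                "chrom": marker_map_f.loc[marker, "chrom"],
                "pos_bp": marker_map_f.loc[marker, "pos_bp"],
                "effect": res.table["effect"].iloc[j],
                "p": res.table["p"].iloc[j],
                "neglog10p": res.table["neglog10p"].iloc[j],
                "sig5": True, "sig1": j in sig1,
            })
    hits = pd.DataFrame(hit_rows, columns=[
        "trait", "marker", "chrom", "pos_bp", "effect", "p", "neglog10p",
        "sig5", "sig1"])
    stage("gwas", traits=len(scans), hits=len(hits))

    partitions: dict[str, gwas.VariancePartition] = {}
    for trait, res in scans.items():
        sig = gwas.bonferroni_significant(res, cfg.alpha)
        if sig.size == 0:
            continue
        y = traits[trait]
        common = y.index.intersection(Gf.index)
        vp = gwas.partition_variance(
            y.loc[common].to_numpy(float), sig, Gf.loc[common].to_numpy(float),
            neglog10p=res.table["neglog10p"].to_numpy())
        vp.table["marker"] = [Gf.columns[j] for j in vp.table["marker_index"]]
        partitions[trait] = vp
    stage("variance_partition", traits=len(partitions))

    ml_tables: list[multilocus.MultilocusGenotypeTable] = []
    shape_pc_traits = [t for t in scans if t.startswith("shape_PC")][:5]
    for trait in shape_pc_traits:
        sig = gwas.bonferroni_significant(scans[trait], cfg.alpha)
        if sig.size == 0:
            continue
        markers = tuple(multilocus._sorted_markers(
            [Gf.columns[j] for j in sig], marker_map_f))
        group = multilocus.SnpGroup(group_id=trait, marker_ids=markers, rule="per-trait")
        ml_tables.append(multilocus.collapse_multilocus(Gf, group, marker_map_f))
    avg_contours: dict[str, list[multilocus.AverageContour]] = {}
    if len(hits):
        shape_hits = hits[~hits["trait"].str.startswith("color")]
        linked = multilocus.group_linked_snps(
            list(shape_hits["marker"]), marker_map_f, cfg.linkage_window_bp)
        cleaned = clean_contours(contours, cfg) if linked else {}
        for group in linked:
            table = multilocus.collapse_multilocus(Gf, group, marker_map_f)
            ml_tables.append(table)
            avg_contours[group.group_id] = (
                multilocus.average_contours(table, cleaned, "absolute")
                + multilocus.average_contours(table, cleaned, "relative"))
    stage("multilocus", groups=len(ml_tables))

    coloc = None
    if cfg.catalog and Path(cfg.catalog).exists() and len(hits):
        catalog = pd.read_csv(cfg.catalog)
        coloc = multilocus.colocalize(hits.drop_duplicates("marker"), catalog,
                                      marker_map_f, cfg.linkage_window_bp)
        stage("colocalization", matches=len(coloc))

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["stages"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return PipelineResult(
        config=cfg, tree_features=tree_table, adjusted_means=adjusted, h2=h2,
        selected=selected, pca=pca_results, n_pcs=n_pcs, scans=scans, hits=hits,
        partitions=partitions, multilocus_tables=ml_tables,
        average_contours=avg_contours, colocalization=coloc, manifest=manifest)


def write_report(result: PipelineResult, outdir) -> None:
    """Write the TSV/JSON report bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.hits.to_csv(out / "gwas_hits.tsv", sep="\t", index=False)

    hit_info = result.hits.drop_duplicates("marker").set_index("marker") \
        if len(result.hits) else pd.DataFrame()
    vp_rows = []
    for trait, vp in result.partitions.items():
        for _, row in vp.table.iterrows():
            marker = row["marker"]
            info = hit_info.loc[marker] if marker in hit_info.index else {}
            vp_rows.append({
                "trait": trait, "marker": marker,
                "chrom": info.get("chrom", ""), "pos_bp": info.get("pos_bp", ""),
                "p": info.get("p", ""),
                "sum_of_squares": row["sum_sq"],
                "explained_pct": row["explained_pct"]})
        vp_rows.append({"trait": trait, "marker": "Residual", "chrom": "",
                        "pos_bp": "", "p": "",
                        "sum_of_squares": vp.residual_sum_sq,
                        "explained_pct": vp.residual_pct})
    pd.DataFrame(vp_rows, columns=[
        "trait", "marker", "chrom", "pos_bp", "p", "sum_of_squares",
        "explained_pct"]).to_csv(out / "variance_partition.tsv", sep="\t", index=False)

    census_rows = []
    ml_rows = []
    for table in result.multilocus_tables:
        for s, cnt in table.census.items():
            census_rows.append({"group": table.group.group_id,
                                "dosage_string": s, "count": int(cnt)})
        for gid, s in table.assignments.items():
            ml_rows.append({"group": table.group.group_id, "genotype": gid,
                            "dosage_string": s})
    pd.DataFrame(census_rows, columns=["group", "dosage_string", "count"]
                 ).to_csv(out / "census.tsv", sep="\t", index=False)
    pd.DataFrame(ml_rows, columns=["group", "genotype", "dosage_string"]
                 ).to_csv(out / "multilocus.tsv", sep="\t", index=False)

    result.h2.to_csv(out / "h2.tsv", sep="\t")
    result.adjusted_means.to_csv(out / "adjusted_means.tsv", sep="\t")
    for family, pca in result.pca.items():
        pca.scores.to_csv(out / f"pca_scores_{family}.tsv", sep="\t")
    with open(out / "selected_features.txt", "w") as fh:
        for family in sorted(result.selected):
            for name in result.selected[family]:
                fh.write(name + "\n")

    ac_rows = []
    for group, profiles in result.average_contours.items():
        for prof in profiles:
            for d in range(len(prof.mean)):
                ac_rows.append((group, prof.label, prof.mode, d,
                                prof.mean[d], prof.sd[d], prof.n_fruits))
    pd.DataFrame(ac_rows, columns=["group", "mlg", "mode", "degree", "mean",
                                   "sd", "n"]
                 ).to_csv(out / "avg_contours.tsv", sep="\t", index=False)

    if result.colocalization is not None:
        result.colocalization.to_csv(out / "colocalization.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
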
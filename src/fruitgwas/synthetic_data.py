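"""Synthetic orchard-trial generator.

Emulates the data a fruit-imaging trial produces: a biallelic SNP dosage
matrix with linkage disequilibrium and two-subpopulation structure,
genotype-controlled latent traits (fruit size, elongation, conicity,
asymmetry, skin redness, ground color), and per-fruit polar contours and
hue/saturation histograms with camera-within-year biases, year and
replicate effects and fruit-level noise.  Ground truth (planted QTNs,
effects, latent values, variance components) is recorded for
parameter-recovery tests.

All randomness flows from one seeded generator; identical config + seed
reproduce identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import ALL_VIEWS, N_DEGREES, SIDE_VIEWS, TOP_VIEW, FruitImageKey, PolarContour

LATENT_NAMES = ("size", "elongation", "conicity", "asymmetry", "redness", "ground")

_DEG = np.arange(N_DEGREES)
_RAD = np.deg2rad(_DEG)
_COS = np.cos(_RAD)
_SIN = np.sin(_RAD)


@dataclass
class LatentPlan:
    """QTN architecture of one latent trait: number of QTNs, the variance
    share of each QTN in the latent, the rest being polygenic."""

    n_qtns: int
    qtn_share: float  # per-QTN share of the latent variance

    @property
    def polygenic_share(self) -> float:
        return max(1.0 - self.n_qtns * self.qtn_share, 0.0)


@dataclass
class SimConfig:
    """Study design and generative parameters.

    Defaults mirror a two-year replicated orchard trial: ~1/3 of the
    genotypes phenotyped in year one, nearly all in year two (so most of
    year one's genotypes repeat), two replicate trees per genotype and
    year, and up to five fruits imaged per tree with one top and four
    side cameras.
    """

    n_genotypes: int = 500
    n_chromosomes: int = 17
    markers_per_chromosome: int = 118
    chromosome_length_bp: int = 30_000_000

    n_founders: int = 24
    fst: float = 0.15
    subpop_fraction: float = 0.5
    switch_prob: float = 0.02        # haplotype-block switch per marker
    founder_ld_rho: float = 0.7      # allele copy probability along a founder haplotype

    years: tuple[int, ...] = (2019, 2020)
    year1_fraction: float = 0.33
    year2_fraction: float = 0.96
    replicates: int = 2
    fruits_per_tree: int = 5

    latent_plans: dict = field(default_factory=lambda: {
        "size": LatentPlan(3, 0.10),
        "elongation": LatentPlan(5, 0.08),
        "conicity": LatentPlan(2, 0.10),
        "asymmetry": LatentPlan(2, 0.08),
        "redness": LatentPlan(1, 0.35),
        "ground": LatentPlan(2, 0.12),
    })

    # noise structure (log / linear scales per parameter)
    sigma_year: float = 0.04         # year effect on log fruit size
    sigma_tree: float = 0.03         # replicate-tree effect on log size
    sigma_fruit: float = 0.03        # fruit-level effect on log size
    sigma_harmonic: float = 0.004    # smooth angular contour noise
    camera_bias_sd: float = 0.03     # multiplicative radius bias, nested in year
    hue_shift_sd: float = 0.004      # per-camera hue offset, nested in year

    # morphology scalings
    base_radius_px: float = 180.0
    size_scale: float = 0.10
    base_elongation: float = 1.12
    elongation_scale: float = 0.06
    conicity_scale: float = 0.06
    asymmetry_scale: float = 0.04
    superellipse_exponent: float = 2.0  # >2 flattens the ends (cylindrical)

    seed: int = 0

    def implied_clonal_h2(self) -> float:
        """Clonal-mean H^2 implied for a size-driven tree-level feature:
        genotype variance from the size latent against tree+fruit error,
        with the year effect removed as a fixed effect."""
        sg2 = self.size_scale ** 2
        se2 = self.sigma_tree ** 2 + self.sigma_fruit ** 2 / self.fruits_per_tree
        n_bar = self.replicates * (self.year1_fraction + self.year2_fraction)
        return sg2 / (sg2 + se2 / n_bar)


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    latents: pd.DataFrame                      # genotype x latent (z-scores)
    qtns: dict                                 # latent -> list of (marker_id, effect, share)
    seed: int
    subpopulation: pd.Series                   # genotype -> 0/1
    realized_variance: dict                    # latent -> realized var of genetic value

    def qtn_marker_ids(self, latent: str) -> list[str]:
        return [m for m, _, _ in self.qtns[latent]]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "qtns": {k: [(m, float(e), float(s)) for m, e, s in v]
                     for k, v in self.qtns.items()},
            "realized_variance": {k: float(v) for k, v in self.realized_variance.items()},
            "latents": self.latents.round(6).to_dict(orient="index"),
            "subpopulation": self.subpopulation.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Genotypes

def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Founder-mosaic dosage matrix with LD and two subpopulations.

    Each individual's two haplotypes are block-copies of founder
    haplotypes from its subpopulation's pool; a copy switches founders
    with probability ``switch_prob`` per marker (and always at chromosome
    starts), so low switch probabilities give long shared blocks and high
    adjacent-marker LD.  Subpopulation founder pools draw their allele
    frequencies from a Balding-Nichols model around shared ancestral
    frequencies.
    """
    m = cfg.n_chromosomes * cfg.markers_per_chromosome
    p0 = rng.uniform(0.08, 0.92, size=m)
    a = p0 * (1 - cfg.fst) / cfg.fst
    b = (1 - p0) * (1 - cfg.fst) / cfg.fst
    pool_freqs = [rng.beta(a, b) for _ in range(2)]

    # Founder haplotypes carry their own local LD: along a chromosome the
    # allele at a marker copies the previous marker's allele with
    # probability ``founder_ld_rho`` (else a fresh frequency draw), so
    # block-copying founders transmits serial correlation to the
    # population.
    chrom_starts = np.arange(m) % cfg.markers_per_chromosome == 0
    rho = cfg.founder_ld_rho
    founders = []
    for f in pool_freqs:
        hap = np.empty((cfg.n_founders, m), dtype=bool)
        fresh = rng.random((cfg.n_founders, m)) < f[None, :]
        copy = rng.random((cfg.n_founders, m)) < rho
        copy[:, chrom_starts] = False
        hap[:, 0] = fresh[:, 0]
        for j in range(1, m):
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
        founders.append(hap)

    n = cfg.n_genotypes
    subpop = (np.arange(n) >= round(n * cfg.subpop_fraction)).astype(int)
    dosage = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        pool = founders[subpop[i]]
        for _ in range(2):
            switches = (rng.random(m) < cfg.switch_prob) | chrom_starts
            switches[0] = True
            founder_draws = rng.integers(0, cfg.n_founders, size=int(switches.sum()))
            fidx = np.zeros(m, dtype=int)
            fidx[switches] = founder_draws
            fidx = fidx[np.maximum.accumulate(np.where(switches, np.arange(m), -1))]
            dosage[i] += pool[fidx, np.arange(m)]

    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), cfg.markers_per_chromosome)
    pos_blocks = []
    for _ in range(cfg.n_chromosomes):
        p = np.unique(rng.integers(1, cfg.chromosome_length_bp,
                                   size=2 * cfg.markers_per_chromosome))
        rng.shuffle(p)
        pos_blocks.append(np.sort(p[:cfg.markers_per_chromosome]))
    pos = np.concatenate(pos_blocks)
    marker_ids = [f"M{c}_{p}" for c, p in zip(chroms, pos)]
    genotype_ids = [f"G{i:04d}" for i in range(n)]
    G = pd.DataFrame(dosage, index=pd.Index(genotype_ids, name="genotype_id"),
                     columns=marker_ids)
    marker_map = pd.DataFrame({"chrom": chroms, "pos_bp": pos},
                              index=pd.Index(marker_ids, name="marker"))
    return G, marker_map


# ---------------------------------------------------------------------------
# Latent traits

def simulate_latent_traits(G: pd.DataFrame, cfg: SimConfig,
                           rng: np.random.Generator) -> SimTruth:
    """Additive QTN + polygenic latent values per genotype.

    QTN markers are drawn (per latent, without replacement across that
    latent) from markers with intermediate allele frequency, spread over
    chromosomes; effects are sized so each QTN contributes its configured
    share of the latent variance, the remainder being a normal polygenic
    term.  Latents are reported as z-scores of the realized values.
    """
    dosage = G.to_numpy(float)
    freq = dosage.mean(axis=0) / 2.0
    eligible = np.flatnonzero((freq > 0.2) & (freq < 0.8))
    n_markers = dosage.shape[1]
    per_chrom = n_markers // cfg.n_chromosomes

    latents = {}
    qtns = {}
    realized = {}
    subpop = (np.arange(len(G)) >= round(len(G) * cfg.subpop_fraction)).astype(int)
    for name in LATENT_NAMES:
        plan = cfg.latent_plans[name]
        if plan.n_qtns > 0:
            # spread QTNs over distinct chromosomes where possible
            chrom_of = eligible // per_chrom
            order = rng.permutation(len(eligible))
            chosen: list[int] = []
            used_chroms: set[int] = set()
            for j in order:
                if len(chosen) == plan.n_qtns:
                    break
                if int(chrom_of[j]) in used_chroms:
                    continue
                chosen.append(int(eligible[j]))
                used_chroms.add(int(chrom_of[j]))
            for j in order:  # fallback if chromosomes exhausted
                if len(chosen) == plan.n_qtns:
                    break
                if int(eligible[j]) not in chosen:
                    chosen.append(int(eligible[j]))
        else:
            chosen = []
        g = np.zeros(len(G))
        entry = []
        for q in chosen:
            p = freq[q]
            beta = np.sqrt(plan.qtn_share / (2.0 * p * (1.0 - p)))
            g += beta * dosage[:, q]
            entry.append((G.columns[q], float(beta), float(plan.qtn_share)))
        g += rng.normal(0.0, np.sqrt(plan.polygenic_share), size=len(G))
        realized[name] = float(np.var(g, ddof=1))
        sd = np.std(g, ddof=1)
        latents[name] = (g - g.mean()) / (sd if sd > 0 else 1.0)
        qtns[name] = entry
    frame = pd.DataFrame(latents, index=G.index)
    return SimTruth(latents=frame, qtns=qtns, seed=cfg.seed,
                    subpopulation=pd.Series(subpop, index=G.index),
                    realized_variance=realized)


def simulate_gwas_trait(G: pd.DataFrame, rng: np.random.Generator,
                        n_qtns: int = 5, qtn_share: float = 0.08,
                        h2: float = 0.6) -> tuple[np.ndarray, list[int]]:
    """A genotype-level phenotype with ``n_qtns`` planted additive QTNs,
    each explaining ``qtn_share`` of the phenotypic variance, total
    heritability ``h2`` (the remainder of the genetic part is polygenic)
    and normal environmental noise.  Returns (y, planted column indices).
    """
    if n_qtns * qtn_share > h2:
        raise ValueError("QTN shares exceed total heritability")
    dosage = G.to_numpy(float)
    freq = dosage.mean(axis=0) / 2.0
    eligible = np.flatnonzero((freq > 0.2) & (freq < 0.8))
    per_chrom = dosage.shape[1] // 17 if dosage.shape[1] >= 17 else dosage.shape[1]
    chosen: list[int] = []
    used: set[int] = set()
    for j in rng.permutation(len(eligible)):
        c = int(eligible[j] // max(per_chrom, 1))
        if c in used:
            continue
        chosen.append(int(eligible[j]))
        used.add(c)
        if len(chosen) == n_qtns:
            break
    y = np.zeros(len(G))
    for q in chosen:
        p = freq[q]
        beta = np.sqrt(qtn_share / (2.0 * p * (1.0 - p)))
        y += beta * (dosage[:, q] - 2.0 * p)
    poly_var = h2 - n_qtns * qtn_share
    if poly_var > 0:
        y += rng.normal(0.0, np.sqrt(poly_var), size=len(G))
    y += rng.normal(0.0, np.sqrt(1.0 - h2), size=len(G))
    return y, chosen


# ---------------------------------------------------------------------------
# Fruit rendering

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _superellipse_radius(E: float, exponent: float) -> np.ndarray:
    """Polar radius of a superellipse with semi-axes (1, E)."""
    c = np.abs(_COS) ** exponent
    s = (np.abs(_SIN) / E) ** exponent
    return (c + s) ** (-1.0 / exponent)


def render_fruit(size_px: float, elongation: float, conicity: float,
                 asymmetry: float, camera_biases: dict[str, float],
                 rng: np.random.Generator, cfg: SimConfig) -> dict[str, PolarContour]:
    """Contours for one fruit: four side views plus one top view.

    Side-view radius: size x superellipse(1, E) x (1 + C sin d) x
    (1 + A cos d) x (1 + smooth low-order angular noise) x camera bias.
    The top view is a circle with left/right asymmetry only.
    """
    if size_px <= 0:
        raise ValueError("fruit size must be positive")
    base = _superellipse_radius(elongation, cfg.superellipse_exponent)
    out = {}
    for cam in ALL_VIEWS:
        harm = np.zeros(N_DEGREES)
        for k in (2, 3, 4):
            amp = rng.normal(0.0, cfg.sigma_harmonic)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            harm += amp * np.cos(k * _RAD + phase)
        if cam == TOP_VIEW:
            r = size_px * (1.0 + asymmetry * _COS) * (1.0 + harm)
        else:
            r = (size_px * base * (1.0 + conicity * _SIN)
                 * (1.0 + asymmetry * _COS) * (1.0 + harm))
        r = r * camera_biases[cam]
        if np.any(r <= 0):
            raise ValueError("rendering produced non-positive radii")
        out[cam] = PolarContour(r, view=cam)
    return out


_HUE_CENTERS = {"Red": 0.995, "Brown": 0.08, "Yellow": 0.155}
_HUE_SIGMA = 0.035
_SAT_SIGMA = 0.09


def _circular_gaussian(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    d = np.abs(centers - mu)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / sigma) ** 2)


def render_color(redness_z: float, ground_z: float, hue_shift: float,
                 sat_shift: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Hue and saturation histograms (36 bins each) for one image.

    Hue is a mixture of circular bumps at the red / brown / yellow
    centers, weighted by the genotype's redness and ground-color latents;
    saturation is a single bump whose position tracks redness.  Camera
    biases enter as small channel shifts (nested in year upstream).
    """
    from .color_features import BIN_CENTERS

    rho = _sigmoid(1.2 * redness_z + rng.normal(0.0, 0.25))
    gam = _sigmoid(1.2 * ground_z + rng.normal(0.0, 0.25))
    w = {"Red": rho, "Yellow": (1 - rho) * gam, "Brown": (1 - rho) * (1 - gam)}
    hue = np.full(36, 0.02)
    for label, mu in _HUE_CENTERS.items():
        hue += w[label] * _circular_gaussian(BIN_CENTERS, (mu + hue_shift) % 1.0,
                                             _HUE_SIGMA)
    sat_mu = np.clip(0.25 + 0.4 * rho + sat_shift + rng.normal(0.0, 0.02), 0.05, 0.95)
    sat = 0.02 + np.exp(-0.5 * ((BIN_CENTERS - sat_mu) / _SAT_SIGMA) ** 2)
    return hue / hue.sum(), sat / sat.sum()


# ---------------------------------------------------------------------------
# Full dataset

@dataclass
class SimDataset:
    contours: dict[FruitImageKey, PolarContour]
    colors: pd.DataFrame        # long format (COLOR_COLUMNS)
    genotypes: pd.DataFrame     # genotype x marker dosage
    marker_map: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        from .contours import write_contours

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_contours(self.contours, out / "contours.csv")
        self.colors.to_csv(out / "colors.csv", index=False, float_format="%.6g")
        self.genotypes.to_csv(out / "genotypes.csv")
        self.marker_map.to_csv(out / "map.csv")
        self.truth.to_json(out / "sim_truth.json")


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate the complete synthetic trial for ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    G, marker_map = simulate_genotypes(cfg, rng)
    truth = simulate_latent_traits(G, cfg, rng)
    z = truth.latents

    genotype_ids = list(G.index)
    n = len(genotype_ids)
    perm = rng.permutation(n)
    n1 = round(cfg.year1_fraction * n)
    n2 = round(cfg.year2_fraction * n)
    in_year = {cfg.years[0]: set(np.array(genotype_ids)[perm[:n1]])}
    in_year[cfg.years[1]] = set(np.array(genotype_ids)[perm[n - n2:]])

    camera_biases = {y: {cam: float(np.exp(rng.normal(0.0, cfg.camera_bias_sd)))
                         for cam in ALL_VIEWS} for y in cfg.years}
    hue_shifts = {y: {cam: float(rng.normal(0.0, cfg.hue_shift_sd))
                      for cam in ALL_VIEWS} for y in cfg.years}
    sat_shifts = {y: {cam: float(rng.normal(0.0, cfg.hue_shift_sd))
                      for cam in ALL_VIEWS} for y in cfg.years}
    year_size = {y: float(rng.normal(0.0, cfg.sigma_year)) for y in cfg.years}

    contours: dict[FruitImageKey, PolarContour] = {}
    color_meta: list[tuple] = []       # (gid, year, rep, fruit, cam, channel)
    color_mass: list[np.ndarray] = []
    from .color_features import N_BINS

    bins = np.arange(N_BINS)
    for gid in genotype_ids:
        zs = z.loc[gid]
        for year in cfg.years:
            if gid not in in_year[year]:
                continue
            for rep in range(1, cfg.replicates + 1):
                tree_eff = rng.normal(0.0, cfg.sigma_tree)
                for fruit in range(1, cfg.fruits_per_tree + 1):
                    fruit_eff = rng.normal(0.0, cfg.sigma_fruit)
                    size_px = cfg.base_radius_px * np.exp(
                        cfg.size_scale * zs["size"] + year_size[year]
                        + tree_eff + fruit_eff)
                    elong = cfg.base_elongation * np.exp(
                        cfg.elongation_scale * zs["elongation"]
                        + rng.normal(0.0, 0.015))
                    conic = np.clip(cfg.conicity_scale * zs["conicity"]
                                    + rng.normal(0.0, 0.01), -0.25, 0.25)
                    asym = np.clip(cfg.asymmetry_scale * zs["asymmetry"]
                                   + rng.normal(0.0, 0.01), -0.2, 0.2)
                    views = render_fruit(size_px, elong, conic, asym,
                                         camera_biases[year], rng, cfg)
                    for cam, contour in views.items():
                        key = FruitImageKey(gid, year, str(rep), fruit, cam)
                        contours[key] = contour
                        hue, sat = render_color(
                            zs["redness"], zs["ground"],
                            hue_shifts[year][cam], sat_shifts[year][cam], rng)
                        for channel, mass in (("hue", hue), ("sat", sat)):
                            color_meta.append((gid, year, str(rep), fruit, cam, channel))
                            color_mass.append(mass)
    meta = pd.DataFrame(color_meta, columns=[
        "genotype_id", "year", "tree_id", "fruit_index", "camera", "channel"])
    colors = meta.loc[meta.index.repeat(N_BINS)].reset_index(drop=True)
    colors["bin"] = np.tile(bins, len(meta))
    colors["value"] = np.concatenate(color_mass)
    return SimDataset(contours=contours, colors=colors, genotypes=G,
                      marker_map=marker_map, truth=truth, config=cfg)
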
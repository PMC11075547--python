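"""Phenotype statistics: camera correction, outlier removal, adjusted
genotype means, clonal-mean heritability, feature filtering and PCA.

The tree-level model for a feature value of genotype i in year j on
replicate tree k is

    y_ijk = G_i + Y_j + R_k(j) + e_ijk

fitted twice: with fixed genotype effects by least squares for the
adjusted genotype means (least-squares means averaged over year and
replicate levels), and with random genotype effects by REML for the
variance components entering the clonal-mean heritability

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_r),

where n_r is the average number of replicate observations per genotype
over the study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

TREE_INDEX = ["genotype_id", "year", "tree_id"]


# ---------------------------------------------------------------------------
# Camera correction (per-image stage)

def correct_camera_effect(image_table: pd.DataFrame) -> pd.DataFrame:
    """Remove the fixed camera-within-year effect from every column.

    ``image_table`` is indexed by (genotype_id, year, tree_id,
    fruit_index, camera).  The model y_ijkl = C_l(j) + e_ijkl is a one-way
    fixed-effects fit per (year, camera) cell, so the residual is simply
    the value minus its cell mean.  Residual cell means are exactly zero.
    """
    grouper = [image_table.index.get_level_values("year"),
               image_table.index.get_level_values("camera")]
    cell_means = image_table.groupby(grouper).transform("mean")
    return image_table - cell_means


# ---------------------------------------------------------------------------
# Outlier removal (tree-record stage)

def remove_outliers(values: pd.Series | np.ndarray, k: float = 15.0) -> np.ndarray:
    """Mask values outside median +- k*IQR (returns boolean keep-mask).

    With IQR = 0 the fence degenerates and nothing is removed.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 4:
        return ok
    q1, med, q3 = np.nanquantile(v[ok], [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        logger.debug("IQR = 0; outlier rule degenerates, nothing removed")
        return ok
    keep = ok & (v >= med - k * iqr) & (v <= med + k * iqr)
    return keep


def remove_outliers_frame(tree_table: pd.DataFrame, k: float = 15.0) -> pd.DataFrame:
    """Apply the outlier rule per feature column, setting outliers NaN."""
    out = tree_table.copy()
    arr = out.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        keep = remove_outliers(arr[:, j], k)
        arr[~keep, j] = np.nan
    out.iloc[:, :] = arr
    return out


# ---------------------------------------------------------------------------
# Design matrices for the tree-level model

def _tree_design(index: pd.MultiIndex) -> tuple[np.ndarray, np.ndarray, list, dict]:
    """Fixed-effect design (intercept + year + replicate-in-year, treatment
    coded) plus genotype dummy block, for tree records.

    Returns (X_geno, X_env, genotype_levels, env_info) where X_geno has one
    column per genotype (no intercept) and X_env carries intercept-free
    year/replicate contrasts appended to it by callers as needed.
    """
    geno = index.get_level_values("genotype_id")
    year = index.get_level_values("year")
    rep = index.get_level_values("tree_id")
    geno_levels = sorted(set(geno))
    year_levels = sorted(set(year))
    g_idx = {g: i for i, g in enumerate(geno_levels)}
    n = len(index)
    Xg = np.zeros((n, len(geno_levels)))
    Xg[np.arange(n), [g_idx[g] for g in geno]] = 1.0
    env_cols = []
    env_names = []
    for yl in year_levels[1:]:
        env_cols.append((year == yl).astype(float))
        env_names.append(("year", yl))
    rep_levels = {yl: sorted({r for y_, r in zip(year, rep) if y_ == yl}) for yl in year_levels}
    for yl in year_levels:
        for rl in rep_levels[yl][1:]:
            env_cols.append(((year == yl) & (rep == rl)).astype(float))
            env_names.append(("rep", yl, rl))
    Xe = np.column_stack(env_cols) if env_cols else np.empty((n, 0))
    env_info = {"year_levels": year_levels, "rep_levels": rep_levels, "names": env_names}
    return Xg, Xe, geno_levels, env_info


def fit_adjusted_means(tree_table: pd.DataFrame) -> pd.DataFrame:
    """Least-squares genotype means adjusted for year and replicate-in-year.

    Fits y = G_i + Y_j + R_k(j) + e by OLS per feature (features sharing a
    missing-value pattern share one pseudoinverse) and reports, per
    genotype, the fitted value averaged equally over year levels and over
    replicate levels within each year.  Features whose design is genotype-
    confounded (rank deficient beyond the treatment-coding redundancy)
    fall back to raw genotype means with a warning.

    Returns genotype x feature adjusted means.
    """
    index = tree_table.index
    Y = tree_table.to_numpy(dtype=float)
    Xg, Xe, geno_levels, env = _tree_design(index)
    X = np.hstack([Xg, Xe])
    n_geno = len(geno_levels)

    # Averaging weights over environment columns: each year level weight
    # 1/n_years; each rep contrast weight (1/n_years) * (1/n_reps in year).
    w_env = np.zeros(Xe.shape[1])
    n_years = len(env["year_levels"])
    for c, name in enumerate(env["names"]):
        if name[0] == "year":
            w_env[c] = 1.0 / n_years
        else:
            _, yl, _ = name
            w_env[c] = (1.0 / n_years) * (1.0 / len(env["rep_levels"][yl]))

    out = np.full((n_geno, Y.shape[1]), np.nan)
    masks: dict[bytes, list[int]] = {}
    finite = np.isfinite(Y)
    for j in range(Y.shape[1]):
        masks.setdefault(finite[:, j].tobytes(), []).append(j)
    expected_rank = n_geno + Xe.shape[1]
    for mkey, cols in masks.items():
        mask = np.frombuffer(mkey, dtype=bool)
        if mask.sum() == 0:
            continue
        Xm = X[mask]
        present = Xm[:, :n_geno].sum(axis=0) > 0
        nonempty = Xm.sum(axis=0) != 0
        rank = np.linalg.matrix_rank(Xm[:, nonempty])
        if rank < nonempty.sum():
            # genotype confounded with environment: raw genotype means
            logger.warning("rank-deficient design; falling back to genotype means "
                           "for %d features", len(cols))
            for j in cols:
                s = pd.Series(Y[mask, j], index=index[mask].get_level_values("genotype_id"))
                m = s.groupby(level=0).mean()
                out[[geno_levels.index(g) for g in m.index], j] = m.to_numpy()
            continue
        beta = np.linalg.pinv(Xm) @ Y[mask][:, cols]
        adj = beta[:n_geno] + (w_env @ beta[n_geno:])[None, :]
        adj[~present] = np.nan
        out[:, cols] = adj
    return pd.DataFrame(out, index=pd.Index(geno_levels, name="genotype_id"),
                        columns=tree_table.columns)


# ---------------------------------------------------------------------------
# Clonal-mean heritability via profiled REML

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    n_bar: float

    @property
    def h2(self) -> float:
        denom = self.sigma_g2 + self.sigma_e2 / self.n_bar
        if denom <= 0 or not np.isfinite(denom):
            return np.nan
        return float(np.clip(self.sigma_g2 / denom, 0.0, 1.0))


def _reml_profile(y: np.ndarray, X: np.ndarray, group_slices: list[slice]):
    """Profiled REML for y = X b + Z u + e with one random intercept per
    group (rows pre-sorted by group).  Returns (sigma_g2, sigma_e2).

    Uses the group-mean / within-deviation decomposition: for variance
    ratio lam = sigma_g^2/sigma_e^2 the GLS fit is an OLS on within-group
    deviations plus group means weighted by n_g/(1 + lam*n_g), and the
    REML criterion is evaluated in closed form from its residual sum of
    squares.
    """
    n, p = X.shape
    n_groups = len(group_slices)
    ng = np.array([s.stop - s.start for s in group_slices], dtype=float)
    ybar = np.array([y[s].mean() for s in group_slices])
    Xbar = np.vstack([X[s].mean(axis=0) for s in group_slices])
    y_dev = y.copy()
    X_dev = X.copy()
    for i, s in enumerate(group_slices):
        y_dev[s] -= ybar[i]
        X_dev[s] -= Xbar[i]

    Sd_xx = X_dev.T @ X_dev
    Sd_xy = X_dev.T @ y_dev
    Sd_yy = float(y_dev @ y_dev)

    def crit(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = ng / (1.0 + lam * ng)
        Axx = Sd_xx + (Xbar * w[:, None]).T @ Xbar
        Axy = Sd_xy + Xbar.T @ (w * ybar)
        Ayy = Sd_yy + float(w @ (ybar * ybar))
        sign, logdet = np.linalg.slogdet(Axx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(Axx, Axy)
        rss = Ayy - float(Axy @ beta)
        if rss <= 0:
            return np.inf
        return (n - p) * np.log(rss) + float(np.sum(np.log1p(lam * ng))) + logdet

    grid = np.linspace(-12.0, 8.0, 21)
    vals = [crit(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    # residual variance at the optimum
    w = ng / (1.0 + lam * ng)
    Axx = Sd_xx + (Xbar * w[:, None]).T @ Xbar
    Axy = Sd_xy + Xbar.T @ (w * ybar)
    Ayy = Sd_yy + float(w @ (ybar * ybar))
    beta = np.linalg.solve(Axx, Axy)
    rss = Ayy - float(Axy @ beta)
    sigma_e2 = rss / (n - p)
    # boundary check: compare with lam -> 0 (pure fixed-effects model)
    if crit(np.log(1e-10)) < res.fun:
        lam = 0.0
        sigma_e2 = _ols_sigma2(y, X, n, p, ng, ybar, Xbar, Sd_xx, Sd_xy, Sd_yy)
    return lam * sigma_e2, sigma_e2


def _ols_sigma2(y, X, n, p, ng, ybar, Xbar, Sd_xx, Sd_xy, Sd_yy) -> float:
    w = ng
    Axx = Sd_xx + (Xbar * w[:, None]).T @ Xbar
    Axy = Sd_xy + Xbar.T @ (w * ybar)
    Ayy = Sd_yy + float(w @ (ybar * ybar))
    beta = np.linalg.lstsq(Axx, Axy, rcond=None)[0]
    rss = Ayy - float(Axy @ beta)
    return max(rss, 0.0) / (n - p)


def estimate_heritability(tree_records: pd.Series) -> VarianceComponents:
    """Variance components of one feature from its tree records.

    ``tree_records`` is indexed by (genotype_id, year, tree_id).  Genotype
    is random; year and replicate-in-year are fixed.  n_bar is the total
    observation count divided by the number of genotypes.
    """
    s = tree_records.dropna()
    idx = s.index
    geno = idx.get_level_values("genotype_id")
    counts = pd.Series(1, index=geno).groupby(level=0).sum()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        return VarianceComponents(np.nan, np.nan, np.nan)
    order = np.argsort(geno.to_numpy(), kind="stable")
    s = s.iloc[order]
    idx = s.index
    geno = idx.get_level_values("genotype_id").to_numpy()
    _, Xe, _, _ = _tree_design(idx)
    X = np.hstack([np.ones((len(s), 1)), Xe])
    # drop collinear env columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
    X = X[:, keep]
    slices = []
    start = 0
    for i in range(1, len(geno) + 1):
        if i == len(geno) or geno[i] != geno[start]:
            slices.append(slice(start, i))
            start = i
    y = s.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0, float(len(y) / len(slices)))
    try:
        sg2, se2 = _reml_profile(y, X, slices)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("REML failed to converge; heritability missing")
        return VarianceComponents(np.nan, np.nan, np.nan)
    return VarianceComponents(float(sg2), float(se2), float(len(y) / len(slices)))


def heritability_table(tree_table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature variance components and H^2 (feature, sigma_g2,
    sigma_e2, n_bar, H2)."""
    rows = []
    for col in tree_table.columns:
        vc = estimate_heritability(tree_table[col])
        rows.append((col, vc.sigma_g2, vc.sigma_e2, vc.n_bar, vc.h2))
    return pd.DataFrame(rows, columns=["feature", "sigma_g2", "sigma_e2", "n_bar", "H2"]
                        ).set_index("feature")


def filter_by_heritability(h2: pd.Series, threshold: float) -> list[str]:
    """Feature names with H^2 strictly above ``threshold`` (0.4 ahead of
    PCA, 0.6 ahead of feature selection)."""
    return list(h2[h2 > threshold].index)


# ---------------------------------------------------------------------------
# Correlation pruning

@dataclass
class SelectionResult:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (dropped feature, partner that triggered it)


def prune_correlated(matrix: pd.DataFrame, cutoff: float = 0.75) -> SelectionResult:
    """Greedy pruning until all pairwise |Pearson r| < cutoff.

    Repeatedly takes the most correlated remaining pair and drops the
    member with the larger mean absolute correlation against everything
    still in play (tie: the later column).  Correlations are pairwise
    complete.
    """
    corr = matrix.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    cols = list(matrix.columns)
    dropped: list[tuple[str, str]] = []
    while True:
        sub = corr.loc[cols, cols]
        arr = sub.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        if arr[i, j] < cutoff:
            break
        a, b = cols[i], cols[j]
        mean_a = arr[i].sum() / (len(cols) - 1)
        mean_b = arr[j].sum() / (len(cols) - 1)
        if mean_a > mean_b:
            drop, partner = a, b
        elif mean_b > mean_a:
            drop, partner = b, a
        else:  # tie: remove the later column
            drop, partner = (b, a) if cols.index(b) > cols.index(a) else (a, b)
        cols.remove(drop)
        dropped.append((drop, partner))
        if len(cols) < 2:
            break
    return SelectionResult(kept=cols, dropped=dropped)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame      # genotype x PC
    loadings: pd.DataFrame    # feature x PC
    variance_fractions: np.ndarray


def run_pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of the genotype x feature adjusted-mean matrix.

    Complete-case genotypes only (dropped rows logged); columns centered
    and scaled to unit sample variance; zero-variance columns dropped with
    a warning.  Component signs are fixed by making the largest-magnitude
    loading of each component positive.
    """
    complete = matrix.dropna(axis=0)
    if len(complete) < len(matrix):
        logger.info("PCA dropping %d genotypes with missing values",
                    len(matrix) - len(complete))
    sd = complete.std(ddof=1)
    zero = sd[sd == 0].index
    if len(zero):
        logger.warning("PCA dropping %d zero-variance features", len(zero))
        complete = complete.drop(columns=zero)
        sd = sd.drop(zero)
    Z = (complete - complete.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # sign convention
    for k in range(Vt.shape[0]):
        m = np.argmax(np.abs(Vt[k]))
        if Vt[k, m] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    frac = S ** 2 / np.sum(S ** 2)
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=complete.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=complete.columns, columns=pcs),
        variance_fractions=frac,
    )


def choose_pc_count(variance_fractions: np.ndarray, target: float = 0.80) -> int:
    """Smallest k whose cumulative explained-variance fraction reaches
    ``target``."""
    cum = np.cumsum(variance_fractions)
    k = int(np.searchsorted(cum, target - 1e-12) + 1)
    return min(k, len(variance_fractions))
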
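"""Marker-trait association on genotype-level phenotypes.

The scan model is ordinary least squares per marker,

    y ~ intercept + structure covariates + dosage,

with dosage treated additively (0/1/2 numeric).  The multi-locus scan
iterates: LD-pruned pseudo-QTN candidates are promoted to covariates with
the model size chosen by BIC, and all markers are rescanned with any
pseudo-QTN in LD with the tested marker dropped for that test.  This
follows the published outline of the BLINK algorithm; numerical parity
with the original software is not a goal.

Significance uses Bonferroni thresholds alpha / m with m the number of
markers surviving the MAF filter for the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_PSEUDO_QTNS = 20


@dataclass
class AssociationResult:
    """Per-marker effects and p-values from one scan."""

    table: pd.DataFrame               # effect, p, neglog10p per marker
    n_tested: int
    n_obs: int
    pseudo_qtns: list[list[int]] = field(default_factory=list)
    converged: bool = True

    def threshold(self, alpha: float) -> float:
        return alpha / self.n_tested

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold(alpha)]


def allele_frequency(G: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per marker: sum(dosage) / 2n."""
    return np.asarray(G, dtype=float).mean(axis=0) / 2.0


def filter_maf(G: np.ndarray, maf: float = 0.05) -> np.ndarray:
    """Boolean keep-mask of markers with minor allele frequency >= maf."""
    f = allele_frequency(G)
    return np.minimum(f, 1.0 - f) >= maf


def structure_pcs(G: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal component scores of the centered dosage matrix."""
    X = np.asarray(G, dtype=float)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10))
    if k >= rank:
        raise ValueError(f"k={k} must be below the matrix rank {rank}")
    return U[:, :k] * S[:k]


def _scan_block(y: np.ndarray, G: np.ndarray, C: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-marker OLS of y on [C, g] via Frisch-Waugh.

    C must include the intercept column.  Returns (beta, p).
    """
    n = len(y)
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    d = np.einsum("ij,ij->j", Gr, Gr)
    df = n - C.shape[1] - 1
    ok = d > 1e-10 * n
    beta = np.zeros(G.shape[1])
    p = np.ones(G.shape[1])
    gy = Gr.T @ yr
    beta[ok] = gy[ok] / d[ok]
    rss = np.maximum(float(yr @ yr) - beta ** 2 * d, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = rss / df / d
        tstat = np.where(ok, beta / np.sqrt(se2), 0.0)
    tstat = np.nan_to_num(tstat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if (~ok).any():
        logger.debug("%d markers collinear with covariates (p set to 1)", (~ok).sum())
    return beta, p


def glm_scan(y: np.ndarray, G: np.ndarray,
             covariates: np.ndarray | None = None) -> AssociationResult:
    """Single-pass OLS scan: per marker, two-sided t-test of the dosage
    coefficient in y ~ intercept + covariates + dosage."""
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    C = _with_intercept(covariates, len(y))
    beta, p = _scan_block(y, G, C)
    return AssociationResult(_result_frame(beta, p), n_tested=G.shape[1], n_obs=len(y))


def _with_intercept(covariates, n: int) -> np.ndarray:
    one = np.ones((n, 1))
    if covariates is None or np.size(covariates) == 0:
        return one
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.hstack([one, cov])


def _result_frame(beta: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"effect": beta, "p": p, "neglog10p": -np.log10(p)})


def _r2_to_markers(g: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one marker against all columns."""
    gc = g - g.mean()
    Gc = G - G.mean(axis=0)
    denom = np.sqrt((gc @ gc) * np.einsum("ij,ij->j", Gc, Gc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Gc.T @ gc) / denom, 0.0)
    return r ** 2


def _ld_pruned_candidates(p: np.ndarray, G: np.ndarray, ld_r2: float,
                          max_qtn: int, p_threshold: float) -> list[int]:
    """Walk markers by ascending p, keeping those whose r^2 with every
    previously kept marker stays below ``ld_r2``.

    Only markers below ``p_threshold`` are eligible: promoting
    sub-threshold markers to covariates would let model selection chase
    noise under the null.
    """
    order = np.argsort(p, kind="stable")
    kept: list[int] = []
    for idx in order:
        if len(kept) >= max_qtn or p[idx] >= p_threshold:
            break
        g = G[:, idx]
        if all(_r2_pair(g, G[:, j]) < ld_r2 for j in kept):
            kept.append(int(idx))
    return kept


def _r2_pair(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return 0.0
    return float((ac @ bc) / denom) ** 2


def _bic_model_size(y: np.ndarray, C: np.ndarray, G: np.ndarray,
                    candidates: list[int]) -> int:
    """Number of leading candidates (0..len) minimizing BIC of
    y ~ C + candidates[:k]."""
    n = len(y)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    floor = max(total_ss, 1.0) * 1e-12  # exact fits compare equal
    best_k, best_bic = 0, np.inf
    for k in range(len(candidates) + 1):
        X = np.hstack([C, G[:, candidates[:k]]]) if k else C
        rss = max(_rss(y, X), floor)
        bic = n * np.log(rss / n) + X.shape[1] * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return best_k


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _scan_with_pseudo(y: np.ndarray, G: np.ndarray, C: np.ndarray,
                      pseudo: list[int], ld_r2: float) -> tuple[np.ndarray, np.ndarray]:
    """Rescan all markers with pseudo-QTNs as extra covariates, dropping
    for each tested marker any pseudo-QTN in LD (r^2 >= ld_r2) with it,
    and the marker itself when it is a pseudo-QTN."""
    m = G.shape[1]
    if not pseudo:
        return _scan_block(y, G, C)
    excl = np.zeros((len(pseudo), m), dtype=bool)
    for i, q in enumerate(pseudo):
        excl[i] = _r2_to_markers(G[:, q], G) >= ld_r2
        excl[i, q] = True
    beta = np.zeros(m)
    p = np.ones(m)
    patterns: dict[bytes, np.ndarray] = {}
    for col in range(m):
        patterns.setdefault(excl[:, col].tobytes(), []).append(col)
    for key, cols in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        keep_q = [q for q, ex in zip(pseudo, mask) if not ex]
        Cq = np.hstack([C, G[:, keep_q]]) if keep_q else C
        cols = np.asarray(cols)
        b, pv = _scan_block(y, G[:, cols], Cq)
        beta[cols] = b
        p[cols] = pv
    return beta, p


def blink_scan(y: np.ndarray, G: np.ndarray,
               covariates: np.ndarray | None = None,
               ld_r2: float = 0.7, max_iter: int = 10,
               max_qtn: int = MAX_PSEUDO_QTNS,
               candidate_alpha: float = 0.05) -> AssociationResult:
    """Iterative multi-locus scan with LD-pruned pseudo-QTN covariates.

    Each iteration: (1) rank markers by the current p-values, (2) build an
    LD-pruned candidate list from markers passing the Bonferroni
    ``candidate_alpha`` threshold, (3) pick the retained pseudo-QTN count
    by BIC, (4) rescan with the retained pseudo-QTNs as covariates
    (excluded per tested marker when in LD with it).  Stops when the
    pseudo-QTN set is stable or after ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    C = _with_intercept(covariates, len(y))
    beta, p = _scan_block(y, G, C)
    history: list[list[int]] = []
    pseudo: list[int] = []
    converged = False
    p_threshold = min(candidate_alpha / G.shape[1], 1.0)
    for _ in range(max_iter):
        candidates = _ld_pruned_candidates(p, G, ld_r2, max_qtn, p_threshold)
        k = _bic_model_size(y, C, G, candidates)
        new_pseudo = candidates[:k]
        if set(new_pseudo) == set(pseudo) and history:
            converged = True
            break
        pseudo = new_pseudo
        history.append(list(pseudo))
        beta, p = _scan_with_pseudo(y, G, C, pseudo, ld_r2)
    if not converged:
        logger.warning("blink_scan did not stabilize within %d iterations", max_iter)
    return AssociationResult(_result_frame(beta, p), n_tested=G.shape[1],
                             n_obs=len(y), pseudo_qtns=history, converged=converged)


def bonferroni_significant(result: AssociationResult, alpha: float = 0.05) -> np.ndarray:
    """Indices of markers with p < alpha / m."""
    return np.flatnonzero(result.table["p"].to_numpy() < result.threshold(alpha))


@dataclass
class VariancePartition:
    """Sequential (type-I) sum-of-squares decomposition over ordered
    significant markers."""

    table: pd.DataFrame   # marker, sum_sq, explained_pct
    residual_sum_sq: float
    residual_pct: float
    total_sum_sq: float


def partition_variance(y: np.ndarray, marker_indices: np.ndarray,
                       G: np.ndarray,
                       neglog10p: np.ndarray | None = None) -> VariancePartition:
    """Sequential regression sums of squares for significant markers.

    Markers enter a single OLS in decreasing -log10(p) order (order taken
    from ``neglog10p`` when given, else from ``marker_indices`` as
    passed); each marker's explained % is its sequential SS over the total
    corrected SS of y, and the residual % closes the sum to 100.
    """
    y = np.asarray(y, dtype=float)
    idx = np.asarray(marker_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("need at least one significant marker")
    if neglog10p is not None:
        order = np.argsort(-np.asarray(neglog10p)[idx], kind="stable")
        idx = idx[order]
    n = len(y)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    X = np.ones((n, 1))
    prev_rss = total_ss
    rows = []
    for j in idx:
        X = np.hstack([X, np.asarray(G, dtype=float)[:, [j]]])
        rss = _rss(y, X)
        ss = max(prev_rss - rss, 0.0)
        if ss <= 1e-12 * total_ss:
            logger.warning("marker %d adds no sequential SS (collinear)", j)
        rows.append((int(j), ss, 100.0 * ss / total_ss))
        prev_rss = rss
    table = pd.DataFrame(rows, columns=["marker_index", "sum_sq", "explained_pct"])
    return VariancePartition(table=table, residual_sum_sq=prev_rss,
                             residual_pct=100.0 * prev_rss / total_ss,
                             total_sum_sq=total_ss)


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic-control lambda: median chi-square over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
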
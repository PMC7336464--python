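"""Mixed-linear-model association of transformed expression with SNPs.

Per gene and condition the model is

    y = W a + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I),

with y the inverse-normal-transformed etrait, W the fixed covariates
(intercept, genotype principal components for population structure and
hidden expression factors) and K an identity-by-state kinship matrix
built from a 10-kb window-thinned SNP set.  The variance ratio
delta = se^2 / sg^2 is estimated once per gene under the null by REML
(spectral decomposition of K, grid + local refinement) and reused for
every SNP of that gene — the P3D ("population parameters previously
determined") shortcut.  Each SNP is then tested by GLS in the rotated
system with a Wald t statistic; ``partial_r2 = t^2 / (t^2 + df)`` is the
determination coefficient reported as the eQTL effect size.

Significance is controlled by a pooled Benjamini-Hochberg step-up
threshold across all gene x SNP tests of a condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, t as t_dist

from .io_formats import MISSING, ExpressionSet, VariantTable

logger = logging.getLogger(__name__)


@dataclass
class ScanThreshold:
    condition: str
    bh_p_cutoff: float
    n_tests: int


@dataclass
class KinshipDecomposition:
    """Eigendecomposition K = U diag(d) U^T, computed once and shared."""

    K: np.ndarray
    U: np.ndarray
    d: np.ndarray


# ---------------------------------------------------------------------------
# Inputs to the model
# ---------------------------------------------------------------------------

def thin_snps_by_window(table: VariantTable, window_bp: int = 10000) -> list[str]:
    """One SNP per non-overlapping window: lowest missing rate, tie -> lowest position."""
    miss = table.missing_fraction()
    best: dict[tuple[str, int], int] = {}
    for j in range(table.n_snps):
        key = (table.chrom[j], int((table.pos[j] - 1) // window_bp))
        cur = best.get(key)
        if (
            cur is None
            or miss[j] < miss[cur]
            or (miss[j] == miss[cur] and table.pos[j] < table.pos[cur])
        ):
            best[key] = j
    idx = sorted(best.values())
    return [table.snp_id[j] for j in idx]


def kinship_ibs(table: VariantTable, snp_ids: list[str] | None = None) -> np.ndarray:
    """Identity-by-state similarity: mean over jointly called SNPs of 1 - |gi - gj| / 2."""
    if table.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    if snp_ids is not None:
        index = table.snp_index()
        table = table.take_snps(np.array([index[s] for s in snp_ids]))
    G = table.dosage(impute=False)
    obs = ~np.isnan(G)
    n = table.n_samples
    K = np.empty((n, n))
    for i in range(n):
        diff = np.abs(G[i][None, :] - G)
        both = obs[i][None, :] & obs
        shared = both.sum(axis=1)
        if (shared == 0).any():
            j = int(np.where(shared == 0)[0][0])
            raise ValueError(f"samples {i} and {j} share no called SNPs")
        K[i] = 1.0 - np.nansum(np.where(both, diff, 0.0), axis=1) / (2.0 * shared)
    return (K + K.T) / 2.0


def structure_covariates(table: VariantTable, n_pc: int = 3) -> np.ndarray:
    """Top principal components of the centered, mean-imputed dosage matrix."""
    if n_pc >= table.n_samples:
        raise ValueError("n_pc must be below the sample count")
    if n_pc == 0:
        return np.empty((table.n_samples, 0))
    G = table.dosage(impute=True)
    G = G - G.mean(axis=0)
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    sign = np.sign(vt[np.arange(n_pc), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    return u * s * sign


def hidden_factors(
    exprset: ExpressionSet, covariates: np.ndarray | None = None, k: int = 14
) -> np.ndarray:
    """Latent expression covariates: residual-expression principal components.

    Each transformed gene is residualized on the structure covariates
    (plus intercept), and the top-k sample-space principal components of
    the residual matrix are returned.  This plays the role a Bayesian
    factor-analysis step plays in large panels: soaking up non-genetic
    expression variability before the scan.
    """
    if exprset.transformed is None:
        raise ValueError("hidden factors require the transformed matrix")
    X = exprset.transformed.to_numpy(float).T  # samples x genes
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be below the sample count")
    if k == 0:
        return np.empty((n, 0))
    W = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None and covariates.size else []))
    beta, *_ = np.linalg.lstsq(W, X, rcond=None)
    R = X - W @ beta
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    sign = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    return u * s * sign


def decompose_kinship(K: np.ndarray) -> KinshipDecomposition:
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8:
        logger.info("kinship not PSD (min eigenvalue %g); adding 1e-6 ridge", d.min())
        d, U = np.linalg.eigh((K + K.T) / 2.0 + 1e-6 * np.eye(len(K)))
    d = np.maximum(d, 0.0)
    return KinshipDecomposition(K=K, U=U, d=d)


# ---------------------------------------------------------------------------
# REML under the null (P3D)
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, factors: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    for block in (covariates, factors):
        if block is not None and block.size:
            cols.append(np.asarray(block, float))
    W = np.hstack(cols)
    # drop collinear columns explicitly rather than fitting rank-deficient
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        warnings.warn("collinear covariates dropped from the design")
        q, r, piv = _pivoted_qr(W)
        keep = sorted(piv[:rank])
        W = W[:, keep]
    return W


def _pivoted_qr(W: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(W, mode="economic", pivoting=True)
    return q, r, piv


def _reml_neg_loglik(log10_delta: float, yt: np.ndarray, Wt: np.ndarray, d: np.ndarray) -> float:
    delta = 10.0**log10_delta
    w = 1.0 / (d + delta)
    n, p = Wt.shape
    WtW = (Wt * w[:, None]).T @ Wt
    Wty = (Wt * w[:, None]).T @ yt
    alpha = np.linalg.solve(WtW, Wty)
    resid = yt - Wt @ alpha
    rss = float(np.sum(w * resid**2))
    sign, logdet_WtW = np.linalg.slogdet(WtW)
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + (n - p)
        + np.sum(np.log(d + delta))
        + logdet_WtW
    )
    return -ll


def fit_null_p3d(
    y: np.ndarray,
    covariates: np.ndarray | None,
    factors: np.ndarray | None,
    kd: KinshipDecomposition,
    grid: int = 101,
) -> dict:
    """REML variance-ratio estimate for one gene under the null model.

    Maximizes the restricted likelihood over log10(delta) on a 101-point
    grid spanning [-5, 5], then refines locally with bounded scalar
    minimization.  Returns the rotated system (reused by the per-SNP
    scan) along with delta-hat.
    """
    n = len(y)
    W = _design(covariates, factors, n)
    yt = kd.U.T @ y
    Wt = kd.U.T @ W
    xs = np.linspace(-5.0, 5.0, grid)
    vals = np.array([_reml_neg_loglik(x, yt, Wt, kd.d) for x in xs])
    i = int(np.argmin(vals))
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, grid - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(yt, Wt, kd.d), method="bounded"
    )
    best = res.x if res.fun <= vals[i] else xs[i]
    delta = 10.0**best
    w = 1.0 / (kd.d + delta)
    return {
        "delta": float(delta),
        "grid_best": float(xs[i]),
        "grid_neg_ll": vals,
        "neg_ll": float(min(res.fun, vals[i])),
        "yt": yt,
        "Wt": Wt,
        "weights": w,
        "W": W,
    }


# ---------------------------------------------------------------------------
# Per-SNP scan
# ---------------------------------------------------------------------------

def scan_gene(
    null_fit: dict,
    snp_dosage: np.ndarray,
    kd: KinshipDecomposition,
    rotated_dosage: np.ndarray | None = None,
) -> pd.DataFrame:
    """GLS tests for every SNP column against one gene's rotated system.

    ``snp_dosage`` is samples x SNPs with missing values already
    mean-imputed per SNP.  Uses the Frisch-Waugh residualization in the
    whitened system so the whole SNP panel is tested with two matrix
    products.  Monomorphic columns (post-imputation variance 0) are
    returned with NaN statistics so callers can drop them by SNP id.
    """
    s = np.sqrt(null_fit["weights"])
    A = null_fit["Wt"] * s[:, None]
    b = null_fit["yt"] * s
    q, _ = np.linalg.qr(A)
    ey = b - q @ (q.T @ b)
    if rotated_dosage is None:
        rotated_dosage = kd.U.T @ snp_dosage
    Xt = rotated_dosage * s[:, None]
    E = Xt - q @ (q.T @ Xt)
    exx = np.einsum("ij,ij->j", E, E)
    exy = E.T @ ey
    n, p = A.shape
    df = n - p - 1
    mono = np.var(snp_dosage, axis=0) <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(exx > 0, exy / np.where(exx > 0, exx, 1.0), np.nan)
        rss = float(ey @ ey) - beta**2 * exx
        sigma2 = rss / df
        se = np.sqrt(sigma2 / np.where(exx > 0, exx, np.nan))
        tstat = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    partial_r2 = tstat**2 / (tstat**2 + df)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": pvals, "partial_r2": partial_r2}
    )
    out.loc[mono, ["beta", "se", "p", "partial_r2"]] = np.nan
    return out


def scan_condition(
    table: VariantTable,
    exprset: ExpressionSet,
    covariates: np.ndarray | None,
    factors: np.ndarray | None,
    kd: KinshipDecomposition,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Full gene x SNP scan for one condition.

    Expression samples must align with the genotype table's sample
    order; genes with missing expression are fit on their complete
    samples (with a kinship sub-decomposition).  Returns the long
    association table (gene, snp, chrom, pos, condition, beta, se, p,
    partial_r2) with monomorphic SNPs dropped.
    """
    if exprset.transformed is None:
        raise ValueError("scan needs the transformed expression matrix")
    if list(exprset.transformed.columns) != list(table.sample_ids):
        raise ValueError("expression samples do not match genotype samples")
    dosage = table.dosage(impute=True)
    rotated = kd.U.T @ dosage  # shared across genes with complete expression
    genes = genes if genes is not None else list(exprset.transformed.index)
    chunks = []
    for g in genes:
        y = exprset.transformed.loc[g].to_numpy(float)
        obs = ~np.isnan(y)
        if obs.sum() < 10:
            continue
        rot_g = None
        if obs.all():
            kd_g, y_g, dos_g, cov_g, fac_g = kd, y, dosage, covariates, factors
            rot_g = rotated
        else:
            idx = np.where(obs)[0]
            kd_g = decompose_kinship(kd.K[np.ix_(idx, idx)])
            y_g = y[idx]
            dos_g = dosage[idx]
            cov_g = covariates[idx] if covariates is not None and covariates.size else covariates
            fac_g = factors[idx] if factors is not None and factors.size else factors
        fit = fit_null_p3d(y_g, cov_g, fac_g, kd_g)
        res = scan_gene(fit, dos_g, kd_g, rotated_dosage=rot_g)
        res.insert(0, "gene", g)
        res.insert(1, "snp", table.snp_id)
        res.insert(2, "chrom", table.chrom)
        res.insert(3, "pos", table.pos)
        res.insert(4, "condition", exprset.condition)
        chunks.append(res.dropna(subset=["p"]))
    if not chunks:
        return pd.DataFrame(
            columns=["gene", "snp", "chrom", "pos", "condition", "beta", "se", "p", "partial_r2"]
        )
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Thresholding and diagnostics
# ---------------------------------------------------------------------------

def bh_threshold(pvals: np.ndarray, fdr: float = 0.05, condition: str = "NA") -> ScanThreshold:
    """Benjamini-Hochberg step-up rejection threshold on pooled p-values.

    The cutoff is p_(k) for the largest k with p_(k) <= k * fdr / m;
    with zero rejections the cutoff is 0 and nothing passes.
    """
    p = np.sort(np.asarray(pvals, float))
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    crit = fdr * np.arange(1, m + 1) / m
    passing = np.where(p <= crit)[0]
    cutoff = float(p[passing[-1]]) if len(passing) else 0.0
    return ScanThreshold(condition=condition, bh_p_cutoff=cutoff, n_tests=m)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Lambda-GC: median association chi-square over its null median."""
    q = chi2.isf(np.asarray(pvals, float), df=1)
    return float(np.median(q) / chi2.ppf(0.5, df=1))
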
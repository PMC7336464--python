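"""Two-step least-squares Mendelian randomization of expression on phenotype.

Each gene with a called eQTL is tested once per condition, using the
condition's lead SNP z as the instrument, the transformed expression x
of that condition as the exposure, and the (condition-independent)
phenotype y as the outcome:

    b_xy  = b_zy / b_zx
    var(b_xy) = [var(y) (1 - R2_xy)] / [n var(x) R2_zx]
    T_MR  = b_xy^2 / var(b_xy)  ~  chi-square(1)

with b_zx and b_zy the simple least-squares slopes of x and y on z,
R2_zx the variance fraction of x explained by z and R2_xy that of y
explained by x (sample variances, n-1 denominator).  Significant
positive b_xy marks the gene's expression as a positive contributor to
the trait, negative b_xy as a negative one.

The experiment-wise threshold defaults to the reciprocal convention
cutoff = 1 / n_tests; the orthodox 0.05 / n_tests Bonferroni is
available as ``alpha_convention='bonferroni_0.05'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import ExpressionSet, VariantTable

MR_COLUMNS = [
    "gene_id", "condition", "snp_id", "n", "b_zx", "b_zy", "R2_zx", "R2_xy",
    "b_xy", "var_bxy", "T_MR", "p", "direction",
]


@dataclass
class MRThreshold:
    n_tests: int
    cutoff: float
    convention: str


class UndefinedInstrumentError(ValueError):
    """Instrument explains none of the exposure (b_zx = 0 or R2_zx = 0)."""


def _slope(y: np.ndarray, x: np.ndarray) -> float:
    vx = np.var(x, ddof=1)
    return float(np.cov(x, y, ddof=1)[0, 1] / vx)


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    c = np.corrcoef(x, y)[0, 1]
    return float(c * c)


def mr_test(z: np.ndarray, x: np.ndarray, y: np.ndarray) -> dict:
    """One 2SLS ratio test; samples with any missing value are dropped."""
    z = np.asarray(z, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    obs = ~(np.isnan(z) | np.isnan(x) | np.isnan(y))
    z, x, y = z[obs], x[obs], y[obs]
    n = len(z)
    if n < 3:
        raise ValueError("fewer than 3 complete samples")
    if np.var(z, ddof=1) == 0:
        raise UndefinedInstrumentError("monomorphic instrument")
    b_zx = _slope(x, z)
    if b_zx == 0 or np.var(x, ddof=1) == 0:
        raise UndefinedInstrumentError("instrument explains no exposure variance")
    b_zy = _slope(y, z)
    r2_zx = _r2(x, z)
    r2_xy = _r2(y, x) if np.var(y, ddof=1) > 0 else 0.0
    if r2_zx == 0:
        raise UndefinedInstrumentError("R2_zx = 0")
    b_xy = b_zy / b_zx
    var_bxy = (np.var(y, ddof=1) * (1.0 - r2_xy)) / (n * np.var(x, ddof=1) * r2_zx)
    if var_bxy == 0:
        warnings.warn("R2_xy = 1: sampling variance is zero, p reported as 0")
        t_mr, p = np.inf, 0.0
    else:
        t_mr = b_xy**2 / var_bxy
        p = float(chi2.sf(t_mr, df=1))
    return {
        "n": n,
        "b_zx": b_zx,
        "b_zy": b_zy,
        "R2_zx": r2_zx,
        "R2_xy": r2_xy,
        "b_xy": b_xy,
        "var_bxy": var_bxy,
        "T_MR": float(t_mr),
        "p": p,
        "direction": "positive" if b_xy > 0 else "negative",
    }


def mr_threshold(n_tests: int, alpha_convention: str = "reciprocal") -> MRThreshold:
    """Experiment-wise cutoff: 1/n (reciprocal) or 0.05/n (Bonferroni)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if alpha_convention == "reciprocal":
        cutoff = 1.0 / n_tests
    elif alpha_convention == "bonferroni_0.05":
        cutoff = 0.05 / n_tests
    else:
        raise ValueError("alpha_convention must be 'reciprocal' or 'bonferroni_0.05'")
    return MRThreshold(n_tests=n_tests, cutoff=cutoff, convention=alpha_convention)


def mr_scan(
    eqtls: pd.DataFrame,
    sets: dict[str, ExpressionSet],
    phenotype: pd.Series,
    table: VariantTable,
    alpha_convention: str = "reciprocal",
) -> tuple[pd.DataFrame, MRThreshold | None]:
    """One MR test per (gene, condition) with a called eQTL.

    The instrument is that condition's most significant lead SNP for the
    gene; the exposure is the same condition's transformed expression.
    Records carry a ``significant`` flag at the experiment-wise cutoff
    and ``best_in_gene`` marking each gene's minimum-p test across
    conditions (the per-gene view).
    """
    if eqtls.empty:
        return pd.DataFrame(columns=MR_COLUMNS), None
    snp_idx = table.snp_index()
    dosage = table.dosage(impute=False)
    rows = []
    best = eqtls.sort_values("lead_p").groupby(["etrait_gene", "condition"]).head(1)
    for _, r in best.iterrows():
        cond, gene = r["condition"], r["etrait_gene"]
        expr = sets[cond]
        if expr.transformed is None or gene not in expr.transformed.index:
            continue
        x = expr.transformed.loc[gene]
        shared = [s for s in expr.sample_ids if s in phenotype.index and s in table.sample_ids]
        zvec = pd.Series(dosage[:, snp_idx[r["lead_snp"]]], index=table.sample_ids)
        try:
            rec = mr_test(
                zvec.loc[shared].to_numpy(),
                x.loc[shared].to_numpy(float),
                phenotype.loc[shared].to_numpy(float),
            )
        except UndefinedInstrumentError:
            continue
        rec.update({"gene_id": gene, "condition": cond, "snp_id": r["lead_snp"]})
        rows.append(rec)
    records = pd.DataFrame(rows, columns=MR_COLUMNS)
    if records.empty:
        return records, None
    thr = mr_threshold(len(records), alpha_convention)
    records["significant"] = records["p"] < thr.cutoff
    records["best_in_gene"] = False
    idx = records.groupby("gene_id")["p"].idxmin()
    records.loc[idx, "best_in_gene"] = True
    return records, thr


def classify_direction(records: pd.DataFrame) -> dict:
    """Positive / negative contributor lists among significant records.

    Counted per gene on each gene's best (minimum-p) significant test.
    """
    sig = records[records["significant"]] if "significant" in records else records
    if len(sig):
        assert (sig["b_xy"] != 0).all(), "significant record with b_xy = 0"
        per_gene = sig.sort_values("p").groupby("gene_id").head(1)
    else:
        per_gene = sig
    pos = sorted(per_gene.loc[per_gene["b_xy"] > 0, "gene_id"])
    neg = sorted(per_gene.loc[per_gene["b_xy"] < 0, "gene_id"])
    return {
        "positive": pos,
        "negative": neg,
        "n_positive": len(pos),
        "n_negative": len(neg),
        "n_total": len(pos) + len(neg),
    }
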
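"""Candidate-region association, haplotype grouping and LD structure.

Generalizes the single-locus follow-up analysis: scan a re-sequenced
region (SNPs plus InDels coded as presence/absence pseudo-bi-allelic
markers) against one gene's transformed expression, group accessions by
their exact allele string over the significant variants, and summarize
pairwise LD and its decay with distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .association_scan import (
    KinshipDecomposition,
    decompose_kinship,
    fit_null_p3d,
    scan_gene,
)
from .io_formats import MISSING, VariantTable


@dataclass
class HaplotypeGroup:
    haplotype_id: int
    alleles: str                 # genotype-code string over the significant variants
    member_samples: list[str]
    n_members: int
    expr_mean: float | None = None
    expr_sd: float | None = None


def region_association(
    table: VariantTable,
    expression: pd.Series,
    covariates: np.ndarray | None = None,
    factors: np.ndarray | None = None,
    kd: KinshipDecomposition | None = None,
) -> pd.DataFrame:
    """Per-variant mixed-model p-values for one expression trait.

    Reuses the genome-wide scan machinery restricted to the region's
    variants; with no kinship given an identity matrix is used, which
    collapses the mixed model to ordinary least squares.  Monomorphic
    variants are skipped.
    """
    y = expression.loc[list(table.sample_ids)].to_numpy(float)
    if np.var(y) == 0:
        raise ValueError("expression vector has zero variance")
    if kd is None:
        kd = decompose_kinship(np.eye(table.n_samples))
    fit = fit_null_p3d(y, covariates, factors, kd)
    res = scan_gene(fit, table.dosage(impute=True), kd)
    res.insert(0, "snp", table.snp_id)
    res.insert(1, "chrom", table.chrom)
    res.insert(2, "pos", table.pos)
    return res.dropna(subset=["p"]).reset_index(drop=True)


def define_haplotypes(
    table: VariantTable,
    pvals: pd.DataFrame,
    expression: pd.Series | None = None,
    p_cut: float = 1e-6,
    min_count: int = 5,
) -> list[HaplotypeGroup]:
    """Group samples by exact allele string over significant variants.

    Samples missing any significant variant call are excluded; groups
    with ``n_members <= min_count`` are discarded; groups come back
    ordered by size (largest first).
    """
    sig = pvals.loc[pvals["p"] < p_cut, "snp"]
    if sig.empty:
        return []
    idx = table.snp_index()
    cols = np.array([idx[s] for s in sig])
    calls = table.calls[:, cols]
    groups: dict[str, list[str]] = {}
    for i, sample in enumerate(table.sample_ids):
        row = calls[i]
        if (row == MISSING).any():
            continue
        groups.setdefault("".join(str(int(c)) for c in row), []).append(sample)
    kept = [
        (alleles, members)
        for alleles, members in groups.items()
        if len(members) > min_count
    ]
    kept.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    out = []
    for hid, (alleles, members) in enumerate(kept, start=1):
        mean = sd = None
        if expression is not None:
            vals = expression.loc[members].to_numpy(float)
            mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        out.append(
            HaplotypeGroup(
                haplotype_id=hid,
                alleles=alleles,
                member_samples=members,
                n_members=len(members),
                expr_mean=mean,
                expr_sd=sd,
            )
        )
    return out


def pairwise_ld(table: VariantTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """r^2 and D' matrices over all variant pairs.

    r^2 is the squared dosage correlation over samples called in both
    variants.  D' uses the inbred shortcut: homozygous rows are treated
    as gametes and heterozygotes are excluded pairwise, so haplotype
    frequencies are directly countable.  Monomorphic pairs are NaN.
    """
    if table.n_snps < 2:
        raise ValueError("need at least two variants")
    m = table.n_snps
    dos = table.dosage()
    r2 = np.full((m, m), np.nan)
    dp = np.full((m, m), np.nan)
    for a in range(m):
        r2[a, a] = 1.0
        dp[a, a] = 1.0
        for b in range(a + 1, m):
            both = ~(np.isnan(dos[:, a]) | np.isnan(dos[:, b]))
            ga, gb = dos[both, a], dos[both, b]
            if len(ga) >= 2 and ga.std() > 0 and gb.std() > 0:
                r2[a, b] = r2[b, a] = np.corrcoef(ga, gb)[0, 1] ** 2
            hom = (np.isin(ga, (0.0, 2.0))) & (np.isin(gb, (0.0, 2.0)))
            ha, hb = ga[hom] / 2.0, gb[hom] / 2.0
            n = len(ha)
            if n == 0:
                continue
            pa, pb = ha.mean(), hb.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            p11 = np.mean(ha * hb)
            D = p11 - pa * pb
            if D >= 0:
                dmax = min(pa * (1 - pb), (1 - pa) * pb)
            else:
                dmax = min(pa * pb, (1 - pa) * (1 - pb))
            dp[a, b] = dp[b, a] = abs(D) / dmax if dmax > 0 else np.nan
    ids = list(table.snp_id)
    return (
        pd.DataFrame(r2, index=ids, columns=ids),
        pd.DataFrame(dp, index=ids, columns=ids),
    )


def ld_decay(
    table: VariantTable,
    r2_target: float = 0.2,
    max_dist_bp: int = 100000,
    bin_bp: int = 100,
) -> tuple[float, pd.DataFrame]:
    """Distance at which mean pairwise r^2 falls below ``r2_target``.

    Pairs within ``max_dist_bp`` on the same chromosome are binned by
    distance; bin means are smoothed with a decreasing isotonic fit and
    the decay distance is the first bin midpoint where the smoothed
    curve drops below the target.  Returns ``inf`` (still above target
    at the maximum distance) together with the binned curve.
    """
    dos = table.dosage(impute=True)
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(dos)
    z[:, ok] = (dos[:, ok] - mu[ok]) / sd[ok]
    n, m = dos.shape
    dists, r2s = [], []
    for k in range(1, m):
        d = table.pos[k:] - table.pos[:-k]
        same = table.chrom[k:] == table.chrom[:-k]
        near = same & (d <= max_dist_bp) & ok[k:] & ok[:-k]
        if not near.any():
            if not same.any() or d[same].min() > max_dist_bp:
                break
            continue
        r = np.einsum("ij,ij->j", z[:, k:], z[:, :-k]) / n
        dists.append(d[near])
        r2s.append(r[near] ** 2)
    if not dists:
        raise ValueError("no variant pairs within max_dist_bp")
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    bins = (dist - 1) // bin_bp
    curve = (
        pd.DataFrame({"bin": bins, "r2": r2})
        .groupby("bin")["r2"]
        .agg(["mean", "count"])
        .reset_index()
    )
    curve["midpoint"] = curve["bin"] * bin_bp + bin_bp / 2.0
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    curve["smoothed"] = iso.fit_transform(curve["midpoint"], curve["mean"])
    below = curve.loc[curve["smoothed"] < r2_target, "midpoint"]
    decay = float(below.iloc[0]) if len(below) else float("inf")
    return decay, curve[["midpoint", "mean", "smoothed", "count"]]
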
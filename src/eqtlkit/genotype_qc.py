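"""Genotype cleaning and cross-dataset concordance.

Inbred panels genotyped from RNA-seq reads carry residual heterozygous
calls that are mostly technical.  The cleaning rule treats them by site
MAF: at rare sites (MAF < 0.05) the het is assumed to be a sequencing
error and is recoded to the major-allele homozygote; at common sites it
is masked as missing.  Two panels covering the same samples can then be
compared call-by-call, with discordant cells masked in the merged panel.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io_formats import MISSING, VariantTable

HET_MAF_THRESHOLD = 0.05


def resolve_heterozygotes(table: VariantTable, maf_threshold: float = HET_MAF_THRESHOLD) -> VariantTable:
    """Recode or mask heterozygous calls by site MAF.

    At SNPs with MAF < ``maf_threshold`` het calls become the
    major-allele homozygote (alt-hom when the alt allele is major);
    elsewhere they become missing.  Homozygote calls are untouched.
    All-missing SNPs are left untouched.
    """
    calls = table.calls.copy()
    p_alt = table.alt_frequency()  # NaN for all-missing SNPs
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p_alt, 1.0 - p_alt)
        rare = maf < maf_threshold
        alt_major = p_alt > 0.5
    rare = np.where(np.isnan(maf), False, rare)
    het = calls == 1
    # rare site: het -> major hom; common site: het -> missing
    major_code = np.where(alt_major, 2, 0).astype(np.int8)
    for j in np.where(het.any(axis=0))[0]:
        rows = het[:, j]
        if np.isnan(maf[j]):
            continue
        calls[rows, j] = major_code[j] if rare[j] else MISSING
    return replace(table, calls=calls)


def filter_snps(
    table: VariantTable, maf_min: float = 0.05, missing_max: float = 0.6
) -> VariantTable:
    """Keep SNPs with missing fraction < ``missing_max`` and MAF >= ``maf_min``.

    The bounds are applied exactly as printed: missing strictly below,
    MAF inclusive.
    """
    with np.errstate(invalid="ignore"):
        maf = np.nan_to_num(table.maf(), nan=-1.0)
    keep = (table.missing_fraction() < missing_max) & (maf >= maf_min)
    return table.take_snps(np.where(keep)[0])


def _overlap(a: VariantTable, b: VariantTable):
    """Shared samples and SNPs keyed on (chrom, pos, ref, alt), with swap detection."""
    samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    key_a = {
        (a.chrom[j], int(a.pos[j]), a.ref[j], a.alt[j]): j for j in range(a.n_snps)
    }
    idx_a, idx_b, swapped = [], [], []
    for j in range(b.n_snps):
        k = (b.chrom[j], int(b.pos[j]), b.ref[j], b.alt[j])
        ks = (b.chrom[j], int(b.pos[j]), b.alt[j], b.ref[j])
        if k in key_a:
            idx_a.append(key_a[k]); idx_b.append(j); swapped.append(False)
        elif ks in key_a:
            idx_a.append(key_a[ks]); idx_b.append(j); swapped.append(True)
    return samples, np.array(idx_a, int), np.array(idx_b, int), np.array(swapped, bool)


def _aligned_calls(a: VariantTable, b: VariantTable):
    samples, ia, ib, swapped = _overlap(a, b)
    if not samples or len(ia) == 0:
        raise ValueError("tables share no samples or no SNPs")
    ca = a.take_samples(samples).calls[:, ia]
    cb = b.take_samples(samples).calls[:, ib]
    cb = cb.copy()
    # ref/alt flipped in b: recode 0 <-> 2
    flip = swapped[None, :] & (cb != MISSING)
    cb[flip] = 2 - cb[flip]
    return samples, ia, ib, ca, cb


def concordance_rate(a: VariantTable, b: VariantTable, pooled: bool = False):
    """Per-sample (default) or pooled genotype concordance between two panels.

    Only cells non-missing in both panels enter the denominator.
    Returns ``(per_sample, mean)`` keyed by sample id, or a single float
    in pooled mode.
    """
    samples, _, _, ca, cb = _aligned_calls(a, b)
    both = (ca != MISSING) & (cb != MISSING)
    agree = both & (ca == cb)
    if pooled:
        denom = both.sum()
        if denom == 0:
            raise ValueError("no jointly called cells")
        return agree.sum() / denom
    denom = both.sum(axis=1)
    if (denom == 0).all():
        raise ValueError("no jointly called cells for any sample")
    with np.errstate(invalid="ignore"):
        rate = np.where(denom > 0, agree.sum(axis=1) / np.maximum(denom, 1), np.nan)
    per_sample = dict(zip(samples, rate))
    return per_sample, float(np.nanmean(rate))


def mask_discordant(a: VariantTable, b: VariantTable) -> VariantTable:
    """Merge panel ``b`` into ``a``, masking cells where they disagree.

    Cells non-missing in both and unequal become missing; agreeing cells
    are kept; cells called in only one source keep that call.  The
    output has panel ``a``'s SNP set and the shared sample subset.
    """
    samples, ia, _, ca, cb = _aligned_calls(a, b)
    merged = a.take_samples(samples)
    calls = merged.calls.copy()
    sub = calls[:, ia]
    discord = (ca != MISSING) & (cb != MISSING) & (ca != cb)
    fill = (ca == MISSING) & (cb != MISSING)
    sub[discord] = MISSING
    sub[fill] = cb[fill]
    calls[:, ia] = sub
    return replace(merged, calls=calls)
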
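"""Containers and readers/writers for the formats the pipeline touches.

The pipeline works with four in-memory objects: a genotype table
(:class:`VariantTable`), a gene annotation (:class:`GeneAnnotation`),
per-condition expression matrices (:class:`ExpressionSet`) and a
per-accession phenotype (a pandas ``Series``).  On disk these map to
VCF 4.x, GFF3, TSV matrices and a two-column TSV respectively.

Coordinates are 1-based inclusive everywhere inside the package; the
only conversion happens in :func:`write_bed`, which emits 0-based
half-open intervals for genome browsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call.  Calls are stored in a small
#: signed integer matrix; NaN-in-integer tricks are never used at the
#: interface level.
MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})


class EmptyResultError(ValueError):
    """Raised when a filter leaves zero records."""


@dataclass
class VariantTable:
    """Sample x SNP genotype codes plus SNP coordinates and alleles.

    ``calls`` uses the coding 0 = ref-hom, 1 = het, 2 = alt-hom,
    :data:`MISSING` = no call.  Codes stay ref/alt-based for the life of
    the object; minor/major identity is derived per SNP on demand (see
    :meth:`maf`), never stored stale.
    """

    snp_id: np.ndarray          # (m,) str
    chrom: np.ndarray           # (m,) str
    pos: np.ndarray             # (m,) int, 1-based bp
    ref: np.ndarray             # (m,) str
    alt: np.ndarray             # (m,) str
    calls: np.ndarray           # (n_samples, m) int8
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_id)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_id)} SNPs"
            )
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("snp_ids are not unique")
        if self.n_snps and self.pos.min() < 1:
            raise ValueError("positions must be >= 1 (1-based)")
        bad = set(np.unique(self.calls)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    # -- derived per-SNP statistics ------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Per-SNP alt-allele frequency among non-missing calls (NaN if all missing)."""
        obs = self.calls != MISSING
        n_called = obs.sum(axis=0)
        alt_count = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency among non-missing calls."""
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Genotype dosages as float, missing as NaN or per-SNP mean-imputed."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute:
            mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            mean = np.where(np.isnan(mean), 0.0, mean)
            idx = np.where(np.isnan(d))
            d[idx] = mean[idx[1]]
        return d

    # -- subsetting -----------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            snp_id=self.snp_id[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[:, index],
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, sample_ids: list[str]) -> "VariantTable":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lookup[s] for s in sample_ids]
        return replace(self, calls=self.calls[rows, :], sample_ids=list(sample_ids))

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_id)}


@dataclass
class GeneAnnotation:
    """Gene coordinates (1-based inclusive) with optional TF-family labels."""

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, strand, is_tf, tf_family

    COLUMNS = ("chrom", "start", "end", "strand", "is_tf", "tf_family")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("gene_ids are not unique")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene with start > end")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def loc(self, gene_id: str) -> pd.Series:
        return self.table.loc[gene_id]

    def genes_containing(self, chrom: str, pos: int) -> list[str]:
        """Gene ids whose body (1-based inclusive) contains the position."""
        t = self.table
        hit = (t["chrom"] == chrom) & (t["start"] <= pos) & (pos <= t["end"])
        return list(t.index[hit])


@dataclass
class ExpressionSet:
    """Gene x sample abundance for one condition, with optional transform.

    ``values`` holds nonnegative FPKM-like abundances.  ``transformed``
    is filled by the normalization steps (quantile normalization across
    samples followed by a per-gene inverse-normal transform) and is the
    matrix the association scan consumes.
    """

    condition: str
    values: pd.DataFrame                     # genes x samples
    transformed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy(float) < 0).any():
            raise ValueError("abundance values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    maf_min: float | None = None,
    missing_max: float | None = None,
    indels: str = "skip",
) -> VariantTable:
    """Read a VCF 4.x into a :class:`VariantTable`.

    Multi-allelic records are always skipped (with a logged count).  With
    ``indels="skip"`` records whose REF/ALT are not single bases are
    skipped too; ``indels="pseudo"`` keeps them as presence/absence
    pseudo-bi-allelic markers (used for candidate-region scans that mix
    SNPs and InDels).

    When ``maf_min`` / ``missing_max`` are given the corresponding
    filters are applied at load time: MAF is computed from non-missing
    calls and must be ``>= maf_min``; the missing fraction must be
    ``< missing_max``.
    """
    from cyvcf2 import VCF

    if indels not in ("skip", "pseudo"):
        raise ValueError("indels must be 'skip' or 'pseudo'")
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    snp_id, chrom, pos, ref, alt, rows = [], [], [], [], [], []
    n_multi = n_indel = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if indels == "skip" and (len(rec.REF) != 1 or len(rec.ALT[0]) != 1):
            n_indel += 1
            continue
        snp_id.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        g = rec.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown under gts012
        g[g == 3] = MISSING
        rows.append(g)
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    if n_indel:
        logger.info("skipped %d indel records in %s", n_indel, path)
    if not rows:
        raise EmptyResultError(f"no usable bi-allelic records in {path}")
    calls = np.stack(rows, axis=1)
    table = VariantTable(
        snp_id=np.array(snp_id, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=calls,
        sample_ids=sample_ids,
    )
    keep = np.ones(table.n_snps, dtype=bool)
    if missing_max is not None:
        keep &= table.missing_fraction() < missing_max
    if maf_min is not None:
        with np.errstate(invalid="ignore"):
            keep &= np.nan_to_num(table.maf(), nan=-1.0) >= maf_min
    if keep.sum() == 0:
        raise EmptyResultError(
            f"no SNPs survive MAF >= {maf_min} / missing < {missing_max} in {path}"
        )
    if not keep.all():
        table = table.take_snps(np.where(keep)[0])
    return table


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a :class:`VariantTable` as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(table.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for j in range(table.n_snps):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in table.calls[:, j])
            fh.write(
                f"{table.chrom[j]}\t{table.pos[j]}\t{table.snp_id[j]}\t"
                f"{table.ref[j]}\t{table.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str, tf_attribute: str = "tf_family") -> GeneAnnotation:
    """Read gene features from a GFF3 file (via gffutils).

    The TF family is taken from the attribute named ``tf_attribute`` when
    present; any gene carrying it is flagged ``is_tf``.  Coordinates stay
    1-based inclusive, as in the file.
    """
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    rows = {}
    for f in db.features_of_type("gene"):
        fam_vals = f.attributes.get(tf_attribute)
        fam = fam_vals[0] if fam_vals else None
        rows[f.id] = {
            "chrom": f.seqid,
            "start": int(f.start),
            "end": int(f.end),
            "strand": f.strand,
            "is_tf": fam is not None,
            "tf_family": fam,
        }
    if not rows:
        found = sorted({f.featuretype for f in db.all_features()})
        raise ValueError(f"no gene features in {path}; feature types found: {found}")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return GeneAnnotation(df)


def write_gff3(annotation: GeneAnnotation, path: str, tf_attribute: str = "tf_family") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in annotation.table.iterrows():
            attrs = f"ID={gid}"
            if row["is_tf"] and row["tf_family"]:
                attrs += f";{tf_attribute}={row['tf_family']}"
            fh.write(
                f"{row['chrom']}\t.\tgene\t{row['start']}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TSV matrices, phenotype, generic tables, BED
# ---------------------------------------------------------------------------

def read_matrix(path: str, condition: str = "NA") -> ExpressionSet:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    ``NA`` cells become missing values, never zero.
    """
    with open(path) as fh:
        n_fields = None
        for lineno, line in enumerate(fh, start=1):
            width = line.rstrip("\n").count("\t") + 1
            if n_fields is None:
                n_fields = width
            elif width != n_fields:
                raise ValueError(
                    f"ragged TSV {path}: row {lineno} has {width} fields, expected {n_fields}"
                )
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionSet(condition=condition, values=df)


def write_matrix(exprset: ExpressionSet, path: str, transformed: bool = False) -> None:
    df = exprset.transformed if transformed else exprset.values
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_phenotype(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise ValueError("duplicated sample ids in phenotype file")
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=list(ids), name="phenotype")


def write_phenotype(pheno: pd.Series, path: str) -> None:
    pd.DataFrame({"sample_id": pheno.index, "value": pheno.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_table(records: pd.DataFrame, path: str) -> None:
    """Canonical TSV export with declared header, no index column."""
    records.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Export 1-based inclusive intervals as BED (0-based half-open).

    ``intervals`` needs columns chrom, start, end, name; conversion is
    exact: BED start = start - 1, BED end = end.
    """
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"].astype(int) - 1,
            "end": intervals["end"].astype(int),
            "name": intervals["name"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
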
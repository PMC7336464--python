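"""Consolidate significant SNPs into eQTLs and classify them.

An eQTL for one etrait under one condition is built in three steps:
(1) significant SNPs closer than 5 kb chain into one cluster,
(2) clusters whose lead SNPs are in LD (r^2 > 0.1, within 250 kb) merge
    transitively, keeping the overall most significant lead,
(3) clusters whose lead SNPs fall inside the same gene body merge.
An etrait-condition pair only yields eQTLs at all when it has at least
three significant SNPs.  The lead SNP then classifies the locus as
local (within 20 kb of the etrait gene body) or distant, and the
cross-condition pattern classifies it as static (all three regimes) or
dynamic (one or two), with a stress-only flag for loci never seen under
the well-watered regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_formats import MISSING, GeneAnnotation, VariantTable

EQTL_COLUMNS = [
    "etrait_gene", "condition", "lead_snp", "lead_chrom", "lead_pos",
    "lead_p", "lead_r2", "n_members", "members", "locality", "resolved_gene",
]


@dataclass
class Cluster:
    """Member rows (indices into the significant-SNP frame) plus the lead row."""

    members: list[int]
    lead: int


def snp_r2(table: VariantTable, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation over samples called in both SNPs (0 if undefined)."""
    idx = table.snp_index()
    ca = table.calls[:, idx[snp_a]]
    cb = table.calls[:, idx[snp_b]]
    both = (ca != MISSING) & (cb != MISSING)
    ga = ca[both].astype(float)
    gb = cb[both].astype(float)
    if len(ga) < 2 or ga.std() == 0 or gb.std() == 0:
        return 0.0
    return float(np.corrcoef(ga, gb)[0, 1] ** 2)


def min_support_filter(sig: pd.DataFrame, k: int = 3) -> bool:
    """True when the etrait-condition pair has at least ``k`` significant SNPs."""
    return len(sig) >= k


def _elect_lead(sig: pd.DataFrame, members: list[int]) -> int:
    """Most significant member; ties by larger partial_r2, then smaller position."""
    sub = sig.loc[members]
    order = sub.sort_values(
        ["p", "partial_r2", "pos"], ascending=[True, False, True], kind="stable"
    )
    return int(order.index[0])


def group_by_distance(sig: pd.DataFrame, gap_bp: int = 5000) -> list[Cluster]:
    """Single-linkage chaining of significant SNPs closer than ``gap_bp``.

    ``sig`` must carry columns chrom, pos, p, partial_r2; the frame is
    sorted internally, so input order does not matter.  SNPs on
    different chromosomes never join.
    """
    if sig.empty:
        return []
    order = sig.sort_values(["chrom", "pos"], kind="stable")
    clusters: list[list[int]] = []
    prev_chrom, prev_pos = None, None
    for row_idx, row in order.iterrows():
        if (
            clusters
            and row["chrom"] == prev_chrom
            and row["pos"] - prev_pos < gap_bp
        ):
            clusters[-1].append(row_idx)
        else:
            clusters.append([row_idx])
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    return [Cluster(members=m, lead=_elect_lead(sig, m)) for m in clusters]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def merge_by_ld(
    clusters: list[Cluster],
    sig: pd.DataFrame,
    table: VariantTable,
    r2_min: float = 0.1,
    max_dist_bp: int = 250000,
) -> list[Cluster]:
    """Transitively merge clusters whose lead SNPs are in LD and nearby.

    LD is the squared dosage correlation between the two lead SNPs; a
    monomorphic lead gives undefined r^2, treated as 0.  Merged clusters
    re-elect the overall most significant lead.
    """
    if len(clusters) < 2:
        return clusters
    uf = _UnionFind(len(clusters))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = sig.loc[clusters[i].lead], sig.loc[clusters[j].lead]
            if a["chrom"] != b["chrom"]:
                continue
            if abs(int(a["pos"]) - int(b["pos"])) > max_dist_bp:
                continue
            if snp_r2(table, a["snp"], b["snp"]) > r2_min:
                uf.union(i, j)
    grouped: dict[int, list[int]] = {}
    for i, c in enumerate(clusters):
        grouped.setdefault(uf.find(i), []).extend(c.members)
    return [
        Cluster(members=sorted(m, key=lambda r: int(sig.loc[r, "pos"])), lead=_elect_lead(sig, m))
        for _, m in sorted(grouped.items())
    ]


def merge_by_gene(
    clusters: list[Cluster], sig: pd.DataFrame, annotation: GeneAnnotation
) -> list[Cluster]:
    """Merge clusters whose lead SNPs fall inside the same gene body."""
    if len(clusters) < 2:
        return clusters
    containing = []
    for c in clusters:
        row = sig.loc[c.lead]
        genes = annotation.genes_containing(row["chrom"], int(row["pos"]))
        containing.append(set(genes))
    uf = _UnionFind(len(clusters))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if containing[i] & containing[j]:
                uf.union(i, j)
    grouped: dict[int, list[int]] = {}
    for i, c in enumerate(clusters):
        grouped.setdefault(uf.find(i), []).extend(c.members)
    return [
        Cluster(members=sorted(m, key=lambda r: int(sig.loc[r, "pos"])), lead=_elect_lead(sig, m))
        for _, m in sorted(grouped.items())
    ]


def classify_locality(
    lead_chrom: str,
    lead_pos: int,
    etrait_gene: str,
    annotation: GeneAnnotation,
    window_bp: int = 20000,
) -> str:
    """local when the lead SNP sits within the gene body +/- ``window_bp``."""
    if etrait_gene not in annotation:
        raise KeyError(f"etrait gene {etrait_gene} absent from annotation")
    g = annotation.loc(etrait_gene)
    if lead_chrom == g["chrom"] and g["start"] - window_bp <= lead_pos <= g["end"] + window_bp:
        return "local"
    return "distant"


def call_condition_eqtls(
    sig: pd.DataFrame,
    table: VariantTable,
    annotation: GeneAnnotation,
    etrait_gene: str,
    condition: str,
    min_snps: int = 3,
    gap_bp: int = 5000,
    r2_min: float = 0.1,
    max_dist_bp: int = 250000,
    min_support: str = "per_condition",
    locality_window_bp: int = 20000,
) -> pd.DataFrame:
    """Run the three consolidation steps for one etrait under one condition.

    ``sig`` holds the genome-wide-significant SNPs (columns snp, chrom,
    pos, p, partial_r2).  With ``min_support='per_condition'`` (default)
    the >=3-SNP rule gates the whole pair before grouping; with
    ``'per_cluster'`` it is applied to each final cluster instead.
    """
    sig = sig.reset_index(drop=True)
    if min_support == "per_condition" and not min_support_filter(sig, min_snps):
        return pd.DataFrame(columns=EQTL_COLUMNS)
    clusters = group_by_distance(sig, gap_bp)
    clusters = merge_by_ld(clusters, sig, table, r2_min, max_dist_bp)
    clusters = merge_by_gene(clusters, sig, annotation)
    if min_support == "per_cluster":
        clusters = [c for c in clusters if len(c.members) >= min_snps]
    rows = []
    for c in clusters:
        lead = sig.loc[c.lead]
        resolved = annotation.genes_containing(lead["chrom"], int(lead["pos"]))
        rows.append(
            {
                "etrait_gene": etrait_gene,
                "condition": condition,
                "lead_snp": lead["snp"],
                "lead_chrom": lead["chrom"],
                "lead_pos": int(lead["pos"]),
                "lead_p": float(lead["p"]),
                "lead_r2": float(lead["partial_r2"]),
                "n_members": len(c.members),
                "members": ",".join(sig.loc[c.members, "snp"]),
                "locality": classify_locality(
                    lead["chrom"], int(lead["pos"]), etrait_gene, annotation,
                    locality_window_bp,
                ),
                "resolved_gene": resolved[0] if resolved else None,
            }
        )
    return pd.DataFrame(rows, columns=EQTL_COLUMNS)


DYNAMICS_COLUMNS = [
    "etrait_gene", "locus_id", "lead_snp", "lead_chrom", "lead_pos",
    "lead_p", "lead_r2", "locality", "conditions_detected", "n_conditions",
    "dynamics", "stress_only",
]


def classify_dynamics(
    eqtls: pd.DataFrame,
    table: VariantTable | None = None,
    conditions: tuple[str, ...] = ("WW", "WS1", "WS2"),
    dist_bp: int = 5000,
    r2_min: float = 0.1,
) -> pd.DataFrame:
    """Cross-condition locus identity and the static/dynamic label.

    Two per-condition eQTLs of the same etrait are the same locus when
    their lead SNPs sit within ``dist_bp`` or are in LD (r^2 >
    ``r2_min``), the same tolerances used within a condition.  A locus
    present in all conditions is static; in one or two, dynamic;
    ``stress_only`` marks loci detected under stress (WS1/WS2) but never
    under WW.
    """
    out_rows = []
    for gene, sub in eqtls.groupby("etrait_gene", sort=True):
        sub = sub.reset_index(drop=True)
        uf = _UnionFind(len(sub))
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                a, b = sub.loc[i], sub.loc[j]
                if a["lead_chrom"] != b["lead_chrom"]:
                    continue
                close = abs(int(a["lead_pos"]) - int(b["lead_pos"])) < dist_bp
                linked = (
                    table is not None
                    and not close
                    and snp_r2(table, a["lead_snp"], b["lead_snp"]) > r2_min
                )
                if close or linked:
                    uf.union(i, j)
        loci: dict[int, list[int]] = {}
        for i in range(len(sub)):
            loci.setdefault(uf.find(i), []).append(i)
        for k, (root, members) in enumerate(sorted(loci.items())):
            conds = sorted(
                set(sub.loc[members, "condition"]), key=lambda c: conditions.index(c)
            )
            static = set(conds) == set(conditions)
            stress_only = "WW" not in conds
            best = sub.loc[members].sort_values(["lead_p", "lead_pos"]).iloc[0]
            out_rows.append(
                {
                    "etrait_gene": gene,
                    "locus_id": f"{gene}:{k + 1}",
                    "lead_snp": best["lead_snp"],
                    "lead_chrom": best["lead_chrom"],
                    "lead_pos": int(best["lead_pos"]),
                    "lead_p": float(best["lead_p"]),
                    "lead_r2": float(best["lead_r2"]),
                    "locality": best["locality"],
                    "conditions_detected": ",".join(conds),
                    "n_conditions": len(conds),
                    "dynamics": "static" if static else "dynamic",
                    "stress_only": bool(stress_only),
                }
            )
    return pd.DataFrame(out_rows, columns=DYNAMICS_COLUMNS)


def call_eqtls(
    scans: dict[str, pd.DataFrame],
    cutoffs: dict[str, float],
    table: VariantTable,
    annotation: GeneAnnotation,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consolidate every condition's scan into eQTLs plus locus dynamics.

    ``scans`` maps condition -> long association frame; ``cutoffs`` maps
    condition -> BH p cutoff (p <= cutoff is significant).  Returns the
    per-condition eQTL table and the cross-condition locus table.
    """
    per_cond = []
    for cond, scan in scans.items():
        cut = cutoffs[cond]
        sig_all = scan[scan["p"] <= cut]
        for gene, sub in sig_all.groupby("gene", sort=True):
            sig = sub[["snp", "chrom", "pos", "p", "partial_r2"]]
            per_cond.append(
                call_condition_eqtls(sig, table, annotation, gene, cond, **kwargs)
            )
    per_cond = [df for df in per_cond if len(df)]
    eqtls = (
        pd.concat(per_cond, ignore_index=True)
        if per_cond
        else pd.DataFrame(columns=EQTL_COLUMNS)
    )
    dynamics = (
        classify_dynamics(eqtls, table)
        if len(eqtls)
        else pd.DataFrame(columns=DYNAMICS_COLUMNS)
    )
    return eqtls, dynamics


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def percentage(part: int, whole: int, decimals: int = 1) -> float:
    """100 * part / whole rounded half-up to ``decimals`` places."""
    if whole == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(part) / Decimal(whole)).quantize(q, rounding=ROUND_HALF_UP)
    )


def summarize_counts(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Static/dynamic x local/distant summary from raw counts.

    ``counts`` maps (dynamics, locality) -> count.  Percentages are of
    the overall total for the dynamics margin and of each locality total
    for the within-locality rows.
    """
    total = sum(counts.values())
    rows = []
    for dyn in ("static", "dynamic"):
        n = sum(v for (d, _), v in counts.items() if d == dyn)
        rows.append({"group": dyn, "of": "total", "count": n, "pct": percentage(n, total)})
    for loc in ("local", "distant"):
        loc_total = sum(v for (_, l), v in counts.items() if l == loc)
        for dyn in ("static", "dynamic"):
            n = counts.get((dyn, loc), 0)
            rows.append(
                {
                    "group": f"{dyn}_{loc}",
                    "of": loc,
                    "count": n,
                    "pct": percentage(n, loc_total),
                }
            )
    return pd.DataFrame(rows)


def summarize_calls(dynamics: pd.DataFrame) -> pd.DataFrame:
    """Count/percentage table over the classified loci."""
    if dynamics.empty:
        return summarize_counts({})
    counts = {
        (dyn, loc): int(((dynamics["dynamics"] == dyn) & (dynamics["locality"] == loc)).sum())
        for dyn in ("static", "dynamic")
        for loc in ("local", "distant")
    }
    return summarize_counts(counts)


def eqtl_intervals(eqtls: pd.DataFrame, table: VariantTable | None = None) -> pd.DataFrame:
    """1-based inclusive intervals for BED export.

    With a genotype table the interval spans the member SNPs; without
    one it degenerates to the lead position.
    """
    pos_of = dict(zip(table.snp_id, table.pos)) if table is not None else {}
    rows = []
    for _, r in eqtls.iterrows():
        members = r["members"].split(",")
        span = [pos_of[s] for s in members if s in pos_of] or [int(r["lead_pos"])]
        rows.append(
            {
                "chrom": r["lead_chrom"],
                "start": int(min(span)),
                "end": int(max(span)),
                "name": f"{r['etrait_gene']}|{r['condition']}|{r['lead_snp']}|{len(members)}snps",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
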
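"""End-to-end driver tying the analysis stages together.

Given a genotype panel, an annotation, per-condition abundance matrices
and a phenotype, this runs: genotype QC, expression normalization,
kinship / structure / hidden-factor construction, the per-condition
mixed-model scan with pooled BH thresholds, eQTL consolidation and
classification, the TF network with hierarchy tiers, and the MR scan.
The stages stay individually importable; this module only sequences
them with the default settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    association_scan as scan_mod,
    eqtl_calling,
    expression_processing as expr_mod,
    genotype_qc,
    mendelian_randomization as mr_mod,
    network_hierarchy,
)
from .io_formats import ExpressionSet, GeneAnnotation, VariantTable


@dataclass
class PipelineResult:
    table: VariantTable
    sets: dict[str, ExpressionSet]
    scans: dict[str, pd.DataFrame]
    thresholds: dict[str, scan_mod.ScanThreshold]
    eqtls: pd.DataFrame
    dynamics: pd.DataFrame
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)
    mr_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    mr_threshold: mr_mod.MRThreshold | None = None


def normalize_sets(sets: dict[str, ExpressionSet]) -> dict[str, ExpressionSet]:
    """Quantile normalization then per-gene inverse-normal transform."""
    return {
        c: expr_mod.inverse_normal_transform(expr_mod.quantile_normalize(s))
        for c, s in sets.items()
    }


def run_pipeline(
    table: VariantTable,
    annotation: GeneAnnotation,
    sets: dict[str, ExpressionSet],
    phenotype: pd.Series | None = None,
    maf_min: float = 0.05,
    missing_max: float = 0.6,
    n_pc: int = 3,
    n_factors: int = 14,
    fdr: float = 0.05,
    kinship_window_bp: int = 10000,
    qc: bool = True,
    **call_kwargs,
) -> PipelineResult:
    if qc:
        table = genotype_qc.filter_snps(
            genotype_qc.resolve_heterozygotes(table), maf_min, missing_max
        )
    norm = normalize_sets(sets)
    thinned = scan_mod.thin_snps_by_window(table, kinship_window_bp)
    K = scan_mod.kinship_ibs(table, thinned)
    kd = scan_mod.decompose_kinship(K)
    covariates = scan_mod.structure_covariates(table, n_pc)

    scans: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, scan_mod.ScanThreshold] = {}
    for cond, exprset in norm.items():
        k = min(n_factors, table.n_samples - covariates.shape[1] - 2)
        factors = scan_mod.hidden_factors(exprset, covariates, k)
        scan = scan_mod.scan_condition(table, exprset, covariates, factors, kd)
        scans[cond] = scan
        thresholds[cond] = scan_mod.bh_threshold(scan["p"].to_numpy(), fdr, cond)

    cutoffs = {c: t.bh_p_cutoff for c, t in thresholds.items()}
    eqtls, dynamics = eqtl_calling.call_eqtls(scans, cutoffs, table, annotation, **call_kwargs)

    edges = pd.DataFrame()
    scores = pd.DataFrame()
    if len(dynamics):
        edges = network_hierarchy.resolve_eqtls_to_tfs(
            dynamics.rename(columns={"locus_id": "locus_id"}), annotation
        )
        if len(edges):
            raw = network_hierarchy.hierarchy_height(edges, annotation)
            if len(raw):
                scores = network_hierarchy.assign_tiers(raw)

    mr_records = pd.DataFrame()
    mr_thr = None
    if phenotype is not None and len(eqtls):
        mr_records, mr_thr = mr_mod.mr_scan(eqtls, norm, phenotype, table)

    return PipelineResult(
        table=table,
        sets=norm,
        scans=scans,
        thresholds=thresholds,
        eqtls=eqtls,
        dynamics=dynamics,
        edges=edges,
        scores=scores,
        mr_records=mr_records,
        mr_threshold=mr_thr,
    )
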
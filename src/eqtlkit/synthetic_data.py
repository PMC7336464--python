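"""Genotype / expression / phenotype simulator with a known regulatory truth.

The generator emulates the study design the pipeline targets: a diverse
inbred panel with ~3 ancestral subpopulations (Balding-Nichols allele
frequencies), linkage disequilibrium decaying on a kb scale along one
chromosome, gene expression measured under three water regimes
(WW / WS1 / WS2), local regulatory variants within +/-20 kb of a gene,
distant regulation transmitted through transcription-factor expression,
hidden confounding factors, and a quantitative phenotype (survival-rate
style, mapped into [0, 1]) linearly mediated by a subset of gene
expressions.  Every nonzero simulated effect is recorded exactly once in
a :class:`TruthLedger` so downstream stages can be scored against the
truth.

Effects are either *static* (active in all conditions) or *dynamic*
(active in a random one- or two-condition subset); the static share
defaults to 0.27, matching the roughly one-quarter constitutive fraction
seen in condition-resolved eQTL panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, ExpressionSet, GeneAnnotation, VariantTable

CONDITIONS = ("WW", "WS1", "WS2")

_TF_FAMILIES = ("bZIP", "NAC", "MYB", "WRKY", "AP2-EREBP", "HB", "C2H2", "TCP")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; ``seed`` is mandatory.

    ``effect_r2_range`` is the variance fraction a causal effect explains
    of its gene's expression (relative to the non-genetic remainder);
    ``ld_decay_bp`` is the distance at which pairwise r^2 falls below
    0.2, matching the ~1.6 kb decay of a diverse inbred association
    panel.
    """

    seed: int
    n_samples: int = 200
    n_snps: int = 12000
    n_genes: int = 200
    n_subpops: int = 3
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_bp: float = 1600.0
    snp_spacing_bp: float = 100.0
    gene_length_bp: int = 2000
    conditions: tuple[str, ...] = CONDITIONS
    n_local_eqtl: int = 40
    n_distant_eqtl: int = 8
    min_trans_distance_bp: int = 100000
    frac_static: float = 0.27
    effect_r2_range: tuple[float, float] = (0.05, 0.4)
    # distant effects travel SNP -> TF expression -> target, so the SNP-level
    # signal at the target is the product of two variance fractions; hotspot
    # regulators are modeled strong enough for the chain to stay visible
    distant_effect_r2_range: tuple[float, float] = (0.25, 0.45)
    n_hidden_factors: int = 14
    factor_loading_sd: float = 0.5
    factor_sparsity: float = 0.8
    n_phenotype_genes: int = 5
    phenotype_effects: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    phenotype_noise_sd: float = 0.25
    missing_rate: float = 0.02
    het_rate: float = 0.01
    chrom_name: str = "1"
    local_window_bp: int = 20000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_samples", "n_snps", "n_genes", "n_subpops"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0,1)")
        lo, hi = self.effect_r2_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("effect_r2_range must sit inside (0,1)")


@dataclass
class TruthLedger:
    """Exhaustive record of every planted effect.

    ``local``:  gene, snp, condition, beta, r2
    ``distant``: tf_gene, target_gene, tf_snp, condition, gamma, r2
    ``phenotype``: gene, effect (on the released [0,1] phenotype scale)
    """

    local: pd.DataFrame = field(default_factory=pd.DataFrame)
    distant: pd.DataFrame = field(default_factory=pd.DataFrame)
    phenotype: pd.DataFrame = field(default_factory=pd.DataFrame)

    def conditions_of_local(self, gene: str) -> set[str]:
        if self.local.empty:
            return set()
        return set(self.local.loc[self.local["gene"] == gene, "condition"])


def _condition_subset(rng: np.random.Generator, conditions, frac_static: float):
    """Static -> all conditions; dynamic -> a random 1-2 condition subset."""
    if rng.uniform() < frac_static:
        return tuple(conditions)
    k = int(rng.integers(1, 3))
    idx = rng.choice(len(conditions), size=k, replace=False)
    return tuple(conditions[i] for i in sorted(idx))


def simulate_genotypes(config: SimulationConfig) -> tuple[VariantTable, GeneAnnotation]:
    """Simulate the inbred genotype panel and the gene annotation.

    Subpopulation allele frequencies follow the Balding-Nichols model:
    an ancestral frequency p ~ Uniform(maf_range) and per-subpopulation
    frequencies Beta(p(1-F)/F, (1-p)(1-F)/F).  Within a chromosome, LD
    comes from an allele-copying process along each haploid genome: at
    SNP j the haplotype keeps its previous allele with probability
    exp(-d_j * ln(5) / (2 * ld_decay_bp)) and otherwise draws a fresh
    allele at its subpopulation's frequency.  The allele-scale
    correlation between SNPs d apart is then ~exp(-d ln5 / (2 L)), so
    r^2 = exp(-d ln5 / L) crosses 0.2 at exactly d = L = ld_decay_bp --
    the field's "r^2 < 0.2 decay distance" convention.  Lines are
    inbred: the base calls are homozygous (0/2), with a small
    heterozygote rate and uniform missingness layered on top.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.n_snps, config.n_samples

    # SNP coordinates: exponential spacings, 1-based
    gaps = rng.exponential(config.snp_spacing_bp, size=m)
    pos = 1 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
    span = int(pos[-1])

    # Balding-Nichols subpopulation frequencies
    p_anc = rng.uniform(*config.maf_range, size=m)
    f = config.fst
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))
    p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)

    # subpopulation memberships, roughly balanced
    membership = rng.integers(0, config.n_subpops, size=n)

    # allele-copying haplotype process; scale set so r^2 hits 0.2 at ld_decay_bp
    copy_prob = np.exp(-np.diff(pos) * (np.log(5.0) / 2.0) / config.ld_decay_bp)
    p_ind = p_sub[membership, :]  # (n, m) per-individual frequencies
    fresh = rng.uniform(size=(n, m)) < p_ind
    keep = rng.uniform(size=(n, m - 1)) < copy_prob[None, :]
    alt = np.empty((n, m), dtype=bool)
    alt[:, 0] = fresh[:, 0]
    for j in range(1, m):
        k = keep[:, j - 1]
        alt[:, j] = np.where(k, alt[:, j - 1], fresh[:, j])
    calls = (2 * alt).astype(np.int8)

    if config.het_rate > 0:
        het = rng.uniform(size=calls.shape) < config.het_rate
        calls[het] = 1
    if config.missing_rate > 0:
        miss = rng.uniform(size=calls.shape) < config.missing_rate
        calls[miss] = MISSING

    table = VariantTable(
        snp_id=np.array([f"snp{j + 1}" for j in range(m)], dtype=object),
        chrom=np.array([config.chrom_name] * m, dtype=object),
        pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        calls=calls,
        sample_ids=[f"acc{i + 1:03d}" for i in range(n)],
    )
    # exposed for structure-aware diagnostics (e.g. checking the Fst limit
    # or that genotype PCs separate the planted subpopulations)
    table.subpop_membership = membership

    # genes tiled along the chromosome
    n_g = config.n_genes
    starts = np.linspace(1, max(span - config.gene_length_bp, 1), n_g).astype(np.int64)
    n_tf = min(config.n_distant_eqtl + 2, n_g)
    tf_idx = np.sort(rng.choice(n_g, size=n_tf, replace=False))
    is_tf = np.zeros(n_g, dtype=bool)
    is_tf[tf_idx] = True
    fams = [
        _TF_FAMILIES[k % len(_TF_FAMILIES)] if is_tf[g] else None
        for k, g in zip(np.cumsum(is_tf) - 1, range(n_g))
    ]
    ann = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "start": starts,
            "end": starts + config.gene_length_bp - 1,
            "strand": np.where(rng.uniform(size=n_g) < 0.5, "+", "-"),
            "is_tf": is_tf,
            "tf_family": fams,
        },
        index=pd.Index([f"gene{g + 1:03d}" for g in range(n_g)], name="gene_id"),
    )
    return table, GeneAnnotation(ann)


def _pick_snp_near(
    rng: np.random.Generator,
    table: VariantTable,
    gene: pd.Series,
    window_bp: int,
    maf_min: float = 0.1,
) -> int | None:
    """Index of a common SNP within the gene's local window (body preferred)."""
    maf = np.nan_to_num(table.maf(), nan=0.0)
    in_body = (
        (table.chrom == gene["chrom"])
        & (table.pos >= gene["start"])
        & (table.pos <= gene["end"])
        & (maf >= maf_min)
    )
    in_window = (
        (table.chrom == gene["chrom"])
        & (table.pos >= gene["start"] - window_bp)
        & (table.pos <= gene["end"] + window_bp)
        & (maf >= maf_min)
    )
    for mask in (in_body, in_window):
        idx = np.where(mask)[0]
        if len(idx):
            return int(rng.choice(idx))
    return None


def simulate_expression(
    table: VariantTable,
    annotation: GeneAnnotation,
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionSet], TruthLedger]:
    """Simulate per-condition expression with planted regulatory effects.

    For gene g under condition c the log-abundance is

        baseline_g + beta * dosage(causal SNP)          (local, if active)
                   + gamma * standardized TF log-x      (distant, if active)
                   + loadings_g . factors_c + noise,

    and abundance = exp(log-abundance).  Effect sizes are calibrated per
    gene so the causal term explains the drawn ``effect_r2`` fraction of
    sample variance relative to the non-genetic remainder.  Distant
    effects are mediated through the regulator TF's own (genetically
    driven) log-expression, so the causal chain SNP -> TF -> target is
    recoverable by the scan and the network stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = table.n_samples
    genes = annotation.gene_ids
    n_g = len(genes)
    conds = list(config.conditions)

    dos = table.dosage(impute=True)  # effects act on observed dosages

    tf_genes = [g for g in genes if annotation.loc(g)["is_tf"]]
    if config.n_distant_eqtl > len(tf_genes):
        raise ValueError("not enough TF genes for requested distant eQTLs")

    # --- plant local eQTLs (TF regulators first so their chain is strong)
    local_rows = []
    local_snp: dict[str, int] = {}
    distant_tfs = tf_genes[: config.n_distant_eqtl]
    non_tf = [g for g in genes if g not in tf_genes]
    want_local = list(distant_tfs)
    pool = [g for g in non_tf if g not in want_local]
    rng.shuffle(pool)
    want_local += pool[: max(0, config.n_local_eqtl - len(want_local))]
    if len(want_local) < config.n_local_eqtl:
        raise ValueError("n_genes too small for requested local eQTLs")
    for g in want_local:
        snp = None
        for _ in range(100):
            snp = _pick_snp_near(rng, table, annotation.loc(g), config.local_window_bp)
            if snp is not None:
                break
        if snp is None:
            raise ValueError(f"no SNP within {config.local_window_bp} bp of {g}")
        local_snp[g] = snp

    # --- distant links TF -> target: acyclic, and genuinely trans
    # (targets far from the TF so the lead SNP cannot look local)
    distant_rows = []
    targets_pool = [g for g in genes if g not in distant_tfs]
    rng.shuffle(targets_pool)
    starts = annotation.table["start"]
    span = int(starts.max() - starts.min())
    min_trans = min(config.min_trans_distance_bp, max(span // 4, 1))
    links = []
    for tf in distant_tfs:
        tf_start = int(annotation.loc(tf)["start"])
        for tg in targets_pool:
            if abs(int(annotation.loc(tg)["start"]) - tf_start) >= min_trans:
                links.append((tf, tg))
                targets_pool.remove(tg)
                break
        else:
            raise ValueError(f"no distant-enough target available for TF {tf}")

    # --- per-effect condition activity
    local_active = {g: _condition_subset(rng, conds, config.frac_static) for g in want_local}
    distant_active = {
        (tf, tg): _condition_subset(rng, conds, config.frac_static) for tf, tg in links
    }
    local_r2 = {g: rng.uniform(*config.effect_r2_range) for g in want_local}
    # regulator TFs get strong local effects so the mediated chain is visible
    for tf in distant_tfs:
        local_r2[tf] = config.effect_r2_range[1]
        local_active[tf] = tuple(conds)
    distant_r2 = {lk: rng.uniform(*config.distant_effect_r2_range) for lk in links}

    baseline = pd.Series(rng.normal(1.5, 0.5, size=n_g), index=genes)

    # hidden factors: scores per condition, sparse loadings shared
    loadings = rng.normal(0.0, config.factor_loading_sd, size=(n_g, config.n_hidden_factors))
    loadings[rng.uniform(size=loadings.shape) < config.factor_sparsity] = 0.0
    loadings = pd.DataFrame(loadings, index=genes)

    sets: dict[str, ExpressionSet] = {}
    # topological order: regulator TFs before everything else
    order = distant_tfs + [g for g in genes if g not in distant_tfs]
    incoming = {tg: (tf, lk) for lk in links for tf, tg in [lk]}

    for c in conds:
        factors = rng.standard_normal((n, config.n_hidden_factors))
        logx = pd.DataFrame(0.0, index=genes, columns=table.sample_ids)
        nongen = (
            loadings.to_numpy() @ factors.T
            + config.noise_sd * rng.standard_normal((n_g, n))
        )
        nongen = pd.DataFrame(nongen, index=genes, columns=table.sample_ids)
        for g in order:
            ngv = nongen.loc[g].to_numpy().copy()
            if g in local_snp and c in local_active[g]:
                z = dos[:, local_snp[g]]
                var_z = float(np.var(z))
                if var_z > 0:
                    # orthogonalize the non-genetic part against the causal
                    # dosage so the configured r2 holds exactly in-sample
                    zc = z - z.mean()
                    ngv = ngv - (ngv @ zc) / (zc @ zc) * zc
            total = baseline[g] + ngv
            var_ng = float(np.var(ngv))
            if g in local_snp and c in local_active[g]:
                z = dos[:, local_snp[g]]
                var_z = float(np.var(z))
                if var_z > 0:
                    r2 = local_r2[g]
                    beta = np.sqrt(r2 / (1 - r2) * var_ng / var_z)
                    total = total + beta * z
                    local_rows.append(
                        {
                            "gene": g,
                            "snp": table.snp_id[local_snp[g]],
                            "condition": c,
                            "beta": beta,
                            "r2": r2,
                        }
                    )
            if g in incoming:
                tf, lk = incoming[g]
                if c in distant_active[lk]:
                    x_tf = logx.loc[tf].to_numpy()
                    sd = x_tf.std()
                    if sd > 0:
                        x_std = (x_tf - x_tf.mean()) / sd
                        r2 = distant_r2[lk]
                        gamma = np.sqrt(r2 / (1 - r2) * var_ng)
                        total = total + gamma * x_std
                        distant_rows.append(
                            {
                                "tf_gene": tf,
                                "target_gene": g,
                                "tf_snp": table.snp_id[local_snp[tf]],
                                "condition": c,
                                "gamma": gamma,
                                "r2": r2,
                            }
                        )
            logx.loc[g] = total
        sets[c] = ExpressionSet(condition=c, values=np.exp(logx))

    ledger = TruthLedger(
        local=pd.DataFrame(local_rows),
        distant=pd.DataFrame(distant_rows),
    )
    return sets, ledger


def simulate_phenotype(
    sets: dict[str, ExpressionSet],
    config: SimulationConfig,
    ledger: TruthLedger | None = None,
    condition: str = "WS2",
) -> pd.Series:
    """Simulate the drought-survival phenotype from severe-stress expression.

    y = sum_g c_g * x_g(transformed) + noise, affinely mapped into
    [0, 1].  Causal genes are drawn among genes whose planted local
    eQTL is active under the phenotype condition (so the MR stage has
    valid instruments: survival under severe stress is mediated by
    severe-stress expression); the effects recorded in the ledger are
    on the released [0, 1] scale.
    """
    from .expression_processing import inverse_normal_transform, quantile_normalize

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    expr = sets[condition]
    expr_t = inverse_normal_transform(quantile_normalize(expr))
    x = expr_t.transformed

    if ledger is not None and not ledger.local.empty:
        loc = ledger.local
        candidates = sorted(set(loc.loc[loc["condition"] == condition, "gene"]))
    else:
        candidates = list(x.index)
    if config.n_phenotype_genes > len(candidates):
        raise ValueError("not enough candidate genes for the phenotype")
    idx = rng.choice(len(candidates), size=config.n_phenotype_genes, replace=False)
    causal = [candidates[i] for i in sorted(idx)]
    if config.phenotype_effects is not None:
        effects = np.asarray(config.phenotype_effects, dtype=float)
        if len(effects) != len(causal):
            raise ValueError("phenotype_effects length mismatch")
    else:
        effects = rng.uniform(0.3, 0.6, size=len(causal)) * rng.choice(
            [-1.0, 1.0], size=len(causal)
        )
    for g in causal:
        if g not in x.index:
            raise ValueError(f"phenotype gene {g} not in expression set")

    y = x.loc[causal].to_numpy().T @ effects
    y = y + config.phenotype_noise_sd * rng.standard_normal(len(y))
    lo, hi = float(y.min()), float(y.max())
    scale = hi - lo if hi > lo else 1.0
    y01 = (y - lo) / scale

    if ledger is not None:
        ledger.phenotype = pd.DataFrame(
            {"gene": causal, "effect": effects / scale, "raw_effect": effects}
        )
    return pd.Series(y01, index=x.columns, name="phenotype")


def simulate_all(
    config: SimulationConfig,
) -> tuple[VariantTable, GeneAnnotation, dict[str, ExpressionSet], pd.Series, TruthLedger]:
    """Full triple: genotypes, annotation, expression, phenotype, truth."""
    table, ann = simulate_genotypes(config)
    sets, ledger = simulate_expression(table, ann, config)
    pheno = simulate_phenotype(sets, config, ledger)
    return table, ann, sets, pheno, ledger
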
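"""Mixed-model machinery: thinning, kinship, covariates, REML, scan, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlkit.association_scan import (
    bh_threshold,
    decompose_kinship,
    fit_null_p3d,
    genomic_inflation,
    hidden_factors,
    kinship_ibs,
    scan_gene,
    structure_covariates,
    thin_snps_by_window,
)
from eqtlkit.io_formats import MISSING, ExpressionSet
from eqtlkit.synthetic_data import SimulationConfig, simulate_genotypes

from conftest import make_table


# -- window thinning ---------------------------------------------------------

def test_thinning_prefers_lowest_missing_then_position():
    calls = np.zeros((10, 3), dtype=np.int8)
    calls[0, 0] = MISSING            # s0 missing 10%
    calls[:2, 2] = MISSING           # s2 missing 20%
    t = make_table(calls.tolist(), pos=[100, 200, 300])
    assert thin_snps_by_window(t, window_bp=10000) == ["s1"]
    # tie on missing rate -> lowest position wins
    t2 = make_table(np.zeros((4, 2), dtype=np.int8).tolist(), pos=[500, 900])
    assert thin_snps_by_window(t2, window_bp=10000) == ["s0"]


def test_thinning_one_snp_per_window_keeps_all():
    t = make_table(np.zeros((4, 3), dtype=np.int8).tolist(), pos=[100, 15000, 29000])
    assert thin_snps_by_window(t, window_bp=10000) == ["s0", "s1", "s2"]


def test_thinning_matches_brute_force_scan():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 100000), size=60, replace=False))
    calls = rng.choice([0, 2, MISSING], size=(15, 60), p=[0.45, 0.45, 0.1])
    t = make_table(calls.tolist(), pos=pos.tolist())
    got = thin_snps_by_window(t, window_bp=10000)
    expected = {}
    miss = (calls == MISSING).mean(axis=0)
    for j in range(60):
        w = (pos[j] - 1) // 10000
        cur = expected.get(w)
        if cur is None or miss[j] < miss[cur] or (miss[j] == miss[cur] and pos[j] < pos[cur]):
            expected[w] = j
    assert got == [f"s{j}" for j in sorted(expected.values())]


# -- kinship -----------------------------------------------------------------

def test_kinship_identical_and_opposite_samples():
    t = make_table([[0, 2, 0], [0, 2, 0], [2, 0, 2]])
    K = kinship_ibs(t)
    assert K[0, 1] == pytest.approx(1.0)
    assert K[0, 2] == pytest.approx(0.0)
    assert np.allclose(K, K.T)


def test_kinship_matches_hand_enumeration():
    rng = np.random.default_rng(1)
    calls = rng.choice([0, 1, 2, MISSING], size=(5, 8))
    t = make_table(calls.tolist())
    K = kinship_ibs(t)
    for i in range(5):
        for j in range(5):
            vals = []
            for s in range(8):
                if calls[i, s] != MISSING and calls[j, s] != MISSING:
                    vals.append(1 - abs(calls[i, s] - calls[j, s]) / 2)
            assert K[i, j] == pytest.approx(np.mean(vals))


def test_kinship_no_shared_snps_errors():
    t = make_table([[0, MISSING], [MISSING, 2]])
    with pytest.raises(ValueError, match="share no called"):
        kinship_ibs(t)


# -- structure covariates ----------------------------------------------------

def test_structure_pcs_separate_planted_subpopulations():
    # two groups with independently drawn, well-separated allele frequencies
    rng = np.random.default_rng(10)
    n_per, m = 40, 400
    p1 = rng.uniform(0.1, 0.9, size=m)
    shift = np.where(p1 < 0.5, 0.3, -0.3)
    p2 = p1 + shift
    g1 = 2 * (rng.uniform(size=(n_per, m)) < p1)
    g2 = 2 * (rng.uniform(size=(n_per, m)) < p2)
    t = make_table(np.vstack([g1, g2]).astype(np.int8).tolist())
    pcs = structure_covariates(t, n_pc=2)
    ind = np.r_[np.zeros(n_per), np.ones(n_per)]
    assert abs(np.corrcoef(ind, pcs[:, 0])[0, 1]) > 0.9


def test_structure_pcs_permute_with_samples(small_panel):
    _, table, _ = small_panel
    pcs = structure_covariates(table, n_pc=2)
    order = list(reversed(table.sample_ids))
    pcs_perm = structure_covariates(table.take_samples(order), n_pc=2)
    np.testing.assert_allclose(pcs_perm, pcs[::-1], atol=1e-8)


def test_structure_pcs_zero_and_too_many():
    t = make_table(np.zeros((5, 4), dtype=np.int8).tolist())
    assert structure_covariates(t, n_pc=0).shape == (5, 0)
    with pytest.raises(ValueError):
        structure_covariates(t, n_pc=5)


# -- hidden factors ----------------------------------------------------------

def _exprset_from_matrix(mat):
    df = pd.DataFrame(
        mat, index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )
    return ExpressionSet("WW", df - df.min().min(), transformed=df)


def test_hidden_factors_recover_planted_dense_factor():
    rng = np.random.default_rng(2)
    n, g = 80, 300
    f = rng.standard_normal(n)
    loadings = rng.normal(0, 1.0, size=g)
    mat = np.outer(loadings, f) + rng.normal(0, 0.3, size=(g, n))
    es = _exprset_from_matrix(mat)
    fac = hidden_factors(es, covariates=None, k=3)
    assert abs(np.corrcoef(fac[:, 0], f)[0, 1]) > 0.95
    # zero-mean columns (orthogonal to an intercept)
    np.testing.assert_allclose(fac.mean(axis=0), 0.0, atol=1e-8)


def test_hidden_factors_k0_and_k_too_large():
    es = _exprset_from_matrix(np.random.default_rng(0).standard_normal((10, 6)))
    assert hidden_factors(es, k=0).shape == (6, 0)
    with pytest.raises(ValueError):
        hidden_factors(es, k=6)


# -- REML / P3D --------------------------------------------------------------

def test_identity_kinship_reduces_to_ols():
    rng = np.random.default_rng(3)
    n = 120
    x = rng.choice([0.0, 2.0], size=n)
    y = 0.4 * x + rng.standard_normal(n)
    kd = decompose_kinship(np.eye(n))
    fit = fit_null_p3d(y, None, None, kd)
    res = scan_gene(fit, x[:, None], kd)
    slope, intercept, r, p_ols, se = stats.linregress(x, y)
    assert abs(res.loc[0, "beta"] - slope) < 1e-8
    assert abs(res.loc[0, "p"] - p_ols) < 1e-8


def test_reml_recovers_variance_ratio():
    rng = np.random.default_rng(4)
    n = 300
    # block kinship: 30 clusters of 10 with shared random effects
    groups = np.repeat(np.arange(30), 10)
    K = (groups[:, None] == groups[None, :]).astype(float)
    u = np.sqrt(2.0) * rng.standard_normal(30)[groups]
    y = u + 1.0 * rng.standard_normal(n)
    kd = decompose_kinship(K)
    fit = fit_null_p3d(y, None, None, kd)
    # delta = sigma_e^2 / sigma_g^2, true 0.5
    assert 0.3 <= fit["delta"] <= 0.9
    # REML at the optimum is at least as good as every grid point
    assert fit["neg_ll"] <= fit["grid_neg_ll"].min() + 1e-9


def test_scan_null_p_values_uniform():
    rng = np.random.default_rng(5)
    n, m = 200, 2000
    X = rng.choice([0.0, 2.0], size=(n, m))
    y = rng.standard_normal(n)
    kd = decompose_kinship(np.eye(n))
    fit = fit_null_p3d(y, None, None, kd)
    res = scan_gene(fit, X, kd)
    ks = stats.kstest(res["p"].dropna(), "uniform")
    assert ks.pvalue > 0.01


def test_scan_power_and_partial_r2_recovery():
    rng = np.random.default_rng(6)
    n = 300
    x = rng.choice([0.0, 2.0], size=n)
    noise = rng.standard_normal(n)
    noise -= (noise @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
    beta = np.sqrt(0.3 / 0.7 * noise.var() / x.var())
    y = beta * x + noise
    kd = decompose_kinship(np.eye(n))
    fit = fit_null_p3d(y, None, None, kd)
    res = scan_gene(fit, x[:, None], kd)
    assert res.loc[0, "p"] < 1e-15
    assert res.loc[0, "partial_r2"] == pytest.approx(0.30, abs=0.07)


def test_monomorphic_snp_skipped_and_collinear_covariate_dropped():
    rng = np.random.default_rng(7)
    n = 50
    y = rng.standard_normal(n)
    kd = decompose_kinship(np.eye(n))
    cov = np.column_stack([np.ones(n), np.ones(n)])  # collinear with intercept
    with pytest.warns(UserWarning, match="collinear"):
        fit = fit_null_p3d(y, cov, None, kd)
    res = scan_gene(fit, np.zeros((n, 1)), kd)
    assert np.isnan(res.loc[0, "p"])


# -- BH threshold ------------------------------------------------------------

def test_bh_step_up_hand_example():
    p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.071, 0.09, 0.1, 0.5]
    thr = bh_threshold(np.array(p), fdr=0.05)
    assert thr.bh_p_cutoff == pytest.approx(0.008)
    assert sum(x <= thr.bh_p_cutoff for x in p) == 2


def test_bh_degenerate_cases():
    assert bh_threshold(np.ones(10)).bh_p_cutoff == 0.0
    thr = bh_threshold(np.full(100, 1e-9))
    assert thr.bh_p_cutoff == pytest.approx(1e-9)
    with pytest.raises(ValueError):
        bh_threshold(np.array([]))


def test_bh_matches_enumeration_oracle_on_random_vectors():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        thr = bh_threshold(p, fdr=0.05)
        ps = np.sort(p)
        cut = 0.0
        for k in range(m, 0, -1):
            if ps[k - 1] <= 0.05 * k / m:
                cut = ps[k - 1]
                break
        assert thr.bh_p_cutoff == pytest.approx(cut)


def test_genomic_inflation_on_uniform_p():
    rng = np.random.default_rng(9)
    lam = genomic_inflation(rng.uniform(size=200000))
    assert lam == pytest.approx(1.0, abs=0.02)
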
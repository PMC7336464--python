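"""Normalization, filtering, DEG calling, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from eqtlkit.expression_processing import (
    call_degs,
    expression_filter,
    inverse_normal_transform,
    kmeans_profiles,
    pca_transcriptomes,
    quantile_normalize,
)
from eqtlkit.io_formats import ExpressionSet


def make_set(matrix, condition="WW", genes=None, samples=None):
    m = np.asarray(matrix, float)
    return ExpressionSet(
        condition,
        pd.DataFrame(
            m,
            index=genes or [f"g{i}" for i in range(m.shape[0])],
            columns=samples or [f"s{j}" for j in range(m.shape[1])],
        ),
    )


# -- quantile normalization --------------------------------------------------

def test_quantile_normalize_hand_example():
    es = make_set(np.array([[1, 4], [2, 5], [3, 6]]))
    out = quantile_normalize(es)
    np.testing.assert_allclose(out.values.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])


def test_quantile_normalize_identical_samples_unchanged():
    es = make_set(np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]]))
    out = quantile_normalize(es)
    np.testing.assert_allclose(out.values.to_numpy(), es.values.to_numpy())


def test_quantile_normalize_equalizes_column_means():
    rng = np.random.default_rng(0)
    es = make_set(rng.gamma(2, 2, size=(100, 6)))
    out = quantile_normalize(es)
    means = out.values.mean(axis=0).to_numpy()
    assert np.ptp(means) < 1e-10


def test_quantile_normalize_ties_get_mean_of_spanned_reference():
    # sample 0 has a two-way tie spanning reference ranks 1 and 2
    es = make_set(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
    out = quantile_normalize(es)
    ref = np.sort(es.values.to_numpy(), axis=0).mean(axis=1)
    tied = out.values.iloc[:2, 0].to_numpy()
    np.testing.assert_allclose(tied, [(ref[0] + ref[1]) / 2] * 2)


# -- inverse normal transform ------------------------------------------------

def test_inverse_normal_plug_in_oracle_n3():
    es = make_set(np.array([[0.3, 7.0, 1.1]]))
    out = inverse_normal_transform(es).transformed.to_numpy()[0]
    a = 3.0 / 8.0
    expected = norm.ppf((np.array([1, 3, 2]) - a) / (3 + 1 - 2 * a))
    np.testing.assert_allclose(out, expected)
    # rank 1 maps to Phi^-1((1-3/8)/3.25) = Phi^-1(0.19231), rank 2 to 0
    np.testing.assert_allclose(
        sorted(out), [norm.ppf(0.625 / 3.25), 0.0, norm.ppf(2.625 / 3.25)]
    )


def test_inverse_normal_preserves_order_and_centers_median():
    rng = np.random.default_rng(1)
    vals = rng.gamma(3, 1, size=(1, 21))
    out = inverse_normal_transform(make_set(vals)).transformed.to_numpy()[0]
    assert (np.argsort(out) == np.argsort(vals[0])).all()
    assert np.median(out) == pytest.approx(0.0, abs=1e-12)


def test_inverse_normal_constant_gene_and_missing():
    vals = np.array([[2.0, 2.0, 2.0, 2.0], [1.0, np.nan, 3.0, 2.0]])
    with pytest.warns(UserWarning, match="constant"):
        out = inverse_normal_transform(make_set(vals)).transformed.to_numpy()
    assert (out[0] == 0).all()
    assert np.isnan(out[1, 1])
    # n excludes the missing value -> n=3 convention (a=3/8)
    assert out[1, 3] == pytest.approx(0.0, abs=1e-12)


def test_transform_is_idempotent_on_ranks():
    rng = np.random.default_rng(2)
    es = make_set(rng.gamma(2, 2, size=(30, 12)))
    once = inverse_normal_transform(quantile_normalize(es))
    again = inverse_normal_transform(
        quantile_normalize(ExpressionSet("WW", once.transformed - once.transformed.min().min()))
    )
    # each half is exactly idempotent on its own axis ...
    qn = quantile_normalize(es)
    qn2 = quantile_normalize(qn)
    np.testing.assert_allclose(qn2.values.to_numpy(), qn.values.to_numpy(), atol=1e-12)
    int1 = inverse_normal_transform(qn)
    int2 = inverse_normal_transform(
        ExpressionSet("WW", int1.transformed - int1.transformed.min().min())
    )
    np.testing.assert_allclose(
        int2.transformed.to_numpy(), int1.transformed.to_numpy(), atol=1e-12
    )
    # ... and the composition keeps per-gene ranks up to the tie-averaging
    # collisions the shared post-transform value grid induces
    from scipy.stats import spearmanr

    a = once.transformed.to_numpy()
    b = again.transformed.to_numpy()
    for i in range(a.shape[0]):
        assert spearmanr(a[i], b[i]).statistic >= 0.98


# -- expression filter -------------------------------------------------------

def test_expression_filter_20_percent_boundary():
    n = 200
    hi = np.zeros((2, n))
    hi[0, :40] = 1.0   # exactly 20% above threshold -> kept
    hi[1, :38] = 1.0   # 19% -> dropped
    kept = expression_filter(make_set(hi), min_value=0.05, min_fraction=0.2)
    assert kept == ["g0"]


def test_expression_filter_matches_brute_force_and_is_monotone():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 0.2, size=(30, 25))
    es = make_set(vals)
    kept = set(expression_filter(es))
    expected = {
        f"g{i}"
        for i in range(30)
        if (vals[i] > 0.05).sum() >= int(np.ceil(0.2 * 25))
    }
    assert kept == expected
    stricter = set(expression_filter(es, min_fraction=0.5))
    assert stricter <= kept


# -- DEG calling -------------------------------------------------------------

def test_identical_conditions_yield_no_degs():
    rng = np.random.default_rng(4)
    vals = rng.gamma(2, 2, size=(20, 30))
    sets = {"WW": make_set(vals, "WW"), "WS1": make_set(vals, "WS1")}
    out = call_degs(sets)
    assert not out["is_deg"].any()


def test_uniform_doubling_is_deg():
    rng = np.random.default_rng(5)
    vals = rng.gamma(2, 2, size=(10, 50)) + 1.0
    sets = {"WW": make_set(vals, "WW"), "WS1": make_set(vals * 2.5, "WS1")}
    out = call_degs(sets)
    assert out["is_deg"].all()


def test_deg_recall_and_fdr_on_planted_shifts():
    rng = np.random.default_rng(6)
    n_genes, n_acc = 1000, 60
    base = rng.gamma(2, 2, size=(n_genes, n_acc)) + 0.5
    shifted = base.copy()
    noise = rng.lognormal(0.0, 0.15, size=(n_genes, n_acc))
    shifted = shifted * noise
    shifted[:100] *= 4.0  # planted true shifts
    sets = {"WW": make_set(base, "WW"), "WS1": make_set(shifted, "WS1")}
    out = call_degs(sets)
    called = set(out.loc[out["is_deg"], "gene_id"])
    truth = {f"g{i}" for i in range(100)}
    recall = len(called & truth) / len(truth)
    fdr = len(called - truth) / max(len(called), 1)
    assert recall >= 0.9
    assert fdr <= 0.1


def test_deg_needs_six_paired_accessions():
    vals = np.ones((5, 4))
    sets = {"WW": make_set(vals, "WW"), "WS1": make_set(vals, "WS1")}
    with pytest.raises(ValueError, match="6"):
        call_degs(sets)


# -- k-means -----------------------------------------------------------------

def test_kmeans_recovers_planted_archetypes():
    rng = np.random.default_rng(7)
    up = np.array([-1.0, 0.0, 1.0])
    down = -up
    flat = np.array([1.0, -2.0, 1.0])
    profiles, truth = [], []
    for arch, label in ((up, 1), (down, 3), (flat, 2)):
        for _ in range(20):
            profiles.append(arch + rng.normal(0, 0.05, 3))
            truth.append(label)
    df = pd.DataFrame(profiles, columns=["WW", "WS1", "WS2"],
                      index=[f"g{i}" for i in range(60)])
    out = kmeans_profiles(df, k=3, seed=0)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0
    # canonical order: cluster 1 has the steepest upward centroid slope
    slopes = out.centroids["WS2"] - out.centroids["WW"]
    assert slopes.loc[1] > slopes.loc[2] > slopes.loc[3]
    again = kmeans_profiles(df, k=3, seed=0)
    pd.testing.assert_series_equal(out.labels, again.labels)


def test_kmeans_k1_and_k_too_large():
    df = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["c1", "c2"])
    out = kmeans_profiles(df, k=1, seed=0)
    np.testing.assert_allclose(out.centroids.iloc[0], df.mean(axis=0))
    with pytest.raises(ValueError):
        kmeans_profiles(df, k=5, seed=0)


# -- PCA ---------------------------------------------------------------------

def test_pca_variance_fraction_matches_closed_form():
    rng = np.random.default_rng(8)
    rho = 0.6
    cov = np.array([[1.0, rho], [rho, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=4000)
    X = X - X.min()  # abundance-scale shift; correlations unchanged
    sets = {"WW": make_set(X.T, "WW", genes=["g1", "g2"],
                           samples=[f"s{j}" for j in range(4000)])}
    scores, explained, loadings = pca_transcriptomes(sets)
    rho_hat = np.corrcoef(X.T)[0, 1]
    assert explained[0] == pytest.approx((1 + rho_hat) / 2, abs=1e-9)
    # score columns orthogonal
    assert abs(np.corrcoef(scores.iloc[:, 0], scores.iloc[:, 1])[0, 1]) < 1e-10


def test_pca_separates_shifted_conditions():
    rng = np.random.default_rng(9)
    base = rng.gamma(2, 2, size=(50, 30))
    sets = {
        "WW": make_set(base, "WW"),
        "WS1": make_set(base * np.exp(rng.normal(0.4, 0.05, size=(50, 1))), "WS1"),
        "WS2": make_set(base * np.exp(rng.normal(1.2, 0.05, size=(50, 1))), "WS2"),
    }
    scores, _, _ = pca_transcriptomes(sets)
    cent = scores.groupby(level="condition").mean()
    d_ww_ws1 = np.linalg.norm(cent.loc["WW"] - cent.loc["WS1"])
    d_ww_ws2 = np.linalg.norm(cent.loc["WW"] - cent.loc["WS2"])
    assert d_ww_ws2 > d_ww_ws1
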
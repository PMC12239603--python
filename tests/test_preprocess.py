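"""Filtering, normalisation, rank transform, identity checks, DE and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mosaicqtl as mq


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


# --- filtering --------------------------------------------------------------


def test_filter_genes_rules():
    n = 10
    rows = {
        "mostly_zero": [0] * 6 + [5, 5, 5, 5],  # zero in 60% -> dropped
        "constant": [10] * n,  # kept
        "low_median": [0.4] * n,  # median 0.4, no zeros -> dropped
        "ok": [2] * n,
    }
    expr = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    kept = mq.filter_genes(expr)
    assert kept == ["constant", "ok"]


def test_filter_empty_errors():
    with pytest.raises(ValueError):
        mq.filter_genes(pd.DataFrame())


# --- upper-quartile ---------------------------------------------------------


def test_uq_scale_invariance_and_identity(rng):
    base = rng.poisson(50, size=(100, 1)).astype(float)
    expr = _frame(np.hstack([base, base, 2 * base]))
    out = mq.upper_quartile_normalize(expr)
    assert np.allclose(out["s0"], out["s1"])
    assert np.allclose(out["s0"], out["s2"])  # doubling a sample is absorbed

    single = _frame(base)
    out1 = mq.upper_quartile_normalize(single)
    ratio = out1["s0"] / single["s0"]
    assert np.allclose(ratio, ratio.iloc[0])  # single sample: global rescale only


def test_uq_all_zero_sample_errors():
    expr = _frame([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="s1"):
        mq.upper_quartile_normalize(expr)


# --- batch correction -------------------------------------------------------


def test_batch_shift_removed(rng):
    X = rng.normal(size=(50, 40))
    batch = pd.Series([0] * 20 + [1] * 20, index=[f"s{j}" for j in range(40)], name="batch")
    X[:, 20:] += 2.0  # planted shift on level 1
    expr = _frame(X)
    out = mq.remove_covariate_effects(expr, batch)
    m0 = out.iloc[:, :20].mean(axis=1)
    m1 = out.iloc[:, 20:].mean(axis=1)
    assert np.allclose(m0, m1, atol=1e-10)
    # grand mean preserved
    assert np.allclose(out.mean(axis=1), expr.mean(axis=1), atol=1e-10)


def test_null_batch_correction_is_gentle(rng):
    X = rng.normal(size=(100, 60))
    expr = _frame(X)
    batch = pd.Series(
        rng.permutation([0, 1, 2] * 20), index=expr.columns, name="batch"
    )
    out = mq.remove_covariate_effects(expr, batch)
    assert np.max(np.abs(out.to_numpy() - X)) < 1.5  # small relative to the SD scale
    assert np.median(np.abs(out.to_numpy() - X)) < 0.3


def test_constant_gene_unchanged_and_small_level_errors():
    expr = _frame(np.vstack([np.full(6, 7.0), np.arange(6.0)]))
    batch = pd.Series([0, 0, 0, 1, 1, 1], index=expr.columns, name="batch")
    out = mq.remove_covariate_effects(expr, batch)
    assert np.allclose(out.iloc[0], 7.0)
    bad = pd.Series([0, 0, 0, 0, 0, 1], index=expr.columns, name="batch")
    with pytest.raises(ValueError, match="single sample"):
        mq.remove_covariate_effects(expr, bad)


# --- rankZ ------------------------------------------------------------------


def test_rankz_closed_form_and_ties():
    expr = _frame([[3.0, 1.0, 2.0]])
    out = mq.rankz(expr)
    expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
    assert np.allclose(out.iloc[0].to_numpy(), expected)
    tied = _frame([[4.0, 4.0, 4.0]])
    assert np.allclose(mq.rankz(tied).to_numpy(), 0.0)


def test_rankz_monotone_invariance_and_idempotence(rng):
    x = rng.normal(size=(5, 30))
    a = mq.rankz(_frame(x))
    b = mq.rankz(_frame(np.exp(x)))  # strictly monotone transform
    assert np.allclose(a.to_numpy(), b.to_numpy())
    assert np.allclose(mq.rankz(a).to_numpy(), a.to_numpy(), atol=1e-12)


# --- sample identity --------------------------------------------------------


def _geno_frames(rng, n=20, m=200, error=0.0):
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    names = [f"d{i}" for i in range(n)]
    A = pd.DataFrame(G, index=names, columns=[f"mk{j}" for j in range(m)])
    B = A.copy()
    if error:
        flip = rng.random(size=B.shape) < error
        B = B.mask(flip, rng.integers(0, 3, size=B.shape).astype(float))
    return A, B


def test_match_samples_recovers_permutation_and_flags_swap(rng):
    A, B = _geno_frames(rng, error=0.05)
    perm = rng.permutation(len(A))
    B_perm = B.iloc[perm]
    B_perm.index = B.index  # same labels, shuffled genotypes
    rep = mq.match_samples(A, B_perm)
    expected = {A.index[perm[i]]: A.index[i] for i in range(len(A))}
    assert all(rep.assignment[a] == b for a, b in expected.items())

    # planted swap of two samples
    B2 = B.copy()
    B2.iloc[[0, 1]] = B.iloc[[1, 0]].to_numpy()
    rep2 = mq.match_samples(A, B2)
    assert set(rep2.mixups) == {"d0", "d1"}
    assert np.isclose(mq.match_samples(A, A).correlation.iloc[0, 0], 1.0)


def test_match_samples_needs_shared_markers():
    A = pd.DataFrame(np.ones((3, 5)), columns=list("abcde"))
    B = pd.DataFrame(np.ones((3, 5)), columns=list("fghij"))
    with pytest.raises(ValueError, match="shared markers"):
        mq.match_samples(A, B)


def test_match_samples_tolerates_ten_percent_error(rng):
    """Planted permutation is recovered exactly at 10% call error, 200 markers."""
    A, B = _geno_frames(rng, n=30, m=200, error=0.10)
    perm = rng.permutation(len(A))
    Bp = B.iloc[perm]
    Bp.index = B.index
    rep = mq.match_samples(A, Bp)
    recovered = [rep.assignment[A.index[perm[i]]] == A.index[i] for i in range(len(A))]
    assert all(recovered)


def test_correlate_transcriptomes_matched_vs_mismatched(rng):
    genes = [f"g{i}" for i in range(150)]
    donors = [f"d{j}" for j in range(25)]
    latent = rng.normal(size=(150, 25))
    A = pd.DataFrame(0.85 * latent + rng.normal(scale=0.55, size=latent.shape), index=genes, columns=donors)
    B = pd.DataFrame(0.85 * latent + rng.normal(scale=0.55, size=latent.shape), index=genes, columns=donors)
    res = mq.correlate_transcriptomes(A, B)
    assert res["median_matched"] > res["median_mismatched"] + 0.2

    mono = mq.correlate_transcriptomes(A, np.exp(A / 3))
    assert np.allclose(mono["matched"], 1.0)


# --- differential expression ------------------------------------------------


def test_de_identical_groups_and_fold_change(rng):
    X = np.abs(rng.normal(10, 1, size=(20, 30)))
    expr = _frame(X)
    res = mq.differential_expression(expr, expr)
    assert (res["p"] > 0.99).all()
    assert (res["label"] == "ns").all()

    A = _frame(np.full((3, 10), 2.0))
    B = _frame(np.full((3, 10), 8.0))
    res2 = mq.differential_expression(A, B)
    assert np.allclose(res2["log2fc"], 2.0)


def test_de_recovers_planted_shifts(rng):
    n_null, n_shift, n_samp = 1000, 50, 40
    base = rng.normal(10, 1, size=(n_null + n_shift, n_samp))
    shifted = base.copy()
    shifted[n_null:] += 3.0  # 3 SD shift
    A, B = _frame(base), _frame(shifted)
    res = mq.differential_expression(A, B, lfc_threshold=0.0)
    hits = res["p_adj"] < 0.05
    assert hits.iloc[n_null:].sum() >= 45
    assert hits.iloc[:n_null].sum() <= 5


def test_de_type_i_error_null(rng):
    X = rng.normal(5, 1, size=(2000, 30))
    Y = rng.normal(5, 1, size=(2000, 30))
    res = mq.differential_expression(_frame(X), _frame(Y))
    assert (res["p_adj"] < 0.05).mean() <= 0.05


# --- PCA --------------------------------------------------------------------


def test_pca_rank1_and_cluster_separation(rng):
    u = rng.normal(size=(30, 1))
    v = rng.normal(size=(1, 12))
    expr = _frame(u @ v)
    res = mq.pca_scores(expr, n_components=3)
    assert res["variance_fraction"][0] > 1 - 1e-10

    X = rng.normal(size=(40, 20))
    X[:, 10:] += 6.0  # two clusters offset by a constant vector
    res2 = mq.pca_scores(_frame(X), n_components=2)
    signs = np.sign(res2["scores"]["PC1"].to_numpy())
    assert abs(signs[:10].sum()) == 10 and abs(signs[10:].sum()) == 10
    assert signs[0] != signs[10]


def test_pca_rotation_invariance_and_rank_guard(rng):
    X = rng.normal(size=(25, 15))
    # rotation of sample space that fixes the constant vector, so per-gene
    # centring commutes with it
    ones = np.ones((15, 1)) / np.sqrt(15)
    basis, _ = np.linalg.qr(np.eye(15) - ones @ ones.T)
    basis = basis[:, :14]
    r, _ = np.linalg.qr(rng.normal(size=(14, 14)))
    q = basis @ r @ basis.T + ones @ ones.T
    r1 = mq.pca_scores(_frame(X), n_components=5)["variance_fraction"]
    r2 = mq.pca_scores(_frame(X @ q), n_components=5)["variance_fraction"]
    assert np.allclose(r1, r2, atol=1e-10)
    with pytest.raises(ValueError, match="components"):
        mq.pca_scores(_frame(X), n_components=16)
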
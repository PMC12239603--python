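"""Kinship, heritability, LMM scans, permutations, q-values, peaks, BLUPs."""

import numpy as np
import pandas as pd
import pytest

import mosaicqtl as mq
from mosaicqtl.scan import blup_effects, est_heritability, qvalues


# --- kinship ----------------------------------------------------------------


def test_kinship_identical_samples(small_map):
    arr = np.zeros((4, 8, small_map.n_markers))
    arr[:, 2, :] = 1.0  # everyone homozygous founder 2 everywhere
    probs = mq.GenotypeProbs(arr, [f"s{i}" for i in range(4)], small_map)
    k = mq.calc_kinship(probs, mode="full")
    assert np.allclose(k.full, k.full[0, 0])
    assert np.linalg.matrix_rank(k.full) == 1


def test_loco_excludes_scan_chromosome(small_probs, small_map, rng):
    k1 = mq.calc_kinship(small_probs, mode="loco")
    shuffled = small_probs.probs.copy()
    idx = small_map.chrom_index("2")
    perm = rng.permutation(small_probs.n_samples)
    shuffled[:, :, idx] = shuffled[perm][:, :, idx]
    k2 = mq.calc_kinship(
        mq.GenotypeProbs(shuffled, small_probs.samples, small_map), mode="loco"
    )
    assert np.allclose(k1.loco["2"], k2.loco["2"])  # chromosome 2 left out
    assert not np.allclose(k1.loco["1"], k2.loco["1"])


def test_kinship_symmetric_psd(small_kinship):
    K = small_kinship.full
    assert np.allclose(K, K.T, atol=1e-10)
    assert np.linalg.eigvalsh(K).min() > -1e-10
    assert (np.diag(K) > 0).all()


# --- heritability -----------------------------------------------------------


def test_heritability_null_and_identity_kinship(small_kinship, rng):
    ests = [
        est_heritability(rng.normal(size=80), small_kinship.full).h2 for _ in range(20)
    ]
    assert np.median(ests) <= 0.1

    res = est_heritability(rng.normal(size=40), np.eye(40))
    assert res.flat and res.h2 == 0.0


def test_heritability_recovery_midrange(desk_dataset, rng):
    probs = desk_dataset["probs"]
    K = mq.calc_kinship(probs, mode="full").full
    K = K / K.diagonal().mean()
    d, U = np.linalg.eigh(K)
    L = U * np.sqrt(np.clip(d, 0, None))
    ests = []
    for _ in range(25):
        g = L @ rng.normal(size=probs.n_samples) * np.sqrt(0.5)
        y = g + rng.normal(size=probs.n_samples) * np.sqrt(0.5)
        ests.append(est_heritability(y, K).h2)
    # smoke-level bound at n=186; the tight n=400 recovery check lives in the
    # acceptance suite
    assert abs(np.median(ests) - 0.5) < 0.15


# --- scan -------------------------------------------------------------------


def brute_force_lods(y, probs, covariates=None):
    """Independent per-marker least-squares oracle (no kinship)."""
    n = y.size
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = ((y - X0 @ b0) ** 2).sum()
    lods = np.empty(probs.gmap.n_markers)
    for m in range(probs.gmap.n_markers):
        X = probs.probs[:, :, m]
        if covariates is not None:
            X = np.column_stack([X, covariates])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ b) ** 2).sum()
        lods[m] = (n / 2) * np.log10(rss0 / rss1)
    return lods


def test_scan_matches_least_squares_oracle(small_probs, rng):
    y = rng.normal(size=small_probs.n_samples)
    res = mq.scan1(y, small_probs, kinship=None)
    oracle = brute_force_lods(y, small_probs)
    assert np.max(np.abs(res.lod.to_numpy() - oracle)) < 1e-6


def test_lod_affine_invariance(small_probs, small_kinship, rng):
    y = rng.normal(size=small_probs.n_samples)
    cov = rng.integers(0, 2, size=small_probs.n_samples).astype(float)
    a = mq.scan1(y, small_probs, small_kinship, cov)
    b = mq.scan1(3.7 * y - 2.0, small_probs, small_kinship, cov)
    assert np.max(np.abs(a.lod.to_numpy() - b.lod.to_numpy())) < 1e-8


def test_scan_rejects_rank_deficient_covariates(small_probs, rng):
    y = rng.normal(size=small_probs.n_samples)
    c = rng.normal(size=small_probs.n_samples)
    with pytest.raises(ValueError, match="rank"):
        mq.scan1(y, small_probs, covariates=np.column_stack([c, 2 * c]))


def test_planted_local_eqtl_found(small_probs, small_kinship):
    spec = mq.ArchitectureSpec(
        local_eqtl=[mq.LocalEqtl("g", "c1m30", np.array([1.0, -1, 1, -1, 1, -1, 1, -1]), h2=0.5)],
        n_background_genes=0,
        sex_effect_sd=0.0,
        batch_effect_sd=0.0,
    )
    _, eb, _ = mq.simulate_expression(small_probs, spec, seed=21)
    res = mq.scan1(eb.loc["g"].to_numpy(), small_probs, small_kinship)
    marker, lod = res.peak()
    truth_cm = small_probs.gmap.markers.set_index("marker").loc["c1m30", "cM"]
    peak_cm = small_probs.gmap.markers.set_index("marker").loc[marker, "cM"]
    assert lod > 7.5
    assert abs(peak_cm - truth_cm) <= 5.0


# --- permutations -----------------------------------------------------------


def test_permutation_threshold_quantiles(small_probs, small_kinship, rng):
    phenos = rng.normal(size=(3, small_probs.n_samples))
    th = mq.permutation_threshold(
        phenos, small_probs, small_kinship, n_perm=20, alphas=(1.0, 0.5, 0.05), seed=5
    )
    assert th.threshold(1.0) == th.null_maxima.min()
    assert th.threshold(1.0) <= th.threshold(0.5) <= th.threshold(0.05)
    with pytest.raises(ValueError):
        mq.permutation_threshold(phenos, small_probs, small_kinship, n_perm=5)


# --- q-values ---------------------------------------------------------------


def test_qvalues_uniform_null(rng):
    p = rng.uniform(size=2000)
    q, pi0 = qvalues(p)
    assert pi0 >= 0.9
    assert q.max() <= pi0 + 1e-12


def test_qvalues_mixture_and_single(rng):
    p = np.concatenate([np.full(10, 0.001), rng.uniform(size=990)])
    q, _ = qvalues(p)
    assert q[:10].max() < 0.2 * np.median(q[10:])
    q1, pi0 = qvalues(np.array([0.5]))
    assert np.isclose(q1[0], pi0 * 0.5)


def test_qvalues_monotone_in_p(rng):
    p = rng.uniform(size=500)
    q, _ = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# --- peaks ------------------------------------------------------------------


def _lod_frame(gmap, gene_peaks):
    """gene -> (marker, lod) helper building a genes x markers LOD frame."""
    lods = pd.DataFrame(
        0.0, index=list(gene_peaks), columns=gmap.markers["marker"].to_numpy()
    )
    for g, (marker, lod) in gene_peaks.items():
        lods.loc[g, marker] = lod
    return lods


def test_peak_classification_rules(small_map):
    # marker c2m30 on chrom 2 sits at 30 cM = 60 Mbp
    ann = pd.DataFrame(
        {
            "gene": ["local_g", "boundary_g", "other_chrom_g"],
            "chrom": ["2", "2", "3"],
            "start": [54.0, 69.9, 60.0],
            "end": [56.0, 70.1, 60.2],
        }
    )
    lods = _lod_frame(
        small_map,
        {"local_g": ("c2m30", 9.0), "boundary_g": ("c2m30", 9.0), "other_chrom_g": ("c2m30", 9.0)},
    )
    peaks = mq.find_and_classify_peaks(lods, small_map, ann, threshold=7.5)
    cls = peaks.set_index("gene")["class"]
    assert cls["local_g"] == "local"  # 5 Mbp from midpoint
    assert cls["boundary_g"] == "local"  # exactly 10 Mbp: boundary inclusive
    assert cls["other_chrom_g"] == "distant"


def test_peaks_require_annotation(small_map):
    lods = _lod_frame(small_map, {"mystery": ("c1m10", 9.0)})
    ann = pd.DataFrame({"gene": ["known"], "chrom": ["1"], "start": [1.0], "end": [2.0]})
    with pytest.raises(KeyError, match="mystery"):
        mq.find_and_classify_peaks(lods, small_map, ann, threshold=7.5)


# --- BLUPs ------------------------------------------------------------------


def test_blup_shrinks_null_and_recovers_partition(small_probs, rng):
    dos = small_probs.at_marker("c1m30")
    y_null = rng.normal(size=small_probs.n_samples)
    u = blup_effects(y_null, dos)
    ols, *_ = np.linalg.lstsq(dos, y_null - y_null.mean(), rcond=None)
    assert np.abs(u).max() < np.abs(ols - ols.mean()).max()

    eff = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
    y = dos @ eff * 3 + rng.normal(scale=0.3, size=small_probs.n_samples)
    u2 = blup_effects(y, dos)
    assert (u2[:4] > 0).all() and (u2[4:] < 0).all()


def test_blup_approaches_fixed_effects_with_strong_signal(desk_dataset, rng):
    probs = desk_dataset["probs"]
    dos = probs.at_marker("c3m100")
    eff = rng.normal(size=8) * 4
    y = dos @ eff + rng.normal(scale=0.2, size=probs.n_samples)
    u = blup_effects(y, dos)
    ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(probs.n_samples), dos]), y, rcond=None)
    fixed = ols[1:] - ols[1:].mean()
    assert np.corrcoef(u, fixed)[0, 1] >= 0.99
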
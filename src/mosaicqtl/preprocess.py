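"""Expression filtering, normalisation, batch correction and QC summaries.

Mirrors the processing chain used for bulk RNA-seq in multiparent eQTL
studies: expression filtering on a TPM-like abundance scale, upper-quartile
library-size normalisation, location-scale batch correction, and a rank-based
inverse-normal transform (rankZ) per gene ahead of mixed-model scans.  Also
provides the sample-identity checks (genotype matching, inter-transcriptome
correlation) and the cross-cell-type summaries (differential expression, PCA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


def tpm_like(counts: pd.DataFrame) -> pd.DataFrame:
    """Length-free abundance proxy: counts scaled to one million per sample.

    Genuine TPM requires transcript lengths; on synthetic data a per-sample
    counts-per-million scale serves the same filtering purpose.
    """
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts / totals * 1e6


def filter_genes(expr: pd.DataFrame, min_median: float = 0.5) -> list[str]:
    """Genes passing the expression filter on a TPM-like matrix.

    A gene is kept when its median abundance across samples is at least
    ``min_median`` AND it is zero in at most half of the samples.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError("abundance values must be non-negative")
    med = expr.median(axis=1)
    zero_frac = (expr == 0).sum(axis=1) / expr.shape[1]
    keep = (med >= min_median) & (zero_frac <= 0.5)
    return expr.index[keep].tolist()


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalisation of a genes x samples count matrix.

    Each sample is divided by the 75th percentile of its nonzero counts and
    rescaled by the geometric mean of those percentiles, so the output stays
    on a counts-like scale and identical samples remain identical.
    """
    uq = {}
    for s in counts.columns:
        col = counts[s].to_numpy(float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {s!r} has all-zero counts")
        uq[s] = np.percentile(nonzero, 75)
    uq = pd.Series(uq)
    scale = np.exp(np.log(uq).mean())  # geometric mean reference
    return counts / uq * scale


def remove_covariate_effects(
    expr: pd.DataFrame, factors: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Equalise per-gene location and scale across factor levels.

    For each gene and each factor (applied sequentially), within-level means
    are shifted to the grand mean and within-level SDs rescaled to the pooled
    within-level SD.  On balanced designs this removes additive and
    multiplicative batch/sex effects; it is a deliberate simplification of
    empirical-Bayes batch correction and applies no cross-gene shrinkage.
    """
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    out = expr.copy().astype(float)
    X = out.to_numpy()
    for fac in factors.columns:
        labels = factors.loc[expr.columns, fac].to_numpy()
        levels, inv = np.unique(labels, return_inverse=True)
        counts = np.bincount(inv)
        if (counts < 2).any():
            bad = levels[counts < 2].tolist()
            raise ValueError(f"factor {fac!r} has levels with a single sample: {bad}")
        grand = X.mean(axis=1, keepdims=True)
        # per-level mean and sd for every gene
        level_sum = np.zeros((X.shape[0], len(levels)))
        level_sq = np.zeros_like(level_sum)
        for li in range(len(levels)):
            cols = inv == li
            level_sum[:, li] = X[:, cols].mean(axis=1)
            level_sq[:, li] = X[:, cols].std(axis=1, ddof=1)
        pooled_var = (level_sq**2 * (counts - 1)).sum(axis=1) / (X.shape[1] - len(levels))
        pooled_sd = np.sqrt(pooled_var)
        for li in range(len(levels)):
            cols = inv == li
            mu = level_sum[:, li][:, None]
            sd = level_sq[:, li][:, None]
            ratio = np.where(sd > 0, pooled_sd[:, None] / np.where(sd > 0, sd, 1.0), 1.0)
            X[:, cols] = (X[:, cols] - mu) * ratio + grand
    return pd.DataFrame(X, index=expr.index, columns=expr.columns)


def rankz(expr: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse-normal transform, per gene.

    Values map to ``Phi^-1((rank - 0.5) / n)`` with average ranks for ties,
    giving each gene mean ~0 and SD ~1; a gene constant across samples maps
    to all zeros.
    """
    X = expr.to_numpy(float)
    n = X.shape[1]
    ranks = stats.rankdata(X, axis=1)
    return pd.DataFrame(
        stats.norm.ppf((ranks - 0.5) / n), index=expr.index, columns=expr.columns
    )


# ---------------------------------------------------------------------------
# sample identity
# ---------------------------------------------------------------------------


@dataclass
class MatchReport:
    """Genotype-based sample matching between two assays."""

    assignment: pd.Series  # for each sample in A, best-correlated sample in B
    mixups: list[str]  # A samples whose labelled partner is not the best match
    correlation: pd.DataFrame  # full A x B correlation matrix


def match_samples(geno_a: pd.DataFrame, geno_b: pd.DataFrame) -> MatchReport:
    """Match samples across assays by correlating genotype dosages.

    Both inputs are samples x markers frames; markers are intersected.  A
    sample is flagged as a mix-up when its best-correlated partner in the
    other assay is not the sample carrying the same label — the pattern that
    identifies swapped or mislabelled lines.
    """
    shared = geno_a.columns.intersection(geno_b.columns)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared markers; need at least 10")
    A = geno_a[shared].to_numpy(float)
    B = geno_b[shared].to_numpy(float)
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    corr = pd.DataFrame(Az @ Bz.T / len(shared), index=geno_a.index, columns=geno_b.index)
    best = corr.idxmax(axis=1)
    mixups = [s for s in geno_a.index if s in geno_b.index and best[s] != s]
    return MatchReport(assignment=best, mixups=mixups, correlation=corr)


def correlate_transcriptomes(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, shared_genes: list[str] | None = None
) -> dict:
    """Spearman correlations between every sample pair across two assays.

    Returns the full cross-matrix plus the matched-donor (same label) and
    mismatched-donor correlation sets with their medians.
    """
    if shared_genes is None:
        shared_genes = expr_a.index.intersection(expr_b.index).tolist()
    if len(shared_genes) < 3:
        raise ValueError("need at least 3 shared genes")
    A = stats.rankdata(expr_a.loc[shared_genes].to_numpy(float), axis=0)
    B = stats.rankdata(expr_b.loc[shared_genes].to_numpy(float), axis=0)
    Az = (A - A.mean(axis=0)) / np.where(A.std(axis=0) > 0, A.std(axis=0), 1.0)
    Bz = (B - B.mean(axis=0)) / np.where(B.std(axis=0) > 0, B.std(axis=0), 1.0)
    corr = pd.DataFrame(
        Az.T @ Bz / len(shared_genes), index=expr_a.columns, columns=expr_b.columns
    )
    shared_samples = expr_a.columns.intersection(expr_b.columns)
    matched = np.array([corr.loc[s, s] for s in shared_samples])
    mask = ~np.eye(corr.shape[0], corr.shape[1], dtype=bool) if corr.shape[0] == corr.shape[1] else None
    if mask is not None and list(corr.index) == list(corr.columns):
        mismatched = corr.to_numpy()[mask]
    else:
        off = corr.to_numpy().copy()
        for i, s in enumerate(corr.index):
            if s in corr.columns:
                off[i, corr.columns.get_loc(s)] = np.nan
        mismatched = off[~np.isnan(off)]
    return {
        "correlation": corr,
        "matched": matched,
        "mismatched": mismatched,
        "median_matched": float(np.median(matched)) if matched.size else np.nan,
        "median_mismatched": float(np.median(mismatched)) if mismatched.size else np.nan,
    }


# ---------------------------------------------------------------------------
# differential expression and PCA
# ---------------------------------------------------------------------------


def differential_expression(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum comparison of two cell types.

    Two-sided p-values (exact for group sizes <= 25, normal approximation
    with tie correction otherwise), Benjamini-Hochberg adjustment across
    genes, and log2 fold change of group-B over group-A means.  Genes are
    labelled up/down only when adjusted p < ``alpha`` and
    \\|log2FC\\| > ``lfc_threshold``; genes with a non-positive group mean get
    an undefined fold change and are excluded from labelling.
    """
    genes = expr_a.index.intersection(expr_b.index)
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    A = expr_a.loc[genes].to_numpy(float)
    B = expr_b.loc[genes].to_numpy(float)
    method = "exact" if min(A.shape[1], B.shape[1]) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided", method=method)
    pvals = np.asarray(res.pvalue)
    padj = multipletests(pvals, method="fdr_bh")[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    valid = (mean_a > 0) & (mean_b > 0)
    log2fc = np.full(len(genes), np.nan)
    log2fc[valid] = np.log2(mean_b[valid] / mean_a[valid])
    label = np.where(
        valid & (padj < alpha) & (log2fc > lfc_threshold),
        "up",
        np.where(valid & (padj < alpha) & (log2fc < -lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {"p": pvals, "p_adj": padj, "log2fc": log2fc, "label": label, "fc_defined": valid},
        index=genes,
    )


def pca_scores(
    expr: pd.DataFrame, n_components: int = 10, driver_quantile: float = 0.95
) -> dict:
    """PCA of a genes x samples matrix (genes centred before decomposition).

    Returns per-sample component scores, per-gene loadings, explained
    variance fractions, and driver-gene sets (top absolute loadings at
    ``driver_quantile``) per component.
    """
    X = expr.to_numpy(float)
    X = X - X.mean(axis=1, keepdims=True)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"requested {n_components} components but rank is at most {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    # samples are observations: transpose so rows are samples
    scores = pca.fit_transform(X.T)
    loadings = pca.components_.T  # genes x components
    drivers = {}
    for k in range(n_components):
        absload = np.abs(loadings[:, k])
        cut = np.quantile(absload, driver_quantile)
        drivers[k] = expr.index[absload >= cut].tolist()
    return {
        "scores": pd.DataFrame(
            scores, index=expr.columns, columns=[f"PC{k + 1}" for k in range(n_components)]
        ),
        "loadings": pd.DataFrame(
            loadings, index=expr.index, columns=[f"PC{k + 1}" for k in range(n_components)]
        ),
        "variance_fraction": pca.explained_variance_ratio_,
        "drivers": drivers,
    }
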
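"""Mediation analysis of QTL effects through candidate mediator genes.

For a target phenotype with a QTL (an individual transcript or a hotspot
eigengene), each candidate mediator is scored by the *LOD drop*: the loss in
association between the target and the eight founder dosages at the QTL peak
when the mediator's expression is added as a covariate.  Base and mediated
LOD scores are computed on the identical complete-case sample subset for each
mediator (the double-LOD-difference construction), so missing expression
values cannot masquerade as mediation.  Significance is judged against a
genome-wide empirical null: the QTL is mediated against all expressed genes
and a candidate is flagged when its mediated LOD falls more than 4 SDs below
the null mean.  Candidates are further corroborated by partial correlation
with the target after removing the genotype-class effect at the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _lod(y: np.ndarray, X_null: np.ndarray, X_alt: np.ndarray) -> float:
    """(n/2) log10(RSS_null / RSS_alt) by least squares with pseudoinverse.

    Residual sums of squares are floored at a small fraction of the
    phenotype's total variation, so saturated models (e.g. the mediator equals
    the target) yield LOD 0 instead of a ratio of numerical noise.
    """
    n = y.size
    floor = max(1e-12 * float(((y - y.mean()) ** 2).sum()), np.finfo(float).tiny)
    rss = []
    for X in (X_null, X_alt):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(max(float(r @ r), floor))
    return max((n / 2.0) * np.log10(rss[0] / rss[1]), 0.0)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class MediationScan:
    """Results of mediating one QTL against a set of candidate genes."""

    results: pd.DataFrame  # mediator, n, lod_base, lod_med, drop (sorted by drop desc)
    peak_marker: str


def mediation_scan(
    target: pd.Series,
    peak_dosages: pd.DataFrame | np.ndarray,
    mediators: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_samples: int = 30,
    peak_marker: str = "",
) -> MediationScan:
    """LOD drop of a target QTL for every candidate mediator.

    ``target`` is indexed by sample; ``peak_dosages`` is samples x 8 founder
    dosages at the QTL peak; ``mediators`` is genes x samples expression
    (e.g. from the same cell type, or from a donor-matched progenitor cell
    type, in which case the scan automatically restricts to the donor
    intersection).  Models are ordinary least squares at the single peak
    marker:

        base:     target ~ founder dosages + covariates
        mediated: target ~ founder dosages + covariates + mediator

    both fitted on the complete cases of that mediator.  Mediators with fewer
    than ``min_samples`` complete cases are skipped.
    """
    dos = (
        peak_dosages
        if isinstance(peak_dosages, pd.DataFrame)
        else pd.DataFrame(np.asarray(peak_dosages), index=target.index)
    )
    samples = target.index.intersection(dos.index).intersection(mediators.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    y_all = target.loc[samples].to_numpy(float)
    G_all = dos.loc[samples].to_numpy(float)
    C_all = covariates.loc[samples].to_numpy(float) if covariates is not None else None
    M_all = mediators[samples].to_numpy(float)
    base_complete = np.isfinite(y_all) & np.isfinite(G_all).all(axis=1)
    if C_all is not None:
        base_complete &= np.isfinite(C_all).all(axis=1)

    rows = []
    med_finite = np.isfinite(M_all)
    med_all_complete = med_finite.all(axis=1)  # per-mediator: no missing values

    def run_single(med_values: np.ndarray, mask: np.ndarray) -> tuple[int, float, float]:
        y, G = y_all[mask], G_all[mask]
        cols = [G]
        null_cols = [np.ones((int(mask.sum()), 1))]
        if C_all is not None:
            cols.append(C_all[mask])
            null_cols.append(C_all[mask])
        m = med_values[mask][:, None]
        base = _lod(y, np.column_stack(null_cols), np.column_stack(cols))
        med = _lod(y, np.column_stack(null_cols + [m]), np.column_stack(cols + [m]))
        return int(mask.sum()), base, med

    if med_all_complete.any() and int(base_complete.sum()) >= min_samples:
        # batched fast path: complete mediators share one sample subset
        sel = base_complete
        y, G = y_all[sel], G_all[sel]
        n = y.size
        X0 = np.column_stack([np.ones((n, 1))] + ([C_all[sel]] if C_all is not None else []))
        X1 = np.column_stack([G] + ([C_all[sel]] if C_all is not None else []))
        r0 = _residualize(y, X0)
        r1 = _residualize(y, X1)
        base_lod = max((n / 2.0) * np.log10(max(r0 @ r0, 1e-300) / max(r1 @ r1, 1e-300)), 0.0)
        M0 = M_all[med_all_complete][:, sel]
        # residualize mediators on both designs, then use the identity
        # RSS(y ~ X + m) = RSS(y ~ X) * (1 - corr(resid_y, resid_m)^2)
        B0, *_ = np.linalg.lstsq(X0, M0.T, rcond=None)
        Rm0 = M0.T - X0 @ B0
        B1, *_ = np.linalg.lstsq(X1, M0.T, rcond=None)
        Rm1 = M0.T - X1 @ B1

        floor = max(1e-12 * float(((y - y.mean()) ** 2).sum()), np.finfo(float).tiny)

        def rss_with(r_y: np.ndarray, Rm: np.ndarray) -> np.ndarray:
            num = Rm.T @ r_y
            den = (Rm**2).sum(axis=0) * float(r_y @ r_y)
            rho2 = np.where(den > 0, num**2 / den, 0.0)
            # floor against the phenotype scale: saturated mediators give LOD 0
            return np.maximum(float(r_y @ r_y) * (1.0 - np.clip(rho2, 0.0, 1.0)), floor)

        lod_med = (n / 2.0) * np.log10(rss_with(r0, Rm0) / rss_with(r1, Rm1))
        lod_med = np.clip(lod_med, 0.0, None)
        for g, lm in zip(mediators.index[med_all_complete], lod_med):
            rows.append((g, n, base_lod, float(lm), base_lod - float(lm)))
        remaining = mediators.index[~med_all_complete]
    else:
        remaining = mediators.index

    for g in remaining:
        mi = mediators.index.get_loc(g)
        mask = base_complete & med_finite[mi]
        if mask.sum() < min_samples:
            continue
        n_s, base, med = run_single(M_all[mi], mask)
        rows.append((g, n_s, base, med, base - med))

    df = pd.DataFrame(rows, columns=["mediator", "n", "lod_base", "lod_med", "drop"])
    df = df.sort_values("drop", ascending=False).reset_index(drop=True)
    return MediationScan(results=df, peak_marker=peak_marker)


def mediation_significance(
    scan: MediationScan,
    annotation: pd.DataFrame | None = None,
    peak_mbp: float | None = None,
    peak_chrom: str | None = None,
    window_mbp: float = 10.0,
    z_cut: float = -4.0,
    statistic: str = "standardized",
) -> pd.DataFrame:
    """Genome-wide null scaling of mediated LOD scores.

    Every expressed gene acts as its own null mediator; a candidate is
    significant when its mediated LOD falls below ``z_cut`` SDs from the null
    mean.  ``statistic='standardized'`` standardises the mediated LODs by
    their genome-wide moments; ``'ranknorm'`` first maps them to rank-based
    normal scores (note that over m candidates rank-normal scores are bounded
    near +/-Phi^-1(1 - 0.5/m), so the 4-SD rule is extremely stringent under
    that variant).  The positional filter afterwards keeps candidates whose
    gene midpoint lies within ``window_mbp`` of the QTL peak.
    """
    df = scan.results.copy()
    if len(df) < 100:
        raise ValueError("need at least 100 genome-wide candidates for null scaling")
    lods = df["lod_med"].to_numpy(float)
    if statistic == "ranknorm":
        ranks = stats.rankdata(lods)
        scores = stats.norm.ppf((ranks - 0.5) / len(ranks))
    elif statistic == "standardized":
        scores = lods
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread in mediated LOD scores")
    df["z"] = (scores - scores.mean()) / sd
    df["significant"] = df["z"] < z_cut
    if annotation is not None and peak_mbp is not None:
        ann = annotation.set_index("gene") if "gene" in annotation.columns else annotation
        mid = (ann["start"] + ann["end"]) / 2.0
        eligible = []
        for g in df["mediator"]:
            if g not in ann.index:
                eligible.append(False)
                continue
            same_chrom = peak_chrom is None or str(ann.loc[g, "chrom"]) == str(peak_chrom)
            eligible.append(same_chrom and abs(float(mid.loc[g]) - peak_mbp) <= window_mbp)
        df["eligible"] = eligible
    else:
        df["eligible"] = True
    return df


# ---------------------------------------------------------------------------
# genotype classes and partial correlation
# ---------------------------------------------------------------------------


def classify_genotype(
    peak_dosages: pd.DataFrame | np.ndarray,
    partition: tuple[tuple[int, ...], tuple[int, ...]],
    het_band: tuple[float, float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Ref/Het/Alt ancestry classes at a peak from a 4:4 founder partition.

    The alt-side dosage g sums the founder dosages over the second partition
    block (diploid dosage rescaled to [0, 1]); samples are Ref when
    g < ``het_band[0]``, Alt when g > ``het_band[1]``, Het in between —
    homozygous ancestry from either block lands at g = 0 or 1, one haplotype
    from each side at g = 0.5.
    """
    ref, alt = partition
    if set(ref) | set(alt) != set(range(8)) or set(ref) & set(alt):
        raise ValueError("partition must be a disjoint 2-colouring of founders 0..7")
    dos = (
        peak_dosages.to_numpy(float)
        if isinstance(peak_dosages, pd.DataFrame)
        else np.asarray(peak_dosages, dtype=float)
    )
    index = (
        peak_dosages.index
        if isinstance(peak_dosages, pd.DataFrame)
        else pd.RangeIndex(len(dos))
    )
    g = dos[:, list(alt)].sum(axis=1)
    lo, hi = het_band
    label = np.where(g < lo, "Ref", np.where(g > hi, "Alt", "Het"))
    return pd.DataFrame({"alt_dosage": g, "label": label}, index=index)


def partial_correlation(
    mediators: pd.DataFrame,
    target: pd.Series,
    genotype_class: pd.DataFrame,
    coding: str = "additive",
) -> pd.DataFrame:
    """Partial correlation of each mediator with the target, controlling genotype.

    Both variables are residualised on the genotype covariate — additive
    0/1/2 coding of Ref/Het/Alt by default, or two indicator columns with
    ``coding='genotypic'`` — and the Pearson correlation of the residuals is
    tested with the standard t statistic at n - 3 degrees of freedom.
    BH adjustment runs across all supplied candidates.
    """
    samples = target.index.intersection(mediators.columns).intersection(genotype_class.index)
    if len(samples) < 10:
        raise ValueError("need at least 10 complete-case samples")
    labels = genotype_class.loc[samples, "label"]
    num = labels.map({"Ref": 0.0, "Het": 1.0, "Alt": 2.0}).to_numpy()
    if coding == "additive":
        X = np.column_stack([np.ones(len(samples)), num])
    elif coding == "genotypic":
        X = np.column_stack(
            [np.ones(len(samples)), (num == 1).astype(float), (num == 2).astype(float)]
        )
    else:
        raise ValueError(f"unknown coding {coding!r}")
    ry = _residualize(target.loc[samples].to_numpy(float), X)
    n = len(samples)
    rows = []
    for g in mediators.index:
        m = mediators.loc[g, samples].to_numpy(float)
        mask = np.isfinite(m)
        if mask.sum() < 10:
            rows.append((g, np.nan, np.nan, True))
            continue
        rm = _residualize(m[mask], X[mask])
        ry_g = ry[mask] if not mask.all() else ry
        if rm.std() == 0 or ry_g.std() == 0:
            rows.append((g, np.nan, np.nan, True))
            continue
        r = float(np.corrcoef(ry_g, rm)[0, 1])
        df_t = mask.sum() - 3
        t = r * np.sqrt(df_t / max(1.0 - r**2, 1e-12))
        p = 2.0 * stats.t.sf(abs(t), df_t)
        rows.append((g, r, p, False))
    out = pd.DataFrame(rows, columns=["mediator", "r_partial", "p", "undefined"])
    ok = ~out["p"].isna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    return out
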
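"""Founder-haplotype linear mixed model genome scans.

The model for one phenotype y (typically a rankZ-transformed transcript) is

    y = X b + g + e,   g ~ N(0, Vg K),   e ~ N(0, Ve I)

where K is a kinship matrix built from founder dosages and X holds an
intercept plus additive covariates (sex).  Scans use leave-one-chromosome-out
(LOCO) kinship: the null variance components are estimated once per
phenotype per chromosome, the data are rotated to the kinship eigenbasis and
whitened, and at each marker the eight founder-dosage columns are fitted by
(pseudoinverse) weighted least squares.  The LOD score is

    LOD = (n / 2) * log10(RSS_null / RSS_marker).

Genome-wide significance comes from permutations of the genotype array
(phenotype/covariate pairing intact), pooling maximum LOD scores across
phenotypes; FDR is estimated with Storey's q-value procedure using the
bootstrap pi0 estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genome import FOUNDER_LETTERS, GenomeMap
from .simdata import GenotypeProbs

# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipSet:
    """Full and leave-one-chromosome-out kinship matrices with cached eigendecompositions."""

    full: np.ndarray
    loco: dict[str, np.ndarray] = field(default_factory=dict)
    _eigen: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    def matrix(self, chrom: str | None) -> np.ndarray:
        if chrom is None or not self.loco:
            return self.full
        return self.loco[str(chrom)]

    def eigen(self, chrom: str | None) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of the kinship for one scan chromosome."""
        key = "__full__" if chrom is None or not self.loco else str(chrom)
        if key not in self._eigen:
            K = self.full if key == "__full__" else self.loco[key]
            d, U = np.linalg.eigh(K)
            self._eigen[key] = (np.clip(d, 0.0, None), U)
        return self._eigen[key]


def calc_kinship(probs: GenotypeProbs, mode: str = "loco") -> KinshipSet:
    """Dosage-based kinship: K = (1/M) sum_m P_m P_m^T over included markers.

    ``mode='loco'`` additionally builds, for every chromosome, the matrix
    computed from all markers NOT on that chromosome.
    """
    P = probs.probs
    gmap = probs.gmap
    chroms = gmap.chromosomes
    if mode == "loco" and len(chroms) < 2:
        raise ValueError("LOCO kinship requires at least 2 chromosomes")
    per_chrom_sums = {}
    per_chrom_counts = {}
    for c in chroms:
        Pc = P[:, :, gmap.chrom_index(c)]
        per_chrom_sums[c] = np.einsum("sfm,tfm->st", Pc, Pc)
        per_chrom_counts[c] = Pc.shape[2]
    total = sum(per_chrom_sums.values())
    M = sum(per_chrom_counts.values())
    full = total / M
    full = (full + full.T) / 2
    loco = {}
    if mode == "loco":
        for c in chroms:
            Kc = (total - per_chrom_sums[c]) / (M - per_chrom_counts[c])
            loco[c] = (Kc + Kc.T) / 2
    return KinshipSet(full=full, loco=loco)


# ---------------------------------------------------------------------------
# variance components / heritability
# ---------------------------------------------------------------------------


@dataclass
class HeritabilityResult:
    h2: float
    vg: float
    ve: float
    loglik: float
    flat: bool  # likelihood uninformative in h2 (e.g. K proportional to I)


def _design(n: int, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return X


def _profile_loglik(h2: float, d: np.ndarray, Uty: np.ndarray, UtX: np.ndarray, reml: bool) -> float:
    """Profile (restricted) log-likelihood of h2 on the kinship eigenbasis."""
    n, p = UtX.shape
    w = h2 * d + (1.0 - h2)
    sw = np.sqrt(w)
    yw = Uty / sw
    Xw = UtX / sw[:, None]
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    if rss <= 0:
        rss = np.finfo(float).tiny
    if reml:
        dof = n - p
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        return -0.5 * (dof * np.log(rss / dof) + np.log(w).sum() + logdet_xx)
    return -0.5 * (n * np.log(rss / n) + np.log(w).sum())


def est_heritability(
    y: np.ndarray,
    kinship: KinshipSet | np.ndarray,
    covariates=None,
    reml: bool = True,
) -> HeritabilityResult:
    """Narrow-sense heritability h2 = Vg / (Vg + Ve) from the full kinship matrix.

    Maximises the (restricted) likelihood over h2 by 1-D bounded optimisation
    on the eigenbasis of K.  A flat likelihood (kinship carries no usable
    structure, e.g. K = I) returns h2 = 0 with ``flat=True``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n = y.size
    if n < 20:
        raise ValueError("need at least 20 samples")
    if isinstance(kinship, KinshipSet):
        d, U = kinship.eigen(None)
    else:
        K = np.asarray(kinship, dtype=float)
        d, U = np.linalg.eigh(K)
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise ValueError("kinship matrix is not positive semidefinite")
        d = np.clip(d, 0.0, None)
    X = _design(n, covariates)
    Uty = U.T @ y
    UtX = U.T @ X

    def neg(h2: float) -> float:
        return -_profile_loglik(h2, d, Uty, UtX, reml)

    res = minimize_scalar(neg, bounds=(0.0, 1.0 - 1e-6), method="bounded", options={"xatol": 1e-5})
    ll0 = _profile_loglik(0.0, d, Uty, UtX, reml)
    ll_hat = -res.fun
    h2 = float(res.x)
    if ll_hat < ll0:
        h2, ll_hat = 0.0, ll0
    flat = abs(ll_hat - ll0) < 1e-4 and not (ll_hat > ll0 + 1e-4)
    if flat:
        h2 = 0.0
    # profile out the total variance at the optimum (ML scale)
    w = h2 * d + (1.0 - h2)
    yw, Xw = Uty / np.sqrt(w), UtX / np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    dof = n - X.shape[1] if reml else n
    s2 = float(r @ r) / dof
    return HeritabilityResult(h2=h2, vg=h2 * s2, ve=(1 - h2) * s2, loglik=ll_hat, flat=flat)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """LOD scores over all markers for one phenotype, plus per-chromosome null components."""

    lod: pd.Series  # indexed by marker id
    vc: dict[str, HeritabilityResult]
    n: int

    @property
    def max_lod(self) -> float:
        return float(self.lod.max())

    def peak(self) -> tuple[str, float]:
        m = self.lod.idxmax()
        return str(m), float(self.lod[m])


class _ChromContext:
    """Whitened quantities for scanning one chromosome of one phenotype."""

    def __init__(self, y, X_null, C_raw, d, U, h2):
        w = h2 * d + (1.0 - h2)
        self.T = U.T / np.sqrt(w)[:, None]  # whitening operator
        self.yw = self.T @ y
        Xw = self.T @ X_null
        beta, *_ = np.linalg.lstsq(Xw, self.yw, rcond=None)
        r = self.yw - Xw @ beta
        self.rss0 = float(r @ r)
        self.Cw = self.T @ C_raw if C_raw is not None else None
        self.yty = float(self.yw @ self.yw)


def _marker_rss(ctx: _ChromContext, Pc: np.ndarray) -> np.ndarray:
    """Batched residual sums of squares of the marker models on one chromosome.

    ``Pc`` is the (samples, 8, markers) dosage slice; the design at each
    marker is [8 whitened founder-dosage columns, whitened covariates] solved
    through the pseudoinverse of the normal equations (the dosage columns sum
    to one, absorbing the intercept, and may be collinear locally).
    """
    n = ctx.T.shape[0]
    M = Pc.shape[2]
    # whiten all dosage columns at once through BLAS: (n, 8*M) matmul
    flat = Pc.reshape(n, 8 * M)
    Gw = (ctx.T @ flat).reshape(n, 8, M).transpose(2, 0, 1)  # (M, n, 8)
    GwT = Gw.transpose(0, 2, 1)  # (M, 8, n)
    Gty = GwT @ ctx.yw
    GtG = GwT @ Gw
    if ctx.Cw is not None and ctx.Cw.shape[1] > 0:
        C = ctx.Cw
        GtC = GwT @ C
        CtC = C.T @ C
        Cty = C.T @ ctx.yw
        M, p = GtG.shape[0], C.shape[1]
        k = 8 + p
        A = np.empty((M, k, k))
        A[:, :8, :8] = GtG
        A[:, :8, 8:] = GtC
        A[:, 8:, :8] = np.transpose(GtC, (0, 2, 1))
        A[:, 8:, 8:] = CtC[None, :, :]
        b = np.concatenate([Gty, np.broadcast_to(Cty, (M, p))], axis=1)
    else:
        A, b = GtG, Gty
    beta = np.linalg.pinv(A, hermitian=True, rcond=1e-10) @ b[:, :, None]
    rss = ctx.yty - np.einsum("mk,mk->m", b, beta[:, :, 0])
    return np.clip(rss, np.finfo(float).tiny, None)


def _build_contexts(
    y: np.ndarray,
    probs: GenotypeProbs,
    kinship: KinshipSet | None,
    covariates,
    reml: bool,
) -> tuple[dict[str, _ChromContext], dict[str, HeritabilityResult]]:
    n = y.size
    X_null = _design(n, covariates)
    C_raw = X_null[:, 1:] if X_null.shape[1] > 1 else None
    contexts, vc = {}, {}
    for chrom in probs.gmap.chromosomes:
        if kinship is None:
            d, U = np.zeros(n), np.eye(n)
            h2res = HeritabilityResult(0.0, 0.0, float(np.var(y)), 0.0, True)
        else:
            d, U = kinship.eigen(chrom)
            Uty, UtX = U.T @ y, U.T @ X_null

            def neg(h2):
                return -_profile_loglik(h2, d, Uty, UtX, reml)

            res = minimize_scalar(
                neg, bounds=(0.0, 1.0 - 1e-6), method="bounded", options={"xatol": 1e-4}
            )
            h2 = float(res.x)
            if -res.fun < _profile_loglik(0.0, d, Uty, UtX, reml):
                h2 = 0.0
            h2res = HeritabilityResult(h2, np.nan, np.nan, -res.fun, False)
        vc[chrom] = h2res
        contexts[chrom] = _ChromContext(y, X_null, C_raw, d, U, h2res.h2)
    return contexts, vc


def scan1(
    y: np.ndarray | pd.Series,
    probs: GenotypeProbs,
    kinship: KinshipSet | None = None,
    covariates=None,
    reml: bool = False,
) -> ScanResult:
    """Genome scan of one phenotype across all markers.

    Null variance components are estimated once per chromosome against the
    LOCO kinship (``kinship=None`` drops the polygenic term entirely, giving
    the plain least-squares scan) and reused at every marker on that
    chromosome.
    """
    y = np.asarray(y, dtype=float)
    if y.size != probs.n_samples:
        raise ValueError("phenotype length does not match the genotype samples")
    contexts, vc = _build_contexts(y, probs, kinship, covariates, reml)
    n = y.size
    lods = np.empty(probs.gmap.n_markers)
    for chrom in probs.gmap.chromosomes:
        ctx = contexts[chrom]
        idx = probs.gmap.chrom_index(chrom)
        rss1 = _marker_rss(ctx, probs.probs[:, :, idx])
        lods[idx] = (n / 2.0) * np.log10(ctx.rss0 / rss1)
    lods = np.clip(lods, 0.0, None)
    return ScanResult(
        lod=pd.Series(lods, index=probs.gmap.markers["marker"].to_numpy()), vc=vc, n=n
    )


def scan_genes(
    expr: pd.DataFrame,
    probs: GenotypeProbs,
    kinship: KinshipSet | None = None,
    covariates=None,
    reml: bool = False,
) -> pd.DataFrame:
    """Scan every gene (row) of an expression matrix; returns genes x markers LODs."""
    out = np.empty((expr.shape[0], probs.gmap.n_markers))
    for i, g in enumerate(expr.index):
        out[i] = scan1(expr.loc[g].to_numpy(), probs, kinship, covariates, reml).lod.to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=probs.gmap.markers["marker"].to_numpy())


# ---------------------------------------------------------------------------
# permutation thresholds and q-values
# ---------------------------------------------------------------------------


@dataclass
class Thresholds:
    """Genome-wide LOD thresholds from genotype permutations."""

    lod: dict[float, float]  # alpha -> LOD threshold
    null_maxima: np.ndarray

    def threshold(self, alpha: float) -> float:
        return self.lod[alpha]

    def perm_pvalue(self, observed_lod: float | np.ndarray) -> np.ndarray:
        """Fraction of null genome-wide maxima at or above the observed LOD."""
        obs = np.atleast_1d(np.asarray(observed_lod, dtype=float))
        p = (self.null_maxima[None, :] >= obs[:, None]).mean(axis=1)
        # never report exactly zero from a finite permutation null
        p = np.maximum(p, 1.0 / (len(self.null_maxima) + 1))
        return p if np.ndim(observed_lod) else float(p[0])


def permutation_threshold(
    phenos: pd.DataFrame | np.ndarray,
    probs: GenotypeProbs,
    kinship: KinshipSet | None = None,
    covariates=None,
    n_perm: int = 100,
    alphas: tuple[float, ...] = (0.05,),
    seed: int | None = None,
    reml: bool = False,
) -> Thresholds:
    """Null distribution of the genome-wide maximum LOD from genotype permutations.

    The sample index of the genotype array is permuted while the
    phenotype/covariate pairing stays intact; ``n_perm`` permutations are run
    for every phenotype row and the maxima are pooled into one genome-wide
    null, from which each alpha threshold is the (1 - alpha) quantile.
    Null variance components of each phenotype are estimated once and reused
    across its permutations.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    Y = np.atleast_2d(np.asarray(phenos, dtype=float))
    rng = np.random.default_rng(seed)
    n = probs.n_samples
    maxima = []
    for y in Y:
        contexts, _ = _build_contexts(y, probs, kinship, covariates, reml)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            best = 0.0
            for chrom in probs.gmap.chromosomes:
                ctx = contexts[chrom]
                idx = probs.gmap.chrom_index(chrom)
                rss1 = _marker_rss(ctx, probs.probs[perm][:, :, idx])
                lod = (n / 2.0) * np.log10(ctx.rss0 / rss1)
                best = max(best, float(lod.max()))
            maxima.append(best)
    maxima = np.asarray(maxima)
    lod = {a: float(np.quantile(maxima, 1.0 - a)) for a in alphas}
    return Thresholds(lod=lod, null_maxima=maxima)


def qvalues(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Storey q-values with the bootstrap pi0 estimator.

    pi0 is estimated on a lambda grid as #{p > lambda} / (m (1 - lambda));
    the lambda minimising the bootstrap mean squared error against the
    minimum pi0 over the grid is selected.  q-values are the usual monotone
    step-down transform q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    pi0_min = max(pi0_grid.min(), 0.0)
    rng = np.random.default_rng(seed)
    mse = np.zeros(len(lambdas))
    for _ in range(n_boot):
        pb = p[rng.integers(m, size=m)]
        pi0_b = np.array([(pb > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
        mse += (pi0_b - pi0_min) ** 2
    pi0 = float(np.clip(pi0_grid[np.argmin(mse)], 0.0, 1.0))
    order = np.argsort(p)
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


# ---------------------------------------------------------------------------
# peak calling and founder effects
# ---------------------------------------------------------------------------


def find_and_classify_peaks(
    lods: pd.DataFrame,
    gmap: GenomeMap,
    annotation: pd.DataFrame,
    threshold: float,
    local_window_mbp: float = 10.0,
) -> pd.DataFrame:
    """Per-gene, per-chromosome QTL peaks above a LOD threshold.

    ``lods`` is genes x markers; ``annotation`` carries gene, chrom, start,
    end in Mbp.  A peak is 'local' when it lies on the gene's chromosome
    within +/-``local_window_mbp`` (inclusive) of the gene midpoint, and
    'distant' otherwise.
    """
    ann = annotation.set_index("gene") if "gene" in annotation.columns else annotation
    markers = gmap.markers
    rows = []
    missing = []
    L = lods.to_numpy()
    for i, gene in enumerate(lods.index):
        gene_known = gene in ann.index
        for chrom in gmap.chromosomes:
            idx = gmap.chrom_index(chrom)
            sub = L[i, idx]
            j = int(np.argmax(sub))
            lod = float(sub[j])
            if lod < threshold:
                continue
            if not gene_known:
                missing.append(gene)
                break
            row = markers.iloc[idx[j]]
            midpoint = (float(ann.loc[gene, "start"]) + float(ann.loc[gene, "end"])) / 2.0
            is_local = (str(ann.loc[gene, "chrom"]) == chrom) and (
                abs(float(row["Mbp"]) - midpoint) <= local_window_mbp
            )
            rows.append(
                (
                    gene,
                    chrom,
                    str(row["marker"]),
                    float(row["cM"]),
                    float(row["Mbp"]),
                    lod,
                    "local" if is_local else "distant",
                )
            )
    if missing:
        raise KeyError(f"no annotation for peaked genes: {sorted(set(missing))}")
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "peak_marker", "cM", "Mbp", "lod", "class"]
    )


def blup_effects(
    y: np.ndarray | pd.Series,
    peak_dosages: np.ndarray,
    kinship: KinshipSet | None = None,
    chrom: str | None = None,
    covariates=None,
    reml: bool = False,
) -> np.ndarray:
    """Shrunken founder allele effects (BLUPs) at a QTL peak.

    The eight founder effects are treated as random with a common variance;
    the effect and residual variances are estimated by maximum likelihood on
    the kinship-whitened model, and the returned BLUPs are centred to sum to
    zero.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    G = np.asarray(peak_dosages, dtype=float)
    if G.shape != (n, 8):
        raise ValueError("peak dosages must be (n_samples, 8)")
    X = _design(n, covariates)
    if kinship is None:
        T = np.eye(n)
    else:
        d, U = kinship.eigen(chrom)
        Uty, UtX = U.T @ y, U.T @ X

        def neg(h2):
            return -_profile_loglik(h2, d, Uty, UtX, reml)

        res = minimize_scalar(neg, bounds=(0.0, 1.0 - 1e-6), method="bounded")
        h2 = float(res.x) if -res.fun > _profile_loglik(0.0, d, Uty, UtX, reml) else 0.0
        T = U.T / np.sqrt(h2 * d + (1.0 - h2))[:, None]
    yw, Xw, Gw = T @ y, T @ X, T @ G
    # absorb fixed effects
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gr = Gw - Q @ (Q.T @ Gw)
    Ur, s, Vt = np.linalg.svd(Gr, full_matrices=False)
    keep = s > 1e-10 * s.max()
    Ur, s, Vt = Ur[:, keep], s[keep], Vt[keep]
    yproj = Ur.T @ yr
    resid2 = float(yr @ yr - yproj @ yproj)
    r = s.size

    def negll(log_tau: float) -> float:
        tau = np.exp(log_tau)  # sigma_u^2 / sigma_e^2
        lam = tau * s**2 + 1.0
        # profile sigma_e^2
        quad = float((yproj**2 / lam).sum() + resid2)
        se2 = quad / n
        return 0.5 * (np.log(lam).sum() + n * np.log(se2))

    res = minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded")
    tau = float(np.exp(res.x))
    lam = tau * s**2 + 1.0
    u = Vt.T @ ((tau * s / lam) * yproj)
    return u - u.mean()


def add_blup_effects(
    peaks: pd.DataFrame,
    expr: pd.DataFrame,
    probs: GenotypeProbs,
    kinship: KinshipSet | None = None,
    covariates=None,
) -> pd.DataFrame:
    """Append founder-effect columns (eff_A..eff_H) to a peak table."""
    effs = np.full((len(peaks), 8), np.nan)
    for i, row in enumerate(peaks.itertuples(index=False)):
        y = expr.loc[row.gene].to_numpy(float)
        dos = probs.at_marker(row.peak_marker)
        effs[i] = blup_effects(y, dos, kinship, row.chrom, covariates)
    out = peaks.copy()
    for j, letter in enumerate(FOUNDER_LETTERS):
        out[f"eff_{letter}"] = effs[:, j]
    return out
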
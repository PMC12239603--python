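"""Synthetic Diversity Outbred-style genomes and two-cell-type expression.

Every downstream stage of the pipeline (scans, hotspots, mediation) is
exercised against data from this module, which plants a known genetic
architecture and returns truth tables alongside the simulated matrices.

The generative model, briefly:

* each sample carries two haploid chromosomes, each a Markov mosaic of the
  8 founder haplotypes (uniform initial founder, exponential inter-crossover
  distances in cM, uniform switch to one of the other 7 founders);
* founder dosages at a marker are the haplotype counts / 2, optionally
  blurred and renormalised to emulate probabilistic ancestry inference;
* a local eQTL contributes ``dosage . effect`` scaled so that the genetic
  variance fraction of (genetic + residual) equals the requested QTL
  heritability;
* one distant-eQTL hotspot is created by routing genotype exclusively
  through a mediator gene: the mediator has a local eQTL at the hotspot
  marker with a 4:4 founder-partition effect, and each target gene is
  ``slope x mediator + noise`` with no direct genotype term;
* negative-binomial counts with per-sample library sizes sit on top of the
  latent values for exercising the normalisation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FOUNDER_LETTERS, N_FOUNDERS, GenomeMap, default_map

# ---------------------------------------------------------------------------
# haplotype mosaics and genotype probabilities
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMosaic:
    """Founder-of-origin segments for every sample.

    ``segments[chrom][i]`` holds the two haplotypes of sample ``i`` on that
    chromosome, each a list of ``(founder_index, segment_end_cM)`` tuples that
    tile the chromosome exactly.
    """

    samples: list[str]
    segments: dict[str, list[tuple[list[tuple[int, float]], list[tuple[int, float]]]]]

    def founder_at(self, chrom: str, cm: float) -> np.ndarray:
        """(n_samples, 2) founder indices at a genetic position."""
        out = np.empty((len(self.samples), 2), dtype=np.int64)
        for i, (hap0, hap1) in enumerate(self.segments[chrom]):
            for j, hap in enumerate((hap0, hap1)):
                for founder, end in hap:
                    if cm <= end:
                        out[i, j] = founder
                        break
                else:
                    out[i, j] = hap[-1][0]
        return out


@dataclass
class GenotypeProbs:
    """Founder-ancestry dosages, shaped (samples, 8 founders, markers).

    Rows over founders sum to one at every (sample, marker).
    """

    probs: np.ndarray
    samples: list[str]
    gmap: GenomeMap

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[1] != N_FOUNDERS:
            raise ValueError("probs must be (samples, 8, markers)")
        if p.shape[2] != self.gmap.n_markers:
            raise ValueError("marker dimension does not match the map")
        self.probs = p

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    def at_marker(self, marker: str) -> np.ndarray:
        """(n_samples, 8) dosage slice at a named marker."""
        return self.probs[:, :, self.gmap.marker_index(marker)]

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return self.probs[:, :, self.gmap.chrom_index(chrom)]

    def subset(self, samples: list[str]) -> "GenotypeProbs":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in samples]
        return GenotypeProbs(self.probs[idx], list(samples), self.gmap)


def _simulate_haplotype(
    length_cm: float, recomb_rate: float, rng: np.random.Generator
) -> list[tuple[int, float]]:
    founder = int(rng.integers(N_FOUNDERS))
    segments: list[tuple[int, float]] = []
    pos = 0.0
    mean_len = 1.0 / recomb_rate
    while True:
        pos += rng.exponential(mean_len)
        if pos >= length_cm:
            segments.append((founder, length_cm))
            return segments
        segments.append((founder, pos))
        # switch to one of the other 7 founders
        founder = (founder + 1 + int(rng.integers(N_FOUNDERS - 1))) % N_FOUNDERS


def simulate_mosaics(
    gmap: GenomeMap,
    n_samples: int,
    recomb_rate: float = 0.2,
    seed: int | None = None,
) -> HaplotypeMosaic:
    """Draw founder-haplotype mosaics for ``n_samples`` diploid genomes.

    ``recomb_rate`` is the expected number of crossovers per cM per haplotype;
    the default 0.2 gives mean founder-segment lengths of ~5 cM, in line with
    an outbred stock after ~20 generations of random intercrossing, which is
    what sets the mapping resolution of the downstream scans.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if recomb_rate <= 0:
        raise ValueError("recomb_rate must be > 0")
    if gmap.n_markers == 0:
        raise ValueError("empty map")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    segments: dict[str, list] = {}
    for chrom in gmap.chromosomes:
        length = gmap.chrom_lengths_cm[chrom]
        segments[chrom] = [
            (
                _simulate_haplotype(length, recomb_rate, rng),
                _simulate_haplotype(length, recomb_rate, rng),
            )
            for _ in range(n_samples)
        ]
    return HaplotypeMosaic(samples, segments)


def mosaics_to_probs(
    mosaics: HaplotypeMosaic,
    gmap: GenomeMap,
    blur_sd: float = 0.0,
    seed: int | None = None,
) -> GenotypeProbs:
    """Convert mosaics to founder-dosage probabilities at the map's markers.

    With ``blur_sd`` > 0, symmetric Gaussian noise is added to each 8-vector,
    values are clipped at zero and renormalised to sum to one — a crude stand-in
    for uncertainty in probabilistic ancestry inference.
    """
    if blur_sd < 0:
        raise ValueError("blur_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(mosaics.samples)
    probs = np.zeros((n, N_FOUNDERS, gmap.n_markers))
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_index(chrom)
        cms = gmap.markers["cM"].to_numpy(float)[idx]
        for i, (hap0, hap1) in enumerate(mosaics.segments[chrom]):
            for hap in (hap0, hap1):
                ends = np.array([end for _, end in hap])
                founders = np.array([f for f, _ in hap])
                seg_of_marker = np.searchsorted(ends, cms, side="left")
                seg_of_marker = np.minimum(seg_of_marker, len(hap) - 1)
                np.add.at(probs[i], (founders[seg_of_marker], idx), 0.5)
    if blur_sd > 0:
        probs += rng.normal(0.0, blur_sd, size=probs.shape)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
    return GenotypeProbs(probs, mosaics.samples, gmap)


# ---------------------------------------------------------------------------
# architecture specification
# ---------------------------------------------------------------------------


@dataclass
class LocalEqtl:
    """A planted local eQTL: gene regulated by the founder dosages at one marker."""

    gene: str
    marker: str
    effects: np.ndarray  # 8-vector of founder effects (relative pattern)
    h2: float = 0.5  # QTL heritability: genetic fraction of genetic+residual variance
    cell_types: tuple[str, ...] = ("A", "B")  # shared across cell types by default

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (N_FOUNDERS,):
            raise ValueError("effects must be an 8-vector")
        if not 0 <= self.h2 < 1:
            raise ValueError("heritability must be in [0, 1)")


@dataclass
class HotspotSpec:
    """A distant-eQTL hotspot whose effect flows entirely through a mediator gene.

    The mediator carries a local eQTL at ``marker`` whose founder effects follow
    the two sides of ``partition`` (+1 for the 'alt' side, -1 for the 'ref'
    side), emulating a 4:4 allele split.  Targets respond to the mediator's
    latent expression only — they carry no direct genotype term.
    """

    marker: str
    mediator_gene: str = "mediator"
    mediator_cell_type: str = "B"  # "A" = progenitor-only expression
    target_genes: tuple[str, ...] = ()
    slopes: tuple[float, ...] = ()  # per-target mediation slopes
    partition: tuple[tuple[int, ...], tuple[int, ...]] = ((0, 1, 2, 3), (4, 5, 6, 7))
    mediator_h2: float = 0.6
    n_decoys: int = 3  # local-eQTL genes at the hotspot marker that do NOT mediate
    decoy_h2: float = 0.5

    def __post_init__(self) -> None:
        ref, alt = self.partition
        if sorted(ref) + sorted(alt) and set(ref) | set(alt) != set(range(N_FOUNDERS)):
            raise ValueError("partition must be a 2-part partition of founders 0..7")
        if set(ref) & set(alt):
            raise ValueError("partition sides must be disjoint")
        if self.mediator_gene in self.target_genes:
            raise ValueError("mediator gene may not be among the targets")
        if self.target_genes and not self.slopes:
            self.slopes = tuple(np.sqrt(2.0) for _ in self.target_genes)
        if len(self.slopes) != len(self.target_genes):
            raise ValueError("one slope per target gene required")

    @property
    def partition_effects(self) -> np.ndarray:
        eff = np.empty(N_FOUNDERS)
        ref, alt = self.partition
        eff[list(ref)] = -1.0
        eff[list(alt)] = 1.0
        return eff


@dataclass
class ArchitectureSpec:
    """Full planted architecture for one two-cell-type simulation.

    Defaults mirror the study design this generator emulates: 186 donor lines
    with expression in the derived cell type (B), of which the first 127 also
    have expression in the progenitor cell type (A); 30 hotspot targets with
    mediation slope sqrt(2) (signal-to-noise 2 against unit residual noise);
    local-eQTL heritability 0.5.
    """

    local_eqtl: list[LocalEqtl] = field(default_factory=list)
    hotspot: HotspotSpec | None = None
    n_background_genes: int = 200  # unregulated genes per cell type
    sex_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3
    residual_sd: float = 1.0
    nb_dispersion: float = 2.0
    library_size_range: tuple[float, float] = (1e6, 3e6)
    seed: int = 0

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.local_eqtl]
        if self.hotspot is not None:
            genes += [self.hotspot.mediator_gene, *self.hotspot.target_genes]
        if len(genes) != len(set(genes)):
            raise ValueError("genes in the architecture must be distinct")


def default_architecture(
    gmap: GenomeMap | None = None,
    n_local: int = 40,
    n_targets: int = 30,
    mediator_cell_type: str = "B",
    local_cell_types: tuple[str, ...] = ("A", "B"),
    seed: int = 0,
) -> ArchitectureSpec:
    """Study-condition preset: shared local eQTL plus one mediated hotspot.

    Local eQTL are spread over the genome away from the hotspot chromosome's
    peak region; the hotspot sits mid-chromosome 1 with ``n_targets`` targets
    placed on the other chromosomes.
    """
    gmap = gmap if gmap is not None else default_map()
    rng = np.random.default_rng(seed)
    markers = gmap.markers
    hotspot_chrom = gmap.chromosomes[0]
    hs_idx = gmap.chrom_index(hotspot_chrom)
    hotspot_marker = str(markers["marker"].iloc[hs_idx[len(hs_idx) // 2]])

    local = []
    candidates = markers.index.to_numpy()
    chosen = rng.choice(candidates, size=n_local, replace=False)
    for k, row_i in enumerate(chosen):
        row = markers.loc[row_i]
        local.append(
            LocalEqtl(
                gene=f"lg{k + 1:03d}",
                marker=str(row["marker"]),
                effects=rng.normal(size=N_FOUNDERS),
                h2=0.5,
                cell_types=local_cell_types,
            )
        )
    hotspot = HotspotSpec(
        marker=hotspot_marker,
        mediator_gene="mediator",
        mediator_cell_type=mediator_cell_type,
        target_genes=tuple(f"tg{k + 1:03d}" for k in range(n_targets)),
    )
    return ArchitectureSpec(local_eqtl=local, hotspot=hotspot, seed=seed)


# ---------------------------------------------------------------------------
# covariates and expression
# ---------------------------------------------------------------------------


def simulate_covariates(
    samples: list[str], n_batches: int = 3, seed: int | None = None
) -> pd.DataFrame:
    """Balanced binary sex and a cyclic batch assignment, shuffled."""
    rng = np.random.default_rng(seed)
    n = len(samples)
    sex = np.array([i % 2 for i in range(n)])
    batch = np.array([i % n_batches for i in range(n)])
    rng.shuffle(sex)
    rng.shuffle(batch)
    return pd.DataFrame({"sex": sex, "batch": batch}, index=pd.Index(samples, name="sample"))


def _scaled_genetic_term(
    dosages: np.ndarray, effects: np.ndarray, h2: float, residual_sd: float
) -> np.ndarray:
    """Scale ``dosages @ effects`` so var(g) / (var(g) + residual_sd^2) == h2."""
    g = dosages @ effects
    g = g - g.mean()
    sd = g.std()
    if sd == 0 or h2 == 0:
        return np.zeros_like(g)
    target_sd = np.sqrt(h2 / (1.0 - h2)) * residual_sd
    return g * (target_sd / sd)


def simulate_expression(
    probs: GenotypeProbs,
    spec: ArchitectureSpec,
    covariates: pd.DataFrame | None = None,
    seed: int | None = None,
    n_shared_samples: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate latent expression for cell types A and B plus truth tables.

    Returns ``(expr_a, expr_b, truth)`` where the expression frames are
    genes x samples (cell type A restricted to the donor subset shared with
    the progenitor assay) and ``truth`` holds the planted-eQTL table, the
    mediator record, and gene annotations in Mbp.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    samples = probs.samples
    if covariates is None:
        covariates = simulate_covariates(samples, seed=int(rng.integers(2**31)))
    n_shared = len(samples) if n_shared_samples is None else n_shared_samples
    samples_a = samples[:n_shared]

    markers = probs.gmap.markers
    sd = spec.residual_sd
    sex = covariates.loc[samples, "sex"].to_numpy(float)
    batch = covariates.loc[samples, "batch"].to_numpy()
    batch_levels = np.unique(batch)

    def covariate_term() -> np.ndarray:
        beta_sex = rng.normal(0.0, spec.sex_effect_sd)
        shifts = rng.normal(0.0, spec.batch_effect_sd, size=len(batch_levels))
        level_shift = dict(zip(batch_levels, shifts))
        return beta_sex * sex + np.array([level_shift[b] for b in batch])

    rows_a: dict[str, np.ndarray] = {}
    rows_b: dict[str, np.ndarray] = {}
    truth_rows = []
    annot_rows = []
    genetic_rows: dict[str, np.ndarray] = {}  # planted genetic components, for audits

    def annotate(gene: str, marker: str | None, chrom: str | None = None, mbp: float | None = None):
        if marker is not None:
            row = markers.iloc[probs.gmap.marker_index(marker)]
            chrom, mbp = str(row["chrom"]), float(row["Mbp"])
        # 0.2 Mbp gene body centred on the stated midpoint
        annot_rows.append((gene, chrom, max(mbp - 0.1, 0.0), mbp + 0.1))

    def add_gene(gene: str, values: np.ndarray, cell_types: tuple[str, ...]) -> None:
        if "A" in cell_types:
            rows_a[gene] = values[: len(samples_a)]
        if "B" in cell_types:
            rows_b[gene] = values

    # --- local eQTL genes ---------------------------------------------------
    for eq in spec.local_eqtl:
        dos = probs.at_marker(eq.marker)
        g = _scaled_genetic_term(dos, eq.effects, eq.h2, sd)
        genetic_rows[eq.gene] = g
        latent = g + covariate_term() + rng.normal(0.0, sd, size=len(samples))
        add_gene(eq.gene, latent, eq.cell_types)
        annotate(eq.gene, eq.marker)
        row = markers.iloc[probs.gmap.marker_index(eq.marker)]
        for ct in eq.cell_types:
            truth_rows.append(
                (eq.gene, ct, "local", eq.marker, str(row["chrom"]), eq.h2, np.nan)
            )

    mediator_latent = None
    hs = spec.hotspot
    if hs is not None:
        # --- mediator: local eQTL with the partition effect pattern ---------
        dos = probs.at_marker(hs.marker)
        g = _scaled_genetic_term(dos, hs.partition_effects, hs.mediator_h2, sd)
        genetic_rows[hs.mediator_gene] = g
        mediator_latent = g + covariate_term() + rng.normal(0.0, sd, size=len(samples))
        ct = ("A",) if hs.mediator_cell_type == "A" else ("B",)
        add_gene(hs.mediator_gene, mediator_latent, ct)
        annotate(hs.mediator_gene, hs.marker)
        hs_row = markers.iloc[probs.gmap.marker_index(hs.marker)]
        truth_rows.append(
            (
                hs.mediator_gene,
                hs.mediator_cell_type,
                "mediator",
                hs.marker,
                str(hs_row["chrom"]),
                hs.mediator_h2,
                np.nan,
            )
        )

        # --- decoy local genes at the hotspot marker (not mediating) --------
        for k in range(hs.n_decoys):
            gname = f"decoy{k + 1:02d}"
            gd = _scaled_genetic_term(dos, hs.partition_effects, hs.decoy_h2, sd)
            latent = gd + covariate_term() + rng.normal(0.0, sd, size=len(samples))
            add_gene(gname, latent, ("A", "B"))
            annotate(gname, hs.marker)
            for ct2 in ("A", "B"):
                truth_rows.append(
                    (gname, ct2, "decoy_local", hs.marker, str(hs_row["chrom"]), hs.decoy_h2, np.nan)
                )

        # --- targets: mediator chain, no direct genotype term ----------------
        med_std = (mediator_latent - mediator_latent.mean()) / mediator_latent.std()
        other_chroms = [c for c in probs.gmap.chromosomes if c != str(hs_row["chrom"])] or [
            str(hs_row["chrom"])
        ]
        for k, (tg, slope) in enumerate(zip(hs.target_genes, hs.slopes)):
            latent = slope * med_std + covariate_term() + rng.normal(0.0, sd, size=len(samples))
            add_gene(tg, latent, ("B",))
            chrom = other_chroms[k % len(other_chroms)]
            sub = probs.gmap.markers[probs.gmap.markers["chrom"].astype(str) == chrom]
            mbp = float(sub["Mbp"].iloc[(10 + k * 7) % len(sub)])
            annotate(tg, None, chrom, mbp)
            truth_rows.append((tg, "B", "hotspot_target", hs.marker, str(hs_row["chrom"]), np.nan, slope))

    # --- unregulated background genes ----------------------------------------
    n_chr = len(probs.gmap.chromosomes)
    for k in range(spec.n_background_genes):
        for ct, rows in (("A", rows_a), ("B", rows_b)):
            gname = f"bg{ct}{k + 1:04d}"
            latent = covariate_term() + rng.normal(0.0, sd, size=len(samples))
            values = latent[: len(samples_a)] if ct == "A" else latent
            rows[gname] = values
            chrom = probs.gmap.chromosomes[int(rng.integers(n_chr))]
            sub = markers[markers["chrom"].astype(str) == chrom]
            mbp = float(sub["Mbp"].iloc[int(rng.integers(len(sub)))])
            annot_rows.append((gname, chrom, max(mbp - 0.1, 0.0), mbp + 0.1))

    expr_a = pd.DataFrame(rows_a, index=pd.Index(samples_a, name="sample")).T
    expr_b = pd.DataFrame(rows_b, index=pd.Index(samples, name="sample")).T
    truth = {
        "eqtl": pd.DataFrame(
            truth_rows,
            columns=["gene", "cell_type", "kind", "marker", "chrom", "h2", "slope"],
        ),
        "annotations": pd.DataFrame(
            annot_rows, columns=["gene", "chrom", "start", "end"]
        ).drop_duplicates(subset="gene"),
        "covariates": covariates,
        "genetic": pd.DataFrame(genetic_rows, index=pd.Index(samples, name="sample")).T,
        "mediator_latent": (
            pd.Series(mediator_latent, index=samples, name="mediator_latent")
            if mediator_latent is not None
            else None
        ),
    }
    return expr_a, expr_b, truth


def latent_to_counts(
    latent: pd.DataFrame,
    dispersion: float = 2.0,
    library_sizes: np.ndarray | None = None,
    library_size_range: tuple[float, float] = (1e6, 3e6),
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial read counts from latent (log-scale) expression.

    The mean model is ``mu_gs = L_s * exp(latent_gs) / n_genes`` — an
    exponential link, so latent values act multiplicatively — with
    gamma-Poisson (negative binomial) noise of shape ``dispersion``:
    ``var = mu + mu^2 / dispersion``.  Large dispersion approaches Poisson.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    n_genes, n_samples = latent.shape
    if library_sizes is None:
        library_sizes = rng.uniform(*library_size_range, size=n_samples)
    library_sizes = np.asarray(library_sizes, dtype=float)
    mu = np.exp(latent.to_numpy(float)) * (library_sizes / n_genes)[None, :]
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    counts[pos] = rng.negative_binomial(dispersion, p)
    return pd.DataFrame(counts, index=latent.index, columns=latent.columns)


def simulate_dataset(
    gmap: GenomeMap | None = None,
    n_samples: int = 186,
    n_shared_samples: int = 127,
    spec: ArchitectureSpec | None = None,
    recomb_rate: float = 0.2,
    blur_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """One-call generator: map, mosaics, probabilities, expression, truth.

    Defaults reproduce the study conditions end-to-end: 186 lines in the
    derived cell type, a 127-donor intersection with the progenitor cell type,
    40 shared local eQTL at heritability 0.5 and one mediated hotspot with 30
    targets on a 4:4 founder split.
    """
    gmap = gmap if gmap is not None else default_map()
    ss = np.random.SeedSequence(seed)
    s_mosaic, s_blur, s_cov, s_expr = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    if spec is None:
        spec = default_architecture(gmap, seed=seed)
    mosaics = simulate_mosaics(gmap, n_samples, recomb_rate=recomb_rate, seed=s_mosaic)
    probs = mosaics_to_probs(mosaics, gmap, blur_sd=blur_sd, seed=s_blur)
    covariates = simulate_covariates(probs.samples, seed=s_cov)
    expr_a, expr_b, truth = simulate_expression(
        probs, spec, covariates, seed=s_expr, n_shared_samples=n_shared_samples
    )
    return {
        "gmap": gmap,
        "mosaics": mosaics,
        "probs": probs,
        "covariates": covariates,
        "expr_a": expr_a,
        "expr_b": expr_b,
        "truth": truth,
        "spec": spec,
    }
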
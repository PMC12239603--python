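# Methods

`mosaicqtl` maps expression QTL in a multiparent (8-founder) mouse
population across two donor-matched cell types, detects distant-eQTL
hotspots, and ranks candidate mediator genes within and across cell types.
Because full-scale data from such a population are large and proprietary to
each study, the package ships a synthetic-data generator that plants a known
genetic architecture; every downstream claim the test suite makes is checked
against that planted truth.

## Synthetic genomes

Each simulated genome is a diploid mosaic of 8 founder haplotypes. Per
haplotype and chromosome, the founder of origin follows a Markov process
along the genetic map: a uniform founder at the chromosome start, crossover
breakpoints from an exponential inter-arrival process, and a uniform switch
to one of the other 7 founders at each breakpoint. Breeding is not simulated
generationally; the mosaic is a generative stand-in whose only job is to
give the downstream mathematics realistic dosage structure and LD decay.

The crossover density default is 0.2 crossovers/cM (mean founder-segment
length 5 cM). This matches the segment lengths of an outbred stock after
roughly 20 generations of random intercrossing and is what sets the mapping
resolution of the scans: with much longer segments, peak locations of
genes sharing one causal locus scatter over tens of cM and no 1 cM-window
hotspot is detectable, while local peaks drift outside the ±10 Mbp
local-classification window.

Founder dosages at a marker are haplotype counts / 2; optional Gaussian
blurring (clip at zero, renormalise to sum to one) emulates uncertainty in
probabilistic ancestry inference. The genetic map is synthetic: by default
5 chromosomes x 100 cM with 200 evenly spaced markers each and a fixed
2 Mbp/cM conversion (a 20-chromosome preset is available). Both coordinate
systems are carried throughout because hotspot windows are genetic (cM)
while local/distant classification is physical (Mbp).

## Planted expression architecture

Defaults mirror the study design the generator emulates: 186 lines with
expression in the derived cell type (B), the first 127 of which also carry
expression in the progenitor cell type (A); 40 local eQTL shared between
cell types at QTL heritability 0.5; one hotspot whose signal flows entirely
through a mediator gene.

* **Local eQTL** — latent expression = (founder dosage · effect vector),
  rescaled so the genetic fraction of (genetic + residual) variance equals
  the requested heritability, plus covariate effects and unit-SD Gaussian
  noise.
* **Hotspot** — the mediator carries a local eQTL at the hotspot marker
  whose founder effects are +1/-1 over the two sides of a 4:4 founder
  partition. Each of the 30 targets is `slope x standardised mediator +
  noise`, with *no* direct genotype term; the default slope sqrt(2) gives a
  mediation signal-to-noise ratio of 2. The linear mediator-target link is a
  modelling choice: the generative relationship behind real hotspots is
  unknown, and everything downstream (LOD drops, partial correlations) is
  interpreted relative to this linear truth model.
* **Decoys** — a few genes receive a local eQTL at the hotspot marker with
  the same 4:4 pattern but independent noise: they share the QTL without
  mediating it, and exist to verify that mediation ranks them below the true
  mediator.
* **Covariates and noise** — balanced binary sex and a 3-level batch, with
  per-gene coefficients drawn at SD 0.3; negative-binomial counts
  (dispersion 2, exponential link `mu = L_s * exp(latent) / n_genes`,
  library sizes uniform in 1-3 million) sit on top of the latent values to
  exercise the normalisation chain.

What the generator does **not** emulate: recombination hotspots,
X-inactivation, imprinting, gene-length effects (so "TPM" is a length-free
counts-per-million proxy), read-level errors, and any nonlinear or
multi-mediator hotspot architecture. Passing tests therefore demonstrate
correctness of the analysis machinery under a known linear architecture,
not robustness to every failure mode of real RNA-seq.

## Preprocessing

Filtering keeps genes with median TPM-like abundance >= 0.5 that are zero in
at most half the samples. Upper-quartile normalisation divides each sample
by the 75th percentile of its nonzero counts and rescales by the geometric
mean of those percentiles (the reference scale is a convention; geometric
mean keeps output on a counts-like scale). Batch correction equalises
per-gene within-level means and SDs (location-scale); it matches
empirical-Bayes correction on balanced designs but applies no cross-gene
shrinkage — a deliberate simplification. rankZ maps each gene to
Phi^-1((rank - 0.5)/n) with average ranks for ties; the 0.5 offset is one of
several common conventions and is idempotent on tie-free data.

Sample identity is audited two ways: genotype-dosage correlation matching
across assays (a sample is flagged when its best-correlated partner is not
the one sharing its label) and Spearman correlation of donor-matched
transcriptomes across cell types. Differential expression between cell
types uses the two-sided Wilcoxon rank-sum test (exact for group sizes
<= 25, normal approximation with tie correction otherwise),
Benjamini-Hochberg adjustment, and log2 fold change of group means; labels
require adjusted p < 0.05 and |log2FC| > 2.

## Genome scans

The model for a phenotype y is `y = Xb + g + e` with `g ~ N(0, Vg K)` and
`e ~ N(0, Ve I)`. Kinship is `K = (1/M) sum_m P_m P_m^T` over founder-dosage
slices; scans use leave-one-chromosome-out (LOCO) kinship, heritability the
full matrix. Null variance components are estimated once per phenotype per
chromosome (profile likelihood over h2 = Vg/(Vg+Ve) on the kinship
eigenbasis, 1-D bounded optimisation, ML for scan nulls and REML for
reported heritabilities — both available behind a flag) and reused at every
marker: the standard scan approximation, which also makes permutations
cheap. At each marker the data are rotated and whitened, and the design
[8 founder dosages + covariates] is solved through the pseudoinverse of the
normal equations — the dosage columns sum to one, absorbing the intercept,
and can be collinear where a founder is locally absent.
`LOD = (n/2) log10(RSS_null/RSS_marker)`, floored at zero.

Genome-wide significance permutes the sample index of the genotype array,
keeping the phenotype-covariate pairing intact; maxima are pooled across
phenotypes and the alpha threshold is the (1 - alpha) quantile. Permutations
reuse each phenotype's null variance components (configurable). FDR uses
Storey's q-values with the bootstrap pi0 estimator (lambda grid 0.05-0.90,
100 bootstrap draws). Peaks are the per-gene per-chromosome LOD maxima above
threshold; a peak is *local* when it lies on the gene's chromosome within
±10 Mbp (inclusive) of the gene midpoint. Founder allele effects at a peak
are BLUPs: the 8 effects are treated as random with a common variance,
variances estimated by ML on the whitened model, and the shrunken effects
centred to sum to zero.

## Hotspots and eigengenes

Significant distant peaks are counted in 1 cM windows shifted by 0.25 cM
(half-open in cM, so interior peaks land in exactly 4 windows). The count
threshold is the (1 - 0.005) quantile of window counts, never below one
peak; bins at or above it merge when they overlap or abut, and merged
intervals need more than 20 significant members (configurable) to be
reported. Only the significant-member gate is enforced; the suggestive-count
is descriptive. Targets are genes whose suggestive distant peak falls inside
the interval. The eigengene is PC1 of the targets' rankZ expression
(stage chosen here; genes centred first), sign-oriented to correlate
positively with mean target expression, and is mapped like any phenotype.

## Cross-cell-type sharing

An eQTL of the focal cell type is *shared* when the comparison cell type
(peaks taken at a relaxed LOD threshold) has a peak for the same gene on the
same chromosome within 5 Mbp whose 8-founder BLUP vector correlates with the
focal one at BH-adjusted p < 0.1 (Pearson on 8 points, two-sided; the
estimator and the adjustment method are conventions, both configurable).
The closest qualifying peak wins, ties broken by LOD. Significant negative
correlations still count as shared and are labelled "opposing", since loci
with inverted allele effects are still the same locus. Genes not expressed
in the comparison cell type are reported separately.

## Mediation and partial correlation

For each candidate mediator, the base LOD (target ~ peak dosages +
covariates) and mediated LOD (same model + mediator covariate) are computed
by ordinary least squares **on the identical complete-case subset** of that
mediator — the double-LOD-difference construction, which collapses to the
plain difference when nothing is missing and prevents missing values from
masquerading as mediation. OLS at the single peak marker keeps a
genome-wide mediator scan to a few matrix products (a kinship-whitened
variant would be the obvious extension); the LOD drop is invariant to affine
transforms of the mediator, and residual sums of squares are floored
relative to the phenotype scale so a mediator identical to the target yields
mediated LOD 0 rather than numerical noise.

Significance scales the mediated LODs genome-wide: every expressed gene acts
as its own null mediator and a candidate is flagged when its mediated LOD
falls more than 4 SDs below the null mean. Standardisation uses moment
estimates (mean/SD) by default: a rank-based normal-score variant is
implemented, but over m candidates rank-normal scores are bounded near
Phi^-1(1 - 0.5/m) (about 3.9 at m = 12,000), which makes a 4-SD rule
essentially unattainable by construction — the moment version is therefore
the default and the rank version is opt-in. Reported candidates must have
their gene midpoint within ±10 Mbp of the QTL peak.

Partial correlation corroborates candidates: samples are classified
Ref/Het/Alt by summing dosages over the alt side of the 4:4 founder
partition (cutpoints 0.25/0.75 on the alt dosage, a rule needed because
blurred dosages are continuous), both mediator and target are residualised
on the additive 0/1/2 class coding (a two-indicator genotypic coding is
available; the choice is a convention), and the residual Pearson correlation
is tested at n - 3 degrees of freedom with BH adjustment across candidates
near the peak.

## Numerical and scale choices

Desk-scale defaults keep the full pipeline around half a minute and the test
suite within minutes: 5 chromosomes x 200 markers, 186 samples, ~270
expressed genes per cell type, 200 pooled genotype permutations for
thresholds, recovery claims evaluated over 20 simulation seeds. These sizes
are the package's chosen operating point for synthetic validation; all of
them are configurable upward (20-chromosome map preset, arbitrary gene and
permutation counts). Tolerances: probability rows sum to 1 within 1e-8;
zero-kinship scans match a brute-force least-squares oracle within 1e-6;
LOD is invariant to affine phenotype transforms within 1e-8. Eigenvalues of
kinship matrices are clipped at zero; a likelihood flat in h2 (e.g. K = I)
returns h2 = 0 with an explicit flag rather than an arbitrary interior
point.

## Known limitations

Batch correction is location-scale only; the mediation models ignore
kinship at the peak marker by default; one peak per gene per chromosome (no
multi-QTL dissection); no interaction scans or X-specific covariate
handling; no formal causal-model selection or colocalisation posteriors —
mediation ranks candidates, it does not prove causality, and a partial
correlation does not establish a direct regulatory interaction.
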
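# Methods

This note records the models, numerical choices and deliberate
simplifications behind `doeqtl`, in the order the pipeline runs.

## Synthetic Diversity Outbred data

The generator is a generative twin of the analysis model: everything the
pipeline estimates is planted with known ground truth.

**Genome and mosaics.**  Marker maps place markers on an even grid per
chromosome with a fixed 0.5 cM/Mb conversion (cM = bp · 5e-7); a single
documented constant keeps bp and cM maps mutually invertible.  Each
sample carries two chromatids per chromosome; a chromatid is split by a
Poisson number of breakpoints (default density 30 crossovers/Morgan)
placed uniformly in genetic distance, each segment labelled with one of
the eight founders uniformly at random.  This reproduces the fine mosaic
block structure accumulated over ~20 DO outbreeding generations without
modelling the pedigree itself: blocks average ~3.3 cM at the default
density, and the expected founder dosage is uniform at 1/8.  Haplotype-
probability uncertainty is modelled as a mixture with the uniform simplex,
`p ← (1−α)p + α/8`, the simplest perturbation that preserves the simplex
invariant.  Note that this blur is an affine map of the probability
vector, so it leaves Pearson correlations between a sample's two
reconstructions at 1; it degrades assignment margins, not matched-pair
correlations.

**Expression.**  Per gene, `y = sex·β_s + gen·β_gen + q + γ + ε` where
`q` is the founder-probability dosage of the causal marker times the
8-allele effect vector (mean-centered; the intercept absorbs the mean,
matching the scan's 7-free-column identifiability convention), `γ` is a
draw from `MVN(0, K)` with `K` the realized kinship of the simulated
probabilities, and `ε ~ N(0, noise_sd²)`.  The QTL and polygenic
components are rescaled so their *realized* sample-variance fractions
equal the requested `qtl_var_frac` and `h2_polygenic` exactly per draw;
total variance is `noise_sd²/(1 − v_q − h²)`.  The rescaled effect
vectors are recorded as the recovery truth.

**Counts.**  Latent log2 abundances become negative-binomial counts with
per-sample mean `libsize · 2^y / Σ 2^y` and dispersion φ (gamma-Poisson;
φ = 0 degenerates to Poisson); library sizes are lognormal with a given
mean and CV.  This exists so TMM/logCPM can be tested against a known
latent matrix, not to model sequencing artifacts.

**Corruptions.**  Choroid-plexus-like contamination adds
`λ_i · loading_g` with `λ_i ~ |N(0, λ_sd)|`, the marker-gene analogs of
Kl and Ttr receiving a large loading.  Sex-chromosome aneuploidies shift
X-linked genes additively in log2 space (X0 female: −1, one copy instead
of two; XXY male: +log2(1.5) on X and a retained Y); the magnitudes are
configurable conventions, not literature estimates — no published values
were available to calibrate them.  Sample swaps apply disjoint
transpositions to expression row labels only, and the permutation is
exported so the RNA-side haplotype reconstruction can be permuted
identically.

**What the generator does not emulate:** pedigree-accurate DO breeding
(no linkage between relatives beyond the realized kinship of the drawn
mosaics), X-specific inheritance, GC/length biases, batch structure, or
count-level contamination.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real striatal RNA-seq.

## Preprocessing

Transcript counts are summed to genes; TMM factors follow the published
trimmed-mean-of-M-values algorithm exactly (reference sample = closest
75th-percentile count fraction to the mean; double trim of 30% on M and
5% on A; inverse approximate-binomial-variance weights; factors rescaled
to geometric mean 1) and were cross-checked against the reference
implementation during development.  The log transform is the voom logCPM,
`log2((count + 0.5)/(libsize·factor + 1)·1e6)`, *without* voom's
per-observation precision weights: the downstream scan is a homoscedastic
Gaussian model, so only the transform is mirrored.

Aneuploidy flags use per-sample mean X/Y expression with robust z-scores
(median/MAD, consistency constant 1.4826) within annotated sex; the
default threshold k = 4 is a design choice.  Contamination scores are the
mean of the log-scale marker genes; remediation regresses every gene on
the score and keeps residuals (a config switch instead carries the score
into the scan covariates — both treatments fit the same linear model).

Mixup repair computes Pearson correlations between flattened 8 × M
probability vectors of the RNA-derived and array-derived reconstructions
and solves the maximum-total-correlation bijection with the Hungarian
algorithm.  Exact ties are broken toward the annotated pairing (a 1e-9
diagonal nudge), conservative against spurious reassignment; assigned
pairs below r = 0.8 are flagged rather than silently accepted.

## The genome scan

Kinship is `K_ab = (1/M) Σ_m Σ_j p_amj p_bmj`; the LOCO matrix for a
chromosome excludes that chromosome's markers so the tested locus does
not absorb itself.  Per (gene, chromosome): the kinship is eigendecomposed
once and cached; the covariates-only null profile likelihood is maximized
over the variance ratio `hsq` by bounded Brent search on [0, 1−1e-6]
(xatol 1e-6, with an explicit boundary check at 0); `hsq` is then held
fixed across markers — the standard genome-scan approximation that makes
the scan one GLS fit per marker.  LOD is `(n/2)·log10(RSS0/RSS1)` on the
rotated, weighted data, clipped at 0; with no kinship (or K = I) this is
exactly the OLS LOD, which the tests verify to 1e-8.  Degenerate markers
(identical probabilities in every sample) score LOD 0 and are logged.

Decisions: one peak per chromosome per gene (the argmax above a strict
LOD > 7, ties to the smallest bp); the cis boundary is inclusive at
exactly 2,000,000 bp; the X chromosome is scanned with the autosomal
model; founder allele effects are reported as the 7 GLS coefficients plus
a zero for the reference founder, mean-centered for display.

**Heritability scale.**  The founder-probability kinship has a diagonal
near 0.5 (it is a probability inner product, not a standardized GRM), so
the raw model-scale ratio `hsq` is not comparable with a realized variance
fraction.  `heritability()` therefore converts the MLE to the observable
scale via the kinship's variance-contribution factor
`c = mean(diag K) − mean(K)`: the reported value is `hsq·c/(hsq·c + 1 −
hsq)`, the fraction of trait variance the genetic random effect
contributes in this population.  Under the overall (non-LOCO) kinship
this total includes any planted QTL's contribution.

**SNP association** collapses founder probabilities into SNP dosages with
an 8-bit strain distribution pattern, `d_i = Σ_j p_ij(pos)·allele_j`,
with probabilities linearly interpolated in bp between flanking markers
(clamped at chromosome ends); monomorphic patterns are rejected.  The
scan is a 1-df GLS fit with the same LOD definition.

## Mediation

Mediation is evaluated at the single peak marker (the viewer's
click-the-peak behaviour), not as a genome re-scan.  For each candidate
mediator the null and marker models are refit with the mediator appended
to the covariates; `hsq` is re-estimated under each augmented null because
a mediator can absorb polygenic variance, and this is cheap at
single-marker scale.  The statistic is the LOD drop (baseline −
conditioned); rows sort by descending drop with gene-id tie-break.
Collinear mediators are flagged, not fatal.  No Sobel tests or partial-
correlation variants are provided — the LOD drop is the whole method.  An
optional bp-window filter can restrict candidates to genes local to the
peak; it is off by default.

## Co-expression

**bicor** uses `u = (x − med)/(9·MAD)` with the raw (unscaled) median
absolute deviation, weights `(1 − u²)²` inside the unit interval, and the
normalized inner product of the weighted centered vectors.  The reference
implementation's `maxPOutliers` side-constraint is not implemented — a
documented divergence.  Zero-MAD variables fall back to Pearson
standardization for pairs involving them (logged); constant vectors yield
NaN with a warning.

**Signed network.**  Adjacency `((1 + bicor)/2)^power`, diagonal zero.
The scale-free fit bins connectivities into 10 equal-width bins and
regresses log10 frequency on log10 bin-mean connectivity; the signed R²
is `−sign(slope)·R²`.  Soft-threshold selection takes the lowest power
reaching R² ≥ 0.9.  Module detection computes the topological overlap
matrix `TOM_ij = ((A²)_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` and applies
average-linkage clustering of 1 − TOM with a *static* height cut (exposed
as `cut_height`, default 0.99) and a 30-gene minimum size — a documented
simplification of the dynamic hybrid tree cut, adequate because the
deliverable is the gene sets, not dendrogram fidelity.  The static cut
interacts with the power: at signed-network powers (≥ ~10) background TOM
similarity stays above the 0.99 dissimilarity cut, so independent genes
remain unassigned while planted modules merge; at low powers a lower cut
is needed.  Modules are labelled 1..N by decreasing size, 0 = unassigned.

**Paraclique.**  The graph has an edge iff |bicor| ≥ 0.5 (unsigned, as
distinct from the signed module network).  Extraction repeats: exact
maximum clique (Bron–Kerbosch with pivoting, lexicographic tie-break;
graphs beyond a configurable vertex bound are rejected with advice to
pre-filter rather than silently degrading to a heuristic); glom-factor
accretion; emit if the result has ≥ 10 members; remove members.
Accretion admits vertices *one at a time* — the best-connected outside
vertex adjacent to at least `⌈(1−glom)·|P|⌉` current members, re-testing
after each admission.  Simultaneous per-round admission was considered
and rejected: two vertices admitted in the same round need not be
adjacent to each other, which can push the emitted set's density below
1 − glom; with sequential admission a counting argument over admissions
guarantees density ≥ 1 − glom, and the extractor asserts it.  The
alternative missed-edge-count reading of the glom factor
(`|P| − ⌊glom·|P|⌋`) is available as `glom_rule="missed_edges"`.

## Problem sizes and calibration checks

The bundled experiments run at desk scale, chosen to make every recovery
statistically crisp while keeping the whole suite to a few minutes:
genome of 3 chromosomes × 50 markers (2.04 Mb spacing), cohorts of
100–400 samples, 100–200 genes per experiment, 100 mediation chains with
50 decoys, 500 random graphs for the paraclique oracle, and a 48-sample
end-to-end pipeline run twice for byte-identity.  Null genes in the
false-positive check carry neither a QTL nor a polygenic term: on a
3-chromosome genome a polygenic background puts ~1/3 of its variance on
each chromosome, and the LOCO scan *correctly* reports that as linkage —
only pure-noise genes measure type-I calibration.  Full-cohort quantities
from real data (tens of thousands of genes, 110k markers) are out of
desk-scale reach and are not asserted anywhere.

## Known limitations

- The generator's realized kinship comes from one draw of mosaics; very
  small cohorts can have poorly conditioned K (the eigenvalue clip at 0
  guards the decomposition).
- `hsq` held fixed across markers slightly understates LOD at very strong
  loci relative to per-marker variance re-estimation; this matches
  standard genome-scan practice.
- The static module cut is not the dynamic hybrid tree cut; on real data
  with nested module structure the two can differ materially.
- bicor without `maxPOutliers` can down-weight heavy asymmetric tails
  more aggressively than the reference implementation.
- SNP dosage interpolation is linear in bp; recombination-aware
  interpolation in cM would differ on sparse maps.
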
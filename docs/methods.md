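# Methods

`lymphsig` analyses cohorts of somatic single-nucleotide variants (SNVs)
from indolent B-cell lymphomas — follicular lymphoma (FL) and chronic
lymphocytic leukemia (CLL) are the motivating diseases — for the
footprint of activation-induced cytidine deaminase (AID) and the
DNA-repair processes that resolve its lesions. This note documents the
models, the tunable parameters and their defaults, what the synthetic
cohort generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Mutation categories

Every SNV is assigned to one of 96 categories: six pyrimidine-anchored
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16
combinations of 5′ and 3′ flanking bases. When the reference base is a
purine, the substitution and both flanks are complemented and the flanks
swap sides, so each mutated base *pair* is counted once regardless of
the reported strand. The category order is substitution-major, flanks
lexicographic — the layout shared by published SBS catalogs, enforced by
a header check so that user-supplied tables (e.g. a COSMIC v3.2 SBS TSV)
align row-for-row. Records whose context cannot be read (contig edge,
ambiguous base) are tallied and skipped, never silently dropped; a
VCF/genome reference-base disagreement raises, since it indicates the
wrong genome build.

## AID motif tracing

Three motifs are matched on both strands: WRCY with a mutated C and
substitutions {C>T, C>G} (canonical AID), WA with a mutated A and
substitution {A>C} (non-canonical, polymerase-η-associated), and RCG
with a mutated C and substitution {C>T} (CpG-overlapping AID targeting).
On the reverse strand WRCY appears as RGYW on the forward sequence with
a mutated G; the matcher checks the forward window and the
reverse-complement window explicitly. Whether the WRCY substitution set
should be exactly {C>T, C>G} or any C>N is reported ambiguously in the
literature; {C>T, C>G} is the default and the set is configurable per
motif.

Two counting modes are always reported. In *exclusive* mode each
mutation is attributed to at most one motif by the priority
WRCY > RCG > WA (most specific first), so per-motif fractions add up to
the combined motif fraction — the convention under which published
per-motif percentages sum to the published combined percentage. In
*overlapping* mode a mutation counts once per motif matched. For the
three default motifs the modes coincide (their mutated-base/substitution
requirements are mutually exclusive), but custom motif sets need not be.
Cohort motif fractions are compared by Pearson's chi-squared on the 2×2
motif/non-motif × cohort table, without continuity correction by
default.

## Signature extraction, matching, fitting

**Extraction.** The 96×S count matrix is factorized by non-negative
matrix factorization under the Poisson (generalized Kullback–Leibler)
objective with Lee–Seung multiplicative updates (counts are
Poisson-like; the objective is verified non-increasing every iteration).
Defaults: 1000 iterations maximum, relative-improvement tolerance 1e-8,
best of 3 random restarts per fit. For each candidate rank the per-sample
counts are bootstrap-resampled (multinomial, totals preserved; 50
resamples by default), each resample is factorized, and the pooled
replicate signatures are consensus-clustered: replicate solutions are
matched to running centroids by Hungarian assignment on cosine
similarity — each replicate contributes exactly one signature per
cluster — and centroids are re-estimated to convergence. The rank's
*stability* is the unweighted mean over clusters of the within-cluster
mean silhouette (cosine distance). The matching constraint is what makes
an overfit rank visible: its surplus cluster collects a different noise
direction from every replicate and drags the score down, whereas
unconstrained hierarchical clustering lets the noise replicates hide
inside tight clusters. The selected rank is the largest with stability
≥ 0.8 whose median reconstruction error improves on the smallest rank's;
if none qualifies, the most stable rank is taken. The stability
threshold and bootstrap count are not derived from any publication and
are configurable. Final signatures are the cluster medoids at the
selected rank, renormalized; exposures are re-fitted on the original
matrix by NNLS and column-normalized.

NMF recovers the generating cone, not necessarily its exact extreme
rays: an extracted signature can be a conic blend of the true ones while
reconstructing the data equally well. Recovery is therefore judged by
the NNLS composite (below), not by one-to-one cosine.

**Matching.** Each extracted signature is decomposed over a reference
catalog by non-negative least squares; weights are normalized,
components with weight ≥ 0.1 are reported, and the cosine between the
signature and its composite decides novelty at the 0.85 threshold — a
signature under 0.85 is flagged novel and (in the pipeline) joins the
fitting basis as extracted. The retention threshold 0.1 is a documented
choice; 0.85 is the standard novelty criterion for SBS signatures. An
exhaustive best-single-or-pair search (`pairwise=True`) is available for
reporting matches as explicit signature pairs instead of full-catalog
combinations.

**Fitting.** Per-sample relative exposures against a fixed basis follow
the deconstructSigs scheme: the 96-count column is normalized to
fractions, the weight vector is seeded with the single best-fitting
signature, and each signature's weight is refined in turn by a
golden-section line search on [0, 1] of the normalized squared error,
sweeping until the per-sweep improvement falls below the tolerance.
Weights below the 6% cutoff are zeroed and the rest renormalized. The
tolerance default is 1e-6 rather than the 1e-3 the original tool uses:
coordinate-wise golden-section descent at 1e-3 can stop ~1e-3 short of
the optimum, which is visible against a brute-force simplex grid search
(the test suite holds the fit to grid-search agreement within 1e-4).
The empty-start corner case motivated the seeding rule: from an all-zero
vector, every single-signature step can *increase* the normalized error
for well-mixed spectra, freezing the descent at zero.

## Chromatin compartments

Variants are labeled A (active) or B (inactive) by half-open interval
containment against a compartment BED; positions outside the track are
counted as unassigned. When only a dense intra-chromosomal Hi-C contact
matrix is available, a classical eigenvector caller substitutes:
observed/expected normalization by diagonal distance, Pearson
correlation matrix, leading eigenvector of the correlation, sign
oriented so the A side has the higher external activity score (gene
density or GC content), contiguous same-sign bins merged. Neural-network
compartment imputation is out of scope; the caller exists so the
pipeline never requires one.

Exposures are re-fitted independently per (sample, compartment) — the
reading of "contribution by compartment" adopted here — with a minimum
of 10 classified mutations per compartment to fit (below that the sample
is excluded from tests rather than fitted noisily). Compartment
differences are tested per signature with a two-sided *paired* Wilcoxon
signed-rank across samples (the same samples contribute both
compartments, making pairing the defensible choice; an unpaired
rank-sum is available), Bonferroni-corrected over the signatures tested
within one disease group.

**Compositional closure.** Exposure vectors live on the simplex, so a
planted shift +d on one signature necessarily shifts every other
signature by about −d·e_j/(1−e₁) in the same samples. A planted shift
can therefore never leave the remaining signatures exactly untouched;
what the method guarantees — and what the tests check — is (i) the
shifted signature is detected (adjusted p < 0.05 in ≥ 90% of
simulations at the default design) and (ii) under the null design with
no shift, all signatures stay non-significant in ≥ 90% of simulations
(type-I control). Requiring the unshifted signatures to stay
non-significant *in the shifted design* is infeasible for any noise
level: a normal-approximation power calculation gives detection ⇒
d ≥ 0.70σ and all-clear ⇒ d ≤ 0.46σ with a five-signature basis. The
same closure pattern appears in real cohorts, where signatures enriched
in one compartment are mirrored by others enriched in the opposite one.

## Cohort structure

The per-sample contribution matrix (rows on the simplex, Euclidean
distance by default, matching common practice for exposure matrices; a
centered log-ratio transform `clr_transform` is available for Aitchison
distances) is examined three ways:

* **Hopkins statistic** with the convention H = Σw/(Σu+Σw): w are
  nearest-neighbour distances among sampled real points, u are distances
  from uniform probes in the data's bounding box to real points, so
  H ≈ 0.5 indicates spatial randomness and H well below 0.5 indicates
  clusterable structure (a flag flips to the complementary convention).
  Sampling fraction 0.1 with a floor of 5 points; zero-width dimensions
  are dropped with a warning.
* **DIANA** divisive clustering (Kaufman–Rousseeuw): repeatedly split
  the cluster with the largest diameter, seeding the splinter with the
  point of maximal average dissimilarity and defecting points whose mean
  dissimilarity favours the splinter, largest margin first. Split
  heights are the diameters, which are non-increasing by construction;
  cutting replays the first k−1 splits. The cut level k is
  user-specified (default 3 in the pipeline); no automatic k selection
  is claimed.
* **Silhouette widths** computed directly from the distance matrix
  (singleton clusters score 0; k = 1 raises), and **PCA** (centered SVD)
  for inspection.

## DNA-repair pathways

Variants are mapped onto repair-gene intervals (a variant may hit
several overlapping genes; genes may belong to several of BER, MMR, FA,
DDR), each sample is flagged per pathway when it carries ≥ 1 variant in
a member gene, and prevalences are compared between the two cohorts by a
two-sided Fisher exact test under Benjamini–Hochberg correction across
pathways. The Fisher p follows the point-probability rule (sum of the
probabilities of all same-margin tables no more probable than the
observed one), computed by exact hypergeometric enumeration — the same
convention as mainstream statistics libraries, which serve as the
independent cross-check in the tests. Odds ratios apply the
Haldane–Anscombe 0.5 correction only when a zero cell would make them
undefined. Upset counts summarize samples per pathway combination.
Somatic novelty (germline/prior-biopsy subtraction) is assumed enforced
upstream in the input VCFs; an exclusion list of prior variants is
accepted. The bundled gene list is a synthetic stand-in with
field-typical member genes (UNG, POLE, FANCD2, TP53, ATM, HUS1, …) and
is user-replaceable.

At the planted design (prevalence 0.30 vs 0.03, 33 vs 30 samples) the
exact power of the two-sided Fisher test is 0.827 at α = 0.05; with BH
correction across the four default pathways detection drops to ≈ 0.73.
The detection property is therefore stated on the raw Fisher p (≥ 80%
power), with BH checked for its ordering guarantees.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
from a single seed, writing FASTA, per-sample VCF v4.2, BED (0-based
half-open) and TSV truth tables byte-identically across runs.

* **Genome**: i.i.d. bases at a configurable GC content (default 0.45),
  two 150 kb contigs by default — large enough that every 96 category
  has thousands of candidate sites.
* **Compartment track**: deterministic Bresenham tiling (10 kb tiles)
  alternating A/B with A share converging to `a_fraction` (default 0.5).
* **Signatures**: five concentrated presets — spontaneous-deamination
  (CpG C>T), near-flat, canonical-AID (C>T/C>G at WRC with pyrimidine 3′
  flank), non-canonical-AID (T>G/T>C with 3′ A/T, i.e. the WA motif on
  the purine strand, whose pyrimidine normalization places W on the 3′
  side), and MMR-failure (non-CpG C>T with pyrimidine 5′ flank); all
  pairwise cosines < 0.8.
* **Cohorts**: 33 FL-like and 30 CLL-like samples; per-sample mutation
  counts negative-binomial with mean 230 and size 20; per-sample
  exposures Dirichlet around the group means with concentration 50
  (sample-to-sample variation is what paired compartment tests and
  clustering operate on). The default generating trio is canonical-AID +
  spontaneous-deamination + MMR-failure — the three processes these
  lymphomas share — with FL-like AID-heavy and CLL-like
  deamination/repair-failure-heavy. A near-flat signature is deliberately
  not part of the default trio: at ~230 mutations per sample a flat
  spectrum is not reliably extractable (the bootstrap likelihood prefers
  splitting a concentrated signature instead), mirroring the well-known
  difficulty of extracting flat SBS5-like signatures de novo.
* **Mutation placement**: compartment by territory share, signature from
  the compartment-adjusted exposures, category from the signature, then
  a uniformly chosen genomic site whose (pyrimidine-normalized) context
  matches, with the mutated strand chosen uniformly; positions are
  unique per sample with re-draws capped at 1000. The compartment shift
  is injected on the log-odds scale (±shift/2 per side, renormalized),
  which keeps exposures valid simplex points at any magnitude; the
  default plants +1 log-odds of canonical-AID toward A in FL-like
  samples only.
* **Pathways**: 20 repair genes (2 kb each) placed deterministically and
  *excluded* from signature-mutation placement, so the planted pathway
  flags (per-sample Bernoulli at the configured prevalence, 1–2 variants
  per hit) round-trip exactly through the pathway-analysis module.
  Default prevalences: BER 0.30/0.03, FA 0.36/0.10, DDR 0.20/0.33, MMR
  0.10/0.10 (FL-like/CLL-like).
* **IG-like regions**: an arbitrary marked interval on the first contig
  for exercising localized (region-restricted) catalogs; no extra AID
  activity is planted there.
* **VAFs**: Beta-distributed, slightly lower in FL-like (7, 13) than
  CLL-like (9, 11).

What the generator does **not** emulate: sequencing noise and coverage,
indels/SVs/CNVs, germline contamination, transcription- or
replication-strand asymmetries, regional mutation-rate covariates
(chromatin marks beyond the binary A/B track), linkage between pathway
genotype and signature activity, and clonal structure in VAFs. Passing
tests therefore demonstrate that the statistical machinery recovers
planted structure under the model's own assumptions — not that the
pipeline is robust to artefacts of real sequencing data.

## Problem sizes and numerical choices

The default study (63 samples × ~230 mutations, ranks 1–6 × 50
bootstraps × 3 restarts) was chosen as the package's reference design;
a full pipeline run takes on the order of two minutes on one core, with
extraction dominating. Ties in DIANA splits resolve toward the
highest-index point (stable, since distances are deterministic);
golden-section searches run to an interval of 1e-9; TSV intermediates
are written with shortest round-trip float formatting and read back with
exact parsing, so re-running any stage from its persisted inputs is
bit-identical to the in-memory pipeline. All randomness flows from one
top-level seed through named NumPy substreams (genome, cohort, pathway
planting; per-rank streams inside extraction).

## Known limitations

* Rank selection reports stability for the ranks scanned; it cannot see
  signatures below the noise floor of the cohort size (flat signatures
  especially), and the extracted basis may be rotated within the
  generating cone (judge recovery by NNLS composite).
* The Hopkins statistic uses a bounding-box null, which is conservative
  for simplex-constrained data.
* The eigenvector compartment caller assumes a single chromosome-scale
  checkerboard; no sub-compartments, no TAD structure, and no .hic/.cool
  parsing.
* Exposure comparisons inherit the compositional caveats above; effects
  should be read jointly across signatures, not one at a time.
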
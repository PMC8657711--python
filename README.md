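# lymphsig

Mutational-signature analysis of indolent B-cell lymphoma cohorts, built
around the question of what activation-induced cytidine deaminase (AID)
does to these genomes and how DNA repair shapes the outcome.

AID physiologically hypermutates immunoglobulin genes in germinal-center
B cells, but it also hits off-target loci, preferring distinct sequence
motifs: canonical C>T/C>G changes at **WRCY**, non-canonical A>C
transversions at **WA**, and C>T transitions at **RCG** (IUPAC W = A/T,
R = A/G, Y = C/T). `lymphsig` takes per-sample somatic SNV VCFs, a
reference FASTA, an A/B chromatin-compartment BED and a reference
signature catalog, and runs the full analysis a lymphoma-genomics study
needs:

* **96-context catalogs** — every SNV classified, pyrimidine-normalized,
  as one of 6 substitution classes × 16 flank pairs; spectrum, CpG and
  transition/transversion (Ti/Tv) summaries; per-sample burden with
  two-group tests.
* **AID motif tracing** — per-cohort motif fractions in exclusive and
  overlapping counting modes, compared across cohorts by Pearson's
  chi-squared.
* **De novo signature extraction** — Poisson/KL NMF of the 96×S count
  matrix V ≈ W·H (W column-stochastic signatures, H exposures), with
  multinomial bootstrap resampling and a consensus-silhouette stability
  score per rank; the selected rank is the largest stable one.
* **Catalog matching** — each extracted signature decomposed over a
  reference catalog (COSMIC-style 96-row TSV) by non-negative least
  squares; cosine(signature, composite) < 0.85 flags a novel signature.
* **Exposure fitting** — deconstructSigs-style per-sample refitting
  against a fixed basis (golden-section coordinate descent, 6%
  contribution cutoff).
* **Chromatin integration** — variants annotated A/B, exposures
  re-fitted per compartment, per-signature paired Wilcoxon A-vs-B tests
  with Bonferroni correction; a classical eigenvector caller
  (observed/expected → correlation → leading eigenvector) builds the
  track from a dense Hi-C contact matrix when no BED is available.
* **Cohort structure** — Hopkins clustering-tendency statistic, DIANA
  divisive hierarchical clustering, silhouette widths, PCA.
* **DNA-repair pathways** — variants mapped to BER/MMR/FA/DDR gene sets,
  per-sample mutation flags, two-sided Fisher exact prevalence tests
  (exact hypergeometric enumeration) with Benjamini–Hochberg correction,
  and upset-style combination counts.
* **Synthetic cohort generator** — a fully self-contained study (genome,
  VCFs, compartment track, catalog, gene/pathway tables, truth tables)
  with planted group-specific exposures, a compartment-differential AID
  shift, and differential pathway prevalences, so the whole pipeline is
  testable without any restricted-access data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/` holds one short script per capability. Extraction on the
default synthetic cohort (63 samples, ~230 mutations each, three
generating signatures):

```bash
$ python examples/extract_signatures.py
rank selection (stability = consensus silhouette of bootstrap replicates):
 rank  stability  median_error
    1      1.000      5569.491
    2      0.988      4400.713
    3      0.860      4072.898
    4      0.464      3896.827
selected rank: 3

NNLS match of each de novo signature to the generating catalog:
signature  cosine  matched                                      components
      DN1   0.988     True   spontaneous-deamination-like+MMR-failure-like
      DN2   0.997     True   MMR-failure-like+spontaneous-deamination-like
      DN3   0.991     True canonical-AID-like+spontaneous-deamination-like

per-sample exposures refitted against the generating catalog: mean
absolute error vs truth = 0.027
```

Reading the numbers: reconstruction error always falls with rank, so
rank is chosen by *stability* — how reproducibly the same signatures
re-emerge across bootstrap resamples. Rank 3 is the largest rank above
the 0.8 stability threshold, matching the three planted processes; at
rank 4 the surplus signature chases noise and stability collapses to
0.46. Each extracted signature is explained by the generating catalog
(cosine ≥ 0.85 against its NNLS composite — extracted bases may be
blends within the catalog cone, which is why the composite, not a
one-to-one cosine, measures recovery), and refitted per-sample exposures
land within 0.027 of the planted values on average.

Motif tracing on the same cohort
(`python examples/trace_aid_motifs.py`):

```
FL-like: 7121 mutations, 33.6% at any AID motif
  WRCY   20.3%  (exclusive; overlapping 20.3%)
  WA      1.9%  (exclusive; overlapping 1.9%)
  RCG    11.4%  (exclusive; overlapping 11.4%)
CLL-like: 7013 mutations, 19.0% at any AID motif
motif fraction FL-like vs CLL-like: chi2 = 385.5, p = 7.87e-86
```

The FL-like cohort carries the larger planted canonical-AID exposure,
and the motif tracer sees it directly in sequence space.

## Command line

The same stages are available as a thin CLI:

```bash
lymphsig simulate --out cohort/ --seed 7      # synthetic study + run_config.yaml
lymphsig run --config cohort/run_config.yaml  # all stages, TSV outputs + manifest
lymphsig contexts|motifs|extract|fit|compartments|cluster|pathways|report \
    --config cohort/run_config.yaml           # any stage alone, same bytes
```

Every intermediate is plain TSV; re-running a stage from persisted
intermediates is bit-identical to the full pipeline. Exit codes: 0
success, 2 validation error, 3 stage failure.

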
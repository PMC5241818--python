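# Methods

This note documents the models and procedures implemented in
`dropcount`, the parameter choices that matter, what the synthetic
generators do and do not emulate, and the numerical decisions taken
where the design was genuinely open.

## Digital counting

**Barcode correction.** An observed barcode that matches the whitelist
is accepted as-is. Otherwise all whitelist barcodes at Hamming
distance exactly 1 are candidates; the observed barcode itself never
competes. For candidate *c* differing at position *i* with base
quality *q*, the likelihood that *c* was sequenced as the observation
is the error probability 10^(−q/10); the posterior is
prior(*c*) × likelihood, normalised over candidates. The prior is the
number of exact whitelist hits in the input plus one pseudocount, so
whitelist barcodes never observed exactly remain reachable (the
smoothing is our choice; the prior itself comes from the overall
barcode count distribution). Correction is accepted when the top
posterior reaches 0.975; exact posterior ties go to the
lexicographically first candidate.

**UMI validation.** A UMI is valid when every base quality is strictly
greater than 10 (Q10 ≈ 90% base-call accuracy), it contains no N, and
it is not a homopolymer. The per-base reading of "sequencing quality
score > 10" is the conservative interpretation and the testable one.

**UMI collapse.** Within one (barcode, gene) group a UMI is corrected
to a 1-Hamming neighbour with *strictly* more reads. All corrections
are computed against the pre-collapse read counts in a single pass —
no transitive chains — which guarantees termination and order
independence; ties leave both UMIs intact. When several neighbours
qualify, the most-read one wins, then lexical order.

**Duplicate marking and counting.** Exactly one record is retained per
distinct (barcode, UMI, gene) triple (first seen). The final matrix
uses only confidently mapped reads (MAPQ = 255 with a unique gene
assignment) with valid barcodes and UMIs. Reads with ambiguous gene
assignments are dropped; no multi-mapping rescue is attempted.

**Cell calling.** With an expected cell count *E*, let
*n* = max(1, round(0.01·E)) and *T* the total UMI count of the rank-*n*
barcode (descending order, ties by barcode lexical order). Barcodes
with totals strictly above 0.10·*T* are called cells. The rule is
deliberately simple — it has no ambient-RNA model — and the strictness
of both comparisons follows the definition as stated.

**Merging and downsampling.** Channels are merged by concatenating
matrices over identical gene lists (barcode collisions get "-1"/"-2"
suffixes); sequencing runs of one library are merged by counting
non-duplicate reads with a dedup key that ignores the run identifier.
Downsampling operates at molecule resolution: per cell a multivariate
hypergeometric draw without replacement over its gene counts, with the
retained total set to rate × cell total. Read-level downsampling is
only approximated this way: molecules are the only resolution the
matrix retains, a caveat that matters when comparing to read-depth
targets.

## Barnyard analytics

Barcodes from a mixed-species run get per-species UMI totals from the
species-tagged gene IDs. The significance cutoff for species X is the
1st percentile of the species-X totals among barcodes whose majority
species is X; a barcode significant in both species is a multiplet
candidate ("mixed"). Because same-species multiplets are invisible in
a two-species design, the inferred multiplet rate is twice the
observed mixed fraction — valid when the species are roughly equally
loaded, which is assumed, not enforced. The percentile is exposed as
a parameter because the definition ("top 1% of UMI counts considered
significant" vs "count > 1% of the species' count distribution")
admits two readings; we implement the distribution-percentile one.
Crosstalk for species A is the fraction of species-B UMIs summed over
pure species-A barcodes. Expected multiplet compositions multiply the
member clusters' relative sizes; the result is a co-encapsulation
probability up to a constant loading factor and is reported in
percent.

## Expression analysis

**Normalisation.** Counts are divided by the cell total and multiplied
by the median of cell totals, then transformed with ln(1 + x); the
pseudocount is the minimal fix for zeros under a natural-log recipe.
Genes are then standardised to mean 0, sd 1 across cells;
zero-variance genes are dropped and listed. Cells with zero totals
are dropped with a warning.

**Variable genes.** Dispersion = variance/mean is computed on
median-scaled (not log, not standardised) counts, where it is a
meaningful count-scale statistic. Genes are placed into 20
equal-frequency bins by mean expression (equal-width bins collapse
under skewed means); the normalised dispersion is
|d − median_bin(d)| / MAD_bin(d) with the raw MAD (no 1.4826 factor)
guarded by ε = 1e−12. Ranking ties break by gene ID, making the
selection invariant to input gene order. With exactly two genes per
bin every normalised dispersion equals 1 by construction and the
ranking degenerates to the tie-break; the bins should therefore be
kept well below half the gene count.

**Clustering.** PCA (50 components by default) runs on the
standardised matrix restricted to the top 1,000 variable genes;
k-means uses k-means++ with 10 restarts and a fixed seed, and the
within-cluster SSE is reported over a user-supplied k range as the
scree for choosing k. tSNE output, when requested, delegates to the
standard Barnes–Hut implementation and is decorative: no numerical
guarantees.

**Markers and classification.** The marker score of gene g in cluster
c is mean(g | cells in c) − median(g | pooled cells of other clusters)
on log-normalised values; the pooled-median reading is implemented and
the mean is available as an option. Cluster dendrograms use average
linkage on 1 − Pearson correlation between cluster mean vectors.
Classification against purified reference profiles takes, per cell,
the population with the highest Spearman correlation (average ranks
for ties) over the shared genes, then applies one round of subset
refinement: when the winner contains other populations (e.g. CD4+
helper contains the CD4+ subsets) and the runner-up is one of them,
the label moves to the runner-up. Cells with undefined correlations
are "unassigned".

**Profile comparison.** Two samples, downsampled to comparable depth
by the caller, are compared through per-gene means: Pearson r over
genes detected in either sample, and a list of genes whose mean ratio
reaches the fold threshold (default 2). Genes absent in the
denominator sample but present in the numerator count as upregulated;
an optional pseudocount (default 0) is available for noisy means.

## Genotype demultiplexing

**Model.** Cells come from K ∈ {1, 2} genomes. Genome k carries a
genotype g ∈ {R/R, R/A, A/A} at each SNV site; given genotype, the
alt-UMI count in a cell is Binomial(n = ref + alt, p) with p = ε, ½,
1 − ε and a fixed base error rate ε = 0.001. Sites with zero coverage
in a cell contribute nothing. Priors are uniform over the three
genotypes per site per genome and uniform over genome assignment; no
Dirichlet prior is placed on the mixture weight, so detection is gated
by the selection rule, not the prior.

**Inference.** A blocked Gibbs sampler alternates (i) sampling each
cell's genome given the genotype vectors and (ii) sampling each
genome's genotype at each site given its assigned cells. For K = 1
step (i) is vacuous and the genotype posteriors factor per site, so
the K = 1 "fit" is computed exactly in closed form. Defaults: 500
sweeps, 200 burn-in, 2 chains, all configurable. Label switching is
removed per chain with Stephens' decision-theoretic relabelling
(iteratively choosing per-iteration permutations that minimise the KL
divergence to the running average assignment probabilities, to a fixed
point; for two components this is a per-iteration swap flag). A
cell's assignment posterior is the frequency of its MAP genome across
the relabelled post-burn-in samples.

**Initialisation.** The default warm start ("misfit") seeds the second
genome with the 15% of cells worst explained by the pooled
single-genome MAP genotypes, measured as the gap to each cell's own
per-site-MAP log-likelihood — the Gibbs analogue of a split move.
A blocked sampler started from a random split has to nucleate the
minor mode through rare coordinated genotype flips and can stay in the
symmetric, unseparated state for arbitrarily long on unlucky datasets;
the warm start removes that failure while remaining self-limiting: the
seeded group flips a discriminating site's genotype only when its
alt-allele share clears roughly ε-driven odds (~10%), which a true
minor population of 3% of cells achieves (≈20% of the seed) and a 1%
population does not (≈7%), so spurious seeds dissolve back and the
detection floor of the method is preserved rather than papered over.
Random initialisation remains available.

**Chain pooling and model selection.** Chains are scored by their mean
complete-state log-likelihood after burn-in; chains trailing the best
by more than 200 nats sit in an inferior mode (in practice the
unseparated one, thousands of nats away) and are excluded before
pooling, which protects the posterior from being averaged with a stuck
chain. K = 2 is selected over K = 1 exactly when at least 90% of
cells have an assignment posterior strictly above 75%; otherwise the
mixture fraction is declared below the detection level. Genotype
overlap between two genotype sets is the percentage of shared sites
with equal MAP genotypes (an expected-dosage correlation is available
as an alternative reading of "average genotype" comparison but is off
by default).

**Cell-line SNV labelling.** For two-cell-line mixtures the simpler
path selects high-quality SNVs (call quality ≥ 100, ≥ 10 UMIs from
≥ 2 cells, indels ignored) observed exclusively in one group, scores
each cell by the fraction f of its enriched-SNV observations from
group B, and labels f < 0.2 as A, f > 0.8 as B, anything between as a
multiplet; the inferred multiplet rate again doubles the observed
fraction.

## Synthetic data

`simulate_reads` emulates the droplet read stream: distinct whitelist
barcodes per GEM, negative-binomial molecule totals per cell (the
dispersion default gives a ~35% coefficient of variation, matching
the overdispersion seen in cell-line data), population-specific gene
weights, optional doublets (a second cell in the GEM), ambient
molecules (drawn from the other species' pool in a two-species design
so that the measured crosstalk equals the configured fraction), PCR
duplicates, and per-base substitution errors on barcodes and UMIs.
Reads are Q30 throughout except at error positions, which carry Q20 —
high enough to pass UMI validation, low enough that the barcode
posterior path is exercised deterministically. True UMIs within one
(barcode, gene) group are kept at Hamming distance ≥ 2 so that at zero
error rate the counting pipeline reproduces the truth matrix exactly;
real data has no such guarantee, so the zero-noise round trip
validates bookkeeping, not robustness.

`simulate_two_donor_alleles` draws per-site alt allele frequencies
uniform on [0.1, 0.9], donor-1 genotypes from Hardy–Weinberg
proportions, and copies donor 1 at the configured IBS fraction of
sites (default 0.73, the between-individual genotype agreement
baseline; 0.98 corresponds to within-individual replicates). At
non-shared sites donor 2 is drawn conditioned to differ, so the
realised genotype agreement equals the configured IBS. Coverage is
sparse and skewed: 2,000 sites with lognormal(σ = 1) weights, a
Poisson number of covered sites per cell (mean 50), and 1 + Poisson
UMIs per covered site (mean 2, mostly 1–3). These match the observed
~50 filtered SNVs per cell at ~1–3 UMIs each; the site count and
weight shape are free choices emulating expression-driven SNV
coverage. The generator does not model doublets, allele-specific
expression, RNA editing, or variant-calling artefacts — the binomial
error model is exactly the fitted model, so recovery results here
measure the inference machinery, not model misspecification.

`simulate_expression_clusters` plants disjoint marker blocks
(effect size 8× over a lognormal baseline, Poisson counts) and emits
truth labels; it is a recovery fixture, not a realistic transcriptome
(no library-size variation beyond Poisson, no dropout model).

## Problem sizes and determinism

All stochastic components consume a `numpy` SeedSequence-derived
generator; identical seeds give bit-identical outputs, including the
Gibbs posteriors. The acceptance script and heavy tests run the
demultiplexer at its design point — 6,000 cells with ~50 covered sites
each (~300k covered cell-site entries) — where one two-chain K = 2 fit
takes roughly 10–15 s on one CPU; sweeps over seeds and mixing
fractions use 20–30 such fits. Unit tests use hundreds of cells and
complete in seconds.

## Known limitations

- The counting pipeline holds all records in memory; it targets
  synthetic and down-sampled inputs, not production BAM volumes.
- Cell calling implements only the rank/threshold rule; knee-point or
  ambient-model callers are out of scope.
- The demultiplexer supports K ≤ 2 and does not model doublet
  genotypes inside the mixture; doublets are handled only by the
  separate enriched-SNV labelling path.
- The ×2 multiplet correction assumes balanced species loading.
- tSNE coordinates are untested visual output by design.
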
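# dropcount

Digital counting and genotype demultiplexing for droplet-based 3′
single-cell RNA-seq.

Droplet platforms encapsulate single cells in emulsion droplets (GEMs)
together with a barcoded gel bead: every cDNA from one droplet shares a
14 nt cell barcode drawn from a designed whitelist, and every molecule
carries a 10 nt unique molecular identifier (UMI). `dropcount`
implements the computational core that turns aligned reads from such a
library into biology:

- **Counting** (`barcode_umi`): posterior-probability barcode
  correction against the whitelist, UMI validation (per-base quality
  and homopolymer rules), directional UMI collapse within each
  (barcode, gene) group, PCR-duplicate marking on the
  (barcode, UMI, gene) triple, and assembly of the sparse gene–barcode
  UMI matrix.
- **Cell calling** (`cell_calling`): separating cell-containing
  barcodes from ambient background using the total-UMI distribution
  (every barcode above 10% of the rank-*n* barcode, *n* = 1% of the
  expected cell count), plus library merging and depth downsampling.
- **Barnyard QC** (`species_mixing`): in mixed human–mouse experiments,
  labelling barcodes by species, inferring the multiplet rate as twice
  the dual-species fraction, and quantifying barcode crosstalk.
- **Expression analysis** (`expression`): median-scaling + log +
  per-gene standardisation, variable-gene selection by binned
  normalised dispersion, PCA + k-means clustering, cluster-marker
  ranking, Spearman classification against purified reference
  profiles, and fresh-vs-frozen profile comparison.
- **Genotype demultiplexing** (`genotype_demux`): assigning cells to
  one of two donors *without prior genotypes*, from per-cell
  reference/alternate UMI counts at transcribed SNVs. Allele counts
  are modelled as a K-genome binomial mixture — the alt count at a
  site is Binomial(n, p) with p = ε, ½ or 1−ε for genotypes R/R, R/A
  and A/A (ε = 0.1%) — fit with a Gibbs sampler, label-switching
  removed by Stephens relabelling, and K chosen by requiring 90% of
  cells to have an assignment posterior above 75%.
- **Synthetic data** (`synthetic_data`): seeded generators, with truth
  tables, for every input format the pipeline consumes.

All on-disk formats are plain text: a TSV dialect (or minimal SAM with
CR/CY/UR/UY tags) for aligned records, MatrixMarket + genes/barcodes
sidecars for count matrices, and a minimal VCF subset for SNV sites.

## Worked example

Simulate a two-donor mixture with a 3% minor population and
demultiplex it:

```sh
dropcount simulate donors --seed 1 --out scratch/donors \
    --config <(echo '{"n_cells": 6000, "mix_fraction": 0.03}')
dropcount demux --counts scratch/donors --seed 1 --out scratch/demux.json
```

which prints

```
6000 cells x 2000 sites
chosen K=2 (100.0% of cells confident); minor fraction 3.0%
```

i.e. the sampler separates the two genotypes, every cell has a
confident genome assignment, and the called minor fraction matches the
simulated 3%. Against the simulation truth this run identifies the
180 minor cells with sensitivity 1.00 and PPV 1.00. At a 1% minor
fraction the same command selects K=1: the mixture is below the
method's detection level and no second genotype is reported.

The barnyard worked example is a one-liner:

```pycon
>>> from dropcount.species_mixing import infer_multiplet_rate
>>> round(100 * infer_multiplet_rate(n_mixed=8, n_cells=1012), 1)
1.6
```

— with 8 of 1,012 cell-containing droplets showing significant UMI
counts from both species, the inferred multiplet rate (doubling the
observed cross-species fraction, since same-species multiplets are
invisible) is 1.6%.

## Layout

```
src/dropcount/      io_formats, barcode_umi, cell_calling,
                    species_mixing, expression, genotype_demux,
                    synthetic_data, cli
tests/              pytest suite (unit + property + acceptance)
docs/methods.md     models, assumptions, parameter choices
scripts/acceptance.py
```
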
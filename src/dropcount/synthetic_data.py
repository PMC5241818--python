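"""Seeded generators for every input the pipeline consumes.

Three generators cover the pipeline's input surface: aligned-read
streams with barcode/UMI errors and droplet artefacts (doublets,
ambient RNA), two-donor per-cell SNV allele-count matrices with
configurable genotype sharing, and clustered expression matrices with
planted marker genes.  Each generator emits a truth object so that
downstream operations can be scored exactly, and each is bit
reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .barcode_umi import build_matrix
from .io_formats import (
    AlignedRecord,
    AlleleCountPair,
    BarcodeWhitelist,
    GeneBarcodeMatrix,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    """One cell population: its size and gene expression weights."""

    n_cells: int
    gene_weights: dict[str, float]      # gene id -> relative expression
    species: str = ""                   # optional species tag for gene ids


@dataclass
class ReadSimConfig:
    """Configuration of the aligned-read simulator.

    UMIs per cell follow a negative binomial whose dispersion mimics
    the ~33-43% coefficient of variation seen in real droplet cell-line
    data.  Base-call errors are substitutions drawn independently per
    base; errored positions carry a reduced quality (Q20) on an
    otherwise constant-Q30 read so that the posterior correction path
    is exercised deterministically.
    """

    populations: dict[str, PopulationSpec]
    seed: int
    whitelist_size: int = 2000
    barcode_length: int = 14
    umi_length: int = 10
    umis_per_cell_mean: float = 200.0
    umis_per_cell_dispersion: float = 8.0   # NB shape; CV ~ sqrt(1/mean + 1/shape)
    reads_per_molecule_mean: float = 1.5
    barcode_error_rate: float = 0.0         # per-base substitution probability
    umi_error_rate: float = 0.0
    ambient_fraction: float = 0.0
    doublet_rate: float = 0.0
    frac_non_confident: float = 0.0         # reads emitted with mapq 254
    base_quality: int = 30
    error_quality: int = 20

    def __post_init__(self) -> None:
        for p in (
            self.barcode_error_rate,
            self.umi_error_rate,
            self.ambient_fraction,
            self.doublet_rate,
            self.frac_non_confident,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class ReadSimTruth:
    """Ground truth emitted alongside the simulated reads."""

    matrix: GeneBarcodeMatrix            # deduplicated true molecule counts
    molecules: list[tuple[str, str, str]]  # (barcode, umi, gene), unique
    barcode_populations: dict[str, list[str]]  # barcode -> population(s)
    doublet_barcodes: set[str]
    record_truth: list[tuple[str, str, str]]   # per read: true (barcode, umi, gene)


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random DNA k-mers (rejection sampling on duplicates)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draws = rng.integers(0, 4, size=(n - len(out) + 8, length))
        for row in draws:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    """Substitute each base independently with probability ``rate``."""
    if rate == 0.0:
        return seq, []
    chars = list(seq)
    positions = []
    for i in range(len(chars)):
        if rng.random() < rate:
            alts = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alts[rng.integers(0, 3)]
            positions.append(i)
    return "".join(chars), positions


def _hamming_le1_conflict(umi: str, existing: set[str]) -> bool:
    if umi in existing:
        return True
    for i, base in enumerate(umi):
        for alt in "ACGT":
            if alt != base and umi[:i] + alt + umi[i + 1 :] in existing:
                return True
    return False


def simulate_reads(config: ReadSimConfig) -> tuple[list[AlignedRecord], BarcodeWhitelist, ReadSimTruth]:
    """Generate an aligned-read stream with full truth bookkeeping.

    Each GEM draws a distinct whitelist barcode and holds one cell (or
    two, with probability ``doublet_rate``).  Per-cell molecule totals
    are negative binomial; genes follow the population's weight vector,
    except that ambient molecules (probability ``ambient_fraction``)
    draw their gene from the opposite species' pool in a two-species
    design (the pooled profile otherwise).  True UMIs within one
    (barcode, gene) group are kept at Hamming distance >= 2 of each
    other so that, at zero error rates, the counting pipeline recovers
    the truth matrix exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_cells_total = sum(p.n_cells for p in config.populations.values())
    if config.whitelist_size < n_cells_total:
        raise ValueError("whitelist smaller than the number of cells")

    whitelist_seqs = _random_kmers(rng, config.whitelist_size, config.barcode_length)
    whitelist = BarcodeWhitelist(sequences=sorted(whitelist_seqs))

    # gene universe, optionally species-tagged
    pop_names = list(config.populations)
    gene_ids: dict[str, list[str]] = {}
    gene_probs: dict[str, np.ndarray] = {}
    for name, popspec in config.populations.items():
        ids = [
            f"{popspec.species}:{g}" if popspec.species else g
            for g in popspec.gene_weights
        ]
        w = np.array(list(popspec.gene_weights.values()), dtype=float)
        gene_ids[name] = ids
        gene_probs[name] = w / w.sum()
    all_genes = sorted({g for ids in gene_ids.values() for g in ids})
    species = sorted({p.species for p in config.populations.values() if p.species})

    # assemble GEMs: cells get barcodes; doublet GEMs hold a second cell
    cells: list[str] = []  # population of each cell
    for name, popspec in config.populations.items():
        cells.extend([name] * popspec.n_cells)
    cells = [cells[i] for i in rng.permutation(len(cells))]
    gem_barcodes = list(rng.choice(whitelist.sequences, size=len(cells), replace=False))
    gem_members: list[list[str]] = [[pop] for pop in cells]
    pop_fractions = np.array([config.populations[p].n_cells for p in pop_names], dtype=float)
    pop_fractions /= pop_fractions.sum()
    for i in range(len(gem_members)):
        if rng.random() < config.doublet_rate:
            extra = pop_names[rng.choice(len(pop_names), p=pop_fractions)]
            gem_members[i].append(extra)

    def ambient_pool(own_pop: str) -> tuple[list[str], np.ndarray]:
        own_species = config.populations[own_pop].species
        if len(species) == 2 and own_species:
            pools = [
                (gene_ids[n], gene_probs[n], config.populations[n].n_cells)
                for n in pop_names
                if config.populations[n].species != own_species
            ]
        else:
            pools = [
                (gene_ids[n], gene_probs[n], config.populations[n].n_cells)
                for n in pop_names
            ]
        ids = [g for p in pools for g in p[0]]
        w = np.concatenate([p[1] * p[2] for p in pools])
        return ids, w / w.sum()

    molecules: list[tuple[str, str, str]] = []
    barcode_pops: dict[str, list[str]] = {}
    doublets: set[str] = set()
    group_umis: dict[tuple[str, str], set[str]] = {}
    for barcode, members in zip(gem_barcodes, gem_members):
        barcode_pops[barcode] = members
        if len(members) > 1:
            doublets.add(barcode)
        for pop in members:
            n_mol = rng.negative_binomial(
                config.umis_per_cell_dispersion,
                config.umis_per_cell_dispersion
                / (config.umis_per_cell_dispersion + config.umis_per_cell_mean),
            )
            amb_ids, amb_probs = (None, None)
            for _ in range(int(n_mol)):
                if config.ambient_fraction and rng.random() < config.ambient_fraction:
                    if amb_ids is None:
                        amb_ids, amb_probs = ambient_pool(pop)
                    gene = amb_ids[rng.choice(len(amb_ids), p=amb_probs)]
                else:
                    gene = gene_ids[pop][rng.choice(len(gene_ids[pop]), p=gene_probs[pop])]
                group = group_umis.setdefault((barcode, gene), set())
                for _attempt in range(50):
                    umi = "".join(_BASES[rng.integers(0, 4, size=config.umi_length)])
                    if len(set(umi)) > 1 and not _hamming_le1_conflict(umi, group):
                        break
                else:  # pragma: no cover - astronomically unlikely
                    continue
                group.add(umi)
                molecules.append((barcode, umi, gene))

    # reads: PCR duplicates, then sequencing errors on barcode and UMI
    records: list[AlignedRecord] = []
    record_truth: list[tuple[str, str, str]] = []
    q_hi, q_lo = config.base_quality, config.error_quality
    for barcode, umi, gene in molecules:
        n_reads = 1 + rng.poisson(max(config.reads_per_molecule_mean - 1.0, 0.0))
        for _ in range(int(n_reads)):
            raw_bc, bc_err = _mutate(rng, barcode, config.barcode_error_rate)
            raw_umi, umi_err = _mutate(rng, umi, config.umi_error_rate)
            bq = [q_lo if i in bc_err else q_hi for i in range(len(raw_bc))]
            uq = [q_lo if i in umi_err else q_hi for i in range(len(raw_umi))]
            mapq = 254 if rng.random() < config.frac_non_confident else 255
            records.append(
                AlignedRecord(
                    barcode_seq=raw_bc,
                    barcode_quals=tuple(bq),
                    umi_seq=raw_umi,
                    umi_quals=tuple(uq),
                    gene_id=gene,
                    mapq=mapq,
                    sample_index="S1",
                    run_id="run1",
                )
            )
            record_truth.append((barcode, umi, gene))

    confident = [
        m for m, rec in zip(record_truth, records) if rec.mapq == 255
    ]
    unique_confident = list(dict.fromkeys(confident))
    truth_matrix = build_matrix(unique_confident, genes=all_genes)
    truth = ReadSimTruth(
        matrix=truth_matrix,
        molecules=unique_confident,
        barcode_populations=barcode_pops,
        doublet_barcodes=doublets,
        record_truth=record_truth,
    )
    return records, whitelist, truth


def make_barnyard_populations(
    n_human: int,
    n_mouse: int,
    n_genes_per_species: int = 50,
    seed: int = 0,
) -> dict[str, PopulationSpec]:
    """Convenience two-species design with lognormal gene weights."""
    rng = np.random.default_rng(seed)
    human_genes = {f"GH{i:04d}": w for i, w in enumerate(rng.lognormal(0, 1, n_genes_per_species))}
    mouse_genes = {f"GM{i:04d}": w for i, w in enumerate(rng.lognormal(0, 1, n_genes_per_species))}
    return {
        "human": PopulationSpec(n_cells=n_human, gene_weights=human_genes, species="hg19"),
        "mouse": PopulationSpec(n_cells=n_mouse, gene_weights=mouse_genes, species="mm10"),
    }


# ---------------------------------------------------------------------------
# Two-donor allele counts


@dataclass
class DonorSimConfig:
    """Configuration of the two-donor SNV allele-count simulator.

    Genotypes for the first donor are drawn per site from Hardy-
    Weinberg proportions at an alt allele frequency uniform on
    [``af_low``, ``af_high``]; the second donor copies the first at an
    ``ibs`` fraction of sites and carries a different genotype at the
    rest, so the realised genotype agreement equals ``ibs``.  Site
    coverage is sparse and skewed (lognormal site weights emulating
    expression-driven SNV coverage), with on average
    ``mean_sites_per_cell`` covered sites per cell at 1-3 UMIs each.
    """

    n_cells: int = 6000
    mix_fraction: float = 0.5
    n_sites: int = 2000
    ibs: float = 0.73
    mean_sites_per_cell: float = 50.0
    mean_umis_per_site: float = 2.0
    error_rate: float = 0.001
    af_low: float = 0.1
    af_high: float = 0.9
    site_weight_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must be in [0, 1]")
        if not 0.0 <= self.ibs <= 1.0:
            raise ValueError("ibs must be in [0, 1]")


@dataclass
class DonorSimTruth:
    donor_labels: np.ndarray            # per cell: 0 (major) or 1 (minor)
    genotypes: np.ndarray               # 2 x n_sites genotype indices
    site_keys: list[tuple]
    allele_frequencies: np.ndarray

    def genotype_dict(self, donor: int) -> dict[tuple, int]:
        return {k: int(g) for k, g in zip(self.site_keys, self.genotypes[donor])}


def _hwe_probs(af: np.ndarray) -> np.ndarray:
    """n_sites x 3 Hardy-Weinberg genotype probabilities."""
    return np.stack([(1 - af) ** 2, 2 * af * (1 - af), af**2], axis=1)


def simulate_two_donor_alleles(
    config: DonorSimConfig,
) -> tuple[AlleleCountPair, DonorSimTruth]:
    """Simulate per-cell ref/alt UMI counts for a two-donor mixture."""
    rng = np.random.default_rng(config.seed)
    n_sites, n_cells = config.n_sites, config.n_cells

    af = rng.uniform(config.af_low, config.af_high, size=n_sites)
    probs = _hwe_probs(af)
    g0 = np.array([rng.choice(3, p=p) for p in probs])
    shared = rng.random(n_sites) < config.ibs
    g1 = g0.copy()
    for s in np.flatnonzero(~shared):
        p = probs[s].copy()
        p[g0[s]] = 0.0
        p /= p.sum()
        g1[s] = rng.choice(3, p=p)
    genotypes = np.stack([g0, g1])

    n_minor = int(round(config.mix_fraction * n_cells))
    labels = np.zeros(n_cells, dtype=int)
    labels[rng.choice(n_cells, size=n_minor, replace=False)] = 1

    log_w = np.log(rng.lognormal(0.0, config.site_weight_sigma, size=n_sites))
    p_alt = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])

    rows, cols, refs, alts = [], [], [], []
    for c in range(n_cells):
        k = int(rng.poisson(config.mean_sites_per_cell))
        k = min(max(k, 1), n_sites)
        # weighted sampling without replacement via Gumbel top-k
        noise = rng.gumbel(size=n_sites)
        covered = np.argpartition(-(log_w + noise), k - 1)[:k]
        depth = 1 + rng.poisson(config.mean_umis_per_site - 1.0, size=k)
        g = genotypes[labels[c], covered]
        a = rng.binomial(depth, p_alt[g])
        r = depth - a
        rows.extend([c] * k)
        cols.extend(covered.tolist())
        refs.extend(r.tolist())
        alts.extend(a.tolist())

    shape = (n_cells, n_sites)
    ref_m = sp.coo_matrix((refs, (rows, cols)), shape=shape).tocsr()
    alt_m = sp.coo_matrix((alts, (rows, cols)), shape=shape).tocsr()
    site_keys = [("1", s + 1, "A", "G") for s in range(n_sites)]
    cells = [f"CELL{c:05d}" for c in range(n_cells)]
    pair = AlleleCountPair(cells=cells, sites=site_keys, ref_counts=ref_m, alt_counts=alt_m)
    truth = DonorSimTruth(
        donor_labels=labels,
        genotypes=genotypes,
        site_keys=site_keys,
        allele_frequencies=af,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Clustered expression matrices


@dataclass
class ClusterSimTruth:
    labels: np.ndarray                  # per cell: cluster index 1..k
    markers: dict[int, list[str]]       # cluster -> planted marker genes


def simulate_expression_clusters(
    n_clusters: int,
    cells_per_cluster: int,
    n_genes: int = 200,
    markers_per_cluster: int = 5,
    effect_size: float = 8.0,
    base_mean: float = 2.0,
    seed: int = 0,
) -> tuple[GeneBarcodeMatrix, ClusterSimTruth]:
    """Poisson expression with planted cluster-specific marker genes.

    Background genes share a lognormal mean profile across clusters;
    each cluster up-regulates its own disjoint block of
    ``markers_per_cluster`` genes by ``effect_size``-fold.
    """
    if n_genes < n_clusters * markers_per_cluster:
        raise ValueError("too few genes for the requested marker blocks")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(np.log(base_mean), 0.5, size=n_genes)
    labels = np.repeat(np.arange(1, n_clusters + 1), cells_per_cluster)
    markers: dict[int, list[str]] = {}
    means = np.tile(base[:, None], (1, n_clusters))
    for c in range(n_clusters):
        block = slice(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        means[block, c] *= effect_size
        markers[c + 1] = genes[block]
    counts = np.column_stack(
        [rng.poisson(means[:, lab - 1]) for lab in labels]
    ).astype(np.int64)
    barcodes = [f"CELL{i:05d}" for i in range(len(labels))]
    matrix = GeneBarcodeMatrix(
        genes=genes, barcodes=barcodes, counts=sp.csr_matrix(counts)
    )
    return matrix, ClusterSimTruth(labels=labels, markers=markers)
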
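"""Raw aligned reads -> deduplicated gene-barcode UMI count matrix.

The stages mirror the digital-counting core of droplet 3' scRNA-seq
processing: posterior-probability barcode correction against a designed
whitelist, UMI validation (base quality and homopolymer rules), UMI
error collapse toward more-abundant 1-Hamming neighbours within each
(barcode, gene) group, PCR-duplicate marking on the (barcode, UMI,
gene) triple, and assembly of the sparse count matrix.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import AlignedRecord, BarcodeWhitelist, GeneBarcodeMatrix

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class CorrectionParams:
    """Thresholds of the counting pipeline.

    posterior_threshold
        Minimum posterior probability that a whitelist barcode produced
        the observed (erroneous) barcode for correction to be accepted.
    umi_min_qual
        UMI base-quality floor; a UMI is valid only if every base
        quality is strictly greater than this (Q10 implies 90% base
        call accuracy, hence the default).
    confident_mapq
        MAPQ value marking a confidently, uniquely mapped read.
    umi_length
        Expected UMI length; 10 nt default, 5 nt dialect supported.
    """

    posterior_threshold: float = 0.975
    umi_min_qual: int = 10
    confident_mapq: int = 255
    umi_length: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.posterior_threshold <= 1:
            raise ValueError("posterior_threshold must be in (0, 1]")
        if self.umi_min_qual < 0:
            raise ValueError("umi_min_qual must be >= 0")


@dataclass
class PipelineMetrics:
    """Per-stage read accounting for :func:`count_pipeline`.

    The `frac_*` properties are the usable-read factors: valid barcode,
    valid UMI and confident unique gene mapping.  The fourth factor
    (reads associated with a called cell barcode) requires cell calling
    and is filled in downstream.
    """

    n_reads: int = 0
    n_valid_barcode: int = 0
    n_valid_umi: int = 0
    n_confidently_mapped: int = 0
    n_molecules: int = 0
    n_duplicates: int = 0
    extra: dict = field(default_factory=dict)

    @staticmethod
    def _frac(num: int, den: int) -> float:
        return num / den if den else 0.0

    @property
    def frac_valid_barcode(self) -> float:
        return self._frac(self.n_valid_barcode, self.n_reads)

    @property
    def frac_valid_umi(self) -> float:
        return self._frac(self.n_valid_umi, self.n_valid_barcode)

    @property
    def frac_confidently_mapped(self) -> float:
        return self._frac(self.n_confidently_mapped, self.n_valid_umi)

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_valid_barcode": self.n_valid_barcode,
            "n_valid_umi": self.n_valid_umi,
            "n_confidently_mapped": self.n_confidently_mapped,
            "n_molecules": self.n_molecules,
            "n_duplicates": self.n_duplicates,
            "frac_valid_barcode": self.frac_valid_barcode,
            "frac_valid_umi": self.frac_valid_umi,
            "frac_confidently_mapped": self.frac_confidently_mapped,
            **self.extra,
        }


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _hamming1_whitelist_neighbours(
    seq: str, whitelist: BarcodeWhitelist
) -> list[tuple[str, int]]:
    """Whitelist barcodes at Hamming distance exactly 1 from ``seq``.

    Returns (candidate, mismatch_position) pairs, enumerated by
    substituting each position; O(L * 4) membership tests.
    """
    out = []
    for i, base in enumerate(seq):
        for alt in _BASES:
            if alt == base:
                continue
            cand = seq[:i] + alt + seq[i + 1 :]
            if cand in whitelist:
                out.append((cand, i))
    return out


def correct_barcode(
    observed_seq: str,
    observed_quals: Sequence[int],
    whitelist: BarcodeWhitelist,
    params: CorrectionParams = CorrectionParams(),
) -> str | None:
    """Correct an observed barcode against the whitelist, or return None.

    A whitelisted observation is returned unchanged.  Otherwise every
    whitelist barcode at Hamming distance exactly 1 is a candidate; the
    likelihood that candidate c produced the observation is the
    sequencing-error probability 10^(-q_i/10) at the mismatched base i,
    and the posterior is prior(c) x likelihood normalised over
    candidates.  The top candidate is accepted if its posterior reaches
    ``params.posterior_threshold``; equal posteriors are broken by
    lexical order.  The prior is the observed exact-match count plus a
    single pseudocount, so unseen whitelist barcodes stay reachable.
    """
    if not len(whitelist):
        raise ValueError("empty whitelist")
    if len(observed_seq) != whitelist.barcode_length:
        raise ValueError(
            f"observed barcode length {len(observed_seq)} != whitelist "
            f"length {whitelist.barcode_length}"
        )
    if observed_seq in whitelist:
        return observed_seq
    candidates = _hamming1_whitelist_neighbours(observed_seq, whitelist)
    if not candidates:
        return None
    posts = np.array(
        [
            (whitelist.prior_counts.get(c, 0) + 1) * 10.0 ** (-observed_quals[i] / 10.0)
            for c, i in candidates
        ]
    )
    posts = posts / posts.sum()
    best = posts.max()
    if best < params.posterior_threshold:
        return None
    # lexical tie-break among maximal-posterior candidates
    winners = sorted(c for (c, _), p in zip(candidates, posts) if p == best)
    return winners[0]


def validate_umi(
    umi_seq: str,
    umi_quals: Sequence[int],
    params: CorrectionParams = CorrectionParams(),
) -> bool:
    """UMI validity: all base qualities > threshold, no N, not a homopolymer."""
    if not umi_seq:
        return False
    if "N" in umi_seq:
        return False
    if min(umi_quals) <= params.umi_min_qual:
        return False
    if len(set(umi_seq)) == 1:
        return False
    return True


def collapse_umis(umi_read_counts: dict[str, int]) -> dict[str, str]:
    """Map each UMI to its corrected form within one (barcode, gene) group.

    A UMI u is relabelled to a 1-Hamming-distance neighbour v with
    strictly more reads.  Corrections are computed in a single pass
    against the pre-collapse read counts (no transitive chaining); ties
    in read count leave u unchanged.  When several neighbours qualify
    the one with most reads wins, then lexical order.
    """
    mapping: dict[str, str] = {}
    umis = set(umi_read_counts)
    for u, n_u in umi_read_counts.items():
        best: tuple[int, str] | None = None
        for i, base in enumerate(u):
            for alt in _BASES:
                if alt == base:
                    continue
                v = u[:i] + alt + u[i + 1 :]
                if v in umis and umi_read_counts[v] > n_u:
                    key = (-umi_read_counts[v], v)
                    if best is None or key < best:
                        best = key
        mapping[u] = best[1] if best is not None else u
    return mapping


def mark_duplicates(
    triples: Iterable[tuple[str, str, str]],
) -> tuple[list[tuple[str, str, str]], int]:
    """Keep the first record per distinct (barcode, UMI, gene) triple.

    Returns (retained unique molecules in first-seen order, number of
    duplicates marked).
    """
    seen: set[tuple[str, str, str]] = set()
    retained = []
    n_dup = 0
    for t in triples:
        if t in seen:
            n_dup += 1
        else:
            seen.add(t)
            retained.append(t)
    return retained, n_dup


def compute_priors(
    records: Iterable[AlignedRecord], whitelist: BarcodeWhitelist
) -> dict[str, int]:
    """Barcode priors: counts of exact whitelist matches in the input."""
    counts: Counter[str] = Counter()
    for rec in records:
        if rec.barcode_seq in whitelist:
            counts[rec.barcode_seq] += 1
    return dict(counts)


def count_pipeline(
    records: Sequence[AlignedRecord],
    whitelist: BarcodeWhitelist,
    params: CorrectionParams = CorrectionParams(),
    genes: Sequence[str] | None = None,
) -> tuple[GeneBarcodeMatrix, PipelineMetrics]:
    """Run the full digital-counting pipeline on aligned records.

    Stages, in order: barcode correction (reads whose barcode cannot be
    corrected are dropped), UMI validation, confident-mapping filter
    (mapq == params.confident_mapq and a unique gene assignment), UMI
    collapse per (barcode, gene), duplicate marking.  The matrix entry
    (g, b) is the number of distinct retained molecules of gene g in
    barcode b.

    If the whitelist carries no priors they are computed here from the
    exact whitelist matches among the input reads.
    """
    metrics = PipelineMetrics(n_reads=len(records))
    if not whitelist.prior_counts:
        whitelist.prior_counts = compute_priors(records, whitelist)

    # stage 1+2+3: per-read filters
    kept: list[tuple[str, str, str]] = []  # (barcode, umi, gene)
    for rec in records:
        bc = correct_barcode(rec.barcode_seq, rec.barcode_quals, whitelist, params)
        if bc is None:
            continue
        metrics.n_valid_barcode += 1
        if not validate_umi(rec.umi_seq, rec.umi_quals, params):
            continue
        metrics.n_valid_umi += 1
        if rec.mapq != params.confident_mapq or rec.gene_id is None:
            continue
        metrics.n_confidently_mapped += 1
        kept.append((bc, rec.umi_seq, rec.gene_id))

    # stage 4: UMI collapse within each (barcode, gene) group
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for bc, umi, gene in kept:
        groups[(bc, gene)][umi] += 1
    umi_maps = {key: collapse_umis(dict(cnt)) for key, cnt in groups.items()}
    corrected = [(bc, umi_maps[(bc, gene)][umi], gene) for bc, umi, gene in kept]

    # stage 5: duplicate marking
    molecules, n_dup = mark_duplicates(corrected)
    metrics.n_molecules = len(molecules)
    metrics.n_duplicates = n_dup

    matrix = build_matrix(molecules, genes=genes)
    if matrix.counts.nnz == 0:
        logger.warning("count pipeline produced an empty matrix")
    return matrix, metrics


def build_matrix(
    molecules: Iterable[tuple[str, str, str]],
    genes: Sequence[str] | None = None,
    barcodes: Sequence[str] | None = None,
) -> GeneBarcodeMatrix:
    """Assemble a GeneBarcodeMatrix from unique (barcode, UMI, gene) triples."""
    molecules = list(molecules)
    if genes is None:
        genes = sorted({g for _, _, g in molecules})
    if barcodes is None:
        barcodes = sorted({b for b, _, _ in molecules})
    g_index = {g: i for i, g in enumerate(genes)}
    b_index = {b: i for i, b in enumerate(barcodes)}
    rows, cols = [], []
    for b, _, g in molecules:
        rows.append(g_index[g])
        cols.append(b_index[b])
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(genes), len(barcodes)),
    ).tocsr()
    return GeneBarcodeMatrix(genes=list(genes), barcodes=list(barcodes), counts=counts)
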
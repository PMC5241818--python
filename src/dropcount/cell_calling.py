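"""Cell calling, library merging and downsampling.

Cell-containing barcodes are separated from background droplets using
the UMI count distribution: taking the barcode at rank n (where n is 1%
of the expected recovered cell count), every barcode whose total UMI
count exceeds 10% of that rank-n total is called a cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .barcode_umi import mark_duplicates
from .io_formats import AlignedRecord, GeneBarcodeMatrix

logger = logging.getLogger(__name__)


@dataclass
class CellSet:
    """Called cell barcodes plus the rule's intermediate quantities."""

    called_barcodes: list[str]
    expected_cells: int
    threshold_umi: float
    barcode_totals: dict[str, int]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._called

    def __post_init__(self) -> None:
        self._called = set(self.called_barcodes)

    def __len__(self) -> int:
        return len(self.called_barcodes)


def call_cells(matrix: GeneBarcodeMatrix, expected_cells: int) -> CellSet:
    """Call cell barcodes from the total-UMI distribution.

    n = max(1, round(0.01 * expected_cells)); T = total UMIs of the
    rank-n barcode in descending order (ties broken by barcode lexical
    order); every barcode with total > 0.10 * T is called.
    """
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    totals = matrix.barcode_totals()
    if len(totals) == 0:
        raise ValueError("empty matrix")
    n = max(1, int(round(0.01 * expected_cells)))
    if n > len(totals):
        logger.warning(
            "rank %d exceeds %d barcodes; using the last barcode", n, len(totals)
        )
        n = len(totals)
    order = sorted(range(len(totals)), key=lambda i: (-totals[i], matrix.barcodes[i]))
    top_nth_total = totals[order[n - 1]]
    threshold = 0.10 * top_nth_total
    called = [matrix.barcodes[i] for i in order if totals[i] > threshold]
    return CellSet(
        called_barcodes=called,
        expected_cells=expected_cells,
        threshold_umi=threshold,
        barcode_totals={b: int(t) for b, t in zip(matrix.barcodes, totals)},
    )


def usable_reads_fraction(m1: float, m2: float, m3: float, m4: float) -> float:
    """Product of the four usable-read metrics.

    m1: fraction of reads with valid barcodes; m2: valid UMIs; m3:
    associated with a called cell barcode; m4: confidently mapped to
    exons.
    """
    for m in (m1, m2, m3, m4):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"metric {m} outside [0, 1]")
    return m1 * m2 * m3 * m4


def capture_efficiency(cells_detected: int, cells_loaded: int) -> float:
    """Ratio of cells detected by sequencing to cells loaded on the chip."""
    if cells_loaded <= 0:
        raise ValueError("cells_loaded must be positive")
    eff = cells_detected / cells_loaded
    if eff > 1:
        logger.warning(
            "capture efficiency %.3f > 1 suggests a cell counting error", eff
        )
    return eff


def merge_libraries(matrices: Sequence[GeneBarcodeMatrix]) -> GeneBarcodeMatrix:
    """Concatenate gene-barcode matrices from multiple channels.

    Gene lists must be identical.  Colliding barcodes across inputs are
    disambiguated with "-1", "-2", ... suffixes by input position.
    """
    matrices = [m for m in matrices if m is not None]
    if not matrices:
        raise ValueError("no matrices to merge")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("gene lists differ between libraries")
    all_barcodes = [b for m in matrices for b in m.barcodes]
    collide = len(set(all_barcodes)) != len(all_barcodes)
    barcodes = []
    for idx, m in enumerate(matrices, start=1):
        suffix = f"-{idx}" if collide else ""
        barcodes.extend(b + suffix for b in m.barcodes)
    counts = sp.hstack([m.counts for m in matrices]).tocsr()
    return GeneBarcodeMatrix(
        genes=list(genes),
        barcodes=barcodes,
        counts=counts,
        gene_names=list(matrices[0].gene_names),
    )


def merge_runs(record_streams: Iterable[Iterable[AlignedRecord]]) -> list[AlignedRecord]:
    """Combine sequencing runs of one library by keeping non-duplicate reads.

    The duplicate key is (barcode, UMI, gene) and deliberately ignores
    run_id, so re-sequencing the same molecules does not inflate counts.
    Reads without a gene assignment are passed through untouched.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[AlignedRecord] = []
    for stream in record_streams:
        for rec in stream:
            if rec.gene_id is None:
                out.append(rec)
                continue
            key = (rec.barcode_seq, rec.umi_seq, rec.gene_id)
            if key in seen:
                continue
            seen.add(key)
            out.append(rec)
    return out


def downsample(
    matrix: GeneBarcodeMatrix, target_mean_per_cell: float, seed: int
) -> GeneBarcodeMatrix:
    """Subsample molecules so cell totals hit the target mean in expectation.

    Each cell's retained molecules are drawn without replacement
    (multivariate hypergeometric over its gene counts), with the number
    retained set to rate x current total, rate = target / current mean.
    """
    totals = matrix.barcode_totals()
    current_mean = totals.mean() if len(totals) else 0.0
    if target_mean_per_cell > current_mean:
        raise ValueError(
            f"target {target_mean_per_cell} exceeds current mean {current_mean:.2f}"
        )
    if current_mean == 0:
        return matrix
    rate = target_mean_per_cell / current_mean
    rng = np.random.default_rng(seed)
    csc = matrix.counts.tocsc()
    new = sp.lil_matrix(csc.shape, dtype=np.int64)
    for j in range(csc.shape[1]):
        col = csc[:, j]
        total = int(col.sum())
        if total == 0:
            continue
        n_keep = int(round(rate * total))
        if n_keep >= total:
            new[:, j] = col
            continue
        if n_keep == 0:
            continue
        idx = col.indices
        kept = rng.multivariate_hypergeometric(col.data.astype(np.int64), n_keep)
        for i, k in zip(idx, kept):
            if k:
                new[i, j] = k
    return GeneBarcodeMatrix(
        genes=list(matrix.genes),
        barcodes=list(matrix.barcodes),
        counts=new.tocsr(),
        gene_names=list(matrix.gene_names),
    )
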
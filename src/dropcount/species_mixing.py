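"""Barnyard (mixed-species) analytics.

In a human-mouse mixing experiment only cross-species multiplets are
observable, so the inferred multiplet rate is defined as twice the rate
of cell barcodes with significant UMI counts from both species.  A
species count is significant when it lies inside the top 99% of that
species' UMI count distribution among barcodes majority-assigned to it
(i.e. it exceeds the 1st percentile); the percentile is exposed as a
parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cell_calling import CellSet
from .io_formats import GeneBarcodeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SpeciesCallResult:
    """Per-barcode species labels and the derived multiplet statistics."""

    barcodes: list[str]
    species: list[str]                      # the two species names (A, B)
    totals: np.ndarray                      # n_barcodes x 2 per-species UMI totals
    labels: list[str]                       # per barcode: species name or "mixed"
    cutoffs: dict[str, float]               # significance cutoff per species
    observed_mixed_fraction: float = 0.0
    inferred_multiplet_rate: float = 0.0
    extra: dict = field(default_factory=dict)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def classify_species(
    matrix: GeneBarcodeMatrix,
    cell_set: CellSet,
    significance_percentile: float = 1.0,
) -> SpeciesCallResult:
    """Assign called barcodes to a species or label them mixed.

    Each called barcode gets a per-species UMI total from the
    species-tagged genes.  The significance cutoff for species X is the
    ``significance_percentile``-th percentile of the species-X totals
    among barcodes whose majority species is X; a barcode is labelled
    mixed iff its count is significant in both species, otherwise it
    takes its majority species.
    """
    species_tags = matrix.species_of_genes()
    names = sorted({s for s in species_tags if s})
    if len(names) < 2:
        raise ValueError(f"need >= 2 species-tagged gene sets, found {names}")
    if len(names) > 2:
        raise ValueError(f"barnyard analysis expects exactly 2 species, found {names}")
    called = [b for b in matrix.barcodes if b in cell_set]
    b_index = {b: i for i, b in enumerate(matrix.barcodes)}
    cols = np.array([b_index[b] for b in called], dtype=int)
    totals = np.zeros((len(called), 2))
    for k, name in enumerate(names):
        mask = species_tags == name
        sub = matrix.counts[np.flatnonzero(mask)][:, cols]
        totals[:, k] = np.asarray(sub.sum(axis=0)).ravel()

    majority = np.argmax(totals, axis=1)  # ties -> first species (lexical)
    cutoffs = {}
    for k, name in enumerate(names):
        pool = totals[majority == k, k]
        if len(pool) == 0:
            raise ValueError(f"no barcodes majority-assigned to species {name!r}")
        cutoffs[name] = float(np.percentile(pool, significance_percentile))

    labels = []
    for i in range(len(called)):
        sig = [totals[i, k] > cutoffs[names[k]] for k in range(2)]
        labels.append("mixed" if all(sig) else names[majority[i]])

    n_mixed = labels.count("mixed")
    mixed_frac = n_mixed / len(called) if called else 0.0
    return SpeciesCallResult(
        barcodes=called,
        species=names,
        totals=totals,
        labels=labels,
        cutoffs=cutoffs,
        observed_mixed_fraction=mixed_frac,
        inferred_multiplet_rate=infer_multiplet_rate(n_mixed, len(called)),
    )


def infer_multiplet_rate(n_mixed: int, n_cells: int) -> float:
    """Multiplet rate = 2 x observed dual-species fraction.

    The doubling accounts for same-species multiplets, which are
    invisible in a barnyard design; it assumes the two species are
    roughly equally represented.  Values above 1 are capped with a
    warning.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not 0 <= n_mixed <= n_cells:
        raise ValueError("n_mixed must be in [0, n_cells]")
    rate = 2.0 * n_mixed / n_cells
    if rate > 1.0:
        logger.warning("inferred multiplet rate %.3f capped at 1", rate)
        rate = 1.0
    return rate


def crosstalk_fraction(
    result: SpeciesCallResult,
) -> dict[str, float | None]:
    """Fraction of wrong-species UMIs in each species' pure barcodes.

    For barcodes labelled species A, the crosstalk is the summed
    species-B UMIs divided by their total UMIs; mixed barcodes are
    excluded.  A species with no pure barcodes reports None.
    """
    out: dict[str, float | None] = {}
    labels = np.array(result.labels)
    for k, name in enumerate(result.species):
        mask = labels == name
        if not mask.any():
            out[name] = None
            continue
        own = result.totals[mask, k].sum()
        other = result.totals[mask, 1 - k].sum()
        denom = own + other
        out[name] = float(other / denom) if denom else None
    return out


def expected_multiplet_composition(
    cluster_fractions: Mapping[str, float], members: Sequence[str]
) -> float:
    """Expected co-encapsulation fraction for a multiplet composition.

    Returns the product of the member clusters' relative sizes, in
    percent: the probability (up to a constant loading factor) that one
    cell from each member cluster lands in the same droplet.
    """
    prod = 1.0
    for m in members:
        if m not in cluster_fractions:
            raise KeyError(f"unknown cluster {m!r}")
        f = cluster_fractions[m]
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"cluster fraction {f} outside [0, 1]")
        prod *= f
    return 100.0 * prod
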
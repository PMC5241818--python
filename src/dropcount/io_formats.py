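"""Readers and writers for the on-disk artifacts of the pipeline.

All formats are plain text: a TSV dialect (or minimal SAM) for aligned
read records carrying raw barcode/UMI sequences and base qualities, the
MatrixMarket + genes.tsv/barcodes.tsv layout for sparse gene-barcode UMI
matrices, and a minimal VCF subset for SNV site tables.  Every
writer/reader pair round-trips exactly, including element ordering.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: Offset used to encode Phred scores as printable characters (FASTQ-style).
PHRED_OFFSET = 33

TSV_COLUMNS = [
    "barcode_seq",
    "barcode_quals",
    "umi_seq",
    "umi_quals",
    "gene_id",
    "mapq",
    "sample_index",
    "run_id",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def quals_to_phred(qual_string: str) -> tuple[int, ...]:
    """Decode a FASTQ-style quality string into Phred integers."""
    return tuple(ord(c) - PHRED_OFFSET for c in qual_string)


def phred_to_quals(phred: Sequence[int]) -> str:
    """Encode Phred integers as a FASTQ-style quality string."""
    return "".join(chr(q + PHRED_OFFSET) for q in phred)


@dataclass(frozen=True, slots=True)
class AlignedRecord:
    """One sequenced cDNA read with its raw barcode/UMI and qualities.

    ``gene_id`` is None when the read was not confidently and uniquely
    assigned to a gene.  ``mapq`` follows SAM conventions (255 denotes a
    confidently, uniquely mapped read in the aligner output we consume).
    """

    barcode_seq: str
    barcode_quals: tuple[int, ...]
    umi_seq: str
    umi_quals: tuple[int, ...]
    gene_id: str | None
    mapq: int
    sample_index: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        if len(self.barcode_seq) != len(self.barcode_quals):
            raise FormatError("barcode sequence/quality length mismatch")
        if len(self.umi_seq) != len(self.umi_quals):
            raise FormatError("UMI sequence/quality length mismatch")
        if not 0 <= self.mapq <= 255:
            raise FormatError(f"mapq {self.mapq} outside [0, 255]")
        for seq in (self.barcode_seq, self.umi_seq):
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise FormatError(
                    f"non-ACGTN base(s) {bad} in record with barcode "
                    f"{self.barcode_seq}"
                )


@dataclass
class BarcodeWhitelist:
    """The set of designed cell barcode sequences plus observed priors.

    ``prior_counts`` holds, for each whitelist barcode, the number of
    times it was observed exactly in the data; it drives the prior term
    of posterior barcode correction.
    """

    sequences: list[str]
    prior_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise FormatError("duplicate sequences in whitelist")
        extra = set(self.prior_counts) - set(self.sequences)
        if extra:
            raise FormatError(f"prior counts for non-whitelist barcodes: {sorted(extra)[:3]}")
        self._index = set(self.sequences)

    def __contains__(self, seq: str) -> bool:
        return seq in self._index

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def barcode_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class GeneBarcodeMatrix:
    """Sparse genes x barcodes matrix of deduplicated UMI counts.

    Gene IDs may carry a ``species:`` prefix (e.g. ``hg19:ENSG...``)
    when counting was done against a combined multi-species reference;
    :mod:`dropcount.species_mixing` relies on that tag.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene IDs")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.gene_names is None:
            self.gene_names = list(self.genes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def barcode_totals(self) -> np.ndarray:
        """Total UMI count per barcode (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def species_of_genes(self) -> np.ndarray:
        """Species tag per gene ('' where untagged)."""
        return np.array([g.split(":", 1)[0] if ":" in g else "" for g in self.genes])

    def equals(self, other: "GeneBarcodeMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
        )


@dataclass(frozen=True, slots=True)
class SnvSite:
    """One biallelic SNV site keyed by (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    n_cells: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SnvTable:
    """Filtered table of biallelic SNV sites."""

    sites: list[SnvSite]
    n_skipped_non_biallelic: int = 0
    n_filtered: int = 0

    def __post_init__(self) -> None:
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chrom, pos) in SNV table")

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [s.key for s in self.sites]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class AlleleCountPair:
    """Paired sparse cells x sites matrices of ref and alt UMI counts."""

    cells: list[str]
    sites: list[tuple[str, int, str, str]]
    ref_counts: sp.csr_matrix
    alt_counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.ref_counts = sp.csr_matrix(self.ref_counts)
        self.alt_counts = sp.csr_matrix(self.alt_counts)
        shape = (len(self.cells), len(self.sites))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise FormatError("allele count matrix shape mismatch")
        for m in (self.ref_counts, self.alt_counts):
            if m.nnz and m.data.min() < 0:
                raise FormatError("negative allele counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref_counts.shape


# ---------------------------------------------------------------------------
# Aligned record I/O


def _parse_tsv_line(line: str, lineno: int) -> AlignedRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != len(TSV_COLUMNS):
        raise FormatError(
            f"line {lineno}: expected {len(TSV_COLUMNS)} columns, got {len(parts)}"
        )
    row = dict(zip(TSV_COLUMNS, parts))
    try:
        mapq = int(row["mapq"])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer mapq {row['mapq']!r}") from exc
    gene = row["gene_id"] if row["gene_id"] not in ("", ".", "None") else None
    try:
        return AlignedRecord(
            barcode_seq=row["barcode_seq"],
            barcode_quals=quals_to_phred(row["barcode_quals"]),
            umi_seq=row["umi_seq"],
            umi_quals=quals_to_phred(row["umi_quals"]),
            gene_id=gene,
            mapq=mapq,
            sample_index=row["sample_index"],
            run_id=row["run_id"],
        )
    except FormatError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_aligned_records(path: str | Path, dialect: str = "tsv") -> Iterator[AlignedRecord]:
    """Stream aligned read records from a TSV or minimal SAM file.

    The TSV dialect has a header line with the columns in
    :data:`TSV_COLUMNS`; qualities are FASTQ-encoded strings.  The SAM
    dialect maps raw barcode/UMI from the CR/CY/UR/UY tags, the gene
    from GX, the sample index from BC and the run from RG.
    """
    path = Path(path)
    if dialect == "tsv":
        yield from _read_tsv_records(path)
    elif dialect == "sam":
        yield from _read_sam_records(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv_records(path: Path) -> Iterator[AlignedRecord]:
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return  # empty file -> empty stream
        cols = header.rstrip("\n").split("\t")
        if cols != TSV_COLUMNS:
            missing = set(TSV_COLUMNS) - set(cols)
            raise FormatError(f"bad TSV header; missing columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            yield _parse_tsv_line(line, lineno)


def _read_sam_records(path: Path) -> Iterator[AlignedRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, aln in enumerate(sam.fetch(until_eof=True), start=1):
            try:
                barcode = aln.get_tag("CR")
                bq = aln.get_tag("CY")
                umi = aln.get_tag("UR")
                uq = aln.get_tag("UY")
            except KeyError as exc:
                raise FormatError(f"record {i}: missing barcode/UMI tag: {exc}") from exc
            gene = aln.get_tag("GX") if aln.has_tag("GX") else None
            yield AlignedRecord(
                barcode_seq=barcode,
                barcode_quals=quals_to_phred(bq),
                umi_seq=umi,
                umi_quals=quals_to_phred(uq),
                gene_id=gene,
                mapq=aln.mapping_quality,
                sample_index=aln.get_tag("BC") if aln.has_tag("BC") else "",
                run_id=aln.get_tag("RG") if aln.has_tag("RG") else "",
            )


def write_aligned_records(records: Iterable[AlignedRecord], path: str | Path) -> int:
    """Write records in the TSV dialect; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.barcode_seq,
                        phred_to_quals(rec.barcode_quals),
                        rec.umi_seq,
                        phred_to_quals(rec.umi_quals),
                        rec.gene_id if rec.gene_id is not None else "",
                        str(rec.mapq),
                        rec.sample_index,
                        rec.run_id,
                    ]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Whitelist I/O


def read_whitelist(path: str | Path) -> BarcodeWhitelist:
    """Read a whitelist file with one barcode sequence per line."""
    seqs = [line.strip() for line in open(path) if line.strip()]
    return BarcodeWhitelist(sequences=seqs)


def write_whitelist(whitelist: BarcodeWhitelist, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in whitelist.sequences:
            fh.write(seq + "\n")


# ---------------------------------------------------------------------------
# Matrix I/O (MatrixMarket + genes.tsv/barcodes.tsv directory layout)


def write_matrix(matrix: GeneBarcodeMatrix, directory: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape),
        field="integer",
    )
    with open(directory / "genes.tsv", "w") as fh:
        for gid, name in zip(matrix.genes, matrix.gene_names):
            fh.write(f"{gid}\t{name}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for bc in matrix.barcodes:
            fh.write(bc + "\n")


def read_matrix(directory: str | Path) -> GeneBarcodeMatrix:
    """Read a matrix directory written by :func:`write_matrix`."""
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")).astype(np.int64))
    genes, names = [], []
    with open(directory / "genes.tsv") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            names.append(parts[1] if len(parts) > 1 else parts[0])
    barcodes = [line.strip() for line in open(directory / "barcodes.tsv") if line.strip()]
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX header {counts.shape} disagrees with sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return GeneBarcodeMatrix(genes=genes, barcodes=barcodes, counts=counts, gene_names=names)


# ---------------------------------------------------------------------------
# SNV site I/O (minimal VCF subset)


def write_snv_vcf(sites: Iterable[SnvSite], path: str | Path) -> None:
    """Write sites as a minimal VCF with per-site NCELLS in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=NCELLS,Number=1,Type=Integer,'
            'Description="Number of cell barcodes supporting the site">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{s.qual:g}\t.\tNCELLS={s.n_cells}\n"
            )


def read_snv_sites(
    vcf_path: str | Path,
    min_qual: float = 30.0,
    min_base_qual: float = 1.0,
    min_cells: int = 2,
    cell_counts: Mapping[tuple[str, int], int] | None = None,
) -> SnvTable:
    """Read and filter biallelic SNVs from a minimal VCF.

    Retains sites with QUAL >= ``min_qual`` and support from at least
    ``min_cells`` cell barcodes; multi-allelic records and indels are
    skipped (counted, not an error).  Supporting-cell counts come from
    the INFO key NCELLS, or from ``cell_counts`` keyed by (chrom, pos)
    when a sidecar table is used instead.  ``min_base_qual`` filters on
    the INFO key MINBQ when present (sites lacking it pass).
    """
    sites: list[SnvSite] = []
    n_skipped = 0
    n_filtered = 0
    with open(vcf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"line {lineno}: VCF row with <6 columns")
            chrom, pos_s, _id, ref, alt, qual_s = parts[:6]
            info = parts[7] if len(parts) > 7 else ""
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt in (".", "*"):
                n_skipped += 1  # multi-allelic or indel
                continue
            pos = int(pos_s)
            qual = float(qual_s) if qual_s != "." else 0.0
            info_map: dict[str, str] = {}
            for kv in info.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    info_map[k] = v
            if cell_counts is not None:
                n_cells = int(cell_counts.get((chrom, pos), 0))
            else:
                n_cells = int(info_map.get("NCELLS", 0))
            min_bq = float(info_map.get("MINBQ", min_base_qual))
            if qual < min_qual or n_cells < min_cells or min_bq < min_base_qual:
                n_filtered += 1
                continue
            sites.append(SnvSite(chrom, pos, ref, alt, qual, n_cells))
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records", n_skipped)
    return SnvTable(sites=sites, n_skipped_non_biallelic=n_skipped, n_filtered=n_filtered)


# ---------------------------------------------------------------------------
# Allele count pair I/O


def write_allele_counts(pair: AlleleCountPair, directory: str | Path) -> None:
    """Write ref.mtx/alt.mtx + cells.tsv + sites.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mat in (("ref", pair.ref_counts), ("alt", pair.alt_counts)):
        coo = mat.tocoo()
        scipy.io.mmwrite(
            str(directory / f"{name}.mtx"),
            sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape),
            field="integer",
        )
    with open(directory / "cells.tsv", "w") as fh:
        for c in pair.cells:
            fh.write(c + "\n")
    with open(directory / "sites.tsv", "w") as fh:
        for chrom, pos, ref, alt in pair.sites:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_allele_counts(directory: str | Path) -> AlleleCountPair:
    directory = Path(directory)
    ref = sp.csr_matrix(scipy.io.mmread(str(directory / "ref.mtx")).astype(np.int64))
    alt = sp.csr_matrix(scipy.io.mmread(str(directory / "alt.mtx")).astype(np.int64))
    cells = [line.strip() for line in open(directory / "cells.tsv") if line.strip()]
    sites = []
    with open(directory / "sites.tsv") as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, r, a = line.rstrip("\n").split("\t")
            sites.append((chrom, int(pos), r, a))
    return AlleleCountPair(cells=cells, sites=sites, ref_counts=ref, alt_counts=alt)


# ---------------------------------------------------------------------------
# Reference profile I/O


def read_reference_profiles(path: str | Path) -> pd.DataFrame:
    """Read a TSV of mean expression profiles: rows=genes, cols=populations."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_reference_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t")
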
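"""Per-SNP reference/alternative read counting for allele-specific expression.

The central quantity is the reference-allele frequency at a heterozygous
site,

    frequency = n_ref / (n_ref + n_alt),

where ``n_ref`` and ``n_alt`` are the reads carrying the reference and
alternative nucleotide. Reads carrying any third base are tallied as
``n_other`` for QC but never enter the frequency denominator.

Counting is done with pysam over a coordinate-sorted, indexed BAM. Reads
that are unmapped, secondary, supplementary or duplicate-flagged, or that
fall below the mapping/base-quality thresholds, are excluded; a read whose
alignment has a deletion or reference skip at the site contributes to no
count. Each read of a pair is counted independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("xciprof")

_BASES = frozenset("ACGT")

COUNT_TABLE_COLUMNS = [
    "chrom", "pos", "gene_id", "ref", "alt", "n_ref", "n_alt", "n_other",
    "sample_id", "status",
]


class UndefinedAlleleFrequencyError(ValueError):
    """No informative reads: the allele frequency is undefined."""


@dataclass(frozen=True)
class SnpSite:
    """One heterozygous SNP: contig, 1-based position, ref/alt bases, gene."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class AlleleCountRecord:
    """Observed read counts at one site in one sample."""

    site: SnpSite
    n_ref: int
    n_alt: int
    n_other: int = 0
    sample_id: str = "sample"
    status: str = "ok"

    def __post_init__(self) -> None:
        if min(self.n_ref, self.n_alt, self.n_other) < 0:
            raise ValueError("counts must be nonnegative")


def reference_allele_frequency(n_ref: int, n_alt: int) -> float:
    """Reference-nucleotide fraction among informative reads.

    Raises :class:`UndefinedAlleleFrequencyError` when no read carries
    either allele (callers map this to a ``no_call``).
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("counts must be nonnegative")
    total = n_ref + n_alt
    if total == 0:
        raise UndefinedAlleleFrequencyError("n_ref + n_alt = 0")
    return n_ref / total


def count_alleles_at_sites(
    alignments: str | Path | pysam.AlignmentFile,
    sites: Sequence[SnpSite],
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    sample_id: str = "sample",
) -> list[AlleleCountRecord]:
    """Count ref/alt/other reads at each site from an indexed alignment file.

    Output order follows input site order. A site whose contig is absent
    from the alignment header yields a zero-count record with status
    ``missing_contig``; an unindexed input raises.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        if not alignments.has_index():
            raise ValueError("alignment file must be coordinate-sorted and indexed")
        contigs = set(alignments.references)
        records = []
        for site in sites:
            if site.chrom not in contigs:
                records.append(
                    AlleleCountRecord(
                        site=site, n_ref=0, n_alt=0, n_other=0,
                        sample_id=sample_id, status="missing_contig",
                    )
                )
                continue
            n_ref = n_alt = n_other = 0
            target = site.pos - 1  # to 0-based
            for read in alignments.fetch(site.chrom, target, site.pos):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                if read.mapping_quality < min_mapping_quality:
                    continue
                qpos = None
                for q, r in read.get_aligned_pairs(matches_only=True):
                    if r == target:
                        qpos = q
                        break
                if qpos is None:  # deletion or reference skip at the site
                    continue
                if read.query_qualities is not None and (
                    read.query_qualities[qpos] < min_base_quality
                ):
                    continue
                base = read.query_sequence[qpos].upper()
                if base == site.ref:
                    n_ref += 1
                elif base == site.alt:
                    n_alt += 1
                else:
                    n_other += 1
            records.append(
                AlleleCountRecord(
                    site=site, n_ref=n_ref, n_alt=n_alt, n_other=n_other,
                    sample_id=sample_id,
                )
            )
        return records
    finally:
        if own:
            alignments.close()


def sam_to_indexed_bam(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Convert a SAM to a coordinate-sorted, indexed BAM (helper for fixtures)."""
    sam_path, bam_path = Path(sam_path), Path(bam_path)
    tmp = bam_path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(sam_path)) as sam, pysam.AlignmentFile(
        str(tmp), "wb", template=sam
    ) as bam:
        for read in sam:
            bam.write(read)
    pysam.sort("-o", str(bam_path), str(tmp))
    tmp.unlink()
    pysam.index(str(bam_path))
    return bam_path


def read_sites_vcf(path: str | Path, gene_info_key: str = "GENE") -> list[SnpSite]:
    """Load biallelic SNV sites from a VCF v4.2; other records are skipped.

    The owning gene is taken from the ``GENE`` INFO field when present,
    otherwise from the record ID, otherwise left as ``"."``.
    """
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _BASES
                or alts[0] not in _BASES
            ):
                logger.warning(
                    "skipping non-biallelic-SNV record at %s:%s", rec.chrom, rec.pos
                )
                continue
            gene = rec.info.get(gene_info_key) if gene_info_key in rec.info else None
            if gene is None:
                gene = rec.id or "."
            sites.append(
                SnpSite(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0],
                        gene_id=str(gene))
            )
    return sites


def write_count_table(records: Iterable[AlleleCountRecord], path: str | Path) -> Path:
    """Write records to the counts TSV (columns fixed and documented)."""
    rows = [
        {
            "chrom": r.site.chrom, "pos": r.site.pos, "gene_id": r.site.gene_id,
            "ref": r.site.ref, "alt": r.site.alt, "n_ref": r.n_ref,
            "n_alt": r.n_alt, "n_other": r.n_other, "sample_id": r.sample_id,
            "status": r.status,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_count_table(path: str | Path) -> list[AlleleCountRecord]:
    """Read a counts TSV back into records; malformed rows raise with the
    offending line number."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        try:
            site = SnpSite(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alt=str(row.alt), gene_id=str(row.gene_id),
            )
            rec = AlleleCountRecord(
                site=site, n_ref=int(row.n_ref), n_alt=int(row.n_alt),
                n_other=int(row.n_other), sample_id=str(row.sample_id),
                status=str(row.status),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed count-table row at line {line_no}: {exc}") from exc
        records.append(rec)
    return records
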
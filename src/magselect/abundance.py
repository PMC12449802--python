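"""Per-contig coverage and per-genome abundance (GenomeCov).

Coverage of a contig m is the total number of read nucleotides aligned to m
divided by the contig length:

    coverage(m) = sum_r count(nucleotides of r mapped to m) / length(m)

and the abundance of a genome (bin) G is the sum of its contigs' coverages
divided by the sum of their lengths:

    GenomeCov(G) = sum_{m in G} coverage(m) / sum_{m in G} length(m)

This is the as-printed statistic and the package default.  Note its units:
because coverages (x-fold) are summed and divided by summed base pairs, it is
coverage-per-bp, not the conventional length-weighted mean per-base coverage
sum(coverage*length)/sum(length); the latter is available as
``mode="weighted_mean"``.

Aligned bases are taken from SAM primary alignments only, counting CIGAR
operations that consume both query and reference (M, =, X); soft/hard clips,
insertions and deletions contribute nothing, and unmapped, secondary and
supplementary records contribute zero.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .io_formats import AbundanceMatrix

ABUNDANCE_MODES = ("as_printed", "weighted_mean")


@dataclass(frozen=True)
class MappingRecord:
    """Aggregated aligned-base count for one contig (from one sample)."""

    contig_id: str
    aligned_bases: int

    def __post_init__(self) -> None:
        if self.aligned_bases < 0:
            raise ValueError(f"{self.contig_id}: aligned_bases < 0")


@dataclass(frozen=True)
class ContigInfo:
    """A contig's length in bp and (optional) bin membership."""

    contig_id: str
    length: int
    bin_id: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.contig_id}: length must be >= 1")


def contig_coverage(
    records: Iterable[MappingRecord], contigs: Iterable[ContigInfo]
) -> dict[str, float]:
    """coverage(m) = summed aligned bases / length(m); 0 with no records."""
    contigs = list(contigs)
    lengths = {c.contig_id: c.length for c in contigs}
    totals: dict[str, int] = defaultdict(int)
    for rec in records:
        if rec.contig_id not in lengths:
            raise KeyError(f"mapping record references unknown contig {rec.contig_id!r}")
        totals[rec.contig_id] += rec.aligned_bases
    return {c.contig_id: totals[c.contig_id] / c.length for c in contigs}


def genome_abundance(
    coverages: Mapping[str, float],
    contigs: Iterable[ContigInfo],
    bin_id: str,
    mode: str = "as_printed",
) -> float:
    """Abundance of one bin from its contigs' coverages.

    ``as_printed`` follows the GenomeCov equation literally
    (sum coverage / sum length); ``weighted_mean`` computes the conventional
    mean per-base coverage sum(coverage*length)/sum(length).
    """
    if mode not in ABUNDANCE_MODES:
        raise ValueError(f"unknown abundance mode {mode!r}")
    members = [c for c in contigs if c.bin_id == bin_id]
    if not members:
        raise ValueError(f"bin {bin_id!r} has no contigs")
    total_len = sum(c.length for c in members)
    if mode == "as_printed":
        return sum(coverages[c.contig_id] for c in members) / total_len
    return sum(coverages[c.contig_id] * c.length for c in members) / total_len


# CIGAR operation codes that consume both query and reference: M, =, X
_ALIGNED_OPS = frozenset({0, 7, 8})


def aligned_bases_from_sam(path: str | Path) -> list[MappingRecord]:
    """Count aligned bases per contig from a SAM/BAM file.

    One aggregated :class:`MappingRecord` is returned per reference contig
    that received at least one primary alignment.
    """
    totals: dict[str, int] = defaultdict(int)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for i, aln in enumerate(fh):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = aln.cigartuples
            if cigar is None:
                raise ValueError(
                    f"{path}: alignment #{i + 1} ({aln.query_name!r}) is mapped "
                    "but has no CIGAR"
                )
            totals[aln.reference_name] += sum(
                length for op, length in cigar if op in _ALIGNED_OPS
            )
    return [MappingRecord(c, n) for c, n in totals.items()]


def read_contig_table(path: str | Path) -> list[ContigInfo]:
    """TSV with columns contig_id, length, bin_id (bin_id may be blank)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    out = []
    for _, row in df.iterrows():
        bin_id = row.get("bin_id")
        if bin_id is not None and (pd.isna(bin_id) or str(bin_id).strip() == ""):
            bin_id = None
        out.append(ContigInfo(str(row["contig_id"]), int(row["length"]), bin_id))
    return out


def read_contig2bin(path: str | Path) -> dict[str, str]:
    """2-column headerless or headered contig->bin membership TSV."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if str(df.iloc[0, 0]).lower() in ("contig_id", "contig"):
        df = df.iloc[1:]
    return {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}


def build_abundance_matrix(
    per_sample: Mapping[str, Iterable[MappingRecord]],
    contigs: Iterable[ContigInfo],
    mode: str = "as_printed",
) -> AbundanceMatrix:
    """Assemble GenomeCov across samples: one row per bin, one column per sample.

    Samples and bins are sorted for a canonical, input-order-independent
    layout.  A contig may belong to at most one bin; unbinned contigs are
    ignored for abundance but still validated against mapping records.
    """
    contigs = list(contigs)
    seen: dict[str, str] = {}
    for c in contigs:
        if c.contig_id in seen:
            raise ValueError(
                f"contig {c.contig_id!r} listed twice "
                f"(bins {seen[c.contig_id]!r} and {c.bin_id!r})"
            )
        seen[c.contig_id] = c.bin_id or ""
    bins = sorted({c.bin_id for c in contigs if c.bin_id is not None})
    if not bins:
        raise ValueError("no binned contigs")
    sample_ids = sorted(per_sample)
    coverages = {s: contig_coverage(per_sample[s], contigs) for s in sample_ids}
    values = [
        [genome_abundance(coverages[s], contigs, b, mode=mode) for s in sample_ids]
        for b in bins
    ]
    return AbundanceMatrix(bins, sample_ids, values)
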
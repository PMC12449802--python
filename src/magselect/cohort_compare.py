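"""Cross-cohort and within-cohort summaries.

Species identity is the full 7-rank taxonomy string (whitespace-trimmed);
two cohorts "share" a species when the strings are equal.  The cohort's mean
abundance is the grand mean over all matrix cells (excluded samples
omitted), and a selected genome counts as "low abundance" when its own mean
abundance falls below that grand mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AbundanceMatrix, GenomeRecord

MEAN_MODES = ("grand_mean", "mean_of_genome_means")


@dataclass
class CohortSummary:
    """One cohort's species sets, selected subset and mean abundance."""

    cohort_id: str
    species_set: set[str]
    uncultivated_species_set: set[str]
    selected_subset: list[str] = field(default_factory=list)
    mean_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not self.uncultivated_species_set <= self.species_set:
            raise ValueError("uncultivated species must be a subset of all species")


def summarize_cohort(
    cohort_id: str,
    records: Sequence[GenomeRecord],
    matrix: AbundanceMatrix,
    selected_subset: Sequence[str] = (),
    mean_mode: str = "grand_mean",
) -> CohortSummary:
    if mean_mode not in MEAN_MODES:
        raise ValueError(f"unknown mean mode {mean_mode!r}")
    species = {r.taxonomy.strip() for r in records}
    unc = {r.taxonomy.strip() for r in records if r.is_uncultivated}
    if mean_mode == "grand_mean":
        mean = float(matrix.values.mean())
    else:
        mean = float(matrix.values.mean(axis=1).mean())
    return CohortSummary(cohort_id, species, unc, list(selected_subset), mean)


def shared_species(a: CohortSummary, b: CohortSummary) -> tuple[int, int, int]:
    """Venn counts (only in a, shared, only in b) over species annotations."""
    inter = a.species_set & b.species_set
    return (len(a.species_set - inter), len(inter), len(b.species_set - inter))


def shared_uncultivated(a: CohortSummary, b: CohortSummary) -> int:
    """Number of uncultivated species annotations present in both cohorts."""
    return len(a.uncultivated_species_set & b.uncultivated_species_set)


def taxonomy_distribution(
    records: Sequence[GenomeRecord], rank: str
) -> dict[str, float]:
    """Fraction of genomes per taxon name at ``rank`` (phylum or class).

    Empty rank values are pooled into "Unclassified"; fractions sum to 1.
    """
    if rank not in ("phylum", "class"):
        raise ValueError(f"rank must be phylum or class, got {rank!r}")
    records = list(records)
    if not records:
        raise ValueError("empty genome collection")
    counts: Counter[str] = Counter()
    for r in records:
        name = r.ranks[rank] or "Unclassified"
        counts[name] += 1
    n = len(records)
    return {name: c / n for name, c in sorted(counts.items())}


def low_abundance_summary(
    selected: Sequence[str],
    matrix: AbundanceMatrix,
    mean_mode: str = "grand_mean",
) -> tuple[float, int, float]:
    """(threshold, n_low, pct_low) for a selected genome subset.

    The threshold is the cohort mean abundance; a selected genome is low
    abundance iff its per-genome mean over the matrix samples is strictly
    below it.  ``pct_low`` is rounded to 2 decimals.
    """
    if not selected:
        raise ValueError("empty selection")
    if mean_mode not in MEAN_MODES:
        raise ValueError(f"unknown mean mode {mean_mode!r}")
    if mean_mode == "grand_mean":
        threshold = float(matrix.values.mean())
    else:
        threshold = float(matrix.values.mean(axis=1).mean())
    sub = matrix.subset_genomes(list(selected))
    genome_means = sub.values.mean(axis=1)
    n_low = int(np.sum(genome_means < threshold))
    pct_low = round(100.0 * n_low / len(selected), 2)
    return threshold, n_low, pct_low
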
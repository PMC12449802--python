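"""MIMAG medium-quality retention and the uncultivated-species flag.

A genome is kept iff completeness >= 50% and contamination < 10% (the MIMAG
medium-quality band; "at least 50%" is inclusive, the 10% contamination bound
is exclusive per the MIMAG medium convention).

A genome is flagged as potentially uncultivated when its closest-species ANI
is absent ("N/A" from the classifier, which refuses to report ANI below its
95% confidence floor).  An extended rule additionally flags genomes whose
reported ANI falls below a threshold (default 95%).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GenomeRecord

logger = logging.getLogger("magselect")

COMPLETENESS_MIN = 50.0
CONTAMINATION_MAX = 10.0

UNCULTIVATED_RULES = ("absent_only", "below_threshold")


def filter_medium_quality(
    records: Iterable[GenomeRecord],
) -> tuple[set[str], set[str]]:
    """Partition genome ids into (kept, dropped) by the medium-quality rule."""
    kept: set[str] = set()
    dropped: set[str] = set()
    for r in records:
        ok = r.completeness >= COMPLETENESS_MIN and r.contamination < CONTAMINATION_MAX
        (kept if ok else dropped).add(r.genome_id)
    logger.info(
        "quality filter: kept %d, dropped %d (completeness >= %g, contamination < %g)",
        len(kept), len(dropped), COMPLETENESS_MIN, CONTAMINATION_MAX,
    )
    return kept, dropped


def flag_uncultivated(
    records: Iterable[GenomeRecord],
    ani_threshold: float = 95.0,
    rule: str = "absent_only",
) -> set[str]:
    """Genome ids flagged as potentially uncultivated.

    ``absent_only`` (default, the operational rule): flagged iff closest ANI
    is absent.  ``below_threshold``: additionally flagged when a reported ANI
    is strictly below ``ani_threshold``.
    """
    if rule not in UNCULTIVATED_RULES:
        raise ValueError(f"unknown uncultivated rule {rule!r}")
    flagged: set[str] = set()
    for r in records:
        if r.closest_ani is None:
            flagged.add(r.genome_id)
        elif rule == "below_threshold" and r.closest_ani < ani_threshold:
            flagged.add(r.genome_id)
    return flagged


def uncultivated_proportion(
    records: Sequence[GenomeRecord],
    ani_threshold: float = 95.0,
    rule: str = "absent_only",
) -> float:
    """Fraction of genomes flagged uncultivated; errors on an empty input."""
    records = list(records)
    if not records:
        raise ValueError("cannot compute a proportion of zero genomes")
    return len(flag_uncultivated(records, ani_threshold, rule)) / len(records)


def write_filter_report(
    records: Iterable[GenomeRecord],
    path: str | Path,
    rule: str = "absent_only",
) -> pd.DataFrame:
    """Per-genome TSV: quality fields, kept flag and uncultivated flag."""
    records = list(records)
    kept, _ = filter_medium_quality(records)
    flagged = flag_uncultivated(records, rule=rule)
    df = pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "kept": r.genome_id in kept,
                "is_uncultivated": r.genome_id in flagged,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
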
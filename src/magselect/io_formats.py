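"""Readers/writers for the on-disk artifacts of the MAG analysis pipeline.

All tabular formats are plain TSV with a single header row.  Every reader
validates its input strictly and returns one of the in-memory domain types
(:class:`AbundanceMatrix`, :class:`SampleMetadata`, :class:`GenomeRecord`)
that the rest of the package operates on.

The canonical orientation of an abundance matrix is genomes-as-rows, one
column per sample, matching MaxBin-style per-genome output; every downstream
module assumes that orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("magselect")

#: status vocabulary: on-disk token (lower-cased) -> canonical status
DEFAULT_STATUS_TOKENS: Mapping[str, str] = {
    "crc": "disease",
    "cancer": "disease",
    "case": "disease",
    "disease": "disease",
    "control": "healthy",
    "healthy": "healthy",
    "adenoma": "excluded",
    "excluded": "excluded",
}

#: spellings of an absent closest-species ANI (case-insensitive)
ANI_ABSENT_TOKENS = frozenset({"n/a", "na", ""})

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Genome-by-sample abundance matrix.

    Values are mean per-base sequencing coverages of each genome in each
    sample (the GenomeCov statistic); they must be finite and non-negative.
    """

    genome_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genomes, n_samples)

    def __post_init__(self) -> None:
        self.genome_ids = list(self.genome_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.genome_ids, "genome")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.genome_ids), len(self.sample_ids)):
            raise ValueError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance matrix contains non-finite values")
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at genome {self.genome_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genome_ids, columns=self.sample_ids
        )

    def subset_genomes(self, genome_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = {g: i for i, g in enumerate(self.genome_ids)}
        missing = [g for g in genome_ids if g not in idx]
        if missing:
            raise KeyError(f"genomes not in matrix: {missing}")
        rows = [idx[g] for g in genome_ids]
        return AbundanceMatrix(list(genome_ids), self.sample_ids, self.values[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return AbundanceMatrix(self.genome_ids, list(sample_ids), self.values[:, cols])

    def row(self, genome_id: str) -> np.ndarray:
        return self.values[self.genome_ids.index(genome_id)]


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's case/control status: disease, healthy or excluded."""

    sample_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in ("disease", "healthy", "excluded"):
            raise ValueError(f"invalid status {self.status!r}")


@dataclass(frozen=True)
class GenomeRecord:
    """Per-genome quality and classification metadata.

    ``closest_ani`` is the average nucleotide identity to the closest named
    species (GTDB-tk), or ``None`` when the classifier reported no confident
    match ("N/A") -- the operational signature of a putatively uncultivated
    species.  ``is_uncultivated`` is derived: true iff ``closest_ani`` is
    absent.
    """

    genome_id: str
    completeness: float
    contamination: float
    taxonomy: str
    closest_ani: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(
                f"{self.genome_id}: completeness {self.completeness} not in [0, 100]"
            )
        if self.contamination < 0:
            raise ValueError(
                f"{self.genome_id}: contamination {self.contamination} < 0"
            )
        if self.closest_ani is not None and not 0 <= self.closest_ani <= 100:
            raise ValueError(
                f"{self.genome_id}: ANI {self.closest_ani} not in [0, 100]"
            )
        parse_taxonomy(self.taxonomy, genome_id=self.genome_id)

    @property
    def is_uncultivated(self) -> bool:
        return self.closest_ani is None

    @property
    def ranks(self) -> dict[str, str]:
        return parse_taxonomy(self.taxonomy, genome_id=self.genome_id)


def parse_taxonomy(taxonomy: str, genome_id: str = "?") -> dict[str, str]:
    """Split a GTDB-style ``d__;p__;...;s__`` string into its 7 rank values.

    Empty rank values are allowed and returned as "".
    """
    parts = [p.strip() for p in taxonomy.split(";")]
    if len(parts) != 7:
        raise ValueError(
            f"genome {genome_id!r}: taxonomy {taxonomy!r} has {len(parts)} "
            "fields, expected 7 (domain..species)"
        )
    names = ("domain", "phylum", "class", "order", "family", "genus", "species")
    out: dict[str, str] = {}
    for name, prefix, part in zip(names, _RANK_PREFIXES, parts):
        if not part.startswith(prefix):
            raise ValueError(
                f"genome {genome_id!r}: rank field {part!r} lacks prefix {prefix!r}"
            )
        out[name] = part[len(prefix):].strip()
    return out


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Abundance matrix I/O
# ---------------------------------------------------------------------------

def read_abundance_matrix(path: str | Path, dialect: str = "genomes_as_rows") -> AbundanceMatrix:
    """Read a TSV abundance table into canonical genomes-as-rows form.

    ``dialect`` says how the file is laid out ("genomes_as_rows" or
    "samples_as_rows"); the returned matrix is always genomes-as-rows.
    """
    if dialect not in ("genomes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row" if dialect == "samples_as_rows" else "genome")
    _check_unique(col_ids, "column")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"invalid abundance {v!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                )
            values[i, j] = v
    if dialect == "samples_as_rows":
        return AbundanceMatrix(col_ids, row_ids, values.T)
    return AbundanceMatrix(row_ids, col_ids, values)


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write in canonical orientation; decimal text round-trips exactly."""
    df = matrix.to_dataframe()
    df.index.name = "genome_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Sample metadata I/O
# ---------------------------------------------------------------------------

def read_sample_metadata(
    path: str | Path,
    status_tokens: Mapping[str, str] = DEFAULT_STATUS_TOKENS,
) -> list[SampleMetadata]:
    """Read the 2-column (sample_id, status) TSV.

    Status tokens are matched case-insensitively against ``status_tokens``;
    excluded samples (e.g. adenoma) are retained but marked, so that the
    association analysis can drop them explicitly.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, status)")
    out: list[SampleMetadata] = []
    for sid, token in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = str(token).strip().lower()
        if key not in status_tokens:
            raise ValueError(
                f"{path}: unknown status token {token!r} for sample {sid!r}; "
                f"accepted tokens: {sorted(status_tokens)}"
            )
        out.append(SampleMetadata(str(sid), status_tokens[key]))
    _check_unique([m.sample_id for m in out], "sample")
    return out


def write_sample_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.status) for m in metadata],
        columns=["sample_id", "status"],
    ).to_csv(path, sep="\t", index=False)


def check_samples_covered(matrix: AbundanceMatrix, metadata: Sequence[SampleMetadata]) -> None:
    """Every matrix sample must carry a status; silent loss would bias means."""
    known = {m.sample_id for m in metadata}
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise ValueError(f"samples in matrix but not in metadata: {missing}")


# ---------------------------------------------------------------------------
# Genome quality + classification tables
# ---------------------------------------------------------------------------

_QUALITY_ALIASES = {
    "genome_id": "genome_id", "bin id": "genome_id", "bin_id": "genome_id",
    "completeness": "completeness", "contamination": "contamination",
}
_CLASSIFICATION_ALIASES = {
    "genome_id": "genome_id", "user_genome": "genome_id",
    "taxonomy": "taxonomy", "classification": "taxonomy",
}


def _normalize_columns(df: pd.DataFrame, aliases: Mapping[str, str], path: str | Path) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in aliases:
            renames[col] = aliases[key]
    df = df.rename(columns=renames)
    missing = set(aliases.values()) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def parse_ani(token: object) -> float | None:
    """Parse a closest-species ANI cell; "N/A"/"NA"/blank mean absent."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    text = str(token).strip()
    if text.lower() in ANI_ABSENT_TOKENS:
        return None
    return float(text)


def read_genome_tables(
    quality_path: str | Path,
    classification_path: str | Path,
    ani_column: str = "closest_placement_ani",
) -> list[GenomeRecord]:
    """Join a CheckM-style quality table with a GTDB-tk-style classification.

    Only genomes present in BOTH tables are returned; one-sided genomes are
    excluded with a logged warning.  ``ani_column`` selects which ANI column
    of the classification table to read (GTDB-tk versions differ); header
    matching is case-insensitive and also accepts a literal "closest_ani".
    """
    qdf = pd.read_csv(quality_path, sep="\t", header=0, dtype=str)
    qdf = _normalize_columns(qdf, _QUALITY_ALIASES, quality_path)
    cdf = pd.read_csv(classification_path, sep="\t", header=0, dtype=str)
    cdf = _normalize_columns(cdf, _CLASSIFICATION_ALIASES, classification_path)
    ani_col = None
    for col in cdf.columns:
        if str(col).strip().lower() in (ani_column.lower(), "closest_ani"):
            ani_col = col
            break
    if ani_col is None:
        raise ValueError(
            f"{classification_path}: no ANI column {ani_column!r} (or 'closest_ani')"
        )

    quality = {
        str(r["genome_id"]): (float(r["completeness"]), float(r["contamination"]))
        for _, r in qdf.iterrows()
    }
    classification = {
        str(r["genome_id"]): (str(r["taxonomy"]), parse_ani(r[ani_col]))
        for _, r in cdf.iterrows()
    }
    shared = [g for g in quality if g in classification]
    n_dropped = (len(quality) - len(shared)) + sum(
        1 for g in classification if g not in quality
    )
    if n_dropped:
        logger.warning(
            "read_genome_tables: %d genome(s) present in only one of the two "
            "tables were excluded", n_dropped,
        )
    records = []
    for g in shared:
        comp, cont = quality[g]
        tax, ani = classification[g]
        records.append(GenomeRecord(g, comp, cont, tax, ani))
    return records


def write_genome_tables(
    records: Iterable[GenomeRecord],
    quality_path: str | Path,
    classification_path: str | Path,
) -> None:
    records = list(records)
    pd.DataFrame(
        [(r.genome_id, r.completeness, r.contamination) for r in records],
        columns=["genome_id", "completeness", "contamination"],
    ).to_csv(quality_path, sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [
            (
                r.genome_id,
                r.taxonomy,
                "N/A" if r.closest_ani is None else f"{r.closest_ani:.6g}",
            )
            for r in records
        ],
        columns=["user_genome", "classification", "closest_placement_ani"],
    ).to_csv(classification_path, sep="\t", index=False)
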
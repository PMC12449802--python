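"""End-to-end pipeline orchestration with seeding and a provenance manifest.

Stages run in a fixed order: read -> quality filter -> abundance ->
differential -> importance -> cumulative selection -> ablations -> cohort
summary.  A single master seed fans out to per-stage seeds through a stable
hash of the stage name, so any stage can be rerun independently and
reproduce the full run's output.  Every run writes a ``manifest.json``
recording the configuration, the derived seeds, library versions, and a
SHA-256 checksum per output file; identical config + seed implies identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .abundance import (
    ABUNDANCE_MODES,
    aligned_bases_from_sam,
    build_abundance_matrix,
    read_contig_table,
)
from .cohort_compare import (
    CohortSummary,
    low_abundance_summary,
    shared_species,
    shared_uncultivated,
    summarize_cohort,
    taxonomy_distribution,
)
from .differential import (
    DEFAULT_EPSILON,
    SIG_METHODS,
    fc_abundance_table,
    write_differential_table,
)
from .feature_selection import (
    IMPORTANCE_MODES,
    CVParams,
    ablation_auroc,
    cumulative_selection,
    importance_scores,
)
from .io_formats import (
    AbundanceMatrix,
    read_abundance_matrix,
    read_genome_tables,
    read_sample_metadata,
)
from .quality_filter import flag_uncultivated, write_filter_report

logger = logging.getLogger("magselect")

STAGES = (
    "read", "quality_filter", "abundance", "differential",
    "importance", "selection", "ablation", "summary",
)


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of "<master>:<stage>", mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one abundance source must be set."""

    # inputs: either a precomputed matrix, or SAM files + a contig table
    abundance_path: str | None = None
    sam_paths: dict[str, str] | None = None  # sample_id -> SAM path
    contig_table_path: str | None = None
    metadata_path: str = ""
    quality_path: str = ""
    classification_path: str = ""
    # parameters
    epsilon: float = DEFAULT_EPSILON
    sig_method: str = "rank_sum"
    n_permutations: int = 999
    importance_mode: str = "permutation"
    importance_trees: int = 1000
    importance_repeats: int = 10
    cv_trees: int = 500
    k_folds: int = 10
    repeats: int = 3
    cap: int | None = None
    abundance_mode: str = "as_printed"
    uncultivated_rule: str = "absent_only"
    seed: int | None = None
    out_dir: str = "run"

    def validate(self) -> None:
        has_matrix = self.abundance_path is not None
        has_sam = self.sam_paths is not None
        if has_matrix == has_sam:
            raise ValueError(
                "exactly one abundance source must be given: a matrix TSV "
                "or SAM files with a contig table"
            )
        if has_sam and not self.contig_table_path:
            raise ValueError("SAM input requires a contig table")
        if self.seed is None:
            raise ValueError("a seed is required; unseeded runs are not allowed")
        if self.sig_method not in SIG_METHODS:
            raise ValueError(f"unknown sig_method {self.sig_method!r}")
        if self.importance_mode not in IMPORTANCE_MODES:
            raise ValueError(f"unknown importance mode {self.importance_mode!r}")
        if self.abundance_mode not in ABUNDANCE_MODES:
            raise ValueError(f"unknown abundance mode {self.abundance_mode!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_dump(obj: object, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: derive_stage_seed(config.seed, stage) for stage in STAGES}
    outputs: dict[str, Path] = {}

    # --- read ---------------------------------------------------------------
    metadata = read_sample_metadata(config.metadata_path)
    records = read_genome_tables(config.quality_path, config.classification_path)
    if config.abundance_path is not None:
        matrix = read_abundance_matrix(config.abundance_path)
    else:
        contigs = read_contig_table(config.contig_table_path)
        per_sample = {
            sid: aligned_bases_from_sam(p) for sid, p in config.sam_paths.items()
        }
        matrix = build_abundance_matrix(per_sample, contigs, mode=config.abundance_mode)
    logger.info("read: %d genomes x %d samples, %d metadata rows, %d genome records",
                matrix.n_genomes, matrix.n_samples, len(metadata), len(records))

    # --- quality filter -----------------------------------------------------
    outputs["filter_report"] = out / "filter_report.tsv"
    report = write_filter_report(records, outputs["filter_report"],
                                 rule=config.uncultivated_rule)
    kept_ids = set(report.loc[report["kept"], "genome_id"])
    known = {r.genome_id for r in records}
    missing = [g for g in matrix.genome_ids if g not in known]
    if missing:
        logger.warning("dropping %d matrix genome(s) absent from genome tables",
                       len(missing))
    keep = [g for g in matrix.genome_ids if g in kept_ids]
    if not keep:
        raise RuntimeError("quality_filter: no genomes survive the quality filter")
    matrix = matrix.subset_genomes(keep)
    records = [r for r in records if r.genome_id in set(keep)]
    logger.info("quality_filter: %d genomes retained", matrix.n_genomes)

    # --- differential -------------------------------------------------------
    rows = fc_abundance_table(
        matrix, metadata,
        epsilon=config.epsilon, sig_method=config.sig_method,
        n_permutations=config.n_permutations, seed=seeds["differential"],
    )
    outputs["differential"] = out / "differential.tsv"
    write_differential_table(rows, outputs["differential"])
    logger.info("differential: %d rows, %d significant",
                len(rows), sum(r.significant for r in rows))

    # --- importance + selection ---------------------------------------------
    by_id = {m.sample_id: m.status for m in metadata}
    included = [s for s in matrix.sample_ids if by_id[s] != "excluded"]
    cls_matrix = matrix.subset_samples(included)
    labels = np.array([1 if by_id[s] == "disease" else 0 for s in included])
    ranking = importance_scores(
        cls_matrix, labels,
        n_trees=config.importance_trees, n_repeats=config.importance_repeats,
        seed=seeds["importance"], mode=config.importance_mode,
    )
    outputs["importance"] = out / "importance.tsv"
    with open(outputs["importance"], "w") as fh:
        fh.write("genome_id\tscore\trank\n")
        for rank, (g, s) in enumerate(ranking, start=1):
            fh.write(f"{g}\t{s:.10g}\t{rank}\n")

    cv = CVParams(k=config.k_folds, repeats=config.repeats,
                  n_trees=config.cv_trees, seed=seeds["selection"])
    result = cumulative_selection(cls_matrix, labels, ranking,
                                  cap=config.cap, cv_params=cv)
    outputs["curve"] = out / "auroc_curve.tsv"
    with open(outputs["curve"], "w") as fh:
        fh.write("size\tmean_auroc\t" +
                 "\t".join(f"repeat_{i + 1}" for i in range(config.repeats)) + "\n")
        for (s, a), reps in zip(result.curve, result.per_repeat):
            fh.write(f"{s}\t{a:.10g}\t" + "\t".join(f"{r:.10g}" for r in reps) + "\n")
    logger.info("selection: best subset size %d, mean AUROC %.4f",
                result.best_size, result.best_auroc)

    # --- ablations ----------------------------------------------------------
    threshold, n_low, pct_low = low_abundance_summary(result.best_subset, cls_matrix)
    sub_means = cls_matrix.subset_genomes(result.best_subset).values.mean(axis=1)
    low_ids = {g for g, m in zip(result.best_subset, sub_means) if m < threshold}
    unc_ids = flag_uncultivated(records, rule=config.uncultivated_rule)
    unc_in_subset = unc_ids & set(result.best_subset)
    for label, exclude in (("low_abundance", low_ids), ("uncultivated", unc_in_subset)):
        if exclude and len(exclude) < len(result.best_subset):
            result.ablations[label] = ablation_auroc(
                cls_matrix, labels, result.best_subset, exclude, cv_params=cv
            )
        else:
            result.ablations[label] = result.best_auroc if not exclude else float("nan")
    logger.info("ablation: %s", result.ablations)

    outputs["selection"] = out / "selection.json"
    _json_dump(
        {
            **result.to_dict(),
            "low_abundance": {"threshold": threshold, "n_low": n_low,
                              "pct_low": pct_low,
                              "low_ids": sorted(low_ids)},
            "uncultivated_in_subset": sorted(unc_in_subset),
            "seeds": seeds,
        },
        outputs["selection"],
    )

    # --- cohort summary -----------------------------------------------------
    summary = summarize_cohort("run", records, cls_matrix, result.best_subset)
    outputs["summary"] = out / "cohort_summary.json"
    _json_dump(
        {
            "cohort_id": summary.cohort_id,
            "n_genomes": len(records),
            "n_species": len(summary.species_set),
            "species_set": sorted(summary.species_set),
            "uncultivated_species_set": sorted(summary.uncultivated_species_set),
            "selected_subset": summary.selected_subset,
            "selected_species": sorted(
                {r.taxonomy.strip() for r in records
                 if r.genome_id in set(result.best_subset)}
            ),
            "mean_abundance": summary.mean_abundance,
            "taxonomy_phylum": taxonomy_distribution(records, "phylum"),
            "taxonomy_class": taxonomy_distribution(records, "class"),
        },
        outputs["summary"],
    )

    # --- manifest -----------------------------------------------------------
    # out_dir is where the manifest lives; keeping it out of the manifest
    # body makes two identical runs in different directories byte-identical
    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "out_dir"},
        "seeds": seeds,
        "versions": _library_versions(),
        "checksums": {name: _sha256(p) for name, p in sorted(outputs.items())},
        "outputs": {name: p.name for name, p in sorted(outputs.items())},
    }
    _json_dump(manifest, out / "manifest.json")
    return manifest


def _library_versions() -> dict[str, str]:
    import sklearn
    import scipy
    import pandas

    return {
        "magselect": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
    }


def compare_cohorts(run_a: str | Path, run_b: str | Path) -> dict:
    """Cross-cohort report from two completed run directories."""
    summaries = []
    for run in (run_a, run_b):
        path = Path(run) / "cohort_summary.json"
        if not path.exists():
            raise FileNotFoundError(f"incomplete run directory: {run} (no {path.name})")
        with open(path) as fh:
            summaries.append(json.load(fh))
    a, b = summaries
    ca = CohortSummary("a", set(a["species_set"]),
                       set(a["uncultivated_species_set"]))
    cb = CohortSummary("b", set(b["species_set"]),
                       set(b["uncultivated_species_set"]))
    only_a, shared, only_b = shared_species(ca, cb)
    sel_a = set(a.get("selected_species", []))
    sel_b = set(b.get("selected_species", []))
    return {
        "shared_species": {"only_a": only_a, "shared": shared, "only_b": only_b},
        "shared_uncultivated": shared_uncultivated(ca, cb),
        "selected_species_overlap": len(sel_a & sel_b),
    }
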
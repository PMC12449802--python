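"""Synthetic case/control MAG cohort generator with known planted structure.

The generator emulates the statistical shape of a co-assembled gut-metagenome
cohort: per-genome baseline abundances (mean per-base coverages) drawn from a
log-normal, a minority of genomes planted with a case/control log2
fold-of-change whose sign is randomized, differential genomes biased toward
the low-abundance stratum (below the median baseline), multiplicative gamma
sampling noise per sample, and a configurable fraction of genomes whose
closest-species ANI is absent (the uncultivated-species signature).

Defaults follow the real cohorts where they state a value: 74 disease / 54
healthy samples and 351 genomes (the larger cohort), an uncultivated fraction
of 39/351, and a baseline log-normal whose grand mean (~1.87x coverage) sits
at the scale of the printed cohort means (1.9066 and 1.447).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    AbundanceMatrix,
    GenomeRecord,
    SampleMetadata,
    write_abundance_matrix,
    write_genome_tables,
    write_sample_metadata,
)

# Small taxonomy pools for synthetic classification strings.  Proportions
# loosely follow a gut microbiome: Firmicutes/Clostridia dominate, with
# Bacteroidota, Proteobacteria and Actinobacteriota minorities.
_TAXA = [
    ("Firmicutes_A", "Clostridia", 0.55),
    ("Bacteroidota", "Bacteroidia", 0.25),
    ("Proteobacteria", "Gammaproteobacteria", 0.10),
    ("Actinobacteriota", "Coriobacteriia", 0.10),
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort; all randomness flows from ``seed``."""

    n_disease: int = 74
    n_healthy: int = 54
    n_genomes: int = 351
    frac_differential: float = 0.05
    effect_log2fc: float = 2.0
    low_abundance_bias: float = 0.9
    baseline_log_mean: float = -0.5
    baseline_log_sd: float = 1.5
    # squared coefficient of variation of the per-sample gamma noise; gut
    # species abundances across hosts are strongly overdispersed, so single
    # planted genomes are informative but not individually sufficient
    noise_dispersion: float = 2.0
    frac_uncultivated: float = 39 / 351
    seed: int = 0
    species_prefix: str = "Synth"

    def __post_init__(self) -> None:
        if min(self.n_disease, self.n_healthy, self.n_genomes) < 1:
            raise ValueError("sample and genome counts must be positive")
        for name in ("frac_differential", "low_abundance_bias", "frac_uncultivated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.effect_log2fc <= 0 and self.frac_differential > 0:
            raise ValueError("effect_log2fc must be positive")
        if self.baseline_log_sd <= 0 or self.noise_dispersion <= 0:
            raise ValueError("baseline_log_sd and noise_dispersion must be positive")
        if self.frac_differential > 0 and self.n_genomes * self.frac_differential < 1:
            raise ValueError(
                "frac_differential > 0 requires at least one differential genome "
                f"(n_genomes*frac_differential = {self.n_genomes * self.frac_differential})"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    differential_ids: frozenset[str]
    planted_log2fc: dict[str, float]  # signed; 0.0 for non-differential genomes
    uncultivated_ids: frozenset[str]
    low_abundance_ids: frozenset[str]  # baseline below the median baseline


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[AbundanceMatrix, list[SampleMetadata], list[GenomeRecord], GroundTruth]:
    """Draw one synthetic cohort.

    Per-genome baseline mu_G ~ exp(Normal(baseline_log_mean, baseline_log_sd));
    differential genomes get a disease-group mean of mu_G * 2**(+-effect_log2fc)
    (sign random) while the healthy mean stays mu_G; each cell is then drawn
    from a gamma with that group mean and squared coefficient of variation
    equal to ``noise_dispersion``.
    """
    rng = np.random.default_rng(spec.seed)
    n_g, n_d, n_h = spec.n_genomes, spec.n_disease, spec.n_healthy
    width = max(3, len(str(n_g)))
    genome_ids = [f"bin.{i:0{width}d}" for i in range(1, n_g + 1)]

    mu = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_g))
    median_mu = float(np.median(mu))
    low_stratum = mu < median_mu

    n_diff = int(round(spec.frac_differential * n_g))
    diff_idx: list[int] = []
    if n_diff:
        low_pool = list(np.flatnonzero(low_stratum))
        high_pool = list(np.flatnonzero(~low_stratum))
        rng.shuffle(low_pool)
        rng.shuffle(high_pool)
        for _ in range(n_diff):
            take_low = rng.random() < spec.low_abundance_bias
            pool = low_pool if (take_low and low_pool) or not high_pool else high_pool
            diff_idx.append(pool.pop())
    diff_idx_arr = np.array(sorted(diff_idx), dtype=int)

    signs = np.zeros(n_g)
    if len(diff_idx_arr):
        signs[diff_idx_arr] = rng.choice([-1.0, 1.0], size=len(diff_idx_arr))
    disease_mean = mu * 2.0 ** (signs * spec.effect_log2fc)
    healthy_mean = mu

    shape = 1.0 / spec.noise_dispersion  # gamma: CV^2 = 1/shape
    values = np.empty((n_g, n_d + n_h))
    values[:, :n_d] = rng.gamma(
        shape, disease_mean[:, None] * spec.noise_dispersion, size=(n_g, n_d)
    )
    values[:, n_d:] = rng.gamma(
        shape, healthy_mean[:, None] * spec.noise_dispersion, size=(n_g, n_h)
    )
    np.clip(values, 0.0, None, out=values)

    sample_ids = [f"D{i:03d}" for i in range(1, n_d + 1)] + [
        f"H{i:03d}" for i in range(1, n_h + 1)
    ]
    matrix = AbundanceMatrix(genome_ids, sample_ids, values)
    metadata = [SampleMetadata(s, "disease") for s in sample_ids[:n_d]] + [
        SampleMetadata(s, "healthy") for s in sample_ids[n_d:]
    ]

    # genome metadata: quality always within the medium-quality band so the
    # quality filter keeps every synthetic genome; ANI absent for an exact
    # round(frac_uncultivated * n) subset.
    completeness = rng.uniform(50.0, 100.0, size=n_g)
    contamination = rng.uniform(0.0, 10.0, size=n_g)
    n_unc = int(round(spec.frac_uncultivated * n_g))
    unc_idx = set(rng.choice(n_g, size=n_unc, replace=False).tolist())
    taxa_p = np.array([t[2] for t in _TAXA])
    taxa_choice = rng.choice(len(_TAXA), size=n_g, p=taxa_p / taxa_p.sum())
    records = []
    for i, g in enumerate(genome_ids):
        phylum, klass = _TAXA[taxa_choice[i]][:2]
        ani = None if i in unc_idx else float(rng.uniform(95.0, 100.0))
        taxonomy = (
            f"d__Bacteria;p__{phylum};c__{klass};o__;f__;"
            f"g__{spec.species_prefix};s__{spec.species_prefix} sp{i + 1:04d}"
        )
        records.append(
            GenomeRecord(
                g,
                float(completeness[i]),
                # keep strictly below the 10% contamination cutoff
                min(float(contamination[i]), 9.999),
                taxonomy,
                ani,
            )
        )

    truth = GroundTruth(
        differential_ids=frozenset(genome_ids[i] for i in diff_idx_arr),
        planted_log2fc={
            genome_ids[i]: float(signs[i] * spec.effect_log2fc) for i in range(n_g)
        },
        uncultivated_ids=frozenset(genome_ids[i] for i in sorted(unc_idx)),
        low_abundance_ids=frozenset(
            genome_ids[i] for i in np.flatnonzero(low_stratum)
        ),
    )
    return matrix, metadata, records, truth


def write_fixture_set(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, str]:
    """Generate a cohort and write the four pipeline input files plus truth.

    Returns a manifest mapping artifact names to file paths; also writes the
    manifest itself as ``manifest.json`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata, records, truth = generate_cohort(spec)
    paths = {
        "abundance": out / "abundance.tsv",
        "metadata": out / "metadata.tsv",
        "quality": out / "quality.tsv",
        "classification": out / "classification.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_abundance_matrix(matrix, paths["abundance"])
    write_sample_metadata(metadata, paths["metadata"])
    write_genome_tables(records, paths["quality"], paths["classification"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "differential_ids": sorted(truth.differential_ids),
                "planted_log2fc": truth.planted_log2fc,
                "uncultivated_ids": sorted(truth.uncultivated_ids),
                "low_abundance_ids": sorted(truth.low_abundance_ids),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest = {k: str(v) for k, v in paths.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
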
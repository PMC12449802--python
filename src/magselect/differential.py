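"""Group means, log2 fold-of-change, significance and FDR per genome.

For each genome G the disease and healthy group means are plain arithmetic
means of its abundance over the included samples of each group; the effect
statistic is

    log2FC(G) = log2((Disease(Abund_G) + eps) / (Healthy(Abund_G) + eps))

with a small epsilon guarding zero means (the statistic converges to the
plain log-ratio as eps -> 0 whenever both means are positive).  Samples with
status "excluded" (e.g. adenoma) never enter any group statistic.

Significance of differential distribution between the two groups is assessed
per genome with an assumption-light two-group test — a two-sided
Mann-Whitney rank-sum test by default (exact enumeration for tiny groups,
normal approximation with tie correction otherwise) or a seeded label-
permutation test on the absolute difference of group means.  This replaces
the count-model (edgeR-style) machinery that is not appropriate for
continuous coverage values; report headers record the substitution.
Multiple testing is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceMatrix, SampleMetadata, check_samples_covered

DEFAULT_EPSILON = 1e-6
SIGNIFICANCE_ALPHA = 0.05  # raw-p highlight threshold for the FC/abundance table
SIG_METHODS = ("rank_sum", "permutation")

REPORT_HEADER_NOTE = (
    "# significance: in-repo two-group test (rank_sum/permutation), "
    "not edgeR as in the original workflow"
)


def _group_columns(
    matrix: AbundanceMatrix, metadata: Sequence[SampleMetadata], status: str
) -> list[int]:
    check_samples_covered(matrix, metadata)
    by_id = {m.sample_id: m.status for m in metadata}
    return [i for i, s in enumerate(matrix.sample_ids) if by_id[s] == status]


def group_mean(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleMetadata],
    group: str,
) -> dict[str, float]:
    """Arithmetic mean abundance of each genome over samples of one status."""
    if group not in ("disease", "healthy"):
        raise ValueError(f"group must be disease or healthy, got {group!r}")
    cols = _group_columns(matrix, metadata, group)
    if not cols:
        raise ValueError(f"no samples with status {group!r}")
    means = matrix.values[:, cols].mean(axis=1)
    return dict(zip(matrix.genome_ids, means.tolist()))


def log2_fold_change(
    disease_mean: float, healthy_mean: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """log2((disease_mean + eps) / (healthy_mean + eps)); eps > 0 required."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if disease_mean < 0 or healthy_mean < 0:
        raise ValueError("group means must be non-negative")
    return float(np.log2((disease_mean + epsilon) / (healthy_mean + epsilon)))


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    # exact enumeration only feasible/needed for tiny groups
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def differential_significance(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleMetadata],
    method: str = "rank_sum",
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Two-sided per-genome p-value for disease-vs-healthy distribution.

    A genome whose value is identical in every included sample is degenerate
    and receives p = 1.0.
    """
    if method not in SIG_METHODS:
        raise ValueError(f"unknown significance method {method!r}")
    d_cols = _group_columns(matrix, metadata, "disease")
    h_cols = _group_columns(matrix, metadata, "healthy")
    if not d_cols or not h_cols:
        raise ValueError("both disease and healthy groups must be non-empty")
    # canonical column order (matrix order) keeps the seeded permutation
    # stream identical under a disease/healthy label swap
    cols = sorted(d_cols + h_cols)
    is_disease = np.isin(cols, d_cols)
    X = matrix.values[:, cols]
    nd, nh = len(d_cols), len(h_cols)
    constant = np.all(X == X[:, [0]], axis=1)

    if method == "rank_sum":
        p = np.ones(matrix.n_genomes)
        for i in range(matrix.n_genomes):
            if not constant[i]:
                p[i] = _rank_sum_p(X[i, is_disease], X[i, ~is_disease])
    else:
        if n_permutations < 99:
            raise ValueError("permutation method needs n_permutations >= 99")
        rng = np.random.default_rng(seed)
        observed = np.abs(
            X[:, is_disease].mean(axis=1) - X[:, ~is_disease].mean(axis=1)
        )
        exceed = np.zeros(matrix.n_genomes)
        n = X.shape[1]
        # the |mean difference| between a random subset of size k and its
        # complement has the same null law whichever group the subset plays,
        # so drawing the smaller group keeps p label-swap symmetric
        k = min(nd, nh)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            a = X[:, perm[:k]].mean(axis=1)
            b = X[:, perm[k:]].mean(axis=1)
            exceed += np.abs(a - b) >= observed
        p = (1.0 + exceed) / (1.0 + n_permutations)
        p[constant] = 1.0
    p = np.clip(p, 0.0, 1.0)
    return dict(zip(matrix.genome_ids, p.tolist()))


def bh_fdr(p_values: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up q-values, clipped to 1."""
    ids = list(p_values)
    p = np.array([p_values[g] for g in ids], dtype=float)
    if p.size == 0:
        return {}
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return dict(zip(ids, q.tolist()))


@dataclass(frozen=True)
class DifferentialRow:
    """Per-genome differential-abundance summary (one row of Table-S2 shape)."""

    genome_id: str
    disease_mean: float
    healthy_mean: float
    overall_mean: float
    log2fc: float
    p_value: float
    fdr: float
    significant: bool
    degenerate: bool = False


def fc_abundance_table(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleMetadata],
    epsilon: float = DEFAULT_EPSILON,
    sig_method: str = "rank_sum",
    n_permutations: int = 999,
    seed: int = 0,
) -> list[DifferentialRow]:
    """The FC-vs-abundance table: means, log2FC, p, FDR and significance flag.

    ``significant`` uses raw p <= 0.05 (the scatter-plot highlight rule), not
    the FDR column.
    """
    d_means = group_mean(matrix, metadata, "disease")
    h_means = group_mean(matrix, metadata, "healthy")
    included = _group_columns(matrix, metadata, "disease") + _group_columns(
        matrix, metadata, "healthy"
    )
    overall = matrix.values[:, included].mean(axis=1)
    X = matrix.values[:, included]
    constant = np.all(X == X[:, [0]], axis=1)
    p = differential_significance(
        matrix, metadata, method=sig_method, n_permutations=n_permutations, seed=seed
    )
    q = bh_fdr(p)
    rows = []
    for i, g in enumerate(matrix.genome_ids):
        rows.append(
            DifferentialRow(
                genome_id=g,
                disease_mean=d_means[g],
                healthy_mean=h_means[g],
                overall_mean=float(overall[i]),
                log2fc=log2_fold_change(d_means[g], h_means[g], epsilon),
                p_value=p[g],
                fdr=q[g],
                significant=p[g] <= SIGNIFICANCE_ALPHA,
                degenerate=bool(constant[i]),
            )
        )
    return rows


def write_differential_table(rows: Sequence[DifferentialRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "disease_mean": r.disease_mean,
                "healthy_mean": r.healthy_mean,
                "overall_mean": r.overall_mean,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
    with open(path, "w") as fh:
        fh.write(REPORT_HEADER_NOTE + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
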
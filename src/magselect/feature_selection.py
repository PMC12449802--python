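"""Random-forest importance ranking and cumulative forward feature selection.

The procedure has two steps.  First, a random forest (1,000 trees by default)
is fit on the full genome-by-sample abundance matrix and a per-genome
importance score is extracted — by default the classical mean-decrease-
accuracy, i.e. permutation importance: the drop in accuracy when one
genome's column is shuffled, averaged over seeded repeats (the named
toolkit's impurity-based importance is available as an alternative mode).
Second, genomes are added one by one in descending importance order and each
prefix subset is scored by stratified 10-fold cross-validated AUROC, repeated
3 times with reshuffled folds and averaged; the smallest subset attaining the
maximal mean AUROC is selected.  Ablations rescore the selected subset with a
set of genomes removed under the identical CV seeding.

AUROC is the Mann-Whitney statistic: the probability that a random positive
sample is scored above a random negative one, ties counted 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_formats import AbundanceMatrix

logger = logging.getLogger("magselect")

IMPORTANCE_MODES = ("permutation", "impurity")


@dataclass(frozen=True)
class CVParams:
    """Cross-validation settings for subset evaluation.

    The importance-extraction forest uses 1,000 trees; inside CV the default
    is 500 trees — subset evaluation fits k*repeats forests per subset size,
    and the tree count there is a cost/variance trade-off, not a stated
    constant.
    """

    k: int = 10
    repeats: int = 3
    n_trees: int = 500
    seed: int = 0


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return labels


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    # sqrt-feature subsampling, unlimited depth, bootstrap on; fully seeded
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def importance_scores(
    matrix: AbundanceMatrix,
    labels: Sequence[int],
    n_trees: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "permutation",
) -> list[tuple[str, float]]:
    """Importance-ranked genomes, descending score, ties broken by genome id.

    ``permutation`` is the classical mean-decrease-accuracy: for every tree,
    accuracy on its out-of-bag samples is compared against accuracy after
    shuffling one genome's column among those samples, with ``n_repeats``
    seeded shuffles per (tree, genome); the decreases are averaged over all
    shuffles and trees.  Scoring on out-of-bag rather than training samples
    matters — a many-tree forest interpolates its training set, which would
    drive every training-set importance to zero.  ``impurity`` uses the
    forest's Gini importance instead.
    """
    if mode not in IMPORTANCE_MODES:
        raise ValueError(f"unknown importance mode {mode!r}")
    labels = _validate_labels(np.asarray(labels))
    if min(np.bincount(labels)) < 2:
        raise ValueError("need >= 2 samples per class")
    X = matrix.values.T  # samples x genomes
    if X.shape[0] != len(labels):
        raise ValueError("labels do not align with matrix samples")
    model = _forest(n_trees, seed).fit(X, labels)
    if mode == "permutation":
        scores = _oob_permutation_importance(model, X, labels, n_repeats, seed)
    else:
        scores = model.feature_importances_
    order = sorted(
        zip(matrix.genome_ids, scores.tolist()), key=lambda t: (-t[1], t[0])
    )
    return order


def _oob_permutation_importance(
    model: RandomForestClassifier,
    X: np.ndarray,
    labels: np.ndarray,
    n_repeats: int,
    seed: int,
) -> np.ndarray:
    """Breiman-style MDA on out-of-bag samples, vectorized per tree.

    For one tree and one repeat, every feature's permuted copy of the tree's
    OOB block is stacked into a single array so the tree predicts once per
    (tree, repeat) instead of once per feature.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    decrease_sum = np.zeros(p)
    n_eval = 0
    for tree, samples in zip(model.estimators_, model.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if len(oob) == 0:
            continue
        Xo = X[oob]
        yo = labels[oob]
        k = len(oob)
        base_acc = float(np.mean(tree.predict(Xo) == yo))
        for _ in range(n_repeats):
            stacked = np.tile(Xo, (p, 1))
            for j in range(p):
                stacked[j * k:(j + 1) * k, j] = Xo[rng.permutation(k), j]
            pred = tree.predict(stacked).reshape(p, k)
            decrease_sum += base_acc - (pred == yo).mean(axis=1)
        n_eval += n_repeats
    if n_eval == 0:
        raise RuntimeError("no out-of-bag samples available for any tree")
    return decrease_sum / n_eval


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random positive scored above random negative), ties counted 1/2."""
    labels = _validate_labels(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def repeated_cv_auroc(
    matrix_subset: AbundanceMatrix,
    labels: Sequence[int],
    params: CVParams = CVParams(),
) -> tuple[float, list[float]]:
    """Mean AUROC over repeated stratified k-fold CV.

    Each repeat r uses its own fold shuffle (seeded ``params.seed + r``); the
    held-out class-1 probabilities of all k folds are pooled into one AUROC
    per repeat, and the repeats' AUROCs are averaged.  If the minority class
    has fewer than k samples, k is lowered to that count (logged).
    """
    labels = _validate_labels(np.asarray(labels))
    minority = int(min(np.bincount(labels)))
    if minority < 2:
        raise ValueError("minority class must have >= 2 samples")
    k = params.k
    if minority < k:
        logger.warning("lowering k from %d to minority class size %d", k, minority)
        k = minority
    X = matrix_subset.values.T
    per_repeat: list[float] = []
    for r in range(params.repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=params.seed + r)
        pooled = np.empty(len(labels))
        for train, test in skf.split(X, labels):
            model = _forest(params.n_trees, params.seed + r).fit(X[train], labels[train])
            pooled[test] = model.predict_proba(X[test])[:, 1]
        per_repeat.append(auroc(pooled, labels))
    return float(np.mean(per_repeat)), per_repeat


@dataclass
class SelectionResult:
    """Cumulative-selection outcome: the AUROC curve and the best subset."""

    curve: list[tuple[int, float]]  # (subset size, mean AUROC)
    per_repeat: list[list[float]]  # per size, the repeats' AUROCs
    best_size: int
    best_subset: list[str]  # importance order
    best_auroc: float
    ranking: list[tuple[str, float]]
    ablations: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "curve": [[s, a] for s, a in self.curve],
            "per_repeat": self.per_repeat,
            "best_size": self.best_size,
            "best_subset": self.best_subset,
            "best_auroc": self.best_auroc,
            "ranking": [[g, s] for g, s in self.ranking],
            "ablations": self.ablations,
        }


def cumulative_selection(
    matrix: AbundanceMatrix,
    labels: Sequence[int],
    ranking: Sequence[tuple[str, float]],
    cap: int | None = None,
    cv_params: CVParams = CVParams(),
) -> SelectionResult:
    """Evaluate top-s ranked genomes for s = 1..cap and pick the best subset.

    ``best_size`` is the smallest size attaining the maximal mean AUROC
    (parsimony tie-break).
    """
    ranked_ids = [g for g, _ in ranking]
    missing = set(matrix.genome_ids) - set(ranked_ids)
    if missing:
        raise ValueError(f"ranking does not cover matrix genomes: {sorted(missing)[:5]}")
    n = matrix.n_genomes
    top = n if cap is None else min(cap, n)
    if cap is not None and cap > n:
        raise ValueError(f"cap {cap} exceeds {n} genomes")
    curve: list[tuple[int, float]] = []
    per_repeat: list[list[float]] = []
    for s in range(1, top + 1):
        subset = matrix.subset_genomes(ranked_ids[:s])
        mean_a, reps = repeated_cv_auroc(subset, labels, cv_params)
        curve.append((s, mean_a))
        per_repeat.append(reps)
    best_auroc = max(a for _, a in curve)
    best_size = min(s for s, a in curve if a == best_auroc)
    return SelectionResult(
        curve=curve,
        per_repeat=per_repeat,
        best_size=best_size,
        best_subset=ranked_ids[:best_size],
        best_auroc=best_auroc,
        ranking=list(ranking),
    )


def ablation_auroc(
    matrix: AbundanceMatrix,
    labels: Sequence[int],
    best_subset: Sequence[str],
    exclude: set[str],
    cv_params: CVParams = CVParams(),
) -> float:
    """Mean CV AUROC of the selected subset with ``exclude`` removed.

    Uses the identical CV seeding policy as the main run, so an empty
    exclusion set reproduces the best-subset AUROC exactly.
    """
    remaining = [g for g in best_subset if g not in exclude]
    if not remaining:
        raise ValueError("ablation would leave no genomes")
    mean_a, _ = repeated_cv_auroc(matrix.subset_genomes(remaining), labels, cv_params)
    return mean_a
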
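"""Lowest-average-distance classification, cross-validation, probe-label
permutation testing and the genetic signature optimizer.

The classifier assigns a sample to the class whose training members have
the lowest mean signature distance to it. Because signatures and distances
are per-sample functions of the ranks, the full pairwise distance matrix
can be computed once and folds simply select which entries are used; this
is exactly equivalent to recomputing signatures from training folds.

The permutation null shuffles, independently within every sample, the
assignment of values to probe labels. A single global relabeling applied
to all samples leaves every distance unchanged (relabeling invariance), so
per-sample shuffling is the only reading of a probe-label permutation that
produces a non-degenerate null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ranksig.io import CohortLabels, ExpressionMatrix
from ranksig.ranks import (
    ESParams,
    RankProfile,
    Signature,
    extract_signature,
    pairwise_distances,
    rank_matrix,
    signature_distance,
)

__all__ = [
    "CVConfig",
    "PermutationConfig",
    "GAConfig",
    "GAResult",
    "classify_sample",
    "cross_validate",
    "permutation_pvalue",
    "permutation_test",
    "candidate_pool",
    "ga_optimize",
    "nested_cross_validate",
]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 30
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    elitism: int = 2
    tournament_size: int = 3
    s_min: int = 1
    s_max: int = 25
    pool_size: int = 50
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_prob", "mutation_prob", "init_density"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (1 <= self.s_min <= self.s_max):
            raise ValueError("require 1 <= s_min <= s_max")


def _labeled_submatrix(matrix: ExpressionMatrix, labels: CohortLabels) -> ExpressionMatrix:
    """Labeled samples in canonical (class, sample_id) order.

    Canonical ordering makes every downstream accuracy a function of
    (values, labels, seed) only — never of the matrix's column order.
    """
    ordered = sorted(
        (s for s in matrix.sample_ids if s in labels.labels),
        key=lambda s: (labels.class_order.index(labels.labels[s]), s),
    )
    return matrix.restrict_samples(ordered)


def classify_sample(
    test_profile: RankProfile,
    training_profiles: Sequence[RankProfile],
    training_signatures: Sequence[Signature],
    labels: CohortLabels,
    s: int,
    params: ESParams = ESParams(),
) -> tuple[str, dict[str, float], bool]:
    """Assign a sample to the class with the lowest averaged distance.

    Returns (class, mean distance per class, tie flag). An exact tie goes
    to the first class in the declared order with the flag set.
    """
    test_sig = extract_signature(test_profile, s)
    by_class: dict[str, list[float]] = {c: [] for c in labels.class_order}
    for prof, sig in zip(training_profiles, training_signatures):
        cls = labels.labels[prof.sample_id]
        by_class[cls].append(signature_distance(test_sig, prof, sig, test_profile, params))
    for cls, ds in by_class.items():
        if not ds:
            raise ValueError(f"class {cls!r} has no training samples")
    means = {c: float(np.mean(ds)) for c, ds in by_class.items()}
    first, second = labels.class_order
    tie = means[first] == means[second]
    winner = first if means[first] <= means[second] else second
    return winner, means, tie


def _fold_splits(y: np.ndarray, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = np.bincount(y, minlength=2)
    if cv.stratified and counts.min() < cv.k:
        raise ValueError(
            f"stratification impossible: class counts {counts.tolist()} with k={cv.k}"
        )
    if cv.k > y.size:
        raise ValueError(f"k={cv.k} exceeds {y.size} samples")
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    strata = y if cv.stratified else np.zeros_like(y)
    return [(tr, te) for tr, te in skf.split(np.zeros(y.size), strata)]


def _accuracy_from_distances(
    dist: np.ndarray, y: np.ndarray, splits: Sequence[tuple[np.ndarray, np.ndarray]]
) -> tuple[float, list[dict]]:
    """Held-out accuracy given a full pairwise distance matrix."""
    correct = 0
    total = 0
    folds: list[dict] = []
    for fold_no, (train, test) in enumerate(splits):
        preds = []
        for t in test:
            m0 = dist[t, train[y[train] == 0]].mean()
            m1 = dist[t, train[y[train] == 1]].mean()
            pred = 0 if m0 <= m1 else 1
            preds.append(pred)
            correct += int(pred == y[t])
            total += 1
        folds.append(
            {
                "fold": fold_no,
                "test_indices": test.tolist(),
                "predictions": preds,
                "truth": y[test].tolist(),
            }
        )
    return correct / total, folds


def cross_validate(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    s: int,
    params: ESParams = ESParams(),
    cv: CVConfig = CVConfig(),
) -> tuple[float, list[dict]]:
    """Stratified k-fold accuracy of the lowest-average-distance rule.

    Deterministic given ``cv.seed``; fold membership is recorded in the
    per-fold report for audit.
    """
    labels.validate_against(matrix)
    sub = _labeled_submatrix(matrix, labels)
    y = labels.vector(sub.sample_ids)
    splits = _fold_splits(y, cv)
    dist = pairwise_distances(rank_matrix(sub), s, params)
    acc, folds = _accuracy_from_distances(dist, y, splits)
    for f in folds:
        f["test_samples"] = [sub.sample_ids[i] for i in f.pop("test_indices")]
    return acc, folds


def permutation_pvalue(observed_accuracy: float, null_accuracies: Sequence[float]) -> float:
    """Add-one empirical p-value, (r + 1)/(B + 1), rounded to 4 decimals."""
    nulls = np.asarray(null_accuracies, dtype=np.float64)
    if nulls.size == 0:
        raise ValueError("null distribution is empty")
    r = int((nulls >= observed_accuracy).sum())
    return round((r + 1) / (nulls.size + 1), 4)


def permutation_test(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    s: int,
    params: ESParams = ESParams(),
    cv: CVConfig = CVConfig(),
    perm: PermutationConfig = PermutationConfig(),
) -> tuple[float, np.ndarray]:
    """Probe-label permutation test of cross-validated accuracy.

    Each of B permutations independently shuffles every sample's
    value-to-probe assignment (equivalently, permutes each sample's rank
    vector), destroying probe correspondence across samples, and the
    cross-validated accuracy is recomputed on the shuffled ranks with the
    same fold splits. Returns (p, null accuracy distribution).
    """
    labels.validate_against(matrix)
    sub = _labeled_submatrix(matrix, labels)
    y = labels.vector(sub.sample_ids)
    splits = _fold_splits(y, cv)
    ranks = rank_matrix(sub)
    observed, _ = _accuracy_from_distances(pairwise_distances(ranks, s, params), y, splits)
    rng = np.random.default_rng(perm.seed)
    n_probes, n_samples = ranks.shape
    nulls = np.empty(perm.n_permutations)
    shuffled = np.empty_like(ranks)
    for b in range(perm.n_permutations):
        for j in range(n_samples):
            shuffled[:, j] = ranks[rng.permutation(n_probes), j]
        nulls[b], _ = _accuracy_from_distances(
            pairwise_distances(shuffled, s, params), y, splits
        )
    return permutation_pvalue(observed, nulls), nulls


def candidate_pool(matrix: ExpressionMatrix, labels: CohortLabels, m: int) -> list[str]:
    """Top-m probes by absolute standardized two-sample rank-sum statistic."""
    labels.validate_against(matrix)
    sub = _labeled_submatrix(matrix, labels)
    y = labels.vector(sub.sample_ids)
    from scipy.stats import rankdata

    ranks = rankdata(sub.values, method="average", axis=1)  # across samples, per probe
    n1 = int((y == 0).sum())
    n2 = int((y == 1).sum())
    n = n1 + n2
    r1 = ranks[:, y == 0].sum(axis=1)
    z = (r1 - n1 * (n + 1) / 2.0) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
    order = np.lexsort((np.array(sub.probe_ids), -np.abs(z)))
    return [sub.probe_ids[i] for i in order[: min(m, len(order))]]


@dataclass
class _Chromosome:
    mask: np.ndarray  # bool over candidate pool
    s: int


@dataclass
class GAResult:
    pool: list[str]
    mask: np.ndarray
    s: int
    fitness: float
    trace: list[float] = field(default_factory=list)

    @property
    def selected_probes(self) -> list[str]:
        return [p for p, keep in zip(self.pool, self.mask) if keep]


def _fitness_key(acc: float, s_eff: int, n_sel: int) -> tuple:
    # higher accuracy first; ties broken toward smaller signatures
    return (acc, -s_eff, -n_sel)


def ga_optimize(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    ga: GAConfig = GAConfig(),
    cv: CVConfig = CVConfig(),
    params: ESParams = ESParams(),
    initial_population: Sequence[tuple[Sequence[bool], int]] | None = None,
) -> GAResult:
    """Genetic search over (signature size, probe inclusion mask).

    The candidate pool is the top probes by absolute two-sample rank
    statistic; a chromosome selects a subset of the pool and a signature
    size. Fitness is the cross-validated accuracy of the restricted
    matrix, with ties broken toward smaller signatures. Tournament
    selection, uniform crossover, per-bit flip mutation and elitism; the
    per-generation best fitness is non-decreasing. Setting
    ``initial_population`` with zero crossover/mutation reduces the search
    to an exhaustive evaluation of the supplied chromosomes.
    """
    pool = candidate_pool(matrix, labels, ga.pool_size)
    if len(pool) < 2 * ga.s_min:
        raise ValueError(
            f"candidate pool of {len(pool)} probes cannot host signatures of size {ga.s_min}"
        )
    m = len(pool)
    sub = _labeled_submatrix(matrix.restrict_probes(pool), labels)
    y = labels.vector(sub.sample_ids)
    splits = _fold_splits(y, cv)
    rng = np.random.default_rng(ga.seed)
    cache: dict[tuple[bytes, int], tuple] = {}

    def evaluate(ch: _Chromosome) -> tuple:
        # a mask must be able to host a signature inside [s_min, s_max]
        n_sel = int(ch.mask.sum())
        if n_sel < 2 * ga.s_min:
            return (-1.0, 0, 0)
        s_eff = int(np.clip(ch.s, ga.s_min, n_sel // 2))
        key = (ch.mask.tobytes(), s_eff)
        if key not in cache:
            ranks = rank_matrix(
                ExpressionMatrix(
                    [p for p, k in zip(pool, ch.mask) if k], list(sub.sample_ids), sub.values[ch.mask]
                )
            )
            acc, _ = _accuracy_from_distances(pairwise_distances(ranks, s_eff, params), y, splits)
            cache[key] = _fitness_key(acc, s_eff, n_sel)
        return cache[key]

    def random_chromosome() -> _Chromosome:
        mask = rng.random(m) < ga.init_density
        if mask.sum() < 2:
            mask[rng.choice(m, size=2, replace=False)] = True
        s = int(rng.integers(ga.s_min, ga.s_max + 1))
        return _Chromosome(mask, s)

    if initial_population is not None:
        population = [
            _Chromosome(np.asarray(mk, dtype=bool).copy(), int(s)) for mk, s in initial_population
        ]
    else:
        population = [random_chromosome() for _ in range(ga.population_size)]

    def sort_pop(pop: list[_Chromosome]) -> list[tuple[tuple, _Chromosome]]:
        scored = [(evaluate(ch), ch) for ch in pop]
        scored.sort(key=lambda t: t[0], reverse=True)  # stable: ties keep insertion order
        return scored

    scored = sort_pop(population)
    trace = [scored[0][0][0]]
    for _ in range(max(0, ga.generations - 1)):
        elites = [
            _Chromosome(ch.mask.copy(), ch.s) for _, ch in scored[: min(ga.elitism, len(scored))]
        ]
        offspring: list[_Chromosome] = []
        while len(elites) + len(offspring) < len(population):

            def tournament() -> _Chromosome:
                # scored is sorted best-first, so the lowest index wins
                picks = rng.integers(0, len(scored), size=min(ga.tournament_size, len(scored)))
                return scored[int(picks.min())][1]

            p1, p2 = tournament(), tournament()
            mask = p1.mask.copy()
            s = p1.s
            if rng.random() < ga.crossover_prob:
                take = rng.random(m) < 0.5
                mask = np.where(take, p1.mask, p2.mask)
                s = p1.s if rng.random() < 0.5 else p2.s
            if ga.mutation_prob > 0:
                flips = rng.random(m) < ga.mutation_prob
                mask = np.where(flips, ~mask, mask)
                if rng.random() < ga.mutation_prob:
                    s = int(np.clip(s + int(rng.integers(-2, 3)), ga.s_min, ga.s_max))
            offspring.append(_Chromosome(mask, s))
        scored = sort_pop(elites + offspring)
        trace.append(max(trace[-1], scored[0][0][0]))

    best_key, best = max(scored, key=lambda t: t[0])
    n_sel = int(best.mask.sum())
    s_eff = min(best.s, max(1, n_sel // 2))
    return GAResult(pool=pool, mask=best.mask.copy(), s=s_eff, fitness=float(best_key[0]), trace=trace)


def nested_cross_validate(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    ga: GAConfig = GAConfig(),
    cv: CVConfig = CVConfig(),
    params: ESParams = ESParams(),
) -> tuple[float, list[dict]]:
    """Honest accuracy: candidate pool and GA run inside each training fold.

    For every fold the pool and the GA see the training samples only; the
    held-out samples are then classified on the fold's selected probes.
    Slower than selecting once on all data but free of selection
    leakage.
    """
    labels.validate_against(matrix)
    sub = _labeled_submatrix(matrix, labels)
    y = labels.vector(sub.sample_ids)
    splits = _fold_splits(y, cv)
    correct = 0
    total = 0
    folds: list[dict] = []
    for fold_no, (train, test) in enumerate(splits):
        train_ids = [sub.sample_ids[i] for i in train]
        train_matrix = sub.restrict_samples(train_ids)
        train_labels = CohortLabels(
            {s_: labels.labels[s_] for s_ in train_ids}, list(labels.class_order)
        )
        inner_cv = CVConfig(
            k=min(cv.k, int(min(np.bincount(y[train], minlength=2)))),
            stratified=cv.stratified,
            seed=cv.seed,
        )
        best = ga_optimize(train_matrix, train_labels, ga, inner_cv, params)
        fold_matrix = sub.restrict_probes(best.selected_probes)
        dist = pairwise_distances(rank_matrix(fold_matrix), best.s, params)
        acc_fold, _ = _accuracy_from_distances(dist, y, [(train, test)])
        correct += int(round(acc_fold * test.size))
        total += test.size
        folds.append(
            {
                "fold": fold_no,
                "selected_probes": best.selected_probes,
                "signature_size": best.s,
                "test_samples": [sub.sample_ids[i] for i in test],
                "fold_accuracy": acc_fold,
            }
        )
    return correct / total, folds
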
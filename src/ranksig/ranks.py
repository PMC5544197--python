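"""Rank transformation, per-sample signatures and the weighted
enrichment-score distance between samples.

The similarity of sample *i* seen from sample *j* is built from two
running-sum enrichment scores: the score of *i*'s up-signature and of its
down-signature inside *j*'s ranked probe list. Walking *j*'s probes from
highest to lowest rank, a probe in the query set adds its weight
``|rank - (N+1)/2|**p`` (normalized to the set's total weight) and any
other probe subtracts ``1/(N - |S|)``; the score is the signed maximum
deviation of this running sum from zero, hence always in [-1, 1]. With
``p = 0`` this reduces to the classic Kolmogorov-Smirnov form.

directed similarity:  sim(i->j) = (ES(up_i in j) - ES(down_i in j)) / 2
distance:             d(i,j) = 1 - (sim(i->j) + sim(j->i)) / 2   in [0, 2]

Everything depends on the data only through ranks, so any strictly
monotone per-sample transform of the values leaves all outputs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from ranksig.io import ExpressionMatrix

__all__ = [
    "ESParams",
    "RankProfile",
    "Signature",
    "DistanceMatrix",
    "rank_transform",
    "rank_matrix",
    "extract_signature",
    "enrichment_score",
    "signature_distance",
    "distance_matrix",
    "pairwise_distances",
]


@dataclass(frozen=True)
class ESParams:
    """Enrichment-score weighting: hit weights are |rank - (N+1)/2| ** p."""

    p: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.p) or self.p < 0:
            raise ValueError(f"weight exponent must be finite and >= 0, got {self.p}")


@dataclass
class RankProfile:
    """Ascending ranks of one sample's probes (1 = lowest, ties averaged)."""

    sample_id: str
    probe_ids: list[str]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.float64)
        if self.ranks.shape != (len(self.probe_ids),):
            raise ValueError("rank vector length mismatch")

    @property
    def n(self) -> int:
        return len(self.probe_ids)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.probe_ids, self.ranks))


@dataclass
class Signature:
    """Ordered extreme probe sets of one sample.

    ``up_set`` holds the s highest-ranked probes in descending rank order,
    ``down_set`` the s lowest-ranked in ascending order. ``tie_at_cut`` is
    set when a rank tie spans either cut; such ties are broken by
    lexicographic probe ID so the result is deterministic.
    """

    sample_id: str
    up_set: list[str]
    down_set: list[str]
    s: int
    tie_at_cut: bool = False

    def __post_init__(self) -> None:
        if len(self.up_set) != self.s or len(self.down_set) != self.s:
            raise ValueError("signature sets must each contain s probes")
        if set(self.up_set) & set(self.down_set):
            raise ValueError("up and down sets overlap")

    @property
    def probes(self) -> set[str]:
        return set(self.up_set) | set(self.down_set)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        lines = []
        if comment:
            lines.append(f"# {comment}")
        lines.append("sample_id\t" + "\t".join(self.sample_ids))
        for s, row in zip(self.sample_ids, self.values):
            lines.append(s + "\t" + "\t".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def rank_transform(values: Mapping[str, float] | Sequence[float], sample_id: str = "",
                   probe_ids: Sequence[str] | None = None) -> RankProfile:
    """Ascending average-tie ranks of one sample's values.

    Accepts a probe->value mapping or a value sequence plus probe IDs.
    Invariant under any strictly increasing transform of the values.
    """
    if isinstance(values, Mapping):
        probe_ids = list(values.keys())
        arr = np.array([values[p] for p in probe_ids], dtype=np.float64)
    else:
        arr = np.asarray(values, dtype=np.float64)
        probe_ids = list(probe_ids) if probe_ids is not None else [str(i) for i in range(arr.size)]
    if arr.size < 2:
        raise ValueError(f"need at least 2 probes to rank, got {arr.size}")
    return RankProfile(sample_id, probe_ids, rankdata(arr, method="average"))


def rank_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Column-wise ascending average-tie ranks of an expression matrix."""
    return rankdata(matrix.values, method="average", axis=0)


def extract_signature(profile: RankProfile, s: int) -> Signature:
    """Top-s / bottom-s probes of a rank profile.

    A rank tie spanning either cut is resolved by lexicographic probe ID
    and flagged via ``tie_at_cut``.
    """
    n = profile.n
    if not (1 <= s <= n // 2):
        raise ValueError(f"signature size {s} outside [1, {n // 2}] for {n} probes")
    order_up = sorted(range(n), key=lambda i: (-profile.ranks[i], profile.probe_ids[i]))
    order_dn = sorted(range(n), key=lambda i: (profile.ranks[i], profile.probe_ids[i]))
    up = [profile.probe_ids[i] for i in order_up[:s]]
    down = [profile.probe_ids[i] for i in order_dn[:s]]
    tie = (
        profile.ranks[order_up[s - 1]] == profile.ranks[order_up[s]]
        or profile.ranks[order_dn[s - 1]] == profile.ranks[order_dn[s]]
    )
    return Signature(profile.sample_id, up, down, s, tie_at_cut=bool(tie))


def _es_from_positions(hp: np.ndarray, wh: np.ndarray, n: int) -> float:
    """ES given sorted 0-based hit positions and their weights.

    Between hits the running sum decays linearly, so its extrema occur
    immediately after a hit (candidate maxima) or just before one
    (candidate minima); only those 2s points are evaluated.
    """
    s = hp.size
    total = wh.sum()
    if total <= 0:  # all hit weights zero (p>0, all hits at the exact center)
        wh = np.ones(s)
        total = float(s)
    miss = 1.0 / (n - s)
    cum = np.cumsum(wh) / total
    misses_before = hp - np.arange(s)
    v_after = cum - (misses_before * miss)
    v_before = v_after - wh / total
    max_dev = v_after.max()
    min_dev = min(v_before.min(), 0.0)
    # near-ties in |deviation| resolve to the positive score so that the
    # sign does not depend on float summation order
    return float(max_dev if max_dev >= -min_dev - 1e-12 else min_dev)


def enrichment_score(probe_set: Sequence[str], profile: RankProfile,
                     params: ESParams = ESParams()) -> float:
    """Weighted running-sum enrichment score of a probe set in a profile.

    An exact tie between the maximum and minimum deviation resolves to the
    positive score.
    """
    probes = list(dict.fromkeys(probe_set))
    if not probes:
        raise ValueError("probe set is empty")
    idx = {p: i for i, p in enumerate(profile.probe_ids)}
    missing = [p for p in probes if p not in idx]
    if missing:
        raise ValueError(f"probes absent from profile: {missing[:10]}")
    n = profile.n
    if len(set(probes)) >= n:
        raise ValueError("probe set must be a proper subset of the profile")
    order = np.lexsort((np.array(profile.probe_ids), -profile.ranks))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    w_ord = np.abs(profile.ranks[order] - (n + 1) / 2.0) ** params.p
    hp = np.sort(pos[[idx[p] for p in probes]])
    return _es_from_positions(hp, w_ord[hp], n)


def signature_distance(
    sig_i: Signature,
    profile_j: RankProfile,
    sig_j: Signature,
    profile_i: RankProfile,
    params: ESParams = ESParams(),
) -> float:
    """Symmetrized enrichment-score distance between two samples."""
    if set(profile_i.probe_ids) != set(profile_j.probe_ids):
        raise ValueError("profiles do not share a probe universe")

    def directed(sig: Signature, prof: RankProfile) -> float:
        return (
            enrichment_score(sig.up_set, prof, params)
            - enrichment_score(sig.down_set, prof, params)
        ) / 2.0

    sim = (directed(sig_i, profile_j) + directed(sig_j, profile_i)) / 2.0
    return 1.0 - sim


def pairwise_distances(ranks: np.ndarray, s: int, params: ESParams = ESParams()) -> np.ndarray:
    """All-pairs signature distances from a probes-by-samples rank matrix.

    Vectorized core used by cross-validation and permutation testing.
    Signature cut ties are broken by probe row position here (the
    profile-level API breaks them by probe ID; tie-free data agree).
    """
    n_probes, n_samples = ranks.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= s <= n_probes // 2):
        raise ValueError(f"signature size {s} outside [1, {n_probes // 2}]")
    center = (n_probes + 1) / 2.0
    miss = 1.0 / (n_probes - s)
    k = np.arange(s)

    orders = np.argsort(-ranks, axis=0, kind="stable")  # descending rank per sample
    # up/down signature probe rows per sample: (n_samples, s)
    ups = orders[:s, :].T
    downs = orders[::-1][:s, :].T
    # sets stacked: first n_samples rows = up sets, next = down sets
    sets = np.vstack([ups, downs])  # (2*n_samples, s)

    es = np.empty((2 * n_samples, n_samples))
    for j in range(n_samples):
        order_j = orders[:, j]
        pos = np.empty(n_probes, dtype=np.int64)
        pos[order_j] = np.arange(n_probes)
        w_ord = np.abs(ranks[order_j, j] - center) ** params.p
        hp = np.sort(pos[sets], axis=1)  # (2n, s)
        wh = w_ord[hp]
        totals = wh.sum(axis=1, keepdims=True)
        degenerate = totals[:, 0] <= 0
        if degenerate.any():
            wh[degenerate] = 1.0
            totals = wh.sum(axis=1, keepdims=True)
        cum = np.cumsum(wh, axis=1) / totals
        v_after = cum - (hp - k) * miss
        v_before = v_after - wh / totals
        max_dev = v_after.max(axis=1)
        min_dev = np.minimum(v_before.min(axis=1), 0.0)
        es[:, j] = np.where(max_dev >= -min_dev - 1e-12, max_dev, min_dev)

    sim_directed = (es[:n_samples, :] - es[n_samples:, :]) / 2.0  # sim(i->j)
    dist = 1.0 - (sim_directed + sim_directed.T) / 2.0
    diag = np.diag(dist).copy()
    diag[np.abs(diag) < 1e-12] = 0.0  # clip float dust on the self-distance
    np.fill_diagonal(dist, diag)
    return dist


def distance_matrix(matrix: ExpressionMatrix, s: int, params: ESParams = ESParams()) -> DistanceMatrix:
    """Pairwise signature distances of all samples in a matrix."""
    matrix.probe_index()  # enforce unique probes
    ranks = rank_matrix(matrix)
    return DistanceMatrix(list(matrix.sample_ids), pairwise_distances(ranks, s, params))
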
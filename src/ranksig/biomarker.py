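"""Biomarker extraction, differential statistics, pathway-restricted
search and hypergeometric over-representation analysis.

A biomarker is the union of the probes appearing in at least one
per-sample signature of the final classifier. Fold-changes are oriented
first-declared-class minus second on the log2 scale; rank-sum p-values are
exact by enumeration for group sizes up to 10 and normal-approximated with
tie correction beyond. Over-representation uses the upper-tail
hypergeometric test with step-down Bonferroni (Holm) adjustment, counting
at gene level: a gene counts once no matter how many probes map to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from ranksig.classify import (
    _labeled_submatrix,
    CVConfig,
    GAConfig,
    GAResult,
    PermutationConfig,
    cross_validate,
    ga_optimize,
    permutation_test,
)
from ranksig.io import CohortLabels, ExpressionMatrix, GeneSetCollection, ProbeGeneMap
from ranksig.ranks import ESParams, RankProfile, Signature, extract_signature, rank_matrix

__all__ = [
    "BiomarkerResult",
    "EnrichmentResult",
    "biomarker_union",
    "differential_stats",
    "discover_biomarker",
    "pathway_restricted_search",
    "ora_enrichment",
    "holm_adjust",
]


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Bonferroni (Holm) adjustment.

    Sort raw p ascending; adjusted_i = max over j <= i of (m - j + 1) * p_j,
    capped at 1; values are reported in the input order.
    """
    raw = np.asarray(pvalues, dtype=np.float64)
    m = raw.size
    order = np.argsort(raw, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * raw[i])
        adjusted[i] = min(running, 1.0)
    return adjusted

EXACT_GROUP_LIMIT = 10  # full enumeration of the rank-sum null up to this size


@dataclass
class BiomarkerResult:
    """Probe union with per-probe statistics and pipeline-level metrics."""

    probes: list[str]
    table: pd.DataFrame  # probe, genes, log2fc, pvalue, direction
    accuracy: float
    permutation_p: float | None
    signature_size: int
    selected_probes: list[str]
    signatures: list[Signature] = field(default_factory=list)
    folds: list[dict] = field(default_factory=list)
    ga: GAResult | None = None

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    """Per-set over-representation statistics."""

    table: pd.DataFrame  # set, overlap, set_size, list_size, universe_size, pvalue, adjusted_p

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] <= alpha]

    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def biomarker_union(signatures: Sequence[Signature]) -> set[str]:
    """Union of all up- and down-set probes across signatures."""
    if not signatures:
        raise ValueError("need at least one signature")
    out: set[str] = set()
    for sig in signatures:
        out |= set(sig.up_set)
        out |= set(sig.down_set)
    return out


def differential_stats(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-probe log2 fold-change and two-sided rank-sum p-value.

    log2FC = mean(first declared class) - mean(second); the exact test is
    used when both groups have <= 10 samples, otherwise the normal
    approximation with tie correction.
    """
    labels.validate_against(matrix)
    idx = matrix.probe_index()
    probes = list(probes) if probes is not None else list(matrix.probe_ids)
    cls1, cls2 = labels.class_order
    cols1 = [j for j, s in enumerate(matrix.sample_ids) if labels.labels.get(s) == cls1]
    cols2 = [j for j, s in enumerate(matrix.sample_ids) if labels.labels.get(s) == cls2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("both classes need at least 2 samples")
    method = "exact" if max(len(cols1), len(cols2)) <= EXACT_GROUP_LIMIT else "asymptotic"
    rows = []
    for p in probes:
        x = matrix.values[idx[p], cols1]
        y = matrix.values[idx[p], cols2]
        fc = float(x.mean() - y.mean())
        use = method
        if method == "exact" and np.unique(np.concatenate([x, y])).size < x.size + y.size:
            use = "asymptotic"  # the exact null is unavailable under ties
        pval = float(mannwhitneyu(x, y, alternative="two-sided", method=use).pvalue)
        direction = (
            f"up in {cls1}" if fc > 0 else (f"up in {cls2}" if fc < 0 else "unchanged")
        )
        rows.append({"probe": p, "log2fc": fc, "pvalue": min(pval, 1.0), "direction": direction})
    return pd.DataFrame(rows)


def _signatures_of(matrix: ExpressionMatrix, s: int) -> list[Signature]:
    ranks = rank_matrix(matrix)
    sigs = []
    for j, sample in enumerate(matrix.sample_ids):
        prof = RankProfile(sample, list(matrix.probe_ids), ranks[:, j])
        sigs.append(extract_signature(prof, s))
    return sigs


def discover_biomarker(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    ga: GAConfig = GAConfig(),
    cv: CVConfig = CVConfig(),
    params: ESParams = ESParams(),
    perm: PermutationConfig | None = None,
    pmap: ProbeGeneMap | None = None,
    perm_signature_size: int | None = None,
) -> BiomarkerResult:
    """Full discovery pipeline: GA signature selection, cross-validated
    accuracy, optional permutation test, probe-union biomarker and
    per-probe differential statistics.

    The permutation test is run on the *input* matrix (at
    ``perm_signature_size``, default ``min(50, n_probes // 2)``), not on
    the GA-selected probes: permuting only the selected subset would
    compare a selection-optimized observation against selection-free
    nulls, which is anti-conservative. The reported p therefore measures
    whether the matrix handed to the pipeline carries class signal.
    """
    labels.validate_against(matrix)
    best = ga_optimize(matrix, labels, ga, cv, params)
    sub = matrix.restrict_probes(best.selected_probes)
    accuracy, folds = cross_validate(sub, labels, best.s, params, cv)
    permutation_p = None
    if perm is not None:
        s_perm = perm_signature_size or max(1, min(50, matrix.n_probes // 2))
        permutation_p, _ = permutation_test(matrix, labels, s_perm, params, cv, perm)
    signatures = _signatures_of(_labeled_submatrix(sub, labels), best.s)
    probes = sorted(biomarker_union(signatures))
    stats = differential_stats(matrix, labels, probes)
    if pmap is not None:
        stats.insert(1, "genes", [";".join(sorted(pmap.genes_for(p))) for p in probes])
    return BiomarkerResult(
        probes=probes,
        table=stats,
        accuracy=accuracy,
        permutation_p=permutation_p,
        signature_size=best.s,
        selected_probes=best.selected_probes,
        signatures=signatures,
        folds=folds,
        ga=best,
    )


def pathway_restricted_search(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    gene_set: Iterable[str],
    pmap: ProbeGeneMap,
    ga: GAConfig = GAConfig(),
    cv: CVConfig = CVConfig(),
    params: ESParams = ESParams(),
    perm: PermutationConfig | None = None,
) -> BiomarkerResult:
    """Reverse-mode search: restrict the matrix to probes whose mapped
    genes intersect ``gene_set``, then run the full discovery pipeline."""
    genes = set(gene_set)
    idx = matrix.probe_index()
    mapped = [p for p in matrix.probe_ids if pmap.genes_for(p) & genes]
    if len(mapped) < 2 * ga.s_min:
        raise ValueError(
            f"only {len(mapped)} probes map to the gene set; "
            f"need at least {2 * ga.s_min} for signatures of size {ga.s_min}"
        )
    return discover_biomarker(
        matrix.restrict_probes(mapped), labels, ga, cv, params, perm, pmap
    )


def ora_enrichment(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation with Holm adjustment.

    Sets are intersected with the universe; the raw p-value for a set with
    K universe genes and an overlap of k with the n-gene query list is
    P(X >= k) under Hypergeom(M=universe size, K, n). Step-down Bonferroni
    (Holm): sort raw p ascending, adjusted_i = max_{j<=i} (m-j+1)*p_j,
    capped at 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(gene_list)
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:10]}")
    m_total = len(universe)
    n_query = len(query)
    rows = []
    for name, (_, genes) in collection.sets.items():
        in_universe = genes & universe
        overlap = len(in_universe & query)
        if in_universe:
            raw = float(hypergeom.sf(overlap - 1, m_total, len(in_universe), n_query))
        else:
            raw = 1.0
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_universe),
                "list_size": n_query,
                "universe_size": m_total,
                "pvalue": min(raw, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = holm_adjust(table["pvalue"].to_numpy())
    return EnrichmentResult(table.sort_values("pvalue", kind="stable").reset_index(drop=True))
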
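"""Figure-data exports: heatmap rank matrices and similarity networks.

Canonical outputs are plain TSV files; rendering is out of scope so tests
never depend on a plotting backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from ranksig.io import CohortLabels, ExpressionMatrix
from ranksig.ranks import DistanceMatrix, rank_matrix

__all__ = ["export_heatmap_data", "export_similarity_network"]


def export_heatmap_data(
    matrix: ExpressionMatrix,
    biomarker: Sequence[str],
    labels: CohortLabels,
    path: str | Path,
    comment: str | None = None,
) -> np.ndarray:
    """Write per-sample ranks of the biomarker probes.

    Ranks are computed within each full sample profile, columns are
    ordered by declared class then sample ID, and rows by average-linkage
    hierarchical leaf order on the rank rows — all deterministic functions
    of the inputs, so shuffling the input sample order leaves the file
    unchanged. Returns the exported rank block.
    """
    labels.validate_against(matrix)
    idx = matrix.probe_index()
    missing = [p for p in biomarker if p not in idx]
    if missing:
        raise KeyError(f"biomarker probes absent from matrix: {missing[:10]}")
    order_cols = sorted(
        (s for s in matrix.sample_ids if s in labels.labels),
        key=lambda s: (labels.class_order.index(labels.labels[s]), s),
    )
    ranks = rank_matrix(matrix)  # full-profile ranks before row selection
    col_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    block = ranks[np.array([idx[p] for p in biomarker])][
        :, np.array([col_pos[s] for s in order_cols])
    ]
    if len(biomarker) > 2:
        row_order = leaves_list(linkage(block, method="average"))
    else:
        row_order = np.arange(len(biomarker))
    block = block[row_order]
    probes = [list(biomarker)[i] for i in row_order]
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("probe_id\t" + "\t".join(order_cols))
    for p, row in zip(probes, block):
        lines.append(p + "\t" + "\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
    return block


def export_similarity_network(
    dmatrix: DistanceMatrix,
    labels: CohortLabels,
    edges_path: str | Path,
    nodes_path: str | Path,
    negligible_threshold: float | None = None,
    comment: str | None = None,
) -> list[tuple[str, str, float]]:
    """Write an edge list keeping pairs whose similarity (1 - distance)
    exceeds the threshold; the default drops the weakest quartile of
    similarities. Edge weight is the distance. Returns the kept edges."""
    ids = dmatrix.sample_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    dist = dmatrix.values[iu]
    sim = 1.0 - dist
    if negligible_threshold is None:
        negligible_threshold = float(np.quantile(sim, 0.25))
    edges = [
        (ids[i], ids[j], float(d))
        for i, j, d, s_ in zip(iu[0], iu[1], dist, sim)
        if s_ > negligible_threshold
    ]
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("source\ttarget\tweight")
    for a, b, w in edges:
        lines.append(f"{a}\t{b}\t{w!r}")
    Path(edges_path).write_text("\n".join(lines) + "\n")
    node_lines = []
    if comment:
        node_lines.append(f"# {comment}")
    node_lines.append("id\tclass")
    for s_ in ids:
        node_lines.append(f"{s_}\t{labels.labels.get(s_, '')}")
    Path(nodes_path).write_text("\n".join(node_lines) + "\n")
    return edges
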
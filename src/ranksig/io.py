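"""Domain types and file I/O.

Formats handled here are all plain text: expression matrices as delimited
probe-by-sample tables, gene sets as GMT, probe-to-gene maps as two-column
TSV and clinical tables as CSV. Lines starting with ``#`` are treated as
comments in the delimited readers so that provenance headers written by the
pipeline round-trip cleanly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortLabels",
    "ProbeGeneMap",
    "GeneSetCollection",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_clinical_table",
    "average_replicate_probes",
]

_DIALECTS = {"tsv": "\t", "csv": ","}


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of log2-scale expression values.

    Probe IDs may repeat until :func:`average_replicate_probes` has been
    applied; sample IDs are always unique. Values are a dense float64 array
    of shape ``(len(probe_ids), len(sample_ids))`` with no missing entries.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if not np.isfinite(self.values).all():
            bad = sorted(set(np.where(~np.isfinite(self.values))[0].tolist()))
            raise ValueError(f"non-finite values in probe rows {bad}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        """Probe ID -> row index; requires unique probe IDs."""
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        if len(idx) != len(self.probe_ids):
            raise ValueError("probe IDs are not unique; average replicates first")
        return idx

    def restrict_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        """Submatrix containing `probes` in the given order."""
        idx = self.probe_index()
        missing = [p for p in probes if p not in idx]
        if missing:
            raise KeyError(f"unknown probes: {missing[:10]}")
        rows = [idx[p] for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[rows, :])

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing[:10]}")
        cols = [pos[s] for s in samples]
        return ExpressionMatrix(list(self.probe_ids), list(samples), self.values[:, cols])


@dataclass
class CohortLabels:
    """Two-class sample labelling with an explicit, ordered class list.

    The first class in ``class_order`` is the reference orientation for
    fold-changes and the deterministic winner of classification ties.
    """

    labels: dict[str, str]
    class_order: list[str]

    def __post_init__(self) -> None:
        if len(self.class_order) != 2:
            raise ValueError(f"exactly two classes required, got {self.class_order}")
        extra = sorted(set(self.labels.values()) - set(self.class_order))
        if extra:
            raise ValueError(f"labels outside declared classes: {extra}")
        for cls in self.class_order:
            n = sum(1 for v in self.labels.values() if v == cls)
            if n < 2:
                raise ValueError(f"class {cls!r} has {n} samples; >=2 required")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = sorted(set(self.labels) - set(matrix.sample_ids))
        if missing:
            raise ValueError(f"labeled samples absent from matrix: {missing}")

    def members(self, cls: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == cls]

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 array: 0 for the first declared class, 1 for the second."""
        return np.array([self.class_order.index(self.labels[s]) for s in sample_ids])


@dataclass
class ProbeGeneMap:
    """Probe ID -> set of gene symbols; unmapped probes are simply absent."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def genes_for(self, probe: str) -> set[str]:
        return self.mapping.get(probe, set())

    def probes_for_genes(self, genes: Iterable[str]) -> list[str]:
        """Probes mapping to at least one of `genes`, in insertion order."""
        genes = set(genes)
        return [p for p, gs in self.mapping.items() if gs & genes]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.mapping.values():
            out |= gs
        return out

    def genes_for_probes(self, probes: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for p in probes:
            out |= self.genes_for(p)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member genes)."""

    sets: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> set[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


_CLINICAL_COLUMNS = ["subject_id", "sex", "age", "bmi", "glucose", "insulin"]


@dataclass
class ClinicalTable:
    """Per-subject clinical covariates used for cohort selection.

    Columns: subject_id, sex ('M'/'F'), age (years), bmi (kg/m2),
    glucose (fasting, mmol/l), insulin (fasting, mU/l) and optionally a
    precomputed homa_ir column. Glucose, insulin and BMI must be strictly
    positive.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLINICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        f = self.frame
        if f["subject_id"].duplicated().any():
            dupes = f.loc[f["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        for col in ("glucose", "insulin", "bmi"):
            if (f[col] <= 0).any():
                bad = f.loc[f[col] <= 0, "subject_id"].tolist()
                raise ValueError(f"non-positive {col} for subjects {bad}")


def _strip(s: str) -> str:
    return s.strip()


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a delimited probe-by-sample matrix.

    First column holds probe IDs, the header row sample IDs. Any row with a
    non-numeric or missing cell is an error reported with its (1-based,
    data-area) row index. Duplicate probe IDs are allowed (replicates).
    """
    sep = _DIALECTS[dialect]
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty expression matrix file")
    header = [_strip(c) for c in lines[0].split(sep)]
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns in header")
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValueError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    bad_rows: list[int] = []
    for i, ln in enumerate(lines[1:], start=1):
        cells = [_strip(c) for c in ln.split(sep)]
        if len(cells) != len(sample_ids) + 1:
            bad_rows.append(i)
            continue
        try:
            vals = [float(c) for c in cells[1:]]
        except ValueError:
            bad_rows.append(i)
            continue
        if not all(np.isfinite(vals)):
            bad_rows.append(i)
            continue
        probe_ids.append(cells[0])
        rows.append(vals)
    if bad_rows:
        raise ValueError(f"{path}: non-numeric or malformed data rows at indices {bad_rows}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(probe_ids, sample_ids, np.array(rows, dtype=np.float64))


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv", comment: str | None = None
) -> None:
    """Write with full float precision so read∘write is the identity."""
    sep = _DIALECTS[dialect]
    buf = _io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    buf.write("probe_id" + sep + sep.join(matrix.sample_ids) + "\n")
    for p, row in zip(matrix.probe_ids, matrix.values):
        buf.write(p + sep + sep.join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene...

    Duplicate genes within a line collapse to one; a duplicated set name or
    a line with fewer than three fields is an error naming the line.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = [_strip(f) for f in ln.split("\t")]
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
        genes = {g for g in fields[2:] if g}
        sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, (desc, genes) in collection.sets.items():
        lines.append("\t".join([name, desc] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Two-column TSV (probe, gene); repeated probe rows accumulate genes."""
    mapping: dict[str, set[str]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = [_strip(f) for f in ln.split("\t")]
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        probe, gene = fields
        if lineno == 1 and probe.lower() in ("probe", "probe_id"):
            continue
        mapping.setdefault(probe, set())
        if gene:
            mapping[probe].add(gene)
    return ProbeGeneMap(mapping)


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    lines = ["probe_id\tgene"]
    for probe, genes in pmap.mapping.items():
        if genes:
            for g in sorted(genes):
                lines.append(f"{probe}\t{g}")
        else:
            lines.append(f"{probe}\t")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort_labels(path: str | Path) -> CohortLabels:
    """Two-column TSV (sample_id, class); class order = first appearance."""
    labels: dict[str, str] = {}
    order: list[str] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = [_strip(f) for f in ln.split("\t")]
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        sample, cls = fields
        if lineno == 1 and sample.lower() in ("sample", "sample_id"):
            continue
        if sample in labels:
            raise ValueError(f"{path}: line {lineno}: duplicate sample {sample!r}")
        labels[sample] = cls
        if cls not in order:
            order.append(cls)
    return CohortLabels(labels, order)


def write_cohort_labels(labels: CohortLabels, path: str | Path) -> None:
    lines = ["sample_id\tclass"]
    for cls in labels.class_order:
        for s in labels.members(cls):
            lines.append(f"{s}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """CSV with named header columns (see :class:`ClinicalTable`)."""
    frame = pd.read_csv(path, comment="#")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    frame["subject_id"] = frame["subject_id"].astype(str).str.strip()
    return ClinicalTable(frame)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def average_replicate_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate probe rows (arithmetic mean per sample).

    Output has one row per distinct probe ID, ordered by first occurrence.
    Idempotent; a matrix without duplicates passes through unchanged.
    """
    order: dict[str, int] = {}
    for p in matrix.probe_ids:
        if p not in order:
            order[p] = len(order)
    if len(order) == matrix.n_probes:
        return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), matrix.values.copy())
    sums = np.zeros((len(order), matrix.n_samples))
    counts = np.zeros(len(order))
    for p, row in zip(matrix.probe_ids, matrix.values):
        i = order[p]
        sums[i] += row
        counts[i] += 1
    return ExpressionMatrix(list(order), list(matrix.sample_ids), sums / counts[:, None])
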
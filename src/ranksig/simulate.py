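"""Synthetic two-group expression cohorts with planted differential probes.

The generator emits every input the downstream pipeline consumes: a
probe-by-sample log2 matrix, two-class labels, a probe-to-gene map, a GMT
gene-set collection with one designated "enriched" set among the
differential genes, a clinical table whose HOMA-IR separates the groups,
and a truth record of the planted effects. Everything is drawn from a
single seeded generator, so the same seed reproduces byte-identical files.

Value model per probe p and sample j:

    x[p, j] = mu_p + effect_p * (class1 - class2 orientation)
              + noise_sd * (sqrt(rho) * z[set(p), j] + sqrt(1 - rho) * eps[p, j])

with mu_p ~ N(0, 1), latent per-set factors z and iid eps ~ N(0, 1).
Probes in the same gene set share the latent factor, giving within-set
correlation rho while keeping the marginal noise SD at ``noise_sd``.
Differential probes are shifted by -effect in the second ("resistant")
class, so the observed class1-minus-class2 log2 fold-change estimates the
planted signed effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ranksig.io import (
    ClinicalTable,
    CohortLabels,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeGeneMap,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_null_cohort",
    "generate_clinical_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_probes: int = 4000
    n_per_group: int = 10
    n_diff_probes: int = 40
    log2fc: float | Sequence[float] = 0.2
    noise_sd: float = 0.5
    rho: float = 0.0
    n_sets: int = 10
    set_size_range: tuple[int, int] = (10, 30)
    enriched_fraction: float = 0.6
    mapped_fraction: float = 0.8
    multi_gene_fraction: float = 0.0
    clinical_separation: float = 1.0
    confound_age: bool = False
    class_names: tuple[str, str] = ("sensitive", "resistant")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diff_probes > self.n_probes:
            raise ValueError("n_diff_probes exceeds n_probes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.set_size_range[0] > self.set_size_range[1] or self.set_size_range[0] < 1:
            raise ValueError("invalid set size range")


@dataclass
class SyntheticTruth:
    differential: dict[str, float]  # probe -> signed planted effect (class1 - class2)
    enriched_set: str
    group_assignment: dict[str, str]
    probe_gene: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "differential": self.differential,
                    "enriched_set": self.enriched_set,
                    "group_assignment": self.group_assignment,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _layout(config: SyntheticConfig, rng: np.random.Generator):
    """Gene sets, probe->gene map and per-probe set membership."""
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    if int(sizes.sum()) > config.n_probes:
        raise ValueError(
            f"pathway layout needs {int(sizes.sum())} probes for set genes, "
            f"only {config.n_probes} available"
        )
    probes = [f"P{i + 1:06d}" for i in range(config.n_probes)]
    n_mapped = int(round(config.mapped_fraction * config.n_probes))
    n_mapped = max(n_mapped, int(sizes.sum()))
    genes = [f"G{i + 1:05d}" for i in range(n_mapped)]

    mapping: dict[str, set[str]] = {p: {g} for p, g in zip(probes[:n_mapped], genes)}
    n_multi = int(round(config.multi_gene_fraction * n_mapped))
    if n_multi:
        extra_targets = rng.choice(n_mapped, size=n_multi, replace=False)
        for t in extra_targets:
            other = int(rng.integers(0, n_mapped))
            mapping[probes[t]].add(genes[other])

    sets: dict[str, tuple[str, set[str]]] = {}
    set_of_probe = np.full(config.n_probes, -1, dtype=np.int64)
    cursor = 0
    for k, size in enumerate(sizes):
        name = f"SET{k + 1:03d}"
        members = set(genes[cursor : cursor + int(size)])
        sets[name] = (f"synthetic gene set {k + 1}", members)
        set_of_probe[cursor : cursor + int(size)] = k
        cursor += int(size)
    return probes, genes, mapping, GeneSetCollection(sets), set_of_probe


def _clinical(config: SyntheticConfig, sample_ids: list[str], groups: np.ndarray,
              rng: np.random.Generator) -> ClinicalTable:
    n = len(sample_ids)
    sep = config.clinical_separation
    glucose = rng.normal(4.6, 0.2, size=n) + 0.4 * sep * groups
    insulin = rng.normal(2.6, 0.4, size=n) + (16.0 * sep) * groups
    insulin = np.clip(insulin, 0.5, None)
    age = rng.normal(37.0, 7.0, size=n)
    if config.confound_age:
        age = age + 9.0 * groups
    bmi = np.clip(rng.normal(22.5, 1.5, size=n), 17.0, 24.9)
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    frame = pd.DataFrame(
        {
            "subject_id": sample_ids,
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "glucose": np.round(glucose, 2),
            "insulin": np.round(insulin, 2),
        }
    )
    return ClinicalTable(frame)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortLabels, ProbeGeneMap, GeneSetCollection, ClinicalTable, SyntheticTruth]:
    """Draw a complete synthetic cohort (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    probes, genes, mapping, collection, set_of_probe = _layout(config, rng)
    n = 2 * config.n_per_group
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    groups = np.array([0] * config.n_per_group + [1] * config.n_per_group)
    cls1, cls2 = config.class_names
    labels = CohortLabels(
        {s: (cls1 if g == 0 else cls2) for s, g in zip(sample_ids, groups)}, [cls1, cls2]
    )

    # planted differential probes: enriched-set genes first, then the rest
    enriched_name = collection.names()[0] if len(collection) else ""
    effects = np.zeros(config.n_probes)
    diff_idx: list[int] = []
    if config.n_diff_probes > 0:
        enriched_probe_idx = np.where(set_of_probe == 0)[0]
        k_enriched = min(
            int(round(config.enriched_fraction * enriched_probe_idx.size)),
            config.n_diff_probes,
        )
        chosen = list(rng.choice(enriched_probe_idx, size=k_enriched, replace=False))
        others = np.setdiff1d(np.arange(config.n_probes), enriched_probe_idx)
        n_rest = config.n_diff_probes - k_enriched
        chosen += list(rng.choice(others, size=n_rest, replace=False))
        diff_idx = sorted(int(i) for i in chosen)
        fc = config.log2fc
        if np.isscalar(fc):
            mags = np.full(len(diff_idx), float(fc))
        else:
            mags = np.asarray(fc, dtype=np.float64)
            if mags.size != len(diff_idx):
                raise ValueError(
                    f"log2fc vector length {mags.size} != n_diff_probes {len(diff_idx)}"
                )
        signs = np.where(rng.random(len(diff_idx)) < 0.5, 1.0, -1.0)
        effects[diff_idx] = signs * np.abs(mags)

    mu = rng.normal(0.0, 1.0, size=config.n_probes)
    eps = rng.normal(0.0, 1.0, size=(config.n_probes, n))
    noise = eps.copy()
    if config.rho > 0:
        z = rng.normal(0.0, 1.0, size=(config.n_sets, n))
        in_set = set_of_probe >= 0
        noise[in_set] = (
            np.sqrt(config.rho) * z[set_of_probe[in_set]]
            + np.sqrt(1.0 - config.rho) * eps[in_set]
        )
    values = mu[:, None] + config.noise_sd * noise
    # class1 - class2 orientation: subtract the signed effect in class 2
    values[:, groups == 1] = values[:, groups == 1] - effects[:, None]

    matrix = ExpressionMatrix(probes, sample_ids, values)
    clinical = _clinical(config, sample_ids, groups, rng)
    truth = SyntheticTruth(
        differential={probes[i]: float(effects[i]) for i in diff_idx},
        enriched_set=enriched_name,
        group_assignment=dict(labels.labels),
        probe_gene={p: sorted(mapping.get(p, set())) for p in probes},
    )
    return matrix, labels, ProbeGeneMap(mapping), collection, clinical, truth


def generate_null_cohort(config: SyntheticConfig):
    """Same cohort structure with every planted effect forced to zero."""
    null_config = dataclasses.replace(config, n_diff_probes=0)
    return generate_cohort(null_config)


def generate_clinical_cohort(
    n_subjects: int = 148, seed: int = 0, confounded: bool = False
) -> ClinicalTable:
    """Stand-alone clinical table with a continuous HOMA-IR spectrum.

    With ``confounded=True`` age rises with insulin resistance, planting
    the kind of imbalance the greedy matching pass must remove.
    """
    rng = np.random.default_rng(seed)
    glucose = rng.normal(4.8, 0.35, size=n_subjects)
    log_insulin = rng.normal(1.6, 0.9, size=n_subjects)
    insulin = np.clip(np.exp(log_insulin), 0.4, 60.0)
    homa = glucose * insulin / 22.5
    age = rng.normal(38.0, 8.0, size=n_subjects)
    if confounded:
        age = age + 6.0 * np.log(homa / np.median(homa) + 1e-9).clip(-2, 2)
    bmi = np.clip(rng.normal(24.5, 3.5, size=n_subjects), 17.0, 38.0)
    sex = np.where(rng.random(n_subjects) < 0.55, "M", "F")
    frame = pd.DataFrame(
        {
            "subject_id": [f"SUBJ{i + 1:04d}" for i in range(n_subjects)],
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "glucose": np.round(glucose, 2),
            "insulin": np.round(insulin, 2),
        }
    )
    return ClinicalTable(frame)
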
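"""End-to-end orchestration with run provenance.

``run_full_pipeline`` executes simulate/load -> GA classification ->
permutation test -> biomarker -> over-representation -> restricted search
-> figure-data exports, all governed by a single seed, and writes a
manifest whose digest covers the configuration and input digests. Stage
timings go to a separate, non-canonical ``timings.json`` so the artifact
set itself is a deterministic function of (inputs, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

from ranksig import __version__
from ranksig.biomarker import discover_biomarker, ora_enrichment, pathway_restricted_search
from ranksig.classify import CVConfig, GAConfig, PermutationConfig
from ranksig.exports import export_heatmap_data, export_similarity_network
from ranksig.io import (
    read_clinical_table,
    read_cohort_labels,
    read_expression_matrix,
    read_gmt,
    read_probe_gene_map,
    write_clinical_table,
    write_cohort_labels,
    write_expression_matrix,
    write_gmt,
    write_probe_gene_map,
)
from ranksig.ranks import ESParams, distance_matrix
from ranksig.simulate import SyntheticConfig, generate_cohort

__all__ = ["run_full_pipeline", "build_manifest"]


def _sha256_text(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(config: dict, input_digests: dict[str, str]) -> dict:
    core = {"config": config, "inputs": input_digests, "version": __version__}
    digest = hashlib.sha256(
        json.dumps(core, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {**core, "digest": digest}


def _subconfig(cfg: dict, key: str, cls, seed: int):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in cfg.get(key, {}).items() if k in fields}
    if "seed" in fields:
        kwargs.setdefault("seed", seed)
    return cls(**kwargs)


def run_full_pipeline(config: dict[str, Any], outdir: str | Path) -> dict:
    """Run every stage and return the manifest dictionary.

    ``config`` keys: ``seed``; either ``simulate`` (SyntheticConfig
    fields) or ``inputs`` (paths: matrix, labels, gene_sets, probe_map,
    clinical); optional ``signature`` (size, weight_p), ``cv``, ``ga``,
    ``permutations``, ``restrict_set``, ``network_threshold``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    timings: dict[str, float] = {}
    input_digests: dict[str, str] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    truth = None
    with stage("inputs"):
        if "simulate" in config:
            sim_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
            sim_kwargs = {k: v for k, v in config["simulate"].items() if k in sim_fields}
            sim_kwargs.setdefault("seed", seed)
            if "set_size_range" in sim_kwargs:
                sim_kwargs["set_size_range"] = tuple(sim_kwargs["set_size_range"])
            if "class_names" in sim_kwargs:
                sim_kwargs["class_names"] = tuple(sim_kwargs["class_names"])
            sim = SyntheticConfig(**sim_kwargs)
            matrix, labels, pmap, collection, clinical, truth = generate_cohort(sim)
            write_expression_matrix(matrix, outdir / "matrix.tsv")
            write_cohort_labels(labels, outdir / "labels.tsv")
            write_gmt(collection, outdir / "gene_sets.gmt")
            write_probe_gene_map(pmap, outdir / "probe_map.tsv")
            write_clinical_table(clinical, outdir / "clinical.csv")
            truth.to_json(outdir / "truth.json")
            for name in ("matrix.tsv", "labels.tsv", "gene_sets.gmt", "probe_map.tsv", "clinical.csv"):
                input_digests[name] = _sha256_text(outdir / name)
        else:
            paths = config["inputs"]
            for key in ("matrix", "labels", "gene_sets", "probe_map"):
                if key in paths and not Path(paths[key]).exists():
                    raise FileNotFoundError(f"missing input path: {paths[key]}")
            matrix = read_expression_matrix(paths["matrix"])
            labels = read_cohort_labels(paths["labels"])
            collection = read_gmt(paths["gene_sets"]) if "gene_sets" in paths else None
            pmap = read_probe_gene_map(paths["probe_map"]) if "probe_map" in paths else None
            if "clinical" in paths:
                read_clinical_table(paths["clinical"])  # validated, selection is a separate command
            for key, p in paths.items():
                input_digests[key] = _sha256_text(Path(p))

    manifest = build_manifest(config, input_digests)
    tag = f"manifest: {manifest['digest']}"

    params = ESParams(p=float(config.get("signature", {}).get("weight_p", 1.0)))
    cv = _subconfig(config, "cv", CVConfig, seed)
    ga = _subconfig(config, "ga", GAConfig, seed)
    perm = PermutationConfig(n_permutations=int(config.get("permutations", 100)), seed=seed)

    with stage("discovery"):
        result = discover_biomarker(matrix, labels, ga, cv, params, perm, pmap)
        result.to_tsv(outdir / "biomarker.tsv", comment=tag)
        dmat = distance_matrix(
            matrix.restrict_probes(result.selected_probes), result.signature_size, params
        )
        dmat.to_tsv(outdir / "distance_matrix.tsv", comment=tag)

    with stage("enrichment"):
        enrichment = None
        if pmap is not None and collection is not None:
            gene_list = sorted(pmap.genes_for_probes(result.probes))
            universe = sorted(pmap.all_genes())
            if gene_list:
                enrichment = ora_enrichment(gene_list, collection, universe)
                enrichment.to_tsv(outdir / "enrichment.tsv", comment=tag)

    restricted = None
    with stage("restricted_search"):
        restrict_set = config.get("restrict_set")
        if restrict_set is None and truth is not None:
            restrict_set = truth.enriched_set
        if restrict_set and pmap is not None and collection is not None:
            restricted = pathway_restricted_search(
                matrix, labels, collection.genes(restrict_set), pmap, ga, cv, params, perm
            )
            restricted.to_tsv(outdir / "restricted_biomarker.tsv", comment=tag)

    with stage("exports"):
        export_heatmap_data(matrix, result.probes, labels, outdir / "heatmap.tsv", comment=tag)
        export_similarity_network(
            dmat,
            labels,
            outdir / "network_edges.tsv",
            outdir / "network_nodes.tsv",
            negligible_threshold=config.get("network_threshold"),
            comment=tag,
        )

    report = {
        "manifest_digest": manifest["digest"],
        "seed": seed,
        "accuracy": result.accuracy,
        "permutation_p": result.permutation_p,
        "signature_size": result.signature_size,
        "n_biomarker_probes": len(result.probes),
        "selected_probes": result.selected_probes,
        "folds": result.folds,
        "restricted": None
        if restricted is None
        else {
            "set": restrict_set,
            "accuracy": restricted.accuracy,
            "permutation_p": restricted.permutation_p,
            "n_biomarker_probes": len(restricted.probes),
        },
        "enrichment_significant": None
        if enrichment is None
        else enrichment.significant().to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["artifacts"] = {
        p.name: _sha256_text(p) for p in sorted(outdir.iterdir()) if p.name not in ("MANIFEST.json", "timings.json")
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True) + "\n")
    return manifest
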
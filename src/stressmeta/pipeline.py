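"""End-to-end orchestration: simulate -> DE -> classify -> orthology ->
overlap -> enrichment -> network, with disk-staged outputs.

Each stage reads its inputs from the previous stage's directory and writes
TSV/JSON outputs plus a ``.stage.json`` marker holding the run's config
hash; a stage whose marker matches the current hash and whose outputs all
exist is reloaded instead of recomputed (``force`` overrides).  All
randomness derives from the configured seed, so identical configs yield
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .classify import (ClassificationConfig, GeneClassification, classify_dataset,
                       summarize)
from .diffexpr import Contrast, DEResult, test_contrast, test_contrast_noreplicate
from .enrichment import consensus_heatmap, enrich
from .exceptions import ConfigurationError
from .network import connectivity_test, filter_edges, to_graph
from .orthology import map_to_reference
from .overlap import multiset_partition, overlap_matrix
from .simulate import (SimConfig, ExpressionDataset, generate_annotations,
                       generate_dataset, generate_network, generate_ortholog_table)

logger = logging.getLogger(__name__)

DIRECTIONS = ("overinduced", "overrepressed")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    min_paralog_score: int = 3
    min_confidence: float = 0.9
    min_datasets: int = 4
    shared_k: int = 2
    n_sim_replicates: int = 5
    sim_fraction: float = 0.2
    sim_variability: float = 0.02

    def __post_init__(self) -> None:
        if self.min_datasets > self.sim.n_datasets:
            raise ConfigurationError(
                f"min_datasets={self.min_datasets} exceeds n_datasets={self.sim.n_datasets}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError(
                f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.shared_k < 1:
            raise ConfigurationError(f"shared_k must be >= 1, got {self.shared_k}")
        if self.min_paralog_score < 1:
            raise ConfigurationError(
                f"min_paralog_score must be >= 1, got {self.min_paralog_score}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return json.loads(json.dumps(out, default=_jsonify))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("sim", {})
        if isinstance(sim, Mapping):
            sim = dict(sim)
            for key in ("species_tags", "platforms", "n_replicates"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "timepoints" in sim:
                sim["timepoints"] = tuple(tuple(tp) for tp in sim["timepoints"])
            if "shared_truth_groups" in sim:
                sim["shared_truth_groups"] = tuple(
                    tuple(g) for g in sim["shared_truth_groups"])
            if "term_size_range" in sim:
                sim["term_size_range"] = tuple(sim["term_size_range"])
            sim = SimConfig(**sim)
        cls_cfg = data.pop("classification", {})
        if isinstance(cls_cfg, Mapping):
            cls_cfg = ClassificationConfig(**cls_cfg)
        return cls(sim=sim, classification=cls_cfg, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _jsonify(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {obj!r}")


# ---------------------------------------------------------------------------
# stage plumbing

def _marker(stage_dir: Path) -> Path:
    return stage_dir / ".stage.json"


def _stage_fresh(stage_dir: Path, cfg_hash: str, outputs: list[str]) -> bool:
    marker = _marker(stage_dir)
    if not marker.exists():
        return False
    try:
        info = json.loads(marker.read_text())
    except json.JSONDecodeError:
        return False
    if info.get("config_hash") != cfg_hash:
        return False
    return all((stage_dir / name).exists() for name in info.get("outputs", [])) and \
        set(outputs) <= set(info.get("outputs", []))


def _write_marker(stage_dir: Path, cfg_hash: str, outputs: list[str]) -> None:
    _marker(stage_dir).write_text(
        json.dumps({"config_hash": cfg_hash, "outputs": sorted(outputs)},
                   sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# stage: simulate

def stage_simulate(config: PipelineConfig, outdir: Path, force: bool = False) -> dict:
    stage = Path(outdir) / "simulate"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = []
    for i in range(config.sim.n_datasets):
        names += [f"dataset{i}_matrix.tsv", f"dataset{i}_samples.tsv", f"dataset{i}_truth.tsv"]
    names += ["ortholog_table.tsv", "annotations.gmt", "network_edges.tsv"]

    if not force and _stage_fresh(stage, h, names):
        logger.info("simulate: reusing cached outputs")
        return load_simulate(config, outdir)

    bundle: dict = {"datasets": [], "truths": []}
    for i in range(config.sim.n_datasets):
        ds, truth = generate_dataset(config.sim, i)
        smio.write_matrix(ds.matrix, stage / f"dataset{i}_matrix.tsv")
        smio.write_samples(ds.samples, stage / f"dataset{i}_samples.tsv")
        truth.to_csv(stage / f"dataset{i}_truth.tsv", sep="\t")
        bundle["datasets"].append(ds)
        bundle["truths"].append(truth)
        logger.info("simulate: %s -> %d genes x %d samples (%s)",
                    ds.name, *ds.matrix.shape, ds.platform)
    bundle["orthologs"] = generate_ortholog_table(config.sim)
    smio.write_ortholog_table(bundle["orthologs"], stage / "ortholog_table.tsv")
    bundle["annotations"] = generate_annotations(config.sim)
    smio.write_gmt(bundle["annotations"], stage / "annotations.gmt")
    bundle["edges"] = generate_network(config.sim)
    smio.write_edge_list(bundle["edges"], stage / "network_edges.tsv")
    _write_marker(stage, h, names)
    return bundle


def load_simulate(config: PipelineConfig, outdir: Path) -> dict:
    stage = Path(outdir) / "simulate"
    bundle: dict = {"datasets": [], "truths": []}
    for i in range(config.sim.n_datasets):
        matrix = smio.read_matrix(stage / f"dataset{i}_matrix.tsv")
        samples = smio.read_samples(stage / f"dataset{i}_samples.tsv")
        bundle["datasets"].append(ExpressionDataset(
            name=f"dataset{i}", matrix=matrix, samples=samples,
            platform=config.sim.platforms[i], species=config.sim.species_tags[i]))
        bundle["truths"].append(
            pd.read_csv(stage / f"dataset{i}_truth.tsv", sep="\t", index_col="gene_id"))
    bundle["orthologs"] = smio.read_ortholog_table(stage / "ortholog_table.tsv")
    bundle["annotations"] = smio.read_gmt(stage / "annotations.gmt")
    bundle["edges"] = smio.read_edge_list(stage / "network_edges.tsv")
    return bundle


# ---------------------------------------------------------------------------
# stage: differential expression

def build_contrasts(dataset: ExpressionDataset) -> tuple[dict, dict]:
    """Stress contrasts per (genotype, timepoint) and genotype contrasts per
    stressed timepoint, as Contrast objects."""
    stressed_tps = sorted(
        dataset.samples.loc[dataset.samples["condition"] == "stressed", "timepoint"].unique())
    stress = {}
    genotype = {}
    for g in ("control", "depleted"):
        for t in stressed_tps:
            stress[(g, float(t))] = Contrast(
                name=f"stress_{g}_t{t:g}",
                group_a={"condition": "baseline", "genotype": g},
                group_b={"condition": "stressed", "genotype": g, "timepoint": t},
            )
    for t in stressed_tps:
        genotype[float(t)] = Contrast(
            name=f"genotype_t{t:g}",
            group_a={"condition": "stressed", "timepoint": t, "genotype": "control"},
            group_b={"condition": "stressed", "timepoint": t, "genotype": "depleted"},
        )
    return stress, genotype


def _run_de_for_dataset(config: PipelineConfig, dataset: ExpressionDataset,
                        dataset_index: int) -> list[DEResult]:
    stress, genotype = build_contrasts(dataset)
    n_rep = int(dataset.samples["replicate"].max())
    per_cell = dataset.samples.groupby(
        ["genotype", "condition", "timepoint"]).size().min()
    results = []
    noreplicate = dataset.platform == "counts" and per_cell == 1
    for contrast in list(stress.values()) + list(genotype.values()):
        if noreplicate:
            res = test_contrast_noreplicate(
                dataset, contrast,
                n_sim_replicates=config.n_sim_replicates,
                sim_fraction=config.sim_fraction,
                sim_variability=config.sim_variability,
                seed=(config.sim.seed * 97 + dataset_index * 13 + 7) & 0x7FFFFFFF,
            )
        else:
            res = test_contrast(dataset, contrast)
        results.append(res)
    logger.info("de: %s -> %d contrasts (%s), replicates=%d",
                dataset.name, len(results), results[0].mode, n_rep)
    return results


def stage_de(config: PipelineConfig, outdir: Path, force: bool = False,
             bundle: dict | None = None) -> dict[str, list[DEResult]]:
    stage = Path(outdir) / "de"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = [f"dataset{i}.tsv" for i in range(config.sim.n_datasets)]
    if not force and _stage_fresh(stage, h, names):
        logger.info("de: reusing cached outputs")
        return load_de(config, outdir)
    bundle = bundle or load_simulate(config, outdir)
    out: dict[str, list[DEResult]] = {}
    for i, dataset in enumerate(bundle["datasets"]):
        results = _run_de_for_dataset(config, dataset, i)
        out[dataset.name] = results
        smio.write_de_table(
            pd.concat([r.to_frame() for r in results]), stage / f"dataset{i}.tsv")
    _write_marker(stage, h, names)
    return out


_STRESS_RE = re.compile(r"^stress_(control|depleted)_t([0-9.]+)$")
_GENOTYPE_RE = re.compile(r"^genotype_t([0-9.]+)$")


def load_de(config: PipelineConfig, outdir: Path) -> dict[str, list[DEResult]]:
    stage = Path(outdir) / "de"
    out: dict[str, list[DEResult]] = {}
    for i in range(config.sim.n_datasets):
        raw = pd.read_csv(stage / f"dataset{i}.tsv", sep="\t", dtype={"gene_id": str})
        results = []
        for contrast, grp in raw.groupby("contrast", sort=False):
            table = grp.set_index("gene_id")[["log2fc", "p", "p_adj"]]
            mode = grp["mode"].iloc[0]
            meta: dict = {"orientation": "B_vs_A"}
            if _GENOTYPE_RE.match(contrast):
                meta["condition"] = "stressed"
            results.append(DEResult(contrast=contrast, mode=mode, table=table, meta=meta))
        out[f"dataset{i}"] = results
    return out


def split_de_results(results: list[DEResult]) -> tuple[dict, dict]:
    """Key DE results back into stress and genotype mappings by contrast name."""
    stress: dict[tuple[str, float], DEResult] = {}
    genotype: dict[float, DEResult] = {}
    for res in results:
        m = _STRESS_RE.match(res.contrast)
        if m:
            stress[(m.group(1), float(m.group(2)))] = res
            continue
        m = _GENOTYPE_RE.match(res.contrast)
        if m:
            genotype[float(m.group(1))] = res
    return stress, genotype


# ---------------------------------------------------------------------------
# stage: classify

def stage_classify(config: PipelineConfig, outdir: Path, force: bool = False,
                   de_results: dict[str, list[DEResult]] | None = None
                   ) -> dict[str, GeneClassification]:
    stage = Path(outdir) / "classify"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = [f"dataset{i}_classification.tsv" for i in range(config.sim.n_datasets)]
    names += ["summary.tsv", "summary.json"]
    if not force and _stage_fresh(stage, h, names):
        logger.info("classify: reusing cached outputs")
        return load_classify(config, outdir)
    de_results = de_results or load_de(config, outdir)
    out: dict[str, GeneClassification] = {}
    for i in range(config.sim.n_datasets):
        name = f"dataset{i}"
        stress, genotype = split_de_results(de_results[name])
        cls = classify_dataset(name, stress, genotype, config.classification)
        out[name] = cls
        cls.table.to_csv(stage / f"{name}_classification.tsv", sep="\t")
        logger.info("classify: %s -> %d responsive, %d dependent", name,
                    int(cls.table["stress_responsive"].sum()),
                    int(cls.table["g9a_dependent"].sum()))
    summary = summarize(out)
    summary.table.to_csv(stage / "summary.tsv", sep="\t")
    (stage / "summary.json").write_text(json.dumps(
        {"mean_pct_unfloored": summary.mean_pct}, sort_keys=True))
    _write_marker(stage, h, names)
    return out


def load_classify(config: PipelineConfig, outdir: Path) -> dict[str, GeneClassification]:
    stage = Path(outdir) / "classify"
    out = {}
    for i in range(config.sim.n_datasets):
        name = f"dataset{i}"
        table = pd.read_csv(stage / f"{name}_classification.tsv", sep="\t",
                            index_col="gene_id",
                            dtype={"responsive_in": str})
        table["responsive_in"] = table["responsive_in"].fillna("")
        out[name] = GeneClassification(dataset=name, table=table,
                                       config=config.classification)
    return out


# ---------------------------------------------------------------------------
# stage: orthology

def stage_orthology(config: PipelineConfig, outdir: Path, force: bool = False,
                    classifications: dict[str, GeneClassification] | None = None,
                    bundle: dict | None = None) -> dict:
    """Map each dataset's direction gene sets and tested universe onto the
    reference namespace.  Reference-species datasets map by identity."""
    stage = Path(outdir) / "orthology"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = []
    for i in range(config.sim.n_datasets):
        names += [f"dataset{i}_overinduced.txt", f"dataset{i}_overrepressed.txt",
                  f"dataset{i}_universe.txt", f"dataset{i}_report.tsv"]
    if not force and _stage_fresh(stage, h, names):
        logger.info("orthology: reusing cached outputs")
        return load_orthology(config, outdir)
    classifications = classifications or load_classify(config, outdir)
    bundle = bundle or load_simulate(config, outdir)
    table = bundle["orthologs"]
    ref = config.sim.reference_species
    sets: dict[str, dict[str, set]] = {d: {} for d in DIRECTIONS}
    universes: dict[str, set] = {}
    for i in range(config.sim.n_datasets):
        name = f"dataset{i}"
        species = config.sim.species_tags[i]
        cls = classifications[name]
        tested = set(cls.table.index)
        if species == ref:
            universes[name] = tested
            for d in DIRECTIONS:
                sets[d][name] = cls.genes_with_direction(d)
            report = pd.DataFrame(columns=["kind", "source_gene", "reference_genes"])
        else:
            uni_map = map_to_reference(tested, table, species=species,
                                       min_paralog_score=config.min_paralog_score)
            universes[name] = uni_map.mapped
            for d in DIRECTIONS:
                m = map_to_reference(cls.genes_with_direction(d), table, species=species,
                                     min_paralog_score=config.min_paralog_score)
                sets[d][name] = m.mapped
            report = uni_map.report_frame()
        smio.write_gene_list(sorted(sets["overinduced"][name]),
                             stage / f"{name}_overinduced.txt")
        smio.write_gene_list(sorted(sets["overrepressed"][name]),
                             stage / f"{name}_overrepressed.txt")
        smio.write_gene_list(sorted(universes[name]), stage / f"{name}_universe.txt")
        report.to_csv(stage / f"{name}_report.tsv", sep="\t", index=False)
        logger.info("orthology: %s (%s) -> universe %d, overinduced %d, overrepressed %d",
                    name, species, len(universes[name]),
                    len(sets["overinduced"][name]), len(sets["overrepressed"][name]))
    _write_marker(stage, h, names)
    return {"sets": sets, "universes": universes}


def load_orthology(config: PipelineConfig, outdir: Path) -> dict:
    stage = Path(outdir) / "orthology"
    sets: dict[str, dict[str, set]] = {d: {} for d in DIRECTIONS}
    universes: dict[str, set] = {}
    for i in range(config.sim.n_datasets):
        name = f"dataset{i}"
        for d in DIRECTIONS:
            sets[d][name] = set(smio.read_gene_list(stage / f"{name}_{d}.txt"))
        universes[name] = set(smio.read_gene_list(stage / f"{name}_universe.txt"))
    return {"sets": sets, "universes": universes}


# ---------------------------------------------------------------------------
# stage: overlap

def stage_overlap(config: PipelineConfig, outdir: Path, force: bool = False,
                  ortho: dict | None = None) -> dict:
    stage = Path(outdir) / "overlap"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = ["pairs.tsv"]
    for d in DIRECTIONS:
        names += [f"{d}_venn.tsv", f"{d}_shared.txt"]
    if not force and _stage_fresh(stage, h, names):
        logger.info("overlap: reusing cached outputs")
        return load_overlap(config, outdir)
    ortho = ortho or load_orthology(config, outdir)
    pairs = overlap_matrix(ortho["sets"], ortho["universes"])
    pairs.to_csv(stage / "pairs.tsv", sep="\t", index=False)
    out = {"pairs": pairs, "partitions": {}}
    for d in DIRECTIONS:
        part = multiset_partition(ortho["sets"][d], k=config.shared_k)
        out["partitions"][d] = part
        venn = pd.DataFrame(
            [(";".join(sorted(region)), count)
             for region, count in sorted(part.venn_counts.items(),
                                         key=lambda kv: sorted(kv[0]))],
            columns=["region", "n_genes"])
        venn.to_csv(stage / f"{d}_venn.tsv", sep="\t", index=False)
        smio.write_gene_list(sorted(part.shared), stage / f"{d}_shared.txt")
        logger.info("overlap: %s -> %d shared (>=%d datasets), %d unique",
                    d, len(part.shared), config.shared_k,
                    sum(len(u) for u in part.unique.values()))
    _write_marker(stage, h, names)
    return out


def load_overlap(config: PipelineConfig, outdir: Path) -> dict:
    stage = Path(outdir) / "overlap"
    pairs = pd.read_csv(stage / "pairs.tsv", sep="\t")
    ortho = load_orthology(config, outdir)
    out = {"pairs": pairs, "partitions": {}}
    for d in DIRECTIONS:
        out["partitions"][d] = multiset_partition(ortho["sets"][d], k=config.shared_k)
    return out


# ---------------------------------------------------------------------------
# stage: enrichment

def stage_enrichment(config: PipelineConfig, outdir: Path, force: bool = False,
                     ortho: dict | None = None, bundle: dict | None = None) -> dict:
    stage = Path(outdir) / "enrichment"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = ["consensus_matrix.tsv"]
    for d in DIRECTIONS:
        names += [f"{d}_dataset{i}.tsv" for i in range(config.sim.n_datasets)]
    if not force and _stage_fresh(stage, h, names):
        logger.info("enrichment: reusing cached outputs")
        return load_enrichment(config, outdir)
    ortho = ortho or load_orthology(config, outdir)
    bundle = bundle or load_simulate(config, outdir)
    annotations = bundle["annotations"]
    results: dict[str, dict[str, pd.DataFrame]] = {d: {} for d in DIRECTIONS}
    for d in DIRECTIONS:
        for name in ortho["sets"][d]:
            table = enrich(ortho["sets"][d][name], annotations, ortho["universes"][name])
            results[d][name] = table
            table.to_csv(stage / f"{d}_{name}.tsv", sep="\t")
    matrix = consensus_heatmap(results, min_datasets=config.min_datasets,
                               alpha=config.classification.alpha)
    matrix.to_csv(stage / "consensus_matrix.tsv", sep="\t")
    logger.info("enrichment: consensus matrix %d terms x %d columns", *matrix.shape)
    _write_marker(stage, h, names)
    return {"results": results, "consensus": matrix}


def load_enrichment(config: PipelineConfig, outdir: Path) -> dict:
    stage = Path(outdir) / "enrichment"
    results: dict[str, dict[str, pd.DataFrame]] = {d: {} for d in DIRECTIONS}
    for d in DIRECTIONS:
        for i in range(config.sim.n_datasets):
            name = f"dataset{i}"
            results[d][name] = pd.read_csv(
                stage / f"{d}_{name}.tsv", sep="\t", index_col="term")
    matrix = pd.read_csv(stage / "consensus_matrix.tsv", sep="\t",
                         header=[0, 1], index_col=0)
    return {"results": results, "consensus": matrix}


# ---------------------------------------------------------------------------
# stage: network

def stage_network(config: PipelineConfig, outdir: Path, force: bool = False,
                  overlap_out: dict | None = None, bundle: dict | None = None) -> dict:
    stage = Path(outdir) / "network"
    stage.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    names = [f"{d}_stats.json" for d in DIRECTIONS] + [f"{d}_degrees.tsv" for d in DIRECTIONS]
    if not force and _stage_fresh(stage, h, names):
        logger.info("network: reusing cached outputs")
        return load_network(config, outdir)
    overlap_out = overlap_out or load_overlap(config, outdir)
    bundle = bundle or load_simulate(config, outdir)
    edges = filter_edges(bundle["edges"], min_confidence=config.min_confidence)
    graph = to_graph(edges)
    out = {}
    for d in DIRECTIONS:
        shared = overlap_out["partitions"][d].shared
        members = sorted(shared & set(graph.nodes))
        if members:
            stats = connectivity_test(graph, shared, method="analytic")
            sub = graph.subgraph(members)
            degrees = pd.DataFrame(
                {"gene_id": members,
                 "within_set_degree": [sub.degree(n) for n in members]})
            result = stats.as_dict()
        else:
            degrees = pd.DataFrame(columns=["gene_id", "within_set_degree"])
            result = {"set_size": len(shared), "n_in_network": 0,
                      "observed_edges": 0, "n_connected": 0,
                      "expected_edges": 0.0, "p_value": 1.0, "method": "analytic",
                      "note": "no shared gene present in the filtered network"}
        (stage / f"{d}_stats.json").write_text(json.dumps(result, sort_keys=True, indent=1))
        degrees.to_csv(stage / f"{d}_degrees.tsv", sep="\t", index=False)
        logger.info("network: %s -> observed=%s expected=%.1f p=%.3g", d,
                    result["observed_edges"], result["expected_edges"],
                    result["p_value"])
        out[d] = result
    _write_marker(stage, h, names)
    return out


def load_network(config: PipelineConfig, outdir: Path) -> dict:
    stage = Path(outdir) / "network"
    return {d: json.loads((stage / f"{d}_stats.json").read_text()) for d in DIRECTIONS}


# ---------------------------------------------------------------------------
# run everything

def run_all(config: PipelineConfig, outdir: str | Path, force: bool = False) -> dict:
    """Execute every stage in order; returns the in-memory result bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = stage_simulate(config, outdir, force)
    de = stage_de(config, outdir, force, bundle=bundle)
    classifications = stage_classify(config, outdir, force, de_results=de)
    ortho = stage_orthology(config, outdir, force,
                            classifications=classifications, bundle=bundle)
    overlap_out = stage_overlap(config, outdir, force, ortho=ortho)
    enrichment_out = stage_enrichment(config, outdir, force, ortho=ortho, bundle=bundle)
    network_out = stage_network(config, outdir, force,
                                overlap_out=overlap_out, bundle=bundle)
    summary = summarize(classifications)
    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    for stage_name in ("simulate", "de", "classify", "orthology", "overlap",
                       "enrichment", "network"):
        stage_dir = outdir / stage_name
        files = sorted(p.name for p in stage_dir.iterdir() if not p.name.startswith("."))
        manifest["stages"][stage_name] = {
            name: sum(1 for _ in open(stage_dir / name)) - 1
            if name.endswith(".tsv") else None
            for name in files
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return {
        "bundle": bundle,
        "de": de,
        "classifications": classifications,
        "summary": summary,
        "orthology": ortho,
        "overlap": overlap_out,
        "enrichment": enrichment_out,
        "network": network_out,
    }
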
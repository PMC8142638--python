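"""Synthetic multi-dataset stress-transcriptome generator with planted truth.

Emulates a five-dataset meta-analysis design: per dataset a genes x samples
expression matrix (negative-binomial counts for sequencing platforms,
Gaussian log-intensities for arrays) over a genotype (control vs depleted)
x condition (baseline vs stressed) x timepoint x replicate layout, with

* a planted subset of stress-responsive genes whose stressed samples are
  shifted by ``base_log2fc`` in both genotypes,
* a planted sub-subset of repressor-dependent genes whose shift in the
  depleted genotype is ``exaggeration_factor`` times larger (same sign), in
  both the induced and the repressed direction,
* multi-species gene namespaces joined by a scored ortholog table,
* GMT annotation sets enriched for the planted dependent genes, and
* a background interaction network containing a planted dense module.

Every output is fully determined by ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "SimConfig",
    "ExpressionDataset",
    "generate_dataset",
    "generate_ortholog_table",
    "generate_annotations",
    "generate_network",
]

_DEFAULT_SPECIES = ("dmel", "dmel", "mmus", "mmus", "hsap")
_DEFAULT_PLATFORMS = ("counts", "counts", "intensity", "intensity", "intensity")
_DEFAULT_TIMEPOINTS = ((6.0, 12.0), (24.0,), (6.0, 12.0), (4.0, 24.0), (4.0, 24.0))
_DEFAULT_REPLICATES = (5, 0, 5, 5, 5)


@dataclass(frozen=True)
class ExpressionDataset:
    """One study's expression matrix plus its sample design.

    ``matrix`` is genes x samples; ``samples`` is indexed by sample_id with
    columns genotype (control|depleted), condition (baseline|stressed),
    timepoint (hours; 0 at baseline) and replicate.
    """

    name: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    platform: str
    species: str

    def __post_init__(self) -> None:
        if self.platform not in ("counts", "intensity"):
            raise ConfigurationError(f"platform must be counts|intensity, got {self.platform!r}")
        if self.matrix.index.duplicated().any():
            raise ConfigurationError("gene_ids must be unique")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ConfigurationError("matrix columns must match sample metadata order")
        for col in ("genotype", "condition", "timepoint", "replicate"):
            if col not in self.samples.columns:
                raise ConfigurationError(f"sample metadata missing field {col!r}")
        if not np.isfinite(self.matrix.to_numpy(float)).all():
            raise ConfigurationError("expression matrix contains non-finite values")


@dataclass(frozen=True)
class SimConfig:
    """Study design and effect sizes for the synthetic experiment suite.

    Defaults mirror the five-dataset design being emulated: two fly
    sequencing datasets (the second without replicates), two mouse and one
    human array dataset, one or two stressed timepoints each.
    """

    n_genes: int = 2000
    n_datasets: int = 5
    species_tags: Sequence[str] = _DEFAULT_SPECIES
    platforms: Sequence[str] = _DEFAULT_PLATFORMS
    timepoints: Sequence[Sequence[float]] = _DEFAULT_TIMEPOINTS
    n_replicates: int | Sequence[int] = _DEFAULT_REPLICATES
    frac_stress_responsive: float = 0.1
    frac_g9a_dependent_of_responsive: float = 0.5
    frac_induced: float = 0.5
    base_log2fc: float = 1.0
    exaggeration_factor: float = 2.0
    nb_dispersion: float = 0.05
    intensity_sd: float = 0.25
    # ortholog-table shape
    frac_unmapped: float = 0.1
    frac_multi: float = 0.2
    # annotations
    n_terms: int = 30
    n_planted_terms: int = 3
    term_size_range: tuple[int, int] = (20, 100)
    annotation_enrichment: float = 10.0
    # network
    edge_prob: float = 0.005
    module_enrichment: float = 5.0
    # dataset index groups that share one truth allocation; the default
    # plants one conserved dependent program across all five datasets
    shared_truth_groups: Sequence[Sequence[int]] = ((0, 1, 2, 3, 4),)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_stress_responsive", "frac_g9a_dependent_of_responsive",
                     "frac_induced", "frac_unmapped", "frac_multi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.exaggeration_factor <= 1.0:
            raise ConfigurationError(
                f"exaggeration_factor must be > 1, got {self.exaggeration_factor}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.intensity_sd <= 0:
            raise ConfigurationError(f"intensity_sd must be > 0, got {self.intensity_sd}")
        if self.n_datasets < 1:
            raise ConfigurationError(f"n_datasets must be >= 1, got {self.n_datasets}")
        if not 0 < self.edge_prob < 1:
            raise ConfigurationError(f"edge_prob must be in (0, 1), got {self.edge_prob}")
        for seq_name in ("species_tags", "platforms", "timepoints"):
            if len(getattr(self, seq_name)) < self.n_datasets:
                raise ConfigurationError(
                    f"{seq_name} must list at least n_datasets={self.n_datasets} entries")
        if self.term_size_range[1] > self.n_genes:
            raise ConfigurationError(
                f"term_size_range upper bound {self.term_size_range[1]} exceeds "
                f"n_genes={self.n_genes}")

    def replicates_for(self, dataset_index: int) -> int:
        if isinstance(self.n_replicates, int):
            return self.n_replicates
        return int(self.n_replicates[dataset_index])

    @property
    def reference_species(self) -> str:
        return self.species_tags[0]

    def gene_ids(self, species: str) -> list[str]:
        return [f"{species}_g{i:05d}" for i in range(self.n_genes)]


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def _allocation_key(config: SimConfig, dataset_index: int) -> int:
    for gi, group in enumerate(config.shared_truth_groups):
        if dataset_index in group:
            return gi
    return 1000 + dataset_index


def _truth_for(config: SimConfig, dataset_index: int) -> pd.DataFrame:
    """Deterministic per-gene truth allocation for one dataset.

    Gene indices are permuted with a seeded RNG, then sliced: the first
    ``round(n * frac_stress_responsive)`` genes are responsive, and of those
    the first ``round(frac_g9a_dependent_of_responsive * n_resp)`` are
    dependent.  Direction is allocated by an independent permutation of the
    responsive genes so induced/repressed mix across both classes.
    """
    n = config.n_genes
    rng = _rng(config, 100, _allocation_key(config, dataset_index))
    perm = rng.permutation(n)
    n_resp = int(round(n * config.frac_stress_responsive))
    n_dep = int(round(n_resp * config.frac_g9a_dependent_of_responsive))
    responsive = perm[:n_resp]
    dependent = set(responsive[:n_dep])

    n_ind = int(round(n_resp * config.frac_induced))
    dir_perm = rng.permutation(n_resp)
    induced_positions = set(dir_perm[:n_ind])

    true_class = np.full(n, "null", dtype=object)
    true_direction = np.full(n, "none", dtype=object)
    lfc_control = np.zeros(n)
    lfc_depleted = np.zeros(n)
    for pos, g in enumerate(responsive):
        sign = 1.0 if pos in induced_positions else -1.0
        true_direction[g] = "induced" if sign > 0 else "repressed"
        lfc_control[g] = sign * config.base_log2fc
        if g in dependent:
            true_class[g] = "g9a_dependent"
            lfc_depleted[g] = sign * config.base_log2fc * config.exaggeration_factor
        else:
            true_class[g] = "responsive_only"
            lfc_depleted[g] = sign * config.base_log2fc

    species = config.species_tags[dataset_index]
    return pd.DataFrame(
        {
            "true_class": true_class,
            "true_direction": true_direction,
            "true_log2fc_control": lfc_control,
            "true_log2fc_depleted": lfc_depleted,
        },
        index=pd.Index(config.gene_ids(species), name="gene_id"),
    )


def _sample_design(config: SimConfig, dataset_index: int) -> pd.DataFrame:
    """Sample sheet for one dataset; 0 replicates means one lone sample per cell."""
    n_rep = config.replicates_for(dataset_index)
    reps = range(1, max(n_rep, 1) + 1)
    stressed_tps = [float(t) for t in config.timepoints[dataset_index]]
    rows = []
    for genotype in ("control", "depleted"):
        for r in reps:
            rows.append((genotype, "baseline", 0.0, r))
        for t in stressed_tps:
            for r in reps:
                rows.append((genotype, "stressed", t, r))
    df = pd.DataFrame(rows, columns=["genotype", "condition", "timepoint", "replicate"])
    df.index = pd.Index(
        [f"ds{dataset_index}_{g[:3]}_{c[:4]}_t{t:g}_r{r}"
         for g, c, t, r in df.itertuples(index=False)],
        name="sample_id",
    )
    return df


def generate_dataset(config: SimConfig, dataset_index: int) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate one dataset's expression matrix and its planted-truth table."""
    if dataset_index >= config.n_datasets:
        raise ConfigurationError(
            f"dataset_index {dataset_index} out of range for n_datasets={config.n_datasets}")
    platform = config.platforms[dataset_index]
    if platform not in ("counts", "intensity"):
        raise ConfigurationError(f"platforms[{dataset_index}] must be counts|intensity")
    truth = _truth_for(config, dataset_index)
    samples = _sample_design(config, dataset_index)
    rng = _rng(config, 200, dataset_index)
    n, s = config.n_genes, len(samples)

    lfc = np.zeros((n, s))
    stressed = (samples["condition"] == "stressed").to_numpy()
    depleted = (samples["genotype"] == "depleted").to_numpy()
    lfc[:, stressed & ~depleted] = truth["true_log2fc_control"].to_numpy()[:, None]
    lfc[:, stressed & depleted] = truth["true_log2fc_depleted"].to_numpy()[:, None]

    if platform == "counts":
        base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)
        size_factors = rng.lognormal(mean=0.0, sigma=0.2, size=s)
        mu = base_mean[:, None] * (2.0 ** lfc) * size_factors[None, :]
        r = 1.0 / config.nb_dispersion  # variance mu + alpha*mu^2
        values = rng.negative_binomial(n=r, p=r / (r + mu)).astype(np.int64)
    else:
        base = rng.normal(loc=8.0, scale=2.0, size=n)
        sample_shift = rng.normal(loc=0.0, scale=0.1, size=s)
        noise = rng.normal(scale=config.intensity_sd, size=(n, s))
        values = base[:, None] + lfc + sample_shift[None, :] + noise

    matrix = pd.DataFrame(values, index=truth.index, columns=samples.index)
    dataset = ExpressionDataset(
        name=f"dataset{dataset_index}",
        matrix=matrix,
        samples=samples,
        platform=platform,
        species=config.species_tags[dataset_index],
    )
    return dataset, truth


def generate_ortholog_table(config: SimConfig) -> pd.DataFrame:
    """Scored (source_gene, source_species, reference_gene, score) records.

    Each non-reference species' gene i has its true ortholog at reference
    gene i (preserving planted identity across namespaces); a seeded
    ``frac_unmapped`` slice of genes carries no record, and a ``frac_multi``
    slice of the mapped genes carries one extra scored paralog record.
    """
    species = list(dict.fromkeys(config.species_tags[: config.n_datasets]))
    if len(species) < 2:
        raise ConfigurationError("need >= 2 species tags to build an ortholog table")
    ref = config.reference_species
    ref_genes = config.gene_ids(ref)
    rng = _rng(config, 300)
    rows: list[tuple[str, str, str, int]] = []
    for sp in species:
        if sp == ref:
            continue
        src_genes = config.gene_ids(sp)
        perm = rng.permutation(config.n_genes)
        n_unmapped = int(round(config.n_genes * config.frac_unmapped))
        mapped = perm[n_unmapped:]
        n_multi = int(round(len(mapped) * config.frac_multi))
        multi = set(mapped[:n_multi])
        for gi in mapped:
            top_score = int(rng.integers(5, 16))
            rows.append((src_genes[gi], sp, ref_genes[gi], top_score))
            if gi in multi:
                other = int(rng.integers(0, config.n_genes))
                if other == gi:
                    other = (other + 1) % config.n_genes
                paralog_score = int(rng.integers(1, top_score + 1))
                rows.append((src_genes[gi], sp, ref_genes[other], paralog_score))
    table = pd.DataFrame(rows, columns=["source_gene", "source_species", "reference_gene", "score"])
    # extra paralog may collide with the top hit for another source; dedup pairs
    table = table.drop_duplicates(["source_gene", "reference_gene"]).reset_index(drop=True)
    return table


def generate_annotations(config: SimConfig) -> dict[str, set[str]]:
    """GMT-style term -> gene-set collection over the reference namespace.

    ``n_planted_terms`` of the terms sample their members with weight
    ``annotation_enrichment`` on the reference dataset's planted dependent
    genes, so ORA against a dependent-gene query shows true enrichment.
    """
    lo, hi = config.term_size_range
    if hi > config.n_genes:
        raise ConfigurationError("term size exceeds n_genes")
    rng = _rng(config, 400)
    ref_genes = np.array(config.gene_ids(config.reference_species))
    truth = _truth_for(config, 0)
    planted_mask = (truth["true_class"] == "g9a_dependent").to_numpy()
    weights = np.where(planted_mask, config.annotation_enrichment, 1.0)
    weights = weights / weights.sum()

    sets: dict[str, set[str]] = {}
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_planted_terms:
            members = rng.choice(config.n_genes, size=size, replace=False, p=weights)
            name = f"planted_term_{i:02d}"
        else:
            members = rng.choice(config.n_genes, size=size, replace=False)
            name = f"background_term_{i:02d}"
        sets[name] = set(ref_genes[members])
    return sets


def generate_network(config: SimConfig) -> pd.DataFrame:
    """Undirected weighted edge list over the reference namespace.

    Background pairs connect with probability ``edge_prob``; pairs inside
    the planted module (the reference dataset's dependent genes) connect
    with probability ``module_enrichment * edge_prob``.  Edge confidences
    are independent Uniform(0, 1).  No self-loops, no duplicate edges.
    """
    rng = _rng(config, 500)
    n = config.n_genes
    ref_genes = np.array(config.gene_ids(config.reference_species))
    truth = _truth_for(config, 0)
    in_module = (truth["true_class"] == "g9a_dependent").to_numpy()

    iu, ju = np.triu_indices(n, k=1)
    p = np.full(iu.shape, config.edge_prob)
    both = in_module[iu] & in_module[ju]
    p[both] = min(1.0, config.module_enrichment * config.edge_prob)
    keep = rng.random(iu.shape[0]) < p
    a, b = iu[keep], ju[keep]
    conf = rng.random(a.shape[0])
    return pd.DataFrame(
        {"node_a": ref_genes[a], "node_b": ref_genes[b], "confidence": np.round(conf, 6)}
    )


def null_config(config: SimConfig) -> SimConfig:
    """Same design with no planted effects (all genes null)."""
    return replace(config, frac_stress_responsive=0.0)
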
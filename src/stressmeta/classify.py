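"""Gene-classification cascade: stress-responsive -> repressor-dependent ->
overinduced / overrepressed, plus the per-dataset summary table.

Definitions (thresholds configurable, defaults printed in parentheses):

* stress-responsive — |linear FC| > fc_threshold (1.2) AND significant
  (p_adj < alpha = 0.05, or q > q_threshold = 0.90 in no-replicate mode)
  in at least one stressed-vs-baseline contrast of either genotype.
* G9a-dependent — stress-responsive AND significantly different between
  depleted and control samples at >= 1 stressed timepoint (same FC and
  significance rules, mode-aware).
* direction — at the classifying timepoint (largest |control response|,
  falling back to largest |depleted response| when the control response is
  sub-threshold): overinduced when both genotypes respond upward and the
  depleted response is larger; overrepressed symmetric for downward;
  anything else (sign disagreement, smaller depleted magnitude) discordant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DEResult
from .exceptions import ConfigurationError, StressmetaError

__all__ = [
    "ClassificationConfig",
    "GeneClassification",
    "ClassificationSummary",
    "call_stress_responsive",
    "call_g9a_dependent",
    "assign_direction",
    "classify_dataset",
    "summarize",
    "summary_from_counts",
]


@dataclass(frozen=True)
class ClassificationConfig:
    fc_threshold: float = 1.2
    alpha: float = 0.05
    q_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1.0:
            raise ConfigurationError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.q_threshold < 1.0:
            raise ConfigurationError(f"q_threshold must be in (0, 1), got {self.q_threshold}")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class GeneClassification:
    """Per-gene flags and labels for one dataset.

    ``table`` is indexed by gene_id with columns: stress_responsive (bool),
    responsive_in (';'-joined passing contrast keys), g9a_dependent (bool),
    direction (overinduced|overrepressed|discordant|none), and the
    supporting log2fc values used for direction assignment.
    """

    dataset: str
    table: pd.DataFrame
    config: ClassificationConfig

    def genes_with_direction(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["direction"] == direction])


def _passes(de: DEResult, config: ClassificationConfig) -> pd.Series:
    """Mode-aware pass flag: FC threshold plus significance."""
    fc_ok = de.table["log2fc"].abs() > config.log2fc_threshold
    if de.mode == "noreplicate_test":
        sig = de.table["p"] > config.q_threshold
    else:
        sig = de.table["p_adj"] < config.alpha
    return fc_ok & sig


def call_stress_responsive(
    stress_results: Mapping[tuple[str, float], DEResult],
    config: ClassificationConfig,
) -> pd.DataFrame:
    """Flag genes passing in ANY (genotype, timepoint) stress contrast.

    ``stress_results`` maps (genotype, timepoint) to the stressed-vs-baseline
    DE result for that cell.  Both genotypes must be represented (the
    definition reads "in either depleted conditions or controls", which
    presumes both were assessed).
    """
    genotypes = {g for g, _ in stress_results}
    if not {"control", "depleted"} <= genotypes:
        raise StressmetaError(
            f"stress contrasts must cover both genotypes; got {sorted(genotypes)}")
    items = sorted(stress_results.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    index = items[0][1].table.index
    flags = pd.Series(False, index=index)
    labels = [[] for _ in range(len(index))]
    for (genotype, timepoint), de in items:
        ok = _passes(de, config).reindex(index, fill_value=False)
        flags |= ok
        key = f"{genotype}@t{timepoint:g}"
        for pos in np.flatnonzero(ok.to_numpy()):
            labels[pos].append(key)
    return pd.DataFrame(
        {"stress_responsive": flags, "responsive_in": [";".join(ls) for ls in labels]},
        index=index,
    )


def call_g9a_dependent(
    responsive: pd.Series,
    genotype_results: Mapping[float, DEResult],
    config: ClassificationConfig,
) -> pd.Series:
    """Intersection rule: responsive AND genotype-different at a stressed timepoint.

    ``genotype_results`` maps stressed timepoint to the depleted-vs-control
    DE result computed among stressed samples at that timepoint.  A result
    computed at baseline is rejected (the rule applies at stress-induced
    timepoints only).
    """
    if not genotype_results:
        raise StressmetaError("genotype contrasts at stressed timepoints are required")
    dep = pd.Series(False, index=responsive.index)
    for timepoint, de in genotype_results.items():
        if de.meta.get("condition", "stressed") == "baseline":
            raise StressmetaError(
                f"genotype contrast at timepoint {timepoint} was computed at baseline; "
                "the dependence rule applies at stressed timepoints")
        dep |= _passes(de, config).reindex(responsive.index, fill_value=False)
    return responsive.astype(bool) & dep


def assign_direction(
    g9a_dependent: pd.Series,
    stress_results: Mapping[tuple[str, float], DEResult],
    config: ClassificationConfig,
) -> pd.DataFrame:
    """Label each dependent gene overinduced / overrepressed / discordant.

    The classifying timepoint is the stressed timepoint with the largest
    |control log2fc|; when the control response is below the FC threshold
    there, the timepoint with the largest |depleted log2fc| is used instead
    and the label follows the depleted response's sign.
    """
    index = g9a_dependent.index
    timepoints = sorted({t for _, t in stress_results})
    lfc_c = np.zeros((len(index), len(timepoints)))
    lfc_d = np.zeros((len(index), len(timepoints)))
    for (genotype, timepoint), de in stress_results.items():
        col = timepoints.index(timepoint)
        vals = de.table["log2fc"].reindex(index).fillna(0.0).to_numpy()
        if genotype == "control":
            lfc_c[:, col] = vals
        else:
            lfc_d[:, col] = vals

    t_star = np.argmax(np.abs(lfc_c), axis=1)
    rows = np.arange(len(index))
    lc = lfc_c[rows, t_star]
    ld = lfc_d[rows, t_star]
    thr = config.log2fc_threshold

    # fall back to the depleted response where control is sub-threshold
    weak_control = np.abs(lc) <= thr
    t_alt = np.argmax(np.abs(lfc_d), axis=1)
    lc = np.where(weak_control, lfc_c[rows, t_alt], lc)
    ld = np.where(weak_control, lfc_d[rows, t_alt], ld)

    direction = np.full(len(index), "none", dtype=object)
    dep = g9a_dependent.to_numpy(dtype=bool)

    sub = np.abs(lc) <= thr  # control response sub-threshold even at t_alt
    up = ld > 0
    down = ld < 0
    direction[dep & sub & up] = "overinduced"
    direction[dep & sub & down] = "overrepressed"
    direction[dep & sub & (ld == 0)] = "discordant"

    strong = dep & ~sub
    same_sign = np.sign(lc) == np.sign(ld)
    bigger = np.abs(ld) > np.abs(lc)
    direction[strong & same_sign & bigger & (lc > 0)] = "overinduced"
    direction[strong & same_sign & bigger & (lc < 0)] = "overrepressed"
    direction[strong & (~same_sign | ~bigger)] = "discordant"

    return pd.DataFrame(
        {
            "direction": direction,
            "log2fc_control": lc,
            "log2fc_depleted": ld,
            "control_subthreshold": sub & dep,
        },
        index=index,
    )


def classify_dataset(
    dataset_name: str,
    stress_results: Mapping[tuple[str, float], DEResult],
    genotype_results: Mapping[float, DEResult],
    config: ClassificationConfig | None = None,
) -> GeneClassification:
    """Run the full cascade for one dataset."""
    config = config or ClassificationConfig()
    resp = call_stress_responsive(stress_results, config)
    dep = call_g9a_dependent(resp["stress_responsive"], genotype_results, config)
    dirs = assign_direction(dep, stress_results, config)
    table = resp.join(dep.rename("g9a_dependent")).join(dirs)
    return GeneClassification(dataset=dataset_name, table=table, config=config)


@dataclass
class ClassificationSummary:
    """Per-dataset counts plus the cross-dataset mean of unfloored percentages."""

    table: pd.DataFrame
    mean_pct: float


def summary_from_counts(counts: Mapping[str, tuple[int, int]]) -> ClassificationSummary:
    """Summary table from (n_stress_responsive, n_g9a_dependent) count pairs.

    The displayed percentage is floor(100 * dependent / responsive); the
    cross-dataset mean averages the unfloored percentages.  A dataset with
    zero responsive genes reports an undefined (<NA>) percentage and is
    excluded from the mean.
    """
    rows = []
    unfloored = []
    for name, (n_resp, n_dep) in counts.items():
        if n_resp == 0:
            pct = pd.NA
        else:
            raw = 100.0 * n_dep / n_resp
            pct = int(np.floor(raw))
            unfloored.append(raw)
        rows.append((name, n_resp, n_dep, pct))
    table = pd.DataFrame(
        rows, columns=["dataset", "n_stress_responsive", "n_g9a_dependent",
                       "pct_g9a_dependent"],
    ).set_index("dataset")
    table["pct_g9a_dependent"] = table["pct_g9a_dependent"].astype("Int64")
    mean_pct = float(np.mean(unfloored)) if unfloored else float("nan")
    return ClassificationSummary(table=table, mean_pct=mean_pct)


def summarize(
    classifications: Sequence[GeneClassification] | Mapping[str, GeneClassification],
) -> ClassificationSummary:
    """Table-style summary over per-dataset classifications."""
    if isinstance(classifications, Mapping):
        items = list(classifications.items())
    else:
        items = [(c.dataset, c) for c in classifications]
    counts = {
        name: (int(c.table["stress_responsive"].sum()), int(c.table["g9a_dependent"].sum()))
        for name, c in items
    }
    return summary_from_counts(counts)
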
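"""Classification cascade: responsive calls, dependence intersection,
direction labels, and the summary table."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_de_result
from stressmeta.classify import (ClassificationConfig, assign_direction,
                                 call_g9a_dependent, call_stress_responsive,
                                 classify_dataset, summarize, summary_from_counts)
from stressmeta.exceptions import ConfigurationError, StressmetaError
from stressmeta.pipeline import PipelineConfig, _run_de_for_dataset, split_de_results
from stressmeta.simulate import generate_dataset

CFG = ClassificationConfig()


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ClassificationConfig(fc_threshold=1.0)
    with pytest.raises(ConfigurationError):
        ClassificationConfig(alpha=0.0)
    with pytest.raises(ConfigurationError):
        ClassificationConfig(q_threshold=1.5)


def _stress_pair(lfc_control, lfc_depleted, p=None, p_dep=None):
    return {
        ("control", 6.0): make_de_result(lfc_control, p=p),
        ("depleted", 6.0): make_de_result(lfc_depleted, p=p_dep),
    }


def test_fc_threshold_is_strict():
    lfc = [np.log2(1.19), np.log2(1.2), np.log2(1.21)]
    res = call_stress_responsive(_stress_pair(lfc, lfc), CFG)
    assert list(res["stress_responsive"]) == [False, False, True]


def test_depleted_only_significance_counts():
    # gene 0 passes only in the depleted genotype
    res = call_stress_responsive(
        _stress_pair([0.0, 0.0], [1.0, 0.0]), CFG)
    assert res.loc["g0", "stress_responsive"]
    assert res.loc["g0", "responsive_in"] == "depleted@t6"
    assert not res.loc["g1", "stress_responsive"]


def test_both_genotypes_required():
    with pytest.raises(StressmetaError, match="genotype"):
        call_stress_responsive({("control", 6.0): make_de_result([1.0])}, CFG)


def test_noreplicate_mode_uses_q_threshold():
    de = make_de_result([1.0, 1.0], p=[0.95, 0.85], mode="noreplicate_test")
    de.table["p_adj"] = np.nan
    res = call_stress_responsive(
        {("control", 6.0): de, ("depleted", 6.0): de}, CFG)
    assert list(res["stress_responsive"]) == [True, False]


def test_dependence_needs_responsiveness():
    responsive = pd.Series([False, True], index=["g0", "g1"])
    geno = {6.0: make_de_result([2.0, 2.0], meta={"condition": "stressed"})}
    dep = call_g9a_dependent(responsive, geno, CFG)
    assert list(dep) == [False, True]


def test_baseline_genotype_contrast_rejected():
    responsive = pd.Series([True], index=["g0"])
    geno = {0.0: make_de_result([2.0], meta={"condition": "baseline"})}
    with pytest.raises(StressmetaError, match="baseline"):
        call_g9a_dependent(responsive, geno, CFG)


@pytest.mark.parametrize(
    "lc,ld,expected",
    [
        (1.0, 1.8, "overinduced"),
        (-1.0, -1.8, "overrepressed"),
        (1.0, -1.0, "discordant"),
        (1.0, 0.5, "discordant"),   # depleted response smaller in magnitude
        (-1.0, -0.5, "discordant"),
    ],
)
def test_direction_rules(lc, ld, expected):
    flags = pd.Series([True], index=["g0"])
    res = assign_direction(flags, _stress_pair([lc], [ld]), CFG)
    assert res.loc["g0", "direction"] == expected


def test_direction_subthreshold_control_uses_depleted_sign():
    flags = pd.Series([True, True], index=["g0", "g1"])
    res = assign_direction(flags, _stress_pair([0.1, -0.1], [1.5, -1.5]), CFG)
    assert res.loc["g0", "direction"] == "overinduced"
    assert res.loc["g1", "direction"] == "overrepressed"
    assert res["control_subthreshold"].all()


def test_direction_none_for_non_dependent():
    flags = pd.Series([False], index=["g0"])
    res = assign_direction(flags, _stress_pair([1.0], [2.0]), CFG)
    assert res.loc["g0", "direction"] == "none"


def test_classifying_timepoint_picks_largest_control_response():
    stress = {
        ("control", 6.0): make_de_result([0.5]),
        ("control", 12.0): make_de_result([-1.0]),
        ("depleted", 6.0): make_de_result([2.0]),
        ("depleted", 12.0): make_de_result([-1.8]),
    }
    flags = pd.Series([True], index=["g0"])
    res = assign_direction(flags, stress, CFG)
    # t=12 dominates (|-1.0| > |0.5|): repressed and deeper in depleted
    assert res.loc["g0", "direction"] == "overrepressed"


def test_partition_and_monotonicity_on_synthetic_data(single_counts_config):
    sim = single_counts_config(seed=13)
    cfg = PipelineConfig(sim=sim, min_datasets=1)
    ds, truth = generate_dataset(sim, 0)
    stress, geno = split_de_results(_run_de_for_dataset(cfg, ds, 0))
    cls = classify_dataset("d0", stress, geno, CFG)
    t = cls.table
    dep = t["g9a_dependent"]
    # labels partition the dependent genes exactly
    assert (t.loc[dep, "direction"].isin(["overinduced", "overrepressed", "discordant"])).all()
    assert (t.loc[~dep, "direction"] == "none").all()
    # dependence implies responsiveness
    assert (t.loc[dep, "stress_responsive"]).all()
    # raising the FC threshold never increases the responsive count
    stricter = classify_dataset("d0", stress, geno,
                                ClassificationConfig(fc_threshold=1.5))
    assert stricter.table["stress_responsive"].sum() <= t["stress_responsive"].sum()


def test_recovered_direction_matches_truth(single_counts_config):
    sim = single_counts_config(seed=17)
    cfg = PipelineConfig(sim=sim, min_datasets=1)
    ds, truth = generate_dataset(sim, 0)
    stress, geno = split_de_results(_run_de_for_dataset(cfg, ds, 0))
    cls = classify_dataset("d0", stress, geno, CFG)
    rec = cls.table["g9a_dependent"] & (truth["true_class"] == "g9a_dependent")
    labels = cls.table.loc[rec, "direction"].map(
        {"overinduced": "induced", "overrepressed": "repressed"})
    agree = (labels == truth.loc[rec, "true_direction"]).mean()
    assert agree >= 0.95


def test_summary_reproduces_published_style_percentages():
    counts = {
        "oxidative": (5737, 2243),
        "virus": (2560, 1290),
        "interferon": (7311, 2130),
        "hypoxia_es": (4165, 1365),
        "hypoxia_mcf7": (3757, 1994),
    }
    summary = summary_from_counts(counts)
    assert list(summary.table["pct_g9a_dependent"]) == [39, 50, 29, 32, 53]
    assert summary.mean_pct > 40.0


def test_summary_undefined_for_zero_responsive():
    summary = summary_from_counts({"empty": (0, 0), "ok": (10, 5)})
    assert summary.table.loc["empty", "pct_g9a_dependent"] is pd.NA
    assert summary.table.loc["ok", "pct_g9a_dependent"] == 50
    assert summary.mean_pct == pytest.approx(50.0)


def test_summarize_accepts_classifications(single_counts_config):
    sim = single_counts_config(seed=19, n_genes=300)
    cfg = PipelineConfig(sim=sim, min_datasets=1)
    ds, _ = generate_dataset(sim, 0)
    stress, geno = split_de_results(_run_de_for_dataset(cfg, ds, 0))
    cls = classify_dataset("d0", stress, geno, CFG)
    summary = summarize([cls])
    assert summary.table.loc["d0", "n_stress_responsive"] == cls.table["stress_responsive"].sum()
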
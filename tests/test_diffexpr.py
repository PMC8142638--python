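"""Differential-expression engines: normalization, moderated test,
no-replicate q statistic, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressmeta.diffexpr import Contrast, adjust_pvalues, normalize
from stressmeta.diffexpr import test_contrast as de_contrast
from stressmeta.diffexpr import test_contrast_noreplicate as de_contrast_noreplicate
from stressmeta.exceptions import ContrastError
from stressmeta.simulate import ExpressionDataset, generate_dataset


def _dataset(matrix, platform="counts", genotype=None, condition=None, timepoint=None):
    matrix = np.asarray(matrix)
    n_samp = matrix.shape[1]
    samples = pd.DataFrame(
        {
            "genotype": genotype or ["control"] * n_samp,
            "condition": condition or ["baseline"] * n_samp,
            "timepoint": timepoint or [0.0] * n_samp,
            "replicate": list(range(1, n_samp + 1)),
        },
        index=pd.Index([f"s{i}" for i in range(n_samp)], name="sample_id"),
    )
    mat = pd.DataFrame(matrix, index=pd.Index([f"g{i}" for i in range(len(matrix))],
                                              name="gene_id"), columns=samples.index)
    return ExpressionDataset(name="t", matrix=mat, samples=samples,
                             platform=platform, species="dmel")


# --- normalize ------------------------------------------------------------

def test_identical_count_columns_share_size_factor():
    ds = _dataset([[10, 10], [20, 20], [5, 5]])
    normed, factors = normalize(ds)
    assert factors.iloc[0] == pytest.approx(factors.iloc[1])
    np.testing.assert_allclose(normed.iloc[:, 0], normed.iloc[:, 1])


def test_pure_depth_effect_removed():
    ds = _dataset([[10, 20], [20, 40], [5, 10]])
    normed, factors = normalize(ds)
    assert factors.iloc[1] / factors.iloc[0] == pytest.approx(2.0)
    np.testing.assert_allclose(normed.iloc[:, 0], normed.iloc[:, 1])


def test_quantile_normalization_hand_example():
    ds = _dataset([[1, 4], [2, 5], [3, 6]], platform="intensity")
    normed, factors = normalize(ds)
    assert factors is None
    np.testing.assert_allclose(normed.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])


def test_counts_fallback_to_column_totals(caplog):
    # every gene has a zero somewhere -> no geometric-mean reference
    ds = _dataset([[0, 10], [10, 0]])
    with caplog.at_level("WARNING"):
        _, factors = normalize(ds)
    assert "column-total" in caplog.text
    assert factors.notna().all()


# --- adjust_pvalues -------------------------------------------------------

def _bh_bruteforce(p):
    """Step-up definition evaluated literally: p_adj(i) = min over j with
    p_(j) >= p_i of p_(j) * m / rank(j), clipped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    for i in range(m):
        candidates = []
        for rank, j in enumerate(order, start=1):
            if p[j] >= p[i] - 1e-15:
                candidates.append(p[j] * m / rank)
        out[i] = min(1.0, min(candidates))
    return out


def test_bh_hand_examples():
    assert adjust_pvalues([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.2])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_matches_stepup_definition_and_dominates_p(p):
    adj = adjust_pvalues(p)
    np.testing.assert_allclose(adj, _bh_bruteforce(p), atol=1e-12)
    assert (adj >= np.asarray(p) - 1e-15).all()


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    np.testing.assert_allclose(adjust_pvalues(p),
                               multipletests(p, method="fdr_bh")[1], atol=1e-12)


# --- test_contrast --------------------------------------------------------

CONTRAST = Contrast("stress", {"condition": "baseline"}, {"condition": "stressed"})


def _two_group_dataset(matrix, platform="counts"):
    n = len(matrix[0]) // 2
    return _dataset(matrix, platform=platform,
                    condition=["baseline"] * n + ["stressed"] * n,
                    timepoint=[0.0] * n + [6.0] * n)


def test_flat_gene_has_zero_fc_unit_p():
    # equal-depth columns so library normalization is neutral
    ds = _two_group_dataset([[10, 10, 10, 10], [20, 20, 20, 20], [5, 5, 5, 5]])
    res = de_contrast(ds, CONTRAST)
    assert res.table.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-9)
    assert res.table.loc["g0", "p"] == pytest.approx(1.0)


def test_statistics_invariant_to_sample_order():
    rng = np.random.default_rng(1)
    mat = rng.poisson(50, size=(30, 8))
    ds = _two_group_dataset(mat)
    res = de_contrast(ds, CONTRAST)
    # permute replicates within each side
    perm = [2, 0, 3, 1, 7, 5, 4, 6]
    ds2 = _two_group_dataset(mat[:, perm])
    res2 = de_contrast(ds2, CONTRAST)
    pd.testing.assert_frame_equal(res.table, res2.table)


def test_swapping_sides_negates_log2fc_keeps_p():
    rng = np.random.default_rng(2)
    ds = _two_group_dataset(rng.poisson(80, size=(40, 6)))
    fwd = de_contrast(ds, CONTRAST)
    rev = de_contrast(ds, Contrast("rev", CONTRAST.group_b, CONTRAST.group_a))
    np.testing.assert_allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12)
    np.testing.assert_allclose(fwd.table["p"], rev.table["p"], atol=1e-12)


def test_single_replicate_side_directs_to_noreplicate():
    ds = _dataset([[1, 2, 3], [4, 5, 6]], condition=["baseline", "stressed", "stressed"],
                  timepoint=[0.0, 6.0, 6.0])
    with pytest.raises(ContrastError, match="noreplicate"):
        de_contrast(ds, CONTRAST)


def test_planted_genes_detected_at_stated_conditions(single_counts_config):
    """Planted responsive genes (lfc=1, dispersion 0.05, n=5/side, seed 7).

    Detection is measured as the classification rule consumes it: a gene
    counts as detected when EITHER genotype's stress contrast passes
    (p_adj < 0.05, |FC| > 1.2).  The union exceeds 0.9; each single
    contrast is noisier (the repressed half loses counts) and is held to a
    looser 0.65 floor.  Sampling tolerance: one seeded draw of 200 planted
    genes, binomial SE about 0.02-0.03.
    """
    cfg = single_counts_config(seed=7)
    ds, truth = generate_dataset(cfg, 0)
    planted = (truth["true_class"] != "null").to_numpy()
    union = np.zeros(cfg.n_genes, dtype=bool)
    for genotype in ("control", "depleted"):
        contrast = Contrast(
            f"stress_{genotype}",
            {"condition": "baseline", "genotype": genotype},
            {"condition": "stressed", "genotype": genotype, "timepoint": 6.0})
        res = de_contrast(ds, contrast)
        hit = ((res.table["p_adj"] < 0.05)
               & (res.table["log2fc"].abs() > np.log2(1.2))).to_numpy()
        assert hit[planted].mean() > 0.65
        union |= hit
    assert union[planted].mean() > 0.9


# --- test_contrast_noreplicate -------------------------------------------

def _norep_dataset(col_a, col_b):
    return _dataset(np.column_stack([col_a, col_b]),
                    condition=["baseline", "stressed"], timepoint=[0.0, 6.0])


def test_identical_columns_give_zero_q():
    ds = _norep_dataset([10, 20, 30, 40], [10, 20, 30, 40])
    res = de_contrast_noreplicate(ds, CONTRAST, seed=1)
    assert (res.table["p"] == 0.0).all()
    assert res.mode == "noreplicate_test"
    assert res.table["p_adj"].isna().all()


def test_noreplicate_deterministic_given_seed():
    rng = np.random.default_rng(3)
    a, b = rng.poisson(100, size=20), rng.poisson(100, size=20)
    ds = _norep_dataset(a, b)
    r1 = de_contrast_noreplicate(ds, CONTRAST, seed=42)
    r2 = de_contrast_noreplicate(ds, CONTRAST, seed=42)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_big_change_gene_attains_max_q():
    a = [100] * 9 + [10]
    b = [100] * 9 + [500]  # 50x change on the last gene
    ds = _norep_dataset(a, b)
    res = de_contrast_noreplicate(ds, CONTRAST, n_sim_replicates=5, seed=5)
    assert res.table["p"].idxmax() == "g9"


def test_replicated_input_directs_to_test_contrast():
    ds = _two_group_dataset([[1, 2, 3, 4], [4, 5, 6, 7]])
    with pytest.raises(ContrastError, match="test_contrast"):
        de_contrast_noreplicate(ds, CONTRAST)


def test_noreplicate_requires_counts():
    ds = _norep_dataset([1.0, 2.0], [2.0, 3.0])
    object.__setattr__(ds, "platform", "intensity")
    with pytest.raises(ContrastError, match="counts"):
        de_contrast_noreplicate(ds, CONTRAST)


def test_null_dataset_false_positive_rate(single_counts_config):
    """Fully null design: fraction of p_adj < 0.05 calls stays near zero."""
    frac = []
    for seed in range(30):
        cfg = single_counts_config(seed=seed, frac_stress_responsive=0.0, n_genes=400)
        ds, _ = generate_dataset(cfg, 0)
        res = de_contrast(ds, Contrast(
            "s", {"condition": "baseline", "genotype": "control"},
            {"condition": "stressed", "genotype": "control"}))
        frac.append((res.table["p_adj"] < 0.05).mean())
    assert np.mean(frac) <= 0.07
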
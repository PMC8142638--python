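"""Per-dataset differential expression for three data regimes.

* ``count_test`` — replicated sequencing counts: median-of-ratios library
  normalization, then a per-gene two-sample t-test on log2(normalized + 0.5)
  with the per-gene variance moderated toward the mean-variance trend.
* ``intensity_test`` — replicated array log-intensities: quantile
  normalization, then the same moderated test on the values directly.
* ``noreplicate_test`` — one sample per condition, counts only: simulated
  technical replicates by multinomial resampling build an empirical
  (|M|, D) noise cloud; a gene's q is the fraction of noise pairs its
  signal pair dominates.  q is stored in the ``p`` column (no BH applied).

Multiple testing for the replicated modes uses Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContrastError, StressmetaError
from .simulate import ExpressionDataset

__all__ = [
    "Contrast",
    "DEResult",
    "normalize",
    "test_contrast",
    "test_contrast_noreplicate",
    "adjust_pvalues",
]

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5  # added to normalized count means before log2
PRIOR_DF = 4.0  # pseudo-degrees of freedom pulling variances to the trend


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups selected by design-field equality.

    ``group_a`` is the reference side; reported log2fc is B relative to A.
    """

    name: str
    group_a: Mapping[str, object]
    group_b: Mapping[str, object]

    def select(self, samples: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        def match(sel: Mapping[str, object]) -> pd.Index:
            mask = pd.Series(True, index=samples.index)
            for key, val in sel.items():
                if key not in samples.columns:
                    raise ContrastError(f"unknown design field {key!r} in contrast {self.name!r}")
                mask &= samples[key] == val
            return samples.index[mask]

        a, b = match(self.group_a), match(self.group_b)
        if len(a) == 0 or len(b) == 0:
            raise ContrastError(f"contrast {self.name!r}: a selector matched no samples")
        if len(a.intersection(b)) > 0:
            raise ContrastError(f"contrast {self.name!r}: selectors overlap")
        return a, b


@dataclass
class DEResult:
    """Per-gene statistics for one contrast.

    ``table`` is indexed by gene_id with columns log2fc, p, p_adj.  In
    ``noreplicate_test`` mode the p column holds the noise-dominance
    probability q and p_adj is NaN (q is not a p-value; no BH).
    """

    contrast: str
    mode: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["contrast"] = self.contrast
        out["mode"] = self.mode
        return out


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def normalize(dataset: ExpressionDataset) -> tuple[pd.DataFrame, pd.Series | None]:
    """Platform-appropriate normalization of the full sample matrix.

    counts: DESeq-style median-of-ratios size factors (falling back to
    column-total factors when no gene is nonzero in every sample); returns
    the matrix divided per sample and the size factors.

    intensity: quantile normalization (every sample shares the mean sorted
    distribution; ties receive the mean of their tied positions); size
    factors are None.
    """
    X = dataset.matrix.to_numpy(dtype=float)
    if dataset.platform == "counts":
        all_nonzero = (X > 0).all(axis=1)
        if all_nonzero.any():
            log_geo = np.log(X[all_nonzero]).mean(axis=1)
            ratios = np.log(X[all_nonzero]) - log_geo[:, None]
            factors = np.exp(np.median(ratios, axis=0))
        else:
            logger.warning(
                "dataset %s: no gene nonzero in all samples; "
                "using column-total size factors", dataset.name)
            totals = X.sum(axis=0)
            factors = totals / np.exp(np.mean(np.log(totals)))
        normed = X / factors[None, :]
        return (pd.DataFrame(normed, index=dataset.matrix.index, columns=dataset.matrix.columns),
                pd.Series(factors, index=dataset.matrix.columns, name="size_factor"))
    if X.shape[1] < 2:
        raise StressmetaError("quantile normalization needs >= 2 samples")
    sorted_mean = np.sort(X, axis=0).mean(axis=1)
    positions = np.arange(1, X.shape[0] + 1, dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, sorted_mean)
    return (pd.DataFrame(out, index=dataset.matrix.index, columns=dataset.matrix.columns),
            None)


def _variance_trend(mean: np.ndarray, s2: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Median pooled variance within mean-quantile bins, per gene."""
    if len(mean) < n_bins * 2:
        return np.full_like(s2, float(np.median(s2)))
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2)
    trend = np.empty_like(s2)
    global_med = float(np.median(s2))
    for b in range(len(edges) - 1):
        sel = idx == b
        trend[sel] = float(np.median(s2[sel])) if sel.any() else global_med
    return trend


def _moderated_test(vals_a: np.ndarray, vals_b: np.ndarray,
                    prior_df: float = PRIOR_DF) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample test with variances shrunk toward the mean-variance trend.

    Returns (mean_b - mean_a, two-sided p).  Degenerate genes with zero
    moderated variance get p = 1 when the group means agree and p = 0
    otherwise.
    """
    n_a, n_b = vals_a.shape[1], vals_b.shape[1]
    mean_a, mean_b = vals_a.mean(axis=1), vals_b.mean(axis=1)
    var_a = vals_a.var(axis=1, ddof=1)
    var_b = vals_b.var(axis=1, ddof=1)
    df_g = n_a + n_b - 2
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df_g
    trend = _variance_trend((mean_a * n_a + mean_b * n_b) / (n_a + n_b), s2)
    s2_mod = (df_g * s2 + prior_df * trend) / (df_g + prior_df)
    diff = mean_b - mean_a
    se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df_g + prior_df)
    p = np.where(diff == 0.0, 1.0, p)
    p = np.where((se == 0.0) & (diff != 0.0), 0.0, p)
    return diff, p


def test_contrast(dataset: ExpressionDataset, contrast: Contrast,
                  prior_df: float = PRIOR_DF) -> DEResult:
    """Moderated two-sample DE test for replicated data (either platform)."""
    idx_a, idx_b = contrast.select(dataset.samples)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ContrastError(
            f"contrast {contrast.name!r}: needs >= 2 replicates per side "
            f"(got {len(idx_a)} vs {len(idx_b)}); use test_contrast_noreplicate")
    normed, _ = normalize(dataset)
    A = normed[idx_a].to_numpy(float)
    B = normed[idx_b].to_numpy(float)
    if dataset.platform == "counts":
        log_a, log_b = np.log2(A + PSEUDOCOUNT), np.log2(B + PSEUDOCOUNT)
        _, p = _moderated_test(log_a, log_b, prior_df)
        log2fc = np.log2(B.mean(axis=1) + PSEUDOCOUNT) - np.log2(A.mean(axis=1) + PSEUDOCOUNT)
        mode = "count_test"
    else:
        log2fc, p = _moderated_test(A, B, prior_df)
        mode = "intensity_test"
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": adjust_pvalues(p)},
        index=dataset.matrix.index,
    )
    meta = {"orientation": "B_vs_A", "group_a": dict(contrast.group_a),
            "group_b": dict(contrast.group_b)}
    shared = {k: v for k, v in contrast.group_a.items()
              if contrast.group_b.get(k) == v}
    meta.update(shared)
    return DEResult(contrast=contrast.name, mode=mode, table=table, meta=meta)


def test_contrast_noreplicate(dataset: ExpressionDataset, contrast: Contrast,
                              n_sim_replicates: int = 5, sim_fraction: float = 0.2,
                              sim_variability: float = 0.02, seed: int = 0) -> DEResult:
    """Simulated-technical-replicate noise test for single-sample contrasts.

    Per sample, ``n_sim_replicates`` technical replicates are drawn by
    multinomial resampling of ``sim_fraction`` of the library with per-gene
    probability jitter ``sim_variability``.  Signal per gene is
    (M, D) = (log2 ratio, |difference|) between the two condition columns
    on the counts-per-million scale; noise is the pooled within-sample
    replicate-pair cloud over all genes.  q = fraction of noise pairs
    strictly dominated by the signal pair (both |M| and D larger).
    """
    if dataset.platform != "counts":
        raise ContrastError("no-replicate mode is defined for counts platforms only")
    idx_a, idx_b = contrast.select(dataset.samples)
    if len(idx_a) != 1 or len(idx_b) != 1:
        raise ContrastError(
            f"contrast {contrast.name!r}: no-replicate mode needs exactly one sample "
            f"per side (got {len(idx_a)} vs {len(idx_b)}); use test_contrast")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    k = PSEUDOCOUNT
    x_a = dataset.matrix[idx_a[0]].to_numpy(float)
    x_b = dataset.matrix[idx_b[0]].to_numpy(float)

    def cpm(x: np.ndarray) -> np.ndarray:
        total = x.sum()
        return x / total * 1e6 if total > 0 else x

    ca, cb = cpm(x_a), cpm(x_b)
    signal_m = np.log2((cb + k) / (ca + k))
    signal_d = np.abs(cb - ca)

    noise_m, noise_d = [], []
    for x in (x_a, x_b):
        total = x.sum()
        if total == 0:
            continue
        probs = x / total
        size = max(1, int(round(total * sim_fraction)))
        reps = []
        for _ in range(n_sim_replicates):
            jitter = 1.0 + sim_variability * rng.uniform(-1.0, 1.0, size=probs.shape)
            pj = probs * jitter
            pj = pj / pj.sum()
            reps.append(cpm(rng.multinomial(size, pj).astype(float)))
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                noise_m.append(np.log2((reps[j] + k) / (reps[i] + k)))
                noise_d.append(np.abs(reps[j] - reps[i]))
    if noise_m:
        nm = np.abs(np.concatenate(noise_m))
        nd = np.concatenate(noise_d)
    else:
        nm = np.zeros(1)
        nd = np.zeros(1)

    q = np.empty_like(signal_m)
    sm = np.abs(signal_m)
    chunk = max(1, int(2e7) // max(nm.size, 1))
    for start in range(0, sm.size, chunk):
        sl = slice(start, start + chunk)
        dom = (sm[sl, None] > nm[None, :]) & (signal_d[sl, None] > nd[None, :])
        q[sl] = dom.mean(axis=1)

    table = pd.DataFrame(
        {"log2fc": signal_m, "p": q, "p_adj": np.nan},
        index=dataset.matrix.index,
    )
    meta = {"orientation": "B_vs_A", "statistic": "q",
            "group_a": dict(contrast.group_a), "group_b": dict(contrast.group_b),
            "n_sim_replicates": n_sim_replicates, "sim_fraction": sim_fraction,
            "sim_variability": sim_variability, "seed": int(seed)}
    shared = {kk: v for kk, v in contrast.group_a.items()
              if contrast.group_b.get(kk) == v}
    meta.update(shared)
    return DEResult(contrast=contrast.name, mode="noreplicate_test", table=table, meta=meta)
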
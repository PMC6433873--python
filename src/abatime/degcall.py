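"""Per-timepoint differential expression via a Bayesian-regularized t-test.

The test follows the Cyber-T scheme: each replicate group's sample
variance is shrunk toward a local "background" variance — the mean sample
variance of the genes nearest in mean expression (a sliding window of
``window_size`` genes) — with prior weight ``nu0`` pseudo-observations:

    s̃² = (ν₀·σ²_bg + (n−1)·s²) / (ν₀ + n − 2)      for ν₀ > 0

    t  = (m_t − m_c) / sqrt(s̃²_t/n_t + s̃²_c/n_c),  df = n_t + n_c − 2 + 2ν₀

With ν₀ = 0 the prior-free limit returns the ordinary per-group sample
variances, so the statistic reduces to the standard two-sample t-test
(identical to the pooled test for balanced groups).  Multiplicity is
handled by Benjamini–Hochberg FDR per timepoint; calls at q ≤ cutoff are
signed by the mean difference and the per-timepoint call pattern maps to a
temporal class (early/mid/late, sustained/transient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, PipelineConfig, PrintedGeneTable

TEMPORAL_CLASSES = (
    "early_sustained",
    "early_transient",
    "mid_transient",
    "mid_sustained",
    "late_up",
    "late_down",
    "mixed",
    "none",
)

_CLASS_MAP: dict[tuple[str, str, str], str] = {
    ("up", "up", "up"): "early_sustained",
    ("up", "up", "none"): "early_transient",
    ("none", "up", "none"): "mid_transient",
    ("none", "up", "up"): "mid_sustained",
    ("none", "none", "up"): "late_up",
    ("none", "none", "down"): "late_down",
    ("none", "none", "none"): "none",
}


@dataclass
class RegularizationParams:
    """Sliding-window size and prior weight of the regularized t-test."""

    window_size: int = 101
    prior_df: float = 10.0

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd positive integer")
        if self.prior_df < 0:
            raise ValueError("prior_df must be non-negative")


def signed_fold_change(mean_log2_treated: float, mean_log2_control: float):
    """Signed linear fold change with negative-reciprocal convention.

    2^(Δlog2) if ≥ 1, else −1/ratio, so |fc| ≥ 1 always and down-regulation
    is encoded by a negative value (e.g. −5.06 means 5.06-fold down).
    Accepts scalars or arrays.
    """
    r = np.power(2.0, np.asarray(mean_log2_treated) - np.asarray(mean_log2_control))
    out = np.where(r >= 1.0, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def background_variance(matrix: ExpressionMatrix, condition: str,
                        timepoint_min: int,
                        params: RegularizationParams) -> pd.Series:
    """Local background variance per gene for one replicate group.

    Genes are ordered by the group mean; each gene's background variance is
    the mean of the sample variances of the ``window_size`` nearest genes
    in that ordering.  Near the edges the window slides within bounds (the
    first/last full window), so it always covers exactly ``window_size``
    genes; with ``window_size`` equal to the gene count every gene gets the
    global mean sample variance.
    """
    group = matrix.group_values(condition, timepoint_min)
    if group.shape[1] < 2:
        raise ValueError("background variance needs ≥ 2 replicates")
    if matrix.n_genes < params.window_size:
        raise ValueError(
            f"window_size {params.window_size} exceeds gene count {matrix.n_genes}"
        )
    means = group.mean(axis=1).to_numpy()
    variances = group.var(axis=1, ddof=1).to_numpy()
    # deterministic ordering: by mean, ties by gene id
    order = np.lexsort((matrix.gene_ids.to_numpy(), means))
    v_sorted = variances[order]
    n = len(v_sorted)
    half = (params.window_size - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(v_sorted)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n - params.window_size)
    hi = lo + params.window_size
    bg_sorted = (csum[hi] - csum[lo]) / params.window_size
    bg = np.empty(n)
    bg[order] = bg_sorted
    return pd.Series(bg, index=matrix.gene_ids, name="background_variance")


def regularized_t_test(matrix: ExpressionMatrix, timepoint_min: int,
                       params: RegularizationParams) -> pd.DataFrame:
    """Treated-vs-control regularized t-test at one timepoint.

    Returns a DataFrame indexed by gene with columns ``t``, ``df``, ``p``,
    ``mean_diff`` and ``degenerate`` (both regularized variances zero →
    p = 1 rather than an exception).
    """
    treated = matrix.group_values("treated", timepoint_min)
    control = matrix.group_values("control", timepoint_min)
    n_t, n_c = treated.shape[1], control.shape[1]
    if n_t < 2 or n_c < 2:
        raise ValueError("need ≥ 2 replicates per condition")
    nu0 = params.prior_df

    def _reg_var(group: pd.DataFrame, condition: str) -> np.ndarray:
        n = group.shape[1]
        s2 = group.var(axis=1, ddof=1).to_numpy()
        if nu0 == 0:
            return s2  # prior-free limit: ordinary sample variance
        bg = background_variance(matrix, condition, timepoint_min, params).to_numpy()
        return (nu0 * bg + (n - 1) * s2) / (nu0 + n - 2)

    var_t = _reg_var(treated, "treated")
    var_c = _reg_var(control, "control")
    diff = treated.mean(axis=1).to_numpy() - control.mean(axis=1).to_numpy()
    denom2 = var_t / n_t + var_c / n_c
    degenerate = denom2 <= 0
    df = n_t + n_c - 2 + 2 * nu0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0, denom2)))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame(
        {"t": t, "df": float(df), "p": p, "mean_diff": diff, "degenerate": degenerate},
        index=matrix.gene_ids,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_temporal(directions) -> str:
    """Map per-timepoint call directions (30, 60, 180 min) to a class.

    Combinations outside the enumerated patterns (e.g. up–none–up) fall
    into ``mixed`` so the classifier is total over all 3³ patterns.
    """
    key = tuple(directions)
    if len(key) != 3:
        raise ValueError("expected directions for exactly 3 timepoints")
    for d in key:
        if d not in ("up", "down", "none"):
            raise ValueError(f"unknown direction token {d!r}")
    return _CLASS_MAP.get(key, "mixed")


def call_degs(matrix: ExpressionMatrix, config: PipelineConfig | None = None,
              params: RegularizationParams | None = None) -> pd.DataFrame:
    """Call DEGs per timepoint and classify their temporal pattern.

    Returns one row per gene with, for each timepoint tp:
    ``fc_<tp>`` (signed fold change, computed for all genes regardless of
    call), ``p_<tp>``, ``q_<tp>``, ``dir_<tp>`` ∈ {up, down, none}; plus
    ``temporal_class``.  A gene is called at tp iff q ≤ the pairwise
    cutoff (ties at the threshold count as called); direction is the sign
    of the mean difference.
    """
    config = config or PipelineConfig()
    params = params or RegularizationParams()
    tps = matrix.timepoints("treated")
    out: dict[str, np.ndarray] = {}
    dirs: list[np.ndarray] = []
    for tp in tps:
        res = regularized_t_test(matrix, tp, params)
        q = bh_fdr(res["p"].to_numpy())
        mt = matrix.group_values("treated", tp).mean(axis=1).to_numpy()
        mc = matrix.group_values("control", tp).mean(axis=1).to_numpy()
        fc = signed_fold_change(mt, mc)
        called = q <= config.q_cutoff_pairwise
        direction = np.where(
            called, np.where(res["mean_diff"].to_numpy() >= 0, "up", "down"), "none"
        )
        out[f"fc_{tp}"] = fc
        out[f"p_{tp}"] = res["p"].to_numpy()
        out[f"q_{tp}"] = q
        out[f"dir_{tp}"] = direction
        dirs.append(direction)
    frame = pd.DataFrame(out, index=matrix.gene_ids)
    if len(tps) == 3:
        frame["temporal_class"] = [
            classify_temporal(d) for d in zip(*(d.tolist() for d in dirs))
        ]
    else:
        warnings.warn(
            "temporal classification requires exactly 3 timepoints; skipped"
        )
        frame["temporal_class"] = "none"
    return frame


def classify_printed_table(table: PrintedGeneTable) -> pd.Series:
    """Temporal class per row of a reference fold-change table.

    Present positive fold change → up; present negative → down; absent
    ("–") → none; then the standard temporal classification applies.
    """

    def _row_class(row) -> str:
        dirs = []
        for col in PrintedGeneTable.FC_COLUMNS:
            v = row[col]
            if pd.isna(v):
                dirs.append("none")
            elif v > 0:
                dirs.append("up")
            else:
                dirs.append("down")
        return classify_temporal(dirs)

    return table.frame.apply(_row_class, axis=1)
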
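"""Nested polynomial ANOVA over the full time course.

Each gene's expression is modelled as a polynomial in time (minutes).
The reduced model fits one shared curve to both conditions pooled
(d+1 parameters); the full model fits an independent curve per condition
(2(d+1) parameters).  A standard nested-model F-test

    F = ((RSS_red − RSS_full)/(df_red − df_full)) / (RSS_full/df_full)

flags genes whose trajectory differs between treatment and control.  With
T distinct timepoints only degree T−1 is identifiable, so the requested
degree (3 by default) is capped at T−1; a design with a time-0 anchor
raises T to 4 and enables the full cubic.

FDR over the per-gene p-values uses either the Storey π₀-scaled q-value
(default, smoother estimator of the null proportion) or plain
Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, PipelineConfig
from .degcall import bh_fdr

logger = logging.getLogger(__name__)

#: numerical tolerance below which a residual sum of squares counts as exact
RSS_TOL = 1e-12


@dataclass
class TimecourseFit:
    """Nested-model comparison result for one gene."""

    gene_id: str
    rss_reduced: float
    rss_full: float
    df_reduced: int
    df_full: int
    f_stat: float
    p_value: float
    q_value: float | None = None
    called: bool | None = None
    exact_fit: bool = False


def _orthonormal_basis(times: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial design in (scaled, centered) time.

    The reported F statistic depends only on the column space, so any
    well-conditioned basis spanning polynomials up to ``degree`` works;
    QR of a scaled Vandermonde keeps the fit stable on the raw minutes
    scale.
    """
    t = times.astype(float)
    t = t - t.mean()
    scale = np.max(np.abs(t))
    if scale > 0:
        t = t / scale
    X = np.vander(t, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(X)
    return Q


def _rss_matrix(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y after projection on Q."""
    proj = Q.T @ Y
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)


def fit_nested_polynomials(matrix: ExpressionMatrix,
                           degree: int = 3) -> pd.DataFrame:
    """Fit reduced (shared) and full (per-condition) polynomial models.

    Returns a DataFrame indexed by gene with columns ``rss_reduced``,
    ``rss_full``, ``df_reduced``, ``df_full``, ``f_stat``, ``p_value`` and
    ``exact_fit`` (RSS_full ≈ 0 → p = 0, flagged rather than raised).
    """
    sheet = matrix.sample_frame
    times = sheet["timepoint_min"].to_numpy(dtype=float)
    conditions = sheet["condition"].to_numpy()
    if len(set(conditions)) < 2:
        raise ValueError("nested comparison requires both conditions")
    T = len(np.unique(times))
    if T < 2:
        raise ValueError("need ≥ 2 distinct timepoints")
    d = min(degree, T - 1)
    if d < degree:
        logger.info("degree capped at %d (only %d distinct timepoints)", d, T)

    N = len(times)
    p_red = d + 1
    p_full = 2 * (d + 1)
    df_red = N - p_red
    df_full = N - p_full
    if df_full <= 0:
        raise ValueError(
            f"too few samples ({N}) for the full model ({p_full} parameters)"
        )

    Y = matrix.values.to_numpy().T  # samples × genes
    Q_red = _orthonormal_basis(times, d)
    rss_red = _rss_matrix(Y, Q_red)

    rss_full = np.zeros(matrix.n_genes)
    for cond in np.unique(conditions):
        mask = conditions == cond
        Qc = _orthonormal_basis(times[mask], d)
        rss_full += _rss_matrix(Y[mask], Qc)

    # clamp tiny negative round-off
    rss_red = np.maximum(rss_red, 0.0)
    rss_full = np.maximum(rss_full, 0.0)

    exact = rss_full <= RSS_TOL
    num = (rss_red - rss_full) / (df_red - df_full)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(exact, np.inf, num / np.where(exact, 1.0, rss_full / df_full))
    f = np.maximum(f, 0.0)  # round-off can push rss_red marginally below rss_full
    p = np.where(exact, 0.0, stats.f.sf(f, df_red - df_full, df_full))
    return pd.DataFrame(
        {
            "rss_reduced": rss_red,
            "rss_full": rss_full,
            "df_reduced": df_red,
            "df_full": df_full,
            "f_stat": f,
            "p_value": p,
            "exact_fit": exact,
        },
        index=matrix.gene_ids,
    )


def storey_pi0(p_values: np.ndarray,
               lambda_grid: np.ndarray | None = None) -> float:
    """Estimate the null proportion π₀ by the smoother method.

    π₀(λ) = #{p > λ}/(m(1−λ)) is computed over the λ grid, a cubic
    polynomial smoother is fitted, and π̂₀ is its value at the largest λ,
    clipped into (0, 1].  A degenerate estimate (≤ 0) falls back to 1 with
    a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if lambda_grid is None:
        lambda_grid = np.linspace(0.05, 0.95, 19)
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any((lam < 0) | (lam > 0.95 + 1e-12)):
        raise ValueError("lambda grid must lie within [0, 0.95]")
    m = len(p)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if len(lam) >= 4:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    if pi0 <= 0:
        logger.warning("degenerate pi0 estimate %.4f; falling back to 1", pi0)
        return 1.0
    return min(pi0, 1.0)


def storey_qvalue(p_values, lambda_grid: np.ndarray | None = None,
                  pi0: float | None = None) -> np.ndarray:
    """Storey q-values: π̂₀-scaled step-up, in input order.

    With ``pi0`` forced to 1 the result equals Benjamini–Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p, lambda_grid)
    return np.minimum(pi0 * bh_fdr(p), 1.0)


def call_timecourse(matrix: ExpressionMatrix,
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-gene nested polynomial ANOVA with FDR; called at q < cutoff.

    The time-course threshold is strict (<), unlike the pairwise ≤.
    """
    config = config or PipelineConfig()
    fits = fit_nested_polynomials(matrix, degree=config.poly_degree_max)
    p = fits["p_value"].to_numpy()
    if config.fdr_method_timecourse == "storey":
        q = storey_qvalue(p)
    else:
        q = bh_fdr(p)
    fits = fits.copy()
    fits["q_value"] = q
    fits["called"] = q < config.q_cutoff_timecourse
    return fits
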
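"""Global subset dynamics: how much of the transcriptome-wide response a
ranked gene subset carries.

The idea: a stimulus changes the transcriptome in concert — hundreds of
genes move together.  Genes are ranked by the variance of their treated
per-timepoint mean profile (strongest temporal response first).  Sliding
windows of 50–500 genes along this ranking are compared to the whole
transcriptome through an *association profile*: for every ordered pair of
(condition, timepoint) group-mean expression vectors, the Pearson
correlation (PC) and the mutual information (MI, plug-in estimate on
equal-frequency bins) across genes.  The Euclidean distance between a
window's profile and the all-gene profile (MI terms rescaled by log(bins)
so both measures live on a comparable [0, 1]-like scale) quantifies how
similarly the subset behaves to the transcriptome as a whole; a
polynomial trend over rank is the summary curve.  Genes with the largest
temporal response, plus genes in windows whose distance is smallest, are
selected as carrying the concerted response.

Sample-level structure is summarized separately by PCA on the gene-centered
samples × genes matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import ExpressionMatrix, PipelineConfig

#: default window sizes of the subset grid; stride is size // 2
DEFAULT_SIZES = (50, 100, 200, 300, 400, 500)


@dataclass
class AssociationProfile:
    """PC and MI per ordered pair of (condition, timepoint) group means."""

    pair_labels: list[tuple[str, str]]
    pc_values: np.ndarray
    mi_values: np.ndarray
    bins: int

    def __post_init__(self) -> None:
        if len(self.pc_values) != len(self.mi_values) != len(self.pair_labels):
            raise ValueError("pc/mi/pair vectors must have identical length")


@dataclass
class PcaResult:
    """Sample scores on leading components and variance explained."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def temporal_response_rank(matrix: ExpressionMatrix,
                           contrast_control: bool = False) -> list[str]:
    """Genes sorted by variance of the treated per-timepoint mean profile.

    Strongest temporal response first; ties broken lexicographically by
    gene id for determinism.  By default control samples do not enter the
    ranking ("response after stimulation"); with ``contrast_control`` the
    profile is the treated-minus-control mean difference per timepoint,
    which also captures sustained (flat but shifted) responses.
    """
    tps = matrix.timepoints("treated")
    if len(tps) < 2:
        raise ValueError("ranking needs treated samples at ≥ 2 timepoints")
    profile = np.column_stack(
        [matrix.group_values("treated", tp).mean(axis=1).to_numpy() for tp in tps]
    )
    if contrast_control:
        profile = profile - np.column_stack(
            [matrix.group_values("control", tp).mean(axis=1).to_numpy()
             for tp in tps]
        )
    var = profile.var(axis=1, ddof=1)
    ids = matrix.gene_ids.to_numpy()
    order = np.lexsort((ids, -var))
    return ids[order].tolist()


def default_bins(subset_size: int) -> int:
    return max(4, int(np.floor(np.sqrt(subset_size))))


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Ties are resolved by stable rank, so binning is invariant under any
    strictly monotone transform of the data.
    """
    n = len(x)
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * bins) // n


def mutual_information(x, y, bins: int) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    Non-negative and symmetric.  A constant input vector is degenerate at
    any binning resolution; MI is defined as 0 there (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < bins:
        raise ValueError(f"need at least {bins} observations for {bins} bins")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: MI defined as 0")
        return 0.0
    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    joint = np.bincount(bx * bins + by, minlength=bins * bins).astype(float)
    joint = joint.reshape(bins, bins) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return max(mi, 0.0)


def association_profile(matrix: ExpressionMatrix, gene_subset,
                        bins: int | None = None) -> AssociationProfile:
    """PC/MI profile of a gene subset across all group-mean pairs.

    Pairs are every ordered pair of distinct (condition, timepoint)
    groups, in canonical group order (control before treated, timepoints
    ascending).  Both statistics are computed across the genes of the
    subset.
    """
    subset = pd.Index(gene_subset)
    if len(subset) == 0:
        raise ValueError("gene subset must be non-empty")
    missing = subset.difference(matrix.gene_ids)
    if len(missing):
        raise ValueError(f"subset genes absent from matrix: {list(missing)[:5]}")
    # canonicalize to matrix row order: PC/MI are permutation-invariant in
    # exact arithmetic, and a fixed order makes them bit-identical too
    subset = matrix.gene_ids.intersection(subset, sort=False)
    if bins is None:
        bins = default_bins(len(subset))
    if len(subset) < bins:
        raise ValueError(
            f"subset of size {len(subset)} cannot support {bins} bins"
        )
    means = matrix.group_means().loc[subset]
    keys = [f"{c}:{t}" for c, t in matrix.group_keys()]
    vectors = {k: means[k].to_numpy() for k in keys}
    labels: list[tuple[str, str]] = []
    pcs: list[float] = []
    mis: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant vectors handled as MI=0/PC=0
        for a in keys:
            for b in keys:
                if a == b:
                    continue
                va, vb = vectors[a], vectors[b]
                if np.ptp(va) == 0 or np.ptp(vb) == 0:
                    pc = 0.0
                else:
                    pc = float(np.corrcoef(va, vb)[0, 1])
                labels.append((a, b))
                pcs.append(pc)
                mis.append(mutual_information(va, vb, bins))
    return AssociationProfile(labels, np.array(pcs), np.array(mis), bins)


def profile_distance(sub: AssociationProfile, ref: AssociationProfile,
                     mi_scale: float | None = None) -> float:
    """Euclidean distance between two association profiles.

    MI terms are divided by ``mi_scale`` (default log(bins), the maximal
    attainable MI at that binning) to make them commensurate with the
    correlation terms; pass ``mi_scale=1`` for no normalization.
    """
    if sub.pair_labels != ref.pair_labels:
        raise ValueError("profiles computed over different pair sets")
    if sub.bins != ref.bins:
        raise ValueError("profiles computed at different binning resolutions")
    if mi_scale is None:
        mi_scale = np.log(sub.bins)
    d2 = np.sum((sub.pc_values - ref.pc_values) ** 2)
    d2 += np.sum(((sub.mi_values - ref.mi_values) / mi_scale) ** 2)
    return float(np.sqrt(d2))


def subset_distance_curve(matrix: ExpressionMatrix,
                          config: PipelineConfig | None = None,
                          sizes=None, trend_degree: int = 3,
                          ranked_genes: list[str] | None = None) -> pd.DataFrame:
    """Distance of sliding ranked-gene windows to the whole transcriptome.

    For each window size k in the grid (default {50, 100, 200, 300, 400,
    500} clipped to [subset_min, subset_max] and to the gene count) windows
    slide along the temporal-response ranking with stride k/2.  The
    reference all-gene profile is recomputed at each size's binning so
    subset and reference MI are commensurate.  A least-squares polynomial
    trend in start rank (``fitted_distance``) summarizes the curve.
    """
    config = config or PipelineConfig()
    n = matrix.n_genes
    if ranked_genes is None:
        ranked_genes = temporal_response_rank(matrix)
    if sizes is None:
        sizes = [s for s in DEFAULT_SIZES if config.subset_min <= s <= config.subset_max]
    sizes = [s for s in sizes if s <= n]
    if not sizes:
        raise ValueError("no window size fits the gene count")
    rows = []
    ranked = np.asarray(ranked_genes)
    for k in sizes:
        bins = config.mi_bins or default_bins(k)
        ref = association_profile(matrix, matrix.gene_ids, bins=bins)
        stride = max(k // 2, 1)
        starts = list(range(0, n - k + 1, stride))
        if starts[-1] != n - k:
            starts.append(n - k)  # always cover the tail of the ranking
        for start in starts:
            window = ranked[start:start + k]
            sub = association_profile(matrix, window, bins=bins)
            rows.append((start, k, profile_distance(sub, ref)))
    curve = pd.DataFrame(rows, columns=["start_rank", "size", "distance"])
    deg = max(min(trend_degree, len(curve) - 1), 0)
    coef = np.polyfit(curve["start_rank"], curve["distance"], deg)
    curve["fitted_distance"] = np.polyval(coef, curve["start_rank"])
    return curve


def select_contributing_genes(curve: pd.DataFrame, ranked_genes,
                              rank_quantile: float = 0.9,
                              distance_quantile: float = 0.25) -> set[str]:
    """Union of top-response genes and genes in transcriptome-like windows.

    (a) genes in the top (1 − rank_quantile) fraction of the temporal
    response ranking; (b) genes of windows whose distance lies below the
    ``distance_quantile`` quantile of the fitted trend.  Loosening either
    quantile can only grow the selection.
    """
    if not 0 < rank_quantile < 1 or not 0 <= distance_quantile < 1:
        raise ValueError("quantiles must lie in (0, 1)")
    ranked = np.asarray(ranked_genes)
    n_top = int(np.floor((1.0 - rank_quantile) * len(ranked)))
    selected: set[str] = set(ranked[:n_top].tolist())
    if len(curve):
        threshold = float(np.quantile(curve["fitted_distance"], distance_quantile))
        good = curve[curve["distance"] < threshold]
        for start, size in zip(good["start_rank"], good["size"]):
            selected.update(ranked[int(start):int(start) + int(size)].tolist())
    return selected


def sample_pca(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples after per-gene centering.

    Scores are indexed by sample id with columns PC1, PC2, …; the
    explained-variance fractions are non-increasing.
    """
    if len(matrix.samples) < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = matrix.values.to_numpy().T  # samples × genes
    k = n_components or min(X.shape[0] - 1, 10)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        scores,
        index=pd.Index([s.sample_id for s in matrix.samples], name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PcaResult(frame, pca.explained_variance_ratio_)
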
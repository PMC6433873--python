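"""Set comparison across timepoints and studies, ortholog collapse,
condition-specific expression filtering and summary-statistics tests.

These are the bookkeeping operations behind Venn/UpSet figures and
cross-species comparisons: exact exclusive-region partitions of labelled
gene sets, deduplication of a gene set through a many-to-one best-hit
ortholog map (paralogs collapse onto one target gene), a strict
specificity filter (a gene qualifies when its minimum across the target
replicates exceeds its maximum everywhere else), and two-sample t-tests
from printed summary statistics (mean ± SD, n) for morphometry claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one measurement group (e.g. wall thickness)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be ≥ 2 for variance-based tests")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def venn_partition(labeled_sets: dict[str, set]) -> dict[frozenset, list]:
    """Exact exclusive-region partition of 2–8 labelled sets.

    Maps each non-empty label combination to the sorted members belonging
    to exactly that combination (standard UpSet semantics).  Regions are
    disjoint and their union is the union of the input sets.
    """
    if not 2 <= len(labeled_sets) <= 8:
        raise ValueError("venn_partition takes between 2 and 8 sets")
    if len(set(labeled_sets)) != len(labeled_sets):  # dict keys are unique;
        raise ValueError("duplicate set labels")      # guard kept for clarity
    universe = set().union(*labeled_sets.values())
    regions: dict[frozenset, list] = {}
    for element in universe:
        membership = frozenset(
            label for label, s in labeled_sets.items() if element in s
        )
        regions.setdefault(membership, []).append(element)
    return {k: sorted(v, key=str) for k, v in regions.items()}


def region_counts(partition: dict[frozenset, list]) -> dict[frozenset, int]:
    return {k: len(v) for k, v in partition.items()}


def collapse_orthologs(genes: set, ortholog_map: dict[str, str]):
    """Map a gene set through a many-to-one best-hit ortholog table.

    Returns ``(mapped, unmapped, paralog_groups)``: the deduplicated image
    of the input, the inputs with no map entry, and the preimages of size
    ≥ 2 (paralogs hitting the same target), keyed by target id.
    """
    mapped: set = set()
    unmapped: set = set()
    preimages: dict[str, set] = {}
    for g in genes:
        if g in ortholog_map:
            target = ortholog_map[g]
            mapped.add(target)
            preimages.setdefault(target, set()).add(g)
        else:
            unmapped.add(g)
    paralog_groups = {t: s for t, s in preimages.items() if len(s) >= 2}
    return mapped, unmapped, paralog_groups


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV ``source_id<TAB>target_id``; one best hit per source."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["source", "target"], dtype=str)
    if frame["source"].duplicated().any():
        dupes = frame.loc[frame["source"].duplicated(), "source"].tolist()
        raise ValueError(f"source gene(s) with multiple hits: {dupes[:5]}")
    return dict(zip(frame["source"], frame["target"]))


def cross_study_overlap(our_set: set, study_sets: dict[str, set]) -> dict:
    """Overlap bookkeeping of one focal set against external study sets.

    Returns pairwise intersections with the focal set, per-study unique
    counts, the union count, and "regulated in at least k studies" counts
    aggregated over exclusive regions of the external sets.
    """
    all_sets = {"ours": our_set, **study_sets}
    partition = venn_partition(all_sets) if len(all_sets) <= 8 else None
    pairwise = {name: len(our_set & s) for name, s in study_sets.items()}
    unique = {
        name: len(s - our_set - set().union(
            *(t for other, t in study_sets.items() if other != name)
        ))
        for name, s in study_sets.items()
    }
    union_count = len(set().union(our_set, *study_sets.values()))
    # at-least-k over the external studies only
    study_partition = venn_partition(study_sets) if len(study_sets) >= 2 else None
    at_least = {}
    if study_partition is not None:
        max_k = len(study_sets)
        for k in range(1, max_k + 1):
            at_least[k] = sum(
                len(members)
                for labels, members in study_partition.items()
                if len(labels) >= k
            )
    return {
        "pairwise_with_ours": pairwise,
        "unique_per_study": unique,
        "union_count": union_count,
        "at_least_k_studies": at_least,
        "partition": partition,
    }


def condition_specific_genes(matrix: ExpressionMatrix,
                             target_sample_ids: list[str]) -> set[str]:
    """Genes expressed strictly higher in the target group than anywhere else.

    A gene qualifies when the minimum over the target replicates exceeds
    the maximum over all other samples in the dataset.
    """
    target = [s for s in target_sample_ids]
    all_ids = [s.sample_id for s in matrix.samples]
    if not target:
        raise ValueError("target group must be non-empty")
    if not set(target) < set(all_ids):
        raise ValueError("target group must be a strict subset of samples")
    others = [s for s in all_ids if s not in set(target)]
    t_min = matrix.values[target].min(axis=1)
    o_max = matrix.values[others].max(axis=1)
    return set(matrix.gene_ids[t_min > o_max])


def percent_increase(mean_treated: float, mean_control: float):
    """Relative increase in percent; returns (rounded_int, full_precision)."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    full = 100.0 * (mean_treated - mean_control) / mean_control
    return int(round(full)), full


def two_sample_t_from_summary(a: GroupSummary, b: GroupSummary,
                              variant: str = "welch"):
    """Two-sample t-test from summary statistics.

    ``variant='welch'`` (default; the groups' printed SDs need not match)
    uses the Welch–Satterthwaite df; ``variant='pooled'`` assumes equal
    variances.  Returns (t, df, p_two_sided).  Two zero-SD groups are
    degenerate: p = 1 for equal means, p = 0 otherwise.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        return np.inf if a.mean > b.mean else -np.inf, float(a.n + b.n - 2), 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)
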
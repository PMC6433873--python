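"""Term over-/under-representation by Fisher's exact test.

A study gene set is tested term-by-term against a declared background
universe with the two-sided Fisher exact test (one call covers both
over- and under-representation; the direction is read off the fold
enrichment (k/n)/(K/N)).  Multiplicity is controlled by Bonferroni
(q = min(1, p·m) over the m tested terms), significant at q < 0.05.

Annotations are consumed as flat gene→term tables (assumed already
propagated up the ontology if that is desired); no ontology graph logic
lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Term → gene-set mapping with a background universe.

    Every annotated gene must belong to the background; term sets must be
    non-empty.
    """

    terms: dict[str, set]
    background: set
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )


def read_annotations(path, background: set | None = None,
                     names_path=None) -> AnnotationMap:
    """Load a two-column TSV ``gene_id<TAB>term_id`` (+ optional term names)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["gene_id", "term_id"], dtype=str)
    terms: dict[str, set] = {}
    for term, group in frame.groupby("term_id"):
        terms[term] = set(group["gene_id"])
    if background is None:
        background = set(frame["gene_id"])
    names = {}
    if names_path is not None:
        nframe = pd.read_csv(names_path, sep="\t", header=None,
                             names=["term_id", "name"], dtype=str)
        names = dict(zip(nframe["term_id"], nframe["name"]))
    return AnnotationMap(terms=terms, background=background, names=names)


def fisher_exact_2x2(k: int, K: int, n: int, N: int,
                     alternative: str = "two-sided"):
    """Fisher exact p and sample odds ratio for a term-membership table.

    ``k``: study genes with the term, ``K``: background genes with the
    term, ``n``: study size, ``N``: background size.  The two-sided p is
    the sum of hypergeometric probabilities no larger than the observed
    table's.
    """
    if not (0 <= k <= K <= N and k <= n <= N and n - k <= N - K):
        raise ValueError(
            f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}"
        )
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    res = stats.fisher_exact(table, alternative=alternative)
    return float(res.pvalue), float(res.statistic)


def run_enrichment(study: set, annotations: AnnotationMap,
                   alternative: str = "two-sided",
                   min_term_size: int = 2,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-term enrichment of a study set against the background.

    Study genes outside the background are dropped (logged).  A term is
    tested when its background count K ≥ ``min_term_size`` and it has
    either k ≥ 1 study genes or an expected count n·K/N ≥ 1.  Bonferroni
    q = min(1, p·m) with m the number of tested terms; significant at
    q < ``alpha``.
    """
    N = len(annotations.background)
    dropped = study - annotations.background
    if dropped:
        logger.warning("dropping %d study genes outside the background",
                       len(dropped))
    study_in = study & annotations.background
    n = len(study_in)
    if n == 0:
        raise ValueError("study set is empty after background intersection")
    rows = []
    for term, genes in sorted(annotations.terms.items()):
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(study_in & genes)
        expected = n * K / N
        if k < 1 and expected < 1:
            continue
        p, odds = fisher_exact_2x2(k, K, n, N, alternative=alternative)
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term_id": term,
                "term_name": annotations.names.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": fold,
                "direction": "over" if fold > 1 else "under",
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        m = len(result)
        result["q_value"] = (result["p_value"] * m).clip(upper=1.0)
        result["significant"] = result["q_value"] < alpha
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    return result
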
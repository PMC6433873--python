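"""Shared builders for expression-matrix test instances."""

from __future__ import annotations

import numpy as np
import pandas as pd

from abatime.core_io import ExpressionMatrix, SampleInfo

TPS = (30, 60, 180)


def build_matrix(groups: dict[tuple[str, int], np.ndarray],
                 gene_ids=None) -> ExpressionMatrix:
    """Build a matrix from {(condition, timepoint): genes × reps array}."""
    columns = {}
    samples = []
    n_genes = next(iter(groups.values())).shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    for (cond, tp), arr in groups.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for r in range(arr.shape[1]):
            sid = f"{cond}_t{tp}_r{r + 1}"
            columns[sid] = arr[:, r]
            samples.append(SampleInfo(sid, cond, tp, r + 1))
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(values, samples)


def random_matrix(rng: np.random.Generator, n_genes: int,
                  tps=TPS, reps: int = 3, scale: float = 1.0) -> ExpressionMatrix:
    """Pure-noise two-condition matrix (no condition effect)."""
    groups = {
        (cond, tp): rng.normal(0.0, scale, size=(n_genes, reps))
        for cond in ("control", "treated")
        for tp in tps
    }
    return build_matrix(groups)
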
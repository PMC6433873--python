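"""Set comparisons: timepoint Venn, synthetic external studies, orthologs,
and the printed-table / morphometry worked values.

External-study DEG lists are derived from the simulation truth with known
dropout/contamination, and a synthetic many-to-one ortholog map exercises
the paralog collapse.  The printed reference tables and cell-wall summary
statistics are re-analyzed exactly as in the source study.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from abatime.compare import (
    GroupSummary,
    collapse_orthologs,
    cross_study_overlap,
    percent_increase,
    region_counts,
    two_sample_t_from_summary,
    venn_partition,
)
from abatime.core_io import load_fixture_table
from abatime.degcall import classify_printed_table
from abatime.synthdata import make_study_lists, read_truth, responsive_genes

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    deg = pd.read_csv(OUT / "deg.tsv", sep="\t", index_col=0)
    truth = read_truth(SIM / "truth.tsv")

    sets = {f"t{tp}": set(deg.index[deg[f"dir_{tp}"] != "none"])
            for tp in (30, 60, 180)}
    counts = region_counts(venn_partition(sets))
    rows = [{"region": "+".join(sorted(k)), "count": v}
            for k, v in sorted(counts.items(), key=lambda kv: sorted(kv[0]))]
    pd.DataFrame(rows).to_csv(OUT / "venn_timepoints.tsv", sep="\t", index=False)
    print("timepoint Venn regions:")
    for row in rows:
        print(f"  {row['region']}: {row['count']}")

    # synthetic external studies with known dropout/contamination
    ours = set(deg.index[deg["temporal_class"] != "none"])
    studies = {
        "studyA": make_study_lists(truth, dropout=0.3, contamination=0.02, seed=1),
        "studyB": make_study_lists(truth, dropout=0.5, contamination=0.05, seed=2),
    }
    overlap = cross_study_overlap(ours, studies)
    print(f"cross-study overlap with our calls: "
          f"{overlap['pairwise_with_ours']}")

    # synthetic many-to-one ortholog map over the responsive genes
    resp = sorted(responsive_genes(truth))
    rng = np.random.default_rng(3)
    targets = [f"AT{i:05d}" for i in range(int(0.7 * len(resp)))]
    omap = {g: targets[rng.integers(0, len(targets))] for g in resp[: int(0.8 * len(resp))]}
    mapped, unmapped, paralogs = collapse_orthologs(ours, omap)
    print(f"ortholog collapse: {len(mapped)} unique targets from "
          f"{len(ours)} DEGs ({len(unmapped)} unmapped, "
          f"{len(paralogs)} paralog groups)")

    # printed-table worked values
    t3 = load_fixture_table("table3_early")
    classes = classify_printed_table(t3).value_counts()
    print(f"early-gene table: {classes.get('early_sustained', 0)} sustained, "
          f"{classes.get('early_transient', 0)} transient of {len(t3)} rows; "
          f"{(t3.frame['annotation'] == 'Unknown').sum()} annotated Unknown")
    t2 = load_fixture_table("table2_aba")
    bio = t2.frame[t2.frame["section"] == "biosynthesis"]
    affected = bio.loc[bio[["fc_30", "fc_60", "fc_180"]].notna().any(axis=1),
                       "gene_id"]
    print(f"biosynthesis section: affected genes {sorted(affected)}")

    # cell-wall morphometry from printed summaries
    rounded, full = percent_increase(53, 37)
    t, df, p = two_sample_t_from_summary(
        GroupSummary(53, 11, 11), GroupSummary(37, 8, 11), variant="welch"
    )
    print(f"cell-wall thickening: {rounded}% ({full:.2f}%); "
          f"Welch t = {t:.3f} (df {df:.1f}), two-sided p = {p:.2e}")


if __name__ == "__main__":
    main()
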
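"""One-config orchestration of the analysis stages.

A YAML config selects stages (``simulate``, ``deg``, ``timecourse``,
``dynamics``, ``compare``, ``enrich``) and their parameters; stages run
sequentially in dependency order, write TSV outputs under ``outdir`` and
are recorded in a JSON :class:`RunManifest` (config snapshot, input
digests, per-stage output paths and row counts, seed).  A single global
seed is expanded into per-stage substreams via ``SeedSequence([seed,
stage_index])`` so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ExpressionMatrix,
    PipelineConfig,
    read_expression,
    read_gene_set,
    write_expression,
)
from .degcall import RegularizationParams, call_degs
from .dynamics import sample_pca, select_contributing_genes, subset_distance_curve, temporal_response_rank
from .enrich import read_annotations, run_enrichment
from .compare import cross_study_overlap, venn_partition
from .synthdata import SimConfig, generate_timecourse
from .timecourse import call_timecourse

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "deg", "timecourse", "dynamics", "compare", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed or a dependency is unsatisfied."""


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path, rows: int) -> None:
        self.stages.setdefault(stage, {})[str(path)] = rows

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2^31)."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([global_seed, idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write_tsv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t")
    return len(frame)


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages; returns the run manifest.

    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("outdir", "abatime_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate", "deg", "timecourse", "dynamics"])
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise StageError(f"unknown stage name(s): {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    manifest = RunManifest(seed=seed, config=cfg)
    manifest.input_digests[str(config_path)] = _digest(config_path)

    pcfg = PipelineConfig(
        q_cutoff_pairwise=cfg.get("deg", {}).get("q", 0.05),
        q_cutoff_timecourse=cfg.get("timecourse", {}).get("q", 0.001),
        subset_min=cfg.get("dynamics", {}).get("subset_min", 50),
        subset_max=cfg.get("dynamics", {}).get("subset_max", 500),
        poly_degree_max=cfg.get("timecourse", {}).get("degree", 3),
        rng_seed=seed,
        fdr_method_timecourse=cfg.get("timecourse", {}).get("fdr", "storey"),
    )

    matrix: ExpressionMatrix | None = None
    truth: pd.DataFrame | None = None
    deg_frame: pd.DataFrame | None = None

    try:
        if "simulate" in stages:
            sim_kwargs = dict(cfg.get("simulate", {}))
            sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
            sim = SimConfig(**sim_kwargs)
            matrix, truth = generate_timecourse(sim)
            mpath, spath = outdir / "matrix.tsv", outdir / "samples.tsv"
            write_expression(matrix, mpath, spath)
            tpath = outdir / "truth.tsv"
            truth.to_csv(tpath, sep="\t")
            manifest.record("simulate", mpath, matrix.n_genes)
            manifest.record("simulate", spath, len(matrix.samples))
            manifest.record("simulate", tpath, len(truth))
        elif "inputs" in cfg:
            matrix = read_expression(cfg["inputs"]["matrix"], cfg["inputs"]["samples"])
            for key in ("matrix", "samples"):
                p = Path(cfg["inputs"][key])
                manifest.input_digests[str(p)] = _digest(p)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    def _need_matrix(stage: str) -> ExpressionMatrix:
        if matrix is None:
            raise StageError(
                f"stage '{stage}' requires an expression matrix: enable the "
                "'simulate' stage or provide 'inputs'"
            )
        return matrix

    for stage in stages:
        if stage == "simulate":
            continue
        try:
            if stage == "deg":
                params = RegularizationParams(
                    window_size=cfg.get("deg", {}).get("window_size", 101),
                    prior_df=cfg.get("deg", {}).get("nu0", 10.0),
                )
                deg_frame = call_degs(_need_matrix(stage), pcfg, params)
                path = outdir / "deg.tsv"
                manifest.record(stage, path, _write_tsv(deg_frame, path))
            elif stage == "timecourse":
                tc = call_timecourse(_need_matrix(stage), pcfg)
                path = outdir / "timecourse.tsv"
                manifest.record(stage, path, _write_tsv(tc, path))
            elif stage == "dynamics":
                m = _need_matrix(stage)
                sizes = cfg.get("dynamics", {}).get("sizes")
                curve = subset_distance_curve(m, pcfg, sizes=sizes)
                path = outdir / "distance_curve.tsv"
                manifest.record(stage, path, _write_tsv(curve, path))
                ranked = temporal_response_rank(m)
                selected = select_contributing_genes(curve, ranked)
                sel_path = outdir / "contributing_genes.txt"
                sel_path.write_text("".join(f"{g}\n" for g in sorted(selected)))
                manifest.record(stage, sel_path, len(selected))
                pca = sample_pca(m)
                ppath = outdir / "pca_scores.tsv"
                manifest.record(stage, ppath, _write_tsv(pca.scores, ppath))
            elif stage == "compare":
                if deg_frame is None:
                    raise StageError(
                        "stage 'compare' requires 'deg' output but the deg "
                        "stage is not enabled"
                    )
                tps = _need_matrix(stage).timepoints("treated")
                sets = {
                    f"t{tp}": set(deg_frame.index[deg_frame[f"dir_{tp}"] != "none"])
                    for tp in tps
                }
                partition = venn_partition(sets)
                rows = [
                    {"region": "+".join(sorted(labels)), "count": len(members)}
                    for labels, members in sorted(
                        partition.items(), key=lambda kv: sorted(kv[0])
                    )
                ]
                frame = pd.DataFrame(rows)
                path = outdir / "venn_timepoints.tsv"
                frame.to_csv(path, sep="\t", index=False)
                manifest.record(stage, path, len(frame))
                study_paths = cfg.get("compare", {}).get("study_sets", [])
                if study_paths:
                    ours = set(deg_frame.index[deg_frame["temporal_class"] != "none"])
                    studies = {Path(p).stem: read_gene_set(p) for p in study_paths}
                    overlap = cross_study_overlap(ours, studies)
                    opath = outdir / "cross_study.json"
                    opath.write_text(json.dumps(
                        {k: v for k, v in overlap.items() if k != "partition"},
                        indent=2, default=str))
                    manifest.record(stage, opath, len(studies))
            elif stage == "enrich":
                if deg_frame is None:
                    raise StageError(
                        "stage 'enrich' requires 'deg' output but the deg "
                        "stage is not enabled"
                    )
                ann_path = cfg.get("enrich", {}).get("annotations")
                if ann_path is None:
                    raise StageError("stage 'enrich' needs an annotations file")
                ann = read_annotations(ann_path)
                study = set(deg_frame.index[deg_frame["temporal_class"] != "none"])
                result = run_enrichment(study & ann.background, ann)
                path = outdir / "enrichment.tsv"
                result.to_csv(path, sep="\t", index=False)
                manifest.record(stage, path, len(result))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage '{stage}' failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable run summary regenerated purely from stage outputs."""
    lines = [f"abatime {manifest.version} run (seed {manifest.seed})", ""]
    outputs = {Path(p).name: Path(p) for st in manifest.stages.values() for p in st}
    for name, path in outputs.items():
        if not path.exists():
            raise StageError(f"missing stage output: {path}")
    if "deg.tsv" in outputs:
        deg = pd.read_csv(outputs["deg.tsv"], sep="\t", index_col=0)
        dir_cols = [c for c in deg.columns if c.startswith("dir_")]
        lines.append("Pairwise DEG counts per timepoint:")
        for c in dir_cols:
            tp = c.split("_")[1]
            up = int((deg[c] == "up").sum())
            down = int((deg[c] == "down").sum())
            lines.append(f"  {tp} min: {up} up, {down} down")
        counts = deg["temporal_class"].value_counts()
        lines.append("Temporal classes (called genes):")
        for cls, cnt in counts.items():
            if cls != "none":
                lines.append(f"  {cls}: {int(cnt)}")
        lines.append("")
    if "timecourse.tsv" in outputs:
        tc = pd.read_csv(outputs["timecourse.tsv"], sep="\t", index_col=0)
        lines.append(f"Time-course ANOVA: {int(tc['called'].sum())} genes called "
                     f"of {len(tc)}")
        lines.append("")
    if "distance_curve.tsv" in outputs:
        curve = pd.read_csv(outputs["distance_curve.tsv"], sep="\t", index_col=0)
        idx = curve["distance"].idxmin()
        lines.append(
            "Subset distance curve: minimum distance "
            f"{curve.loc[idx, 'distance']:.4f} at start rank "
            f"{int(curve.loc[idx, 'start_rank'])} (size {int(curve.loc[idx, 'size'])})"
        )
        lines.append("")
    if "enrichment.tsv" in outputs:
        enr = pd.read_csv(outputs["enrichment.tsv"], sep="\t")
        lines.append("Top enrichment rows:")
        for _, row in enr.head(5).iterrows():
            lines.append(
                f"  {row['term_id']} {row['direction']} fold="
                f"{row['fold_enrichment']:.2f} q={row['q_value']:.3g}"
            )
        lines.append("")
    return "\n".join(lines)
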
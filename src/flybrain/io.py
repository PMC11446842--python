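"""Table readers/writers, pipeline configuration and the staged pipeline.

All tables are CSV (optionally gzip-compressed, by file suffix) with fixed
documented headers; coordinates are integer nanometres.  Column-name
variations of public data dumps are absorbed by an optional rename map.
Writers emit a deterministic column order and row sort, and every pipeline
output directory carries a ``provenance.json`` with the configuration
hash, seed and per-stage row counts so runs are auditable and exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, core, flow, projectome, regions as regions_mod, stats
from .core import SYNAPSE_COLUMNS, FilterConfig, ThresholdConfig
from .regions import AssignConfig, RegionSet

logger = logging.getLogger(__name__)

CONNECTION_COLUMNS = ["pre_root_id", "post_root_id", "neuropil", "syn_count", "nt_type"]
ANNOTATION_COLUMNS = ["root_id", "flow", "superclass", "side", "soma_inside", "nt_type"]

_SYNAPSE_DTYPES = {
    "record_id": np.int64,
    "pre_root_id": np.int64,
    "post_root_id": np.int64,
    "pre_x": np.int64,
    "pre_y": np.int64,
    "pre_z": np.int64,
    "post_x": np.int64,
    "post_y": np.int64,
    "post_z": np.int64,
    "score": np.int64,
}


def read_synapse_table(path: str | Path, rename: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a synapse table (CSV/CSV.GZ); extra columns are preserved.

    ``rename`` maps on-disk column names to the canonical schema, isolating
    dump-version differences.
    """
    df = pd.read_csv(path, dtype={"neuropil": str, "nt_type": str})
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns and c not in ("nt_type", "nt_prob")]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "nt_type" not in df.columns:
        df["nt_type"] = ""
    if "nt_prob" not in df.columns:
        df["nt_prob"] = np.nan
    for col, dt in _SYNAPSE_DTYPES.items():
        try:
            df[col] = df[col].astype(dt)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            rows = df.index[bad].tolist()[:5]
            raise ValueError(f"{path}: cannot parse column {col!r} (rows {rows})") from exc
    df["neuropil"] = df["neuropil"].fillna("")
    df["nt_type"] = df["nt_type"].fillna("")
    extras = [c for c in df.columns if c not in SYNAPSE_COLUMNS]
    return df[SYNAPSE_COLUMNS + extras]


def write_synapse_table(df: pd.DataFrame, path: str | Path) -> None:
    extras = [c for c in df.columns if c not in SYNAPSE_COLUMNS]
    out = df[SYNAPSE_COLUMNS + extras].sort_values("record_id")
    out.to_csv(path, index=False)


def read_connections(path: str | Path, rename: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"neuropil": str, "nt_type": str})
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in ("pre_root_id", "post_root_id", "syn_count") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in ("pre_root_id", "post_root_id", "syn_count"):
        df[c] = df[c].astype(np.int64)
    if "neuropil" in df.columns:
        df["neuropil"] = df["neuropil"].fillna("")
    return df


def write_connections(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CONNECTION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    keys = [c for c in ("pre_root_id", "post_root_id", "neuropil") if c in df.columns]
    df[cols].sort_values(keys, ignore_index=True).to_csv(path, index=False)


def read_annotations(path: str | Path, rename: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if rename:
        df = df.rename(columns=rename)
    if "root_id" not in df.columns:
        raise ValueError(f"{path}: missing columns ['root_id']")
    df["root_id"] = df["root_id"].astype(np.int64)
    for c in ("flow", "superclass", "side", "nt_type"):
        if c in df.columns:
            df[c] = df[c].fillna("")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].sort_values("root_id", ignore_index=True).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serialisable and hashable."""

    synapses_path: str
    regions_path: str
    annotations_path: str | None = None
    out_dir: str = "pipeline_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    laterality: annotation.LateralityConfig = field(default_factory=annotation.LateralityConfig)
    traversal: flow.TraversalConfig = field(default_factory=flow.TraversalConfig)
    seed_sets: dict[str, list[int]] = field(default_factory=dict)
    rng_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute filter -> dedup -> assign -> aggregate -> threshold ->
    classify -> projectome -> flow -> stats, writing each stage's output.

    Returns a dict of in-memory results; identical configs produce
    byte-identical files.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    results: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    table = stage("read", read_synapse_table, cfg.synapses_path)
    counts["input_rows"] = len(table)
    regions = stage("read-regions", regions_mod.load_regions, cfg.regions_path)

    table = stage("filter", core.filter_synapses, table, cfg.filter)
    counts["after_filter"] = len(table)
    table, removed = stage("dedup", core.dedup_synapses, table, cfg.filter)
    counts["after_dedup"] = len(table)
    logger.info("filter kept %d rows, dedup removed %d", counts["after_filter"], len(removed))

    table = stage("assign", regions_mod.assign_synapses_to_neuropils, table, regions, cfg.assign)
    write_synapse_table(table, out / "synapses_clean.csv")
    results["synapses"] = table

    edges_np = stage("aggregate", core.aggregate_edges, table, True)
    edges = core.collapse_neuropil_edges(edges_np)
    counts["edges"] = len(edges)
    edges_thr = stage("threshold", core.threshold_edges, edges, cfg.threshold)
    counts["edges_thresholded"] = len(edges_thr)
    write_connections(core.threshold_edges(edges_np, cfg.threshold), out / "connections.csv")
    results["edges"] = edges_thr

    # neuron classification
    neuron_ids = np.union1d(table["pre_root_id"].unique(), table["post_root_id"].unique())
    ann = pd.DataFrame({"root_id": neuron_ids})
    if cfg.annotations_path:
        given = read_annotations(cfg.annotations_path)
        ann = ann.merge(given, on="root_id", how="left")
    if "soma_inside" not in ann.columns:
        ann["soma_inside"] = np.nan
    flows = stage("classify", annotation.classify_flow_table, table, regions, ann)
    ann["flow"] = ann["root_id"].map(flows)
    write_annotations(ann, out / "classification.csv")
    results["annotations"] = ann

    intrinsic = ann.loc[ann["flow"] == "intrinsic", "root_id"].tolist()
    proj = stage("projectome", projectome.build_projectome, intrinsic, table, regions)
    proj.to_frame().to_csv(out / "projectome.csv")
    results["projectome"] = proj

    if cfg.seed_sets:
        tr_cfg = flow.TraversalConfig(
            saturation_fraction=cfg.traversal.saturation_fraction,
            n_runs=cfg.traversal.n_runs,
            max_rounds=cfg.traversal.max_rounds,
            unreached_distance_rule=cfg.traversal.unreached_distance_rule,
            rng_seed=cfg.rng_seed,
        )
        emb = stage(
            "flow", flow.build_rank_embedding, edges_thr,
            {k: set(v) for k, v in cfg.seed_sets.items()}, tr_cfg,
        )
        stacked = pd.concat(
            [r.table.assign(modality=label) for label, r in emb.results.items()],
            ignore_index=True,
        )
        stacked.to_csv(out / "ranks.csv", index=False)
        results["rank_embedding"] = emb

    per_deg, deg_summary = stage("stats", stats.degree_stats, edges_thr, neuron_ids.tolist())
    per_deg.to_csv(out / "degrees.csv")
    results["degree_summary"] = deg_summary

    provenance = {
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "stage_row_counts": counts,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    results["provenance"] = provenance
    return results
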
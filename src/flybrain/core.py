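"""Canonical synapse/connection data model and the core cleaning steps.

The working representation of a synapse table is a :class:`pandas.DataFrame`
with one row per predicted pre->post synaptic link (polyadic boutons appear
as several rows sharing a presynaptic coordinate).  Required columns:

========== ======================================================
column      meaning
========== ======================================================
record_id   unique integer identifier of the annotation
pre_root_id presynaptic neuron id, ``-1`` if unassigned to a segment
post_root_id postsynaptic neuron id, ``-1`` if unassigned
pre_x/y/z   presynaptic location, integer nanometres
post_x/y/z  postsynaptic location, integer nanometres
score       cleft confidence score, integer 0-255
neuropil    region name, ``""`` if unassigned
nt_type     predicted transmitter label (optional, ``""`` if absent)
nt_prob     probability of ``nt_type`` (optional, NaN if absent)
========== ======================================================

Edge lists are DataFrames with ``pre_root_id, post_root_id, syn_count`` and
optionally a ``neuropil`` column (one row per (pre, post, neuropil)).

Cleaning follows the published pipeline: drop links whose cleft score is at
or below the cutoff or whose partners are unassigned, then remove spatial
near-duplicate annotations of the same ordered neuron pair, aggregate the
survivors into connections, and finally keep only connections with at least
``min_synapses`` synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: sentinel for a pre/post location that was not assigned to any segment
UNASSIGNED_ID = -1
#: sentinel for a synapse not assigned to any neuropil
NO_REGION = ""

SYNAPSE_COLUMNS = [
    "record_id",
    "pre_root_id",
    "post_root_id",
    "pre_x",
    "pre_y",
    "pre_z",
    "post_x",
    "post_y",
    "post_z",
    "score",
    "neuropil",
    "nt_type",
    "nt_prob",
]

NT_LABELS = ["ACH", "GABA", "GLUT", "SER", "DA", "OCT"]


@dataclass(frozen=True)
class FilterConfig:
    """Synapse-level cleaning parameters.

    score_min_exclusive
        A link is kept only if ``score > score_min_exclusive``.  The default
        of 50 removes the low-confidence tail of the detector output.
    dedup_radius
        Radius in nanometres within which two annotations of the same
        ordered (pre, post) pair count as duplicates (presynaptic
        coordinates, Euclidean).
    drop_unassigned
        Drop rows where either partner is not assigned to a segment.
    """

    score_min_exclusive: int = 50
    dedup_radius: float = 100.0
    drop_unassigned: bool = True

    def __post_init__(self) -> None:
        if self.dedup_radius < 0:
            raise ValueError("dedup_radius must be >= 0")


@dataclass(frozen=True)
class ThresholdConfig:
    """Connection threshold: a connection requires >= min_synapses synapses."""

    min_synapses: int = 5

    def __post_init__(self) -> None:
        if self.min_synapses < 1:
            raise ValueError("min_synapses must be >= 1")


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")


def filter_synapses(table: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Remove low-score rows and (optionally) rows with unassigned partners.

    Row order is preserved and the input is not modified.
    """
    cfg = cfg or FilterConfig()
    _require_columns(table, ["score", "pre_root_id", "post_root_id"])
    keep = table["score"].to_numpy() > cfg.score_min_exclusive
    if cfg.drop_unassigned:
        keep &= (table["pre_root_id"].to_numpy() != UNASSIGNED_ID) & (
            table["post_root_id"].to_numpy() != UNASSIGNED_ID
        )
    return table.loc[keep].copy()


def _greedy_keep(coords: np.ndarray, order: np.ndarray, radius: float) -> np.ndarray:
    """Greedy sweep over one (pre, post) group.

    ``coords`` are the presynaptic coordinates (float, nm), ``order`` the
    sweep order (indices into coords).  Returns a boolean kept mask aligned
    with ``coords``.  A row is kept iff it is more than ``radius`` away from
    every previously kept row of the group.
    """
    n = len(coords)
    kept = np.zeros(n, dtype=bool)
    if n == 0:
        return kept
    if n <= 64:
        kept_idx: list[int] = []
        for i in order:
            c = coords[i]
            ok = True
            for j in kept_idx:
                d = c - coords[j]
                if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] <= radius * radius:
                    ok = False
                    break
            if ok:
                kept[i] = True
                kept_idx.append(i)
        return kept
    # large group: prune candidate neighbours with a KD-tree
    tree = cKDTree(coords)
    neighbours = tree.query_ball_point(coords, r=radius)
    for i in order:
        if any(kept[j] for j in neighbours[i] if j != i):
            continue
        kept[i] = True
    return kept


def dedup_synapses(
    table: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, set[int]]:
    """Remove spatial near-duplicate annotations of the same (pre, post) pair.

    Within each ordered pair, rows are swept in descending score (ties
    broken by ascending record_id) and a row is kept iff its presynaptic
    coordinate is more than ``cfg.dedup_radius`` (Euclidean, nm) from every
    already-kept row of that pair, so the highest-confidence annotation of a
    duplicate cluster survives.  Rows belonging to different pairs never
    suppress each other.  Idempotent.

    Returns the deduplicated table (original row order) and the set of
    removed record ids.
    """
    cfg = cfg or FilterConfig()
    _require_columns(table, ["record_id", "pre_root_id", "post_root_id", "pre_x", "pre_y", "pre_z"])
    if table.empty:
        return table.copy(), set()

    coords = table[["pre_x", "pre_y", "pre_z"]].to_numpy(dtype=float)
    score = table["score"].to_numpy()
    rid = table["record_id"].to_numpy()
    pair_codes = pd.MultiIndex.from_arrays(
        [table["pre_root_id"], table["post_root_id"]]
    ).factorize()[0]

    kept_mask = np.zeros(len(table), dtype=bool)
    df_idx = np.arange(len(table))
    group_order = np.argsort(pair_codes, kind="stable")
    boundaries = np.flatnonzero(np.diff(pair_codes[group_order])) + 1
    for grp in np.split(group_order, boundaries):
        sweep = np.lexsort((rid[grp], -score[grp]))
        kept_mask[grp] = _greedy_keep(coords[grp], sweep, cfg.dedup_radius)

    removed = set(rid[~kept_mask].tolist())
    return table.loc[kept_mask[df_idx]].copy(), removed


def aggregate_edges(table: pd.DataFrame, by_neuropil: bool = False) -> pd.DataFrame:
    """Aggregate synapse rows into a neuron->neuron connection list.

    The synapse count of a connection is the number of rows with that
    ordered (pre, post) pair; with ``by_neuropil`` the count is further
    split per region.  Total synapses are conserved.
    """
    _require_columns(table, ["pre_root_id", "post_root_id"])
    ids = table[["pre_root_id", "post_root_id"]].to_numpy()
    if (ids == UNASSIGNED_ID).any():
        raise ValueError("aggregate requires assigned partners")
    keys = ["pre_root_id", "post_root_id"] + (["neuropil"] if by_neuropil else [])
    edges = (
        table.groupby(keys, sort=True, dropna=False)
        .size()
        .rename("syn_count")
        .reset_index()
    )
    return edges


def threshold_edges(edges: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Keep connections with at least ``min_synapses`` synapses.

    For per-neuropil edge lists the threshold applies to the total synapse
    count of the (pre, post) pair — a connection is the full set of synapses
    between two neurons — and all surviving rows of that pair are kept.
    """
    cfg = cfg or ThresholdConfig()
    _require_columns(edges, ["pre_root_id", "post_root_id", "syn_count"])
    totals = edges.groupby(["pre_root_id", "post_root_id"])["syn_count"].transform("sum")
    return edges.loc[totals >= cfg.min_synapses].copy()


def collapse_neuropil_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-neuropil edge list to plain (pre, post) connections."""
    return (
        edges.groupby(["pre_root_id", "post_root_id"], sort=True)["syn_count"]
        .sum()
        .reset_index()
    )
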
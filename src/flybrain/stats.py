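"""Descriptive network statistics and quality-assurance metrics.

Degrees and synapse totals over the thresholded connection graph,
connection-strength tail counts, group-to-group aggregated connectivity
matrices, synapse attachment (completion) rates per neuropil, the
precision/recall/F1 triple used to score proofreading, and volumetric
synapse density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NO_REGION
from .regions import RegionSet


@dataclass(frozen=True)
class QAOutcome:
    """Precision / recall / F1 from true-positive, false-positive and
    false-negative volumes (or counts)."""

    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float


def degree_stats(
    edges: pd.DataFrame, population, include_autapses: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-neuron in/out degree and synapse totals over an edge list.

    Degree counts distinct partners among the surviving (usually
    thresholded) connections; synapse totals sum ``syn_count``.  Every
    neuron of ``population`` appears, including isolated ones with zeros.
    Autapses are excluded from degrees by default.

    Returns ``(per_neuron, summary)`` where summary holds medians and the
    maximum-degree neurons.
    """
    population = pd.Index(sorted(set(population)))
    if population.empty:
        raise ValueError("empty population")
    e = edges
    if not include_autapses:
        e = e.loc[e["pre_root_id"] != e["post_root_id"]]
    out_deg = e.groupby("pre_root_id").size()
    in_deg = e.groupby("post_root_id").size()
    out_syn = e.groupby("pre_root_id")["syn_count"].sum()
    in_syn = e.groupby("post_root_id")["syn_count"].sum()
    per = pd.DataFrame(
        {
            "in_degree": in_deg.reindex(population, fill_value=0).astype(int),
            "out_degree": out_deg.reindex(population, fill_value=0).astype(int),
            "in_synapses": in_syn.reindex(population, fill_value=0).astype(int),
            "out_synapses": out_syn.reindex(population, fill_value=0).astype(int),
        }
    )
    per.index.name = "root_id"
    summary = {
        "median_in_degree": float(per["in_degree"].median()),
        "median_out_degree": float(per["out_degree"].median()),
        "median_in_synapses": float(per["in_synapses"].median()),
        "median_out_synapses": float(per["out_synapses"].median()),
        "max_in_degree_neuron": int(per["in_degree"].idxmax()),
        "max_out_degree_neuron": int(per["out_degree"].idxmax()),
        "max_in_degree": int(per["in_degree"].max()),
        "max_out_degree": int(per["out_degree"].max()),
    }
    return per, summary


def strength_histogram(edges: pd.DataFrame, bounds) -> dict[int, int]:
    """Number of connections with more than ``bound`` synapses, per bound."""
    syn = edges["syn_count"].to_numpy()
    return {int(b): int((syn > b).sum()) for b in bounds}


def group_matrix(
    edges: pd.DataFrame, grouping: dict[int, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate the connection graph between neuron groups.

    Neurons without a group fall into ``"other"``.  Returns the
    (synapse-count, connection-count) matrix pair; synapse totals are
    conserved under any grouping.
    """
    pre_g = edges["pre_root_id"].map(grouping).fillna("other")
    post_g = edges["post_root_id"].map(grouping).fillna("other")
    df = pd.DataFrame({"pre": pre_g, "post": post_g, "syn": edges["syn_count"].to_numpy()})
    syn = df.pivot_table(index="pre", columns="post", values="syn", aggfunc="sum", fill_value=0)
    conn = df.pivot_table(index="pre", columns="post", values="syn", aggfunc="size", fill_value=0)
    groups = sorted(set(syn.index) | set(syn.columns))
    syn = syn.reindex(index=groups, columns=groups, fill_value=0).astype(int)
    conn = conn.reindex(index=groups, columns=groups, fill_value=0).astype(int)
    return syn, conn


def attachment_rates(
    table: pd.DataFrame, proofread, regions: RegionSet | None = None
) -> pd.DataFrame:
    """Fraction of synaptic sites attached to proofread neurons, per
    neuropil and direction.

    For every assigned neuropil and for the overall table, the ``pre``
    (resp. ``post``) rate is the fraction of rows whose presynaptic
    (postsynaptic) partner belongs to the proofread set.
    """
    proofread = set(proofread)
    assigned = table.loc[table["neuropil"] != NO_REGION]
    rows = []
    for direction, col in (("pre", "pre_root_id"), ("post", "post_root_id")):
        attached_mask = assigned[col].isin(proofread)
        per_np = assigned.groupby("neuropil").size()
        att_np = assigned.loc[attached_mask].groupby("neuropil").size()
        for np_name, total in per_np.items():
            att = int(att_np.get(np_name, 0))
            rows.append(
                {
                    "neuropil": np_name,
                    "direction": direction,
                    "attached": att,
                    "total": int(total),
                    "rate": att / total,
                }
            )
        total_all = len(assigned)
        att_all = int(attached_mask.sum())
        rows.append(
            {
                "neuropil": "ALL",
                "direction": direction,
                "attached": att_all,
                "total": total_all,
                "rate": att_all / total_all if total_all else 0.0,
            }
        )
    return pd.DataFrame(rows)


def proofreading_f1(tp: float, fp: float, fn: float) -> QAOutcome:
    """Precision, recall and their harmonic mean F1.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) = 2TP/(2TP+FP+FN).
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("TP, FP, FN must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("zero denominator in precision or recall")
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return QAOutcome(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)


def synapse_density(synapse_count: float, neuropil_volume_um3: float) -> float:
    """Synapses per cubic micrometre of neuropil."""
    if neuropil_volume_um3 <= 0:
        raise ValueError("neuropil volume must be positive")
    return synapse_count / neuropil_volume_um3
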
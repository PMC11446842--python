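"""Neuron-level classification rules.

A neuron is *intrinsic* when every one of its synapses lies within brain
regions; otherwise it is *afferent* (cell body outside the brain: sensory,
ascending) or *efferent* (cell body inside: descending, motor, endocrine).
Laterality compares where a neuron's outputs sit relative to its dominant
input hemisphere; neurotransmitter identity aggregates per-synapse
predictions to a single per-neuron label under the assumption that a neuron
releases one transmitter at all of its outputs (Dale's law).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NO_REGION, NT_LABELS
from .regions import RegionSet, side_counts

logger = logging.getLogger(__name__)

FLOW_CLASSES = ("intrinsic", "afferent", "efferent")

#: superclass -> flow mapping
SUPERCLASS_FLOW = {
    "sensory": "afferent",
    "ascending": "afferent",
    "central": "intrinsic",
    "optic": "intrinsic",
    "visual_projection": "intrinsic",
    "visual_centrifugal": "intrinsic",
    "endocrine": "efferent",
    "descending": "efferent",
    "motor": "efferent",
}

#: transmitter -> functional sign (+1 excitatory, -1 inhibitory, 0 unknown)
NT_SIGN = {"ACH": +1, "GABA": -1, "GLUT": -1, "SER": 0, "DA": 0, "OCT": 0}

# dominant-side ties resolved in this fixed order
_SIDE_TIE_ORDER = ("centre", "left", "right")


@dataclass(frozen=True)
class LateralityConfig:
    """Cutoffs on the contralateral output fraction.

    ``contralateral_min_fraction``: at or above this fraction of (non-centre)
    presynapses on the side opposite the dominant input side, the neuron is
    contralateral.  ``ipsilateral_max_fraction``: at or below it, ipsilateral.
    In between, bilateral.
    """

    contralateral_min_fraction: float = 0.95
    ipsilateral_max_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.ipsilateral_max_fraction < self.contralateral_min_fraction <= 1:
            raise ValueError("need 0 <= ipsi_max < contra_min <= 1")


def _neuron_rows(neuron: int, table: pd.DataFrame) -> pd.DataFrame:
    return table.loc[(table["pre_root_id"] == neuron) | (table["post_root_id"] == neuron)]


def classify_flow(
    neuron: int,
    table: pd.DataFrame,
    regions: RegionSet,
    soma_inside_brain: bool | None = None,
) -> str:
    """Flow class of one neuron: intrinsic / afferent / efferent.

    Intrinsic iff every synapse row touching the neuron is assigned to a
    brain region.  Otherwise the soma position decides: outside the brain ->
    afferent, inside -> efferent.
    """
    rows = _neuron_rows(neuron, table)
    if rows.empty and soma_inside_brain is None:
        raise ValueError(f"neuron {neuron}: no synapses and no soma information")
    if not rows.empty and (rows["neuropil"] != NO_REGION).all():
        return "intrinsic"
    if soma_inside_brain is None:
        raise ValueError(f"neuron {neuron}: cannot resolve afferent/efferent (unknown soma)")
    return "efferent" if soma_inside_brain else "afferent"


def classify_flow_table(
    table: pd.DataFrame, regions: RegionSet, neurons: pd.DataFrame
) -> pd.Series:
    """Vectorized :func:`classify_flow` for a whole annotation table.

    ``neurons`` needs columns ``root_id`` and ``soma_inside`` (boolean or
    NaN for unknown).  Returns a Series indexed by root_id.
    """
    assigned = table["neuropil"] != NO_REGION
    touched_unassigned = set(table.loc[~assigned, "pre_root_id"]) | set(
        table.loc[~assigned, "post_root_id"]
    )
    out = {}
    for root_id, soma in zip(neurons["root_id"], neurons["soma_inside"]):
        if root_id not in touched_unassigned:
            out[root_id] = "intrinsic"
        elif pd.isna(soma):
            raise ValueError(f"neuron {root_id}: cannot resolve afferent/efferent (unknown soma)")
        else:
            out[root_id] = "efferent" if soma else "afferent"
    return pd.Series(out, name="flow")


def dominant_input_side(neuron: int, table: pd.DataFrame, regions: RegionSet) -> str:
    """Hemisphere (left/right/centre) receiving most of the neuron's inputs.

    Ties are broken centre > left > right and logged.
    """
    counts = side_counts(neuron, table, regions, "incoming")
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"neuron {neuron}: no inputs")
    best = max(counts.values())
    winners = [s for s in _SIDE_TIE_ORDER if counts[s] == best]
    if len(winners) > 1:
        logger.warning(
            "neuron %s: dominant input side tie %s resolved to %r", neuron, counts, winners[0]
        )
    return winners[0]


def laterality_classify(
    neuron: int,
    table: pd.DataFrame,
    regions: RegionSet,
    cfg: LateralityConfig | None = None,
) -> str:
    """Ipsilateral / bilateral / contralateral / excluded, from output side.

    Excluded when the dominant input side is centre or most presynapses sit
    in centre regions.  Otherwise classify by the fraction of non-centre
    presynapses that lie on the hemisphere opposite the dominant input side.
    """
    cfg = cfg or LateralityConfig()
    out_counts = side_counts(neuron, table, regions, "outgoing")
    n_out = sum(out_counts.values())
    if n_out == 0:
        raise ValueError(f"neuron {neuron}: no outputs")
    in_side = dominant_input_side(neuron, table, regions)
    if in_side == "centre" or out_counts["centre"] * 2 > n_out:
        return "excluded"
    opposite = "right" if in_side == "left" else "left"
    lateral = out_counts["left"] + out_counts["right"]
    if lateral == 0:
        return "excluded"
    f = out_counts[opposite] / lateral
    if f >= cfg.contralateral_min_fraction:
        return "contralateral"
    if f <= cfg.ipsilateral_max_fraction:
        return "ipsilateral"
    return "bilateral"


def classify_optic_projection(
    neuron: int,
    table: pd.DataFrame,
    regions: RegionSet,
    optic_group: str = "optic_lobe",
    central_group: str = "central_brain",
) -> str:
    """Optic-lobe projection pattern of an intrinsic neuron.

    ``optic_intrinsic`` if all synapses sit in optic-lobe regions, ``central``
    if none do; ``VPN`` (visual projection neuron) when the majority of
    inputs are optic and the majority of outputs central, ``VCN`` (visual
    centrifugal) for the reverse; ``other`` otherwise.  The definition uses
    synapse locations only.
    """
    optic = set(regions.group(optic_group))
    central = set(regions.group(central_group))
    rows = _neuron_rows(neuron, table)
    rows = rows.loc[rows["neuropil"] != NO_REGION]
    in_optic = rows["neuropil"].isin(optic)
    if in_optic.all() and len(rows):
        return "optic_intrinsic"
    if not in_optic.any():
        return "central"
    post = rows.loc[rows["post_root_id"] == neuron, "neuropil"]  # the neuron's inputs
    pre = rows.loc[rows["pre_root_id"] == neuron, "neuropil"]  # the neuron's outputs
    in_optic_frac = post.isin(optic).mean() if len(post) else 0.0
    in_central_frac = post.isin(central).mean() if len(post) else 0.0
    out_optic_frac = pre.isin(optic).mean() if len(pre) else 0.0
    out_central_frac = pre.isin(central).mean() if len(pre) else 0.0
    if in_optic_frac > 0.5 and out_central_frac > 0.5:
        return "VPN"
    if in_central_frac > 0.5 and out_optic_frac > 0.5:
        return "VCN"
    return "other"


def assign_neuron_nt(neuron: int, table: pd.DataFrame) -> tuple[str, int]:
    """Per-neuron transmitter label and functional sign.

    Sums the per-synapse predicted probabilities over all of the neuron's
    outgoing synapses and takes the argmax (ties resolved in the fixed
    order ACH, GABA, GLUT, SER, DA, OCT and logged).  Sign: +1 for ACH,
    -1 for GABA/GLUT, 0 for the monoamines.
    """
    rows = table.loc[
        (table["pre_root_id"] == neuron)
        & (table["nt_type"] != "")
        & table["nt_prob"].notna()
    ]
    if rows.empty:
        raise ValueError(f"neuron {neuron}: no neurotransmitter evidence")
    sums = rows.groupby("nt_type")["nt_prob"].sum()
    totals = np.array([sums.get(lbl, 0.0) for lbl in NT_LABELS])
    best = totals.max()
    winners = [lbl for lbl, t in zip(NT_LABELS, totals) if t == best]
    if len(winners) > 1:
        logger.warning("neuron %s: neurotransmitter tie %s resolved to %r", neuron, winners, winners[0])
    label = winners[0]
    return label, NT_SIGN[label]
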
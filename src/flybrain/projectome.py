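"""Neuropil-to-neuropil projectome from per-neuron fractional synapse vectors.

For every intrinsic neuron we form two vectors over the N neuropils: the
fraction of its (assigned) incoming synapses per neuropil and the fraction
of its outgoing synapses per neuropil.  Their outer product is the neuron's
N x N fractional weight matrix (summing to one), and summing these matrices
over all intrinsic neurons yields the projectome: rows index the neuropil
information is received in, columns the neuropil it is sent to, and the
grand total equals the number of contributing neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NO_REGION
from .regions import RegionSet


@dataclass
class FractionalVectors:
    """Per-neuropil input/output synapse fractions of one neuron.

    Zero-synapse sides are flagged (all-zero vector, ``has_in``/``has_out``
    False) rather than raising.
    """

    neuron_id: int
    f_in: np.ndarray
    f_out: np.ndarray
    has_in: bool
    has_out: bool


@dataclass
class ProjectomeMatrix:
    """Summed fractional projection weights between neuropils.

    values[a, b] = summed weight received in neuropil a and sent out in
    neuropil b.  The grand total equals ``contributing_neuron_count``
    (neurons with assigned synapses on both sides).  ``marginals`` holds
    per-superclass afferent/efferent vectors: for afferent superclasses the
    summed output fractions (their inputs are outside the brain and are not
    counted), for efferent superclasses the summed input fractions.
    """

    values: np.ndarray
    neuropils: list[str]
    contributing_neuron_count: int
    marginals: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.neuropils, columns=self.neuropils)


def _direction_counts(
    table: pd.DataFrame, regions: RegionSet, id_col: str
) -> pd.DataFrame:
    """neuron x neuropil synapse counts for one direction (assigned rows)."""
    assigned = table.loc[table["neuropil"] != NO_REGION]
    counts = (
        assigned.groupby([id_col, "neuropil"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=regions.names, fill_value=0)


def fractional_vectors(
    neuron: int, table: pd.DataFrame, regions: RegionSet
) -> FractionalVectors:
    """Input/output neuropil fraction vectors of a single neuron."""
    n = len(regions)
    name_idx = {nm: i for i, nm in enumerate(regions.names)}
    f_in = np.zeros(n)
    f_out = np.zeros(n)
    assigned = table.loc[table["neuropil"] != NO_REGION]
    for col, vec in (("post_root_id", f_in), ("pre_root_id", f_out)):
        rows = assigned.loc[assigned[col] == neuron, "neuropil"]
        for reg, c in rows.value_counts().items():
            vec[name_idx[reg]] = c
    has_in = f_in.sum() > 0
    has_out = f_out.sum() > 0
    if has_in:
        f_in /= f_in.sum()
    if has_out:
        f_out /= f_out.sum()
    return FractionalVectors(neuron, f_in, f_out, has_in, has_out)


def neuron_projection_matrix(v: FractionalVectors) -> np.ndarray:
    """Outer product f_in x f_out: the neuron's fractional weight matrix.

    Sums to 1 for a contributing neuron; all-zero if either side has no
    assigned synapses (the neuron then does not count as contributing).
    """
    if not (v.has_in and v.has_out):
        return np.zeros((len(v.f_in), len(v.f_out)))
    return np.outer(v.f_in, v.f_out)


def build_projectome(
    neurons,
    table: pd.DataFrame,
    regions: RegionSet,
    nt_filter: str | None = None,
    neuron_nt: dict[int, str] | None = None,
    neuron_superclass: dict[int, str] | None = None,
) -> ProjectomeMatrix:
    """Sum per-neuron projection matrices over a set of intrinsic neurons.

    ``nt_filter`` restricts the sum to neurons with that transmitter label
    (``neuron_nt`` maps neuron -> label); weights keep the global
    normalisation, so the per-transmitter matrices sum to the full one.
    ``neuron_superclass`` (for afferent/efferent neurons passed alongside)
    feeds the marginal vectors.
    """
    neurons = list(neurons)
    if nt_filter is not None:
        if neuron_nt is None:
            raise ValueError("nt_filter requires neuron_nt labels")
        neurons = [n for n in neurons if neuron_nt.get(n) == nt_filter]

    r = len(regions)
    values = np.zeros((r, r))
    contributing = 0
    if neurons:
        sub = table.loc[
            table["pre_root_id"].isin(neurons) | table["post_root_id"].isin(neurons)
        ]
        in_counts = _direction_counts(sub, regions, "post_root_id")
        out_counts = _direction_counts(sub, regions, "pre_root_id")
        idx = pd.Index(neurons)
        fin = in_counts.reindex(idx, fill_value=0).to_numpy(dtype=float)
        fout = out_counts.reindex(idx, fill_value=0).to_numpy(dtype=float)
        in_tot = fin.sum(axis=1, keepdims=True)
        out_tot = fout.sum(axis=1, keepdims=True)
        contrib = (in_tot[:, 0] > 0) & (out_tot[:, 0] > 0)
        contributing = int(contrib.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            fin = np.where(in_tot > 0, fin / in_tot, 0.0)[contrib]
            fout = np.where(out_tot > 0, fout / out_tot, 0.0)[contrib]
        values = fin.T @ fout

    marginals: dict[str, np.ndarray] = {}
    if neuron_superclass:
        from .annotation import SUPERCLASS_FLOW

        sc_table = pd.DataFrame(
            {"root_id": list(neuron_superclass), "superclass": list(neuron_superclass.values())}
        )
        all_ids = sc_table["root_id"]
        sub = table.loc[table["pre_root_id"].isin(all_ids) | table["post_root_id"].isin(all_ids)]
        in_counts = _direction_counts(sub, regions, "post_root_id")
        out_counts = _direction_counts(sub, regions, "pre_root_id")
        for sc in sorted(set(neuron_superclass.values())):
            flow = SUPERCLASS_FLOW.get(sc)
            ids = [n for n, s in neuron_superclass.items() if s == sc]
            # afferent inputs / efferent outputs lie outside the brain: skip
            if flow == "afferent":
                counts, key = out_counts, "out"
            elif flow == "efferent":
                counts, key = in_counts, "in"
            else:
                continue
            mat = counts.reindex(pd.Index(ids), fill_value=0).to_numpy(dtype=float)
            tot = mat.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(tot > 0, mat / tot, 0.0)
            marginals[f"{sc}_{key}"] = frac.sum(axis=0)

    return ProjectomeMatrix(
        values=values,
        neuropils=regions.names,
        contributing_neuron_count=contributing,
        marginals=marginals,
    )


def plot_projectome(matrix: ProjectomeMatrix, ax=None, log: bool = True):
    """Heatmap of the projectome (lazy matplotlib import)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    vals = matrix.values
    if log:
        vals = np.log10(vals + 1e-3)
    im = ax.imshow(vals, cmap="viridis")
    ax.set_xticks(range(len(matrix.neuropils)), matrix.neuropils, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.neuropils)), matrix.neuropils, fontsize=6)
    ax.set_xlabel("output neuropil")
    ax.set_ylabel("input neuropil")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
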
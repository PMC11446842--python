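"""Neuropil regions: membership, distance, side labels and groupings.

Regions are axis-aligned boxes in integer-nanometre space.  Real neuropils
are meshes; the :class:`RegionSet` interface (containment + distance
oracles) is all downstream code sees, so a mesh-backed implementation can
be slotted in without touching the pipeline.  Every left region has a right
twin whose name shares the stem (``AL_L`` / ``AL_R``); unpaired regions are
``centre``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NO_REGION

SIDES = ("left", "right", "centre")


@dataclass(frozen=True)
class Region:
    """One neuropil: an axis-aligned box [lo, hi] in nm, with a side label."""

    name: str
    side: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not all(l <= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"region {self.name}: lo must be <= hi")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((points >= lo) & (points <= hi), axis=1)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the box (0 inside)."""
        points = np.atleast_2d(points).astype(float)
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        d = np.maximum(np.maximum(lo - points, points - hi), 0.0)
        return np.sqrt((d * d).sum(axis=1))


@dataclass
class RegionSet:
    """An ordered collection of named regions plus named groups of regions."""

    regions: list[Region]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        stems_l = {r.name.removesuffix("_L") for r in self.regions if r.side == "left"}
        stems_r = {r.name.removesuffix("_R") for r in self.regions if r.side == "right"}
        if stems_l != stems_r:
            raise ValueError("every left region needs a right twin with matching stem")
        for g, members in self.groups.items():
            unknown = set(members) - set(names)
            if unknown:
                raise ValueError(f"group {g!r} references unknown regions {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def side_of(self) -> dict[str, str]:
        return {r.name: r.side for r in self.regions}

    def group(self, name: str) -> list[str]:
        return list(self.groups[name])

    def assign_points(self, points: np.ndarray, max_snap_distance: float) -> np.ndarray:
        """Region name per point: containing region, else nearest region
        within ``max_snap_distance`` nm (ties -> lexicographically smallest
        name), else unassigned (``""``)."""
        points = np.atleast_2d(points).astype(float)
        n = len(points)
        # evaluate regions in lexicographic name order so the first hit wins ties
        order = np.argsort(np.array(self.names, dtype=object))
        dists = np.empty((len(self.regions), n), dtype=float)
        for row, ri in enumerate(order):
            dists[row] = self.regions[ri].distance(points)
        best_row = np.argmin(dists, axis=0)  # argmin returns first minimum: tie rule
        best_d = dists[best_row, np.arange(n)]
        sorted_names = np.array([self.regions[ri].name for ri in order], dtype=object)
        out = sorted_names[best_row]
        out[best_d > max_snap_distance] = NO_REGION
        return out

    def mirrored(self) -> "RegionSet":
        """Reflect the region set through the mid-sagittal plane x -> -x.

        Left and right labels (and name suffixes) swap; centre regions must
        be symmetric about x=0 for the result to be valid.
        """
        swap = {"left": "right", "right": "left", "centre": "centre"}

        def swap_name(name: str, side: str) -> str:
            if side == "left" and name.endswith("_L"):
                return name[:-2] + "_R"
            if side == "right" and name.endswith("_R"):
                return name[:-2] + "_L"
            return name

        regs = [
            Region(
                name=swap_name(r.name, r.side),
                side=swap[r.side],
                lo=(-r.hi[0], r.lo[1], r.lo[2]),
                hi=(-r.lo[0], r.hi[1], r.hi[2]),
            )
            for r in self.regions
        ]
        name_map = {r.name: swap_name(r.name, r.side) for r in self.regions}
        groups = {g: [name_map[m] for m in members] for g, members in self.groups.items()}
        return RegionSet(regions=regs, groups=groups)


@dataclass(frozen=True)
class AssignConfig:
    """max_snap_distance: how far (nm) outside every region a synapse may lie
    and still be snapped to the nearest one (default 10 um)."""

    max_snap_distance: float = 10_000.0

    def __post_init__(self) -> None:
        if self.max_snap_distance < 0:
            raise ValueError("max_snap_distance must be >= 0")


def assign_synapses_to_neuropils(
    table: pd.DataFrame, regions: RegionSet, cfg: AssignConfig | None = None
) -> pd.DataFrame:
    """Assign each synapse row to a neuropil from its presynaptic location.

    A row gets the region containing its presynaptic point; failing that,
    the nearest region if within ``max_snap_distance``; otherwise it stays
    unassigned.  Returns a copy with the ``neuropil`` column filled in.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    cfg = cfg or AssignConfig()
    out = table.copy()
    if out.empty:
        out["neuropil"] = pd.Series([], dtype=object)
        return out
    pts = out[["pre_x", "pre_y", "pre_z"]].to_numpy(dtype=float)
    out["neuropil"] = regions.assign_points(pts, cfg.max_snap_distance)
    return out


def side_counts(
    neuron: int, table: pd.DataFrame, regions: RegionSet, direction: str
) -> dict[str, int]:
    """Count a neuron's assigned synapses per hemisphere side.

    ``direction="incoming"`` counts the neuron's postsynapses (rows where it
    is the postsynaptic partner); ``"outgoing"`` its presynapses.  Only
    neuropil-assigned rows are counted; an unknown neuron yields zeros.
    """
    if direction not in ("incoming", "outgoing"):
        raise ValueError("direction must be 'incoming' or 'outgoing'")
    col = "post_root_id" if direction == "incoming" else "pre_root_id"
    rows = table.loc[(table[col] == neuron) & (table["neuropil"] != NO_REGION)]
    side_of = regions.side_of()
    counts = {"left": 0, "right": 0, "centre": 0}
    for reg, n in rows["neuropil"].value_counts().items():
        counts[side_of[reg]] += int(n)
    return counts


def load_regions(path: str | Path) -> RegionSet:
    """Read region definitions from JSON.

    Schema: ``{"regions": [{"name", "side", "lo": [x,y,z], "hi": [x,y,z]}],
    "groups": {"optic_lobe": [...], ...}}`` with coordinates in nm.
    """
    with open(path) as fh:
        payload = json.load(fh)
    regs = [
        Region(name=r["name"], side=r["side"], lo=tuple(r["lo"]), hi=tuple(r["hi"]))
        for r in payload["regions"]
    ]
    return RegionSet(regions=regs, groups=payload.get("groups", {}))


def save_regions(regions: RegionSet, path: str | Path) -> None:
    payload = {
        "regions": [
            {"name": r.name, "side": r.side, "lo": list(r.lo), "hi": list(r.hi)}
            for r in regions.regions
        ],
        "groups": regions.groups,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
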
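"""Synthetic brain generator with ground truth for recovery tests.

Generates a miniature brain with the statistical structure the analysis
pipeline assumes: mirror-symmetric left/right neuropil boxes plus centre
boxes, neurons drawn from a superclass composition, polyadic presynaptic
boutons (several pre->post rows sharing one presynaptic coordinate),
heavy-tailed and correlated in/out synapse counts, cleft-score noise,
spatial near-duplicate annotations, spurious low-score rows, and — for
traversal tests — optional planted feedforward layer structure and an
optional planted neuropil->neuropil projection matrix.

Everything is deterministic given ``rng_seed``; each generation stage draws
from its own sub-stream so stages stay reproducible individually.  The
tables written by this module use the same schemas as :mod:`flybrain.io`,
so synthetic and real data are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.spatial import cKDTree

from .core import NT_LABELS, SYNAPSE_COLUMNS, UNASSIGNED_ID
from .annotation import SUPERCLASS_FLOW
from .regions import Region, RegionSet

BOX_SIZE = 40_000  # nm, edge length of a neuropil box
BOX_GAP = 6_000  # nm, spacing between stacked boxes
INTERIOR_MARGIN = 500  # nm, keep synapses strictly inside their box
DUPLICATE_MAX_OFFSET = 90  # nm, duplicates stay safely within the 100 nm radius
MIN_BOUTON_SPACING = 110  # nm, same-neuron boutons never collide with dedup
PERIPHERY_ROWS_PER_NEURON = 5  # out-of-brain synapses per non-intrinsic neuron
SECONDARY_REGION_WEIGHT = 0.15  # share of a neuron's synapses in its secondary neuropil
NT_ACCURACY = 0.87  # per-synapse probability the predicted transmitter is the true one

#: baseline per-neuron true transmitter frequencies
NT_FREQS = {"ACH": 0.55, "GABA": 0.25, "GLUT": 0.12, "DA": 0.04, "SER": 0.02, "OCT": 0.02}


# --------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class DiscretePMF:
    """Finite discrete distribution over integers: ((value, prob), ...)."""

    probs: tuple

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.probs)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")
        if any(p < 0 for _, p in self.probs):
            raise ValueError("probabilities must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return np.array([v for v, _ in self.probs])

    @property
    def p(self) -> np.ndarray:
        return np.array([p for _, p in self.probs])

    @property
    def mean(self) -> float:
        return float((self.values * self.p).sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.values, size=n, p=self.p)


@dataclass(frozen=True)
class ClippedNormalInt:
    """Rounded normal clipped to [lo, hi] (inclusive)."""

    mean: float
    sd: float
    lo: int
    hi: int

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = np.rint(rng.normal(self.mean, self.sd, size=n))
        return np.clip(draws, self.lo, self.hi).astype(int)


@dataclass(frozen=True)
class UniformInt:
    """Uniform integers on [lo, hi] inclusive."""

    lo: int
    hi: int

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.lo, self.hi + 1, size=n)


def default_polyad_dist(mean_targets: float = 5.0, max_size: int = 15) -> DiscretePMF:
    """Shifted-Poisson bouton fan-out: 1 + Poisson(mean_targets - 1), truncated."""
    sizes = np.arange(1, max_size + 1)
    p = sp_stats.poisson.pmf(sizes - 1, mean_targets - 1)
    p /= p.sum()
    return DiscretePMF(tuple(zip(sizes.tolist(), p.tolist())))


# --------------------------------------------------------------------------
# specification


def _default_composition() -> dict[str, int]:
    # scaled-down fly-like composition: ~82% intrinsic, optic-lobe heavy
    return {
        "central": 450,
        "optic": 300,
        "visual_projection": 60,
        "visual_centrifugal": 15,
        "sensory": 80,
        "ascending": 25,
        "descending": 40,
        "motor": 20,
        "endocrine": 10,
    }


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic brain.

    ``mean_out_synapses`` is the expected number of outgoing synapse rows
    per bouton-emitting neuron (intrinsic and afferent superclasses);
    per-neuron rates are heavy-tailed (lognormal) around it, with in- and
    out-rates correlated.  ``duplicate_rate`` is the probability that a
    genuine row gains a near-duplicate annotation within 100 nm of its
    presynaptic coordinate; ``noise_synapse_fraction`` the fraction of the
    final table made of spurious low-score rows.  ``planted_projectome``
    (optional, R x R row-stochastic) replaces the side-based neuropil
    choice: each intrinsic neuron then receives all inputs in one uniformly
    drawn neuropil ``a`` and sends all outputs to ``b ~ P[a]``.
    ``planted_layers`` maps neuron *index* (generation order) to an integer
    depth and rewires connectivity into a feedforward chain.
    """

    n_neuropils_per_side: int = 4
    centre_neuropils: int = 2
    neuron_counts_by_superclass: dict[str, int] = field(default_factory=_default_composition)
    mean_out_synapses: float = 200.0
    polyad_size_dist: DiscretePMF = field(default_factory=default_polyad_dist)
    score_dist_true: ClippedNormalInt = ClippedNormalInt(140.0, 40.0, 51, 255)
    score_dist_noise: UniformInt = UniformInt(0, 50)
    duplicate_rate: float = 0.05
    noise_synapse_fraction: float = 0.3
    planted_projectome: np.ndarray | None = None
    planted_layers: dict[int, int] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neuropils_per_side < 0 or self.centre_neuropils < 0:
            raise ValueError("region counts must be >= 0")
        if any(c < 0 for c in self.neuron_counts_by_superclass.values()):
            raise ValueError("neuron counts must be >= 0")
        if sum(self.neuron_counts_by_superclass.values()) == 0:
            raise ValueError("empty specification")
        for name in self.neuron_counts_by_superclass:
            if name not in SUPERCLASS_FLOW:
                raise ValueError(f"unknown superclass {name!r}")
        for p in (self.duplicate_rate, self.noise_synapse_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mean_out_synapses <= 0:
            raise ValueError("mean_out_synapses must be positive")
        if self.planted_projectome is not None:
            P = np.asarray(self.planted_projectome, dtype=float)
            r = 2 * self.n_neuropils_per_side + self.centre_neuropils
            if P.shape != (r, r):
                raise ValueError(f"planted_projectome must be {r}x{r}")
            if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("planted_projectome rows must be probability vectors")

    @property
    def n_neurons(self) -> int:
        return sum(self.neuron_counts_by_superclass.values())


@dataclass
class GroundTruth:
    """What the pipeline should recover from an uncorrupted brain."""

    true_edge_list: pd.DataFrame  # (pre_root_id, post_root_id, syn_count), >=5 synapses
    true_flow_class: dict[int, str]
    true_projectome: np.ndarray  # over the RegionSet's neuropil order
    true_layer_depth: dict[int, int]
    injected_duplicates: set[int]  # record ids of near-duplicate annotations
    injected_noise: set[int]  # record ids of spurious rows
    true_nt: dict[int, str]  # emitting neuron -> true transmitter
    contributing_intrinsic: int  # neurons entering the true projectome


# --------------------------------------------------------------------------
# layout


def make_regions(n_per_side: int, n_centre: int) -> RegionSet:
    """Mirror-symmetric axis-aligned box layout.

    Left boxes sit at x < 0, their right twins are mirror images at x > 0,
    centre boxes straddle x = 0; boxes stack along y.  When there are at
    least two pairs the last pair (``OL_L``/``OL_R``) models the optic
    lobes; everything else is the central brain.
    """
    if n_per_side == 0 and n_centre == 0:
        raise ValueError("need at least one region")
    step = BOX_SIZE + BOX_GAP
    regions: list[Region] = []
    for i in range(n_per_side):
        stem = "OL" if (n_per_side >= 2 and i == n_per_side - 1) else f"NP{i + 1}"
        y0 = i * step
        regions.append(
            Region(f"{stem}_L", "left", (-BOX_SIZE - BOX_GAP // 2, y0, 0),
                   (-BOX_GAP // 2, y0 + BOX_SIZE, BOX_SIZE))
        )
        regions.append(
            Region(f"{stem}_R", "right", (BOX_GAP // 2, y0, 0),
                   (BOX_SIZE + BOX_GAP // 2, y0 + BOX_SIZE, BOX_SIZE))
        )
    for i in range(n_centre):
        y0 = (n_per_side + i) * step
        regions.append(
            Region(f"CNP{i + 1}", "centre", (-BOX_SIZE // 2, y0, 0),
                   (BOX_SIZE // 2, y0 + BOX_SIZE, BOX_SIZE))
        )
    names = [r.name for r in regions]
    optic = [n for n in names if n.startswith("OL_")]
    central = [n for n in names if not n.startswith("OL_")]
    groups = {"optic_lobe": optic, "central_brain": central}
    return RegionSet(regions=regions, groups=groups)


def _uniform_in_region(rng: np.random.Generator, region: Region, n: int) -> np.ndarray:
    lo = np.asarray(region.lo) + INTERIOR_MARGIN
    hi = np.asarray(region.hi) - INTERIOR_MARGIN
    return rng.integers(lo, hi + 1, size=(n, 3))


# --------------------------------------------------------------------------
# generation


def _assign_neuron_regions(spec, rng, regions, sides, superclasses):
    """Primary/secondary input and output neuropils per neuron.

    Without a planted projectome: optic-superclass neurons live in their
    own side's optic lobe, visual projection/centrifugal neurons bridge
    optic and central, everything else sits in central-brain regions with a
    bias to its own side and a secondary region elsewhere.  With a planted
    projectome, intrinsic neurons get pure single-region vectors drawn from
    it.
    """
    names = regions.names
    n = len(superclasses)
    side_of = regions.side_of()
    optic = regions.group("optic_lobe") or names
    central = regions.group("central_brain") or names

    def pool(kind: str, side: str) -> list[str]:
        base = optic if kind == "optic" else central
        own = [r for r in base if side_of[r] in (side, "centre")]
        return own or base

    in_primary = np.empty(n, dtype=object)
    in_secondary = np.empty(n, dtype=object)
    out_primary = np.empty(n, dtype=object)
    out_secondary = np.empty(n, dtype=object)

    if spec.planted_projectome is not None:
        P = np.asarray(spec.planted_projectome, dtype=float)
        a = rng.integers(0, len(names), size=n)
        b = np.array([rng.choice(len(names), p=P[ai]) for ai in a])
        for i in range(n):
            in_primary[i] = names[a[i]]
            out_primary[i] = names[b[i]]
            in_secondary[i] = None
            out_secondary[i] = None
        return in_primary, in_secondary, out_primary, out_secondary

    kind_in = {"optic": "optic", "visual_projection": "optic", "visual_centrifugal": "central"}
    kind_out = {"optic": "optic", "visual_projection": "central", "visual_centrifugal": "optic"}
    for i, (sc, side) in enumerate(zip(superclasses, sides)):
        pin = pool(kind_in.get(sc, "central"), side)
        pout = pool(kind_out.get(sc, "central"), side)
        in_primary[i] = pin[rng.integers(len(pin))]
        out_primary[i] = pout[rng.integers(len(pout))]
        alt_in = [r for r in pin if r != in_primary[i]]
        alt_out = [r for r in pout if r != out_primary[i]]
        in_secondary[i] = alt_in[rng.integers(len(alt_in))] if alt_in else None
        out_secondary[i] = alt_out[rng.integers(len(alt_out))] if alt_out else None
    return in_primary, in_secondary, out_primary, out_secondary


def _spaced_bouton_positions(rng, regions_per_bouton, region_lookup, owner):
    """Uniform positions inside each bouton's box, resampled until no two
    boutons of the same neuron are within MIN_BOUTON_SPACING nm."""
    n = len(regions_per_bouton)
    pos = np.empty((n, 3), dtype=np.int64)
    for reg_name in pd.unique(regions_per_bouton):
        mask = regions_per_bouton == reg_name
        pos[mask] = _uniform_in_region(rng, region_lookup[reg_name], int(mask.sum()))
    # collisions between same-neuron boutons are ~1e-7 likely; fix the rare ones
    for _ in range(32):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=MIN_BOUTON_SPACING, output_type="ndarray")
        if len(pairs) == 0:
            break
        bad = pairs[owner[pairs[:, 0]] == owner[pairs[:, 1]]]
        if len(bad) == 0:
            break
        redo = np.unique(bad[:, 1])
        for i in redo:
            pos[i] = _uniform_in_region(rng, region_lookup[regions_per_bouton[i]], 1)[0]
    return pos


def _ball_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform integer offsets within a ball of the given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return np.rint(v * r[:, None]).astype(np.int64)


def _draw_unique_partners(slots, draw, rng, max_iter: int = 40) -> np.ndarray:
    """Draw one partner per slot so that partners are distinct within each
    bouton (slot group), redrawing collisions.

    Redrawing (rather than dropping) keeps the total record count intact.
    Slots that still collide after ``max_iter`` redraws (possible only when
    a bouton wants more distinct partners than exist) come back as -1.
    """
    partners = draw(len(slots))
    base = 2**31  # partner ids are far below this
    for _ in range(max_iter):
        key = slots.astype(np.int64) * base + partners
        order = np.argsort(key, kind="stable")
        sk = key[order]
        dup_sorted = np.zeros(len(key), dtype=bool)
        dup_sorted[1:] = sk[1:] == sk[:-1]
        dup_idx = order[dup_sorted]
        if len(dup_idx) == 0:
            return partners
        partners[dup_idx] = draw(len(dup_idx))
    # unresolved collisions: invalidate the extra occurrences
    key = slots.astype(np.int64) * base + partners
    order = np.argsort(key, kind="stable")
    sk = key[order]
    dup_sorted = np.zeros(len(key), dtype=bool)
    dup_sorted[1:] = sk[1:] == sk[:-1]
    partners[order[dup_sorted]] = -1
    return partners


def generate_brain(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, RegionSet, GroundTruth]:
    """Generate a synthetic brain.

    Returns ``(synapse_table, neuron_table, regions, ground_truth)``.  The
    synapse table carries an extra ``bouton_id`` column (-1 for duplicate,
    noise and out-of-brain rows) so the polyadic structure is inspectable.
    """
    streams = np.random.SeedSequence(spec.rng_seed).spawn(8)
    rng_attr, rng_bout, rng_part, rng_score, rng_nt, rng_noise, rng_dup, rng_peri = (
        np.random.default_rng(s) for s in streams
    )

    regions = make_regions(spec.n_neuropils_per_side, spec.centre_neuropils)
    region_lookup = {r.name: r for r in regions.regions}

    # ---- neurons -----------------------------------------------------------
    superclasses = np.concatenate(
        [np.full(c, sc, dtype=object) for sc, c in sorted(spec.neuron_counts_by_superclass.items())]
    )
    n = len(superclasses)
    root_ids = 10_001 + np.arange(n)
    flows = np.array([SUPERCLASS_FLOW[sc] for sc in superclasses], dtype=object)
    sides = rng_attr.choice(["left", "right"], size=n)
    soma_inside = flows != "afferent"

    # heavy-tailed, correlated in/out activity (lognormal, rho ~ 0.6)
    z = rng_attr.multivariate_normal([0.0, 0.0], [[1.0, 0.6], [0.6, 1.0]], size=n)
    out_w = np.exp(z[:, 0])
    in_w = np.exp(z[:, 1])

    emitters = (flows == "intrinsic") | (flows == "afferent")  # boutons inside the brain
    receivers = (flows == "intrinsic") | (flows == "efferent")  # targets inside the brain
    if spec.planted_layers is not None:
        depth = np.array([spec.planted_layers.get(i, 0) for i in range(n)])
        max_depth = depth.max() if n else 0
        emitters = emitters & (depth < max_depth)
        receivers = receivers & (depth > 0)

    # normalise so expected total rows = mean_out_synapses * n_emitters exactly
    lam = np.zeros(n)
    if emitters.any():
        w = out_w[emitters]
        lam[emitters] = spec.mean_out_synapses * w * emitters.sum() / w.sum()

    true_nt = dict(
        zip(
            root_ids[emitters].tolist(),
            rng_nt.choice(list(NT_FREQS), size=int(emitters.sum()), p=list(NT_FREQS.values())),
        )
    )

    in_primary, in_secondary, out_primary, out_secondary = _assign_neuron_regions(
        spec, rng_attr, regions, sides, superclasses
    )

    # ---- boutons -----------------------------------------------------------
    # Draw the total row count (Poisson), cut it into iid polyad-sized
    # boutons (at most one truncated bouton overall, so the empirical fan-out
    # distribution stays faithful), then hand boutons to neurons with
    # probability proportional to their heavy-tailed activity.
    total_rows = int(rng_bout.poisson(lam.sum())) if lam.sum() > 0 else 0
    if total_rows > 0:
        mean_k = spec.polyad_size_dist.mean
        sizes_list = []
        drawn = 0
        while drawn < total_rows:
            batch = spec.polyad_size_dist.sample(
                rng_bout, max(int((total_rows - drawn) / mean_k * 1.1) + 16, 16)
            ).astype(int)
            sizes_list.append(batch)
            drawn += int(batch.sum())
        sizes_all = np.concatenate(sizes_list)
        cum = np.cumsum(sizes_all)
        k = int(np.searchsorted(cum, total_rows)) + 1
        bouton_sizes = sizes_all[:k].copy()
        bouton_sizes[-1] -= int(cum[k - 1] - total_rows)
        bouton_owner = rng_bout.choice(n, size=len(bouton_sizes), p=lam / lam.sum())
    else:
        bouton_sizes = np.empty(0, dtype=np.int64)
        bouton_owner = np.empty(0, dtype=np.int64)
    n_boutons = len(bouton_owner)

    # bouton neuropil: primary out-region, or the secondary with small probability
    bouton_region = np.array([out_primary[i] for i in bouton_owner], dtype=object)
    has_secondary = np.array([out_secondary[i] is not None for i in bouton_owner])
    use_secondary = has_secondary & (rng_bout.random(n_boutons) < SECONDARY_REGION_WEIGHT)
    bouton_region[use_secondary] = [out_secondary[i] for i in bouton_owner[use_secondary]]

    bouton_pos = (
        _spaced_bouton_positions(rng_bout, bouton_region, region_lookup, bouton_owner)
        if n_boutons
        else np.empty((0, 3), dtype=np.int64)
    )

    # ---- partners ----------------------------------------------------------
    # candidate receivers per region, weighted by in-activity and by whether
    # the region is the receiver's primary or secondary input neuropil
    cand_ids: dict[str, np.ndarray] = {}
    cand_p: dict[str, np.ndarray] = {}
    for reg in regions.names:
        ids, wts = [], []
        for i in np.flatnonzero(receivers):
            if in_primary[i] == reg:
                share = 1.0 if in_secondary[i] is None else 1.0 - SECONDARY_REGION_WEIGHT
            elif in_secondary[i] == reg:
                share = SECONDARY_REGION_WEIGHT
            else:
                continue
            ids.append(i)
            wts.append(share * in_w[i])
        if ids:
            p = np.array(wts)
            cand_ids[reg] = np.array(ids)
            cand_p[reg] = p / p.sum()

    depth_arr = None
    if spec.planted_layers is not None:
        depth_arr = np.array([spec.planted_layers.get(i, 0) for i in range(n)])

    rec_pre: list[np.ndarray] = []
    rec_post: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    rec_bouton: list[np.ndarray] = []
    slot_bouton_all = np.repeat(np.arange(n_boutons), bouton_sizes)
    slot_region_all = bouton_region[slot_bouton_all] if n_boutons else np.empty(0, dtype=object)
    for reg in pd.unique(bouton_region) if n_boutons else []:
        slots = slot_bouton_all[slot_region_all == reg]
        if len(slots) == 0:
            continue
        if depth_arr is not None:
            # feedforward rewiring: target the next layer, ignore regions
            owners = bouton_owner[slots]
            partners = np.full(len(slots), -1, dtype=np.int64)
            for d in np.unique(depth_arr[owners]):
                cand = np.flatnonzero(receivers & (depth_arr == d + 1))
                sl = np.flatnonzero(depth_arr[owners] == d)
                if len(cand):
                    p = in_w[cand] / in_w[cand].sum()

                    def draw(k, cand=cand, p=p):
                        return rng_part.choice(cand, size=k, p=p)

                    partners[sl] = _draw_unique_partners(slots[sl], draw, rng_part)
            ok = partners >= 0
            slots, partners = slots[ok], partners[ok]
        else:
            if reg not in cand_ids:
                continue

            def draw(k, reg=reg):
                return rng_part.choice(cand_ids[reg], size=k, p=cand_p[reg])

            partners = _draw_unique_partners(slots, draw, rng_part)
            ok = partners >= 0
            slots, partners = slots[ok], partners[ok]
        rec_pre.append(bouton_owner[slots])
        rec_post.append(partners)
        rec_pos.append(bouton_pos[slots])
        rec_bouton.append(slots)

    if rec_pre:
        pre_idx = np.concatenate(rec_pre)
        post_idx = np.concatenate(rec_post)
        pre_xyz = np.concatenate(rec_pos)
        bouton_of_row = np.concatenate(rec_bouton)
        order = np.argsort(bouton_of_row, kind="stable")
        pre_idx, post_idx, pre_xyz, bouton_of_row = (
            pre_idx[order], post_idx[order], pre_xyz[order], bouton_of_row[order]
        )
    else:
        pre_idx = post_idx = bouton_of_row = np.empty(0, dtype=np.int64)
        pre_xyz = np.empty((0, 3), dtype=np.int64)

    n_true = len(pre_idx)
    post_xyz = pre_xyz + rng_part.integers(-300, 301, size=(n_true, 3))
    scores = spec.score_dist_true.sample(rng_score, n_true)

    # transmitter predictions: correct with NT_ACCURACY, else a random other label
    true_labels = np.array([true_nt[root_ids[i]] for i in pre_idx], dtype=object)
    flip = rng_nt.random(n_true) >= NT_ACCURACY
    wrong = rng_nt.choice(NT_LABELS, size=n_true)
    nt_pred = np.where(flip, wrong, true_labels)
    same = nt_pred == true_labels
    nt_pred[flip & same] = np.roll(NT_LABELS, 1)[
        [NT_LABELS.index(x) for x in nt_pred[flip & same]]
    ]
    nt_prob = np.round(0.5 + 0.5 * rng_nt.random(n_true), 4)

    frames = [
        pd.DataFrame(
            {
                "pre_root_id": root_ids[pre_idx],
                "post_root_id": root_ids[post_idx],
                "pre_x": pre_xyz[:, 0], "pre_y": pre_xyz[:, 1], "pre_z": pre_xyz[:, 2],
                "post_x": post_xyz[:, 0], "post_y": post_xyz[:, 1], "post_z": post_xyz[:, 2],
                "score": scores,
                "neuropil": "",
                "nt_type": nt_pred,
                "nt_prob": nt_prob,
                "bouton_id": bouton_of_row,
            }
        )
    ]

    # ---- out-of-brain rows for non-intrinsic neurons -----------------------
    non_intr = np.flatnonzero(flows != "intrinsic")
    if len(non_intr):
        aff = np.flatnonzero(flows == "afferent")
        eff = np.flatnonzero(flows == "efferent")
        pre_list, post_list = [], []
        for i in non_intr:
            if flows[i] == "afferent":  # its inputs lie outside the brain
                partners = eff if len(eff) else aff
                pre_list.append(rng_peri.choice(partners, size=PERIPHERY_ROWS_PER_NEURON))
                post_list.append(np.full(PERIPHERY_ROWS_PER_NEURON, i))
            else:  # efferent: outputs outside the brain
                partners = aff if len(aff) else eff
                pre_list.append(np.full(PERIPHERY_ROWS_PER_NEURON, i))
                post_list.append(rng_peri.choice(partners, size=PERIPHERY_ROWS_PER_NEURON))
        p_pre = np.concatenate(pre_list)
        p_post = np.concatenate(post_list)
        m = len(p_pre)
        # a far-away grid, > 10 um from every region, 1 um pitch
        gx = (np.arange(m) % 1000) * 1000 - 500_000
        gz = (np.arange(m) // 1000) * 1000
        peri_xyz = np.stack([gx, np.full(m, -300_000), gz], axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "pre_root_id": root_ids[p_pre],
                    "post_root_id": root_ids[p_post],
                    "pre_x": peri_xyz[:, 0], "pre_y": peri_xyz[:, 1], "pre_z": peri_xyz[:, 2],
                    "post_x": peri_xyz[:, 0] + 200, "post_y": peri_xyz[:, 1], "post_z": peri_xyz[:, 2],
                    "score": spec.score_dist_true.sample(rng_peri, m),
                    "neuropil": "",
                    "nt_type": "",
                    "nt_prob": np.nan,
                    "bouton_id": -1,
                }
            )
        )

    true_table = pd.concat(frames, ignore_index=True)
    true_table.insert(0, "record_id", 1 + np.arange(len(true_table)))

    # ---- near-duplicate annotations ----------------------------------------
    parts = [true_table]
    next_id = len(true_table) + 1
    injected_duplicates: set[int] = set()
    if spec.duplicate_rate > 0 and len(true_table):
        is_dup = rng_dup.random(len(true_table)) < spec.duplicate_rate
        parents = true_table.loc[is_dup]
        if len(parents):
            dup = parents.copy()
            off = _ball_offsets(rng_dup, len(dup), DUPLICATE_MAX_OFFSET)
            dup[["pre_x", "pre_y", "pre_z"]] += off
            dup[["post_x", "post_y", "post_z"]] += off
            # never outscore the parent, so the parent survives deduplication
            dup["score"] = rng_dup.integers(51, parents["score"].to_numpy() + 1)
            dup["record_id"] = next_id + np.arange(len(dup))
            dup["bouton_id"] = -1
            injected_duplicates = set(dup["record_id"].tolist())
            next_id += len(dup)
            parts.append(dup)

    # ---- spurious low-score rows -------------------------------------------
    injected_noise: set[int] = set()
    if spec.noise_synapse_fraction > 0:
        m = int(round(
            spec.noise_synapse_fraction / (1 - spec.noise_synapse_fraction) * len(true_table)
        ))
        if m:
            reg_choice = rng_noise.integers(0, len(regions.regions), size=m)
            pos = np.empty((m, 3), dtype=np.int64)
            for ri in np.unique(reg_choice):
                mask = reg_choice == ri
                pos[mask] = _uniform_in_region(rng_noise, regions.regions[ri], int(mask.sum()))
            pre_ids = root_ids[rng_noise.integers(0, n, size=m)].astype(np.int64)
            post_ids = root_ids[rng_noise.integers(0, n, size=m)].astype(np.int64)
            # a share of spurious rows is also unattached to any segment
            drop_side = rng_noise.random(m)
            pre_ids[drop_side < 0.15] = UNASSIGNED_ID
            post_ids[(drop_side >= 0.15) & (drop_side < 0.3)] = UNASSIGNED_ID
            noise = pd.DataFrame(
                {
                    "record_id": next_id + np.arange(m),
                    "pre_root_id": pre_ids,
                    "post_root_id": post_ids,
                    "pre_x": pos[:, 0], "pre_y": pos[:, 1], "pre_z": pos[:, 2],
                    "post_x": pos[:, 0] + 100, "post_y": pos[:, 1], "post_z": pos[:, 2],
                    "score": spec.score_dist_noise.sample(rng_noise, m),
                    "neuropil": "",
                    "nt_type": "",
                    "nt_prob": np.nan,
                    "bouton_id": -1,
                }
            )
            injected_noise = set(noise["record_id"].tolist())
            next_id += m
            parts.append(noise)

    synapses = pd.concat(parts, ignore_index=True)
    synapses = synapses[SYNAPSE_COLUMNS + ["bouton_id"]]

    neurons = pd.DataFrame(
        {
            "root_id": root_ids,
            "flow": flows,
            "superclass": superclasses,
            "side": sides,
            "soma_inside": soma_inside,
            "nt_type": [true_nt.get(r, "") for r in root_ids],
        }
    )

    ground_truth = _build_ground_truth(
        spec, regions, root_ids, flows, true_table, pre_idx, post_idx, bouton_region,
        bouton_of_row, injected_duplicates, injected_noise, true_nt,
    )
    return synapses, neurons, regions, ground_truth


def _build_ground_truth(
    spec, regions, root_ids, flows, true_table, pre_idx, post_idx,
    bouton_region, bouton_of_row, injected_duplicates, injected_noise, true_nt,
) -> GroundTruth:
    # connection list over genuine rows, at the standard >=5 synapse threshold
    agg = (
        true_table.groupby(["pre_root_id", "post_root_id"], sort=True)
        .size()
        .rename("syn_count")
        .reset_index()
    )
    true_edges = agg.loc[agg["syn_count"] >= 5].reset_index(drop=True)

    flow_map = dict(zip(root_ids.tolist(), flows.tolist()))

    # projectome over intrinsic neurons from the genuine in-brain rows
    name_idx = {nm: k for k, nm in enumerate(regions.names)}
    r = len(regions)
    n = len(root_ids)
    in_counts = np.zeros((n, r))
    out_counts = np.zeros((n, r))
    row_region = np.array([name_idx[bouton_region[b]] for b in bouton_of_row], dtype=int)
    np.add.at(out_counts, (pre_idx, row_region), 1)
    np.add.at(in_counts, (post_idx, row_region), 1)
    intr = flows == "intrinsic"
    contrib = intr & (in_counts.sum(axis=1) > 0) & (out_counts.sum(axis=1) > 0)
    proj = np.zeros((r, r))
    if contrib.any():
        fin = in_counts[contrib] / in_counts[contrib].sum(axis=1, keepdims=True)
        fout = out_counts[contrib] / out_counts[contrib].sum(axis=1, keepdims=True)
        proj = fin.T @ fout

    depth_map = {}
    if spec.planted_layers is not None:
        depth_map = {
            int(root_ids[i]): int(d) for i, d in spec.planted_layers.items() if i < len(root_ids)
        }

    return GroundTruth(
        true_edge_list=true_edges,
        true_flow_class=flow_map,
        true_projectome=proj,
        true_layer_depth=depth_map,
        injected_duplicates=injected_duplicates,
        injected_noise=injected_noise,
        true_nt=true_nt,
        contributing_intrinsic=int(contrib.sum()),
    )


# --------------------------------------------------------------------------
# layered fixture networks


def generate_layered_network(
    n_layers: int, width: int, p_skip: float, rng_seed: int
) -> tuple[pd.DataFrame, set[int], dict[int, int]]:
    """Feedforward fixture network for traversal tests.

    Neurons sit in ``n_layers`` layers of ``width`` nodes; every node in
    layer k >= 1 receives connections from the previous layer only, except
    that with probability ``p_skip`` a node (k >= 2) gains one extra
    connection from a random earlier layer.  With ``p_skip=0`` all of a
    node's inputs come from layer k-1, so the traversal model reaches it at
    round k deterministically.

    Returns ``(edge_list, seeds, true_layer_depth)``.
    """
    if n_layers < 2 or width < 1:
        raise ValueError("need n_layers >= 2 and width >= 1")
    rng = np.random.default_rng(rng_seed)
    node_id = lambda k, j: k * width + j + 1  # noqa: E731
    rows = []
    for k in range(1, n_layers):
        prev = [node_id(k - 1, j) for j in range(width)]
        for j in range(width):
            target = node_id(k, j)
            n_par = 1 + rng.integers(0, min(3, width))
            for p in rng.choice(prev, size=min(n_par, width), replace=False):
                rows.append((int(p), target, int(rng.integers(5, 16))))
            if k >= 2 and rng.random() < p_skip:
                src_layer = int(rng.integers(0, k - 1))
                src = node_id(src_layer, int(rng.integers(0, width)))
                rows.append((src, target, int(rng.integers(5, 16))))
    edges = pd.DataFrame(rows, columns=["pre_root_id", "post_root_id", "syn_count"])
    edges = edges.groupby(["pre_root_id", "post_root_id"], as_index=False)["syn_count"].sum()
    seeds = {node_id(0, j) for j in range(width)}
    depths = {node_id(k, j): k for k in range(n_layers) for j in range(width)}
    return edges, seeds, depths
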
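"""Probabilistic information-flow traversal over the connection graph.

Starting from a seed set (for example one sensory modality's afferent
neurons), the model grows a traversed set in discrete rounds.  Each round,
an untraversed neuron that receives a fraction ``f`` of its incoming
synapses from already-traversed neurons is added independently with
probability ``min(f / tau, 1)``: the likelihood rises linearly with the
traversed-input fraction and saturates at 1 once ``f`` reaches the
saturation fraction ``tau`` (default 0.3).  A neuron's traversal distance
is the round in which it was added (seeds are round 0); averaging over many
runs yields a mean distance per neuron, which is rounded to a layer and
converted to a rank percentile.  Stacking the rank vectors of several seed
sets gives a per-neuron embedding.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class TraversalConfig:
    """Parameters of the traversal model.

    saturation_fraction
        Traversed-input fraction at which per-round addition becomes
        certain (tau, default 0.3).
    n_runs
        Monte-Carlo repetitions averaged into mean distances.
    max_rounds
        Cap on rounds per run; ``None`` means one round per neuron.
    unreached_distance_rule
        Distance assigned to neurons never traversed in a run:
        ``"rounds_plus_one"`` (one past the run's last round, keeps means
        finite) or ``"infinity"``.
    """

    saturation_fraction: float = 0.3
    n_runs: int = 10_000
    max_rounds: int | None = None
    unreached_distance_rule: str = "rounds_plus_one"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.saturation_fraction <= 1:
            raise ValueError("saturation_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.unreached_distance_rule not in ("rounds_plus_one", "infinity"):
            raise ValueError("unknown unreached_distance_rule")


def traversal_probability(f, tau: float = 0.3):
    """Per-round addition probability for traversed-input fraction ``f``.

    Linear from p(0)=0 up to p(tau)=1 and saturated at 1 beyond.
    """
    return np.minimum(np.asarray(f, dtype=float) / tau, 1.0)


@dataclass
class TraversalResult:
    """Per-neuron traversal statistics for one seed set."""

    table: pd.DataFrame  # neuron, mean_distance, layer, rank, percentile
    seed_label: str = ""

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class RankEmbedding:
    """neurons x modalities matrix of traversal ranks."""

    ranks: pd.DataFrame  # index: neuron, columns: modality labels
    results: dict[str, TraversalResult] = field(default_factory=dict)

    @property
    def modalities(self) -> list[str]:
        return list(self.ranks.columns)


class _Graph:
    """Incoming-synapse structure of a collapsed edge list.

    The node set is the union of edge endpoints and seeds, so seed neurons
    without surviving connections still take part (at distance 0).
    """

    def __init__(self, edges: pd.DataFrame, seeds=()):
        nodes = pd.Index(
            np.union1d(
                np.union1d(edges["pre_root_id"].unique(), edges["post_root_id"].unique()),
                np.asarray(sorted(seeds), dtype=edges["pre_root_id"].dtype)
                if len(list(seeds))
                else [],
            )
        )
        self.nodes = nodes
        pre = nodes.get_indexer(edges["pre_root_id"])
        post = nodes.get_indexer(edges["post_root_id"])
        w = edges["syn_count"].to_numpy(dtype=float)
        n = len(nodes)
        # column j = synapses contributed by presynaptic neuron j
        self.a_csc = sparse.csc_matrix((w, (post, pre)), shape=(n, n))
        self.in_total = np.asarray(self.a_csc.sum(axis=1)).ravel()

    def seed_mask(self, seeds) -> np.ndarray:
        idx = self.nodes.get_indexer(pd.Index(list(seeds)))
        if (idx < 0).any():
            missing = [s for s, i in zip(seeds, idx) if i < 0]
            raise ValueError(f"seeds not in graph: {missing}")
        mask = np.zeros(len(self.nodes), dtype=bool)
        mask[idx] = True
        return mask


def _single_run(
    graph: _Graph, seed_mask: np.ndarray, cfg: TraversalConfig, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic traversal; returns the per-node distance vector."""
    n = len(graph.nodes)
    tau = cfg.saturation_fraction
    max_rounds = cfg.max_rounds if cfg.max_rounds is not None else n
    dist = np.full(n, np.inf)
    dist[seed_mask] = 0.0
    traversed = seed_mask.copy()
    counts = np.asarray(graph.a_csc[:, traversed].sum(axis=1)).ravel()
    pos = graph.in_total > 0
    rounds_done = 0
    for r in range(1, max_rounds + 1):
        f = np.zeros(n)
        f[pos] = counts[pos] / graph.in_total[pos]
        p = np.minimum(f / tau, 1.0)
        p[traversed] = 0.0
        if not (p > 0).any():
            break
        rounds_done = r
        newly = rng.random(n) < p
        if newly.any():
            dist[newly] = r
            traversed |= newly
            counts += np.asarray(graph.a_csc[:, newly].sum(axis=1)).ravel()
        if traversed.all():
            break
    if cfg.unreached_distance_rule == "rounds_plus_one":
        dist[np.isinf(dist)] = rounds_done + 1
    return dist


def _run_rng(rng_seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=rng_seed, spawn_key=(run_index,)))


def traversal_run(
    edges: pd.DataFrame, seeds, cfg: TraversalConfig | None = None, run_index: int = 0
) -> dict[int, float]:
    """One traversal over the edge list; deterministic in (rng_seed, run_index)."""
    cfg = cfg or TraversalConfig()
    if not len(list(seeds)):
        raise ValueError("no seeds")
    graph = _Graph(edges, seeds)
    dist = _single_run(graph, graph.seed_mask(seeds), cfg, _run_rng(cfg.rng_seed, run_index))
    return dict(zip(graph.nodes.tolist(), dist.tolist()))


def traversal_distances(
    edges: pd.DataFrame,
    seeds,
    cfg: TraversalConfig | None = None,
    seed_label: str = "",
    extra_nodes=(),
) -> TraversalResult:
    """Mean traversal distance, layer, rank and percentile per neuron.

    Distances are averaged over ``cfg.n_runs`` independent runs.  Layers
    round the mean to the nearest integer (halves away from zero); ranks
    sort by ascending mean distance with neuron-id tie-break, and the
    percentile spreads ranks evenly over [0, 100].  ``extra_nodes`` widens
    the analysed population beyond the edge endpoints (used to keep all
    modalities of an embedding on one universe).
    """
    cfg = cfg or TraversalConfig()
    seeds = list(seeds)
    if not seeds:
        raise ValueError("no seeds")
    graph = _Graph(edges, set(seeds) | set(extra_nodes))
    seed_mask = graph.seed_mask(seeds)
    total = np.zeros(len(graph.nodes))
    for i in range(cfg.n_runs):
        total += _single_run(graph, seed_mask, cfg, _run_rng(cfg.rng_seed, i))
    mean = total / cfg.n_runs

    neurons = graph.nodes.to_numpy()
    order = np.lexsort((neurons, mean))
    rank = np.empty(len(neurons), dtype=int)
    rank[order] = np.arange(len(neurons))
    denom = max(len(neurons) - 1, 1)
    percentile = 100.0 * rank / denom
    with np.errstate(invalid="ignore"):
        layer = np.where(np.isfinite(mean), np.floor(np.abs(mean) + 0.5) * np.sign(mean), np.inf)
    table = pd.DataFrame(
        {
            "neuron": neurons,
            "mean_distance": mean,
            "layer": layer,
            "rank": rank,
            "percentile": percentile,
        }
    ).sort_values("rank", ignore_index=True)
    return TraversalResult(table=table, seed_label=seed_label)


def _modality_seed(rng_seed: int, seeds) -> int:
    """Deterministic per-modality RNG seed from the seed *set* itself, so
    identical seed sets give identical results and different sets are
    decorrelated."""
    payload = ",".join(str(s) for s in sorted(seeds)).encode()
    return zlib.crc32(payload)


def build_rank_embedding(
    edges: pd.DataFrame, seed_sets: dict[str, set], cfg: TraversalConfig | None = None
) -> RankEmbedding:
    """Run the traversal for every modality and stack the rank columns."""
    cfg = cfg or TraversalConfig()
    if not seed_sets:
        raise ValueError("at least one seed set required")
    for label, seeds in seed_sets.items():
        if not len(list(seeds)):
            raise ValueError(f"empty seed set for modality {label!r}")
    universe: set = set()
    for seeds in seed_sets.values():
        universe |= set(seeds)
    results: dict[str, TraversalResult] = {}
    columns = {}
    for label, seeds in seed_sets.items():
        sub_cfg = TraversalConfig(
            saturation_fraction=cfg.saturation_fraction,
            n_runs=cfg.n_runs,
            max_rounds=cfg.max_rounds,
            unreached_distance_rule=cfg.unreached_distance_rule,
            rng_seed=int(
                np.random.SeedSequence(
                    entropy=cfg.rng_seed, spawn_key=(_modality_seed(cfg.rng_seed, seeds),)
                ).generate_state(1)[0]
            ),
        )
        res = traversal_distances(edges, seeds, sub_cfg, seed_label=label, extra_nodes=universe)
        results[label] = res
        columns[label] = res.table.set_index("neuron")["rank"]
    ranks = pd.DataFrame(columns)
    return RankEmbedding(ranks=ranks, results=results)


#: 2-D projection parameters used for the rank embedding
UMAP_PARAMS = dict(
    n_components=2,
    min_dist=0.35,
    metric="cosine",
    n_neighbors=50,
    learning_rate=0.1,
    n_epochs=1000,
)


def umap_project(embedding: RankEmbedding, rng_seed: int = 0, **overrides) -> pd.DataFrame:
    """Project the rank embedding to 2-D with UMAP (cosine metric).

    Parameters default to :data:`UMAP_PARAMS`; ``rng_seed`` fixes the
    layout.  Requires at least ``n_neighbors + 1`` neurons.
    """
    params = {**UMAP_PARAMS, **overrides}
    n = len(embedding.ranks)
    if n < params["n_neighbors"] + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params['n_neighbors'] + 1} neurons, have {n}; "
            "reduce n_neighbors"
        )
    import umap

    reducer = umap.UMAP(random_state=rng_seed, **params)
    coords = reducer.fit_transform(embedding.ranks.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=embedding.ranks.index, columns=["umap_x", "umap_y"])
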
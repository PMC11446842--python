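"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal route possible
(all-pairs distances, exhaustive state enumeration) so they stay independent
of the library's implementation choices.
"""

from itertools import combinations

import numpy as np


def greedy_dedup_oracle(table, radius):
    """Brute-force per-pair greedy sweep with all-pairs distances.

    Returns the set of kept record_ids.  Sweep order: descending score,
    ties by ascending record_id.
    """
    kept = set()
    for _, grp in table.groupby(["pre_root_id", "post_root_id"]):
        rows = grp.sort_values(["score", "record_id"], ascending=[False, True])
        accepted = []
        for _, row in rows.iterrows():
            c = np.array([row["pre_x"], row["pre_y"], row["pre_z"]], dtype=float)
            if all(np.linalg.norm(c - a) > radius for a in accepted):
                accepted.append(c)
                kept.add(int(row["record_id"]))
    return kept


def traversal_expectations(edges, seeds, tau, max_rounds, tol=1e-13):
    """Exhaustive Markov-chain expectation of traversal distances.

    Enumerates the distribution over traversed-set states round by round;
    every untraversed node with traversed-input fraction f joins
    independently with probability min(f/tau, 1).  Nodes not yet traversed
    when the chain is truncated at ``max_rounds`` get distance
    ``max_rounds + 1`` (the finite-distance rule).  Returns (E[d], E[d^2])
    arrays over sorted node order.
    """
    nodes = sorted(set(edges["pre_root_id"]) | set(edges["post_root_id"]))
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for pre, post, syn in edges[["pre_root_id", "post_root_id", "syn_count"]].itertuples(index=False):
        w[idx[post], idx[pre]] += syn
    in_tot = w.sum(axis=1)

    seed_mask = 0
    for s in seeds:
        seed_mask |= 1 << idx[s]

    def probs(state):
        out = {}
        for i in range(n):
            if state >> i & 1 or in_tot[i] == 0:
                continue
            f = sum(w[i, j] for j in range(n) if state >> j & 1) / in_tot[i]
            p = min(f / tau, 1.0)
            if p > 0:
                out[i] = p
        return out

    trans_cache = {}

    def transitions(state):
        if state in trans_cache:
            return trans_cache[state]
        p = probs(state)
        cand = list(p)
        out = []
        for k in range(len(cand) + 1):
            for subset in combinations(cand, k):
                pr = 1.0
                for i in cand:
                    pr *= p[i] if i in subset else 1 - p[i]
                if pr > 0:
                    new = state
                    for i in subset:
                        new |= 1 << i
                    out.append((new, frozenset(subset), pr))
        trans_cache[state] = out
        return out

    e1 = np.zeros(n)
    e2 = np.zeros(n)
    dist = {seed_mask: 1.0}
    for r in range(1, max_rounds + 1):
        new_dist = {}
        for state, mass in dist.items():
            if mass < tol:
                continue
            trs = transitions(state)
            if len(trs) == 1 and not trs[0][1]:  # absorbing: no candidates
                new_dist[state] = new_dist.get(state, 0.0) + mass
                continue
            for new_state, added, pr in trs:
                m = mass * pr
                for i in added:
                    e1[i] += r * m
                    e2[i] += r * r * m
                new_dist[new_state] = new_dist.get(new_state, 0.0) + m
        dist = new_dist
    # truncated mass: unreached nodes get max_rounds + 1
    d_trunc = max_rounds + 1
    for state, mass in dist.items():
        for i in range(n):
            if not state >> i & 1:
                e1[i] += d_trunc * mass
                e2[i] += d_trunc * d_trunc * mass
    return np.array(nodes), e1, e2
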
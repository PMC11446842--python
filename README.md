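# flybrain

Analysis pipeline for whole-brain synapse-level connectomes, modelled on the
adult *Drosophila melanogaster* wiring diagram: it turns raw automatically
detected synapse tables into cleaned connection graphs, neuropil-level
projection matrices, neuron classifications and probabilistic
information-flow rankings, and ships a synthetic-brain generator so every
stage can be validated against known ground truth.

It is intended for connectomics researchers who want the published analysis
rules as reusable, tested building blocks — either to re-analyse public
synapse dumps or to prototype methods on simulated brains with controlled
statistics.

## What it computes

**Synapse cleaning.** A synapse table has one row per predicted pre→post
link (polyadic boutons appear as several rows sharing a presynaptic
coordinate), with a cleft confidence score in 0–255. Rows are removed if
the score is ≤ 50 or either partner is unattached to a segment; remaining
annotations of the same ordered neuron pair within 100 nm of each other
(Euclidean, presynaptic coordinates) are deduplicated by a greedy sweep
that keeps the highest-scoring member of each cluster. Rows aggregate into
connections, and a connection requires ≥ 5 synapses.

**Neuropil assignment and classification.** Each synapse is assigned to the
neuropil containing its presynaptic point, or to the nearest neuropil
within 10 µm. A neuron whose synapses all lie inside brain regions is
*intrinsic*; otherwise it is *afferent* (soma outside the brain) or
*efferent* (soma inside). Laterality (ipsi-/bi-/contralateral) compares
where a neuron's outputs sit relative to its dominant input hemisphere, and
per-neuron neurotransmitter labels come from summed per-synapse predictions
(ACH excitatory; GABA and GLUT inhibitory).

**Projectome.** For every intrinsic neuron, fractional input and output
vectors over the N neuropils, f_in and f_out, are multiplied into an outer
product M = f_in f_outᵀ (which sums to 1), and these matrices are summed
over neurons. Row = neuropil where input is received, column = neuropil
where output is sent; the grand total equals the number of contributing
neurons.

**Information flow.** From a seed set (e.g. one sensory modality), the
traversal model adds an untraversed neuron receiving fraction f of its
inputs from traversed neurons with per-round probability

    p(f) = min(f / τ, 1),        τ = 0.3

so traversal is guaranteed once 30 % of a neuron's inputs are traversed.
Distances (round of first traversal, averaged over 10,000 runs by default)
become layers, ranks and percentiles; stacking rank columns across seed
modalities yields a per-neuron embedding that can be projected to 2-D with
UMAP (cosine metric).

## Worked example

```python
from flybrain import (SyntheticSpec, generate_brain, filter_synapses,
                      dedup_synapses, assign_synapses_to_neuropils,
                      aggregate_edges, threshold_edges, build_projectome,
                      traversal_distances, TraversalConfig)

spec = SyntheticSpec(rng_seed=42)          # ~1,000 neurons, 10 neuropils
synapses, neurons, regions, truth = generate_brain(spec)
print(f"raw rows: {len(synapses)}")

table = filter_synapses(synapses)          # score > 50, partners attached
table, removed = dedup_synapses(table)     # 100 nm near-duplicates
table = assign_synapses_to_neuropils(table, regions)
edges = threshold_edges(aggregate_edges(table))

intrinsic = [r for r, f in truth.true_flow_class.items() if f == "intrinsic"]
proj = build_projectome(intrinsic, table, regions)
print(f"projectome total: {proj.values.sum():.3f} "
      f"over {proj.contributing_neuron_count} neurons")

seeds = neurons.loc[neurons.superclass == "sensory", "root_id"]
res = traversal_distances(edges, seeds, TraversalConfig(n_runs=200, rng_seed=0))
```

Output:

```
raw rows: 276233
after score/attachment filter: 196160
after 100 nm dedup: 186836 (9324 duplicates removed)
connections (>=5 synapses): 8862
projectome total: 823.000 over 823 neurons
```

The filter drops the planted low-score/unattached rows, dedup removes the
planted near-duplicate annotations, and the projectome total equals the
count of intrinsic neurons with assigned synapses on both sides — each
neuron contributes exactly weight one. `res.table` then holds one row per
neuron with its mean traversal distance from the sensory seeds, layer,
rank and percentile.

The same stages are available from the shell:

```sh
flybrain simulate --seed 42 --out brain/
flybrain filter --synapses brain/synapses.csv --out filtered.csv
flybrain assign --synapses filtered.csv --regions brain/regions.json --out assigned.csv
flybrain build-edges --synapses assigned.csv --out connections.csv
flybrain flow --edges connections.csv --seeds seeds.json --runs 10000 --seed 42 --out ranks.csv
```

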
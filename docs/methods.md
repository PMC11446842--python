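# Methods

This note records the models implemented by `flybrain`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices made where the published analysis rules
leave room.

## Synapse cleaning

A synapse table holds one row per predicted pre→post link; polyadic
boutons (one presynaptic site contacting several partners) appear as
multiple rows sharing a presynaptic coordinate. Cleaning applies, in
order:

1. **Score filter** — keep rows with cleft score > 50 (the published rule
   removes score ≤ 50) and, by default, drop rows where either partner is
   unattached to a segment. Both cutoffs sit in `FilterConfig`.
2. **Spatial deduplication** — within each ordered (pre, post) pair, rows
   are swept in descending score (ties: ascending record id) and a row is
   kept iff its presynaptic coordinate is > 100 nm (Euclidean) from every
   already-kept row of that pair. The sweep order is our choice — the rule
   defining duplicates does not say which member of a cluster survives —
   and is fixed so the highest-confidence annotation wins deterministically.
   "Within 100 nm" is read inclusively: distance exactly 100 nm counts as a
   duplicate. Rows of different pairs never suppress each other, and the
   operation is idempotent.
3. **Aggregation and threshold** — rows collapse to connections with
   synapse counts; a connection requires ≥ 5 synapses (`ThresholdConfig`,
   i.e. the ">4" rule). On per-neuropil edge lists the threshold applies
   to the pair's *total* count, since a connection is the full synapse set
   between two neurons.

Filtering precedes deduplication. The published order is not stated; doing
the cheap row filter first means the greedy sweep sees fewer candidates,
and the two orders differ only when a low-score row would have suppressed
a high-score one, which the keep-best sweep order makes impossible anyway.

## Neuropil geometry

Regions are axis-aligned boxes with exact containment and point-to-box
distance oracles, behind a `RegionSet` interface that hides the geometry
(mesh-backed regions can be slotted in without touching the pipeline).
The real neuropils are meshes, so our nearest-region distance is
point-to-box rather than point-to-mesh — an acknowledged substitution.
A synapse gets the region containing its presynaptic point; otherwise the
nearest region within `max_snap_distance` = 10 µm; otherwise it stays
unassigned. Nearest-region ties break to the lexicographically smallest
name (with meshes such ties are measure-zero; with boxes they occur on
mid-planes and need a deterministic rule).

Every left region has a right twin (`*_L`/`*_R`); unpaired regions are
`centre`. Laterality rules use this three-way side partition.

## Neuron classification

* **Flow** — a neuron is *intrinsic* iff every synapse row touching it is
  assigned to a brain region; otherwise its soma position decides:
  outside → afferent, inside → efferent. Superclasses map onto flow
  classes as sensory/ascending → afferent; central, optic, visual
  projection, visual centrifugal → intrinsic; descending/motor/endocrine →
  efferent.
* **Dominant input side** — argmax of the neuron's assigned postsynapse
  counts per side; ties resolve centre > left > right and are logged.
* **Laterality** — excluded if the dominant input side is centre or most
  presynapses sit in centre regions; otherwise classify by the fraction f
  of non-centre presynapses on the hemisphere opposite the dominant input
  side: contralateral at f ≥ 0.95, ipsilateral at f ≤ 0.05, bilateral
  between. The 0.95/0.05 cutoffs are our realisation of "almost
  exclusively" — the source shows a histogram but prints no numbers — and
  sit in `LateralityConfig`.
* **Optic projection** — synapse-location-based: fully optic → optic
  intrinsic; none optic → central; input-majority optic with
  output-majority central → VPN; the reverse → VCN. Strict majorities are
  a stated approximation of a definition that may have involved curation.
* **Neurotransmitter** — per-neuron label = argmax of summed per-synapse
  predicted probabilities over outgoing synapses (one transmitter per
  neuron, Dale's-law assumption), ties in the fixed order ACH, GABA, GLUT,
  SER, DA, OCT. Summing probabilities rather than majority-voting labels
  is our choice of how to "combine" the predictions; both agree except on
  near-ties. Signs: ACH +1, GABA/GLUT −1, monoamines 0.

## Projectome

Per intrinsic neuron, f_in and f_out are the fractions of its assigned
incoming/outgoing synapses per neuropil; its projection matrix is the
outer product f_in f_outᵀ, summing to one; the projectome sums these over
neurons. Direction convention: rows index the neuropil where input is
received, columns where output is sent. Neurons lacking assigned synapses
on either side contribute a zero matrix and are excluded from the
normalisation count, so matrix-total = contributing-neuron-count holds
exactly. Per-transmitter variants filter the neuron set but keep the
global normalisation, so the per-transmitter matrices sum to the full one
(the alternative, renormalising within each class, is not used).
The projectome is built from the cleaned synapse table without the ≥ 5
connection threshold, since its inputs are per-neuron synapse counts, not
connections. Afferent/efferent superclasses enter only as marginal
vectors: summed output fractions for afferents, input fractions for
efferents (their other side lies outside the brain and is not counted).

## Information-flow traversal

Round 0 traverses the seed set. Each subsequent round, every untraversed
neuron with fraction f of its incoming synapses from traversed neurons is
added independently with probability p(f) = min(f/τ, 1), τ = 0.3; p(0) = 0.
The fraction's denominator is the neuron's total in-synapses within the
analysed (filtered, thresholded) edge list, keeping the model
self-contained. A failed draw is re-drawn next round (memoryless), which
makes waiting times geometric — this is the interpretation under which a
"per-round likelihood linear in f" is well-defined. A run stops when no
untraversed neuron has positive probability (a round in which every
candidate merely fails its draw does *not* stop the run) or when
`max_rounds` (default: the number of neurons) is reached; neurons never
traversed get distance last-round + 1 by default so means stay finite
(`unreached_distance_rule="infinity"` is available).

Distances average over `n_runs` = 10,000 runs. Layers round the mean to
the nearest integer, halves away from zero. Ranks sort by ascending mean
distance with neuron-id tie-break; percentile = 100·rank/(n−1). Per
modality, the RNG stream derives from the seed *set* content, so identical
seed sets reproduce identical columns and different sets are decorrelated.
The rank embedding projects to 2-D with UMAP (n_components=2,
min_dist=0.35, cosine metric, n_neighbors=50, learning_rate=0.1,
n_epochs=1000), seeded.

The traversal is verified against exhaustive enumeration of the Markov
chain over traversed-set states on graphs of ≤ 10 nodes, including the
truncation rule, so simulation and oracle share the exact same model.

## Synthetic brains

The generator emulates the statistical structure the analyses rely on:

* mirror-symmetric left/right neuropil boxes plus centre boxes (40 µm
  cubes, 6 µm gaps, integer-nm coordinates); with ≥ 2 pairs the last pair
  models the optic lobes;
* a superclass composition defaulting to ~1,000 neurons, ~82 % intrinsic
  and optic-heavy, echoing the whole-brain proportions at miniature scale;
* polyadic boutons with a shifted-Poisson fan-out (mean 5 partners,
  matching the several-partners-per-presynapse regime of fly neuropil);
  bouton positions of one neuron are kept > 110 nm apart so genuine rows
  of a pair are never deduplicated;
* heavy-tailed per-neuron activity (lognormal rates, in/out correlation
  0.6), with rates normalised so the total row count is exactly
  Poisson(mean_out_synapses × n_emitters) — bouton sizes are drawn iid
  against that total (at most one truncated bouton per brain), and boutons
  are assigned to neurons proportionally to their rates;
* cleft scores from a clipped normal on [51, 255] for genuine rows and
  uniform [0, 50] for spurious rows (30 % of the table by default, a share
  of them unattached), mirroring the roughly half of raw detections the
  published cleaning removes;
* near-duplicates (5 % rate by default) placed ≤ 90 nm from the parent's
  presynaptic coordinate with score ≤ parent, so deduplication provably
  removes exactly the injected set;
* out-of-brain synapse rows (5 per non-intrinsic neuron, > 10 µm from all
  regions) so afferent/efferent neurons genuinely straddle the brain
  boundary — this is the one place a synapse row deliberately violates the
  "within 10 µm of a region" layout, because flow classification is
  defined by exactly such rows;
* optional planted structure: a row-stochastic neuropil→neuropil matrix
  (each intrinsic neuron then receives in one uniformly drawn neuropil and
  sends to one drawn from the planted row — pure single-region vectors, so
  the recovery error is exactly binomial), or a neuron-index→depth map
  that rewires connectivity into a feedforward chain.

Everything is deterministic given `rng_seed`, with per-stage RNG
sub-streams. What the generator does **not** emulate: neurite geometry and
morphology, mesh-shaped regions, electrical synapses, glia, cell types,
distance-dependent connectivity, and realistic between-neuropil wiring
statistics. Passing the recovery tests therefore shows the *rules* are
implemented faithfully, not that the pipeline is robust to every artefact
of real electron-microscopy data.

## Problem sizes and numerics

Tests and examples run at desk scale: ~150–1,000-neuron brains for
pipeline identity and conservation checks, 5,000 neurons for the
planted-projectome recovery (binomial standard errors shrink as n^{-1/2};
5,000 keeps 3·SE around 2 % absolute), 10,000 traversal runs against the
enumeration oracle on ≤ 10-node fixtures, and 1,000 clustered rows for the
dedup oracle. Tolerances: exact frame equality for discrete outputs,
1e-9 for projectome sums (floating accumulation), 3 standard errors for
Monte-Carlo and sampling comparisons, and a χ² goodness-of-fit at α = 0.01
for the polyad distribution.

Degenerate inputs are defined, not silently handled: empty seed sets,
zero-synapse neurons in classification, zero denominators in QA metrics
and zero volumes raise; zero-synapse sides in fractional vectors are
flagged rather than raised so whole-population sweeps don't abort.

## Known limitations

* Box regions make nearest-neuropil snapping geometrically cruder than
  the mesh-based original; distances beyond a box face are exact for
  boxes but not for the true neuropil surfaces.
* The traversal denominator uses the analysed graph only; neurons whose
  inputs were mostly below the connection threshold have optimistic
  fractions.
* Per-neuron transmitter assignment inherits the per-synapse predictor's
  confusions on real data; the synthetic generator plants an 87 %
  per-synapse accuracy but real error is structured, not uniform.
* `run_pipeline` classifies only neurons present in the synapse table;
  annotation-only neurons pass through untouched.
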
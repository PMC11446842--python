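"""Synthetic brain generator: determinism, statistical structure, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from flybrain import core, regions as rm
from flybrain.synthetic import (
    DiscretePMF,
    SyntheticSpec,
    generate_brain,
    generate_layered_network,
    make_regions,
)


def small_spec(**kw):
    base = dict(
        rng_seed=0,
        neuron_counts_by_superclass={
            "central": 120, "optic": 40, "sensory": 20, "ascending": 5,
            "descending": 10, "motor": 5,
        },
        mean_out_synapses=50.0,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestSpecValidation:
    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError, match="empty specification"):
            SyntheticSpec(neuron_counts_by_superclass={"central": 0})

    def test_bad_planted_rows_rejected(self):
        P = np.full((10, 10), 0.2)
        with pytest.raises(ValueError, match="probability vectors"):
            SyntheticSpec(planted_projectome=P)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SyntheticSpec(duplicate_rate=1.5)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = generate_brain(small_spec())
        b = generate_brain(small_spec())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[3].true_edge_list, b[3].true_edge_list)

    def test_different_seed_differs(self):
        a = generate_brain(small_spec())
        b = generate_brain(small_spec(rng_seed=1))
        assert not a[0].equals(b[0])


class TestStructure:
    def test_layout_mirror_symmetric_with_groups(self):
        regions = make_regions(4, 2)
        assert len(regions) == 10
        for r in regions.regions:
            if r.side == "left":
                twin = regions[r.name[:-2] + "_R"]
                assert twin.lo[0] == -r.hi[0] and twin.hi[0] == -r.lo[0]
        assert set(regions.groups) == {"optic_lobe", "central_brain"}

    def test_every_neuron_has_flow_and_every_inbrain_row_is_assignable(self):
        syn, neurons, regions, gt = generate_brain(small_spec())
        assert set(neurons["root_id"]) == set(gt.true_flow_class)
        in_brain = syn["bouton_id"] >= 0
        pts = syn.loc[in_brain, ["pre_x", "pre_y", "pre_z"]].to_numpy(dtype=float)
        assigned = regions.assign_points(pts, 10_000)
        assert (assigned != "").all()

    def test_polyadic_boutons_share_presynaptic_coordinate(self):
        syn, *_ = generate_brain(small_spec())
        rows = syn[syn["bouton_id"] >= 0]
        per_bouton = rows.groupby("bouton_id")[["pre_x", "pre_y", "pre_z", "pre_root_id"]].nunique()
        assert (per_bouton <= 1).all().all()

    def test_duplicates_sit_within_radius_of_a_same_pair_parent(self):
        syn, _, _, gt = generate_brain(small_spec(duplicate_rate=0.2))
        dups = syn[syn["record_id"].isin(gt.injected_duplicates)]
        originals = syn[(syn["bouton_id"] >= 0) | (syn["nt_type"] == "")]
        originals = originals[~originals["record_id"].isin(gt.injected_duplicates | gt.injected_noise)]
        merged = dups.merge(
            originals, on=["pre_root_id", "post_root_id"], suffixes=("_d", "_o")
        )
        d = np.sqrt(
            (merged["pre_x_d"] - merged["pre_x_o"]) ** 2
            + (merged["pre_y_d"] - merged["pre_y_o"]) ** 2
            + (merged["pre_z_d"] - merged["pre_z_o"]) ** 2
        )
        near = merged.assign(d=d).groupby("record_id_d")["d"].min()
        assert (near <= 100).all()

    def test_total_rows_follow_poisson_count(self):
        """1,000 emitting neurons at 50 expected outputs each: the total row
        count is Poisson(50,000) to within 3 sigma."""
        spec = SyntheticSpec(
            rng_seed=11, duplicate_rate=0, noise_synapse_fraction=0,
            neuron_counts_by_superclass={"central": 1000}, mean_out_synapses=50,
        )
        syn, *_ = generate_brain(spec)
        assert abs(len(syn) - 50_000) <= 3 * np.sqrt(50_000)

    def test_polyad_sizes_match_planted_distribution(self):
        """Chi-square goodness of fit at alpha=0.01 over >= 10^4 boutons."""
        spec = SyntheticSpec(
            rng_seed=3, duplicate_rate=0, noise_synapse_fraction=0,
            neuron_counts_by_superclass={"central": 600}, mean_out_synapses=100,
        )
        syn, *_ = generate_brain(spec)
        sizes = syn[syn["bouton_id"] >= 0].groupby("bouton_id").size()
        assert len(sizes) >= 10_000
        pmf = spec.polyad_size_dist
        obs = np.array([(sizes == v).sum() for v in pmf.values], dtype=float)
        exp = pmf.p * len(sizes)
        ok = exp > 5
        obs_t = np.append(obs[ok], obs[~ok].sum())
        exp_t = np.append(exp[ok], exp[~ok].sum())
        chi2 = ((obs_t - exp_t) ** 2 / exp_t).sum()
        assert chi2 < sp_stats.chi2.ppf(0.99, len(exp_t) - 1)

    def test_heavy_tailed_and_correlated_in_out_synapse_counts(self):
        spec = SyntheticSpec(
            rng_seed=5, duplicate_rate=0, noise_synapse_fraction=0,
            neuron_counts_by_superclass={"central": 800}, mean_out_synapses=60,
        )
        syn, neurons, *_ = generate_brain(spec)
        out_c = syn.groupby("pre_root_id").size().reindex(neurons["root_id"], fill_value=0)
        in_c = syn.groupby("post_root_id").size().reindex(neurons["root_id"], fill_value=0)
        assert out_c.max() > 6 * out_c.median()  # heavy tail
        rho = sp_stats.spearmanr(out_c, in_c).statistic
        assert rho > 0.25

    def test_noise_rows_all_low_score(self):
        syn, _, _, gt = generate_brain(small_spec(noise_synapse_fraction=0.2))
        noise = syn[syn["record_id"].isin(gt.injected_noise)]
        assert (noise["score"] <= 50).all()
        assert len(noise) > 0

    def test_superclass_composition_exact(self):
        _, neurons, _, _ = generate_brain(small_spec())
        got = neurons["superclass"].value_counts().to_dict()
        assert got == small_spec().neuron_counts_by_superclass


class TestRecovery:
    def test_uncorrupted_brain_pipeline_identity(self):
        """With no injected corruption, filter+dedup leave the table intact
        and the thresholded edge list equals the ground truth."""
        syn, neurons, regions, gt = generate_brain(
            small_spec(duplicate_rate=0.0, noise_synapse_fraction=0.0)
        )
        t = core.filter_synapses(syn)
        assert len(t) == len(syn)
        t, removed = core.dedup_synapses(t)
        assert not removed
        edges = core.threshold_edges(core.aggregate_edges(t))
        pd.testing.assert_frame_equal(
            edges.sort_values(["pre_root_id", "post_root_id"]).reset_index(drop=True),
            gt.true_edge_list,
            check_dtype=False,
        )

    def test_dedup_removes_exactly_injected_duplicates(self):
        syn, _, _, gt = generate_brain(small_spec(duplicate_rate=0.1))
        t = core.filter_synapses(syn)
        assert set(syn["record_id"]) - set(t["record_id"]) == gt.injected_noise
        _, removed = core.dedup_synapses(t)
        assert removed == gt.injected_duplicates


class TestLayeredNetwork:
    def test_width_one_chain(self):
        edges, seeds, depths = generate_layered_network(3, 1, 0.0, rng_seed=0)
        assert seeds == {1}
        assert depths == {1: 0, 2: 1, 3: 2}
        assert set(zip(edges["pre_root_id"], edges["post_root_id"])) == {(1, 2), (2, 3)}

    def test_all_inputs_from_prior_layer_without_skips(self):
        edges, seeds, depths = generate_layered_network(4, 5, 0.0, rng_seed=1)
        for _, row in edges.iterrows():
            assert depths[row["post_root_id"]] == depths[row["pre_root_id"]] + 1

    def test_every_nonseed_has_an_input(self):
        edges, seeds, depths = generate_layered_network(5, 7, 0.3, rng_seed=2)
        targets = set(edges["post_root_id"])
        for node, d in depths.items():
            if d > 0:
                assert node in targets

    def test_skip_connections_never_deepen_shortest_path(self):
        import networkx as nx

        edges, seeds, depths = generate_layered_network(4, 5, 0.3, rng_seed=3)
        g = nx.from_pandas_edgelist(edges, "pre_root_id", "post_root_id", create_using=nx.DiGraph)
        for s in seeds:
            g.add_node(s)
        hops = {}
        for s in seeds:
            for node, h in nx.single_source_shortest_path_length(g, s).items():
                hops[node] = min(hops.get(node, 10**9), h)
        for node, d in depths.items():
            assert hops[node] <= d

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_layered_network(1, 5, 0.0, 0)


class TestDistributions:
    def test_pmf_must_normalise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DiscretePMF(((1, 0.5), (2, 0.4)))

    def test_pmf_sampling_respects_support(self):
        pmf = DiscretePMF(((2, 0.5), (5, 0.5)))
        draws = pmf.sample(np.random.default_rng(0), 500)
        assert set(np.unique(draws)) <= {2, 5}
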
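"""Synthetic generator: trees, Mk characters, clusters, events, replayable logs."""
import copy

import dendropy
import numpy as np
import pytest

from pvdevol.simulate import (
    EventLogEntry,
    SimulationConfig,
    apply_event,
    evolve_discrete_character,
    inject_event,
    render_cluster,
    scale_tree_height,
    simulate_clade,
    simulate_nrps_cluster,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_smallest_tree(self):
        tree = simulate_species_tree(2, 1.0, seed=1)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        depths = [l.distance_from_root() for l in leaves]
        assert depths[0] == pytest.approx(depths[1])

    def test_sixteen_tips_ultrametric(self):
        tree = simulate_species_tree(16, 1.0, seed=5)
        assert len(tree.leaf_nodes()) == 16
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 16 - 1
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length > 0

    def test_seed_determinism_byte_identical(self):
        a = simulate_species_tree(10, 1.0, seed=42).as_string(schema="newick")
        b = simulate_species_tree(10, 1.0, seed=42).as_string(schema="newick")
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, seed=0)

    def test_height_scaling(self):
        tree = scale_tree_height(simulate_species_tree(8, 2.0, seed=3), 1.0)
        assert max(l.distance_from_root() for l in tree.leaf_node_iter()) == pytest.approx(1.0)


class TestDiscreteCharacter:
    def test_zero_rate_freezes_character(self):
        tree = simulate_species_tree(12, 1.0, seed=2)
        tips, nodes = evolve_discrete_character(tree, 4, 0.0, root_state=2, seed=1)
        assert set(tips.values()) == {2}
        assert set(nodes.values()) == {2}

    def test_star_tree_matches_closed_form(self):
        # fraction of tips flipped after time t: 1/2 - e^(-2qt)/2
        n, q, t = 2000, 0.7, 0.9
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
        tree = dendropy.Tree(taxon_namespace=taxa)
        for i in range(n):
            leaf = tree.seed_node.new_child(taxon=taxa[i], edge_length=t)
        tips, _ = evolve_discrete_character(tree, 2, q, root_state=0, seed=9)
        frac = sum(v != 0 for v in tips.values()) / n
        p = 0.5 - 0.5 * np.exp(-2 * q * t)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_determinism(self):
        tree = simulate_species_tree(10, 1.0, seed=4)
        a, _ = evolve_discrete_character(tree, 3, 0.5, 0, seed=11)
        b, _ = evolve_discrete_character(tree, 3, 0.5, 0, seed=11)
        assert a == b

    def test_bad_root_state_rejected(self):
        tree = simulate_species_tree(4, 1.0, seed=1)
        with pytest.raises(ValueError):
            evolve_discrete_character(tree, 3, 0.5, root_state=3, seed=0)


class TestClusterSimulation:
    def test_module_count_matches_spec(self, library):
        spec = [("Ser", False)] * 6
        proteins, rows, cluster = simulate_nrps_cluster(spec, library, seed=1)
        assert len(cluster.modules) == 6
        assert 1 <= len(proteins) <= 4
        assert [r["gene_index"] for r in rows] == list(range(1, len(proteins) + 1))

    def test_epimerized_module_has_one_e_domain(self, library):
        spec = [("Ser", False), ("Thr", True)]
        _, _, cluster = simulate_nrps_cluster(spec, library, seed=2)
        assert "E" not in cluster.modules[0].seqs
        assert "E" in cluster.modules[1].seqs

    def test_empty_spec_rejected(self, library):
        with pytest.raises(ValueError):
            simulate_nrps_cluster([], library, seed=1)

    def test_determinism(self, library):
        spec = [("Ser", False), ("Orn", True), ("Lys", False), ("Dab", False)]
        a, _, _ = simulate_nrps_cluster(spec, library, noise_rate=0.05, seed=7)
        b, _, _ = simulate_nrps_cluster(spec, library, noise_rate=0.05, seed=7)
        assert [(p.id, p.sequence) for p in a] == [(p.id, p.sequence) for p in b]


def two_cluster_setup(library, seed=1):
    spec_a = [("Ser", False), ("Lys", False), ("Thr", False), ("Orn", True)]
    spec_b = [("Glu", False), ("Tyr", True), ("Dab", False), ("Ala", False)]
    _, _, ca = simulate_nrps_cluster(spec_a, library, seed=seed, strain="a")
    _, _, cb = simulate_nrps_cluster(spec_b, library, seed=seed + 1, strain="b")
    return {"a": ca, "b": cb}


class TestInjectEvent:
    def test_full_replacement_copies_backbone(self, library):
        clusters = two_cluster_setup(library)
        config = SimulationConfig(seed=0, copy_noise=0.0)
        entry = inject_event(
            clusters, {"kind": "full_replacement", "recipient": "a", "donor": "b"},
            seed=3, library=library, config=config,
        )
        assert clusters["a"].residue_string() == clusters["b"].residue_string()
        assert entry.module_ordinals == (1, 2, 3, 4)

    def test_partial_replacement_retains_prefix(self, library):
        clusters = two_cluster_setup(library)
        before = clusters["a"].residue_string().split("-")
        config = SimulationConfig(seed=0, copy_noise=0.0)
        inject_event(
            clusters,
            {"kind": "partial_replacement", "recipient": "a", "donor": "b", "module": 2},
            seed=3, library=library, config=config,
        )
        after = clusters["a"].residue_string().split("-")
        assert after[:2] == before[:2]
        assert after[2:] == clusters["b"].residue_string().split("-")[2:]

    def test_swap_changes_only_last_residue(self, library):
        clusters = two_cluster_setup(library)
        before = clusters["a"].residue_string().split("-")
        inject_event(
            clusters,
            {"kind": "specificity_swap", "recipient": "a", "module": 4, "new_substrate": "Ala"},
            seed=5, library=library,
        )
        after = clusters["a"].residue_string().split("-")
        assert after[:-1] == before[:-1]
        assert after[-1] == "Ala" != before[-1]

    def test_accessory_gain_and_loss(self, library):
        clusters = two_cluster_setup(library)
        inject_event(
            clusters, {"kind": "accessory_gain", "recipient": "a", "module": 1},
            seed=2, library=library,
        )
        assert clusters["a"].modules[0].has_E
        inject_event(
            clusters, {"kind": "accessory_loss", "recipient": "a", "module": 1},
            seed=2, library=library,
        )
        assert not clusters["a"].modules[0].has_E

    def test_duplication_inserts_adjacent_copy(self, library):
        clusters = two_cluster_setup(library)
        inject_event(
            clusters, {"kind": "domain_duplication", "recipient": "a", "module": 3},
            seed=2, library=library,
        )
        mods = clusters["a"].modules
        assert len(mods) == 5
        assert mods[2].substrate == mods[3].substrate == "Thr"
        assert not mods[3].has_E

    def test_out_of_range_module_rejected(self, library):
        clusters = two_cluster_setup(library)
        with pytest.raises(ValueError):
            inject_event(
                clusters, {"kind": "specificity_swap", "recipient": "a", "module": 9},
                seed=1, library=library,
            )

    def test_unknown_kind_rejected(self, library):
        with pytest.raises(ValueError):
            inject_event(two_cluster_setup(library), {"kind": "inversion"}, seed=1, library=library)


class TestCladeSimulation:
    def test_vertical_inheritance_with_zero_rates(self, library):
        config = SimulationConfig(n_tips=8, seed=5, noise_rate=0.0, seq_rate=0.0)
        clade = simulate_clade(config)
        for tip, cluster in clade.clusters.items():
            group_type = 0 if clade.groups[tip] == "G1" else 1
            peers = [
                c.residue_string() for t, c in clade.clusters.items()
                if clade.groups[t] == clade.groups[tip]
            ]
            assert len(set(peers)) == 1
        assert clade.event_log == []

    def test_event_log_replay_reproduces_tip_clusters(self, library):
        config = SimulationConfig(n_tips=10, seed=8)
        clade = simulate_clade(
            config,
            event_requests=[
                {"kind": "full_replacement"},
                {"kind": "accessory_gain"},
                {"kind": "domain_duplication"},
            ],
        )
        replayed = copy.deepcopy(clade.ancestral_clusters)
        for entry in clade.event_log:
            apply_event(replayed, entry, library, config)
        for tip in clade.clusters:
            a, _ = render_cluster(replayed[tip], tip)
            b, _ = render_cluster(clade.clusters[tip], tip)
            assert [(p.id, p.sequence) for p in a] == [(p.id, p.sequence) for p in b]

    def test_event_log_completeness_and_kinds(self):
        config = SimulationConfig(n_tips=10, seed=3)
        clade = simulate_clade(
            config, event_requests=[{"kind": "specificity_swap"}, {"kind": "accessory_loss"}]
        )
        assert [e.kind for e in clade.event_log] == ["specificity_swap", "accessory_loss"]
        for e in clade.event_log:
            n = len(clade.clusters[e.recipient].modules)
            assert all(1 <= o <= n for o in e.module_ordinals)
            assert e.timestamp == "post-hoc"

    def test_determinism_across_runs(self):
        config = SimulationConfig(n_tips=8, seed=21)
        reqs = [{"kind": "partial_replacement"}]
        a = simulate_clade(config, event_requests=reqs)
        b = simulate_clade(SimulationConfig(n_tips=8, seed=21), event_requests=reqs)
        pa, _ = a.proteins()
        pb, _ = b.proteins()
        assert [(p.id, p.sequence) for p in pa] == [(p.id, p.sequence) for p in pb]
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")
        assert a.receptors == b.receptors

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(backbone_length_range=(2, 12))
        with pytest.raises(ValueError):
            SimulationConfig(noise_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_states=1)
        with pytest.raises(ValueError):
            EventLogEntry("inversion", None, "x", (1,))
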
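"""Typing, cross-group sharing, heatmaps, event detectors and receptor concordance."""
import numpy as np
import pytest

from pvdevol import events as ev
from pvdevol.architecture import BackbonePrediction
from pvdevol.pipeline import analyze_simulated
from pvdevol.simulate import SimulationConfig, simulate_clade


def bb(residues, chirality=None):
    chirality = chirality or "L" * len(residues)
    return BackbonePrediction(tuple(zip(residues, chirality)))


class TestRomanNumerals:
    @pytest.mark.parametrize(
        "n,expected", [(1, "I"), (4, "IV"), (9, "IX"), (16, "XVI"), (30, "XXX"), (44, "XLIV")]
    )
    def test_values(self, n, expected):
        assert ev.roman(n) == expected


class TestAssignTypes:
    def test_identical_backbones_share_label(self):
        reg, labels = ev.assign_types(
            {"a": bb(["Ser", "Lys"]), "b": bb(["Ser", "Lys"])}
        )
        assert labels["a"][0] == labels["b"][0] == "I"
        assert reg.n_types == 1

    def test_last_residue_difference_makes_new_type(self):
        _, labels = ev.assign_types(
            {"a": bb(["Ser", "Thr", "Lys"]), "b": bb(["Ser", "Thr", "Ala"])}
        )
        assert labels["a"][0] == "I" and labels["b"][0] == "II"

    def test_chirality_difference_makes_subtypes_of_one_type(self):
        _, labels = ev.assign_types(
            {
                "a": bb(["Ser", "Orn"], "LL"),
                "b": bb(["Ser", "Orn"], "LD"),
                "c": bb(["Ser", "Orn"], "LL"),
            }
        )
        types = {labels[s][0] for s in "abc"}
        assert types == {"I"}
        assert labels["a"][1] == labels["c"][1] == "Ia"
        assert labels["b"][1] == "Ib"

    def test_first_seen_order_is_stable(self):
        data = {
            "a": bb(["Ser"]),
            "b": bb(["Thr"]),
            "c": bb(["Ser"]),
            "d": bb(["Orn"]),
        }
        _, labels1 = ev.assign_types(data)
        _, labels2 = ev.assign_types(data)
        assert labels1 == labels2
        assert [labels1[s][0] for s in "abcd"] == ["I", "II", "I", "III"]


class TestSharedTypes:
    def test_disjoint_groups_give_empty(self):
        labels = {"a": ("I", "Ia"), "b": ("II", "IIa")}
        groups = {"a": "G1", "b": "G2"}
        assert ev.detect_shared_types(labels, groups) == []

    def test_one_shared_type_reported(self):
        labels = {"a": ("I", "Ia"), "b": ("I", "Ia"), "c": ("II", "IIa")}
        groups = {"a": "G1", "b": "G2", "c": "G3"}
        assert ev.detect_shared_types(labels, groups) == [("I", ["G1", "G2"])]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(6)
        strains = [f"s{i}" for i in range(30)]
        labels = {s: (ev.roman(int(rng.integers(1, 6))), "") for s in strains}
        groups = {s: f"G{int(rng.integers(1, 4))}" for s in strains}
        got = dict(ev.detect_shared_types(labels, groups))
        tally = {}
        for s in strains:
            tally.setdefault(labels[s][0], set()).add(groups[s])
        expected = {t: sorted(gs) for t, gs in tally.items() if len(gs) >= 2}
        assert got == expected


class TestHeatmapAndDetectors:
    @pytest.fixture(scope="class")
    def swap_clade(self):
        clade = simulate_clade(
            SimulationConfig(n_tips=10, seed=31),
            event_requests=[{"kind": "specificity_swap"}],
        )
        return clade, analyze_simulated(clade)

    def test_self_heatmap_is_all_ones(self, swap_clade):
        clade, res = swap_clade
        strain = sorted(res.assemblies)[0]
        seqs = {p.id: p.sequence for p in clade.proteins()[0]}
        heat = ev.identity_heatmap(res.assemblies[strain], res.assemblies[strain], seqs, seqs)
        vals = heat.values[np.isfinite(heat.values)]
        assert np.allclose(vals, 1.0)

    def test_swapped_module_is_the_identity_minimum(self, swap_clade):
        clade, res = swap_clade
        entry = clade.event_log[0]
        recipient = entry.recipient
        partner = sorted(
            s for s in res.assemblies
            if s != recipient and clade.groups[s] == clade.groups[recipient]
        )[0]
        seqs = {p.id: p.sequence for p in clade.proteins()[0]}
        heat = ev.identity_heatmap(
            res.assemblies[recipient], res.assemblies[partner], seqs, seqs
        )
        a_col = heat.values[:, heat.kinds.index("A")]
        assert int(np.nanargmin(a_col)) + 1 == entry.module_ordinals[0]
        # symmetry under argument swap
        heat_r = ev.identity_heatmap(
            res.assemblies[partner], res.assemblies[recipient], seqs, seqs
        )
        assert np.allclose(heat.values, heat_r.values, equal_nan=True)

    def test_swap_detected_and_attributed(self, swap_clade):
        clade, res = swap_clade
        entry = clade.event_log[0]
        found = [e for e in res.events if e.kind == "specificity_swap"]
        assert len(found) == 1
        assert found[0].strain == entry.recipient
        assert found[0].module_ordinals == entry.module_ordinals

    def test_identical_architectures_give_no_swap(self, swap_clade):
        clade, res = swap_clade
        strain = sorted(res.assemblies)[0]
        seqs = {p.id: p.sequence for p in clade.proteins()[0]}
        subs = [res.predictions[d].substrate
                for d, (s, _) in sorted(res.domain_info.items(), key=lambda x: x[1])
                if s == strain]
        heat = ev.identity_heatmap(res.assemblies[strain], res.assemblies[strain], seqs, seqs)
        assert ev.detect_specificity_swap(
            res.assemblies[strain], res.assemblies[strain], subs, subs, heat
        ) is None


class TestAccessoryAndDuplication:
    def test_accessory_gain_detected_with_flanking_evidence(self):
        clade = simulate_clade(
            SimulationConfig(n_tips=10, seed=37),
            event_requests=[{"kind": "accessory_gain"}],
        )
        res = analyze_simulated(clade)
        entry = clade.event_log[0]
        found = [e for e in res.events if e.kind.startswith("accessory")]
        assert [(e.kind, e.strain, e.module_ordinals) for e in found] == [
            ("accessory_gain", entry.recipient, entry.module_ordinals)
        ]

    def test_duplication_detected_at_adjacent_ordinals(self):
        clade = simulate_clade(
            SimulationConfig(n_tips=10, seed=41),
            event_requests=[{"kind": "domain_duplication"}],
        )
        res = analyze_simulated(clade)
        entry = clade.event_log[0]
        found = [e for e in res.events if e.kind == "domain_duplication"]
        assert [(e.strain, e.module_ordinals) for e in found] == [
            (entry.recipient, entry.module_ordinals)
        ]

    def test_no_duplication_without_mutual_nearest_neighbors(self):
        # vertical clades can carry adjacent same-substrate modules, but their
        # A domains sit with their cross-strain counterparts, not each other
        for seed in (1, 2, 3, 4):
            clade = simulate_clade(SimulationConfig(n_tips=10, seed=seed))
            res = analyze_simulated(clade)
            assert [e for e in res.events if e.kind == "domain_duplication"] == []


class TestProvenance:
    def test_full_replacement_copy_points_to_donor(self):
        clade = simulate_clade(
            SimulationConfig(n_tips=10, seed=43),
            event_requests=[{"kind": "full_replacement"}],
        )
        res = analyze_simulated(clade)
        entry = clade.event_log[0]
        prov = res.provenance[entry.recipient]
        neighbors = {e[1] for e in prov.entries.values()}
        assert neighbors == {entry.donor}

    def test_self_never_returned(self):
        clade = simulate_clade(SimulationConfig(n_tips=8, seed=2))
        res = analyze_simulated(clade)
        for strain, prov in res.provenance.items():
            for entry in prov.entries.values():
                assert entry[1] != strain


class TestTransferHypotheses:
    def test_full_replacement_yields_type_clustered(self):
        clade = simulate_clade(
            SimulationConfig(n_tips=12, seed=47),
            event_requests=[{"kind": "full_replacement"}],
        )
        res = analyze_simulated(clade)
        assert len(res.shared_types) == 1
        (hyp,) = res.transfer_hypotheses
        assert hyp.verdict == "type_clustered"
        assert sorted(hyp.groups) == ["G1", "G2"]

    def test_vertical_clade_emits_no_hypotheses(self):
        clade = simulate_clade(SimulationConfig(n_tips=12, seed=53))
        res = analyze_simulated(clade)
        assert res.shared_types == []
        assert res.transfer_hypotheses == []
        assert res.events == []


class TestReceptorConcordance:
    def test_per_type_templates_give_full_concordance(self):
        clade = simulate_clade(SimulationConfig(n_tips=12, seed=59))
        res = analyze_simulated(clade)
        assert res.receptor_concordance == 1.0

    def test_single_bearer_types_excluded(self):
        from pvdevol import phylo
        from pvdevol.simulate import simulate_receptor_set

        type_of = {"a": "T1", "b": "T1", "c": "T2"}
        receptors = simulate_receptor_set(type_of, seed=3)
        tree = phylo.neighbor_joining(phylo.distance_matrix(receptors))
        frac, per_type = ev.receptor_type_concordance(tree, type_of)
        assert set(per_type) == {"T1"}
        assert frac == 1.0

    def test_label_permutation_destroys_concordance(self):
        from pvdevol.experiments import receptor_permutation_null

        out = receptor_permutation_null(n_types=6, strains_per_type=3, n_shuffles=20, seed=5)
        assert out["true_concordance"] == 1.0
        assert out["null_below_0.2_fraction"] >= 0.9
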
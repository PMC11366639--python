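"""Seeded benchmark experiments over the synthetic generator.

Each function runs one calibration or validation experiment end to end and
returns plain numbers, so the analysis scripts, the test suite and the
reproduction script share a single implementation. Problem sizes follow the
package's standard study conditions (see docs/methods.md).
"""
from __future__ import annotations

import numpy as np

from . import mk
from .pipeline import analyze_simulated, score_event_recovery
from .simulate import (
    EVENT_KINDS,
    SimulationConfig,
    evolve_discrete_character,
    scale_tree_height,
    simulate_clade,
    simulate_nrps_cluster,
    simulate_receptor_set,
    simulate_species_tree,
)
from .templates import load_reference_table, load_template_library
from .architecture import assemble_backbone, scan_domains, segment_modules
from .specificity import predict_substrates
from . import events as ev
from . import phylo


def backbone_roundtrip(n_specs: int, noise_rate: float, seed: int,
                       protect_code: bool = False) -> dict:
    """Scan -> segment -> predict -> assemble over random backbone specs.

    Returns per-residue substrate/chirality recovery fractions and the
    fraction of specs recovered perfectly.
    """
    library = load_template_library()
    refs = load_reference_table()
    alphabet = [e.substrate for e in refs]
    rng = np.random.default_rng(seed)
    n_res = n_sub_ok = n_chir_ok = n_perfect = 0
    for i in range(n_specs):
        length = int(rng.integers(4, 13))
        spec = [
            (alphabet[rng.integers(0, len(alphabet))], bool(rng.random() < 0.3))
            for _ in range(length)
        ]
        proteins, _, _ = simulate_nrps_cluster(
            spec, library, noise_rate=noise_rate, seed=int(rng.integers(2**31)),
            strain=f"s{i}", protect_code=protect_code,
        )
        hits = [(p.id, scan_domains(p, library)) for p in proteins]
        asm = segment_modules(hits, strain=f"s{i}")
        seqs = {p.id: p.sequence for p in proteins}
        adoms = {}
        for g, arch in enumerate(asm.architectures, start=1):
            for j, mod in enumerate(arch.modules, start=1):
                a = mod.a_hit
                adoms[f"s{i}_S{g}_A{j}"] = seqs[arch.protein_id][a.start - 1 : a.end]
        preds = predict_substrates(adoms, library, refs)
        ordered = [preds[d].substrate for d in adoms]
        bb = assemble_backbone(asm, ordered)
        truth_sub = [s for s, _ in spec]
        truth_chir = ["D" if e else "L" for _, e in spec]
        got_sub = [s for s, _ in bb.residues]
        got_chir = [c for _, c in bb.residues]
        ok = len(got_sub) == length
        n_res += length
        if ok:
            n_sub_ok += sum(a == b for a, b in zip(truth_sub, got_sub))
            n_chir_ok += sum(a == b for a, b in zip(truth_chir, got_chir))
            n_perfect += int(truth_sub == got_sub and truth_chir == got_chir)
    return {
        "n_specs": n_specs,
        "substrate_recovery": n_sub_ok / n_res,
        "chirality_recovery": n_chir_ok / n_res,
        "perfect_fraction": n_perfect / n_specs,
    }


def er_parameter_recovery(n_reps: int = 20, n_tips: int = 200, q_true: float = 0.5,
                          k: int = 4, seed: int = 1) -> dict:
    """Median fitted ER rate over replicate Mk simulations on unit-depth Yule trees."""
    fitted = []
    for rep in range(n_reps):
        s = seed + rep
        tree = scale_tree_height(simulate_species_tree(n_tips, 1.0, seed=s), 1.0)
        tips, _ = evolve_discrete_character(tree, k, q_true, 0, seed=s)
        fit = mk.fit_mk(tree, tips, mk.MkModelSpec(k=k))
        fitted.append(float(fit.rates[0]))
    return {"median_q": float(np.median(fitted)), "fitted": fitted, "q_true": q_true}


def model_selection_consistency(n_reps: int = 50, n_tips: int = 200, q_true: float = 0.5,
                                k: int = 4, seed: int = 1) -> dict:
    """Fraction of ER-generated datasets on which AIC ranks ER above SYM."""
    wins = 0
    for rep in range(n_reps):
        s = seed + rep
        tree = scale_tree_height(simulate_species_tree(n_tips, 1.0, seed=10_000 + s), 1.0)
        tips, _ = evolve_discrete_character(tree, k, q_true, 0, seed=s)
        fer = mk.fit_mk(tree, tips, mk.MkModelSpec(k=k, parameterization="ER"))
        fsym = mk.fit_mk(tree, tips, mk.MkModelSpec(k=k, parameterization="SYM"))
        comp = mk.compare_models([fer, fsym])
        wins += comp.ranking[0].spec.parameterization == "ER"
    return {"er_first_fraction": wins / n_reps, "n_reps": n_reps}


def root_state_recovery(n_reps: int = 100, n_tips: int = 100, depth_times_q: float = 0.2,
                        k: int = 4, seed: int = 1) -> dict:
    """Fraction of low-rate simulations whose modal reconstructed root state is true."""
    hits = 0
    for rep in range(n_reps):
        s = seed + rep
        tree = scale_tree_height(simulate_species_tree(n_tips, 1.0, seed=s), 1.0)
        root_state = int(np.random.default_rng(s).integers(0, k))
        tips, nodes = evolve_discrete_character(tree, k, depth_times_q, root_state, seed=s + 7)
        fit = mk.fit_mk(tree, tips, mk.MkModelSpec(k=k))
        marg = mk.marginal_ancestral_states(tree, tips, fit.q_matrix)
        root_label = tree.seed_node.label
        hits += int(np.argmax(marg[root_label]) == nodes[root_label])
    return {"modal_root_recovery": hits / n_reps, "n_reps": n_reps}


def event_recovery(n_clades: int = 50, n_tips: int = 12, events_per_clade: int = 3,
                   seed: int = 1) -> dict:
    """Per-kind precision/recall of event detection over mixed synthetic clades."""
    rng = np.random.default_rng(seed)
    pairs = []
    for rep in range(n_clades):
        kinds = list(rng.choice(EVENT_KINDS, size=events_per_clade, replace=False))
        clade = simulate_clade(
            SimulationConfig(n_tips=n_tips, seed=seed + rep),
            event_requests=[{"kind": k} for k in kinds],
        )
        pairs.append((analyze_simulated(clade), clade.event_log))
    table = score_event_recovery(pairs)
    present = table.dropna(subset=["precision", "recall"])
    return {
        "table": table,
        "min_precision": float(present["precision"].min()),
        "min_recall": float(present["recall"].min()),
        "n_clades": n_clades,
    }


def negative_control(n_clades: int = 5, n_tips: int = 12, seed: int = 1) -> dict:
    """Event-free clades: counts of spurious events and transfer hypotheses."""
    n_events = n_hyp = 0
    concordances = []
    for rep in range(n_clades):
        clade = simulate_clade(SimulationConfig(n_tips=n_tips, seed=seed + rep))
        res = analyze_simulated(clade)
        n_events += len(res.events)
        n_hyp += len(res.transfer_hypotheses)
        if res.receptor_concordance is not None:
            concordances.append(res.receptor_concordance)
    return {
        "spurious_events": n_events,
        "spurious_hypotheses": n_hyp,
        "mean_receptor_concordance": float(np.mean(concordances)),
        "n_clades": n_clades,
    }


def transfer_congruence_control(n_reps: int = 50, n_tips: int = 12, seed: int = 1) -> dict:
    """Detection rate of the type-clustered verdict after one full replacement."""
    hits = 0
    for rep in range(n_reps):
        clade = simulate_clade(
            SimulationConfig(n_tips=n_tips, seed=seed + rep),
            event_requests=[{"kind": "full_replacement"}],
        )
        res = analyze_simulated(clade)
        verdicts = {h.verdict for h in res.transfer_hypotheses}
        hits += "type_clustered" in verdicts
    return {"type_clustered_rate": hits / n_reps, "n_reps": n_reps}


def receptor_permutation_null(n_types: int = 10, strains_per_type: int = 4,
                              n_shuffles: int = 100, seed: int = 1) -> dict:
    """Receptor concordance under a per-type simulation and label-permutation null."""
    library = load_template_library()
    type_of = {
        f"s{t}_{i}": f"T{t}"
        for t in range(n_types)
        for i in range(strains_per_type)
    }
    receptors = simulate_receptor_set(type_of, seed, library)
    tree = phylo.neighbor_joining(phylo.distance_matrix(receptors))
    true_frac, _ = ev.receptor_type_concordance(tree, type_of)
    rng = np.random.default_rng(seed)
    strains = sorted(type_of)
    labels = [type_of[s] for s in strains]
    below = 0
    null = []
    for _ in range(n_shuffles):
        perm = list(rng.permutation(labels))
        frac, _ = ev.receptor_type_concordance(tree, dict(zip(strains, perm)))
        null.append(frac)
        below += frac < 0.2
    return {
        "true_concordance": true_frac,
        "null_below_0.2_fraction": below / n_shuffles,
        "null_mean": float(np.mean(null)),
        "n_shuffles": n_shuffles,
    }
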
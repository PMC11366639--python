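"""End-to-end analysis: proteins → backbones → types → trees → events.

:func:`analyze_clade` is the core driver the scripts, tests and acceptance
checks share. It takes exactly what a real dataset provides — protein
records, gene order, a species tree, phylogroup assignments and (optionally)
receptor sequences — and runs domain scanning, substrate prediction,
backbone assembly, typing, A-domain/receptor tree building, transfer
screening and event detection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import architecture as arch_mod
from . import events as ev
from . import phylo, specificity
from .architecture import MotifScanner, segment_modules
from .simulate import CladeData
from .templates import load_reference_table, load_template_library


@dataclass
class AnalysisResult:
    assemblies: dict            # strain -> ClusterAssembly
    backbones: dict             # strain -> BackbonePrediction
    predictions: dict           # A-domain id -> Prediction
    registry: ev.TypeRegistry
    labels: dict                # strain -> (type, subtype)
    domain_info: dict           # A-domain id -> (strain, cluster ordinal)
    adomain_dm: object
    adomain_tree: object
    shared_types: list
    transfer_hypotheses: list
    provenance: dict            # strain -> ProvenanceMap
    events: list                # DomainEvent
    receptor_concordance: float | None = None
    receptor_per_type: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def events_table(self) -> pd.DataFrame:
        rows = [
            {
                "kind": e.kind,
                "strain": e.strain,
                "module_ordinals": ",".join(map(str, e.module_ordinals)),
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["kind", "strain", "module_ordinals"])

    def types_table(self) -> pd.DataFrame:
        rows = [
            {
                "strain": s,
                "type": t,
                "subtype": sub,
                "backbone": self.backbones[s].residue_string,
                "chirality": self.backbones[s].chirality_string,
            }
            for s, (t, sub) in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["strain", "type", "subtype", "backbone", "chirality"])


def _nearest_relative(species_tree, strain: str) -> str:
    dm = phylo.patristic_distances(species_tree)
    ids = list(dm.ids)
    i = ids.index(strain)
    best = min(
        ((dm[i, j], ids[j]) for j in range(len(ids)) if ids[j] != strain),
        key=lambda x: (x[0], x[1]),
    )
    return best[1]


def _foreign_ordinals(prov, domain_info, dm, groups, strain, margin):
    """Ordinals whose nearest neighbor is cross-group by a clear distance margin."""
    ids = list(dm.ids)
    pos = {d: i for i, d in enumerate(ids)}
    own = {o: d for d, (s, o) in domain_info.items() if s == strain}
    foreign = []
    for o, entry in prov.entries.items():
        if entry is None:
            continue
        _, n_strain, n_group, dist = entry
        if n_group == groups[strain]:
            continue
        same_group = [
            dm[pos[own[o]], pos[d]]
            for d, (s, _) in domain_info.items()
            if s != strain and groups.get(s) == groups[strain]
        ]
        if not same_group or dist <= margin * min(same_group):
            foreign.append(o)
    return sorted(foreign)


def analyze_clade(
    proteins: list,
    gene_order: pd.DataFrame,
    species_tree,
    groups: dict,
    receptors: dict | None = None,
    library=None,
    reference_table=None,
    scan_threshold: float = arch_mod.DEFAULT_SCAN_THRESHOLD,
    min_score: int = specificity.DEFAULT_MIN_SCORE,
    swap_low: float = ev.SWAP_LOW_IDENTITY,
    swap_high: float = ev.SWAP_HIGH_IDENTITY,
    monophyly_fraction: float = ev.MONOPHYLY_FRACTION,
    foreign_margin: float = ev.FOREIGN_MARGIN,
    use_phylo_vote: bool = True,
    detect: bool = True,
) -> AnalysisResult:
    library = library or load_template_library()
    reference_table = reference_table or load_reference_table()
    seq_by_id = {p.id: p.sequence for p in proteins}
    scanner = MotifScanner(library, scan_threshold)

    # scan + segment per strain, in gene order
    assemblies = {}
    order = gene_order.sort_values(["strain", "gene_index"])
    for strain, sub in order.groupby("strain", sort=True):
        hits = [
            (pid, scanner.scan(seq_by_id[pid])) for pid in sub["protein_id"]
        ]
        assemblies[strain] = segment_modules(hits, strain=str(strain))

    # A-domain inventory
    adomain_seqs, domain_info, per_strain_ids = {}, {}, {}
    for strain, asm in assemblies.items():
        ids = []
        ordinal = 0
        for g, arch in enumerate(asm.architectures, start=1):
            pseq = seq_by_id[arch.protein_id]
            for i, mod in enumerate(arch.modules, start=1):
                ordinal += 1
                a = mod.a_hit
                dom_id = f"{strain}_S{g}_A{i}"
                adomain_seqs[dom_id] = pseq[a.start - 1 : a.end]
                domain_info[dom_id] = (strain, ordinal)
                ids.append(dom_id)
        per_strain_ids[strain] = ids

    # one distance matrix over queries + references, reused everywhere
    ref_labeled = {
        f"ref|{e.substrate}|{i}": e.sequence for i, e in enumerate(reference_table)
    }
    full_dm = phylo.distance_matrix({**adomain_seqs, **ref_labeled})
    pred_tree = phylo.neighbor_joining(full_dm) if use_phylo_vote else None
    adomain_dm = full_dm.filter(sorted(adomain_seqs))
    adomain_tree = phylo.neighbor_joining(adomain_dm) if len(adomain_seqs) >= 3 else None

    predictions = {}
    for dom_id, seq in adomain_seqs.items():
        try:
            code = specificity.extract_code(seq, library)
            code_vote = specificity.classify_code(code, reference_table, min_score)
        except specificity.ExtractionFailure:
            code_vote = (specificity.XXX, 0)
        phylo_vote = (
            specificity.phylo_classify(dom_id, adomain_seqs, reference_table, tree=pred_tree)
            if use_phylo_vote
            else (None, 0)
        )
        predictions[dom_id] = specificity.consensus_predict(code_vote, phylo_vote, min_score)

    substrates = {
        strain: [predictions[d].substrate for d in per_strain_ids[strain]]
        for strain in assemblies
    }
    backbones = {
        strain: arch_mod.assemble_backbone(assemblies[strain], substrates[strain])
        for strain in sorted(assemblies)
    }
    registry, labels = ev.assign_types(backbones)

    shared = ev.detect_shared_types(labels, groups)
    hypotheses = []
    if adomain_tree is not None:
        for t_label, _ in shared:
            hypotheses.append(
                ev.domain_tree_congruence(
                    adomain_tree, domain_info, groups, t_label, labels, monophyly_fraction
                )
            )

    provenance = {
        strain: ev.per_domain_provenance(strain, domain_info, adomain_dm, groups)
        for strain in sorted(assemblies)
    }

    detected: list = []
    if detect and len(assemblies) >= 2:
        pat = phylo.patristic_distances(species_tree)
        pat_ids = list(pat.ids)
        pat_pos = {s: i for i, s in enumerate(pat_ids)}

        # per-strain foreign ordinals (cross-group nearest neighbors by margin)
        foreign_of = {
            strain: _foreign_ordinals(
                provenance[strain], domain_info, adomain_dm, groups, strain, foreign_margin
            )
            for strain in sorted(assemblies)
        }

        for strain in sorted(assemblies):
            foreign = foreign_of[strain]
            n_mod = len(assemblies[strain].modules)
            is_block = foreign and foreign == list(
                range(foreign[0], foreign[0] + len(foreign))
            )
            # transfer is symmetric in sequence space: suppress the donor
            # side, whose foreign-looking modules are still the ancestral
            # state of its own group (a clean same-group peer shares them)
            if foreign and not _group_ancestral(
                strain, foreign, substrates, groups, foreign_of, assemblies
            ):
                if len(foreign) == n_mod:
                    detected.append(
                        ev.DomainEvent("full_replacement", strain, tuple(foreign), {})
                    )
                elif len(foreign) >= 2 and is_block:
                    detected.append(
                        ev.DomainEvent("partial_replacement", strain, tuple(foreign), {})
                    )

            # duplication (needs only this strain's architecture + the tree)
            detected.extend(
                ev.detect_domain_duplication(
                    assemblies[strain], substrates[strain], per_strain_ids[strain], adomain_dm
                )
            )

        # pairwise comparisons with the nearest species-tree relatives; a
        # single nearest relative may itself carry an event (e.g. a module
        # count change), so the closest few are examined
        compared = set()
        for strain in sorted(assemblies):
            relatives = sorted(
                ((pat[pat_pos[strain], pat_pos[o]], o) for o in pat_ids if o != strain),
            )[:3]
            for _, relative in relatives:
                pair = tuple(sorted((strain, relative)))
                if pair in compared:
                    continue
                compared.add(pair)
                a, b = pair
                heat = ev.identity_heatmap(assemblies[a], assemblies[b], seq_by_id, seq_by_id)
                swap = ev.detect_specificity_swap(
                    assemblies[a], assemblies[b], substrates[a], substrates[b], heat,
                    swap_low, swap_high,
                )
                if swap is not None:
                    m = swap.module_ordinals[0]
                    affected = _attribute_swap(
                        a, b, m, domain_info, adomain_dm, groups, per_strain_ids
                    )
                    detected.append(
                        ev.DomainEvent("specificity_swap", affected, (m,), swap.evidence)
                    )
                for acc in ev.detect_accessory_diff(
                    assemblies[a], assemblies[b], substrates[a], substrates[b], heat
                ):
                    m = acc.module_ordinals[0]
                    affected, kind = _attribute_accessory(
                        a, b, m, assemblies, backbones, acc.evidence["a_has_E"]
                    )
                    detected.append(ev.DomainEvent(kind, affected, (m,), acc.evidence))

        # full replacement suppresses subsidiary calls on the same strain
        full = {e.strain for e in detected if e.kind == "full_replacement"}
        detected = [
            e for e in detected if e.kind == "full_replacement" or e.strain not in full
        ]
        # deduplicate
        seen = set()
        unique = []
        for e in detected:
            key = (e.kind, e.strain, e.module_ordinals)
            if key not in seen:
                seen.add(key)
                unique.append(e)
        detected = unique

    concordance, per_type = None, {}
    if receptors:
        rec_dm = phylo.distance_matrix(receptors)
        rec_tree = phylo.neighbor_joining(rec_dm)
        concordance, per_type = ev.receptor_type_concordance(
            rec_tree, {s: t for s, (t, _) in labels.items()}
        )

    return AnalysisResult(
        assemblies=assemblies,
        backbones=backbones,
        predictions=predictions,
        registry=registry,
        labels=labels,
        domain_info=domain_info,
        adomain_dm=adomain_dm,
        adomain_tree=adomain_tree,
        shared_types=shared,
        transfer_hypotheses=hypotheses,
        provenance=provenance,
        events=detected,
        receptor_concordance=concordance,
        receptor_per_type=per_type,
    )


def _group_ancestral(strain, ordinals, substrates, groups, foreign_of, assemblies):
    """True when a clean same-group peer carries the same substrates at ``ordinals``.

    Peers whose own provenance is foreign-free represent the group's
    ancestral state; if one of them matches the strain's substrates at the
    candidate ordinals, the strain is the donor side of a transfer, not the
    recipient.
    """
    mine = [substrates[strain][o - 1] for o in ordinals]
    for peer in assemblies:
        if peer == strain or groups.get(peer) != groups.get(strain):
            continue
        if foreign_of[peer]:
            continue
        if max(ordinals) > len(assemblies[peer].modules):
            continue
        theirs = [substrates[peer][o - 1] for o in ordinals]
        if theirs == mine:
            return True
    return False


def _attribute_swap(a, b, ordinal, domain_info, dm, groups, per_strain_ids):
    """The swapped strain is the one whose A domain is orphaned within its group."""
    ids = list(dm.ids)
    pos = {d: i for i, d in enumerate(ids)}

    def orphan_score(strain, partner):
        own = per_strain_ids[strain][ordinal - 1]
        dists = [
            dm[pos[own], pos[d]]
            for d, (s, _) in domain_info.items()
            if s not in (strain, partner) and groups.get(s) == groups[strain]
        ]
        return min(dists) if dists else np.inf

    return a if orphan_score(a, b) >= orphan_score(b, a) else b


def _attribute_accessory(a, b, ordinal, assemblies, backbones, a_has_e):
    """Majority E-state among same-backbone bearers decides who gained/lost."""
    rs = backbones[a].residue_string
    votes = []
    for s, asm in assemblies.items():
        if s in (a, b) or backbones[s].residue_string != rs:
            continue
        if ordinal <= len(asm.modules):
            votes.append(asm.modules[ordinal - 1].has_E)
    majority_has_e = (sum(votes) > len(votes) / 2) if votes else False
    # the deviant strain is affected
    if a_has_e != majority_has_e:
        affected, gained = a, a_has_e
    else:
        affected, gained = b, not a_has_e
    return affected, ("accessory_gain" if gained else "accessory_loss")


def analyze_simulated(clade: CladeData, **kw) -> AnalysisResult:
    """Run :func:`analyze_clade` on a simulated clade's rendered outputs."""
    proteins, rows = clade.proteins()
    return analyze_clade(
        proteins,
        pd.DataFrame(rows),
        clade.tree,
        clade.groups,
        receptors=clade.receptors,
        library=clade.library,
        **kw,
    )


def score_event_recovery(results_and_logs: list) -> pd.DataFrame:
    """Per-kind precision/recall of detected events against the simulation logs.

    ``results_and_logs`` is a list of (AnalysisResult, event_log) pairs;
    events match on (kind, recipient strain).
    """
    from .simulate import EVENT_KINDS

    tp = {k: 0 for k in EVENT_KINDS}
    fp = {k: 0 for k in EVENT_KINDS}
    fn = {k: 0 for k in EVENT_KINDS}
    for result, log in results_and_logs:
        truth = {(e.kind, e.recipient) for e in log}
        found = {(e.kind, e.strain) for e in result.events}
        for k, s in found & truth:
            tp[k] += 1
        for k, s in found - truth:
            fp[k] += 1
        for k, s in truth - found:
            fn[k] += 1
    rows = []
    for k in EVENT_KINDS:
        n_true = tp[k] + fn[k]
        n_found = tp[k] + fp[k]
        rows.append(
            {
                "kind": k,
                "n_true": n_true,
                "n_detected": n_found,
                "precision": tp[k] / n_found if n_found else float("nan"),
                "recall": tp[k] / n_true if n_true else float("nan"),
            }
        )
    return pd.DataFrame(rows)
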
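"""Pyoverdine typing and inference of the events that diversify the NRPS loci.

Backbone residue strings are collapsed into numbered pyoverdine types
(chirality differences make subtypes of one type). Cross-phylogroup type
sharing is screened for horizontal transfer by testing, per module ordinal,
whether the bearers' A domains cluster by type rather than by phylogroup in
the A-domain tree. Pairwise architecture comparisons plus per-domain
nearest-neighbor provenance then discriminate full and partial replacement
of the NRPS set, single A-domain specificity swaps, accessory E-domain
gain/loss, and intragenic domain duplication.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .architecture import ClusterAssembly

#: A-domain identity below this marks a module as foreign in a swap signature.
SWAP_LOW_IDENTITY = 0.70
#: Mean identity of the remaining domains must exceed this for a swap call.
SWAP_HIGH_IDENTITY = 0.90
#: Fraction of module ordinals that must be type-monophyletic for an HGT verdict.
MONOPHYLY_FRACTION = 0.80
#: A foreign nearest neighbor only counts when it is this much closer than the
#: nearest same-group domain (guards against deep-coalescence false calls).
FOREIGN_MARGIN = 0.6


@dataclass
class TypeRegistry:
    """First-seen-order map between backbone residue strings and Roman-numeral labels."""

    types: dict = field(default_factory=dict)      # residue string -> label
    subtypes: dict = field(default_factory=dict)   # (residue string, chirality) -> subtype label

    def label_of(self, residue_string: str) -> str:
        return self.types[residue_string]

    @property
    def n_types(self) -> int:
        return len(self.types)


def roman(n: int) -> str:
    vals = [1000, 900, 500, 400, 100, 90, 50, 40, 10, 9, 5, 4, 1]
    syms = ["M", "CM", "D", "CD", "C", "XC", "L", "XL", "X", "IX", "V", "IV", "I"]
    out = []
    for v, s in zip(vals, syms):
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def assign_types(backbones: dict) -> tuple:
    """Label backbones with Roman-numeral types in first-seen order.

    ``backbones`` maps strain -> BackbonePrediction. Identical residue strings
    (chirality ignored) share a type; distinct chirality signatures within a
    type become subtypes ``<label>a``, ``<label>b``, ...

    Returns (TypeRegistry, {strain: (type label, subtype label)}).
    """
    registry = TypeRegistry()
    chirality_seen: dict[str, list] = {}
    labels = {}
    for strain, bb in backbones.items():
        rs = bb.residue_string
        if rs not in registry.types:
            registry.types[rs] = roman(len(registry.types) + 1)
            chirality_seen[rs] = []
        t_label = registry.types[rs]
        chir = bb.chirality_string
        if chir not in chirality_seen[rs]:
            chirality_seen[rs].append(chir)
        sub = t_label + "abcdefghij"[chirality_seen[rs].index(chir)]
        registry.subtypes[(rs, chir)] = sub
        labels[strain] = (t_label, sub)
    return registry, labels


def detect_shared_types(labels: dict, groups: dict) -> list:
    """Types borne by strains of two or more phylogroups: [(type, sorted groups)]."""
    by_type: dict[str, set] = {}
    for strain, (t_label, _) in labels.items():
        by_type.setdefault(t_label, set()).add(groups[strain])
    return [
        (t, sorted(gs)) for t, gs in sorted(by_type.items()) if len(gs) >= 2
    ]


@dataclass
class TransferHypothesis:
    type_label: str
    groups: list
    verdict: str  # type_clustered | group_clustered | unresolved
    ordinal_monophyly: dict  # ordinal -> bool (type-wise monophyly)
    bearers: list


def domain_tree_congruence(
    adomain_tree,
    domain_info: dict,
    groups: dict,
    shared_type: str,
    labels: dict,
    monophyly_fraction: float = MONOPHYLY_FRACTION,
) -> TransferHypothesis:
    """HGT verdict for one cross-group type from A-domain tree clustering.

    ``domain_info`` maps A-domain tip label -> (strain, ordinal). For each
    module ordinal of the type, the bearers' domains are tested for
    monophyly across groups (the transfer signature: one clade per ordinal
    holding both groups' subclades). If instead each group's domains join
    within-group clades, the pattern is compatible with vertical descent.
    """
    bearers = sorted(s for s, (t, _) in labels.items() if t == shared_type)
    bearer_groups = sorted({groups[s] for s in bearers})
    ordinals = sorted({o for d, (s, o) in domain_info.items() if s in bearers})
    tips = {l.taxon.label for l in adomain_tree.leaf_node_iter()}

    type_mono: dict[int, bool] = {}
    group_mono: dict[int, bool] = {}
    for o in ordinals:
        domains = [d for d, (s, oo) in domain_info.items() if s in bearers and oo == o]
        if not set(domains) <= tips:
            raise ValueError(f"A-domain tips missing for ordinal {o}")
        mono, _ = phylo.monophyly_test(adomain_tree, domains)
        type_mono[o] = mono
        per_group = []
        for g in bearer_groups:
            sub = [d for d in domains if groups[domain_info[d][0]] == g]
            if sub:
                m, _ = phylo.monophyly_test(adomain_tree, sub)
                per_group.append(m)
        group_mono[o] = bool(per_group) and all(per_group) and not mono

    frac_type = sum(type_mono.values()) / len(ordinals)
    frac_group = sum(group_mono.values()) / len(ordinals)
    if frac_type >= monophyly_fraction:
        verdict = "type_clustered"
    elif frac_group >= monophyly_fraction:
        verdict = "group_clustered"
    else:
        verdict = "unresolved"
    return TransferHypothesis(shared_type, bearer_groups, verdict, type_mono, bearers)


@dataclass
class ProvenanceMap:
    strain: str
    entries: dict  # ordinal -> (neighbor domain id, neighbor strain, neighbor group, distance)


def per_domain_provenance(
    strain: str,
    domain_info: dict,
    dm,
    groups: dict,
) -> ProvenanceMap:
    """Nearest non-self-strain neighbor of each of a strain's A domains.

    ``dm`` is the A-domain distance matrix; ``domain_info`` maps domain id ->
    (strain, ordinal). Ties break by label order.
    """
    ids = list(dm.ids)
    pos = {d: i for i, d in enumerate(ids)}
    entries = {}
    query = sorted(
        (o, d) for d, (s, o) in domain_info.items() if s == strain
    )
    for o, d in query:
        best = None
        for other in sorted(ids):
            if other == d or domain_info[other][0] == strain:
                continue
            dist = dm[pos[d], pos[other]]
            if best is None or dist < best[3]:
                o_strain = domain_info[other][0]
                best = (other, o_strain, groups.get(o_strain), dist)
        entries[o] = best
    return ProvenanceMap(strain=strain, entries=entries)


@dataclass
class IdentityHeatmap:
    ordinals: list
    kinds: list
    values: np.ndarray  # (n_modules, n_kinds), NaN where a counterpart is absent

    def a_identities(self) -> dict:
        j = self.kinds.index("A")
        return {o: self.values[i, j] for i, o in enumerate(self.ordinals)}


def identity_heatmap(
    arch_a: ClusterAssembly,
    arch_b: ClusterAssembly,
    seqs_a: dict,
    seqs_b: dict,
) -> IdentityHeatmap:
    """Domain-by-domain alignment identities between two architectures.

    Modules are aligned by ordinal and domains by kind; cells where either
    side lacks the counterpart are NaN. ``seqs_*`` map protein id -> sequence.
    """
    kinds = ["C", "A", "T", "E"]
    mods_a, mods_b = arch_a.modules, arch_b.modules
    n = max(len(mods_a), len(mods_b))
    values = np.full((n, len(kinds)), np.nan)
    for i in range(n):
        if i >= len(mods_a) or i >= len(mods_b):
            continue
        da = {d.kind: d for d in mods_a[i].domains}
        db = {d.kind: d for d in mods_b[i].domains}
        for j, kind in enumerate(kinds):
            if kind in da and kind in db:
                sa = seqs_a[mods_a[i].protein_id][da[kind].start - 1 : da[kind].end]
                sb = seqs_b[mods_b[i].protein_id][db[kind].start - 1 : db[kind].end]
                values[i, j] = phylo.pairwise_identity(sa, sb)
    return IdentityHeatmap(list(range(1, n + 1)), kinds, values)


@dataclass
class DomainEvent:
    kind: str
    strain: str
    module_ordinals: tuple
    evidence: dict = field(default_factory=dict)


def detect_specificity_swap(
    arch_a: ClusterAssembly,
    arch_b: ClusterAssembly,
    substrates_a: list,
    substrates_b: list,
    heatmap: IdentityHeatmap,
    low: float = SWAP_LOW_IDENTITY,
    high: float = SWAP_HIGH_IDENTITY,
) -> DomainEvent | None:
    """Single-module substrate change with the replacement identity signature.

    Fires only when exactly one module's substrates differ, that module's
    A-domain identity falls below ``low``, and the mean identity of all other
    comparable domains exceeds ``high``. The affected strain is not decided
    here (the pair is symmetric); callers attribute it.
    """
    if len(arch_a.modules) != len(arch_b.modules):
        return None
    diffs = [
        i + 1
        for i, (sa, sb) in enumerate(zip(substrates_a, substrates_b))
        if sa != sb
    ]
    if len(diffs) != 1:
        return None
    m = diffs[0]
    i = m - 1
    a_ident = heatmap.values[i, heatmap.kinds.index("A")]
    if not np.isfinite(a_ident) or a_ident >= low:
        return None
    mask = np.ones(heatmap.values.shape[0], dtype=bool)
    mask[i] = False
    others = heatmap.values[mask]
    others = others[np.isfinite(others)]
    if others.size == 0 or others.mean() <= high:
        return None
    return DomainEvent(
        "specificity_swap",
        arch_a.strain,
        (m,),
        {
            "a_identity": float(a_ident),
            "other_mean_identity": float(others.mean()),
            "substrates": (substrates_a[i], substrates_b[i]),
            "partner": arch_b.strain,
        },
    )


def detect_accessory_diff(
    arch_a: ClusterAssembly,
    arch_b: ClusterAssembly,
    substrates_a: list,
    substrates_b: list,
    heatmap: IdentityHeatmap | None = None,
) -> list:
    """Per-module E-domain presence differences between same-backbone architectures."""
    if len(arch_a.modules) != len(arch_b.modules) or substrates_a != substrates_b:
        return []
    out = []
    for i, (ma, mb) in enumerate(zip(arch_a.modules, arch_b.modules)):
        if ma.has_E != mb.has_E:
            evidence = {"partner": arch_b.strain, "a_has_E": ma.has_E}
            if heatmap is not None:
                for kind in ("C", "T"):
                    v = heatmap.values[i, heatmap.kinds.index(kind)]
                    if np.isfinite(v):
                        evidence[f"flanking_{kind}_identity"] = float(v)
            out.append(
                DomainEvent(
                    "accessory_gain" if ma.has_E else "accessory_loss",
                    arch_a.strain,
                    (i + 1,),
                    evidence,
                )
            )
    return out


def detect_domain_duplication(
    arch: ClusterAssembly,
    substrates: list,
    adomain_ids: list,
    dm,
) -> list:
    """Adjacent same-substrate modules whose A domains are mutual nearest neighbors.

    ``adomain_ids`` lists the strain's A-domain labels in module order; ``dm``
    is a distance matrix containing them (and everyone else's domains).
    """
    ids = list(dm.ids)
    pos = {d: i for i, d in enumerate(ids)}

    def is_nearest(d, partner):
        # partner must be at (or tied with, within float noise) d's minimum
        others = min(dm[pos[d], pos[o]] for o in ids if o != d)
        return dm[pos[d], pos[partner]] <= others + 1e-12

    out = []
    for i in range(len(substrates) - 1):
        if substrates[i] != substrates[i + 1]:
            continue
        da, db = adomain_ids[i], adomain_ids[i + 1]
        if is_nearest(da, db) and is_nearest(db, da):
            out.append(
                DomainEvent(
                    "domain_duplication",
                    arch.strain,
                    (i + 1, i + 2),
                    {"pair": (da, db)},
                )
            )
    return out


def receptor_type_concordance(receptor_tree, strain_types: dict) -> tuple:
    """Fraction of multi-bearer types whose receptors are monophyletic.

    ``strain_types`` maps strain -> type label; tree tips are strain names.
    Returns (concordance fraction, {type: is_monophyletic}).
    """
    import warnings as _warnings

    tips = {l.taxon.label for l in receptor_tree.leaf_node_iter()}
    untyped = tips - set(strain_types)
    if untyped:
        _warnings.warn(f"untyped receptor tips ignored: {sorted(untyped)}")
    by_type: dict[str, list] = {}
    for strain, t in strain_types.items():
        if strain in tips:
            by_type.setdefault(t, []).append(strain)
    per_type = {}
    for t, bearers in sorted(by_type.items()):
        if len(bearers) < 2:
            continue
        mono, _ = phylo.monophyly_test(receptor_tree, bearers)
        per_type[t] = mono
    frac = (sum(per_type.values()) / len(per_type)) if per_type else float("nan")
    return frac, per_type
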
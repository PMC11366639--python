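"""Synthetic species trees, evolving pyoverdine types, NRPS clusters and receptors.

The generator produces everything the inference stages consume, with logged
ground truth: a Yule species tree; a discrete pyoverdine-type character
evolving under an equal-rates Mk process; per-tip NRPS clusters whose module
grammar (C-A-T with optional E, terminal TE) encodes the type's backbone via
implanted specificity codes; per-type receptor sequences; and implanted
evolutionary events — full or partial replacement of the NRPS set across
phylogroups, A-domain specificity swaps, accessory E-domain gain/loss and
intragenic module duplication — recorded in an event log that can be
replayed exactly.

Clusters are represented structurally (modules of domain sequences) until
rendered to protein FASTA records; point substitutions are the only noise
process (no indels), so template coordinates stay exact and the scanner's
ground truth is unambiguous.
"""
from __future__ import annotations

import copy
import random
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .architecture import ProteinRecord
from .templates import DomainTemplateLibrary, load_reference_table, load_template_library

_AAS = "ACDEFGHIKLMNPQRSTVWY"

EVENT_KINDS = (
    "full_replacement",
    "partial_replacement",
    "specificity_swap",
    "accessory_gain",
    "accessory_loss",
    "domain_duplication",
)


@dataclass
class SimulationConfig:
    n_tips: int = 12
    birth_rate: float = 1.0
    n_states: int = 4
    char_rate: float = 0.3
    backbone_length_range: tuple = (4, 12)
    substrate_alphabet: list = None
    noise_rate: float = 0.02
    seed: int = 0
    # generator internals (study conditions; see docs/methods.md)
    seq_rate: float = 0.03          # per-site substitutions per unit branch length
    module_divergence: float = 0.10  # ancestral per-module identity perturbation
    copy_noise: float = 0.01        # per-site noise on horizontally copied material
    swap_divergence: float = 0.25   # divergence of a swapped-in foreign A domain
    receptor_type_divergence: float = 0.15
    receptor_tip_noise: float = 0.02
    epimerize_prob: float = 0.3
    min_group_size: int = 4
    type_mode: str = "group_private"  # group_private | mk

    def __post_init__(self):
        if self.substrate_alphabet is None:
            self.substrate_alphabet = [e.substrate for e in load_reference_table()]
        lo, hi = self.backbone_length_range
        if not (4 <= lo <= hi <= 12):
            raise ValueError("backbone length range must lie within [4, 12]")
        if len(set(self.substrate_alphabet)) != len(self.substrate_alphabet):
            raise ValueError("substrate alphabet entries must be unique")
        for rate in (self.birth_rate, self.char_rate, self.seq_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise rate must be a probability")
        if self.n_states < 2:
            raise ValueError("need at least 2 character states")


@dataclass
class EventLogEntry:
    kind: str
    donor: str | None
    recipient: str
    module_ordinals: tuple
    timestamp: str = "post-hoc"
    seed: int | None = None  # sub-seed used when applying, for exact replay
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind}")


@dataclass
class SimModule:
    substrate: str
    has_E: bool
    seqs: dict  # domain kind -> amino-acid sequence


@dataclass
class SimCluster:
    modules: list
    boundaries: list  # modules per protein, in gene order
    te_seq: str

    def backbone(self) -> list:
        return [(m.substrate, m.has_E) for m in self.modules]

    def residue_string(self) -> str:
        return "-".join(m.substrate for m in self.modules)


def _derive_seed(seed: int, *salt) -> int:
    salted = [zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in salt]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *salted])
    return int(ss.generate_state(1)[0] % (2**31))


def _mutate(seq: str, p: float, rng, protected=frozenset()) -> str:
    """Per-site substitution with probability p to a uniformly drawn other residue."""
    if p <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        if (i + 1) in protected:
            continue
        cur = chars[i]
        choices = [a for a in _AAS if a != cur]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate_species_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Rooted ultrametric pure-birth (Yule) tree with ``n_tips`` labeled tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops exactly at the final split; run the clock on to the
    # next (uncommitted) birth so every terminal branch is strictly positive
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.is_rooted = True
    return tree


def scale_tree_height(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    factor = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def _er_transition(k: int, q: float, t: float, same: bool) -> float:
    stay = 1.0 / k + (k - 1) / k * np.exp(-k * q * t)
    return stay if same else (1.0 - stay) / (k - 1)


def evolve_discrete_character(
    tree: dendropy.Tree, n_states: int, char_rate: float, root_state: int, seed: int
) -> tuple:
    """Equal-rates Mk simulation; returns (tip states, all-node true states)."""
    if not 0 <= root_state < n_states:
        raise ValueError("root state out of range")
    if char_rate < 0:
        raise ValueError("char_rate must be non-negative")
    rng = np.random.default_rng(int(seed))
    node_states, tip_states = {}, {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = root_state
        else:
            parent = node.parent_node._sim_state
            t = node.edge.length or 0.0
            stay = _er_transition(n_states, char_rate, t, same=True)
            if rng.random() < stay:
                state = parent
            else:
                others = [s for s in range(n_states) if s != parent]
                state = others[rng.integers(0, len(others))]
        node._sim_state = state
        if node.is_leaf():
            tip_states[node.taxon.label] = state
        else:
            if not node.label:
                counter += 1
                node.label = f"N{counter}"
            node_states[node.label] = state
    return tip_states, node_states


def build_sim_cluster(
    backbone_spec: list,
    library: DomainTemplateLibrary,
    rng,
    module_divergence: float = 0.0,
    n_proteins: int | None = None,
    reference_codes: dict | None = None,
) -> SimCluster:
    """Structured cluster implementing ``backbone_spec`` = [(substrate, epimerized), ...]."""
    if not backbone_spec:
        raise ValueError("backbone spec must be non-empty")
    codes = reference_codes or {e.substrate: e.code for e in load_reference_table()}
    protected = frozenset(library.code_positions)
    modules = []
    for substrate, has_e in backbone_spec:
        if substrate not in codes:
            raise ValueError(f"substrate {substrate} not in reference alphabet")
        a = list(library.templates["A"])
        for pos, res in zip(library.code_positions, codes[substrate]):
            a[pos - 1] = res
        seqs = {
            "C": _mutate(library.templates["C"], module_divergence, rng),
            "A": _mutate("".join(a), module_divergence, rng, protected=protected),
            "T": _mutate(library.templates["T"], module_divergence, rng),
        }
        if has_e:
            seqs["E"] = _mutate(library.templates["E"], module_divergence, rng)
        modules.append(SimModule(substrate, has_e, seqs))
    n_mod = len(modules)
    if n_proteins is None:
        n_proteins = int(rng.integers(1, min(4, n_mod) + 1))
    cuts = sorted(rng.choice(np.arange(1, n_mod), size=n_proteins - 1, replace=False)) if n_proteins > 1 else []
    bounds = np.diff([0, *cuts, n_mod]).tolist()
    return SimCluster(modules=modules, boundaries=bounds, te_seq=library.templates["TE"])


def mutate_cluster(cluster: SimCluster, p: float, rng, library: DomainTemplateLibrary,
                   protect_code: bool = True) -> SimCluster:
    """Copy of ``cluster`` with per-site noise applied outside A-domain code columns."""
    protected = frozenset(library.code_positions) if protect_code else frozenset()
    out = copy.deepcopy(cluster)
    for mod in out.modules:
        for kind in mod.seqs:
            mod.seqs[kind] = _mutate(
                mod.seqs[kind], p, rng, protected=protected if kind == "A" else frozenset()
            )
    out.te_seq = _mutate(out.te_seq, p, rng)
    return out


def render_cluster(cluster: SimCluster, strain: str) -> tuple:
    """Protein records plus gene-order TSV rows for one strain's cluster."""
    proteins, rows = [], []
    mod_iter = iter(cluster.modules)
    for g, count in enumerate(cluster.boundaries, start=1):
        seq = ""
        for _ in range(count):
            mod = next(mod_iter)
            seq += mod.seqs["C"] + mod.seqs["A"] + mod.seqs["T"] + mod.seqs.get("E", "")
        if g == len(cluster.boundaries):
            seq += cluster.te_seq
        pid = f"{strain}_S{g}"
        proteins.append(ProteinRecord(pid, seq))
        rows.append({"strain": strain, "cluster_id": f"{strain}_cluster", "gene_index": g, "protein_id": pid})
    return proteins, rows


def simulate_nrps_cluster(
    backbone_spec: list,
    library: DomainTemplateLibrary | None = None,
    noise_rate: float = 0.0,
    seed: int = 0,
    strain: str = "strain",
    protect_code: bool = True,
    n_proteins: int | None = None,
) -> tuple:
    """Simulate one strain's NRPS cluster; returns (proteins, gene-order rows, SimCluster)."""
    library = library or load_template_library()
    rng = np.random.default_rng(int(seed))
    cluster = build_sim_cluster(backbone_spec, library, rng, n_proteins=n_proteins)
    cluster = mutate_cluster(cluster, noise_rate, rng, library, protect_code=protect_code)
    proteins, rows = render_cluster(cluster, strain)
    return proteins, rows, cluster


def apply_event(
    clusters: dict,
    entry: EventLogEntry,
    library: DomainTemplateLibrary,
    config: SimulationConfig,
) -> None:
    """Apply one logged event to ``clusters`` in place (deterministic via entry.seed)."""
    rng = np.random.default_rng(entry.seed if entry.seed is not None else 0)
    recipient = clusters[entry.recipient]
    kind = entry.kind

    def noisy_copy(cluster):
        return mutate_cluster(cluster, config.copy_noise, rng, library)

    if kind == "full_replacement":
        clusters[entry.recipient] = noisy_copy(clusters[entry.donor])
    elif kind == "partial_replacement":
        keep = entry.detail["keep_prefix"]
        donor = noisy_copy(clusters[entry.donor])
        new_modules = recipient.modules[:keep] + donor.modules[keep:]
        clusters[entry.recipient] = SimCluster(
            modules=new_modules,
            boundaries=_rebalance(len(new_modules), recipient.boundaries),
            te_seq=donor.te_seq,
        )
    elif kind == "specificity_swap":
        ordinal = entry.module_ordinals[0]
        mod = recipient.modules[ordinal - 1]
        new_sub = entry.detail["new_substrate"]
        ref = {e.substrate: e for e in load_reference_table()}[new_sub]
        protected = frozenset(library.code_positions)
        mod.seqs["A"] = _mutate(ref.sequence, config.swap_divergence, rng, protected=protected)
        mod.substrate = new_sub
    elif kind == "accessory_gain":
        ordinal = entry.module_ordinals[0]
        mod = recipient.modules[ordinal - 1]
        if mod.has_E:
            raise ValueError(f"module {ordinal} already epimerized")
        mod.seqs["E"] = _mutate(library.templates["E"], config.module_divergence, rng)
        mod.has_E = True
    elif kind == "accessory_loss":
        ordinal = entry.module_ordinals[0]
        mod = recipient.modules[ordinal - 1]
        if not mod.has_E:
            raise ValueError(f"module {ordinal} has no E domain")
        del mod.seqs["E"]
        mod.has_E = False
    elif kind == "domain_duplication":
        ordinal = entry.module_ordinals[0]
        src = recipient.modules[ordinal - 1]
        dup = SimModule(
            substrate=src.substrate,
            has_E=False,
            seqs={
                k: _mutate(src.seqs[k], config.copy_noise, rng,
                           protected=frozenset(library.code_positions) if k == "A" else frozenset())
                for k in ("C", "A", "T")
            },
        )
        recipient.modules.insert(ordinal, dup)
        recipient.boundaries = _grow_boundary(recipient.boundaries, ordinal)
    else:  # pragma: no cover - EventLogEntry validates kinds
        raise ValueError(kind)


def _rebalance(n_modules: int, old_bounds: list) -> list:
    """Protein boundaries for a rebuilt cluster, keeping the old gene count when possible."""
    n_prot = min(len(old_bounds), n_modules)
    base = n_modules // n_prot
    bounds = [base] * n_prot
    for i in range(n_modules - base * n_prot):
        bounds[i] += 1
    return bounds


def _grow_boundary(bounds: list, ordinal: int) -> list:
    """Grow the protein containing module ``ordinal`` by one (intragenic duplication)."""
    out = list(bounds)
    acc = 0
    for i, b in enumerate(out):
        acc += b
        if ordinal <= acc:
            out[i] += 1
            return out
    out[-1] += 1
    return out


def inject_event(
    clusters: dict,
    event_request: dict,
    seed: int,
    library: DomainTemplateLibrary | None = None,
    config: SimulationConfig | None = None,
    groups: dict | None = None,
) -> EventLogEntry:
    """Realize one requested event on ``clusters`` (in place) and return its log entry.

    ``event_request`` carries ``kind`` and optionally ``recipient``, ``donor``,
    ``module``; unset choices are drawn reproducibly from ``seed``.
    """
    library = library or load_template_library()
    config = config or SimulationConfig(seed=seed)
    kind = event_request["kind"]
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind}")
    rng = np.random.default_rng(_derive_seed(seed, "choose", kind))
    tips = sorted(clusters)

    def pick(candidates, label):
        if not candidates:
            raise ValueError(f"no eligible {label} for event {kind}")
        return candidates[rng.integers(0, len(candidates))]

    recipient = event_request.get("recipient")
    donor = event_request.get("donor")
    module = event_request.get("module")

    if kind in ("full_replacement", "partial_replacement"):
        if recipient is None:
            recipient = pick(tips, "recipient")
        if donor is None:
            pool = [t for t in tips if t != recipient]
            if groups:
                cross = [t for t in pool if groups[t] != groups[recipient]]
                pool = cross or pool
            donor = pick(pool, "donor")
        n_r, n_d = len(clusters[recipient].modules), len(clusters[donor].modules)
        if kind == "partial_replacement":
            max_keep = min(n_r, n_d) - 2
            if max_keep < 1:
                raise ValueError("clusters too short for a partial replacement")
            keep = module if module is not None else int(rng.integers(1, max_keep + 1))
            ordinals = tuple(range(keep + 1, n_d + 1))
            detail = {"keep_prefix": keep}
        else:
            ordinals = tuple(range(1, n_d + 1))
            detail = {}
    else:
        cluster = clusters[recipient] if recipient else None
        if kind == "specificity_swap":
            if recipient is None:
                recipient = pick(tips, "recipient")
                cluster = clusters[recipient]
            m = module if module is not None else int(rng.integers(1, len(cluster.modules) + 1))
            if not 1 <= m <= len(cluster.modules):
                raise ValueError(f"module ordinal out of range for {recipient}")
            old = cluster.modules[m - 1].substrate
            new = event_request.get("new_substrate") or pick(
                [s for s in config.substrate_alphabet if s != old], "substrate"
            )
            ordinals, detail = (m,), {"new_substrate": new, "old_substrate": old}
        elif kind == "accessory_gain":
            if recipient is None:
                recipient = pick(
                    [t for t in tips if any(not m.has_E for m in clusters[t].modules)], "recipient"
                )
                cluster = clusters[recipient]
            cands = [i + 1 for i, m in enumerate(cluster.modules) if not m.has_E]
            m = module if module is not None else pick(cands, "module")
            ordinals, detail = (m,), {}
        elif kind == "accessory_loss":
            if recipient is None:
                recipient = pick(
                    [t for t in tips if any(m.has_E for m in clusters[t].modules)], "recipient"
                )
                cluster = clusters[recipient]
            cands = [i + 1 for i, m in enumerate(cluster.modules) if m.has_E]
            m = module if module is not None else pick(cands, "module")
            ordinals, detail = (m,), {}
        else:  # domain_duplication
            if recipient is None:
                recipient = pick(tips, "recipient")
                cluster = clusters[recipient]
            m = module if module is not None else int(rng.integers(1, len(cluster.modules) + 1))
            ordinals, detail = (m, m + 1), {}
        donor = None

    n_modules = len(clusters[recipient].modules)
    if kind in ("specificity_swap", "accessory_gain", "accessory_loss") and any(
        o > n_modules for o in ordinals
    ):
        raise ValueError(f"module ordinal out of range for {recipient}")
    if kind == "domain_duplication" and ordinals[0] > n_modules:
        raise ValueError(f"module ordinal out of range for {recipient}")

    entry = EventLogEntry(
        kind=kind,
        donor=donor,
        recipient=recipient,
        module_ordinals=ordinals,
        seed=_derive_seed(seed, "apply", kind, recipient),
        detail=detail,
    )
    apply_event(clusters, entry, library, config)
    return entry


@dataclass
class CladeData:
    """One simulated clade: the full ground-truth bundle for the inference stages."""

    config: SimulationConfig
    tree: dendropy.Tree
    groups: dict            # tip -> phylogroup name
    tip_types: dict         # tip -> type index (post-event backbones may differ)
    ancestral_clusters: dict  # tip -> SimCluster before events
    clusters: dict          # tip -> SimCluster after events
    receptors: dict         # tip -> receptor sequence
    event_log: list
    library: DomainTemplateLibrary

    def proteins(self) -> tuple:
        """All protein records and gene-order rows, tips in sorted order."""
        proteins, rows = [], []
        for tip in sorted(self.clusters):
            p, r = render_cluster(self.clusters[tip], tip)
            proteins.extend(p)
            rows.extend(r)
        return proteins, rows


def _random_backbone(rng, config: SimulationConfig) -> list:
    lo, hi = config.backbone_length_range
    length = int(rng.integers(lo, hi + 1))
    subs = [config.substrate_alphabet[rng.integers(0, len(config.substrate_alphabet))] for _ in range(length)]
    flags = list(rng.random(length) < config.epimerize_prob)
    # keep both chirality states represented so accessory gain and loss are
    # always realizable on any lineage
    if all(flags):
        flags[rng.integers(0, length)] = False
    elif not any(flags):
        flags[rng.integers(0, length)] = True
    return list(zip(subs, map(bool, flags)))


def simulate_receptor_set(
    type_of: dict,
    seed: int,
    library: DomainTemplateLibrary | None = None,
    type_divergence: float = 0.15,
    tip_noise: float = 0.02,
) -> dict:
    """Per-strain receptor sequences: one diverged template per type plus tip noise."""
    library = library or load_template_library()
    base = library.receptor_template
    variants = {}
    for t in sorted(set(type_of.values()), key=str):
        v_rng = np.random.default_rng(_derive_seed(seed, "receptor-type", str(t)))
        variants[t] = _mutate(base, type_divergence, v_rng)
    out = {}
    for strain in sorted(type_of):
        s_rng = np.random.default_rng(_derive_seed(seed, "receptor-tip", strain))
        out[strain] = _mutate(variants[type_of[strain]], tip_noise, s_rng)
    return out


def simulate_clade(
    config: SimulationConfig,
    event_requests: list | None = None,
    library: DomainTemplateLibrary | None = None,
) -> CladeData:
    """Simulate a full clade with ground truth and optional implanted events.

    Tips split into two phylogroups at the root; in ``group_private`` mode
    each group starts from its own ancestral backbone (so types are
    group-private until an event shares them), while ``mk`` mode evolves the
    type character over the whole catalog along the tree. Domain sequences
    drift along branches at ``seq_rate`` per site per unit time.
    """
    library = library or load_template_library()
    seed = config.seed
    event_requests = event_requests or []

    # species tree with both root clades big enough to carry group signal
    tree = None
    for attempt in range(200):
        cand = simulate_species_tree(config.n_tips, config.birth_rate, _derive_seed(seed, "tree", attempt))
        scale_tree_height(cand, 1.0)
        sides = [len(c.leaf_nodes()) for c in cand.seed_node.child_nodes()]
        if len(sides) == 2 and min(sides) >= min(config.min_group_size, config.n_tips // 3):
            tree = cand
            break
    if tree is None:
        raise RuntimeError("could not simulate a tree with two sizeable root clades")

    root_children = tree.seed_node.child_nodes()
    groups = {}
    for g, child in enumerate(root_children, start=1):
        for leaf in child.leaf_iter():
            groups[leaf.taxon.label] = f"G{g}"

    # type catalog: distinct backbones
    cat_rng = np.random.default_rng(_derive_seed(seed, "catalog"))
    catalog = []
    while len(catalog) < config.n_states:
        bb = _random_backbone(cat_rng, config)
        if all("-".join(s for s, _ in bb) != "-".join(s for s, _ in c) for c in catalog):
            catalog.append(bb)

    ancestral = {}
    for t in range(config.n_states):
        a_rng = np.random.default_rng(_derive_seed(seed, "ancestor", t))
        ancestral[t] = build_sim_cluster(
            catalog[t], library, a_rng, module_divergence=config.module_divergence
        )

    # assign types
    if config.type_mode == "group_private":
        tip_types = {tip: (0 if groups[tip] == "G1" else 1) for tip in groups}
        tree.seed_node._sim_type = 0
        for g, child in enumerate(root_children):
            for nd in child.preorder_iter():
                nd._sim_type = g
    else:
        tip_types, node_types = evolve_discrete_character(
            tree, config.n_states, config.char_rate, root_state=0,
            seed=_derive_seed(seed, "types"),
        )
        tree.seed_node._sim_type = 0
        for nd in tree.preorder_node_iter():
            nd._sim_type = nd._sim_state

    # evolve cluster sequences down the tree
    drift_rng = np.random.default_rng(_derive_seed(seed, "drift"))
    tree.seed_node._sim_cluster = copy.deepcopy(ancestral[getattr(tree.seed_node, "_sim_type", 0)])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node.parent_node
        t = node.edge.length or 0.0
        p = 1.0 - np.exp(-config.seq_rate * t)
        if node._sim_type != parent._sim_type:
            depth = node.distance_from_root()
            base = copy.deepcopy(ancestral[node._sim_type])
            node._sim_cluster = mutate_cluster(
                base, 1.0 - np.exp(-config.seq_rate * depth), drift_rng, library
            )
        else:
            node._sim_cluster = mutate_cluster(parent._sim_cluster, p, drift_rng, library)

    clusters = {l.taxon.label: l._sim_cluster for l in tree.leaf_node_iter()}
    # per-tip measurement noise
    for tip in sorted(clusters):
        n_rng = np.random.default_rng(_derive_seed(seed, "noise", tip))
        clusters[tip] = mutate_cluster(clusters[tip], config.noise_rate, n_rng, library)
    ancestral_clusters = copy.deepcopy(clusters)

    event_log = []
    used = set()
    for i, req in enumerate(event_requests):
        req = dict(req)
        pick_rng = np.random.default_rng(_derive_seed(seed, "pick", i))
        if req.get("recipient") is None:
            cands = [t for t in sorted(clusters) if t not in used]
            req["recipient"] = cands[pick_rng.integers(0, len(cands))]
        used.add(req["recipient"])
        if req["kind"] in ("full_replacement", "partial_replacement") and req.get("donor") is None:
            pool = [
                t for t in sorted(clusters)
                if t not in used and groups[t] != groups[req["recipient"]]
            ] or [t for t in sorted(clusters) if t not in used]
            req["donor"] = pool[pick_rng.integers(0, len(pool))]
        entry = inject_event(
            clusters, req, seed=_derive_seed(seed, "event", i),
            library=library, config=config, groups=groups,
        )
        if entry.donor:
            used.add(entry.donor)
        event_log.append(entry)

    final_types = {tip: clusters[tip].residue_string() for tip in clusters}
    receptors = simulate_receptor_set(
        final_types, _derive_seed(seed, "receptors"), library,
        type_divergence=config.receptor_type_divergence,
        tip_noise=config.receptor_tip_noise,
    )

    return CladeData(
        config=config,
        tree=tree,
        groups=groups,
        tip_types=tip_types,
        ancestral_clusters=ancestral_clusters,
        clusters=clusters,
        receptors=receptors,
        event_log=event_log,
        library=library,
    )
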
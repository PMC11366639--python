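"""Consensus A-domain substrate prediction.

Each adenylation domain is classified two ways: (i) its ten binding-pocket
residues (the specificity code) are read off a global alignment to the
canonical anchor domain and matched against a table of characterized codes;
(ii) the domain is placed on a neighbor-joining tree together with the
characterized reference domains and inherits the unanimous substrate of the
smallest clade containing it and at least one reference. The consensus rule
prefers agreement, then a well-supported phylogenetic vote (the precedent
being code-level glycine calls that group with characterized alanine
domains), then the code vote, and otherwise falls back to ``Xxx``.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import phylo
from .templates import DomainTemplateLibrary, ReferenceEntry

GAP = "-"
XXX = "Xxx"

#: Minimum code matches (out of 10) for a code-based call.
DEFAULT_MIN_SCORE = 7

#: Minimum characterized references in the clade for a phylogenetic override.
DEFAULT_OVERRIDE_SUPPORT = 2


class ExtractionFailure(ValueError):
    """Alignment leaves too many code columns gapped to read a code."""


@dataclass(frozen=True)
class SpecificityCode:
    residues: str
    anchor_positions: tuple

    def __post_init__(self):
        if len(self.residues) != 10:
            raise ValueError("specificity code must have length 10")


@dataclass(frozen=True)
class Prediction:
    substrate: str
    code_vote: tuple  # (substrate, matches out of 10)
    phylo_vote: tuple  # (substrate or None, reference count in clade)
    method: str  # agreement | phylo_override | code_only | xxx


def extract_code(sequence: str, library: DomainTemplateLibrary) -> SpecificityCode:
    """Read the query residues in the anchor's marked code columns."""
    anchor = library.anchor_sequence
    aln = phylo.needleman_wunsch(anchor, sequence)
    # map anchor columns -> query residues
    code = []
    anchor_pos = 0
    wanted = set(library.code_positions)
    for a_res, q_res in zip(aln.aligned_a, aln.aligned_b):
        if a_res != GAP:
            anchor_pos += 1
            if anchor_pos in wanted:
                code.append(q_res if q_res != GAP else GAP)
    n_gapped = sum(c == GAP for c in code)
    if n_gapped >= 5:
        raise ExtractionFailure(f"{n_gapped}/10 code columns gapped in alignment")
    return SpecificityCode("".join(code), tuple(library.code_positions))


def classify_code(
    code: SpecificityCode,
    reference_table: list,
    min_score: int = DEFAULT_MIN_SCORE,
) -> tuple:
    """Nearest characterized code by match count; ties or weak matches give Xxx."""
    if not reference_table:
        raise ValueError("reference table is empty")
    best: dict[str, int] = {}
    for entry in reference_table:
        matches = sum(a == b for a, b in zip(code.residues, entry.code))
        if matches > best.get(entry.substrate, -1):
            best[entry.substrate] = matches
    top = max(best.values())
    winners = sorted(s for s, m in best.items() if m == top)
    if len(winners) > 1 or top < min_score:
        return XXX, top
    return winners[0], top


def phylo_classify(
    query_id: str,
    query_sequences: dict,
    reference_table: list,
    tree=None,
) -> tuple:
    """Substrate of the smallest clade holding the query and >=1 reference.

    ``tree`` may be a precomputed NJ tree over queries plus references (tips
    labeled ``ref|<substrate>|<i>`` for references); otherwise one is built.
    Returns ``(substrate or None, reference count in that clade)``.
    """
    ref_labels = {
        f"ref|{e.substrate}|{i}": e.substrate for i, e in enumerate(reference_table)
    }
    if tree is None:
        seqs = dict(query_sequences)
        for (label, _), entry in zip(ref_labels.items(), reference_table):
            seqs[label] = entry.sequence
        if len(seqs) < 3:
            return None, 0
        tree = phylo.neighbor_joining(phylo.distance_matrix(seqs))
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    refs_in_tree = frozenset(l for l in all_tips if l in ref_labels)
    if not refs_in_tree or query_id not in all_tips:
        return None, 0
    best_side, best_key = None, None
    for side in phylo.edge_leafsets(tree):
        for clade in (side, all_tips - side):
            if query_id in clade and clade & refs_in_tree:
                # smallest clade wins; equal-size ties go to the clade with
                # more characterized references, then lexicographic order
                key = (len(clade), -len(clade & refs_in_tree), tuple(sorted(clade)))
                if best_key is None or key < best_key:
                    best_side, best_key = clade, key
    if best_side is None:
        return None, 0
    substrates = {ref_labels[l] for l in best_side & refs_in_tree}
    if len(substrates) != 1:
        return None, 0
    return substrates.pop(), len(best_side & refs_in_tree)


def consensus_predict(
    code_vote: tuple,
    phylo_vote: tuple,
    min_score: int = DEFAULT_MIN_SCORE,
    override_support: int = DEFAULT_OVERRIDE_SUPPORT,
) -> Prediction:
    code_sub, code_score = code_vote
    phylo_sub, support = phylo_vote
    if code_sub != XXX and phylo_sub == code_sub:
        return Prediction(code_sub, code_vote, phylo_vote, "agreement")
    if phylo_sub is not None and support >= override_support:
        return Prediction(phylo_sub, code_vote, phylo_vote, "phylo_override")
    if code_sub != XXX and code_score >= min_score:
        return Prediction(code_sub, code_vote, phylo_vote, "code_only")
    return Prediction(XXX, code_vote, phylo_vote, "xxx")


def predict_substrates(
    adomain_sequences: dict,
    library: DomainTemplateLibrary,
    reference_table: list,
    min_score: int = DEFAULT_MIN_SCORE,
    use_phylo: bool = True,
) -> dict:
    """Consensus prediction for every A domain in ``adomain_sequences``.

    One NJ tree over all queries plus references is shared across queries.
    """
    tree = None
    if use_phylo and len(adomain_sequences) + len(reference_table) >= 3:
        seqs = dict(adomain_sequences)
        for i, entry in enumerate(reference_table):
            seqs[f"ref|{entry.substrate}|{i}"] = entry.sequence
        tree = phylo.neighbor_joining(phylo.distance_matrix(seqs))
    out = {}
    for dom_id, seq in adomain_sequences.items():
        try:
            code = extract_code(seq, library)
            code_vote = classify_code(code, reference_table, min_score)
        except ExtractionFailure:
            code_vote = (XXX, 0)
        if use_phylo:
            phylo_vote = phylo_classify(dom_id, adomain_sequences, reference_table, tree=tree)
        else:
            phylo_vote = (None, 0)
        out[dom_id] = consensus_predict(code_vote, phylo_vote, min_score)
    return out
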
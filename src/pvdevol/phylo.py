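"""Pairwise protein alignment, distance matrices, neighbor joining and tree utilities.

Global affine-gap alignment runs through Biopython's PairwiseAligner with
BLOSUM62; neighbor joining through scikit-bio with negative branch-length
clamping; trees are dendropy objects throughout. The gap convention is that a
gap of length L costs ``gap_open + L * gap_extend``.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from dendropy.calculate import treecompare
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def _aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; shift so that a length-L gap
    # costs gap_open + L * gap_extend.
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def needleman_wunsch(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps.

    Identity is the fraction of identical-residue columns over *all*
    alignment columns, gaps included.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    al = _aligner(matrix if matrix is not None else BLOSUM62, gap_open, gap_extend)
    aln = al.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(a, b)) / len(a)
    return AlignmentResult(a, b, float(aln.score), ident)


def alignment_score(seq_a, seq_b, matrix=None, gap_open=10.0, gap_extend=1.0) -> float:
    """Score-only variant of :func:`needleman_wunsch` (faster; no traceback)."""
    al = _aligner(matrix if matrix is not None else BLOSUM62, gap_open, gap_extend)
    return float(al.score(seq_a, seq_b))


def pairwise_identity(seq_a: str, seq_b: str, **kw) -> float:
    return needleman_wunsch(seq_a, seq_b, **kw).identity


def distance_matrix(sequences: dict) -> _SkbioDM:
    """All-vs-all ``1 - alignment identity`` distances; labels must be unique."""
    labels = list(sequences)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate sequence labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(
                sequences[labels[i]], sequences[labels[j]]
            )
    return _SkbioDM(d, ids=labels)


def neighbor_joining(dm: _SkbioDM) -> dendropy.Tree:
    """NJ tree from a distance matrix; unrooted, negative branch lengths clamped to 0.

    Labels are sorted before joining so the result does not depend on input
    label order.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    tree = _skbio_nj(dm, neg_as_zero=True)
    newick = _io.StringIO()
    tree.write(newick, format="newick")
    out = dendropy.Tree.get(data=newick.getvalue(), schema="newick")
    out.is_rooted = False
    return out


def read_newick(source) -> dendropy.Tree:
    if hasattr(source, "read"):
        return dendropy.Tree.get(file=source, schema="newick")
    return dendropy.Tree.get(path=str(source), schema="newick")


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=False,
        real_value_format_specifier=".17g",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def _common_namespace_copies(tree_a, tree_b):
    # bipartitions are compared unrooted, so rooting is dropped on the copies
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=write_newick(tree_a), schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=write_newick(tree_b), schema="newick", taxon_namespace=ns)
    ta.is_rooted = False
    tb.is_rooted = False
    return ta, tb


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Count of bipartitions present in exactly one of the two trees."""
    tips_a = {l.taxon.label for l in tree_a.leaf_node_iter()}
    tips_b = {l.taxon.label for l in tree_b.leaf_node_iter()}
    if tips_a != tips_b:
        raise ValueError("tip label sets differ")
    ta, tb = _common_namespace_copies(tree_a, tree_b)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def edge_leafsets(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf-label set below each edge (one side of each bipartition)."""
    sets = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(c._leafset for c in node.child_nodes()))
            node._leafset = s
        if node.parent_node is not None:
            sets.append(node._leafset)
    return sets


def monophyly_test(tree: dendropy.Tree, tip_subset) -> tuple[bool, int]:
    """Bipartition-based monophyly, valid for unrooted trees.

    Returns (is_monophyletic, size of the smallest bipartition side containing
    the subset).
    """
    subset = frozenset(tip_subset)
    if not subset:
        raise ValueError("tip subset must be non-empty")
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    unknown = subset - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(subset) in (1, len(all_tips)):
        return True, len(subset)
    mono = False
    smallest = len(all_tips)
    for side in edge_leafsets(tree):
        for clade in (side, all_tips - side):
            if subset <= clade:
                smallest = min(smallest, len(clade))
            if subset == clade:
                mono = True
    return mono, smallest


def patristic_distances(tree: dendropy.Tree) -> _SkbioDM:
    """Tip-to-tip path-length distances as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return _SkbioDM(d, ids=labels)
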
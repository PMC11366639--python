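# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `pvdevol`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Domain detection and backbone assembly

NRPS domains (condensation C, adenylation A, thiolation/carrier T,
epimerization E, thioesterase TE) are located by sliding a full-length
template of each kind along the protein and scoring every window with
BLOSUM62 — a position-specific profile built from the template. A window is
a hit when its score reaches `threshold × self-score` of the template
(default 0.4). Uniform-random amino-acid sequence scores *below zero* in
expectation against any profile, so the false-positive rate at this cutoff
is far under 1% (measured on 1,000 random 1,000-residue sequences), while
homologs diverged beyond 30% per site still score. Overlapping hits are
resolved best-score-first, leftmost on ties. Unknown residue letters score
zero (neutral). Users with externally produced domain annotations can
bypass the scanner via a TSV table (`protein_id, kind, start, end`;
coordinates are 1-based inclusive, following protein-annotation convention).

Hits are segmented into modules by a grammar automaton: `C?-A-T-E?`, with
the leading C waived only for the initiation module of the assembly line,
and a single TE allowed only after the last module of the last gene (a
missing TE is a warning, not an error, since the TE region itself varies
between clusters). Out-of-grammar layouts (e.g. T before A) raise an error
naming the protein and coordinate rather than guessing — dual C/E and other
unusual orders are deliberately out of scope. Gene order in the companion
TSV is authoritative for the assembly-line order; module ordinals run
consecutively across genes.

The backbone follows the colinearity rule: residue *i* is module *i*'s
predicted substrate, with D-chirality exactly where the module carries an E
domain. PvdL, the conserved chromophore-precursor synthetase, is excluded
from cluster assemblies; its invariant L-Glu/D-Tyr/L-Dab leader is exposed
as a constant that reports may prepend.

## Substrate prediction

Each A domain's ten binding-pocket residues (the specificity code) are read
from a global alignment to the canonical anchor A-domain; the code positions
ship as data in the bundled motif library rather than being hard-coded. A
code with ≥5 gapped columns is an extraction failure. The code vote is the
reference entry with the most matching positions (score out of 10); ties
across substrates or scores below `min_score` (default 7/10, a conservative
cutoff exposed in config) fall back to `Xxx`. The phylogenetic vote places
the query on a neighbor-joining tree together with the characterized
reference domains and returns the unanimous substrate of the smallest clade
(bipartition side) containing the query and at least one reference —
abstaining when that clade's references disagree. Equal-size clade ties are
broken toward the clade with more characterized references, then
lexicographically, so the vote is deterministic.

Consensus: agreement wins; otherwise a phylogenetic vote supported by ≥2
characterized references overrides the code (this encodes the precedent of
code-level glycine calls that sit inside a clade of characterized alanine
domains and are reassigned to alanine); otherwise the code vote stands if it
meets `min_score`; otherwise `Xxx`. The bundled reference table is a
synthetic stand-in (12 substrate classes with mutually distant codes, min
pairwise Hamming distance ≥6 of 10); real-data results depend on the
reference table supplied.

## Pairwise alignment, trees and tree statistics

Global affine-gap protein alignment runs through Biopython's
`PairwiseAligner` with BLOSUM62. The gap convention is that a gap of length
L costs `gap_open + L·gap_extend` (defaults 10 and 1 in matrix score
units); identity is identical-residue columns divided by *all* alignment
columns, gaps included. Distances are `1 − identity`. Neighbor joining runs
through scikit-bio with negative branch-length estimates clamped to zero;
labels are sorted before joining, so the topology does not depend on input
order. Robinson–Foulds distances count bipartitions present in exactly one
tree (trees compared unrooted); monophyly is bipartition-based — a tip set
is monophyletic iff some edge separates exactly that set — which avoids
rooting assumptions for the unrooted NJ trees. Maximum-likelihood tree
inference is a non-goal: externally computed Newick trees (e.g. from a
dedicated ML package) are accepted wherever a tree is an input.

## Mk models of type evolution

The pyoverdine type is modeled as a k-state unordered character evolving by
a continuous-time Markov process on the fixed species tree. Parameterizations:
`ER` (one rate for every pair), `SYM` (one symmetric rate per pair,
k(k−1)/2 parameters), and gamma-rate `SYM`, in which the likelihood is
averaged over `ncat` equal-probability rate categories (default 10) of a
mean-1 gamma distribution with fitted shape α. Categories are represented
by their exact category means (computed from regularized incomplete gamma
functions); a stochastic sampling of category rates would not be
reproducible, and the deterministic means are the standard discretization.
With `ncat=1` the gamma model reduces exactly to the homogeneous one.

Likelihoods use Felsenstein pruning with per-node rescaling; transition
matrices come from the eigendecomposition of the symmetric rate matrix
(scaling-and-squaring fallback otherwise). The root prior is flat over the
k states, avoiding stationary-distribution circularity. Missing tips
contribute all-ones partial likelihoods; non-producer strains are *excluded*
by default (the type character is defined for producers), with
inclusion-as-missing behind a flag.

Fitting maximizes the log-likelihood over log-rates (bounds 1e−8 to 1e3;
gamma shape 0.05 to 1e4, whose upper end is numerically rate-homogeneous so
SYM stays nested in gamma-SYM) with bounded L-BFGS-B. The likelihood is
first evaluated at five log-spaced initial rate scales and optimization is
launched from the two best — full restarts from all five multiply runtime
roughly threefold without changing any result at the problem sizes used
here. Models are compared by AIC (2p − 2·logL) with likelihood-ratio
statistics reported for nested pairs. Marginal ancestral reconstruction
combines each node's subtree partial likelihoods with an outside (up-pass)
term under the same root prior; with gamma rates the per-category joints
are averaged on a common scale before normalizing. Both are verified
against brute-force enumeration over all internal-node state assignments on
small trees.

## Event inference

Types are assigned in first-seen order (Roman numerals); type identity is
the backbone residue string *ignoring chirality*, because E-domain variants
of one backbone are versions of the same pyoverdine, not new types —
chirality signatures create subtypes (`XVIa`, `XVIb`, …). `Xxx` is a
legitimate residue token for typing: two backbones with `Xxx` at the same
position can share a type. The registry reports substrate counts both with
and without `Xxx`.

A type borne by strains of two or more phylogroups is screened for
horizontal transfer: for each module ordinal, the bearers' A domains are
tested for monophyly in the A-domain NJ tree. If ≥80% of ordinals are
monophyletic across groups (per-ordinal clades containing both groups'
subclades), the verdict is `type_clustered` (transfer-supported); if each
group's domains instead join within-group clades, `group_clustered`
(vertical-compatible); otherwise `unresolved`. The 80% fraction, like the
swap identity thresholds below, is a calibrated default exposed in config;
the calibration experiments are scripted (`analysis/04_event_recovery.py`).
Hypotheses are undirected — donor and recipient cannot be told apart from
sequence clustering alone.

Replacement events are localized by per-domain provenance: each A domain's
nearest non-self-strain neighbor in the distance matrix. An ordinal counts
as *foreign* when that neighbor is cross-group **and** closer than 0.6× the
nearest same-group domain — the margin guards against deep-coalescence
false calls where cross-group and within-group distances are comparable.
All ordinals foreign → full replacement; a contiguous block of ≥2 →
partial replacement. Because transfer is symmetric in sequence space, the
donor side shows the same signal; a candidate is suppressed when a clean
(foreign-free) same-group peer carries the same substrates at the candidate
ordinals, i.e. when the "foreign-looking" modules are actually the group's
ancestral state.

Pairwise architecture comparisons against the nearest species-tree
relatives (the closest three are examined, since the single nearest may
itself carry an event) drive the remaining detectors. A specificity swap
requires *exactly one* module's substrates to differ, that module's
A-domain identity below 0.70, and the mean identity of all other domains
above 0.90 — the replacement signature of a foreign A domain inside an
otherwise near-identical protein. The affected strain of the pair is the
one whose A domain is orphaned within its own group. Accessory E-domain
gain/loss requires identical substrates with differing E-presence; the
deviant strain against the majority E-state of same-backbone bearers is the
affected one, and the flanking T and C identities are reported as evidence
(the gain/loss perturbs neighboring sequence). Intragenic duplication is
called for adjacent same-substrate modules whose A domains are mutual
nearest neighbors in the tree, with ties in distance tolerated (a fresh
duplicate can be exactly as close to its template's ortholog as to its
template).

Receptor concordance is the fraction of types with ≥2 bearers whose
receptors are monophyletic in the receptor NJ tree; single-bearer types are
excluded from the denominator, untyped tips are ignored with a warning, and
strains with multiple receptors are accepted (nearest-to-clade receptor
counts; extras are reported separately).

## Synthetic generator: what it emulates, and what it does not

The generator is the package's study system. Species trees are pure-birth
(Yule) in continuous time — the simplest process giving ultrametric trees
with positive branch lengths — with the terminal branches extended by the
waiting time to the next uncommitted birth, and the tree height normalized
to 1.0 so that rates have fixed meaning. Tips split into two phylogroups at
the root (redrawn until both sides have ≥4 tips, so group-level signals are
testable); pyoverdine types are either group-private (each group descends
from its own ancestral backbone — the default for event experiments) or
evolve over the whole catalog under an equal-rates Mk process.

Backbones are 4–12 residues over 12 substrate classes, each residue
epimerized with probability 0.3 (both chirality states are kept represented
so accessory gain and loss are always realizable). Clusters are built from
one template per domain kind with the substrate's reference code implanted
at the A-domain code columns, split across 1–4 genes. Three nested noise
processes shape realism:

* a per-module "identity perturbation" (10% per site, applied once at the
  clade ancestor) that makes same-substrate A domains at different ordinals
  distinguishable — without it, per-ordinal monophyly and mutual-NN
  duplication tests would be ill-posed;
* per-site substitution along branches at rate 0.03 per unit time (code
  columns protected), giving within-group divergence of roughly 1–4% and
  cross-group divergence near 6%;
* per-tip measurement noise (default 2%).

Events are applied post hoc to tip data (the inference stages only ever see
tips). Horizontally copied material carries 1% copy noise. A specificity
swap implants the new substrate's *reference* A-domain sequence diverged 25%
outside the code columns — a foreign homolog, matching the observed
signature of low identity concentrated in the swapped domain — rather than
editing ten code residues in place, which would leave ~92% identity and no
detectable signature. Duplication copies the module's C domain along with A
and T so the result still parses under the module grammar. Receptors are
one 15%-diverged template per type plus 2% per-tip noise, which reproduces
type-concordant receptor clustering as a positive control. Every event is
logged with the sub-seed used to apply it, so replaying the log from the
pre-event clusters reproduces the emitted data byte-for-byte.

Not emulated: nucleotide-level evolution (no codon structure, no dN/dS),
indels (domain coordinates stay template-aligned by design), recombination
breakpoints within domains, tailoring-domain chemistry, receptor–ligand
coevolution beyond the per-type template, and any ecological dynamics.
Passing tests therefore demonstrate the *inference logic* under controlled
signal strengths, not performance on real proteomes, where domain
boundaries blur, identities are lower, and reference tables are incomplete.

## Numerical choices and degenerate inputs

Alignment traceback ties follow the aligner's canonical first path; scores
and identities are unaffected. NJ negative branch estimates are clamped to
zero. Likelihood rescaling is per node; enumeration agreement is asserted
to 1e−8, closed-form transition probabilities to 1e−10, reconstruction
normalization to 1e−9. Empty protein sequences scan to an empty hit list;
a cluster with zero A domains yields an empty assembly with a warning; a
monomorphic type character warns and pins the rate at its lower bound.
Seeds: every stochastic routine takes an explicit seed; sub-seeds are
derived by CRC-salted `SeedSequence`, never by Python's randomized `hash`.

## Study conditions (problem sizes)

The standard validation sizes, chosen once as desk-scale defaults: 100
random instances (≤6 tips) for likelihood-oracle agreement; 20 replicates
of 200-tip trees for rate recovery (median fitted rate within [0.35, 0.65]
of truth 0.5); 50 replicates for ER-vs-SYM AIC selection; 100 replicates of
100-tip trees at depth×rate = 0.2 for modal root-state recovery; 200 random
backbone specs for architecture round trips; 50 mixed-event clades of 12
tips for event precision/recall; 10 types × 4 strains × 100 shuffles for
the receptor permutation null. `scripts/acceptance.py --seed N` reruns all
of them.

## Known limitations

* The domain scanner assumes template-scale homology and no indels; real
  NRPS domains need an HMM-based annotator, which the domain-table import
  path accommodates.
* The bundled specificity reference table is synthetic; real predictions
  require a curated table of characterized A domains.
* NJ on pairwise identities is a desk-scale stand-in for ML tree inference;
  for publication-grade trees, import externally computed Newick.
* The Gly/Ala-style phylogenetic override depends on reference density:
  with fewer than two characterized domains per clade it never fires.
* Transfer direction, event dating and donor identification beyond
  nearest-neighbor provenance are out of scope.
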
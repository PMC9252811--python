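# Methods

## Pseudo-atom representation

A residue's position *and orientation* are encoded as a pair of
pseudo-atoms.  For amino acids, **Key Start** is the side-chain
attachment point — the centroid of `{CB}`, or `CA` for glycine — and
**Key End** is the centroid of a functional-tip atom set chosen per
residue type (Arg: NE/CZ/NH1/NH2; Lys: NZ; Asp: OD1/OD2; Glu: OE1/OE2;
His/Phe/Tyr/Trp: ring atoms; full table in
`submotif.representation.DEFAULT_PSEUDO_ATOM_TABLE`).  Glycine and
alanine carry no directional side chain, so their keys coincide.  Using
centroids over chemically equivalent atoms (carboxylates, guanidinium,
aromatic rings) makes the representation insensitive to the arbitrary
naming of symmetric atoms.  For RNA bases, Key Start is the
six-membered-ring centroid; Key End is the five-membered-ring centroid
for purines and the glycosidic N1 for pyrimidines.

The atom sets are data, not code: they can be replaced from a plain-text
config (`parse_pseudo_atom_config`), because no published source
enumerates a canonical set and reasonable variants exist.  Single-key
(conceptual-query) mode uses the Key End set only, approximating "where
the functional group is" without orientation.

Hypothetical queries with no coordinates are matched on single keys
against distance *ranges*; the default "close proximity" window is
(0, 13] Å, chosen as the span of a compact cluster of about eight
residues (key starts within a ~10 Å ring plus side-chain reach).  It is
configurable per query pair and recorded in result headers via the
tolerance column.

## Matching engines

**Exact engine.**  Candidate sets per query residue are built by label
membership and, for key pairs, the intra-residue Key Start→End distance;
a distance sieve then removes target residues with no partner within the
query diameter plus tolerance (pure pruning, output-invariant).  Ullmann
refinement iterates: candidate *t* for query node *i* survives only
while every other query node *j* retains some candidate *u ≠ t*
compatible with (*i*,*t*).  Depth-first enumeration with forward
checking then emits every injective assignment whose pairwise pseudo-atom
distances all satisfy the tolerance.  The output is defined entirely by
that post-condition; tests verify equality with brute-force enumeration.

Tolerances: protein searches use an absolute window, default 1.5 Å; RNA
searches a fractional window, default 30% **of the query distance**
(`|d_q − d_t| ≤ 0.30·d_q`).  Whether the fraction should be taken of the
query or the target distance is a genuine design choice; the query is
the reference arrangement, so we anchor on it, and the choice is
explicit in `ToleranceConfig`.

**Partial engine.**  Correspondence-graph vertices are (query residue,
target residue) pairs — not pseudo-atom pairs — so the two keys of a
residue move together and the graph stays small.  Vertices sharing a
query node or target residue are never adjacent; an edge requires all
four cross-residue key distances to be compatible.  Maximal cliques are
enumerated with networkx's Bron–Kerbosch implementation
(`find_cliques`); cliques below `min_size` (default 3, the smallest
valid query) are discarded.  Full-size cliques provably coincide with
exact-engine matches, which the tests assert instance-by-instance.

**Cluster engine.**  Hydrogen bonds between bases are detected as
heavy-atom donor–acceptor contacts in a 2.4–3.4 Å window (no explicit
hydrogens, no angle term; the donor/acceptor sets per base are tabulated
and the window configurable).  This is a deliberately simple, documented
geometric criterion — distance-window detection is standard practice and
the exact parameters of specialized predictors vary.  Bonds aggregate
into a connection table (bases as nodes, bond counts per pair as edge
weights).  Connected induced subsets of 2–6 bases are enumerated with an
ESU-style anchor-and-extend scheme that visits each subset exactly once;
patterns (labels or wildcards plus minimum bond counts per edge, required
connected) are matched with the same Ullmann core used by the exact
engine, deduplicated by target base set.  Two-structure comparison
canonicalizes each cluster to a signature — the lexicographically
minimal (labels, edge-code) encoding over node permutations, feasible
because clusters have ≤ 6 nodes — and reports shared/unique signatures
with counts.

## Superposition and ranking

Matched substructures are scored by RMSD of the query pseudo-atoms after
a Kabsch fit (SVD of the cross-covariance with determinant sign
correction, so only proper rotations are returned; mirror-image
arrangements therefore score poorly instead of matching, which is the
chirality filter).  RMSD is computed over pseudo-atoms rather than all
side-chain atoms because the engines match pseudo-atom geometry and a
full-atom RMSD would mix in atom-naming ambiguity; the superposition can
be applied to full query coordinates for visual output
(`write_superposed_query`).

Assignments that land on the same target residue set (query
automorphisms — frequent for queries with repeated labels) collapse to
one hit, keeping the lowest-RMSD mapping: the tool reports *sites*, not
mappings.  Ranking is a total order: RMSD ascending, then matched size
descending, target id, first matched residue identifier.  Hypothetical
queries have no reference geometry, so their hits carry no RMSD and rank
by the fallback keys.  Filters (RMSD ceiling, heteroatom proximity
within 4.0 Å by default, same-/cross-chain) apply conjunctively.

## Structure I/O policies

PDB and mmCIF are parsed with gemmi into a minimal uniform model.  Only
the first model of multi-model files is used (search databases hold
single conformers); alternate locations collapse to the
highest-occupancy atom, ties resolved toward altloc 'A'; waters are
excluded from the heteroatom list used for proximity flags, since that
flag is meant to mark ligand/metal adjacency.  Residues are identified
by author numbering (chain, seqnum, icode) throughout; no renumbering.
Biological-assembly files are treated as ordinary pre-expanded
coordinates — the tool applies no symmetry operators.  Residues with
names outside the 20 standard amino acids / A,C,G,U are ignored by the
engines (modified residues are out of scope).  Resolution is read from
headers where present; scans can skip targets whose recorded resolution
is numerically worse than a cutoff (targets without recorded resolution
are kept).

## Synthetic data

The fixture generator inverts the pseudo-atom tables: given requested
key positions per planted residue, atoms are placed so the configured
centroids land exactly on the keys (smallest atom set first; one free
atom per set absorbs the centroid correction), plus dummy backbone
atoms.  Decoy residues receive uniform labels and box-uniform positions
(40 Å box by default) and are rejection-sampled — against an independent
brute-force matcher, not the engines — until no unplanned site matches
the planted-key query at the generation tolerance, making recovery tests
exact rather than probabilistic.  Per-atom jitter is Gaussian (σ = 0.2 Å
in the standard recovery conditions) or bounded-uniform for worst-case
recovery proofs: a displacement bound of ε/4 per atom bounds each
pairwise distance error by ε/2 < ε, so recovery is certain.

RNA cluster fixtures space bases 20 Å apart and move the designated
donor/acceptor atoms of each requested bond to the pair midpoint, 2.9 Å
apart, successive bonds offset 6 Å laterally; the construction is
verified at generation time to contain no other donor–acceptor pair
within 5 Å.  What these fixtures deliberately do **not** emulate:
realistic covalent geometry, backbone connectivity, crystallographic
noise or density of real decoy environments.  Passing tests demonstrate
the correctness of the graph algorithms and scoring on controlled
geometry, not retrieval performance on the PDB.

## Problem sizes and numerical choices

The bundled verification runs use problem sizes that keep exhaustive
oracles exact: 200 random instances (targets of 20–60 residues, queries
of 3–5) for the exact engine, 60 correspondence graphs of ≤ 40 vertices
for the clique engine, 100 planted fixtures (50 decoys each) for
recovery, connection tables of ≤ 10 bases for cluster enumeration.
Distance comparisons are inclusive at the boundary (a deviation of
exactly 30% of the query distance is accepted).  Coincident keys and
near-coincident target pseudo-atoms are legal; no minimum-separation
rule is applied in distance checks.  CSV output prints RMSD to two
decimals and is byte-deterministic for a fixed input.

## Known limitations

Chirality is handled only at the scoring stage (proper-rotation RMSD),
not inside the graph engines, so a mirror-image site appears as a
high-RMSD hit rather than being suppressed during matching.  No
statistical significance is attached to RMSD scores.  Modified residues,
DNA chains, and base-pair edge classification (Leontis–Westhof) are out
of scope.  The hydrogen-bond criterion is distance-only by default; an
angular term would require hydrogen placement and is left as an
extension point.
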
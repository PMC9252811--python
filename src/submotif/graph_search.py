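"""The matching engines.

Three ways of finding a query arrangement inside a target structure:

* **Exact subgraph isomorphism** (:func:`ullmann_match`) — every query
  residue must map to a label-compatible target residue such that all
  pairwise pseudo-atom distances agree within tolerance.  Solved with
  Ullmann-style candidate refinement plus backtracking; the output is
  defined purely by the post-condition (all consistent injective
  assignments), refinement is only pruning.
* **Partial matching via maximal cliques** (:func:`clique_partial_match`) —
  a correspondence graph is built whose vertices are compatible
  (query residue, target residue) pairs and whose edges join mutually
  distance-consistent pairs; Bron–Kerbosch maximal cliques (networkx)
  are partial matches.
* **Hydrogen-bonded cluster search** (:func:`enumerate_base_clusters`,
  :func:`match_cluster_pattern`) — operates on a base connection table
  instead of distances: a substructure is a set of bases connected by
  hydrogen bonds, and patterns constrain base identities and minimum
  bond counts per pair.

Distance tolerances: amino-acid searches use an absolute window
(default 1.5 Å); RNA searches use a fractional window (default 30% of the
query distance).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .representation import (
    ConnectionTable,
    KeyRole,
    PseudoAtomMode,
    PseudoAtomNode,
    structure_pseudoatoms,
)
from .structure_io import (
    Residue,
    ResidueKind,
    STANDARD_AMINO_ACIDS,
    RNA_BASES,
    Structure,
)

log = logging.getLogger(__name__)

COORDINATE_QUERY_SIZE = (3, 12)
HYPOTHETICAL_QUERY_SIZE = (3, 8)
CLUSTER_PATTERN_SIZE = (2, 6)

RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "BASIC": frozenset({"LYS", "ARG", "HIS"}),
    "BASIC_NO_HIS": frozenset({"LYS", "ARG"}),
    "ACIDIC": frozenset({"ASP", "GLU"}),
    "AROMATIC": frozenset({"PHE", "TYR", "TRP"}),
    "ANY": STANDARD_AMINO_ACIDS,
}


class SearchMode(Enum):
    PROTEIN = "PROTEIN"
    RNA = "RNA"


class Engine(Enum):
    EXACT = "EXACT"      # Ullmann subgraph isomorphism
    PARTIAL = "PARTIAL"  # Bron-Kerbosch maximal cliques
    CLUSTER = "CLUSTER"  # connection-table pattern matching


class QueryError(ValueError):
    """Invalid query definition (size limits, empty label sets, ...)."""


@dataclass(frozen=True)
class ToleranceConfig:
    """Distance tolerances for the geometric engines.

    ``protein_abs_tol`` is an absolute window in Å; ``rna_frac_tol`` is a
    fraction of the *query* distance.
    """

    protein_abs_tol: float = 1.5
    rna_frac_tol: float = 0.30

    def __post_init__(self) -> None:
        if self.protein_abs_tol <= 0:
            raise ValueError("protein_abs_tol must be positive")
        if not 0 < self.rna_frac_tol < 1:
            raise ValueError("rna_frac_tol must be in (0, 1)")

    def compatible(self, d_query: float, d_target: float, mode: SearchMode) -> bool:
        if mode is SearchMode.PROTEIN:
            return abs(d_query - d_target) <= self.protein_abs_tol
        return abs(d_query - d_target) <= self.rna_frac_tol * d_query


@dataclass(frozen=True)
class QueryResidue:
    """One query node: allowed residue names plus (optionally) key geometry.

    ``keys`` holds the pseudo-atom positions — shape (2, 3) for Key
    Start/End pairs, (1, 3) for single-key nodes — or ``None`` for
    hypothetical nodes that carry no coordinates.
    """

    labels: frozenset[str]
    keys: np.ndarray | None = None
    source: Residue | None = None

    def __post_init__(self) -> None:
        if not self.labels:
            raise QueryError("query node with empty label set")
        if self.keys is not None:
            object.__setattr__(self, "keys", np.asarray(self.keys, dtype=float))


@dataclass
class MotifQuery:
    """A query graph: labeled nodes plus pairwise distance constraints."""

    residues: list[QueryResidue]
    mode: SearchMode
    engine: Engine
    pair_mode: PseudoAtomMode = PseudoAtomMode.PAIR
    # hypothetical queries: (i, j) with i < j -> inclusive (min, max) Å range
    ranges: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_hypothetical(self) -> bool:
        return self.residues[0].keys is None

    def range_for(self, i: int, j: int) -> tuple[float, float]:
        return self.ranges[(min(i, j), max(i, j))]


@dataclass(frozen=True, eq=False)  # identity equality: keys are ndarrays
class TargetResidue:
    """A target residue reduced to its pseudo-atom keys."""

    residue: Residue
    keys: np.ndarray  # (k, 3)
    label: str


@dataclass
class Assignment:
    """An injective mapping of query residues onto target residues."""

    query: MotifQuery
    mapping: dict[int, TargetResidue]  # query residue index -> target

    @property
    def matched_size(self) -> int:
        return len(self.mapping)

    @property
    def residue_set(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(
            (t.residue.chain_id, t.residue.seq_num, t.residue.icode)
            for t in self.mapping.values()
        )


def group_target_residues(nodes: Sequence[PseudoAtomNode]) -> list[TargetResidue]:
    """Collect per-residue key arrays from a flat pseudo-atom node list."""
    order: list[int] = []
    by_res: dict[int, list[PseudoAtomNode]] = {}
    for n in nodes:
        k = id(n.residue)
        if k not in by_res:
            by_res[k] = []
            order.append(k)
        by_res[k].append(n)
    out = []
    for k in order:
        ns = by_res[k]
        ns.sort(key=lambda n: 0 if n.role is not KeyRole.KEY_END else 1)
        out.append(
            TargetResidue(
                residue=ns[0].residue,
                keys=np.array([n.pos for n in ns]),
                label=ns[0].label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# query construction

def build_query_from_coordinates(
    s: Structure,
    engine: Engine = Engine.EXACT,
    mode: SearchMode = SearchMode.PROTEIN,
) -> MotifQuery:
    """Turn a small motif coordinate file into a query.

    The structure must contain only the motif residues (3–12 of the kind
    selected by ``mode``); residues of the other kind are ignored with a
    warning.  Query nodes carry Key Start/End pseudo-atoms and the
    constraints are the observed pairwise distances.
    """
    kind = ResidueKind.AMINO if mode is SearchMode.PROTEIN else ResidueKind.BASE
    ignored = [r for r in s.residues if r.kind is not kind]
    for r in ignored:
        log.warning("query residue %s ignored (wrong kind for %s mode)", r.ident, mode.value)
    nodes = structure_pseudoatoms(s, kind, PseudoAtomMode.PAIR)
    targets = group_target_residues(nodes)
    lo, hi = COORDINATE_QUERY_SIZE
    if not lo <= len(targets) <= hi:
        raise QueryError(
            f"coordinate query must have {lo}-{hi} residues, got {len(targets)}"
        )
    residues = [
        QueryResidue(labels=frozenset({t.label}), keys=t.keys, source=t.residue)
        for t in targets
    ]
    return MotifQuery(residues=residues, mode=mode, engine=engine)


def expand_label(label: str | Iterable[str]) -> frozenset[str]:
    """Expand a residue name, class shortcut, or explicit set to a label set."""
    if isinstance(label, str):
        label = label.upper()
        if label in RESIDUE_CLASSES:
            return RESIDUE_CLASSES[label]
        return frozenset({label})
    return frozenset(l.upper() for l in label)


def build_hypothetical_query(
    labels: Sequence[str | Iterable[str]],
    distance_ranges: dict[tuple[int, int], tuple[float, float]] | None = None,
    proximity_default: tuple[float, float] = (0.0, 13.0),
    mode: SearchMode = SearchMode.PROTEIN,
) -> MotifQuery:
    """Build a conceptual arrangement query (3–8 residues, single keys).

    Every unconstrained residue pair receives the ``proximity_default``
    distance range; explicit per-pair ranges override it.
    """
    lo, hi = HYPOTHETICAL_QUERY_SIZE
    if not lo <= len(labels) <= hi:
        raise QueryError(
            f"hypothetical query must have {lo}-{hi} residues, got {len(labels)}"
        )
    residues = [QueryResidue(labels=expand_label(l)) for l in labels]
    for r in residues:
        unknown = r.labels - STANDARD_AMINO_ACIDS
        if unknown:
            raise QueryError(f"unknown residue label(s): {sorted(unknown)}")
    ranges = {
        (i, j): proximity_default
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    for (i, j), (dmin, dmax) in (distance_ranges or {}).items():
        if dmin > dmax or dmax <= 0:
            raise QueryError(f"invalid distance range {dmin}-{dmax} for pair {(i, j)}")
        ranges[(min(i, j), max(i, j))] = (dmin, dmax)
    return MotifQuery(
        residues=residues,
        mode=mode,
        engine=Engine.EXACT,
        pair_mode=PseudoAtomMode.SINGLE,
        ranges=ranges,
    )


# ---------------------------------------------------------------------------
# Ullmann core

def _ullmann_refine(
    candidates: list[set[int]],
    compatible: Callable[[int, int, int, int], bool],
) -> bool:
    """Ullmann-style refinement to a fixpoint.

    A candidate t for query node i survives only if every other query node
    j still has some candidate u != t with compatible(i, j, t, u).  Returns
    False if any candidate set empties (no match possible).
    """
    n = len(candidates)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for t in list(candidates[i]):
                for j in range(n):
                    if j == i:
                        continue
                    if not any(
                        u != t and compatible(i, j, t, u) for u in candidates[j]
                    ):
                        candidates[i].discard(t)
                        changed = True
                        break
            if not candidates[i]:
                return False
    return True


def _ullmann_enumerate(
    candidates: list[set[int]],
    compatible: Callable[[int, int, int, int], bool],
) -> list[tuple[int, ...]]:
    """All injective assignments consistent with the pairwise predicate."""
    n = len(candidates)
    cand = [set(c) for c in candidates]
    if not _ullmann_refine(cand, compatible):
        return []
    results: list[tuple[int, ...]] = []

    def dfs(depth: int, assigned: list[int], live: dict[int, set[int]]) -> None:
        if depth == n:
            results.append(tuple(assigned))
            return
        for t in sorted(live[depth]):
            nxt: dict[int, set[int]] = {}
            feasible = True
            for j in range(depth + 1, n):
                cj = {u for u in live[j] if u != t and compatible(depth, j, t, u)}
                if not cj:
                    feasible = False
                    break
                nxt[j] = cj
            if feasible:
                merged = dict(live)
                merged.update(nxt)
                dfs(depth + 1, assigned + [t], merged)

    dfs(0, [], {i: cand[i] for i in range(n)})
    return results


def _geometry_predicates(
    q: MotifQuery,
    targets: list[TargetResidue],
    tol: ToleranceConfig,
) -> tuple[
    Callable[[int, int], bool],
    Callable[[int, int, int, int], bool],
]:
    """Node- and edge-compatibility predicates for the geometric engines.

    Node check: label membership plus (for Key pairs) the intra-residue
    start→end distance.  Edge check: every cross-residue key pair distance
    must satisfy the tolerance (coordinate queries) or fall in the stated
    range (hypothetical queries).
    """
    hypothetical = q.is_hypothetical

    def node_ok(i: int, t: int) -> bool:
        qr, tr = q.residues[i], targets[t]
        if tr.label not in qr.labels:
            return False
        if hypothetical:
            return True
        if qr.keys.shape != tr.keys.shape:
            return False
        if len(qr.keys) == 2:
            dq = float(np.linalg.norm(qr.keys[0] - qr.keys[1]))
            dt = float(np.linalg.norm(tr.keys[0] - tr.keys[1]))
            if not tol.compatible(dq, dt, q.mode):
                return False
        return True

    if hypothetical:

        def edge_ok(i: int, j: int, ti: int, tj: int) -> bool:
            dmin, dmax = q.range_for(i, j)
            d = float(
                np.linalg.norm(targets[ti].keys[0] - targets[tj].keys[0])
            )
            return dmin <= d <= dmax

    else:

        def edge_ok(i: int, j: int, ti: int, tj: int) -> bool:
            qa, qb = q.residues[i].keys, q.residues[j].keys
            ta, tb = targets[ti].keys, targets[tj].keys
            for a in range(len(qa)):
                for b in range(len(qb)):
                    dq = float(np.linalg.norm(qa[a] - qb[b]))
                    dt = float(np.linalg.norm(ta[a] - tb[b]))
                    if not tol.compatible(dq, dt, q.mode):
                        return False
            return True

    return node_ok, edge_ok


def _distance_sieve(
    q: MotifQuery,
    targets: list[TargetResidue],
    candidates: list[set[int]],
    tol: ToleranceConfig,
) -> None:
    """Drop target residues with no partner within query diameter + slack.

    Purely an optimization: a residue that cannot see any other candidate
    within the largest allowed query distance can never take part in an
    assignment (queries have >= 3 mutually constrained nodes).
    """
    if q.is_hypothetical:
        reach = max(hi for (_, hi) in q.ranges.values())
    else:
        all_keys = np.concatenate([r.keys for r in q.residues])
        diam = float(
            max(
                np.linalg.norm(a - b)
                for a, b in itertools.combinations(all_keys, 2)
            )
        )
        slack = (
            tol.protein_abs_tol
            if q.mode is SearchMode.PROTEIN
            else tol.rna_frac_tol * diam
        )
        reach = diam + slack
    live = set().union(*candidates) if candidates else set()
    centers = {t: targets[t].keys.mean(axis=0) for t in live}
    spans = {
        t: float(
            max(np.linalg.norm(k - centers[t]) for k in targets[t].keys)
        )
        for t in live
    }
    for t in list(live):
        has_partner = any(
            u != t
            and np.linalg.norm(centers[t] - centers[u])
            <= reach + spans[t] + spans[u]
            for u in live
        )
        if not has_partner:
            for c in candidates:
                c.discard(t)


def ullmann_match(
    q: MotifQuery,
    target_nodes: Sequence[PseudoAtomNode],
    tol: ToleranceConfig | None = None,
) -> list[Assignment]:
    """Exact subgraph-isomorphism search of ``q`` in the target pseudo-atoms.

    Returns every assignment for which each query label set contains the
    mapped residue's name and every constrained residue pair satisfies the
    distance tolerance (absolute for proteins, fractional for RNA,
    explicit ranges for hypothetical queries).  Assignments are injective
    on target residues.
    """
    tol = tol or ToleranceConfig()
    targets = group_target_residues(target_nodes)
    node_ok, edge_ok = _geometry_predicates(q, targets, tol)
    candidates = [
        {t for t in range(len(targets)) if node_ok(i, t)} for i in range(len(q))
    ]
    if any(not c for c in candidates):
        return []
    _distance_sieve(q, targets, candidates, tol)
    tuples = _ullmann_enumerate(candidates, edge_ok)
    return [
        Assignment(query=q, mapping={i: targets[t] for i, t in enumerate(tp)})
        for tp in tuples
    ]


def build_correspondence_graph(
    q: MotifQuery,
    targets: list[TargetResidue],
    tol: ToleranceConfig,
) -> nx.Graph:
    """Correspondence graph for clique-based partial matching.

    Vertices are label- and geometry-compatible (query residue, target
    residue) pairs; edges join vertices whose two pairings are mutually
    distance-consistent.  Vertices sharing a query node or a target
    residue are never adjacent, so every clique is an injective partial
    assignment.
    """
    node_ok, edge_ok = _geometry_predicates(q, targets, tol)
    g = nx.Graph()
    verts = [
        (i, t)
        for i in range(len(q))
        for t in range(len(targets))
        if node_ok(i, t)
    ]
    g.add_nodes_from(verts)
    for (i, ti), (j, tj) in itertools.combinations(verts, 2):
        if i == j or ti == tj:
            continue
        if edge_ok(*(i, j, ti, tj)) if i < j else edge_ok(*(j, i, tj, ti)):
            g.add_edge((i, ti), (j, tj))
    return g


def clique_partial_match(
    q: MotifQuery,
    target_nodes: Sequence[PseudoAtomNode],
    tol: ToleranceConfig | None = None,
    min_size: int = 3,
) -> list[Assignment]:
    """Partial matching via Bron–Kerbosch maximal cliques.

    Each maximal clique of size >= ``min_size`` in the correspondence
    graph is returned as a partial assignment; full-size cliques coincide
    with :func:`ullmann_match` results on the same input.
    """
    if min_size > len(q):
        raise QueryError(
            f"min_size {min_size} exceeds query size {len(q)}"
        )
    tol = tol or ToleranceConfig()
    targets = group_target_residues(target_nodes)
    g = build_correspondence_graph(q, targets, tol)
    out = []
    for clique in nx.find_cliques(g):
        if len(clique) < min_size:
            continue
        out.append(
            Assignment(query=q, mapping={i: targets[t] for i, t in sorted(clique)})
        )
    return out


# ---------------------------------------------------------------------------
# hydrogen-bonded cluster search

@dataclass
class ClusterPattern:
    """A hydrogen-bond connection pattern over 2–6 bases.

    ``labels[i]`` is a base name (A/C/G/U) or ``None`` for a wildcard;
    ``edges`` maps base index pairs to the minimum number of hydrogen
    bonds required between them.  The pattern graph must be connected —
    bases must be linked by hydrogen bonds to count as one substructure.
    """

    labels: list[str | None]
    edges: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        lo, hi = CLUSTER_PATTERN_SIZE
        n = len(self.labels)
        if not lo <= n <= hi:
            raise QueryError(f"cluster pattern must have {lo}-{hi} bases, got {n}")
        self.edges = {
            (min(i, j), max(i, j)): m for (i, j), m in self.edges.items()
        }
        for (i, j), m in self.edges.items():
            if i == j or not 0 <= i < n or not 0 <= j < n:
                raise QueryError(f"invalid pattern edge {(i, j)}")
            if m < 1:
                raise QueryError("minimum bond count must be >= 1")
        for l in self.labels:
            if l is not None and l not in RNA_BASES:
                raise QueryError(f"unknown base label {l!r}")
        g = nx.Graph(list(self.edges))
        g.add_nodes_from(range(n))
        if n > 1 and not nx.is_connected(g):
            raise QueryError("cluster pattern must be connected by hydrogen bonds")

    def __len__(self) -> int:
        return len(self.labels)


def enumerate_base_clusters(
    ct: ConnectionTable,
    size_range: tuple[int, int] = CLUSTER_PATTERN_SIZE,
) -> list[frozenset[int]]:
    """Every connected set of 2–6 bases in the connection table, once each.

    Uses ESU-style enumeration (grow from each anchor vertex using only
    exclusive neighbors with a higher index), which visits each connected
    vertex set exactly once.
    """
    lo, hi = size_range
    if lo < CLUSTER_PATTERN_SIZE[0] or hi > CLUSTER_PATTERN_SIZE[1] or lo > hi:
        raise QueryError(f"cluster sizes must lie within {CLUSTER_PATTERN_SIZE}")
    n = len(ct.bases)
    adj = {i: set(ct.neighbors(i)) for i in range(n)}
    found: set[frozenset[int]] = set()

    def extend(sub: set[int], ext: set[int], v: int) -> None:
        if lo <= len(sub) <= hi:
            found.add(frozenset(sub))
        if len(sub) >= hi:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            neighborhood = set().union(*(adj[u] for u in sub)) | sub
            new_ext = ext | {u for u in adj[w] - neighborhood if u > v}
            extend(sub | {w}, new_ext, v)

    for v in range(n):
        extend({v}, {u for u in adj[v] if u > v}, v)
    return sorted(found, key=lambda s: (len(s), sorted(s)))


def match_cluster_pattern(
    p: ClusterPattern, ct: ConnectionTable
) -> list[Assignment]:
    """All injective mappings of a connection pattern into a table.

    Each required pattern edge must be backed by at least the requested
    number of hydrogen bonds in the table.  Mappings that hit the same
    target base set (pattern automorphisms) collapse to one hit.
    """
    n = len(p)
    labels = [b.name for b in ct.bases]
    candidates = [
        {t for t in range(len(labels)) if p.labels[i] in (None, labels[t])}
        for i in range(n)
    ]

    def edge_ok(i: int, j: int, ti: int, tj: int) -> bool:
        if ti == tj:
            return False
        need = p.edges.get((min(i, j), max(i, j)))
        if need is None:
            return True
        return ct.bond_count(ti, tj) >= need

    tuples = _ullmann_enumerate(candidates, edge_ok)
    seen: set[frozenset[int]] = set()
    out = []
    # cluster hits carry no geometry; an empty query records engine/mode only
    cluster_query = MotifQuery(
        residues=[],
        mode=SearchMode.RNA,
        engine=Engine.CLUSTER,
        pair_mode=PseudoAtomMode.SINGLE,
    )
    for tp in sorted(tuples):
        key = frozenset(tp)
        if key in seen:
            continue
        seen.add(key)
        mapping = {
            i: TargetResidue(
                residue=ct.bases[t],
                keys=np.zeros((1, 3)),
                label=ct.bases[t].name,
            )
            for i, t in enumerate(tp)
        }
        out.append(Assignment(query=cluster_query, mapping=mapping))
    return out


def cluster_signature(ct: ConnectionTable, members: frozenset[int]) -> str:
    """Canonical signature of one cluster: sorted labels + edge code.

    Minimizes the (labels, edges-with-bond-counts) encoding over all node
    permutations, so isomorphic clusters — same base composition and same
    bonded topology — share a signature regardless of residue numbering.
    """
    nodes = sorted(members)
    labels = [ct.bases[i].name for i in nodes]
    edges = {
        (a, b): ct.bond_count(nodes[a], nodes[b])
        for a, b in itertools.combinations(range(len(nodes)), 2)
        if ct.bond_count(nodes[a], nodes[b]) > 0
    }
    best: tuple | None = None
    for perm in itertools.permutations(range(len(nodes))):
        lab = tuple(labels[p] for p in perm)
        pos = {p: i for i, p in enumerate(perm)}
        edg = tuple(
            sorted(
                (min(pos[a], pos[b]), max(pos[a], pos[b]), c)
                for (a, b), c in edges.items()
            )
        )
        cand = (lab, edg)
        if best is None or cand < best:
            best = cand
    lab, edg = best
    edge_str = ",".join(f"{a}-{b}:{c}" for a, b, c in edg)
    return "|".join([",".join(lab), edge_str])


@dataclass
class ClusterComparison:
    """Signature-level comparison of the clusters of two structures."""

    shared: dict[str, tuple[int, int]]
    only_in_1: dict[str, int]
    only_in_2: dict[str, int]


def compare_structures_by_clusters(
    ct1: ConnectionTable,
    ct2: ConnectionTable,
    size_range: tuple[int, int] = CLUSTER_PATTERN_SIZE,
) -> ClusterComparison:
    """Set algebra on canonical cluster signatures of two connection tables."""

    def census(ct: ConnectionTable) -> dict[str, int]:
        counts: dict[str, int] = {}
        for members in enumerate_base_clusters(ct, size_range):
            sig = cluster_signature(ct, members)
            counts[sig] = counts.get(sig, 0) + 1
        return counts

    c1, c2 = census(ct1), census(ct2)
    return ClusterComparison(
        shared={s: (c1[s], c2[s]) for s in sorted(set(c1) & set(c2))},
        only_in_1={s: c1[s] for s in sorted(set(c1) - set(c2))},
        only_in_2={s: c2[s] for s in sorted(set(c2) - set(c1))},
    )


# ---------------------------------------------------------------------------
# text schema for hypothetical queries and cluster patterns

def parse_query_schema(text: str):
    """Parse the small text schema for conceptual queries.

    ``node <id> <label|class>`` lines declare residues; ``dist <i> <j>
    <min> <max>`` lines add distance ranges (hypothetical queries);
    ``edge <i> <j> <min_bonds>`` lines instead define a hydrogen-bond
    cluster pattern.  Returns a :class:`MotifQuery` or a
    :class:`ClusterPattern` accordingly.
    """
    nodes: dict[str, str] = {}
    dists: list[tuple[str, str, float, float]] = []
    edges: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kw = parts[0].lower()
        try:
            if kw == "node" and len(parts) == 3:
                nodes[parts[1]] = parts[2]
            elif kw == "dist" and len(parts) == 5:
                dists.append((parts[1], parts[2], float(parts[3]), float(parts[4])))
            elif kw == "edge" and len(parts) == 4:
                edges.append((parts[1], parts[2], int(parts[3])))
            else:
                raise ValueError("unrecognized record")
        except ValueError as exc:
            raise QueryError(f"schema line {lineno}: {raw!r} ({exc})") from exc
    if not nodes:
        raise QueryError("schema defines no nodes")
    ids = list(nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    if edges:
        labels = [
            None if nodes[nid].upper() in ("ANY", "N", "*") else nodes[nid].upper()
            for nid in ids
        ]
        return ClusterPattern(
            labels=labels,
            edges={(index[a], index[b]): m for a, b, m in edges},
        )
    ranges = {
        (index[a], index[b]): (lo, hi) for a, b, lo, hi in dists
    }
    return build_hypothetical_query(
        [nodes[nid] for nid in ids], distance_ranges=ranges
    )
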
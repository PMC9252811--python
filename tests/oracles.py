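"""Independent brute-force oracles used to verify the search engines.

Everything here is deliberately naive — plain enumeration with explicit
distance checks — and shares no code with the engine implementations.
"""

import itertools

import numpy as np


def _pair_ok(q, i, j, keys_i, keys_j, tol):
    """All cross pseudo-atom distances between two mapped residues agree."""
    if q.is_hypothetical:
        lo, hi = q.range_for(i, j)
        d = float(np.linalg.norm(keys_i[0] - keys_j[0]))
        return lo <= d <= hi
    qa, qb = q.residues[i].keys, q.residues[j].keys
    for a in range(len(qa)):
        for b in range(len(qb)):
            dq = float(np.linalg.norm(qa[a] - qb[b]))
            dt = float(np.linalg.norm(keys_i[a] - keys_j[b]))
            if not tol.compatible(dq, dt, q.mode):
                return False
    return True


def _node_ok(q, i, label, keys, tol):
    if label not in q.residues[i].labels:
        return False
    if q.is_hypothetical:
        return True
    qk = q.residues[i].keys
    if qk.shape != keys.shape:
        return False
    if len(qk) == 2:
        dq = float(np.linalg.norm(qk[0] - qk[1]))
        dt = float(np.linalg.norm(keys[0] - keys[1]))
        if not tol.compatible(dq, dt, q.mode):
            return False
    return True


def exhaustive_assignments(q, targets, tol):
    """All injective consistent assignments; targets = [(label, keys array)].

    Returns a set of index tuples (query order), the reference answer for
    the exact engine.
    """
    n = len(q)
    cands = [
        [t for t, (label, keys) in enumerate(targets) if _node_ok(q, i, label, keys, tol)]
        for i in range(n)
    ]
    out = set()
    for combo in itertools.product(*cands):
        if len(set(combo)) != n:
            continue
        if all(
            _pair_ok(q, i, j, targets[combo[i]][1], targets[combo[j]][1], tol)
            for i, j in itertools.combinations(range(n), 2)
        ):
            out.add(combo)
    return out


def exhaustive_maximal_cliques(vertices, adjacent, min_size):
    """All maximal cliques by plain recursion over adjacency sets.

    ``vertices`` is a list; ``adjacent(u, v)`` a symmetric predicate.
    """
    idx = range(len(vertices))
    adj = {
        u: {v for v in idx if v != u and adjacent(vertices[u], vertices[v])}
        for u in idx
    }

    cliques = []

    def grow(clique, candidates, banned):
        if not candidates and not banned:
            if len(clique) >= min_size:
                cliques.append(frozenset(clique))
            return
        for v in sorted(candidates):
            grow(clique | {v}, candidates & adj[v], banned & adj[v])
            candidates = candidates - {v}
            banned = banned | {v}

    grow(set(), set(idx), set())
    return {frozenset(vertices[v] for v in c) for c in cliques}


def connected_subsets(n_nodes, edges, lo, hi):
    """All connected induced vertex subsets with lo <= size <= hi."""
    adj = {i: set() for i in range(n_nodes)}
    for (i, j) in edges:
        adj[i].add(j)
        adj[j].add(i)

    def is_connected(sub):
        sub = set(sub)
        seen = {next(iter(sub))}
        frontier = list(seen)
        while frontier:
            u = frontier.pop()
            for v in adj[u] & sub - seen:
                seen.add(v)
                frontier.append(v)
        return seen == sub

    out = set()
    for k in range(lo, hi + 1):
        for combo in itertools.combinations(range(n_nodes), k):
            if is_connected(combo):
                out.add(frozenset(combo))
    return out


def pattern_matches(labels_p, edges_p, labels_t, bond_counts, dedupe=True):
    """Injective pattern embeddings by raw permutation enumeration.

    ``edges_p``: {(i, j): min_bonds}; ``bond_counts``: {(i, j): count} on
    the target (symmetric keys normalized to i < j).
    """
    n = len(labels_p)
    hits = set()
    for combo in itertools.permutations(range(len(labels_t)), n):
        if any(
            labels_p[i] is not None and labels_p[i] != labels_t[combo[i]]
            for i in range(n)
        ):
            continue
        ok = all(
            bond_counts.get((min(combo[i], combo[j]), max(combo[i], combo[j])), 0) >= m
            for (i, j), m in edges_p.items()
        )
        if ok:
            hits.add(frozenset(combo) if dedupe else combo)
    return hits
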
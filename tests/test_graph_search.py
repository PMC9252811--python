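import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from submotif.fixtures import (
    FixtureSpec,
    default_motif,
    generate_planted_structure,
)
from submotif.graph_search import (
    ClusterPattern,
    Engine,
    MotifQuery,
    QueryError,
    QueryResidue,
    SearchMode,
    ToleranceConfig,
    build_hypothetical_query,
    build_query_from_coordinates,
    clique_partial_match,
    compare_structures_by_clusters,
    cluster_signature,
    enumerate_base_clusters,
    group_target_residues,
    match_cluster_pattern,
    parse_query_schema,
    ullmann_match,
)
from submotif.representation import PseudoAtomMode, structure_pseudoatoms
from submotif.structure_io import ResidueKind, Structure

from conftest import make_connection_table, make_residue, random_rotation, transform_structure
import oracles

AMINO = ["ALA", "ARG", "ASP", "GLU", "HIS", "LYS", "SER", "TRP", "TYR", "VAL"]


def random_target_structure(rng, n_residues, box=30.0):
    """Residues with random labels; keys realized via the fixture inverter."""
    from submotif.fixtures import TYPICAL_KEY_LENGTH, realize_atoms

    residues = []
    for i in range(n_residues):
        lab = AMINO[rng.integers(len(AMINO))]
        start = rng.uniform(-box / 2, box / 2, 3)
        length = TYPICAL_KEY_LENGTH[lab]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        end = start if length == 0 else start + length * direction
        residues.append(
            make_residue(lab, realize_atoms(lab, start, end), seq=i + 1)
        )
    return Structure(id=f"rand{n_residues}", residues=residues)


def query_from_target(s, rng, k, engine=Engine.EXACT):
    """Extract k residues of a structure as a coordinate query."""
    idx = rng.choice(len(s.residues), size=k, replace=False)
    nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
    targets = group_target_residues(nodes)
    residues = [
        QueryResidue(labels=frozenset({targets[i].label}), keys=targets[i].keys.copy())
        for i in idx
    ]
    return MotifQuery(residues=residues, mode=SearchMode.PROTEIN, engine=engine)


def target_label_keys(s):
    nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
    return [(t.label, t.keys) for t in group_target_residues(nodes)]


class TestQueryValidation:
    @pytest.mark.parametrize("n", [2, 13])
    def test_coordinate_query_size_limits(self, n):
        rng = np.random.default_rng(n)
        s = random_target_structure(rng, n)
        with pytest.raises(QueryError, match="3-12"):
            build_query_from_coordinates(s)

    def test_hypothetical_query_size_limits(self):
        with pytest.raises(QueryError, match="3-8"):
            build_hypothetical_query(["LYS"] * 9)
        with pytest.raises(QueryError, match="3-8"):
            build_hypothetical_query(["LYS", "ARG"])

    def test_cluster_pattern_size_limits(self):
        with pytest.raises(QueryError, match="2-6"):
            ClusterPattern(
                labels=["G"] * 7,
                edges={(i, i + 1): 1 for i in range(6)},
            )

    def test_cluster_pattern_must_be_connected(self):
        with pytest.raises(QueryError, match="connected"):
            ClusterPattern(labels=["G", "C", "A"], edges={(0, 1): 1})

    def test_class_shortcuts_expand(self):
        q = build_hypothetical_query(["BASIC_NO_HIS"] * 3)
        assert q.residues[0].labels == frozenset({"LYS", "ARG"})

    def test_explicit_range_overrides_default(self):
        q = build_hypothetical_query(
            ["LYS", "ARG", "ASP"], distance_ranges={(0, 1): (5.0, 7.0)}
        )
        assert q.range_for(0, 1) == (5.0, 7.0)
        assert q.range_for(0, 2) == (0.0, 13.0)

    def test_wrong_kind_residue_ignored_with_warning(self, caplog):
        s = random_target_structure(np.random.default_rng(1), 3)
        s.residues.append(make_residue("G", {"N1": (50, 0, 0)}, chain="R", seq=1))
        q = build_query_from_coordinates(s, mode=SearchMode.PROTEIN)
        assert len(q) == 3


class TestExactEngine:
    def test_self_match_contains_identity(self, rng):
        s = random_target_structure(rng, 20)
        q = query_from_target(s, rng, 4)
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        hits = ullmann_match(q, nodes)
        query_keys = {tuple(np.round(r.keys[0], 6)) for r in q.residues}
        identity = [
            a
            for a in hits
            if {tuple(np.round(t.keys[0], 6)) for t in a.mapping.values()} == query_keys
        ]
        assert identity, "self-extraction must recover itself"

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        s = random_target_structure(rng, 20)
        q = query_from_target(s, rng, 3)
        tol = ToleranceConfig()
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        # residues are numbered 1..n in grouping order, so seq-1 = target index
        got = {
            tuple(a.mapping[i].residue.seq_num - 1 for i in sorted(a.mapping))
            for a in ullmann_match(q, nodes, tol)
        }
        expected = oracles.exhaustive_assignments(q, target_label_keys(s), tol)
        assert got == expected

    def test_invariant_to_residue_order_and_rigid_motion(self, rng):
        s = random_target_structure(rng, 25)
        q = query_from_target(s, rng, 4)
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        base = {a.residue_set for a in ullmann_match(q, nodes)}

        shuffled = Structure(id=s.id, residues=list(reversed(s.residues)))
        nodes2 = structure_pseudoatoms(shuffled, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        assert {a.residue_set for a in ullmann_match(q, nodes2)} == base

        moved = transform_structure(s, random_rotation(rng), rng.uniform(-9, 9, 3))
        nodes3 = structure_pseudoatoms(moved, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        assert {a.residue_set for a in ullmann_match(q, nodes3)} == base

    @given(st.integers(0, 30))
    @settings(max_examples=30)
    def test_tolerance_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        s = random_target_structure(rng, 18)
        q = query_from_target(s, rng, 3)
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        small = {a.residue_set for a in ullmann_match(q, nodes, ToleranceConfig(protein_abs_tol=0.8))}
        large = {a.residue_set for a in ullmann_match(q, nodes, ToleranceConfig(protein_abs_tol=2.5))}
        assert small <= large

    @pytest.mark.parametrize("seed", range(100))
    def test_bounded_jitter_always_recovered(self, seed):
        """Per-atom displacement <= tol/4 can shift each pseudo-atom pair
        distance by at most tol, so recovery must be certain."""
        tol = ToleranceConfig()
        spec = FixtureSpec(
            seed=seed,
            motif=default_motif(["ASP", "HIS", "SER", "ARG"]),
            n_decoys=10,
            jitter_sigma=0.0,
            jitter_bound=tol.protein_abs_tol / 4,
        )
        s, truth = generate_planted_structure(spec)
        q = MotifQuery(
            residues=[
                QueryResidue(labels=frozenset({lab}), keys=truth.requested_keys[seq])
                for _, seq, lab in truth.planted
            ],
            mode=SearchMode.PROTEIN,
            engine=Engine.EXACT,
        )
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        hits = {a.residue_set for a in ullmann_match(q, nodes, tol)}
        planted = frozenset((c, n, "") for c, n, _ in truth.planted)
        assert planted in hits

    def test_rna_fractional_tolerance_boundary(self):
        """An RNA pair distance is accepted up to exactly 30% deviation."""
        tol = ToleranceConfig()

        coords = {
            "N1": (0, 0, 0), "C2": (1.3, 0.6, 0), "N3": (2.5, 0, 0),
            "C4": (2.5, -1.4, 0), "C5": (1.3, -2.1, 0), "C6": (0, -1.4, 0),
        }
        ring = {k: np.asarray(v, dtype=float) for k, v in coords.items()}

        def rna_structure(scale):
            # uniform scaling deviates EVERY pair distance by exactly scale-1
            positions = [np.zeros(3), np.array([10.0, 0, 0]), np.array([5.0, 8.0, 0])]
            return Structure(
                id=f"rna{scale}",
                residues=[
                    make_residue(
                        "C",
                        {k: scale * (v + p) for k, v in ring.items()},
                        seq=i + 1,
                    )
                    for i, p in enumerate(positions)
                ],
            )

        reference = rna_structure(1.0)
        targets = group_target_residues(
            structure_pseudoatoms(reference, ResidueKind.BASE, PseudoAtomMode.PAIR)
        )
        q = MotifQuery(
            residues=[
                QueryResidue(labels=frozenset({"C"}), keys=t.keys.copy())
                for t in targets
            ],
            mode=SearchMode.RNA,
            engine=Engine.EXACT,
        )
        nodes = structure_pseudoatoms(
            rna_structure(1.299), ResidueKind.BASE, PseudoAtomMode.PAIR
        )
        assert ullmann_match(q, nodes, tol)
        nodes = structure_pseudoatoms(
            rna_structure(1.301), ResidueKind.BASE, PseudoAtomMode.PAIR
        )
        assert not ullmann_match(q, nodes, tol)


def _correspondence_vertices(q, targets, tol):
    from submotif.graph_search import _geometry_predicates

    node_ok, edge_ok = _geometry_predicates(q, targets, tol)
    verts = [
        (i, t) for i in range(len(q)) for t in range(len(targets)) if node_ok(i, t)
    ]

    def adjacent(u, v):
        (i, ti), (j, tj) = u, v
        if i == j or ti == tj:
            return False
        if i > j:
            i, j, ti, tj = j, i, tj, ti
        return edge_ok(i, j, ti, tj)

    return verts, adjacent


class TestCliqueEngine:
    def test_full_query_present_gives_full_clique(self, rng):
        spec = FixtureSpec(
            seed=4, motif=default_motif(["ASP", "HIS", "SER", "ARG"]),
            n_decoys=20, jitter_sigma=0.1,
        )
        s, truth = generate_planted_structure(spec)
        q = MotifQuery(
            residues=[
                QueryResidue(labels=frozenset({lab}), keys=truth.requested_keys[seq])
                for _, seq, lab in truth.planted
            ],
            mode=SearchMode.PROTEIN,
            engine=Engine.PARTIAL,
        )
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        hits = clique_partial_match(q, nodes, min_size=3)
        assert max(h.matched_size for h in hits) == 4

    @pytest.mark.parametrize("seed", range(8))
    def test_maximal_cliques_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_target_structure(rng, 14)
        q = query_from_target(s, rng, 4, engine=Engine.PARTIAL)
        tol = ToleranceConfig()
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        targets = group_target_residues(nodes)
        verts, adjacent = _correspondence_vertices(q, targets, tol)
        assert len(verts) <= 40
        expected = oracles.exhaustive_maximal_cliques(verts, adjacent, 3)
        got = {
            frozenset((i, t.residue.seq_num - 1) for i, t in a.mapping.items())
            for a in clique_partial_match(q, nodes, tol, min_size=3)
        }
        assert got == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_full_size_cliques_bijective_with_exact_engine(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_target_structure(rng, 16)
        q = query_from_target(s, rng, 3, engine=Engine.PARTIAL)
        tol = ToleranceConfig()
        nodes = structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        def key(a):
            return frozenset((i, t.residue.seq_num) for i, t in a.mapping.items())

        full = {
            key(a)
            for a in clique_partial_match(q, nodes, tol, min_size=3)
            if a.matched_size == len(q)
        }
        exact = {key(a) for a in ullmann_match(q, nodes, tol)}
        assert full == exact

    def test_partial_site_of_planted_subset(self):
        """Only 4 residues of an 8-residue query exist in the target."""
        labels8 = ["LYS", "ARG", "ARG", "LYS", "ARG", "ARG", "LYS", "ARG"]
        spec = FixtureSpec(
            seed=9, motif=default_motif(labels8, spread=10.0),
            n_decoys=15, jitter_sigma=0.05,
            decoy_labels=["ASP", "GLU", "SER", "TYR"],
        )
        s, truth = generate_planted_structure(spec)
        q = MotifQuery(
            residues=[
                QueryResidue(labels=frozenset({lab}), keys=truth.requested_keys[i + 1])
                for i, lab in enumerate(labels8)
            ],
            mode=SearchMode.PROTEIN,
            engine=Engine.PARTIAL,
        )
        subset = Structure(
            id="sub",
            residues=[r for r in s.residues if r.seq_num in (1, 2, 3, 5) or r.seq_num > 100],
        )
        nodes = structure_pseudoatoms(subset, ResidueKind.AMINO, PseudoAtomMode.PAIR)
        hits = clique_partial_match(q, nodes, min_size=3)
        best = max(hits, key=lambda a: a.matched_size)
        assert best.matched_size == 4
        assert sorted(t.residue.seq_num for t in best.mapping.values()) == [1, 2, 3, 5]

    def test_min_size_validation(self, rng):
        s = random_target_structure(rng, 10)
        q = query_from_target(s, rng, 3, engine=Engine.PARTIAL)
        with pytest.raises(QueryError):
            clique_partial_match(
                q,
                structure_pseudoatoms(s, ResidueKind.AMINO, PseudoAtomMode.PAIR),
                min_size=4,
            )


class TestClusterEnumeration:
    def test_no_edges_no_clusters(self):
        ct = make_connection_table(["A", "C", "G"], {})
        assert enumerate_base_clusters(ct) == []

    def test_path_of_four(self):
        ct = make_connection_table("ACGU", {(0, 1): 1, (1, 2): 1, (2, 3): 1})
        clusters = enumerate_base_clusters(ct)
        by_size = {
            k: sum(1 for c in clusters if len(c) == k) for k in (2, 3, 4)
        }
        assert by_size == {2: 3, 3: 2, 4: 1}

    def test_triangle(self):
        ct = make_connection_table("AGC", {(0, 1): 1, (1, 2): 1, (0, 2): 1})
        clusters = enumerate_base_clusters(ct)
        assert sum(1 for c in clusters if len(c) == 2) == 3
        assert sum(1 for c in clusters if len(c) == 3) == 1

    @given(st.integers(0, 40))
    @settings(max_examples=40)
    def test_equals_bruteforce_connected_subsets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        edges = {
            (i, j): int(rng.integers(1, 4))
            for i, j in itertools.combinations(range(n), 2)
            if rng.random() < 0.3
        }
        labels = [("ACGU")[rng.integers(4)] for _ in range(n)]
        ct = make_connection_table(labels, edges)
        got = set(enumerate_base_clusters(ct))
        expected = oracles.connected_subsets(n, edges, 2, 6)
        assert got == expected


class TestClusterPatternMatching:
    def test_gc_triple_bond_pattern(self):
        ct = make_connection_table(["G", "C", "A"], {(0, 1): 3, (1, 2): 1})
        p = ClusterPattern(labels=["G", "C"], edges={(0, 1): 3})
        hits = match_cluster_pattern(p, ct)
        assert len(hits) == 1
        assert {t.residue.name for t in hits[0].mapping.values()} == {"G", "C"}

    def test_wildcard_path_pattern(self):
        ct = make_connection_table("ACGU", {(0, 1): 1, (1, 2): 1, (2, 3): 1})
        p = ClusterPattern(labels=[None, None, None], edges={(0, 1): 1, (1, 2): 1})
        hits = match_cluster_pattern(p, ct)
        sets = {frozenset(t.residue.seq_num for t in h.mapping.values()) for h in hits}
        assert sets == {frozenset({1, 2, 3}), frozenset({2, 3, 4})}

    def test_unsatisfied_bond_minimum_empty(self):
        ct = make_connection_table(["G", "C"], {(0, 1): 2})
        p = ClusterPattern(labels=["G", "C"], edges={(0, 1): 3})
        assert match_cluster_pattern(p, ct) == []

    @given(st.integers(0, 25))
    @settings(max_examples=25)
    def test_equals_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        labels = [("ACGU")[rng.integers(4)] for _ in range(n)]
        edges = {
            (i, j): int(rng.integers(1, 4))
            for i, j in itertools.combinations(range(n), 2)
            if rng.random() < 0.35
        }
        ct = make_connection_table(labels, edges)
        p = ClusterPattern(
            labels=[None, "G", None][: 3], edges={(0, 1): 1, (1, 2): 1}
        )
        got = {
            frozenset(t.residue.seq_num - 1 for t in h.mapping.values())
            for h in match_cluster_pattern(p, ct)
        }
        expected = oracles.pattern_matches(
            p.labels, p.edges, labels, ct.edges
        )
        assert got == expected


class TestClusterComparison:
    def test_identical_structures_share_everything(self):
        ct = make_connection_table("ACGU", {(0, 1): 1, (1, 2): 2})
        rep = compare_structures_by_clusters(ct, ct)
        assert rep.only_in_1 == {} and rep.only_in_2 == {}

    def test_extra_bonded_pair_shows_up_only_in_2(self):
        ct1 = make_connection_table(["A", "C", "G", "U"], {(0, 1): 1})
        ct2 = make_connection_table(["A", "C", "G", "U"], {(0, 1): 1, (2, 3): 2})
        rep = compare_structures_by_clusters(ct1, ct2)
        assert rep.only_in_1 == {}
        assert set(rep.only_in_2) == {
            cluster_signature(ct2, frozenset({2, 3}))
        }

    @given(st.integers(0, 20))
    @settings(max_examples=20)
    def test_counts_equal_oracle_set_algebra(self, seed):
        rng = np.random.default_rng(seed)

        def random_ct():
            n = int(rng.integers(3, 8))
            labels = [("ACGU")[rng.integers(4)] for _ in range(n)]
            edges = {
                (i, j): int(rng.integers(1, 3))
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.4
            }
            return make_connection_table(labels, edges)

        ct1, ct2 = random_ct(), random_ct()
        rep = compare_structures_by_clusters(ct1, ct2)

        def census(ct):
            out = {}
            for members in oracles.connected_subsets(
                len(ct.bases), ct.edges, 2, 6
            ):
                sig = cluster_signature(ct, members)
                out[sig] = out.get(sig, 0) + 1
            return out

        c1, c2 = census(ct1), census(ct2)
        assert rep.shared == {s: (c1[s], c2[s]) for s in set(c1) & set(c2)}
        assert rep.only_in_1 == {s: c1[s] for s in set(c1) - set(c2)}
        assert rep.only_in_2 == {s: c2[s] for s in set(c2) - set(c1)}


class TestQuerySchema:
    def test_hypothetical_schema(self):
        q = parse_query_schema(
            "node 1 LYS\nnode 2 BASIC_NO_HIS\nnode 3 ASP\ndist 1 2 5.0 7.0\n"
        )
        assert isinstance(q, MotifQuery)
        assert q.range_for(0, 1) == (5.0, 7.0)
        assert q.residues[1].labels == frozenset({"LYS", "ARG"})

    def test_cluster_schema(self):
        p = parse_query_schema("node 1 G\nnode 2 C\nedge 1 2 3\n")
        assert isinstance(p, ClusterPattern)
        assert p.edges == {(0, 1): 3}

    def test_malformed_line_rejected(self):
        with pytest.raises(QueryError):
            parse_query_schema("node 1 LYS\nbogus line here\n")
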
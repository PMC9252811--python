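"""Seeded synthetic structures for testing the engines offline.

The generator inverts the pseudo-atom representation: given a requested
Key Start / Key End geometry for each planted residue, it emits dummy
atoms placed so the configured atom-set centroids land exactly on the
requested keys, optionally jittered, and surrounds the planted site with
decoy residues whose positions are rejection-sampled (against an
independent brute-force matcher) so they never accidentally realize the
motif within tolerance.  All randomness flows from one explicit seed.

No physical realism beyond what the pseudo-atom inversion needs is
attempted: bond lengths and angles of the dummy atoms are arbitrary.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_search import (
    ClusterPattern,
    MotifQuery,
    SearchMode,
    ToleranceConfig,
)
from .representation import (
    BASE_ACCEPTORS,
    BASE_DONORS,
    DEFAULT_BASE_TABLE,
    DEFAULT_PSEUDO_ATOM_TABLE,
    PseudoAtomEntry,
)
from .structure_io import Atom, Residue, ResidueKind, Structure

log = logging.getLogger(__name__)


class FixtureError(ValueError):
    """Unrealizable fixture specification."""


# Plausible Key Start -> Key End separations used when inventing side-chain
# orientations (planted residues with unspecified Key End, and decoys).
TYPICAL_KEY_LENGTH: dict[str, float] = {
    "GLY": 0.0, "ALA": 0.0,
    "SER": 1.4, "CYS": 1.8, "THR": 1.4,
    "VAL": 1.6, "LEU": 2.2, "ILE": 2.5, "MET": 2.8, "PRO": 1.5,
    "PHE": 3.4, "TYR": 3.4, "TRP": 3.9, "HIS": 2.8,
    "ASP": 2.3, "GLU": 3.2, "ASN": 2.3, "GLN": 3.2,
    "LYS": 3.5, "ARG": 4.1,
    # bases: ring-centroid separation (purines) / centroid-to-N1 (pyrimidines)
    "A": 2.4, "G": 2.4, "C": 1.4, "U": 1.4,
}


@dataclass
class PlantedResidue:
    label: str
    key_start: np.ndarray
    key_end: np.ndarray | None = None  # None: invent a typical-length direction

    def __post_init__(self) -> None:
        self.key_start = np.asarray(self.key_start, dtype=float)
        if self.key_end is not None:
            self.key_end = np.asarray(self.key_end, dtype=float)


@dataclass
class FixtureSpec:
    """Conditions for one planted-motif structure.

    Defaults reflect the standard test conditions: a handful of decoys in
    a 40 Å box, per-atom Gaussian jitter of 0.2 Å, protein mode.
    """

    seed: int
    motif: list[PlantedResidue]
    n_decoys: int = 50
    jitter_sigma: float = 0.2
    jitter_bound: float | None = None  # uniform-in-ball displacement instead
    box_size: float = 40.0
    mode: SearchMode = SearchMode.PROTEIN
    generation_tol: ToleranceConfig = field(default_factory=ToleranceConfig)
    decoy_labels: list[str] | None = None  # default: all residues of the mode


@dataclass
class GroundTruth:
    """Which residues of a generated structure carry the planted site."""

    planted: list[tuple[str, int, str]]  # (chain, seq_num, label)
    requested_keys: dict[int, np.ndarray]  # seq_num -> (2, 3) exact key positions


def _entry_for(label: str) -> PseudoAtomEntry:
    entry = DEFAULT_PSEUDO_ATOM_TABLE.get(label) or DEFAULT_BASE_TABLE.get(label)
    if entry is None:
        raise FixtureError(f"no pseudo-atom table entry for label {label!r}")
    return entry


def _offset_ring(k: int, radius: float = 0.7) -> np.ndarray:
    """k planar offsets summing exactly to zero (regular k-gon; k>=1)."""
    if k == 1:
        return np.zeros((1, 3))
    ang = 2 * np.pi * np.arange(k) / k
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(k)], axis=1)
    return pts - pts.mean(axis=0)


def realize_atoms(label: str, key_start: np.ndarray, key_end: np.ndarray) -> dict[str, np.ndarray]:
    """Place atoms so the table centroids land exactly on the requested keys.

    Sets are processed smallest-first; atoms shared with an already-placed
    set stay fixed and one free atom per set absorbs the centroid
    correction, so every configured centroid is exact by construction.
    """
    entry = _entry_for(label)
    placed: dict[str, np.ndarray] = {}
    sets: list[tuple[tuple[str, ...], np.ndarray]] = [(entry.start_atoms, key_start)]
    if not entry.coincident:
        sets.append((entry.end_atoms, key_end))
    sets.sort(key=lambda se: len(se[0]))
    for atoms, centroid in sets:
        free = [a for a in atoms if a not in placed]
        if not free:
            raise FixtureError(
                f"{label}: atom set {atoms} fully constrained by earlier sets"
            )
        offsets = _offset_ring(len(free))
        for a, off in zip(free[:-1], offsets[:-1]):
            placed[a] = centroid + off
        total = len(atoms) * centroid
        fixed_sum = sum(
            (placed[a] for a in atoms if a in placed and a != free[-1]),
            np.zeros(3),
        )
        placed[free[-1]] = total - fixed_sum
    # dummy backbone so the file looks like a residue; never part of any key
    if "CA" not in placed:
        placed["CA"] = key_start + np.array([-1.2, -0.8, 0.4])
    if label in DEFAULT_PSEUDO_ATOM_TABLE:
        placed.setdefault("N", placed["CA"] + np.array([-1.3, 0.6, 0.0]))
        placed.setdefault("C", placed["CA"] + np.array([0.9, 1.1, 0.0]))
    return placed


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _residue_from_atoms(
    chain: str, seq: int, label: str, atoms: dict[str, np.ndarray]
) -> Residue:
    return Residue(
        chain_id=chain,
        seq_num=seq,
        icode="",
        name=label,
        atoms=[
            Atom(name=n, element=_element_of(n), pos=p)
            for n, p in sorted(atoms.items())
        ],
    )


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _resolve_keys(pr: PlantedResidue, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    start = pr.key_start
    if pr.key_end is not None:
        return start, pr.key_end
    length = TYPICAL_KEY_LENGTH.get(pr.label, 2.0)
    if _entry_for(pr.label).coincident or length == 0.0:
        return start, start.copy()
    return start, start + length * _random_direction(rng)


def brute_force_hits(
    q: MotifQuery,
    target_residue_keys: list[tuple[str, np.ndarray]],
    tol: ToleranceConfig,
) -> list[tuple[int, ...]]:
    """Exhaustive label+distance matcher, independent of the search engines.

    Enumerates all injective label-consistent assignments of query residues
    onto target residues and keeps those whose every pseudo-atom pair
    distance is compatible.  Used for decoy rejection during generation and
    as the test oracle.
    """
    n = len(q)
    cands = [
        [t for t, (label, _) in enumerate(target_residue_keys) if label in q.residues[i].labels]
        for i in range(n)
    ]
    hits = []
    for combo in itertools.product(*cands):
        if len(set(combo)) != n:
            continue
        ok = True
        for i, j in itertools.combinations(range(n), 2):
            ti, tj = combo[i], combo[j]
            if q.is_hypothetical:
                lo, hi = q.range_for(i, j)
                d = float(
                    np.linalg.norm(
                        target_residue_keys[ti][1][0] - target_residue_keys[tj][1][0]
                    )
                )
                if not lo <= d <= hi:
                    ok = False
                    break
            else:
                qa, qb = q.residues[i].keys, q.residues[j].keys
                ta, tb = target_residue_keys[ti][1], target_residue_keys[tj][1]
                for a in range(len(qa)):
                    for b in range(len(qb)):
                        dq = float(np.linalg.norm(qa[a] - qb[b]))
                        dt = float(np.linalg.norm(ta[a] - tb[b]))
                        if not tol.compatible(dq, dt, q.mode):
                            ok = False
                            break
                    if not ok:
                        break
            if not ok:
                break
        # intra-residue key distance must also agree for pair-key queries
        if ok and not q.is_hypothetical:
            for i in range(n):
                qk = q.residues[i].keys
                tk = target_residue_keys[combo[i]][1]
                if len(qk) == 2 and len(tk) == 2:
                    dq = float(np.linalg.norm(qk[0] - qk[1]))
                    dt = float(np.linalg.norm(tk[0] - tk[1]))
                    if not tol.compatible(dq, dt, q.mode):
                        ok = False
                        break
        if ok:
            hits.append(combo)
    return hits


def _query_from_planted(
    keys: list[tuple[str, np.ndarray, np.ndarray]], mode: SearchMode
) -> MotifQuery:
    from .graph_search import Engine, QueryResidue

    residues = [
        QueryResidue(labels=frozenset({label}), keys=np.array([s, e]))
        for label, s, e in keys
    ]
    return MotifQuery(residues=residues, mode=mode, engine=Engine.EXACT)


def generate_planted_structure(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Build one structure containing the requested motif plus decoys.

    The planted residues realize the requested key geometry exactly before
    jitter; decoy residues get uniform labels and box-uniform positions,
    rejection-sampled (up to 1000 rounds) so that the only site matching
    the planted-key query at ``generation_tol`` is the planted one.
    """
    if not spec.motif:
        raise FixtureError("empty motif")
    rng = np.random.default_rng(spec.seed)
    labels_pool = spec.decoy_labels or (
        sorted(DEFAULT_PSEUDO_ATOM_TABLE)
        if spec.mode is SearchMode.PROTEIN
        else sorted(DEFAULT_BASE_TABLE)
    )

    resolved = []
    for pr in spec.motif:
        start, end = _resolve_keys(pr, rng)
        resolved.append((pr.label, start, end))
    for (_, s1, _), (_, s2, _) in itertools.combinations(resolved, 2):
        if np.linalg.norm(s1 - s2) < 1.0:
            raise FixtureError("two planted residues requested < 1 Å apart")

    query = _query_from_planted(resolved, spec.mode)
    half = spec.box_size / 2.0

    def jitter() -> np.ndarray:
        if spec.jitter_bound is not None:
            r = spec.jitter_bound * rng.uniform() ** (1 / 3)
            return r * _random_direction(rng)
        if spec.jitter_sigma > 0:
            return rng.normal(scale=spec.jitter_sigma, size=3)
        return np.zeros(3)

    planted_residues: list[Residue] = []
    requested_keys: dict[int, np.ndarray] = {}
    for seq, (label, start, end) in enumerate(resolved, start=1):
        atoms = realize_atoms(label, start, end)
        atoms = {n: p + jitter() for n, p in atoms.items()}
        planted_residues.append(_residue_from_atoms("A", seq, label, atoms))
        requested_keys[seq] = np.array([start, end])

    planted_set = frozenset(range(len(resolved)))
    for attempt in range(1000):
        decoys: list[tuple[str, np.ndarray, np.ndarray]] = []
        existing = [s for _, s, _ in resolved]
        for _ in range(spec.n_decoys):
            for _ in range(100):
                pos = rng.uniform(-half, half, size=3)
                if all(np.linalg.norm(pos - p) >= 1.0 for p in existing):
                    break
            label = labels_pool[rng.integers(len(labels_pool))]
            length = TYPICAL_KEY_LENGTH.get(label, 2.0)
            end = pos if length == 0.0 else pos + length * _random_direction(rng)
            decoys.append((label, pos, end))
            existing.append(pos)
        all_keys = [
            (label, np.array([s, e])) for label, s, e in resolved + decoys
        ]
        hits = brute_force_hits(query, all_keys, spec.generation_tol)
        if all(frozenset(h) == planted_set for h in hits):
            break
    else:
        raise FixtureError("could not place decoys without spurious hits")
    if attempt:
        log.info("decoy rejection sampling needed %d extra rounds", attempt)

    residues = list(planted_residues)
    for k, (label, start, end) in enumerate(decoys, start=101):
        atoms = realize_atoms(label, start, end)
        residues.append(_residue_from_atoms("A", k, label, atoms))

    structure = Structure(id=f"fixture{spec.seed}", residues=residues)
    truth = GroundTruth(
        planted=[("A", seq, label) for seq, (label, _, _) in enumerate(resolved, 1)],
        requested_keys=requested_keys,
    )
    return structure, truth


def default_motif(labels: list[str], spread: float = 8.0) -> list[PlantedResidue]:
    """A deterministic compact arrangement for the given residue labels.

    Key Starts sit on a ring of radius ``spread``/2 with alternating z
    offsets; Key Ends point inward toward the ring axis at the typical
    side-chain length, like residues lining a binding pocket, so the same
    label list always yields the identical pre-jitter geometry.
    """
    n = len(labels)
    ang = 2 * np.pi * np.arange(n) / n
    r = spread / 2.0
    out = []
    for i, (lab, a) in enumerate(zip(labels, ang)):
        start = np.array([r * np.cos(a), r * np.sin(a), 1.5 * ((i % 2) * 2 - 1)])
        length = TYPICAL_KEY_LENGTH.get(lab, 2.0)
        if length == 0.0 or _entry_for(lab).coincident:
            end = start.copy()
        else:
            inward = np.array([-np.cos(a), -np.sin(a), 0.0])
            end = start + length * inward
        out.append(PlantedResidue(label=lab, key_start=start, key_end=end))
    return out


# ---------------------------------------------------------------------------
# RNA hydrogen-bond cluster fixtures

_BASE_ATOM_SETS: dict[str, tuple[str, ...]] = {
    b: tuple(
        sorted(
            set(DEFAULT_BASE_TABLE[b].start_atoms)
            | set(DEFAULT_BASE_TABLE[b].end_atoms)
            | set(BASE_DONORS[b])
            | set(BASE_ACCEPTORS[b])
        )
    )
    for b in "ACGU"
}

_BOND_LENGTH = 2.9       # donor-acceptor distance realized for requested bonds
_MIN_NONBOND_DIST = 5.0  # every other donor-acceptor pair must exceed this
_BASE_SPACING = 20.0
_BOND_LATERAL = 6.0


def generate_rna_cluster_fixture(
    pattern: ClusterPattern, seed: int = 0
) -> tuple[Structure, dict[tuple[int, int], int]]:
    """A synthetic RNA structure realizing exactly the requested bonds.

    Bases are spaced 20 Å apart along x; for each required edge the needed
    donor/acceptor atoms are moved to the pair midpoint, 2.9 Å apart, with
    successive bonds of one pair offset 6 Å laterally.  All other
    donor-acceptor distances are verified > 5 Å, so hydrogen-bond
    detection recovers the requested connection table and nothing else.
    Wildcard pattern positions are filled with seeded random bases.
    """
    rng = np.random.default_rng(seed)
    labels = [
        l if l is not None else "ACGU"[rng.integers(4)] for l in pattern.labels
    ]
    n = len(labels)
    centers = [np.array([_BASE_SPACING * i, 0.0, 0.0]) for i in range(n)]
    atoms: list[dict[str, np.ndarray]] = []
    for i, lab in enumerate(labels):
        names = _BASE_ATOM_SETS[lab]
        # small deterministic scatter: atoms distinguishable, same residue
        pos = {
            nm: centers[i] + 0.35 * _offset_ring(len(names))[k] + np.array([0, 0, 0.05 * k])
            for k, nm in enumerate(names)
        }
        atoms.append(pos)

    used: list[set[str]] = [set() for _ in range(n)]
    moved: list[tuple[int, str]] = []

    for (i, j), count in sorted(pattern.edges.items()):
        mid = (centers[i] + centers[j]) / 2.0
        axis = (centers[j] - centers[i]) / np.linalg.norm(centers[j] - centers[i])
        lateral = np.array([0.0, 1.0, 0.0])
        for b in range(count):
            pair = None
            for d in BASE_DONORS[labels[i]]:
                if d in used[i]:
                    continue
                for a in BASE_ACCEPTORS[labels[j]]:
                    if a not in used[j]:
                        pair = (i, d, j, a)
                        break
                if pair:
                    break
            if pair is None:
                for d in BASE_DONORS[labels[j]]:
                    if d in used[j]:
                        continue
                    for a in BASE_ACCEPTORS[labels[i]]:
                        if a not in used[i]:
                            pair = (j, d, i, a)
                            break
                    if pair:
                        break
            if pair is None:
                raise FixtureError(
                    f"edge {labels[i]}-{labels[j]} cannot realize {count} bonds: "
                    "not enough distinct donor/acceptor atoms"
                )
            di, dn, ai, an = pair
            offset = _BOND_LATERAL * b * lateral
            atoms[di][dn] = mid + offset + (_BOND_LENGTH / 2) * axis
            atoms[ai][an] = mid + offset - (_BOND_LENGTH / 2) * axis
            used[di].add(dn)
            used[ai].add(an)
            moved.extend([(di, dn), (ai, an)])

    # verify the construction: no unintended donor-acceptor proximity
    intended = set()
    for k in range(0, len(moved), 2):
        intended.add((moved[k], moved[k + 1]))
    for i in range(n):
        for d in BASE_DONORS[labels[i]]:
            for j in range(n):
                if i == j:
                    continue
                for a in BASE_ACCEPTORS[labels[j]]:
                    pr = ((i, d), (j, a))
                    dist = float(np.linalg.norm(atoms[i][d] - atoms[j][a]))
                    if pr in intended:
                        continue
                    if dist <= _MIN_NONBOND_DIST:
                        raise FixtureError(
                            f"unintended donor-acceptor contact {pr} at {dist:.2f} Å"
                        )

    residues = [
        _residue_from_atoms("R", i + 1, lab, atoms[i]) for i, lab in enumerate(labels)
    ]
    structure = Structure(id=f"rnafix{seed}", residues=residues)
    truth = {(min(i, j), max(i, j)): c for (i, j), c in pattern.edges.items()}
    return structure, truth


# ---------------------------------------------------------------------------
# fixture sets on disk

def write_fixture_set(
    out_dir: str | Path,
    seed: int,
    n_structures: int = 10,
    n_with_motif: int = 4,
    motif_labels: list[str] | None = None,
    n_decoys: int = 50,
    jitter_sigma: float = 0.2,
) -> Path:
    """Write a directory of PDB files plus a ground-truth TSV.

    ``n_with_motif`` of the ``n_structures`` files contain the planted
    motif; the rest hold only decoys (generated by planting in a throwaway
    location outside the reported set: they simply omit the motif).
    Returns the ground-truth TSV path.
    """
    from .structure_io import write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    motif_labels = motif_labels or ["ASP", "HIS", "SER", "ARG"]
    rows = ["file\tchain\tresnum\tlabel\tplanted_site_id"]
    rng = np.random.default_rng(seed)
    for k in range(n_structures):
        sub_seed = int(rng.integers(2**31 - 1))
        has_motif = k < n_with_motif
        spec = FixtureSpec(
            seed=sub_seed,
            motif=default_motif(motif_labels),
            n_decoys=n_decoys,
            jitter_sigma=jitter_sigma,
        )
        structure, truth = generate_planted_structure(spec)
        if not has_motif:
            keep = {(c, s) for c, s, _ in truth.planted}
            structure.residues = [
                r for r in structure.residues if (r.chain_id, r.seq_num) not in keep
            ]
        name = f"target_{k:03d}.pdb"
        structure.id = f"target_{k:03d}"
        write_structure(structure, out_dir / name)
        if has_motif:
            for c, s, lab in truth.planted:
                rows.append(f"{name}\t{c}\t{s}\t{lab}\t{k}")
    tsv = out_dir / "ground_truth.tsv"
    tsv.write_text("\n".join(rows) + "\n")
    return tsv
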
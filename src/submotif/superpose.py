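"""Least-squares superposition, RMSD scoring, ranking, and hit filtering.

Matched substructures are scored by superposing the query pseudo-atoms
onto the matched target pseudo-atoms with the Kabsch closed-form fit
(proper rotation only — mirror solutions are rejected by the determinant
sign correction, since side-chain arrangements are chiral) and ranking
hits by the resulting RMSD.  Hypothetical queries carry no reference
geometry, so their hits have no RMSD and rank by matched size instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_search import Assignment, MotifQuery
from .structure_io import Residue, Structure, list_het_neighbors

# one-letter codes for compositions (amino acids + the four RNA bases)
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "A": "A", "C": "C", "G": "G", "U": "U",
}


def one_letter(name: str) -> str:
    return _THREE_TO_ONE.get(name, "X")


@dataclass
class Superposition:
    """A proper-rotation least-squares fit of one point set onto another."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_points: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(ref: np.ndarray, mov: np.ndarray) -> Superposition:
    """Fit ``mov`` onto ``ref``: find R (proper rotation) and t minimizing
    the RMSD of ``mov @ R.T + t`` against ``ref``.

    Uses the standard SVD solution of the cross-covariance matrix with the
    determinant sign correction, so reflections are never returned.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {ref.shape} vs {mov.shape}")
    n = len(ref)
    if n < 1:
        raise ValueError("need at least one point")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = mov - mov_c
    q = ref - ref_c
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_points=n)


@dataclass
class Match:
    """A scored hit: assignment plus superposition and report flags."""

    assignment: Assignment
    superposition: Superposition | None
    target_id: str
    same_chain: bool
    near_het: bool

    @property
    def matched_size(self) -> int:
        return self.assignment.matched_size

    @property
    def rmsd(self) -> float | None:
        return self.superposition.rmsd if self.superposition else None

    @property
    def matched_residues(self) -> list[Residue]:
        return [
            self.assignment.mapping[i].residue
            for i in sorted(self.assignment.mapping)
        ]

    @property
    def composition(self) -> str:
        return "".join(one_letter(r.name) for r in self.matched_residues)

    @property
    def first_residue_ident(self) -> str:
        res = self.matched_residues
        return res[0].ident if res else ""


def _matched_point_pairs(
    a: Assignment, q: MotifQuery
) -> tuple[np.ndarray, np.ndarray]:
    """Query and target pseudo-atom coordinate arrays, in query order."""
    ref, mov = [], []
    for i in sorted(a.mapping):
        qk = q.residues[i].keys
        tk = a.mapping[i].keys
        for k in range(len(qk)):
            mov.append(qk[k])
            ref.append(tk[k])
    return np.array(ref), np.array(mov)


def score_match(
    a: Assignment,
    q: MotifQuery,
    target: Structure,
    het_cutoff: float = 4.0,
) -> Match:
    """Score one assignment against its target structure.

    Coordinate queries are superposed (query onto target) over the matched
    pseudo-atoms and scored by RMSD.  Hypothetical queries have no
    reference geometry: the superposition is absent and downstream ranking
    falls back to matched size.  ``same_chain`` / ``near_het`` flags are
    set from the matched target residues.
    """
    sup = None
    if not q.is_hypothetical and q.residues:
        ref, mov = _matched_point_pairs(a, q)
        sup = kabsch_superpose(ref, mov)
    residues = [a.mapping[i].residue for i in sorted(a.mapping)]
    chains = {r.chain_id for r in residues}
    positions = np.concatenate([a.mapping[i].keys for i in sorted(a.mapping)])
    return Match(
        assignment=a,
        superposition=sup,
        target_id=target.id,
        same_chain=len(chains) == 1,
        near_het=list_het_neighbors(target, positions, cutoff=het_cutoff),
    )


def dedupe_matches(matches: list[Match]) -> list[Match]:
    """Collapse hits sharing a target residue set, keeping the best mapping.

    Assignments related by query automorphism land on the same residues;
    the search reports sites, not mappings, so one representative — the
    lowest-RMSD mapping (ties: first in rank order) — survives.
    """
    best: dict[tuple, Match] = {}
    for m in sorted(matches, key=_rank_key):
        key = (m.target_id, m.assignment.residue_set)
        if key not in best:
            best[key] = m
    return sorted(best.values(), key=_rank_key)


def _rank_key(m: Match):
    rmsd = m.rmsd if m.rmsd is not None else float("inf")
    return (rmsd, -m.matched_size, m.target_id, m.first_residue_ident)


class ChainFilter:
    ANY = "ANY"
    SAME = "SAME"
    CROSS = "CROSS"


def rank_and_filter(
    matches: list[Match],
    max_rmsd: float | None = None,
    require_het: bool = False,
    chain_filter: str = ChainFilter.ANY,
) -> list[Match]:
    """Stable total ordering plus conjunctive filters.

    Sort key: RMSD ascending (hits without RMSD last), then matched size
    descending, target id, first matched residue.  Filters: optional RMSD
    ceiling, heteroatom-proximity requirement, and same-chain /
    cross-chain restriction.
    """
    out = []
    for m in matches:
        if max_rmsd is not None and (m.rmsd is None or m.rmsd > max_rmsd):
            continue
        if require_het and not m.near_het:
            continue
        if chain_filter == ChainFilter.SAME and not m.same_chain:
            continue
        if chain_filter == ChainFilter.CROSS and m.same_chain:
            continue
        out.append(m)
    return sorted(out, key=_rank_key)


def write_superposed_query(
    m: Match, q: MotifQuery, path
) -> None:
    """Write the query, transformed onto the hit, as a PDB file.

    Only meaningful for coordinate queries; the target is left untouched.
    """
    from .structure_io import Structure as _S, write_structure

    if m.superposition is None:
        raise ValueError("hypothetical-query hits have no superposition to write")
    residues = []
    for qr in q.residues:
        if qr.source is None:
            continue
        src = qr.source
        moved_atoms = []
        for atom in src.atoms:
            new = type(atom)(
                name=atom.name,
                element=atom.element,
                pos=m.superposition.apply(atom.pos[None, :])[0],
                altloc=atom.altloc,
                occupancy=atom.occupancy,
                is_hetero=atom.is_hetero,
            )
            moved_atoms.append(new)
        residues.append(
            type(src)(
                chain_id=src.chain_id,
                seq_num=src.seq_num,
                icode=src.icode,
                name=src.name,
                atoms=moved_atoms,
            )
        )
    out = _S(id=f"{m.target_id}_fit", residues=residues)
    write_structure(out, path)
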
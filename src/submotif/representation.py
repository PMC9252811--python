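"""Pseudo-atom graph representation of residues and RNA hydrogen-bond tables.

Each amino-acid side chain (and each RNA base) is reduced to one or two
pseudo-atoms: a *Key Start* near the chain attachment point and a *Key End*
at the functional tip, so that the pair encodes both position and
orientation of the side chain as a vector.  Hypothetical (conceptual)
queries use a *single Key* placed at the functional tip instead.  RNA base
hydrogen bonding is summarized in a connection table: an adjacency list of
base pairs with the number of donor/acceptor contacts between them.

The atom sets behind every pseudo-atom are data, not code: they live in
:data:`DEFAULT_PSEUDO_ATOM_TABLE` and can be replaced wholesale from a
plain-text config (see :func:`parse_pseudo_atom_config`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np

from .structure_io import Residue, ResidueKind, Structure

log = logging.getLogger(__name__)


class KeyRole(Enum):
    KEY_START = "KEY_START"
    KEY_END = "KEY_END"
    KEY_SINGLE = "KEY_SINGLE"


class PseudoAtomMode(Enum):
    PAIR = "PAIR"      # Key Start + Key End (exact / partial engines)
    SINGLE = "SINGLE"  # one Key (hypothetical-arrangement engine)


@dataclass
class PseudoAtomNode:
    """One graph node: a pseudo-atom standing in for a residue."""

    residue: Residue
    role: KeyRole
    pos: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)


@dataclass(frozen=True)
class PseudoAtomEntry:
    start_atoms: tuple[str, ...]
    end_atoms: tuple[str, ...]
    coincident: bool = False  # Key Start and Key End are the same point


# Key Start is the side-chain attachment (CB; CA for glycine).  Key End is
# the centroid of the functional-tip atoms; chemically symmetric tips
# (Asp/Glu carboxylates, Arg guanidinium, aromatic rings) use the centroid
# of all equivalent atoms, which removes atom-naming ambiguity.  Gly and Ala
# carry no directional side chain, so their two keys coincide.
DEFAULT_PSEUDO_ATOM_TABLE: dict[str, PseudoAtomEntry] = {
    "GLY": PseudoAtomEntry(("CA",), ("CA",), coincident=True),
    "ALA": PseudoAtomEntry(("CB",), ("CB",), coincident=True),
    "SER": PseudoAtomEntry(("CB",), ("OG",)),
    "CYS": PseudoAtomEntry(("CB",), ("SG",)),
    "THR": PseudoAtomEntry(("CB",), ("OG1",)),
    "VAL": PseudoAtomEntry(("CB",), ("CG1", "CG2")),
    "LEU": PseudoAtomEntry(("CB",), ("CD1", "CD2")),
    "ILE": PseudoAtomEntry(("CB",), ("CD1",)),
    "MET": PseudoAtomEntry(("CB",), ("SD", "CE")),
    "PRO": PseudoAtomEntry(("CB",), ("CG", "CD")),
    "PHE": PseudoAtomEntry(("CB",), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TYR": PseudoAtomEntry(("CB",), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TRP": PseudoAtomEntry(
        ("CB",), ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    ),
    "ASP": PseudoAtomEntry(("CB",), ("OD1", "OD2")),
    "GLU": PseudoAtomEntry(("CB",), ("OE1", "OE2")),
    "ASN": PseudoAtomEntry(("CB",), ("OD1", "ND2")),
    "GLN": PseudoAtomEntry(("CB",), ("OE1", "NE2")),
    "HIS": PseudoAtomEntry(("CB",), ("CG", "ND1", "CD2", "CE1", "NE2")),
    "LYS": PseudoAtomEntry(("CB",), ("NZ",)),
    "ARG": PseudoAtomEntry(("CB",), ("NE", "CZ", "NH1", "NH2")),
}

_PURINE_5RING = ("C4", "C5", "N7", "C8", "N9")
_SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

# Bases: Key Start = six-membered-ring centroid for all four bases; Key End
# = five-membered-ring centroid for purines, the glycosidic N1 for
# pyrimidines, so each base is again an oriented vector.
DEFAULT_BASE_TABLE: dict[str, PseudoAtomEntry] = {
    "A": PseudoAtomEntry(_SIX_RING, _PURINE_5RING),
    "G": PseudoAtomEntry(_SIX_RING, _PURINE_5RING),
    "C": PseudoAtomEntry(_SIX_RING, ("N1",)),
    "U": PseudoAtomEntry(_SIX_RING, ("N1",)),
}

# Heavy-atom hydrogen-bond donors/acceptors on the base moieties.
BASE_DONORS: dict[str, tuple[str, ...]] = {
    "A": ("N6",),
    "G": ("N1", "N2"),
    "C": ("N4",),
    "U": ("N3",),
}
BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}


@dataclass(frozen=True)
class HBond:
    donor_residue: Residue
    acceptor_residue: Residue
    donor_atom: str
    acceptor_atom: str
    distance: float


@dataclass
class ConnectionTable:
    """Hydrogen-bond adjacency among the bases of one structure."""

    bases: list[Residue]
    # (i, j) with i < j (indices into `bases`) -> number of hydrogen bonds
    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def bond_count(self, i: int, j: int) -> int:
        return self.edges.get((min(i, j), max(i, j)), 0)

    def to_tsv(self) -> str:
        """Serialize: node list block then one edge per line."""
        lines = ["# bases"]
        for i, b in enumerate(self.bases):
            lines.append(f"node\t{i}\t{b.ident}")
        lines.append("# edges: base_i\tbase_j\tbond_count")
        for (i, j), n in sorted(self.edges.items()):
            lines.append(f"edge\t{i}\t{j}\t{n}")
        return "\n".join(lines) + "\n"


def _centroid(r: Residue, names: tuple[str, ...]) -> np.ndarray | None:
    pos = r.atom_positions(names)
    return None if pos is None else pos.mean(axis=0)


def _build_nodes(
    r: Residue,
    entry: PseudoAtomEntry,
    mode: PseudoAtomMode,
) -> list[PseudoAtomNode]:
    end = _centroid(r, entry.end_atoms)
    if end is None:
        log.warning("residue %s: missing pseudo-atom atoms, skipped", r.ident)
        return []
    if mode is PseudoAtomMode.SINGLE:
        return [PseudoAtomNode(r, KeyRole.KEY_SINGLE, end, r.name)]
    start = _centroid(r, entry.start_atoms)
    if start is None:
        log.warning("residue %s: missing pseudo-atom atoms, skipped", r.ident)
        return []
    if entry.coincident:
        end = start
    return [
        PseudoAtomNode(r, KeyRole.KEY_START, start, r.name),
        PseudoAtomNode(r, KeyRole.KEY_END, end, r.name),
    ]


def build_sidechain_pseudoatoms(
    r: Residue,
    mode: PseudoAtomMode = PseudoAtomMode.PAIR,
    table: dict[str, PseudoAtomEntry] | None = None,
) -> list[PseudoAtomNode]:
    """Pseudo-atom node(s) for one amino-acid residue.

    PAIR mode yields the Key Start / Key End pair (coincident for Gly/Ala);
    SINGLE mode yields one Key at the functional-tip centroid.  Residues
    missing required atoms are skipped with a warning (empty list).
    """
    if r.kind is not ResidueKind.AMINO:
        log.warning("residue %s is not a standard amino acid, skipped", r.ident)
        return []
    entry = (table or DEFAULT_PSEUDO_ATOM_TABLE).get(r.name)
    if entry is None:
        log.warning("residue %s: no pseudo-atom table entry, skipped", r.ident)
        return []
    return _build_nodes(r, entry, mode)


def build_base_pseudoatoms(
    r: Residue,
    mode: PseudoAtomMode = PseudoAtomMode.PAIR,
    table: dict[str, PseudoAtomEntry] | None = None,
) -> list[PseudoAtomNode]:
    """Pseudo-atom node(s) for one RNA base (see :data:`DEFAULT_BASE_TABLE`)."""
    if r.kind is not ResidueKind.BASE:
        log.warning("residue %s is not an RNA base, skipped", r.ident)
        return []
    entry = (table or DEFAULT_BASE_TABLE).get(r.name)
    if entry is None:
        log.warning("residue %s: no base table entry, skipped", r.ident)
        return []
    return _build_nodes(r, entry, mode)


def structure_pseudoatoms(
    s: Structure,
    kind: ResidueKind,
    mode: PseudoAtomMode = PseudoAtomMode.PAIR,
) -> list[PseudoAtomNode]:
    """All pseudo-atoms of one kind for a structure, residue order preserved."""
    build = (
        build_sidechain_pseudoatoms
        if kind is ResidueKind.AMINO
        else build_base_pseudoatoms
    )
    nodes: list[PseudoAtomNode] = []
    for r in s.residues:
        if r.kind is kind:
            nodes.extend(build(r, mode))
    return nodes


def detect_hydrogen_bonds(
    s: Structure,
    max_da_distance: float = 3.4,
    min_da_distance: float = 2.4,
) -> list[HBond]:
    """Distance-window hydrogen-bond detection between base heavy atoms.

    A bond is recorded for every donor-atom/acceptor-atom pair of two
    distinct bases whose distance lies in ``[min_da_distance,
    max_da_distance]``.  Explicit hydrogens and angular terms are not used;
    the window is the documented geometric criterion and both ends are
    configurable.
    """
    bases = [r for r in s.residues if r.kind is ResidueKind.BASE]
    bonds: list[HBond] = []
    for r1 in bases:
        donors = [(n, r1.atom(n)) for n in BASE_DONORS.get(r1.name, ())]
        for r2 in bases:
            if r1 is r2:
                continue
            acceptors = [(n, r2.atom(n)) for n in BASE_ACCEPTORS.get(r2.name, ())]
            for dn, da in donors:
                if da is None:
                    continue
                for an, aa in acceptors:
                    if aa is None:
                        continue
                    d = float(np.linalg.norm(da.pos - aa.pos))
                    if min_da_distance <= d <= max_da_distance:
                        bonds.append(HBond(r1, r2, dn, an, d))
    return bonds


def build_connection_table(s: Structure, bonds: list[HBond]) -> ConnectionTable:
    """Aggregate hydrogen bonds into a per-base-pair connection table.

    Bases without any bond are kept as isolated nodes.  A bond referring to
    a residue that is not part of ``s`` raises ``ValueError``.
    """
    bases = [r for r in s.residues if r.kind is ResidueKind.BASE]
    index = {id(r): i for i, r in enumerate(bases)}
    table = ConnectionTable(bases=bases)
    for b in bonds:
        try:
            i = index[id(b.donor_residue)]
            j = index[id(b.acceptor_residue)]
        except KeyError as exc:
            raise ValueError(
                "hydrogen bond references a residue absent from the structure"
            ) from exc
        key = (min(i, j), max(i, j))
        table.edges[key] = table.edges.get(key, 0) + 1
    return table


# ---------------------------------------------------------------------------
# plain-text configuration

def parse_pseudo_atom_config(text: str) -> dict[str, PseudoAtomEntry]:
    """Parse a pseudo-atom table from plain text.

    One record per line::

        RES START atom [atom ...]
        RES END atom [atom ...]
        RES COINCIDENT

    Lines starting with ``#`` and blank lines are ignored.
    """
    starts: dict[str, tuple[str, ...]] = {}
    ends: dict[str, tuple[str, ...]] = {}
    coincident: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: malformed record {raw!r}")
        res, role, atoms = parts[0].upper(), parts[1].upper(), tuple(parts[2:])
        if role == "COINCIDENT":
            coincident.add(res)
        elif role == "START":
            if not atoms:
                raise ValueError(f"line {lineno}: empty atom list")
            starts[res] = atoms
        elif role == "END":
            if not atoms:
                raise ValueError(f"line {lineno}: empty atom list")
            ends[res] = atoms
        else:
            raise ValueError(f"line {lineno}: unknown role {role!r}")
    table = {}
    for res in sorted(set(starts) | set(ends) | coincident):
        if res not in starts or res not in ends:
            raise ValueError(f"residue {res}: both START and END atom lists required")
        table[res] = PseudoAtomEntry(starts[res], ends[res], res in coincident)
    return table


def pair_key_distances(
    table: dict[str, PseudoAtomEntry], residues: list[Residue]
) -> dict[str, float]:
    """Observed Key Start -> Key End distance per residue name (first seen)."""
    out: dict[str, float] = {}
    for r in residues:
        if r.name in out:
            continue
        entry = table.get(r.name)
        if entry is None:
            continue
        start = _centroid(r, entry.start_atoms)
        end = start if entry.coincident else _centroid(r, entry.end_atoms)
        if start is not None and end is not None:
            out[r.name] = float(np.linalg.norm(end - start))
    return out
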
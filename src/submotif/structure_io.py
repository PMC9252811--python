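"""Reading and writing of structure coordinate files.

PDB and mmCIF files are parsed (via gemmi) into a small uniform model —
:class:`Structure` holding chains of :class:`Residue` objects — that the
search engines consume.  Only the first model of multi-model files is kept,
alternate locations are collapsed to the highest-occupancy conformer, and
waters are dropped from the heteroatom inventory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
RNA_BASES = frozenset({"A", "C", "G", "U"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class ResidueKind(Enum):
    AMINO = "AMINO"
    BASE = "BASE"
    OTHER = "OTHER"


class StructureError(Exception):
    """Raised when a coordinate file cannot be turned into a usable model."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) in Angstrom
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def kind(self) -> ResidueKind:
        if self.name in STANDARD_AMINO_ACIDS:
            return ResidueKind.AMINO
        if self.name in RNA_BASES:
            return ResidueKind.BASE
        return ResidueKind.OTHER

    @property
    def ident(self) -> str:
        """Author identifier ``chain:seqnum[icode]:name``."""
        ic = self.icode.strip()
        return f"{self.chain_id}:{self.seq_num}{ic}:{self.name}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_positions(self, names: Iterable[str]) -> np.ndarray | None:
        """Positions of the named atoms, or None if any is missing."""
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            out.append(a.pos)
        return np.array(out)


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    het_atoms: list[Atom] = field(default_factory=list)
    resolution: float | None = None
    source_format: str = "PDB"
    assembly_id: str | None = None

    def key(self, r: Residue) -> tuple[str, int, str]:
        return (r.chain_id, r.seq_num, r.icode)


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc 'A' first."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        else:
            # higher occupancy wins; on ties the alphabetically first altloc
            if (a.occupancy, prev.altloc or "~") > (prev.occupancy, a.altloc or "~"):
                by_name[a.name] = a
    return list(by_name.values())


def _mmcif_resolution(path: Path) -> float | None:
    """Resolution from refine/reflns items that bare coordinate files carry."""
    try:
        block = gemmi.cif.read(str(path)).sole_block()
    except (RuntimeError, ValueError):
        return None
    for item in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
        val = block.find_value(item)
        if val and val not in (".", "?"):
            try:
                return float(val)
            except ValueError:
                continue
    return None


def load_structure(path: str | Path) -> Structure:
    """Load a PDB or mmCIF file into a :class:`Structure`.

    Policies: first model only; alternate locations collapsed to the
    highest-occupancy atom (ties -> altloc 'A'); waters excluded from the
    heteroatom list and not retained elsewhere.

    Raises
    ------
    StructureError
        If the file cannot be parsed or contains no polymer residues.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models present")
    fmt = "MMCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = st[0]

    residues: list[Residue] = []
    het_atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_NAMES or res.is_water()
            is_het = res.het_flag == "H"
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    altloc=a.altloc if a.altloc else "",
                    occupancy=a.occ,
                    is_hetero=is_het,
                )
                for a in res
            ]
            atoms = _collapse_altlocs(atoms)
            r = Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip() if res.seqid.icode else "",
                name=res.name.strip(),
                atoms=atoms,
            )
            if is_water:
                continue
            if is_het and r.kind is ResidueKind.OTHER:
                het_atoms.extend(atoms)
            else:
                residues.append(r)

    if not any(r.kind in (ResidueKind.AMINO, ResidueKind.BASE) for r in residues):
        raise StructureError(f"{path}: no polymer residues found")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if resolution is None and fmt == "MMCIF":
        resolution = _mmcif_resolution(path)
    return Structure(
        id=st.name.strip() or path.stem,
        residues=residues,
        het_atoms=het_atoms,
        resolution=resolution,
        source_format=fmt,
    )


def select_residues(s: Structure, kind: ResidueKind) -> list[Residue]:
    """Residues of the requested kind in stable chain-then-sequence order."""
    picked = [r for r in s.residues if r.kind is kind]
    picked.sort(key=lambda r: (r.chain_id, r.seq_num, r.icode))
    return picked


def list_het_neighbors(
    s: Structure, positions: Sequence[np.ndarray], cutoff: float = 4.0
) -> bool:
    """True iff any position lies within ``cutoff`` of a non-water heteroatom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not s.het_atoms or len(positions) == 0:
        return False
    tree = cKDTree(np.array([a.pos for a in s.het_atoms]))
    dists, _ = tree.query(np.asarray(positions, dtype=float), k=1)
    return bool(np.min(dists) <= cutoff)


# ---------------------------------------------------------------------------
# writing

def to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in s.residues:
        chain = chains.get(r.chain_id)
        if chain is None:
            chain = gemmi.Chain(r.chain_id)
            chains[r.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = r.name
        gres.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
        gres.het_flag = "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)
    if s.het_atoms:
        het_chain = gemmi.Chain("Z")
        gres = gemmi.Residue()
        gres.name = "LIG"
        gres.seqid = gemmi.SeqId(1, " ")
        gres.het_flag = "H"
        for a in s.het_atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            gres.add_atom(ga)
        het_chain.add_residue(gres)
        chains["Z"] = het_chain
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path) -> None:
    """Write as PDB (``.pdb``) or mmCIF (``.cif``), chosen by extension."""
    path = Path(path)
    st = to_gemmi(s)
    if path.suffix.lower() in (".cif", ".mmcif"):
        doc = st.make_mmcif_document()
        if s.resolution is not None:
            # gemmi does not emit refine metadata for bare coordinates
            doc.sole_block().set_pair("_refine.ls_d_res_high", f"{s.resolution:.2f}")
        doc.write_file(str(path))
    else:
        st.write_pdb(str(path))
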
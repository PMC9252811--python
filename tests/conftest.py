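import numpy as np
import pytest
from hypothesis import settings

from submotif.representation import ConnectionTable
from submotif.structure_io import Atom, Residue, Structure

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_residue(name, atoms, chain="A", seq=1, icode=""):
    """Residue from a {atom_name: (x, y, z)} dict."""
    return Residue(
        chain_id=chain,
        seq_num=seq,
        icode=icode,
        name=name,
        atoms=[
            Atom(name=n, element=n[0], pos=np.asarray(p, dtype=float))
            for n, p in atoms.items()
        ],
    )


def make_connection_table(labels, edges):
    """ConnectionTable from base labels and {(i, j): bond_count} edges."""
    bases = [
        Residue(chain_id="R", seq_num=i + 1, icode="", name=lab, atoms=[])
        for i, lab in enumerate(labels)
    ]
    return ConnectionTable(
        bases=bases,
        edges={(min(i, j), max(i, j)): c for (i, j), c in edges.items()},
    )


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def transform_structure(s: Structure, rot, shift) -> Structure:
    """Rigidly transformed deep copy of a structure."""
    out = Structure(
        id=s.id, resolution=s.resolution, source_format=s.source_format
    )
    for r in s.residues:
        out.residues.append(
            Residue(
                chain_id=r.chain_id,
                seq_num=r.seq_num,
                icode=r.icode,
                name=r.name,
                atoms=[
                    Atom(a.name, a.element, rot @ a.pos + shift, a.altloc, a.occupancy, a.is_hetero)
                    for a in r.atoms
                ],
            )
        )
    out.het_atoms = [
        Atom(a.name, a.element, rot @ a.pos + shift, a.altloc, a.occupancy, a.is_hetero)
        for a in s.het_atoms
    ]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
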
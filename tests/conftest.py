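import numpy as np
import pytest

from protdepth import make_fixture
from protdepth.params import default_parameters
from protdepth.structures import Residue, Structure, make_atom


def pdb_atom_line(serial, name, res, chain, resseq, x, y, z, element,
                  altloc=" ", icode=" ", occ=1.0, b=0.0):
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {nm:<4s}{altloc}{res:<3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{b:6.2f}          {element:>2s}")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Hand-written 3-residue PDB file (GLY-ALA-SER backbone + CB/OG)."""
    lines = []
    serial = 0
    residues = [("GLY", ["N", "CA", "C", "O"]),
                ("ALA", ["N", "CA", "C", "O", "CB"]),
                ("SER", ["N", "CA", "C", "O", "CB", "OG"])]
    for i, (res, names) in enumerate(residues):
        for j, name in enumerate(names):
            serial += 1
            lines.append(pdb_atom_line(serial, name, res, "A", i + 1,
                                       3.8 * i + 0.3 * j, 1.1 * j, 0.5 * i,
                                       name[0]))
    lines.append("END")
    path = tmp_path / "tri.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def micro_structure(atom_specs):
    """Structure from [(chain, resseq, res_type, [(name, element, xyz)...])]."""
    pset = default_parameters()
    st = Structure(id="micro")
    serial = 0
    for ridx, (chain, resseq, res_type, atoms) in enumerate(atom_specs):
        res = Residue(chain, resseq, "", res_type)
        for name, element, xyz in atoms:
            serial += 1
            res.atoms.append(make_atom(serial, name, element, ridx, chain,
                                       np.asarray(xyz, float), res_type,
                                       pset))
        st.add_residue(res)
    return st


@pytest.fixture(scope="session")
def carved_sphere():
    """Solid 2.8 Å lattice cube with a carved r = 4 Å central sphere."""
    return make_fixture("lattice_with_cavity",
                        {"extent": 19.6, "cavity_radius": 4.0})


@pytest.fixture(scope="session")
def solid_ball():
    """Solid lattice ball of radius 12 Å, no cavity."""
    return make_fixture("lattice_with_cavity",
                        {"extent": 26.0, "ball_radius": 12.0,
                         "cavity_shape": "none"})
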
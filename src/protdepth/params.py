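"""Packaged parameter tables: van der Waals radii, partial charges,
polar side-chain atoms, hydrogen-bond donors/acceptors and side-chain
reference accessible surface areas.

All tables ship as tab-delimited files under ``protdepth/data`` and can be
replaced by user-supplied files of the same layout.  Charges are a minimal,
condensed heavy-atom set: hydrogens are not modelled explicitly, so the
formal charge of each ionizable group (carboxylate -1, ammonium +1,
guanidinium +1, doubly protonated imidazole +1) is distributed over its
heavy atoms.  Backbone amide/carbonyl dipoles carry compensating charges
that sum to zero per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Heavy-atom side-chain topology (beyond N, CA, C, O) for the 20 standard
#: residue types, in a canonical order.
SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
            "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

#: Heavy atoms of the ionizable group used for hydrogen-bond counting and
#: electrostatics.  Acids are deprotonated, LYS is protonated, HIS is
#: doubly protonated (+1).
IONIZABLE_GROUP_ATOMS = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
    "LYS": ["NZ"],
}

DEFAULT_RADIUS = 1.70  # fallback for elements absent from the table


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("protdepth.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class ParameterSet:
    """Atom-level parameters shared by the depth, cavity, ASA and pKa code.

    Attributes
    ----------
    radii_by_element : dict
        van der Waals radius per element symbol, Å.
    charges_by_residue_atom : dict
        (res_type, atom_name) -> partial charge (e).  Entries keyed with
        res_type ``"*"`` apply to every residue type (backbone atoms).
    polar_sidechain_atoms : set
        (res_type, atom_name) pairs of polar side-chain atoms.
    donors_acceptors : dict
        (res_type, atom_name) -> (role, antecedent) with role in
        {"D", "A", "DA"}; ``"*"`` wildcard as above.
    sidechain_ref_asa : dict
        res_type -> reference side-chain ASA of the fully exposed residue, Å².
    """

    radii_by_element: dict = field(default_factory=dict)
    charges_by_residue_atom: dict = field(default_factory=dict)
    polar_sidechain_atoms: set = field(default_factory=set)
    donors_acceptors: dict = field(default_factory=dict)
    sidechain_ref_asa: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ParameterSet":
        radii = dict(zip(*(lambda df: (df["element"], df["radius"]))(
            _read_table("vdw_radii.tsv"))))
        charges = {
            (r.res_type, r.atom): float(r.charge)
            for r in _read_table("partial_charges.tsv").itertuples()
        }
        polar = {
            (r.res_type, r.atom)
            for r in _read_table("polar_sidechain.tsv").itertuples()
        }
        donacc = {
            (r.res_type, r.atom): (r.role, r.antecedent)
            for r in _read_table("donors_acceptors.tsv").itertuples()
        }
        ref_asa = {
            r.res_type: float(r.ref_asa)
            for r in _read_table("sidechain_ref_asa.tsv").itertuples()
        }
        return cls(radii, charges, polar, donacc, ref_asa)

    def radius(self, element: str) -> float:
        return float(self.radii_by_element.get(element.upper(),
                                               DEFAULT_RADIUS))

    def charge(self, res_type: str, atom_name: str) -> float:
        key = (res_type, atom_name)
        if key in self.charges_by_residue_atom:
            return self.charges_by_residue_atom[key]
        return self.charges_by_residue_atom.get(("*", atom_name), 0.0)

    def is_polar_sidechain(self, res_type: str, atom_name: str) -> bool:
        return (res_type, atom_name) in self.polar_sidechain_atoms

    def donor_acceptor(self, res_type: str, atom_name: str):
        """Return (role, antecedent) or None for a non-participating atom."""
        key = (res_type, atom_name)
        if key in self.donors_acceptors:
            return self.donors_acceptors[key]
        return self.donors_acceptors.get(("*", atom_name))


_DEFAULT: ParameterSet | None = None


def default_parameters() -> ParameterSet:
    """Cached default :class:`ParameterSet`."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ParameterSet.default()
    return _DEFAULT
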
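"""Molecular data model and PDB input/output.

The in-memory model is deliberately small: a :class:`Structure` is an
ordered collection of chains of :class:`Residue` objects, each holding
:class:`Atom` records with coordinates (Å), a van der Waals radius and a
partial charge taken from the packaged :class:`~protdepth.params.ParameterSet`.
Parsing is delegated to gemmi; waters and other heteroatoms are kept in a
side list and never enter the protein model, because the solvation engine
generates its own solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .params import (BACKBONE_ATOMS, SIDECHAIN_ATOMS, STANDARD_RESIDUES,
                     ParameterSet, default_parameters)


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no usable ATOM records."""


class UnsupportedMutationError(ValueError):
    """Raised by :func:`truncate_to_ala` for residues without a CB atom."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    chain_id: str
    coords: np.ndarray
    radius: float
    partial_charge: float
    is_backbone: bool
    is_polar_sidechain: bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    atoms: list = field(default_factory=list)

    @property
    def key(self):
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_type in STANDARD_RESIDUES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def backbone_atoms(self):
        return [a for a in self.atoms if a.is_backbone]

    def sidechain_atoms(self):
        return [a for a in self.atoms if not a.is_backbone]


@dataclass
class Structure:
    """Protein model: ordered chains of residues plus a HETATM side list."""

    id: str = ""
    chains: dict = field(default_factory=dict)  # chain_id -> list[Residue]
    het_atoms: list = field(default_factory=list)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coords for a in self.atoms()
               if not (heavy_only and a.element == "H")]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def heavy_atoms(self):
        return [a for a in self.atoms() if a.element != "H"]

    def residue(self, chain_id: str, seq_number: int,
                insertion_code: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number and \
                    res.insertion_code == insertion_code:
                return res
        raise KeyError((chain_id, seq_number, insertion_code))

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def residue_list(self):
        return list(self.residues())


def _element_of(gatom: gemmi.Atom) -> str:
    el = gatom.element.name.upper()
    return el if el else "C"


def make_atom(serial, name, element, residue_index, chain_id, coords,
              res_type, params: ParameterSet) -> Atom:
    """Build an Atom with radius/charge/typing from the parameter set."""
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_index=residue_index,
        chain_id=chain_id,
        coords=np.asarray(coords, dtype=float),
        radius=params.radius(element),
        partial_charge=params.charge(res_type, name),
        is_backbone=name in BACKBONE_ATOMS,
        is_polar_sidechain=params.is_polar_sidechain(res_type, name),
    )


def read_pdb(path, model_policy: str = "first",
             params: ParameterSet | None = None,
             skip_nonstandard: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Waters and HETATM records are excluded from the protein model but kept
    in ``Structure.het_atoms``.  Alternate locations are resolved by keeping
    the first-listed conformer.  ``model_policy`` selects behaviour for
    multi-model files: ``"first"`` keeps model 1, ``"error"`` raises.
    Non-standard residues are skipped with a warning by default.
    """
    params = params or default_parameters()
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps the first-listed conformer
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if len(st) > 1 and model_policy == "error":
        raise ValueError(f"{path} contains {len(st)} models")
    model = st[0]

    out = Structure(id=st.name or "structure")
    serial = 0
    residue_index = 0
    for chain in model:
        for gres in chain:
            is_water = gres.is_water()
            res_type = gres.name.upper()
            het = gres.het_flag == "H" or is_water
            nonstandard = not het and res_type not in STANDARD_RESIDUES
            if het or (nonstandard and skip_nonstandard):
                if nonstandard:
                    warnings.warn(
                        f"skipping non-standard residue {res_type} "
                        f"{chain.name}{gres.seqid.num}")
                for ga in gres:
                    serial += 1
                    out.het_atoms.append(make_atom(
                        serial, ga.name, _element_of(ga), -1, chain.name,
                        [ga.pos.x, ga.pos.y, ga.pos.z], res_type, params))
                continue
            res = Residue(
                chain_id=chain.name,
                seq_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_type=res_type,
            )
            for ga in gres:
                serial += 1
                res.atoms.append(make_atom(
                    serial, ga.name, _element_of(ga), residue_index,
                    chain.name, [ga.pos.x, ga.pos.y, ga.pos.z],
                    res_type, params))
            residue_index += 1
            out.add_residue(res)
    if out.n_atoms() == 0:
        raise EmptyStructureError(f"no ATOM records in {path}")
    return out


def write_pdb(structure: Structure, path, per_atom_values=None) -> None:
    """Write a Structure as PDB text.

    ``per_atom_values`` is an optional mapping ``id(atom) -> value`` or a
    sequence aligned with ``structure.atoms()``; values land in the
    B-factor column with two decimals (field range 0-999.99).
    """
    values = None
    if per_atom_values is not None:
        if isinstance(per_atom_values, dict):
            values = [per_atom_values[id(a)] for a in structure.atoms()]
        else:
            values = list(per_atom_values)
        for v in values:
            if not -9.99 <= v <= 999.99:
                raise ValueError(
                    f"B-factor value {v} does not fit the PDB field")
    lines = []
    serial = 0
    i = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for a in res.atoms:
                serial += 1
                b = values[i] if values is not None else 0.0
                i += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{res.res_type:>4s} "
                    f"{chain_id[:1]:1s}{res.seq_number:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{1.00:6.2f}{b:6.2f}          "
                    f"{a.element:>2s}")
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def truncate_to_ala(structure: Structure, chain_id: str, seq_number: int,
                    insertion_code: str = "") -> Structure:
    """Mutate one residue to alanine by deleting side-chain atoms past CB.

    Returns a new Structure; every other residue is untouched (atom objects
    are shared, not copied).  No geometry minimisation is performed.  GLY
    targets are rejected because they lack a CB atom.
    """
    target = structure.residue(chain_id, seq_number, insertion_code)
    if target.atom("CB") is None:
        raise UnsupportedMutationError(
            f"residue {target.res_type} {chain_id}{seq_number} has no CB")
    keep = {"N", "CA", "C", "O", "CB", "OXT"}
    out = Structure(id=structure.id, het_atoms=list(structure.het_atoms))
    for cid, residues in structure.chains.items():
        for res in residues:
            if res.key == target.key:
                atoms = [replace(a) for a in res.atoms if a.name in keep]
                out.add_residue(Residue(cid, res.seq_number,
                                        res.insertion_code, "ALA", atoms))
            else:
                out.add_residue(res)
    return out
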
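"""Synthetic structure generator for testing and validation.

Four fixture families are produced, each with an analytic ground-truth
record:

``lattice_with_cavity``
    a solid cubic lattice of carbon pseudo-atoms with an optional carved
    spherical or cuboid void of known analytic volume;
``water_box``
    a box of water oxygens at the solvation-lattice density;
``peptide``
    an idealized extended peptide chain with full heavy-atom side chains,
    hydrogen-bond donors/acceptors and charged groups;
``single_atom``
    one isolated atom.

Geometry of the peptide fixture is schematic (bond lengths ~1.5 Å,
extended chain): it exercises topology-dependent code (H-bond typing,
charge assignment, ASA references), not real stereochemistry.
"""

from __future__ import annotations

import numpy as np

from .params import IONIZABLE_GROUP_ATOMS, SIDECHAIN_ATOMS, default_parameters
from .structures import Residue, Structure, make_atom


def _lattice_points(extent: float, spacing: float) -> np.ndarray:
    """Cubic lattice centred on the origin covering [-extent/2, extent/2]."""
    n = int(np.floor(extent / (2 * spacing)))
    axis = np.arange(-n, n + 1) * spacing
    return np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                    axis=-1).reshape(-1, 3)


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a synthetic Structure plus its ground-truth record.

    Deterministic for a fixed seed.  Returns ``(structure, truth)`` where
    ``truth`` is a dict whose content depends on ``kind`` (see module
    docstring).
    """
    params = dict(params or {})
    if kind == "lattice_with_cavity":
        return _lattice_with_cavity(params)
    if kind == "water_box":
        return _water_box(params)
    if kind == "peptide":
        return _peptide(params)
    if kind == "single_atom":
        return _single_atom(params)
    raise ValueError(f"unknown fixture kind: {kind}")


def _add_pseudo_residues(structure: Structure, coords: np.ndarray,
                         element: str = "C", res_type: str = "UNK",
                         atom_name: str = "C", chain_id: str = "A"):
    pset = default_parameters()
    for i, xyz in enumerate(coords):
        res = Residue(chain_id, i + 1, "", res_type)
        res.atoms.append(make_atom(i + 1, atom_name, element, i, chain_id,
                                   xyz, res_type, pset))
        structure.add_residue(res)


def _lattice_with_cavity(params: dict):
    spacing = float(params.get("spacing", 2.8))
    extent = float(params.get("extent", 6 * 2.8))
    shape = params.get("cavity_shape", "sphere")
    centre = np.asarray(params.get("cavity_centre", (0.0, 0.0, 0.0)))
    element = params.get("element", "C")

    pts = _lattice_points(extent, spacing)
    ball_radius = params.get("ball_radius")
    if ball_radius is not None:      # solid ball instead of a solid cube
        pts = pts[np.linalg.norm(pts, axis=1) <= float(ball_radius)]
    if shape == "none":
        removed = np.zeros(len(pts), dtype=bool)
        volume = 0.0
    elif shape == "sphere":
        radius = float(params.get("cavity_radius", 4.0))
        if 2 * radius >= extent:
            raise ValueError("cavity does not fit inside the lattice")
        removed = np.linalg.norm(pts - centre, axis=1) < radius
        volume = 4.0 / 3.0 * np.pi * radius ** 3
    elif shape == "cuboid":
        dims = np.asarray(params.get("cavity_dims", (4.0, 4.0, 4.0)))
        if np.any(dims >= extent):
            raise ValueError("cavity does not fit inside the lattice")
        removed = np.all(np.abs(pts - centre) < dims / 2.0, axis=1)
        volume = float(np.prod(dims))
    else:
        raise ValueError(f"unknown cavity shape: {shape}")

    st = Structure(id=f"lattice_{shape}")
    _add_pseudo_residues(st, pts[~removed], element=element)
    truth = {
        "cavity_volume": volume,
        "cavity_centre": centre,
        "removed_sites": pts[removed],
        "n_sites": int((~removed).sum()),
        "spacing": spacing,
        "ball_radius": ball_radius,
        "material_volume": float((~removed).sum()) * spacing ** 3,
    }
    return st, truth


def _water_box(params: dict):
    edge = float(params.get("edge", 20.0))
    spacing = float(params.get("spacing", 3.1))
    pts = _lattice_points(edge, spacing)
    pset = default_parameters()
    st = Structure(id="water_box")
    for i, xyz in enumerate(pts):
        res = Residue("W", i + 1, "", "HOH")
        res.atoms.append(make_atom(i + 1, "O", "O", i, "W", xyz, "HOH",
                                   pset))
        st.add_residue(res)
    return st, {"n_waters": len(pts), "spacing": spacing, "edge": edge}


#: Schematic local offsets (Å) of backbone atoms relative to CA.
_BACKBONE_OFFSETS = {
    "N": (-1.2, 0.7, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.3, 0.7, 0.0),
    "O": (1.3, 1.95, 0.0),
}


def _sidechain_coords(res_type: str, ca: np.ndarray, flip: int):
    """Grow side-chain heavy atoms away from the backbone in a zig-zag."""
    names = SIDECHAIN_ATOMS[res_type]
    coords = {}
    direction = np.array([0.0, -1.0 * flip, 1.0])
    direction /= np.linalg.norm(direction)
    side = np.array([1.0, 0.0, 0.0])
    pos = ca.copy()
    for i, name in enumerate(names):
        step = 1.5 * direction + 0.55 * ((-1) ** i) * side
        step *= 1.5 / np.linalg.norm(step)
        pos = pos + step
        coords[name] = pos.copy()
    return coords


def _peptide(params: dict):
    sequence = params.get("sequence", ["ALA", "ASP", "LYS", "GLY"])
    chain_id = params.get("chain_id", "A")
    spacing = float(params.get("ca_spacing", 3.8))
    pset = default_parameters()
    st = Structure(id="peptide")
    donors, acceptors, charges = [], [], []
    serial = 0
    for i, res_type in enumerate(sequence):
        res = Residue(chain_id, i + 1, "", res_type)
        ca = np.array([i * spacing, 0.0, 0.0])
        placed = {n: ca + np.asarray(off)
                  for n, off in _BACKBONE_OFFSETS.items()}
        placed.update(_sidechain_coords(res_type, ca, flip=(-1) ** i))
        for name, xyz in placed.items():
            serial += 1
            element = name[0] if name[0] in "CNOS" else "C"
            atom = make_atom(serial, name, element, i, chain_id, xyz,
                             res_type, pset)
            res.atoms.append(atom)
            da = pset.donor_acceptor(res_type, name)
            if da is not None:
                if "D" in da[0]:
                    donors.append((res.key, name))
                if "A" in da[0]:
                    acceptors.append((res.key, name))
            if atom.partial_charge != 0.0:
                charges.append((res.key, name, atom.partial_charge))
        st.add_residue(res)
    truth = {"donors": donors, "acceptors": acceptors, "charges": charges,
             "sequence": list(sequence),
             "group_atoms": {
                 res.key: IONIZABLE_GROUP_ATOMS[res.res_type]
                 for res in st.residues()
                 if res.res_type in IONIZABLE_GROUP_ATOMS}}
    return st, truth


def _single_atom(params: dict):
    element = params.get("element", "C")
    st = Structure(id="single_atom")
    _add_pseudo_residues(st, np.zeros((1, 3)), element=element)
    return st, {"element": element}
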
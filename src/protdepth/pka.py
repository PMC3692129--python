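"""Empirical pKa prediction for ASP, GLU, HIS and LYS residues.

The predicted pKa is the model (free amino acid) pKa shifted by a linear
combination of five environment features:

    pKa = pKa_model + c0 + c1*DEPTH_MC + c2*DEPTH_polarSC + c3*HB
          + c4*EE + c5*ASA_SC

where DEPTH_MC is the mean depth of main-chain atoms (Å), DEPTH_polarSC
the mean depth of polar side-chain atoms (Å), HB the number of hydrogen
bonds made by the ionizable group (heavy-atom geometry: donor-acceptor
distance <= 3.5 Å and donor-acceptor-antecedent angle >= 100 deg), EE the
vacuum Coulomb interaction energy between the group and its environment
truncated at 12 Å (kcal/mol) and ASA_SC the side-chain accessible surface
fraction in [0, 1].  Coefficients are packaged per residue type and can
be refit with :func:`fit_coefficients`.

Hydrogens are not modelled: hydrogen bonds use heavy-atom geometry and
group charges are condensed onto heavy atoms summing to the formal
charge.  The shipped coefficients assume this convention; refit when
using a different one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import (IONIZABLE_GROUP_ATOMS, ParameterSet, _read_table,
                     default_parameters)
from .solvation import DepthResult
from .structures import Residue, Structure

COULOMB_K = 332.06  # kcal Å / (mol e^2)
FEATURE_NAMES = ("depth_mc", "depth_polar_sc", "hb", "ee", "asa_sc")


@dataclass
class PkaFeatures:
    depth_mc: float
    depth_polar_sc: float
    hb: int
    ee: float
    asa_sc: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.depth_mc, self.depth_polar_sc, self.hb,
                         self.ee, self.asa_sc], dtype=float)


@dataclass
class PkaModel:
    """Per-residue-type model pKa and linear coefficients c0..c5."""

    model_pka: dict
    coefficients: dict   # res_type -> (c0, c1, c2, c3, c4, c5)
    include_model_pka: bool = True

    @classmethod
    def default(cls) -> "PkaModel":
        df = _read_table("pka_coefficients.tsv")
        model_pka = {r.res_type: float(r.model_pka) for r in df.itertuples()}
        coeff = {r.res_type: tuple(float(getattr(r, f"c{i}"))
                                   for i in range(6))
                 for r in df.itertuples()}
        return cls(model_pka=model_pka, coefficients=coeff)

    @property
    def residue_types(self):
        return sorted(self.coefficients)


def detect_hbonds(structure: Structure, group_atoms: list,
                  params: ParameterSet | None = None,
                  max_distance: float = 3.5,
                  min_angle: float = 100.0) -> int:
    """Count hydrogen bonds involving the given ionizable-group atoms.

    A donor-acceptor pair (the group atom on either side) bonds when the
    heavy-atom distance is at most ``max_distance`` and the
    donor-acceptor-antecedent angle is at least ``min_angle`` degrees.
    Pairs within the same residue are excluded; each pair counts once.
    An acceptor without its antecedent atom is skipped with a warning.
    """
    params = params or default_parameters()
    group_ids = {id(a) for a in group_atoms}
    group_res = {a.residue_index for a in group_atoms}

    donors, acceptors = [], []
    antecedent_of = {}
    for res in structure.residues():
        for atom in res.atoms:
            da = params.donor_acceptor(res.res_type, atom.name)
            if da is None:
                continue
            role, ante = da
            if "D" in role:
                donors.append(atom)
            if "A" in role:
                acceptors.append(atom)
                antecedent_of[id(atom)] = res.atom(ante)

    def angle(p, q, r):
        v1, v2 = p - q, r - q
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))

    n = 0
    seen = set()
    for d in donors:
        for a in acceptors:
            if id(d) == id(a):
                continue
            involved = id(d) in group_ids or id(a) in group_ids
            if not involved:
                continue
            if d.residue_index == a.residue_index and \
                    d.residue_index in group_res:
                continue
            pair = (id(d), id(a))
            if pair in seen:
                continue
            seen.add(pair)
            if np.linalg.norm(d.coords - a.coords) > max_distance:
                continue
            ante = antecedent_of.get(id(a))
            if ante is None:
                warnings.warn(
                    f"acceptor {a.name} lacks antecedent; pair skipped")
                continue
            if angle(d.coords, a.coords, ante.coords) >= min_angle:
                n += 1
    return n


def electrostatic_energy(structure: Structure, group_atoms: list,
                         cutoff: float = 12.0) -> float:
    """Vacuum Coulomb energy (kcal/mol) between the group and its
    environment, truncated at ``cutoff``; atoms of the group's own
    residue are excluded from the environment."""
    group_res = {a.residue_index for a in group_atoms}
    group_ids = {id(a) for a in group_atoms}
    env = [a for a in structure.atoms()
           if id(a) not in group_ids and a.residue_index not in group_res]
    if not env:
        return 0.0
    epos = np.array([a.coords for a in env])
    eq = np.array([a.partial_charge for a in env])
    ee = 0.0
    for g in group_atoms:
        if g.partial_charge == 0.0:
            continue
        d = np.linalg.norm(epos - g.coords, axis=1)
        mask = (d <= cutoff) & (eq != 0.0)
        ee += COULOMB_K * g.partial_charge * np.sum(eq[mask] / d[mask])
    return float(ee)


def asa_shrake_rupley(structure: Structure, probe: float = 1.4,
                      n_points: int = 960,
                      params: ParameterSet | None = None):
    """Per-atom accessible surface area (Å^2) by sphere-point sampling.

    Points are spread on each heavy atom's solvent-expanded sphere with a
    golden-spiral (Fibonacci) distribution; a point is accessible when it
    lies outside every other atom's expanded sphere.  Returns
    ``(atom_asa, sidechain_fraction)`` where the fraction is the residue's
    side-chain ASA over the packaged fully exposed reference value,
    clipped to [0, 1].
    """
    params = params or default_parameters()
    heavy = structure.heavy_atoms()
    pos = np.array([a.coords for a in heavy])
    rad = np.array([a.radius for a in heavy]) + probe

    i = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    sphere = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z],
                      axis=1)

    tree = cKDTree(pos)
    asa = np.zeros(len(heavy))
    max_rad = rad.max()
    for k in range(len(heavy)):
        pts = pos[k] + rad[k] * sphere
        neigh = [j for j in tree.query_ball_point(pos[k],
                                                  rad[k] + max_rad)
                 if j != k]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            accessible &= d2 > rad[j] ** 2
        asa[k] = accessible.mean() * 4.0 * np.pi * rad[k] ** 2

    sc_fraction = {}
    by_res: dict = {}
    for atom, a in zip(heavy, asa):
        by_res.setdefault(atom.residue_index, []).append((atom, a))
    for res in structure.residues():
        pairs = by_res.get(res.atoms[0].residue_index, [])
        sc = sum(a for atom, a in pairs if not atom.is_backbone)
        ref = params.sidechain_ref_asa.get(res.res_type)
        if not ref:
            sc_fraction[res.key] = 0.0
        else:
            sc_fraction[res.key] = float(np.clip(sc / ref, 0.0, 1.0))
    return asa, sc_fraction


def compute_features(structure: Structure, residue: Residue,
                     depth: DepthResult,
                     asa_fraction: dict | None = None,
                     params: ParameterSet | None = None) -> PkaFeatures:
    """Assemble the five-feature environment vector of one ionizable
    residue.  Residues whose polar side-chain atoms are absent fall back
    to the mean side-chain depth."""
    params = params or default_parameters()
    if residue.res_type not in IONIZABLE_GROUP_ATOMS:
        raise ValueError(
            f"{residue.res_type} is not a supported ionizable type")
    group = [a for a in residue.atoms
             if a.name in IONIZABLE_GROUP_ATOMS[residue.res_type]]
    d_mc = depth.residue_depth("mainchain")[residue.key]
    d_psc = depth.residue_depth("polar_sidechain")[residue.key]
    if np.isnan(d_psc):
        warnings.warn(f"{residue.key}: no polar side-chain atoms; "
                      "using side-chain mean depth")
        d_psc = depth.residue_depth("sidechain")[residue.key]
    if asa_fraction is None:
        _, asa_fraction = asa_shrake_rupley(structure, params=params)
    return PkaFeatures(
        depth_mc=float(d_mc),
        depth_polar_sc=float(d_psc),
        hb=detect_hbonds(structure, group, params),
        ee=electrostatic_energy(structure, group),
        asa_sc=float(asa_fraction[residue.key]),
    )


def predict_pka(features: PkaFeatures, res_type: str,
                model: PkaModel | None = None) -> float:
    """Linear pKa prediction (pH units)."""
    model = model or PkaModel.default()
    c = model.coefficients[res_type]
    base = model.model_pka[res_type] if model.include_model_pka else 0.0
    return float(base + c[0] + np.dot(c[1:], features.as_vector()))


def evaluate_rmsd(predicted, experimental) -> float:
    """Root-mean-square deviation between predictions and experiment."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape or predicted.size == 0:
        raise ValueError("prediction and experiment lengths differ")
    return float(np.sqrt(np.mean((predicted - experimental) ** 2)))


def fit_coefficients(training, model_pka: dict | None = None) -> PkaModel:
    """Least-squares refit of c0..c5 per residue type.

    ``training`` is an iterable of (features, res_type, experimental_pka);
    the shift pKa_exp - pKa_model is regressed on the five features plus
    an intercept.  Rank-deficient designs fall back to a ridge-regularised
    solution with a warning.
    """
    model_pka = model_pka or PkaModel.default().model_pka
    groups: dict = {}
    for feats, res_type, pka in training:
        groups.setdefault(res_type, []).append((feats, pka))
    coeff = {}
    for res_type, rows in groups.items():
        if len(rows) < 7:
            raise ValueError(
                f"need at least 7 examples for {res_type}, got {len(rows)}")
        X = np.array([[1.0, *f.as_vector()] for f, _ in rows])
        y = np.array([pka - model_pka[res_type] for _, pka in rows])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"rank-deficient design for {res_type}; "
                          "using ridge-regularised fit")
            beta = np.linalg.solve(X.T @ X + 1e-8 * np.eye(X.shape[1]),
                                   X.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coeff[res_type] = tuple(float(b) for b in beta)
    return PkaModel(model_pka=dict(model_pka), coefficients=coeff)
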
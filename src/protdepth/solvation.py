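"""Iterative pseudo-solvation and depth computation.

The protein is immersed in a cubic lattice of water-oxygen sites at bulk
water density.  Each solvation iteration applies a fresh uniformly random
rotation to the lattice about the protein centroid (geometrically
equivalent to re-solvating a rotated copy of the protein, but leaving all
waters in the common protein frame).  Waters clashing with protein heavy
atoms are removed.  A water with fewer than ``min_neighbours_bulk`` other
waters within ``neighbour_cutoff`` is non-bulk; non-bulk waters mark
cavities.  The depth of an atom is its distance to the closest bulk water,
averaged over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import Structure


class SolvationError(RuntimeError):
    """No bulk water found; the solvent box is degenerate."""


@dataclass
class SolvationConfig:
    """Parameters of the solvation/depth engine.

    neighbour_cutoff and min_neighbours_bulk implement the bulk rule
    (non-bulk = fewer than 2 waters within 4.2 Å).  The water lattice
    spacing of 3.1 Å reproduces bulk water number density
    (0.0334 molecules/Å^3); clash_cutoff is the closest allowed
    water-oxygen to protein heavy-atom distance.
    """

    neighbour_cutoff: float = 4.2
    min_neighbours_bulk: int = 2
    n_iterations: int = 10
    clash_cutoff: float = 2.6
    box_padding: float = 10.0
    lattice_spacing: float = 3.1
    water_radius: float = 1.4
    seed: int = 0

    def __post_init__(self):
        for name in ("neighbour_cutoff", "clash_cutoff", "box_padding",
                     "lattice_spacing", "water_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class WaterSet:
    """Water-oxygen sites of one solvation iteration (protein frame).

    ``in_box`` flags waters inside the nominal solvent box; waters in a
    boundary ring one neighbour_cutoff wide are carried along so that the
    bulk classification of box-edge waters sees complete neighbourhoods,
    and are discarded by :func:`classify_bulk` afterwards.
    """

    coords: np.ndarray           # (n, 3)
    iteration: int
    is_bulk: np.ndarray | None = None   # (n,) bool, set by classify_bulk
    in_box: np.ndarray | None = None

    def __len__(self):
        return len(self.coords)

    @property
    def bulk_coords(self) -> np.ndarray:
        return self.coords[self.is_bulk]

    @property
    def non_bulk_coords(self) -> np.ndarray:
        return self.coords[~self.is_bulk]


@dataclass
class DepthResult:
    """Atom and residue depths plus the per-iteration water sets."""

    structure: Structure
    atom_depth: np.ndarray               # (n_heavy,) mean over iterations
    per_iteration: np.ndarray            # (n_iter, n_heavy)
    water_sets: list = field(default_factory=list)

    def residue_depth(self, mode: str = "all") -> dict:
        """Aggregate atom depths per residue.

        mode: "all" (mean over heavy atoms, the default residue depth),
        "mainchain", "polar_sidechain", "sidechain" or "min".
        """
        heavy = self.structure.heavy_atoms()
        by_res: dict = {}
        for atom, d in zip(heavy, self.atom_depth):
            by_res.setdefault(atom.residue_index, []).append((atom, d))
        out = {}
        for res in self.structure.residues():
            pairs = by_res.get(res.atoms[0].residue_index, [])
            if mode == "mainchain":
                vals = [d for a, d in pairs if a.is_backbone]
            elif mode == "polar_sidechain":
                vals = [d for a, d in pairs if a.is_polar_sidechain]
            elif mode == "sidechain":
                vals = [d for a, d in pairs if not a.is_backbone]
            else:
                vals = [d for _, d in pairs]
            if mode == "min":
                out[res.key] = float(min(d for _, d in pairs)) if pairs \
                    else np.nan
            else:
                out[res.key] = float(np.mean(vals)) if vals else np.nan
        return out

    def pooled_non_bulk(self):
        """Non-bulk water coordinates and iteration labels, all iterations."""
        coords, iters = [], []
        for ws in self.water_sets:
            nb = ws.non_bulk_coords
            coords.append(nb)
            iters.append(np.full(len(nb), ws.iteration))
        if coords:
            return np.concatenate(coords), np.concatenate(iters)
        return np.zeros((0, 3)), np.zeros(0, dtype=int)


def solvate_once(structure: Structure, config: SolvationConfig,
                 iteration: int) -> WaterSet:
    """Place one randomly oriented water lattice around the protein.

    The lattice is rotated about the protein centroid by a uniform random
    rotation seeded by (config.seed, iteration), then clipped to the
    protein bounding box plus padding, and waters within ``clash_cutoff``
    of any protein heavy atom are discarded.
    """
    pts = structure.coords(heavy_only=True)
    if len(pts) == 0:
        raise ValueError("structure has no heavy atoms")
    centre = pts.mean(axis=0)
    lo = pts.min(axis=0) - config.box_padding
    hi = pts.max(axis=0) + config.box_padding

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, iteration])
    rot = Rotation.random(rng=rng)

    # generate a lattice large enough that its rotation covers the box
    ring = config.neighbour_cutoff
    half = float(np.max(np.maximum(hi - centre, centre - lo))) + ring
    reach = half * np.sqrt(3.0) + config.lattice_spacing
    n = int(np.ceil(reach / config.lattice_spacing))
    axis = np.arange(-n, n + 1) * config.lattice_spacing
    lattice = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                       axis=-1).reshape(-1, 3)
    waters = rot.apply(lattice) + centre
    inside = np.all((waters >= lo - ring) & (waters <= hi + ring), axis=1)
    waters = waters[inside]

    tree = cKDTree(pts)
    dmin, _ = tree.query(waters, k=1)
    waters = waters[dmin > config.clash_cutoff]
    in_box = np.all((waters >= lo) & (waters <= hi), axis=1)
    return WaterSet(coords=waters, iteration=iteration, in_box=in_box)


def classify_bulk(waters: WaterSet, config: SolvationConfig) -> WaterSet:
    """Label each water bulk/non-bulk by its water-neighbour count.

    A water is bulk when at least ``min_neighbours_bulk`` other waters lie
    within ``neighbour_cutoff`` (closed ball, self excluded).
    """
    if len(waters) == 0:
        waters.is_bulk = np.zeros(0, dtype=bool)
        return waters
    tree = cKDTree(waters.coords)
    counts = np.array([len(idx) - 1 for idx in tree.query_ball_point(
        waters.coords, config.neighbour_cutoff)])
    waters.is_bulk = counts >= config.min_neighbours_bulk
    if waters.in_box is not None:       # drop the boundary ring
        waters.coords = waters.coords[waters.in_box]
        waters.is_bulk = waters.is_bulk[waters.in_box]
        waters.in_box = None
    return waters


def compute_depth(structure: Structure,
                  config: SolvationConfig | None = None) -> DepthResult:
    """Run all solvation iterations and average atom depths.

    Raises :class:`SolvationError` when an iteration produces no bulk
    water (increase ``box_padding``).
    """
    config = config or SolvationConfig()
    heavy = structure.coords(heavy_only=True)
    per_iter = np.empty((config.n_iterations, len(heavy)))
    water_sets = []
    for it in range(config.n_iterations):
        ws = classify_bulk(solvate_once(structure, config, it), config)
        bulk = ws.bulk_coords
        if len(bulk) == 0:
            raise SolvationError(
                "no bulk water found; increase box_padding")
        tree = cKDTree(bulk)
        per_iter[it], _ = tree.query(heavy, k=1)
        water_sets.append(ws)
    return DepthResult(structure=structure,
                       atom_depth=per_iter.mean(axis=0),
                       per_iteration=per_iter,
                       water_sets=water_sets)
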
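"""Cavity detection and calibrated volume estimation.

Non-bulk waters pooled over all solvation iterations (which share the
protein frame) are single-linkage clustered at 1.2 Å; a cluster with at
least two waters is a cavity.  Cavity volume is measured on a voxel grid
with a radius-weighted (power-distance) assignment of voxels to the
nearest site among protein atoms and waters: the protein-assigned volume
is computed once with all waters present and once with the cavity's
waters removed, and the difference is the raw cavity volume.  Raw volumes
are re-calibrated by the affine fit V_c = m1*V + m2 with m1 = 0.8 and
m2 = 21 Å^3.  A cavity whose lining residues all have depth greater than
3.75 Å is classified as buried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .solvation import DepthResult, SolvationConfig
from .structures import Structure


@dataclass
class VolumeCalibration:
    """Affine volume re-calibration V_c = m1*V + m2 (Å^3)."""

    m1: float = 0.8
    m2: float = 21.0

    def __post_init__(self):
        if self.m1 <= 0:
            raise ValueError("m1 must be positive")

    def calibrate(self, raw: float) -> float:
        return self.m1 * raw + self.m2

    def uncalibrate(self, calibrated: float) -> float:
        return (calibrated - self.m2) / self.m1


@dataclass
class Cavity:
    """A cluster of non-bulk waters, possibly drawn from several iterations."""

    member_coords: np.ndarray           # (n, 3)
    member_iterations: np.ndarray       # (n,)
    lining_residues: list = field(default_factory=list)
    raw_volume: float | None = None
    calibrated_volume: float | None = None
    buried: bool | None = None

    @property
    def n_waters(self) -> int:
        return len(self.member_coords)

    @property
    def centre(self) -> np.ndarray:
        return self.member_coords.mean(axis=0)


def cluster_cavity_waters(coords: np.ndarray,
                          iterations: np.ndarray | None = None,
                          link_cutoff: float = 1.2,
                          min_waters: int = 2) -> list:
    """Single-linkage cluster non-bulk waters into cavities.

    Waters (rows of ``coords``) closer than ``link_cutoff`` are linked;
    connected components with at least ``min_waters`` members become
    :class:`Cavity` objects.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n == 0:
        return []
    if iterations is None:
        iterations = np.zeros(n, dtype=int)
    pairs = cKDTree(coords).query_pairs(link_cutoff, output_type="ndarray")
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    cavities = []
    for c in range(n_comp):
        mask = labels == c
        if mask.sum() >= min_waters:
            cavities.append(Cavity(member_coords=coords[mask],
                                   member_iterations=iterations[mask]))
    cavities.sort(key=lambda cav: -cav.n_waters)
    return cavities


def _grid_points(structure: Structure, grid_step: float, margin: float):
    pts = structure.coords(heavy_only=True)
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    axes = [np.arange(lo[k] + grid_step / 2.0, hi[k], grid_step)
            for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"),
                    axis=-1).reshape(-1, 3)
    return grid


def _envelope_voxels(structure: Structure, grid_step: float,
                     envelope_margin: float) -> np.ndarray:
    """Voxel centres within (atom radius + margin) of some protein atom."""
    atoms = structure.heavy_atoms()
    apos = np.array([a.coords for a in atoms])
    arad = np.array([a.radius for a in atoms])
    grid = _grid_points(structure, grid_step, arad.max() + envelope_margin)
    d1, i1 = cKDTree(apos).query(grid, k=1)
    return grid[d1 <= arad[i1] + envelope_margin]


def _assign_voxels(voxels: np.ndarray, sites: np.ndarray,
                   radii: np.ndarray, k: int = 16) -> np.ndarray:
    """Index of the power-distance-nearest site for each voxel centre.

    Exact for the radius range in use: candidate sites are the k nearest
    by Euclidean distance, re-ranked by power distance |x-c|^2 - r^2.
    """
    tree = cKDTree(sites)
    k = min(k, len(sites))
    winners = np.empty(len(voxels), dtype=np.int64)
    chunk = 200_000
    for start in range(0, len(voxels), chunk):
        vox = voxels[start:start + chunk]
        d, idx = tree.query(vox, k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        power = d ** 2 - radii[idx] ** 2
        winners[start:start + len(vox)] = \
            idx[np.arange(len(vox)), power.argmin(axis=1)]
    return winners


def system_volume(structure: Structure,
                  water_coords: np.ndarray | None = None,
                  grid_step: float = 0.5,
                  water_radius: float = 1.4,
                  envelope_margin: float = 2.8,
                  grid: np.ndarray | None = None,
                  envelope: np.ndarray | None = None) -> float:
    """Protein volume by power-distance voxel assignment, Å^3.

    Each voxel centre inside the occupied envelope (within atom radius +
    ``envelope_margin`` of some protein atom) is assigned to the site --
    protein atom or water oxygen -- minimising the power distance
    |x - c|^2 - r^2; the returned volume is the count of protein-assigned
    voxels times the voxel volume.  Precomputed ``grid``/``envelope``
    arrays may be passed to share work between repeated calls.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    atoms = structure.heavy_atoms()
    apos = np.array([a.coords for a in atoms])
    arad = np.array([a.radius for a in atoms])

    if grid is not None or envelope is not None:
        voxels = grid[envelope] if envelope is not None else grid
    else:
        voxels = _envelope_voxels(structure, grid_step, envelope_margin)

    if water_coords is None or len(water_coords) == 0:
        n_protein = len(voxels)
    else:
        water_coords = np.asarray(water_coords).reshape(-1, 3)
        sites = np.concatenate([apos, water_coords])
        radii = np.concatenate([arad,
                                np.full(len(water_coords), water_radius)])
        winner = _assign_voxels(voxels, sites, radii)
        n_protein = int((winner < len(atoms)).sum())
    return n_protein * grid_step ** 3


def _match_waters(water_coords: np.ndarray, member_coords: np.ndarray):
    """Boolean mask of rows of ``water_coords`` that are member waters."""
    d, _ = cKDTree(member_coords).query(water_coords, k=1)
    return d < 1e-9


def measure_cavity_volumes(structure: Structure, water_coords: np.ndarray,
                           non_bulk_coords: np.ndarray, cavities: list,
                           calibration: VolumeCalibration | None = None,
                           grid_step: float = 0.5,
                           water_radius: float = 1.4,
                           envelope_margin: float = 2.8) -> list:
    """Measure raw and calibrated volumes of all cavities at once.

    The protein-plus-water system is voxel-assigned twice: with the full
    water ensemble, and with every non-bulk water removed; bulk waters
    bound the protein from outside in both runs.
    Each voxel lost by the water ensemble and reclaimed by the protein is
    credited to the cavity nearest (member-water distance, capped at
    ``assoc_cutoff``) to the water that claimed it, so that non-bulk
    waters whose 1.2 Å cluster stayed below the two-water threshold still
    contribute to the physical cavity they sit in.  Per-cavity raw
    volumes then sum to the total with/without volume difference, up to
    voxels claimed by non-bulk waters remote from every cavity.
    """
    calibration = calibration or VolumeCalibration()
    if not cavities:
        return []
    assoc_cutoff = 4.2
    water_coords = np.asarray(water_coords).reshape(-1, 3)
    non_bulk_coords = np.asarray(non_bulk_coords).reshape(-1, 3)
    atoms = structure.heavy_atoms()
    apos = np.array([a.coords for a in atoms])
    arad = np.array([a.radius for a in atoms])
    n_atoms = len(atoms)

    voxels = _envelope_voxels(structure, grid_step, envelope_margin)
    is_non_bulk = _match_waters(water_coords, non_bulk_coords)

    sites_all = np.concatenate([apos, water_coords])
    radii_all = np.concatenate([arad,
                                np.full(len(water_coords), water_radius)])
    winner_all = _assign_voxels(voxels, sites_all, radii_all)

    # removing sites only changes the assignment of voxels they won
    removed_site = np.zeros(len(sites_all), dtype=bool)
    removed_site[n_atoms:] = is_non_bulk
    affected = removed_site[winner_all]
    kept = water_coords[~is_non_bulk]
    sites_wo = np.concatenate([apos, kept])
    radii_wo = np.concatenate([arad, np.full(len(kept), water_radius)])
    reclaimed = np.zeros(len(voxels), dtype=bool)
    if affected.any():
        winner_wo = _assign_voxels(voxels[affected], sites_wo, radii_wo)
        reclaimed[affected] = winner_wo < n_atoms

    # cavity id for every water: own cluster, else nearest within cutoff
    cavity_of = np.full(len(water_coords), -1, dtype=np.int64)
    dist_to_cav = np.full(len(water_coords), np.inf)
    for ci, cav in enumerate(cavities):
        d, _ = cKDTree(cav.member_coords).query(water_coords, k=1)
        closer = d < dist_to_cav
        cavity_of[closer] = ci
        dist_to_cav[closer] = d[closer]
    cavity_of[~is_non_bulk | (dist_to_cav > assoc_cutoff)] = -1

    site_cavity = np.full(len(sites_all), -1, dtype=np.int64)
    site_cavity[n_atoms:] = cavity_of
    voxel_cavity = site_cavity[winner_all]
    voxel_cavity[~reclaimed] = -1

    vvol = grid_step ** 3
    for ci, cav in enumerate(cavities):
        cav.raw_volume = float((voxel_cavity == ci).sum()) * vvol
        cav.calibrated_volume = calibration.calibrate(cav.raw_volume)
    return [(c.raw_volume, c.calibrated_volume) for c in cavities]


def cavity_volume(structure: Structure, water_coords: np.ndarray,
                  cavity: Cavity,
                  calibration: VolumeCalibration | None = None,
                  grid_step: float = 0.5,
                  water_radius: float = 1.4,
                  envelope_margin: float = 2.8,
                  non_bulk_coords: np.ndarray | None = None):
    """Raw and calibrated volume of one cavity.

    ``water_coords`` is the full water ensemble the cavity was detected
    in.  The raw volume is the increase in protein-assigned volume when
    the cavity's waters are removed from the ensemble, clamped at zero
    against grid noise.  By default only the cavity's member waters are
    removed; passing ``non_bulk_coords`` removes every non-bulk water
    (the full-protocol measurement, see
    :func:`measure_cavity_volumes`) while still crediting only the
    member waters' voxels to this cavity.  Sets and returns
    ``(raw_volume, calibrated_volume)``.
    """
    calibration = calibration or VolumeCalibration()
    if non_bulk_coords is None:
        non_bulk_coords = cavity.member_coords
    measure_cavity_volumes(structure, water_coords, non_bulk_coords,
                           [cavity], calibration, grid_step, water_radius,
                           envelope_margin)
    return cavity.raw_volume, cavity.calibrated_volume


def find_lining_residues(cavity: Cavity, structure: Structure,
                         shell: float = 5.6) -> list:
    """Residues with at least one heavy atom within ``shell`` of a member
    water; stored on the cavity and returned as residue keys."""
    heavy = structure.heavy_atoms()
    apos = np.array([a.coords for a in heavy])
    tree = cKDTree(apos)
    hit_atoms = set()
    for idx in tree.query_ball_point(cavity.member_coords, shell):
        hit_atoms.update(idx)
    index_to_key = {}
    for res in structure.residues():
        index_to_key[res.atoms[0].residue_index] = res.key
    keys = sorted({index_to_key[heavy[i].residue_index]
                   for i in hit_atoms})
    cavity.lining_residues = keys
    return keys


def classify_buried(cavity: Cavity, structure: Structure,
                    depth: DepthResult, burial_cutoff: float = 3.75,
                    lining_shell: float = 5.6) -> bool:
    """A cavity is buried when its shallowest lining residue is deeper
    than ``burial_cutoff`` (strict inequality)."""
    if not cavity.lining_residues:
        find_lining_residues(cavity, structure, lining_shell)
    if not cavity.lining_residues:
        raise ValueError("cavity has no lining residues")
    rdepth = depth.residue_depth("all")
    cavity.buried = min(rdepth[k] for k in cavity.lining_residues) \
        > burial_cutoff
    return cavity.buried


def detect_cavities(structure: Structure,
                    config: SolvationConfig | None = None,
                    depth: DepthResult | None = None,
                    calibration: VolumeCalibration | None = None,
                    grid_step: float = 0.5,
                    link_cutoff: float = 1.2,
                    lining_shell: float = 5.6,
                    burial_cutoff: float = 3.75,
                    compute_volumes: bool = True):
    """Full pipeline: solvate, pool non-bulk waters, cluster, measure.

    Volumes are measured against the pooled water ensemble of all
    iterations, whose overlapping waters jointly fill each cavity.
    Returns ``(depth_result, cavities)``.
    """
    from .solvation import compute_depth
    config = config or SolvationConfig()
    if depth is None:
        depth = compute_depth(structure, config)
    nb_coords, nb_iters = depth.pooled_non_bulk()
    cavities = cluster_cavity_waters(nb_coords, nb_iters, link_cutoff)
    cavities = [c for c in cavities
                if find_lining_residues(c, structure, lining_shell)]
    for cav in cavities:
        classify_buried(cav, structure, depth, burial_cutoff, lining_shell)
    if compute_volumes and cavities:
        all_waters = np.concatenate([ws.coords for ws in depth.water_sets])
        measure_cavity_volumes(structure, all_waters, nb_coords, cavities,
                               calibration, grid_step,
                               config.water_radius)
    return depth, cavities
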
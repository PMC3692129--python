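"""High-level pipelines tying the modules together.

These are the entry points the command-line interface and the validation
scripts use: depth profiling, cavity detection with volumes, binding-site
prediction and pKa prediction for whole structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_sites import (BindingProbabilityTable, adjust_probability,
                            call_binding_residues, displacement_likelihood,
                            normalize_scores, two_water_smoothing)
from .cavities import VolumeCalibration, detect_cavities
from .conservation import ConservationProfile
from .params import IONIZABLE_GROUP_ATOMS
from .pka import PkaModel, asa_shrake_rupley, compute_features, predict_pka
from .solvation import DepthResult, SolvationConfig, compute_depth
from .structures import Structure


def depth_table(depth: DepthResult) -> pd.DataFrame:
    """Tidy per-residue depth table (chain, residue, type, depth in Å)."""
    rd = depth.residue_depth("all")
    rows = [(res.chain_id, res.seq_number, res.insertion_code,
             res.res_type, rd[res.key])
            for res in depth.structure.residues()]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode",
                                       "res_type", "depth"])


def cavity_table(cavities) -> pd.DataFrame:
    rows = [(i, c.n_waters, c.raw_volume, c.calibrated_volume, c.buried,
             ";".join(f"{k[0]}{k[1]}{k[2]}" for k in c.lining_residues))
            for i, c in enumerate(cavities)]
    return pd.DataFrame(rows, columns=["cavity", "n_waters", "raw_volume",
                                       "calibrated_volume", "buried",
                                       "lining_residues"])


@dataclass
class BindingSiteResult:
    predicted: set
    residue_table: pd.DataFrame
    cavities: list = field(default_factory=list)
    depth: DepthResult | None = None


def predict_binding_sites(structure: Structure,
                          ptable: BindingProbabilityTable,
                          conservation: ConservationProfile | None = None,
                          config: SolvationConfig | None = None,
                          depth: DepthResult | None = None,
                          cavities: list | None = None,
                          alpha: float = 0.7,
                          beta: float = 0.8,
                          water_shell: float = 5.6,
                          residue_shell: float = 6.5,
                          consensus: float = 0.6) -> BindingSiteResult:
    """Predict ligand-binding residues for a structure.

    Without a conservation profile the adjusted probability reduces to
    the normalised binding probability (q = P').  Cavity-water
    displacement likelihoods are smoothed over the pooled cavity waters
    of all iterations, whose overlapping positions describe the same
    physical cavity; candidate residues are still nominated per
    iteration and filtered by the consensus rule.
    """
    config = config or SolvationConfig()
    if depth is None or cavities is None:
        depth, cavities = detect_cavities(structure, config, depth,
                                          compute_volumes=False)
    residues = structure.residue_list()
    rdepth = depth.residue_depth("all")
    _, asa_fraction = asa_shrake_rupley(structure)

    P = np.array([ptable.lookup(r.res_type, rdepth[r.key],
                                100.0 * asa_fraction[r.key])
                  for r in residues])
    P_norm = normalize_scores(P)
    if conservation is not None:
        J = np.array([conservation.scores[r.key] for r in residues])
        J_norm = normalize_scores(J)
        q = adjust_probability(P_norm, J_norm, alpha)
    else:
        J = np.full(len(residues), np.nan)
        J_norm = np.full(len(residues), np.nan)
        q = P_norm.copy()
    q_by_residue = {r.key: float(v) for r, v in zip(residues, q)}

    if cavities:
        coords = np.concatenate([c.member_coords for c in cavities])
        iters = np.concatenate([c.member_iterations for c in cavities])
        D = displacement_likelihood(coords, structure, q_by_residue,
                                    water_shell)
        smoothed = two_water_smoothing(coords, D, config.neighbour_cutoff)
        iteration_waters = {
            it: (coords[iters == it], smoothed[iters == it])
            for it in range(config.n_iterations)}
        predicted = call_binding_residues(
            structure, iteration_waters, beta, residue_shell, consensus,
            n_iterations=config.n_iterations)
    else:
        predicted = set()

    table = pd.DataFrame({
        "chain": [r.chain_id for r in residues],
        "resnum": [r.seq_number for r in residues],
        "res_type": [r.res_type for r in residues],
        "P": P, "J": J, "P_norm": P_norm, "J_norm": J_norm, "q": q,
        "predicted": [r.key in predicted for r in residues],
    })
    return BindingSiteResult(predicted=predicted, residue_table=table,
                             cavities=cavities, depth=depth)


def predict_pka_table(structure: Structure,
                      config: SolvationConfig | None = None,
                      depth: DepthResult | None = None,
                      model: PkaModel | None = None) -> pd.DataFrame:
    """Predict pKa for every ASP/GLU/HIS/LYS residue of a structure."""
    config = config or SolvationConfig()
    model = model or PkaModel.default()
    if depth is None:
        depth = compute_depth(structure, config)
    _, asa_fraction = asa_shrake_rupley(structure)
    rows = []
    for res in structure.residues():
        if res.res_type not in IONIZABLE_GROUP_ATOMS:
            continue
        feats = compute_features(structure, res, depth, asa_fraction)
        rows.append((res.chain_id, res.seq_number, res.res_type,
                     feats.depth_mc, feats.depth_polar_sc, feats.hb,
                     feats.ee, feats.asa_sc,
                     predict_pka(feats, res.res_type, model)))
    return pd.DataFrame(rows, columns=["chain", "resnum", "res_type",
                                       "depth_mc", "depth_polar_sc", "hb",
                                       "ee", "asa_sc", "pka"])


def run_cavity_pipeline(structure: Structure,
                        config: SolvationConfig | None = None,
                        grid_step: float = 0.5,
                        calibration: VolumeCalibration | None = None):
    """Convenience wrapper returning (depth, cavities) with volumes."""
    return detect_cavities(structure, config, calibration=calibration,
                           grid_step=grid_step)
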
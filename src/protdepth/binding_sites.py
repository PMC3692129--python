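"""Small-molecule ligand-binding site prediction.

Each residue gets a binding probability P from a lookup table binned on
residue type, depth and side-chain accessibility; P and the conservation
score J are normalised per protein against the means of their five
smallest/largest values and mixed as q = alpha*P' + (1-alpha)*J' with
alpha = 0.7.  Every cavity water then receives a displacement likelihood
D = 1 - prod_c prod_i (1 - q_ic) over the residues i of chain c within
5.6 Å (a noisy-OR, independent across chains), smoothed by the two-water
rule: the likelihood of a water is the mean of the two highest
likelihoods among itself and its neighbouring cavity waters within
4.2 Å, and a water without any such neighbour cannot be displaced.
Waters whose smoothed likelihood exceeds beta = 0.8 nominate all
residues within 6.5 Å; residues nominated in more than 60% of solvation
iterations are the predicted binding site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import STANDARD_RESIDUES
from .structures import Structure


@dataclass
class BinSpec:
    """Bin edges for the (depth, accessibility) probability table."""

    depth_edges: tuple = tuple(float(x) for x in range(0, 11))  # then open
    asa_edges: tuple = tuple(float(x) for x in range(0, 101, 10))

    def depth_bin(self, depth: float) -> int:
        return min(int(np.searchsorted(self.depth_edges, depth,
                                       side="right")) - 1,
                   len(self.depth_edges) - 1)

    def asa_bin(self, asa_pct: float) -> int:
        return min(int(np.searchsorted(self.asa_edges, asa_pct,
                                       side="right")) - 1,
                   len(self.asa_edges) - 2)


@dataclass
class BindingProbabilityTable:
    """P(binding | residue type, depth bin, accessibility bin).

    Backed by a DataFrame with columns res_type, d_lo, d_hi, s_lo, s_hi,
    p.  Unseen (type, depth, accessibility) combinations fall back to the
    residue-type marginal.  The packaged table is a small synthetic
    stand-in for a table trained on a ligand-bound protein corpus; users
    supply their own via :meth:`from_tsv`.
    """

    table: pd.DataFrame
    marginals: dict = field(default_factory=dict)

    def __post_init__(self):
        if not ((self.table.p >= 0) & (self.table.p <= 1)).all():
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.marginals:
            self.marginals = dict(
                self.table.groupby("res_type").p.mean())
        missing = set(STANDARD_RESIDUES) - set(self.marginals)
        if missing:
            raise ValueError(f"residue types missing from table: {missing}")

    @classmethod
    def from_tsv(cls, path) -> "BindingProbabilityTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def lookup(self, res_type: str, depth: float, asa_pct: float) -> float:
        rows = self.table[(self.table.res_type == res_type)
                          & (self.table.d_lo <= depth)
                          & ((depth < self.table.d_hi)
                             | ~np.isfinite(self.table.d_hi))
                          & (self.table.s_lo <= asa_pct)
                          & (asa_pct <= self.table.s_hi)]
        if len(rows):
            return float(rows.p.iloc[0])
        return float(self.marginals[res_type])


def build_probability_table(records: pd.DataFrame,
                            bins: BinSpec | None = None,
                            smoothing: tuple = (1.0, 2.0)
                            ) -> BindingProbabilityTable:
    """Estimate a binding-probability table from labelled residues.

    ``records`` must have columns res_type, depth, asa_pct and is_binding
    (bool).  P(bin) = (#binding + a) / (#total + b) with Laplace-style
    smoothing (a, b) = ``smoothing``; empty bins inherit the residue-type
    marginal at lookup time.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty training set")
    bins = bins or BinSpec()
    a, b = smoothing
    d_edges = list(bins.depth_edges) + [math.inf]
    s_edges = list(bins.asa_edges)
    rows = []
    for res_type, sub in records.groupby("res_type"):
        for di in range(len(d_edges) - 1):
            for si in range(len(s_edges) - 1):
                mask = ((sub.depth >= d_edges[di])
                        & (sub.depth < d_edges[di + 1])
                        & (sub.asa_pct >= s_edges[si])
                        & (sub.asa_pct <= s_edges[si + 1]
                           if si == len(s_edges) - 2
                           else sub.asa_pct < s_edges[si + 1]))
                n = int(mask.sum())
                if n == 0:
                    continue
                k = int(sub.is_binding[mask].sum())
                rows.append((res_type, d_edges[di], d_edges[di + 1],
                             s_edges[si], s_edges[si + 1],
                             (k + a) / (n + b)))
    table = pd.DataFrame(rows, columns=["res_type", "d_lo", "d_hi",
                                        "s_lo", "s_hi", "p"])
    marginals = {rt: float((sub.is_binding.sum() + a) / (len(sub) + b))
                 for rt, sub in records.groupby("res_type")}
    for rt in STANDARD_RESIDUES:
        marginals.setdefault(rt, float(a / b))
    return BindingProbabilityTable(table, marginals)


def normalize_scores(values) -> np.ndarray:
    """Normalise scores against the means of the five smallest and five
    largest values, clipped to [0, 1].

    With fewer than five values the plain min/max are used; a constant
    input maps everything to 0.5 with a warning.
    """
    values = np.asarray(list(values), dtype=float)
    srt = np.sort(values)
    k = 5 if len(values) >= 5 else 1
    lo, hi = srt[:k].mean(), srt[-k:].mean()
    if hi == lo:
        warnings.warn("constant scores; normalisation returns 0.5")
        return np.full_like(values, 0.5)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def adjust_probability(p_norm, j_norm, alpha: float = 0.7):
    """Weighted average q = alpha*P' + (1-alpha)*J'."""
    return alpha * np.asarray(p_norm) + (1.0 - alpha) * np.asarray(j_norm)


def displacement_likelihood(water_coords: np.ndarray, structure: Structure,
                            q_by_residue: dict,
                            shell: float = 5.6) -> np.ndarray:
    """Noisy-OR displacement likelihood of each water.

    Per chain c, D_c = 1 - prod_{i in shell(c)} (1 - q_i); chains combine
    independently, D = 1 - prod_c (1 - D_c).  (Algebraically this equals
    the flat noisy-OR over all shell residues.)  Waters with an empty
    shell get D = 0.
    """
    water_coords = np.asarray(water_coords, dtype=float).reshape(-1, 3)
    heavy = structure.heavy_atoms()
    apos = np.array([a.coords for a in heavy])
    tree = cKDTree(apos)
    index_to_key = {res.atoms[0].residue_index: res.key
                    for res in structure.residues()}
    D = np.zeros(len(water_coords))
    for w, idx in enumerate(tree.query_ball_point(water_coords, shell)):
        shell_res = {}
        for i in idx:
            key = index_to_key[heavy[i].residue_index]
            shell_res.setdefault(key[0], set()).add(key)
        prod_chains = 1.0
        for chain, keys in shell_res.items():
            d_c = 1.0 - np.prod([1.0 - q_by_residue[k] for k in keys])
            prod_chains *= 1.0 - d_c
        D[w] = 1.0 - prod_chains
    return D


def two_water_smoothing(water_coords: np.ndarray, likelihoods: np.ndarray,
                        neighbour_cutoff: float = 4.2) -> np.ndarray:
    """Smooth likelihoods by the two-water displacement rule.

    Each water's smoothed likelihood is the mean of the two highest
    likelihoods among itself and its neighbours within
    ``neighbour_cutoff``.  A water without neighbours cannot satisfy the
    two-water requirement and is set to 0.
    """
    water_coords = np.asarray(water_coords, dtype=float).reshape(-1, 3)
    likelihoods = np.asarray(likelihoods, dtype=float)
    out = np.zeros(len(water_coords))
    if len(water_coords) == 0:
        return out
    tree = cKDTree(water_coords)
    for w, idx in enumerate(tree.query_ball_point(water_coords,
                                                  neighbour_cutoff)):
        vals = likelihoods[idx]
        if len(vals) < 2:
            out[w] = 0.0
        else:
            top2 = np.sort(vals)[-2:]
            out[w] = top2.mean()
    return out


def call_binding_residues(structure: Structure, iteration_waters: dict,
                          beta: float = 0.8, residue_shell: float = 6.5,
                          consensus: float = 0.6,
                          n_iterations: int | None = None) -> set:
    """Consensus binding-site call across solvation iterations.

    ``iteration_waters`` maps iteration -> (coords, smoothed_likelihoods)
    of that iteration's cavity waters.  Per iteration, residues with any
    heavy atom within ``residue_shell`` of a water whose smoothed
    likelihood exceeds ``beta`` are candidates; residues appearing in
    strictly more than ``consensus`` of all iterations are predicted.
    """
    if n_iterations is None:
        n_iterations = len(iteration_waters)
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    heavy = structure.heavy_atoms()
    apos = np.array([a.coords for a in heavy])
    tree = cKDTree(apos)
    index_to_key = {res.atoms[0].residue_index: res.key
                    for res in structure.residues()}
    support: dict = {}
    for it, (coords, smoothed) in iteration_waters.items():
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        displaced = coords[np.asarray(smoothed) > beta]
        listed = set()
        for idx in tree.query_ball_point(displaced, residue_shell):
            for i in idx:
                listed.add(index_to_key[heavy[i].residue_index])
        for key in listed:
            support[key] = support.get(key, 0) + 1
    return {key for key, n in support.items()
            if n / n_iterations > consensus}


@dataclass
class ClassificationMetrics:
    """Confusion rates and derived binary-classification statistics.

    Rates are fractions of all residues (they sum to 1).  Undefined
    ratios (zero denominators) are reported as 0 and flagged in
    ``undefined``.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float = 0.0
    specificity: float = 0.0
    accuracy: float = 0.0
    precision: float = 0.0
    mcc: float = 0.0
    undefined: list = field(default_factory=list)

    @classmethod
    def from_rates(cls, tp: float, fp: float, tn: float,
                   fn: float) -> "ClassificationMetrics":
        m = cls(tp=tp, fp=fp, tn=tn, fn=fn)
        m.undefined = []

        def ratio(num, den, name):
            if den == 0:
                m.undefined.append(name)
                return 0.0
            return num / den

        m.sensitivity = ratio(tp, tp + fn, "sensitivity")
        m.specificity = ratio(tn, tn + fp, "specificity")
        m.precision = ratio(tp, tp + fp, "precision")
        m.accuracy = tp + tn
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        m.mcc = ratio(tp * tn - fp * fn, denom, "mcc")
        return m


def evaluate_predictions(predicted: set, truth: set,
                         all_residues) -> ClassificationMetrics:
    """Confusion rates of a residue-set prediction against the truth."""
    all_residues = set(all_residues)
    if not truth <= all_residues:
        raise ValueError("truth contains residues outside the universe")
    n = len(all_residues)
    predicted = set(predicted) & all_residues
    tp = len(predicted & truth) / n
    fp = len(predicted - truth) / n
    fn = len(truth - predicted) / n
    tn = len(all_residues - predicted - truth) / n
    return ClassificationMetrics.from_rates(tp, fp, tn, fn)
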
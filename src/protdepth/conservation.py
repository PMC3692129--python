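"""Sequence conservation scores from a multiple sequence alignment.

The conservation score of an alignment column is its Jensen-Shannon
divergence (natural log, equal weights) between the column's amino-acid
distribution and a background distribution of amino-acid occurrence.
Column frequencies are smoothed with substitution-matrix pseudo-counts:
for amino acid a at column i,

    f_ia = (n_ia + b_ia) / (N_i + B_i),      B_i = m * R_i
    b_ia = B_i * sum_k (n_ik / N_i) * (t_ka / T_k)   (row-normalised)

where n_ia are observed counts, N_i their total, R_i the number of
distinct residue types in the column, m = 5, t_ka the probability that
amino acid k is substituted by a (from BLOSUM62 target frequencies) and
T_k the overall substitution probability of k.  Gaps and non-standard
letters are excluded from counts; an all-gap column scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .params import THREE_TO_ONE, _read_table
from .structures import Structure

AMINO_ACIDS = list("ARNDCQEGHILKMFPSTWYV")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class Alignment:
    """Equal-length gapped sequences; one row (the query) maps onto the
    structure."""

    sequences: list
    ids: list = field(default_factory=list)
    query_index: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("alignment rows differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]

    @classmethod
    def from_fasta(cls, path, query_index: int = 0) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([str(r.seq) for r in records], [r.id for r in records],
                   query_index)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def query_columns(self) -> list:
        """Alignment columns of the ungapped query positions, in order."""
        return [i for i, c in enumerate(self.query) if c in _AA_INDEX]


@dataclass
class SubstitutionPrior:
    """Substitution probabilities and background frequencies.

    t[k, a] is the probability that amino acid k is substituted by a
    (rows sum to 1); T[k] the overall substitution probability of k;
    background the amino-acid occurrence distribution.
    """

    t: np.ndarray
    T: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of t must sum to 1")
        if not np.isclose(self.T.sum(), 1.0, atol=1e-9) or \
                not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("T and background must sum to 1")
        if np.any(self.t <= 0) or np.any(self.background <= 0):
            raise ValueError("prior entries must be positive")

    @classmethod
    def from_blosum62(cls) -> "SubstitutionPrior":
        """Build the prior from the BLOSUM62 log-odds matrix.

        Target frequencies are reconstructed from the half-bit log-odds
        scores s via q_ka ∝ p_k * p_a * 2^(s_ka / 2) with the packaged
        background frequencies p, then row-normalised into substitution
        probabilities.
        """
        df = _read_table("background_frequencies.tsv")
        bg = np.array([float(df.frequency[df.aa == a].iloc[0])
                       for a in AMINO_ACIDS])
        bg = bg / bg.sum()
        blosum = substitution_matrices.load("BLOSUM62")
        s = np.array([[blosum[k, a] for a in AMINO_ACIDS]
                      for k in AMINO_ACIDS])
        q = np.outer(bg, bg) * np.power(2.0, s / 2.0)
        t = q / q.sum(axis=1, keepdims=True)
        T = bg @ t
        return cls(t=t, T=T / T.sum(), background=bg)


@dataclass
class ConservationProfile:
    """Per-residue conservation scores for a structure chain."""

    scores: dict                 # residue key -> J (nats)
    column_scores: np.ndarray    # per alignment column
    frequencies: np.ndarray      # (columns, 20) smoothed f
    m: int = 5


def column_counts(alignment: Alignment, column: int):
    """Counts (n_ia vector, N_i, R_i) for one column; gaps and letters
    outside the 20 standard amino acids are excluded."""
    counts = np.zeros(len(AMINO_ACIDS))
    for seq in alignment.sequences:
        idx = _AA_INDEX.get(seq[column])
        if idx is not None:
            counts[idx] += 1
    return counts, int(counts.sum()), int((counts > 0).sum())


def pseudo_count_frequencies(counts: np.ndarray, prior: SubstitutionPrior,
                             m: int = 5) -> np.ndarray:
    """Pseudo-count-smoothed column frequencies f_ia (sum to 1, all > 0)."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    if N < 1:
        raise ValueError("column has no observed residues")
    R = int((counts > 0).sum())
    B = m * R
    g = (counts / N) @ (prior.t / prior.T[:, None])
    b = B * g / g.sum()
    return (counts + b) / (N + B)


def js_divergence(f: np.ndarray, background: np.ndarray) -> float:
    """Equal-weight Jensen-Shannon divergence in nats, in [0, ln 2]."""
    f = np.asarray(f, dtype=float)
    background = np.asarray(background, dtype=float)
    mix = 0.5 * (f + background)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_f = np.where(f > 0, f * np.log(f / mix), 0.0).sum()
        kl_b = np.where(background > 0,
                        background * np.log(background / mix), 0.0).sum()
    return float(0.5 * kl_f + 0.5 * kl_b)


def column_score(alignment: Alignment, column: int,
                 prior: SubstitutionPrior, m: int = 5):
    """(J, f) of one column; an all-gap column scores J = 0 with the
    background as its distribution."""
    counts, N, _ = column_counts(alignment, column)
    if N == 0:
        return 0.0, prior.background.copy()
    f = pseudo_count_frequencies(counts, prior, m)
    return js_divergence(f, prior.background), f


def conservation_profile(alignment: Alignment, structure: Structure,
                         prior: SubstitutionPrior | None = None,
                         chain_id: str | None = None,
                         m: int = 5) -> ConservationProfile:
    """Map per-column scores onto structure residues via the query row.

    The ungapped query must match the chain's residue sequence in length
    (a mismatch raises).  Residues outside the mapped chain receive the
    minimum score of the protein.
    """
    prior = prior or SubstitutionPrior.from_blosum62()
    all_scores = np.empty(alignment.length)
    freqs = np.empty((alignment.length, len(AMINO_ACIDS)))
    for col in range(alignment.length):
        all_scores[col], freqs[col] = column_score(alignment, col, prior, m)

    if chain_id is None:
        chain_id = next(iter(structure.chains))
    chain = structure.chains[chain_id]
    qcols = alignment.query_columns()
    if len(qcols) != len(chain):
        raise ValueError(
            f"ungapped query length {len(qcols)} does not match chain "
            f"{chain_id} with {len(chain)} residues")
    for res, col in zip(chain, qcols):
        qaa = alignment.query[col]
        if THREE_TO_ONE.get(res.res_type) not in (qaa, None):
            warnings.warn(
                f"query letter {qaa} differs from structure residue "
                f"{res.res_type} at {res.key}")
    scores = {res.key: float(all_scores[col])
              for res, col in zip(chain, qcols)}
    fallback = min(scores.values()) if scores else 0.0
    for res in structure.residues():
        scores.setdefault(res.key, fallback)
    return ConservationProfile(scores=scores, column_scores=all_scores,
                               frequencies=freqs, m=m)
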
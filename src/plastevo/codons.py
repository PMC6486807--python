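"""Codon-level machinery shared by the simulator and the rate estimators.

Genetic code: translation table 11 (bacterial/plastid), 61 sense codons.
The substitution model is the Goldman–Yang-type codon model: single-nucleotide
exchanges only, transition/transversion ratio ``kappa``, nonsynonymous scaling
``omega``, stationary codon frequencies ``pi`` (typically F3x4), generator
scaled so the mean substitution rate per codon is 1.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import eigh

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "translate",
    "f3x4_frequencies",
    "uniform_frequencies",
    "gy94_generator",
    "transition_matrix",
    "substitution_flux",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
NUCS = "TCAG"
ALL_CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
STOP_CODONS = set(_TABLE.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate(codon: str) -> str:
    return AA[codon]


def _pair_class() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify all sense-codon pairs differing at one site.

    Returns boolean matrices (is_single_step, is_transition, is_synonymous).
    """
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = diffs[0] in _TRANSITIONS
            syn[i, j] = AA[ci] == AA[cj]
    return single, ts, syn


_SINGLE, _TS, _SYN = _pair_class()


def uniform_frequencies() -> np.ndarray:
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


def f3x4_frequencies(pos_nuc_freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a (3, 4) array of per-position T/C/A/G freqs.

    Stop codons are excluded and the vector renormalized over sense codons.
    """
    pos = np.asarray(pos_nuc_freqs, dtype=float)
    if pos.shape != (3, 4):
        raise ValueError("expected shape (3, 4) in TCAG order")
    nuc_idx = {b: k for k, b in enumerate(NUCS)}
    freqs = np.array(
        [
            pos[0, nuc_idx[c[0]]] * pos[1, nuc_idx[c[1]]] * pos[2, nuc_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies")
    return freqs / total


def f3x4_from_sequences(seqs: list[str]) -> np.ndarray:
    """Empirical F3x4 frequencies pooled over the given in-frame sequences."""
    counts = np.zeros((3, 4))
    nuc_idx = {b: k for k, b in enumerate(NUCS)}
    for s in seqs:
        s = s.upper().replace("U", "T")
        for i in range(0, len(s) - 2, 3):
            for p in range(3):
                b = s[i + p]
                if b in nuc_idx:
                    counts[p, nuc_idx[b]] += 1
    counts += 0.5  # avoid zero-frequency codons for sparse inputs
    return f3x4_frequencies(counts / counts.sum(axis=1, keepdims=True))


def gy94_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 rate matrix Q over sense codons, scaled to mean rate 1 per codon."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(SENSE_CODONS),) or np.any(pi < 0):
        raise ValueError("frequencies must be a nonnegative vector over sense codons")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    rate = np.where(_SINGLE, 1.0, 0.0)
    rate = np.where(_TS, kappa * rate, rate)
    rate = np.where(~_SYN & _SINGLE, omega * rate, np.where(_SINGLE, rate, 0.0))
    Q = rate * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / mean_rate


class SpectralGenerator:
    """Eigendecomposition of a reversible Q for cheap P(t) at many t."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        mask = self.pi > 0
        if not mask.all():
            raise ValueError("zero stationary frequencies are not supported")
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * Q) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetric for reversible Q; enforce numerically
        self.w, V = eigh(B)
        self.left = V / sq[:, None]
        self.right = V * sq[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.right * np.exp(self.w * t)) @ self.left.T
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def transition_matrix(kappa: float, omega: float, pi: np.ndarray, t: float) -> np.ndarray:
    return SpectralGenerator(gy94_generator(kappa, omega, pi), pi).transition_matrix(t)


def substitution_flux(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) shares of the substitution flux of the
    mean-rate-1 generator."""
    Q = gy94_generator(kappa, omega, pi)
    off = Q * (~np.eye(len(pi), dtype=bool))
    syn_flux = (pi[:, None] * np.where(_SYN, off, 0.0)).sum()
    nonsyn_flux = (pi[:, None] * np.where(~_SYN & _SINGLE, off, 0.0)).sum()
    total = syn_flux + nonsyn_flux
    return syn_flux / total, nonsyn_flux / total


def site_proportions(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Proportions of synonymous/nonsynonymous sites, defined mutationally
    (the same model with omega = 1), as used to convert t into dS and dN."""
    return substitution_flux(kappa, 1.0, pi)
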
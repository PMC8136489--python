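"""GY94 codon substitution model with F3x4 equilibrium frequencies.

The Goldman-Yang codon model assigns rate ``q_ij = pi_j * kappa^[transition]
* omega^[nonsynonymous]`` to single-nucleotide codon changes and zero to
multi-nucleotide changes.  F3x4 builds the 61 sense-codon frequencies from
position-specific nucleotide frequencies of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codons import (
    AA_OF,
    CODON_INDEX,
    GAP_CODON,
    N_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_transition,
    single_nt_difference,
)

# precomputed single-nucleotide change structure of the 61-state space
_TS_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)   # transition changes
_TV_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)   # transversion changes
_NONSYN_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        _pos = single_nt_difference(_ci, _cj)
        if _pos is None:
            continue
        if is_transition(_ci[_pos], _cj[_pos]):
            _TS_MASK[_i, _j] = True
        else:
            _TV_MASK[_i, _j] = True
        if AA_OF[_ci] != AA_OF[_cj]:
            _NONSYN_MASK[_i, _j] = True
_SINGLE_MASK = _TS_MASK | _TV_MASK


@dataclass
class CodonModelParams:
    """GY94 parameters: kappa (ts/tv), omega (dN/dS), pi (61 codon freqs)."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if not np.isfinite(self.pi).all() or (self.pi < 0).any():
            raise ValueError("pi must be finite and non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1 within 1e-9")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and non-negative")
        if not (np.isfinite(self.omega) and self.omega >= 0):
            raise ValueError("omega must be finite and non-negative")


def build_f3x4(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Nucleotide frequencies are tallied separately at codon positions
    1-3 over all taxa and sites (gap codons skipped, ambiguous characters
    ignored), multiplied across positions for each sense codon, and
    renormalized after excluding stop codons.
    """
    counts = np.zeros((3, 4))
    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    for ti in range(aln.n_taxa):
        row = aln.rows[ti]
        for site in range(aln.n_sites):
            codon = row[3 * site: 3 * site + 3]
            if codon == GAP_CODON:
                continue
            for pos in range(3):
                k = nt_index.get(codon[pos])
                if k is not None:
                    counts[pos, k] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.where(totals == 0)[0][0]) + 1
        raise ValueError(f"no observed nucleotides at codon position {bad}")
    freqs = counts / totals[:, None]
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]]
            * freqs[1, nt_index[c[1]]]
            * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("all F3x4 codon frequencies are zero")
    return pi / total


def gy94_unscaled(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 generator (rows sum to zero, no rate normalization)."""
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_SINGLE_MASK] = np.broadcast_to(pi, (N_CODONS, N_CODONS))[_SINGLE_MASK]
    Q[_TS_MASK] *= kappa
    Q[_NONSYN_MASK & _SINGLE_MASK] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time under pi."""
    return float(-np.dot(pi, np.diag(Q)))


def gy94_rate_matrix(params: CodonModelParams) -> np.ndarray:
    """GY94 generator scaled so the expected substitution rate is 1.

    Under this scaling a branch length is the expected number of codon
    substitutions per site at the supplied omega.
    """
    Q = gy94_unscaled(params.kappa, params.omega, params.pi)
    rate = expected_rate(Q, params.pi)
    if rate <= 0:
        raise ValueError("degenerate model: expected substitution rate is 0")
    return Q / rate


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetric eigendecomposition of a
    reversible generator (pi entries must be positive)."""
    vals, vecs, sqrt_pi = eigen_decompose(Q, pi)
    return probs_from_eigen(vals, vecs, sqrt_pi, np.array([t]))[0]


def eigen_decompose(
    Q: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of a reversible Q through its symmetrization.

    Returns (eigenvalues, eigenvectors of the symmetrized matrix, sqrt(pi)).
    Zero pi entries are floored at 1e-12 for numerical stability.
    """
    safe_pi = np.maximum(pi, 1e-12)
    sqrt_pi = np.sqrt(safe_pi)
    S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)  # symmetrize residual asymmetry
    vals, vecs = np.linalg.eigh(S)
    return vals, vecs, sqrt_pi


def probs_from_eigen(
    vals: np.ndarray, vecs: np.ndarray, sqrt_pi: np.ndarray, ts: np.ndarray
) -> np.ndarray:
    """Stack of P(t) for each t in ``ts`` from a stored eigendecomposition."""
    expo = np.exp(vals[None, :] * np.asarray(ts)[:, None])  # (n_t, 61)
    inner = np.einsum("ik,tk,jk->tij", vecs, expo, vecs)
    P = (1.0 / sqrt_pi)[None, :, None] * inner * sqrt_pi[None, None, :]
    return np.clip(P, 0.0, None)


def codon_index_row(row: str) -> np.ndarray:
    """Map a nucleotide row to per-site codon indices (-1 = gap/missing)."""
    n_sites = len(row) // 3
    out = np.full(n_sites, -1, dtype=np.int64)
    for s in range(n_sites):
        idx = CODON_INDEX.get(row[3 * s: 3 * s + 3])
        if idx is not None:
            out[s] = idx
    return out
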
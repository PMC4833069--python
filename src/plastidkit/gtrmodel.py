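"""General time reversible (GTR) nucleotide substitution model.

The model is parameterized by the stationary base frequencies pi (A, C, G, T)
and six symmetric exchangeabilities in the canonical order
(AC, AG, AT, CG, CT, GT).  The rate matrix is normalized so that the expected
number of substitutions per unit time at stationarity is 1; branch lengths are
therefore in expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GtrParams:
    """GTR parameters: base frequencies and symmetric exchangeabilities."""

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exch: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.pi.shape != (4,):
            raise ValueError("pi must have 4 entries")
        if self.exch.shape != (6,):
            raise ValueError("exch must have 6 entries")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be positive and sum to 1")
        if np.any(self.exch <= 0):
            raise ValueError("exchangeabilities must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q (mean rate 1)."""
        q = np.zeros((4, 4))
        for s, (i, j) in zip(self.exch, _EXCH_PAIRS):
            q[i, j] = s * self.pi[j]
            q[j, i] = s * self.pi[i]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(q)))
        return q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the symmetrized matrix.

        Returns (eigenvalues, right_vectors, inverse_vectors) such that
        P(t) = right @ diag(exp(lam * t)) @ inverse.
        """
        q = self.rate_matrix()
        d = np.sqrt(self.pi)
        sym = (q * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        right = u / d[:, None]
        inv = u.T * d[None, :]
        return lam, right, inv

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), clipped to valid probabilities."""
        lam, right, inv = self.eigensystem()
        p = (right * np.exp(lam * t)) @ inv
        return np.clip(p, 0.0, 1.0)


def transition_matrices(params: GtrParams, lengths: np.ndarray) -> np.ndarray:
    """Stack of P(t) for many branch lengths (shared eigensystem)."""
    lam, right, inv = params.eigensystem()
    lengths = np.asarray(lengths, dtype=float)
    p = np.einsum("ik,bk,kj->bij", right, np.exp(np.outer(lengths, lam)), inv)
    return np.clip(p, 0.0, 1.0)
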
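"""Empirical amino-acid substitution models (JTT by default).

The model is a general time-reversible 20-state Markov process defined by a
symmetric exchangeability matrix S and stationary frequencies pi:
Q_ij = S_ij * pi_j (i != j), rows summing to zero, normalized so that
-sum_i pi_i Q_ii = 1, i.e. branch lengths are expected substitutions per site.

The Jones-Taylor-Thornton exchangeabilities and frequencies are bundled in
PAML ``.dat`` dialect (lower-triangular exchangeabilities followed by the
frequency row, amino acids in ARNDCQEGHILKMFPSTWYV order).

Transition probabilities P(t) = exp(Qt) are computed once per model by
spectral decomposition of the symmetrized generator, so repeated calls at
different t are cheap and exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .family_io import AMINO_ACIDS

__all__ = ["SubstitutionModel", "jtt_model", "load_paml_dat"]


def load_paml_dat(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-dialect rate file: 19 lower-triangle rows, then frequencies."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            vals = line.split()
            if vals:
                rows.append([float(v) for v in vals])
    tri, freqs = rows[:-1], np.asarray(rows[-1])
    if len(tri) != 19 or any(len(r) != i + 1 for i, r in enumerate(tri)):
        raise ValueError(f"{path}: not a 20-state lower-triangular rate file")
    if freqs.shape != (20,):
        raise ValueError(f"{path}: expected 20 stationary frequencies")
    S = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return S, freqs / freqs.sum()


@dataclass
class SubstitutionModel:
    """Reversible rate matrix Q with stationary frequencies pi.

    ``states`` gives the residue ordering of all matrix axes.
    """

    Q: np.ndarray
    pi: np.ndarray
    name: str = "JTT"
    states: str = AMINO_ACIDS

    # spectral decomposition of the symmetrized generator, filled lazily
    _evals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _left: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _right: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = len(self.pi)
        if self.Q.shape != (n, n):
            raise ValueError("Q and pi dimensions disagree")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1) > 1e-10:
            raise ValueError("pi must be strictly positive and sum to 1")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10:
            raise ValueError("rows of Q must sum to 0")
        self._decompose()

    @classmethod
    def from_exchangeabilities(
        cls, S: np.ndarray, pi: np.ndarray, name: str = "custom"
    ) -> "SubstitutionModel":
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = np.asarray(S, dtype=float) * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))  # expected rate
        return cls(Q=Q / mu, pi=pi, name=name)

    def _decompose(self) -> None:
        sqrt_pi = np.sqrt(self.pi)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        evals, U = np.linalg.eigh((B + B.T) / 2)
        self._evals = evals
        self._right = U / sqrt_pi[:, None] * 1.0  # D^{-1/2} U
        self._left = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0 for roundoff."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._right * np.exp(self._evals * t)) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def state_index(self, residue: str) -> int:
        i = self.states.find(residue)
        if i < 0:
            raise KeyError(f"unknown residue {residue!r}")
        return i

    @property
    def rate(self) -> float:
        """Expected substitutions per site per unit time (1 by construction)."""
        return -float(np.dot(self.pi, np.diag(self.Q)))


def jtt_model() -> SubstitutionModel:
    """The bundled Jones-Taylor-Thornton model, normalized to unit rate."""
    with resources.as_file(
        resources.files("phylofold").joinpath("data/jtt.dat")
    ) as p:
        S, pi = load_paml_dat(p)
    return SubstitutionModel.from_exchangeabilities(S, pi, name="JTT")
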
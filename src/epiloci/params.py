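"""Gauge-fixed fields/couplings container shared by the simulator and the fitter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: number of genotype levels per coding scheme
CODING_LEVELS = {"genotypic": 3, "dominant": 2, "recessive": 2}


@dataclass
class PottsParams:
    """Fields ``h_i(a)`` and pairwise couplings ``J_ij(a,b)`` over genotype levels.

    Gauge convention: the reference level 0 carries zero parameters,
    ``h_i(0) = 0`` and ``J_ij(a,0) = J_ij(0,b) = 0``; couplings are symmetric,
    ``J_ij(a,b) = J_ji(b,a)``, with zero diagonal blocks.

    ``h`` has shape (m, L); ``J`` has shape (m, m, L, L).
    """

    coding: str
    h: np.ndarray
    J: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        m, L = self.h.shape
        if CODING_LEVELS[self.coding] != L:
            raise ValueError(f"{self.coding} coding requires {CODING_LEVELS[self.coding]} levels")
        if self.J is None:
            self.J = np.zeros((m, m, L, L))
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (m, m, L, L):
            raise ValueError("J must have shape (m, m, L, L)")
        self.validate()

    def validate(self) -> None:
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("non-finite parameters")
        if not np.allclose(self.h[:, 0], 0.0):
            raise ValueError("gauge violated: h(0) != 0")
        if not (np.allclose(self.J[:, :, 0, :], 0.0) and np.allclose(self.J[:, :, :, 0], 0.0)):
            raise ValueError("gauge violated: J at level 0 != 0")
        if not np.allclose(self.J, self.J.transpose(1, 0, 3, 2)):
            raise ValueError("couplings not symmetric")
        m = self.h.shape[0]
        if not np.allclose(self.J[np.arange(m), np.arange(m)], 0.0):
            raise ValueError("self-couplings must be zero")

    @property
    def n_snps(self) -> int:
        return self.h.shape[0]

    @property
    def n_levels(self) -> int:
        return self.h.shape[1]

    @classmethod
    def zeros(cls, m: int, coding: str = "genotypic") -> "PottsParams":
        L = CODING_LEVELS[coding]
        return cls(coding, np.zeros((m, L)))

    @classmethod
    def from_marginals(cls, probs: np.ndarray, coding: str = "genotypic") -> "PottsParams":
        """Independent-SNP fields reproducing the given level probabilities."""
        probs = np.asarray(probs, dtype=float)
        if np.any(probs <= 0):
            raise ValueError("marginal probabilities must be strictly positive")
        h = np.log(probs / probs[:, [0]])
        return cls(coding, h)

    def coupling_dense(self) -> np.ndarray:
        """Couplings at non-reference levels as a (m(L-1), m(L-1)) matrix."""
        m, L = self.h.shape
        d = m * (L - 1)
        return self.J[:, :, 1:, 1:].transpose(0, 2, 1, 3).reshape(d, d)

    def field_vector(self) -> np.ndarray:
        """Fields at non-reference levels as a flat m(L-1) vector."""
        return self.h[:, 1:].ravel()
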
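"""The 20-state general time-reversible substitution model components.

An exchangeability matrix R is the symmetric, frequency-independent part
of the instantaneous rate matrix: Q = R * diag(pi), with the diagonal of
Q set so rows sum to zero and the whole matrix conventionally rescaled so
the mean substitution rate at stationarity, -sum_i pi_i q_ii, is one
(branch lengths then read as expected substitutions per site).  R is only
defined up to a positive scale; 189 of its 190 off-diagonal pairs are
free parameters once one reference pair is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, MISSING_CODE
from .properties import AMINO_ACIDS

__all__ = [
    "ExchangeabilityMatrix",
    "RateMatrix",
    "N_STATES",
    "N_PAIRS",
    "PAIR_INDEX",
    "REFERENCE_PAIR",
    "pair_values",
    "matrix_from_pairs",
    "empirical_frequencies",
    "validate_frequencies",
    "build_rate_matrix",
    "transition_matrix",
    "read_paml_matrix",
    "write_paml_matrix",
]

N_STATES = 20
N_PAIRS = 190

#: Lower-triangular pair order (row-major, the PAML .dat layout).
PAIR_INDEX = np.tril_indices(N_STATES, -1)

#: The pair whose exchangeability is held fixed during optimisation:
#: (W, V) in the canonical residue order.
REFERENCE_PAIR = (AMINO_ACIDS.index("V"), AMINO_ACIDS.index("W"))  # (19, 17)

_REFERENCE_FLAT = int(
    np.nonzero((PAIR_INDEX[0] == REFERENCE_PAIR[0]) & (PAIR_INDEX[1] == REFERENCE_PAIR[1]))[0][0]
)


def pair_values(matrix: np.ndarray) -> np.ndarray:
    """The 190 off-diagonal pair entries in canonical (PAML) order."""
    return np.asarray(matrix, dtype=float)[PAIR_INDEX]


def matrix_from_pairs(pairs: np.ndarray) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape != (N_PAIRS,):
        raise ValueError(f"expected {N_PAIRS} pair values, got {pairs.shape}")
    m = np.zeros((N_STATES, N_STATES))
    m[PAIR_INDEX] = pairs
    return m + m.T


@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric 20x20 exchangeability matrix with zero diagonal."""

    matrix: np.ndarray
    reference_pair: tuple = REFERENCE_PAIR

    def __post_init__(self):
        m = np.array(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(m[PAIR_INDEX] < 0):
            raise ValueError("exchangeabilities must be non-negative")
        np.fill_diagonal(m, 0.0)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_pairs(cls, pairs) -> "ExchangeabilityMatrix":
        return cls(matrix_from_pairs(pairs))

    @classmethod
    def flat(cls) -> "ExchangeabilityMatrix":
        """All pairwise exchangeabilities equal (the uninformative start)."""
        return cls.from_pairs(np.ones(N_PAIRS))

    @classmethod
    def random(cls, seed=None, sd=1.0) -> "ExchangeabilityMatrix":
        """Log-normal random exchangeabilities (testing / fixtures)."""
        rng = np.random.default_rng(seed)
        return cls.from_pairs(np.exp(rng.normal(0.0, sd, size=N_PAIRS)))

    @property
    def pairs(self) -> np.ndarray:
        return pair_values(self.matrix)

    def scaled(self, c: float) -> "ExchangeabilityMatrix":
        if c <= 0:
            raise ValueError("scale must be positive")
        return ExchangeabilityMatrix(self.matrix * c, self.reference_pair)

    def mean_rate(self, pi) -> float:
        """Mean substitution rate of R*diag(pi) before normalisation."""
        pi = np.asarray(pi, dtype=float)
        q_off = self.matrix * pi[None, :]
        return float(np.sum(pi[:, None] * q_off))

    def rescaled_to_mean_rate(self, pi) -> "ExchangeabilityMatrix":
        """Rescale so Q = R*diag(pi) has mean rate one (for comparisons)."""
        mu = self.mean_rate(pi)
        if mu <= 0:
            raise ValueError("degenerate matrix: zero mean rate")
        return self.scaled(1.0 / mu)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


@dataclass(frozen=True)
class RateMatrix:
    """Normalised instantaneous rate matrix Q with its scale constant.

    ``scale`` is the factor by which the raw R*diag(pi) rates were divided
    to reach a mean rate of one.
    """

    q: np.ndarray
    pi: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        q = np.array(self.q, dtype=float)
        pi = np.array(self.pi, dtype=float)
        q.setflags(write=False)
        pi.setflags(write=False)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "pi", pi)

    @property
    def mean_rate(self) -> float:
        return float(-np.sum(self.pi * np.diag(self.q)))


def validate_frequencies(pi) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_STATES,):
        raise ValueError("frequency vector must have 20 entries")
    if np.any(pi < 0):
        raise ValueError("negative frequency")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError(f"frequencies sum to {pi.sum()!r}, not 1")
    return pi


def empirical_frequencies(msa: Alignment, pseudocount: float = 1e-6) -> np.ndarray:
    """Empirical amino-acid frequencies of an alignment (+F convention).

    Gaps and ambiguity codes are excluded from the counts.  A small
    pseudocount keeps every frequency strictly positive even for subsets
    dominated by a handful of residues.
    """
    codes = msa.codes()
    observed = codes[codes != MISSING_CODE]
    if observed.size == 0:
        raise ValueError("alignment subset contains no canonical residue")
    counts = np.bincount(observed, minlength=N_STATES).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def build_rate_matrix(R: ExchangeabilityMatrix, pi, normalize: bool = True) -> RateMatrix:
    """Assemble Q = R * diag(pi), zero row sums, mean rate one.

    Detailed balance pi_i q_ij = pi_j q_ji holds by construction.
    """
    if isinstance(R, np.ndarray):
        R = ExchangeabilityMatrix(R)
    pi = validate_frequencies(pi)
    if np.any(pi == 0):
        bad = np.nonzero(pi == 0)[0]
        raise ValueError(
            "zero equilibrium frequency for "
            + ",".join(AMINO_ACIDS[i] for i in bad)
            + "; estimate frequencies with a pseudocount"
        )
    q = R.matrix * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = float(-np.sum(pi * np.diag(q)))
    if normalize:
        if mu <= 0:
            raise ValueError("degenerate rate matrix: zero mean rate")
        q = q / mu
        return RateMatrix(q, pi, scale=mu)
    return RateMatrix(q, pi, scale=1.0)


class _Eigensystem:
    """Spectral decomposition of a reversible Q via its symmetrisation.

    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric; with B = V L V',
    Q = S L S^{-1} where S = diag(1/sqrt(pi)) V.  P(t) = S exp(L t) S^{-1}
    is then numerically stable for any t >= 0.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.S = V / sqrt_pi[:, None]
        self.Sinv = V.T * sqrt_pi[None, :]

    def expm(self, t: float) -> np.ndarray:
        P = (self.S * np.exp(self.lam * t)[None, :]) @ self.Sinv
        np.clip(P, 0.0, None, out=P)
        # renormalise away the eigen-roundoff so rows sum to exactly 1
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt): row-stochastic 20x20 transition probabilities."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    return _Eigensystem(Q.q, Q.pi).expm(t)


# -- PAML .dat layout ---------------------------------------------------


def write_paml_matrix(R: ExchangeabilityMatrix, pi, path) -> None:
    """Write 19 lower-triangular exchangeability rows plus 20 frequencies."""
    pi = validate_frequencies(pi)
    lines = []
    for i in range(1, N_STATES):
        lines.append(" ".join(f"{R.matrix[i, j]:.6f}" for j in range(i)))
    lines.append("")
    lines.append(" ".join(f"{p:.6f}" for p in pi))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_paml_matrix(path):
    """Read a PAML-style .dat file -> (ExchangeabilityMatrix, pi or None)."""
    tokens = []
    with open(path) as fh:
        for line in fh:
            stripped = line.split("#")[0].strip()
            if stripped:
                tokens.extend(stripped.split())
    values = []
    for tok in tokens:
        try:
            values.append(float(tok))
        except ValueError:
            break  # trailing annotation (residue labels etc.)
    if len(values) < N_PAIRS:
        # report the first incomplete triangular row
        total, row = 0, 1
        while total + row <= len(values):
            total += row
            row += 1
        raise ValueError(
            f"{path}: truncated exchangeability triangle at row {row} "
            f"({len(values)} of {N_PAIRS} values)"
        )
    tri = np.zeros((N_STATES, N_STATES))
    pos = 0
    for i in range(1, N_STATES):
        tri[i, :i] = values[pos : pos + i]
        pos += i
    R = ExchangeabilityMatrix(tri + tri.T)
    rest = values[pos:]
    pi = None
    if len(rest) >= N_STATES:
        pi = np.asarray(rest[:N_STATES], dtype=float)
        pi = pi / pi.sum()
    return R, pi
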
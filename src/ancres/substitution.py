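"""Amino-acid substitution model: LG exchangeabilities, equilibrium
frequencies, discrete-gamma rate heterogeneity, and transition matrices.

The model is a general time-reversible continuous-time Markov chain on the
20 amino acids.  A symmetric exchangeability matrix ``S`` and an equilibrium
frequency vector ``pi`` define the instantaneous rate matrix

    Q_ij = S_ij * pi_j   (i != j),      Q_ii = -sum_{j!=i} Q_ij,

rescaled so that ``-sum_i pi_i Q_ii = 1``, i.e. branch lengths are expected
substitutions per site.  Among-site rate variation uses the discrete-gamma
approximation: a unit-mean gamma(alpha, alpha) split into K equal-probability
bins, each represented by its conditional mean rate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

#: Canonical amino-acid ordering (PAML / most empirical matrices).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20

#: Integer codes for non-residue symbols; both are treated as missing data
#: in likelihood computations.
GAP_CODE = 20
UNKNOWN_CODE = 21

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_residue(symbol: str) -> int:
    """Map a one-letter residue symbol to its integer code.

    Gaps ('-', '.') map to ``GAP_CODE``; any symbol outside the 20-letter
    alphabet (e.g. 'X', 'B', 'Z') maps to ``UNKNOWN_CODE``.
    """
    s = symbol.upper()
    if s in _AA_INDEX:
        return _AA_INDEX[s]
    if s in ("-", "."):
        return GAP_CODE
    return UNKNOWN_CODE


def load_paml_matrix(path=None) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-format empirical matrix file.

    The format is 19 rows of lower-triangle exchangeabilities followed by a
    row of 20 equilibrium frequencies, whitespace-delimited.  Returns the
    symmetric 20x20 exchangeability matrix and the frequency vector.  With no
    path, the vendored LG file is read.
    """
    if path is None:
        ref = importlib.resources.files("ancres.data") / "lg.dat"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    values = [float(tok) for tok in text.split()]
    if len(values) < 190 + N_STATES:
        raise ValueError(
            f"empirical matrix file needs 190 exchangeabilities + 20 "
            f"frequencies, found {len(values)} numbers"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.asarray(values[k : k + N_STATES])
    pi = pi / pi.sum()
    return S, pi


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Assemble the reversible rate matrix Q from exchangeabilities and
    frequencies, normalised to one expected substitution per unit time.
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ValueError("S must be 20x20")
    if not np.allclose(S, S.T):
        raise ValueError("exchangeability matrix must be symmetric")
    if np.any(pi <= 0):
        raise ValueError("equilibrium frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("equilibrium frequencies must sum to 1")
    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))  # expected rate
    return Q / mu


def discretize_gamma(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma rates (conditional bin means).

    A unit-mean gamma with shape ``alpha`` is split into ``n_categories``
    equal-probability bins; each category rate is the mean of its bin, so the
    weighted mean of the rates is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    K = n_categories
    if K == 1:
        return np.ones(1)
    # Bin edges are gamma quantiles; with shape=a, rate=a the mean is 1 and
    # E[X; X<x] = P(a+1, a*x) with P the regularised lower incomplete gamma.
    probs = np.arange(1, K) / K
    edges = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges)])
    rates = K * (upper - lower)
    return rates


@dataclass
class SubstitutionModel:
    """A reversible amino-acid CTMC with discrete-gamma rate categories.

    Parameters
    ----------
    S : 20x20 symmetric exchangeability matrix.
    pi : equilibrium frequency vector.
    alpha : gamma shape for among-site rate variation.
    n_categories : number of equal-probability rate categories (K).
    """

    S: np.ndarray
    pi: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    Q: np.ndarray = field(init=False, repr=False)
    rates: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = build_rate_matrix(self.S, self.pi)
        self.rates = discretize_gamma(self.alpha, self.n_categories)
        self.weights = np.full(self.n_categories, 1.0 / self.n_categories)
        # Symmetrised generator B = D^{1/2} Q D^{-1/2} is symmetric for a
        # reversible chain; its eigendecomposition gives stable matrix
        # exponentials for any branch length.
        sqrt_pi = np.sqrt(self.pi)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]          # U^T D^{1/2}
        self._right = eigvec / sqrt_pi[:, None]           # D^{-1/2} U

    @classmethod
    def lg(cls, alpha: float = 1.0, n_categories: int = 4,
           frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        """The LG model, optionally with replacement (+F) frequencies."""
        S, pi = load_paml_matrix()
        if frequencies is not None:
            pi = np.asarray(frequencies, dtype=float)
            pi = pi / pi.sum()
        return cls(S=S, pi=pi, alpha=alpha, n_categories=n_categories)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(S=self.S, pi=self.pi, alpha=alpha,
                                 n_categories=self.n_categories)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if rate <= 0:
            raise ValueError("category rate must be positive")
        expd = np.exp(self._eigval * (rate * t))
        P = self._right @ (expd[:, None] * self._left)
        np.clip(P, 0.0, None, out=P)
        # renormalise away eigendecomposition round-off
        P /= P.sum(axis=1, keepdims=True)
        return P


def empirical_frequencies(alignment, pseudocount: float = 1e-6) -> np.ndarray:
    """Observed amino-acid frequencies of an alignment (+F), gaps excluded.

    A small pseudocount keeps unobserved residues at non-zero frequency so the
    reversible rate matrix stays well defined.
    """
    counts = np.full(N_STATES, pseudocount)
    codes = alignment.codes
    observed = codes[codes < N_STATES]
    counts += np.bincount(observed, minlength=N_STATES)
    return counts / counts.sum()
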
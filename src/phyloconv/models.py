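"""Substitution models: WAG/JTT empirical amino-acid matrices, HKY for
nucleotides, empirical ("f_genes") frequency estimation, and discrete-gamma
rate heterogeneity.

The WAG and JTT exchangeabilities and default frequencies are shipped as
packaged text files in PAML matrix format (lower-triangle exchangeabilities
followed by a frequency line), state order ARNDCQEGHILKMFPSTWYV.  Rate
matrices are assembled as q_ij = s_ij * pi_j and normalized so the mean rate
at stationarity is one substitution per site, so branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import ModelError
from .seqio import AA_STATES, DNA_STATES, Alignment

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _load_paml_matrix(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-format amino-acid matrix file from the packaged data."""
    text = (
        resources.files("phyloconv.data").joinpath(name).read_text().split()
    )
    vals = [float(x) for x in text]
    if len(vals) != 190 + 20:
        raise ModelError(f"{name}: expected 190 exchangeabilities + 20 freqs")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    freqs = np.array(vals[190:])
    freqs = freqs / freqs.sum()
    return S, freqs


@dataclass
class SubstitutionModel:
    """A reversible CTMC substitution model with optional discrete-gamma
    among-site rate variation (equal-probability categories)."""

    kind: str  # "WAG" | "JTT" | "HKY"
    alphabet_tag: str  # "aa" | "dna"
    states: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if abs(f.sum() - 1.0) > 1e-12:
            f = f / f.sum()
        if np.any(f <= 0):
            raise ModelError("all equilibrium frequencies must be positive")
        self.frequencies = f
        S = np.asarray(self.exchangeabilities, dtype=float)
        if not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric")
        self.exchangeabilities = S
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ModelError("need at least one rate category")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero and mean rate normalized to 1."""
        S, pi = self.exchangeabilities, self.frequencies
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        return discrete_gamma(self.gamma_shape, self.n_rate_categories)

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the symmetrized similarity transform,
        returning (eigenvalues, left, right) with P(t) = left @ diag(exp(w t)) @ right."""
        if self._eigen is None:
            Q = self.rate_matrix
            sqrt_pi = np.sqrt(self.frequencies)
            B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            B = (B + B.T) / 2.0  # enforce exact symmetry
            w, U = np.linalg.eigh(B)
            left = U / sqrt_pi[:, None]
            right = U.T * sqrt_pi[None, :]
            self._eigen = (w, left, right)
        return self._eigen

    def with_gamma_shape(self, alpha: float) -> "SubstitutionModel":
        """Copy sharing the (cached) rate matrix but a new gamma shape."""
        m = SubstitutionModel(
            self.kind,
            self.alphabet_tag,
            self.states,
            self.exchangeabilities,
            self.frequencies,
            gamma_shape=alpha,
            n_rate_categories=self.n_rate_categories,
        )
        m._eigen = self._eigen or self.eigen()
        return m


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (bin means), mean
    renormalized to exactly 1."""
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return np.array([1.0])
    # X ~ Gamma(alpha, rate=alpha) has mean 1; bin mean over (q_i, q_{i+1})
    # is k * [I(alpha+1, alpha*q_{i+1}) - I(alpha+1, alpha*q_i)].
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * edges)])
    rates = k * (upper - lower)
    return rates / rates.mean()


def empirical_aa_frequencies(
    aln: Alignment, pseudocount: float = 0.1
) -> np.ndarray:
    """Observed amino-acid proportions with a pseudocount floor per symbol
    (gaps and ambiguity codes are ignored)."""
    counts = np.zeros(20)
    index = {a: i for i, a in enumerate(AA_STATES)}
    for sym, n in zip(*np.unique(aln.columns, return_counts=True)):
        if sym in index:
            counts[index[sym]] += n
    counts = counts + pseudocount
    if np.any(counts <= 0):
        raise ModelError(
            "zero observed frequency with no pseudocount; increase pseudocount"
        )
    return counts / counts.sum()


def _hky_exchangeabilities(kappa: float) -> np.ndarray:
    S = np.ones((4, 4))
    np.fill_diagonal(S, 0.0)
    for i, a in enumerate(DNA_STATES):
        for j, b in enumerate(DNA_STATES):
            if i != j and (
                (a in _PURINES and b in _PURINES)
                or (a in _PYRIMIDINES and b in _PYRIMIDINES)
            ):
                S[i, j] = kappa
    return S


def build_model(
    kind: str,
    frequencies: str | np.ndarray = "model",
    alignment: Alignment | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 4,
    kappa: float = 2.0,
    pseudocount: float = 0.1,
) -> SubstitutionModel:
    """Assemble a substitution model.

    ``frequencies`` is ``"model"`` (matrix-file defaults for WAG/JTT, uniform
    for HKY), ``"empirical"`` (estimated from ``alignment`` with a pseudocount
    floor — the "f_genes" convention), or an explicit simplex vector.
    """
    kind = kind.upper()
    if kind in ("WAG", "JTT"):
        S, default_freqs = _load_paml_matrix(
            "wag.dat" if kind == "WAG" else "jtt.dat"
        )
        states, tag = AA_STATES, "aa"
    elif kind == "HKY":
        S = _hky_exchangeabilities(kappa)
        default_freqs = np.full(4, 0.25)
        states, tag = DNA_STATES, "dna"
    else:
        raise ModelError(f"unknown model kind {kind!r}")

    if isinstance(frequencies, str):
        if frequencies == "model":
            freqs = default_freqs
        elif frequencies == "empirical":
            if alignment is None:
                raise ModelError("empirical frequencies require an alignment")
            if tag == "aa":
                freqs = empirical_aa_frequencies(alignment, pseudocount)
            else:
                counts = np.array(
                    [
                        np.sum(alignment.columns == b)
                        for b in DNA_STATES
                    ],
                    dtype=float,
                )
                counts += pseudocount
                freqs = counts / counts.sum()
        else:
            raise ModelError(f"unknown frequency mode {frequencies!r}")
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if len(freqs) != len(states):
            raise ModelError("frequency vector length mismatch")

    return SubstitutionModel(
        kind, tag, states, S, freqs, gamma_shape=gamma_shape,
        n_rate_categories=n_categories,
    )
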
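"""Nucleotide substitution models shared by the simulator and the likelihood engine.

The general time-reversible (GTR) model is parameterised by six symmetric
exchangeabilities (order AC, AG, AT, CG, CT, GT), four stationary base
frequencies, and an optional gamma shape ``alpha`` for among-site rate
heterogeneity discretised into ``ncat`` equal-weight categories.  The rate
matrix is always rescaled so that branch lengths are expected substitutions
per site at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: integer code for a fully ambiguous character (N, gap, anything non-ACGT)
AMBIGUOUS = 4
RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_RATE_POS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRModel:
    rates: tuple = (1.0,) * 6
    freqs: tuple = (0.25,) * 4
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self):
        if len(self.rates) != 6:
            raise ValueError("GTR needs six exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if len(self.freqs) != 4:
            raise ValueError("GTR needs four base frequencies")
        if any(r <= 0 for r in self.rates):
            raise ValueError("exchangeabilities must be positive")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("base frequencies must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")

    def with_alpha(self, alpha):
        return replace(self, alpha=alpha)

    def with_rates(self, rates):
        return replace(self, rates=tuple(rates))


def equal_rates_model(alpha=None, ncat: int = 4) -> GTRModel:
    """Equal exchangeabilities and frequencies (JC-like), optional gamma."""
    return GTRModel(alpha=alpha, ncat=ncat)


def rate_matrix(model: GTRModel) -> np.ndarray:
    """Instantaneous rate matrix Q, scaled to one expected substitution/site."""
    pi = np.asarray(model.freqs, dtype=float)
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, _RATE_POS):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def discrete_gamma_rates(alpha: float | None, ncat: int) -> np.ndarray:
    """Median-of-quantile discrete gamma rates, normalised to mean 1."""
    if alpha is None:
        return np.ones(1)
    q = _gamma_dist.ppf((2 * np.arange(ncat) + 1.0) / (2 * ncat), a=alpha, scale=1.0 / alpha)
    return q / q.mean()


class TransitionCalculator:
    """Eigendecomposition-backed P(t) for a GTR(+gamma) model.

    ``probs(t)`` returns an (ncat, 4, 4) stack of transition matrices, one per
    discrete rate category (a single category when ``alpha`` is None).
    """

    def __init__(self, model: GTRModel):
        self.model = model
        self.pi = np.asarray(model.freqs, dtype=float)
        Q = rate_matrix(model)
        d = np.sqrt(self.pi)
        A = Q * d[:, None] / d[None, :]
        w, U = np.linalg.eigh((A + A.T) / 2.0)
        self._eigvals = w
        self._left = U / d[:, None]          # diag(1/sqrt(pi)) @ U
        self._right = (U * d[:, None]).T     # U.T @ diag(sqrt(pi))
        self.rates = discrete_gamma_rates(model.alpha, model.ncat)
        self.weights = np.full(len(self.rates), 1.0 / len(self.rates))

    def probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        e = np.exp(np.outer(self.rates * t, self._eigvals))  # (ncat, 4)
        P = np.einsum("ik,ck,kj->cij", self._left, e, self._right)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def probs_single(self, t: float, rate: float = 1.0) -> np.ndarray:
        """One 4x4 transition matrix at relative rate ``rate``."""
        e = np.exp(self._eigvals * (t * rate))
        P = (self._left * e[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def encode_sequence(seq) -> np.ndarray:
    """ACGT string (or iterable) -> uint8 codes; anything else -> AMBIGUOUS."""
    if isinstance(seq, np.ndarray) and seq.dtype == np.uint8:
        return seq
    arr = np.frombuffer(str(seq).upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, AMBIGUOUS, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def decode_sequence(codes: np.ndarray, missing: str = "N") -> str:
    lut = np.array(list(BASES + missing))
    return "".join(lut[np.minimum(codes, AMBIGUOUS)])
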
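"""Nucleotide substitution models: JC69 / K80 / HKY85 / TN93 / GTR, with
optional invariant-sites (+I) and discrete-gamma (+G) among-site rate
variation.

Rate matrices follow the standard GTR parameterization
``Q[i,j] = s_ij * pi_j`` (exchangeabilities ``s`` in the fixed order
AC, AG, AT, CG, CT, GT), scaled so the expected substitution rate at
stationarity is 1 — branch lengths are then expected substitutions per
site. ``+G`` uses Yang's mean-of-category discretization with ``k``
equal-probability bins; ``+I`` adds a zero-rate class of weight ``I``
with the gamma classes reweighted to ``(1 - I)/k``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.linalg import eigh
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SubstitutionModel",
    "discrete_gamma_rates",
    "model_from_id",
    "FAMILIES",
    "STATES",
]

STATES = "ACGT"
#: exchangeability index order
PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
#: transitions are AG (index 1) and CT (index 4)
_TRANSITIONS = (1, 4)

#: free parameters beyond equal-frequency JC69 (frequencies count 3,
#: exchangeabilities count per family)
FAMILIES = {
    "JC69": {"free_freqs": False, "n_exch": 0},
    "K80": {"free_freqs": False, "n_exch": 1},
    "HKY85": {"free_freqs": True, "n_exch": 1},
    "TN93": {"free_freqs": True, "n_exch": 2},
    "GTR": {"free_freqs": True, "n_exch": 5},
}


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-category discretization of a mean-1 gamma distribution.

    The rate axis is cut at the ``i/k`` quantiles of Gamma(alpha, alpha);
    each category's rate is the conditional mean within its bin, computed
    from the regularized incomplete gamma function, so the category mean is
    exactly 1. Rates are returned sorted ascending.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts * alpha, [np.inf]])
    # E[X · 1{a<X<b}] for X~Gamma(alpha, 1) equals the increment of the
    # regularized incomplete gamma with shape alpha+1 (times alpha).
    upper = gammainc(alpha + 1, bounds[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1, bounds[:-1])
    rates = (upper - lower) * k
    rates /= rates.mean()  # remove last-digit drift; analytically mean 1
    return rates


@dataclass(frozen=True)
class SubstitutionModel:
    """A (possibly +I/+G) nucleotide model on the unrooted-tree likelihood."""

    family: str = "JC69"
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    p_inv: float = 0.0
    alpha: Optional[float] = None
    n_categories: int = 4

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        freqs = np.asarray(self.base_freqs, float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
            raise ValueError(f"base frequencies must be 4 positives summing to 1")
        if len(self.exchangeabilities) != 6 or min(self.exchangeabilities) <= 0:
            raise ValueError("need 6 positive exchangeabilities")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError(f"p_inv must be in [0, 1), got {self.p_inv}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"gamma shape must be positive, got {self.alpha}")
        if not FAMILIES[self.family]["free_freqs"]:
            if not np.allclose(freqs, 0.25, atol=1e-9):
                raise ValueError(f"{self.family} requires equal base frequencies")

    # ------------------------------------------------------------ identifiers
    @property
    def model_id(self) -> str:
        name = self.family
        if self.p_inv > 0:
            name += "+I"
        if self.alpha is not None:
            name += "+G"
        return name

    @property
    def n_free_params(self) -> int:
        spec = FAMILIES[self.family]
        n = spec["n_exch"] + (3 if spec["free_freqs"] else 0)
        if self.p_inv > 0:
            n += 1
        if self.alpha is not None:
            n += 1
        return n

    # ---------------------------------------------------------------- algebra
    def rate_matrix(self) -> np.ndarray:
        """4x4 generator, scaled to mean rate 1 at stationarity."""
        freqs = np.asarray(self.base_freqs, float)
        q = np.zeros((4, 4))
        for (a, b), s in zip(PAIRS, self.exchangeabilities):
            i, j = STATES.index(a), STATES.index(b)
            q[i, j] = s * freqs[j]
            q[j, i] = s * freqs[i]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(freqs, np.diag(q))
        return q / mu

    def eigen(self):
        """(left, eigenvalues, right) with P(t) = left @ diag(e^{λt}) @ right."""
        freqs = np.asarray(self.base_freqs, float)
        sq = np.sqrt(freqs)
        sym = self.rate_matrix() * sq[:, None] / sq[None, :]
        lam, u = eigh((sym + sym.T) / 2.0)
        left = u / sq[:, None]
        right = u.T * sq[None, :]
        return left, lam, right

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) over the +I/+G site-rate mixture."""
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.n_categories)
        weights = np.full(len(rates), (1.0 - self.p_inv) / len(rates))
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], rates])
            weights = np.concatenate([[self.p_inv], weights])
        # rescale so the mixture mean rate is 1 (branch lengths stay in
        # expected substitutions per site under the full mixture)
        mean = float(np.dot(rates, weights))
        return rates / mean, weights

    def with_params(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)


def model_from_id(
    model_id: str,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    kappa: float = 2.0,
    exchangeabilities=None,
    p_inv: float = 0.0,
    alpha: Optional[float] = None,
    n_categories: int = 4,
) -> SubstitutionModel:
    """Build a model from an identifier such as ``"HKY85+I+G"``.

    ``kappa`` fills the transition exchangeabilities for K80/HKY85 (and both
    transition rates for TN93 unless explicit exchangeabilities are given).
    """
    parts = model_id.split("+")
    family = parts[0]
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    has_i = "I" in parts[1:]
    has_g = "G" in parts[1:]
    if exchangeabilities is None:
        ex = [1.0] * 6
        if family in ("K80", "HKY85", "TN93"):
            ex[1] = ex[4] = kappa
        exchangeabilities = tuple(ex)
    if not FAMILIES[family]["free_freqs"]:
        base_freqs = (0.25, 0.25, 0.25, 0.25)
    return SubstitutionModel(
        family=family,
        base_freqs=tuple(base_freqs),
        exchangeabilities=tuple(exchangeabilities),
        p_inv=p_inv if has_i else 0.0,
        alpha=(alpha if alpha is not None else 0.5) if has_g else None,
        n_categories=n_categories,
    )
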
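"""Combining discrete p-values from multiple experiments.

Monte Carlo tests with n control samples (such as the toroidal-shift
test) yield p-values on the discrete grid {i/(n+1)}.  Taking the minimum
p over m experiments inflates the type I error — for m = 10 independent
null experiments at alpha = 0.05 the chance of at least one "significant"
result is 1 - 0.95^10 ≈ 0.40 — and the classical continuous correction
p* = 1 - (1 - p_min)^m breaks down for discrete p-values, whose corrected
minimum is bounded below by 1 - (n/(n+1))^m and therefore drifts to 1 as
m grows.

The discrete-aware alternative implemented here counts how many of the m
per-experiment p-values fall at or below a preset threshold p0 and refers
that count k to a right-sided binomial test:

    p* = P(X >= k),  X ~ Binomial(m, p0).

Under the null the per-experiment p-values are discrete-uniform, so
P(p <= p0) = p0 whenever p0 is an achievable grid value, and p* is valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PValueCollection",
    "CombinedResult",
    "combine_p_binomial",
    "combine_p_values",
    "min_p_correction_continuous",
    "discrete_min_p_lower_bound",
]


@dataclass(frozen=True)
class PValueCollection:
    """Per-experiment p-values with the control count of the generating test.

    ``n_controls`` (optional) is n, the number of Monte Carlo controls per
    experiment; when given, every p-value must sit on the grid {i/(n+1)}.
    ``p0`` is the counting threshold of the binomial combination.
    """

    pvalues: np.ndarray
    p0: float = 0.05
    n_controls: int | None = None

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.pvalues, float))
        if p.size < 1:
            raise ValueError("need at least one p-value")
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if self.n_controls is not None:
            grid = p * (self.n_controls + 1)
            off = np.abs(grid - np.round(grid)) > 1e-6
            if np.any(off):
                raise ValueError(
                    f"p-value {p[off][0]!r} is not a multiple of "
                    f"1/{self.n_controls + 1}")
        object.__setattr__(self, "pvalues", p)

    @property
    def m(self) -> int:
        return int(self.pvalues.size)


@dataclass(frozen=True)
class CombinedResult:
    """Overall p* from the binomial combination of m experiments."""

    p_star: float
    k: int  # number of p-values <= p0
    m: int
    p0: float


def combine_p_binomial(coll: PValueCollection) -> CombinedResult:
    """Right-sided binomial combination of m discrete p-values.

    k = #{p_i <= p0};  p* = P(X >= k) = 1 - sum_{i=0}^{k-1} C(m,i) p0^i (1-p0)^(m-i).
    """
    k = int(np.count_nonzero(coll.pvalues <= coll.p0 + 1e-12))
    p_star = float(stats.binom.sf(k - 1, coll.m, coll.p0))
    return CombinedResult(p_star=p_star, k=k, m=coll.m, p0=coll.p0)


def combine_p_values(pvalues, p0: float = 0.05,
                     n_controls: int | None = None) -> CombinedResult:
    """Convenience wrapper: build the collection and combine in one call."""
    return combine_p_binomial(
        PValueCollection(pvalues=np.asarray(pvalues, float), p0=p0,
                         n_controls=n_controls))


def min_p_correction_continuous(p_min: float, m: int) -> float:
    """Correct the minimum of m *continuous* p-values: 1 - (1 - p_min)^m.

    Valid only for continuously distributed p-values; provided as the
    classical reference the binomial combination replaces.
    """
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - p_min) ** m


def discrete_min_p_lower_bound(n: int, m: int) -> float:
    """Smallest achievable corrected min-p for discrete grids: 1 - (n/(n+1))^m.

    With p-values on {i/(n+1)} the smallest observable p is 1/(n+1), so the
    continuous correction cannot go below this bound, which tends to 1 as
    the number of experiments m grows — the reason the continuous
    correction is useless for Monte Carlo p-values at large m.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    return 1.0 - (n / (n + 1)) ** m
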
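"""Repeated-simulation characterization of significance tests.

Everything a validity or power study needs: rejection-rate estimates with
Wilson confidence intervals, discrete-uniform goodness-of-fit for p-value
histograms, ROC curves from paired null/alternative p-value samples, and
sensitivity grids for the joint (binomial-combined) analysis of multiple
experiments.

A *scenario* is any callable ``scenario(rng) -> p`` that simulates one
experiment and returns its p-value; per-run generators are spawned
deterministically from the master generator, so every estimate is
reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .combine import combine_p_values

__all__ = [
    "SensitivityEstimate",
    "RocCurve",
    "UniformityResult",
    "estimate_rejection_rate",
    "roc_points",
    "uniformity_statistic",
    "sensitivity_grid",
]

logger = logging.getLogger(__name__)

Scenario = Callable[[np.random.Generator], float]


@dataclass(frozen=True)
class SensitivityEstimate:
    """Rejection rate with its Wilson 95% confidence interval."""

    rate: float
    n_runs: int
    wilson_ci: tuple[float, float]
    alpha: float
    scenario_tag: str = ""
    pvalues: np.ndarray | None = None  # per-run p-values, for reuse


@dataclass(frozen=True)
class RocCurve:
    """ROC points (false positive rate, true positive rate) over thresholds."""

    points: np.ndarray  # (K, 2)
    thresholds: np.ndarray  # (K,)

    def area(self) -> float:
        """Trapezoidal area under the step curve, anchored at (0,0) and (1,1)."""
        fpr = np.concatenate([[0.0], self.points[:, 0], [1.0]])
        tpr = np.concatenate([[0.0], self.points[:, 1], [1.0]])
        return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class UniformityResult:
    """Chi-square goodness of fit against the discrete uniform p-value grid."""

    statistic: float
    pvalue: float
    counts: np.ndarray


def estimate_rejection_rate(scenario: Scenario, n_runs: int = 100,
                            alpha: float = 0.05,
                            rng: np.random.Generator | int | None = None,
                            scenario_tag: str = "",
                            n_controls: int | None = None) -> SensitivityEstimate:
    """Fraction of simulated experiments with p <= alpha.

    Under a null scenario this estimates the false positive rate (1 -
    specificity); under an alternative it estimates the sensitivity.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_controls is not None and alpha <= 1.0 / (n_controls + 1):
        logger.warning(
            "alpha=%.4g is at or below the smallest achievable p-value "
            "1/(n+1)=%.4g; the rejection rate will be zero", alpha,
            1.0 / (n_controls + 1))
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pvals = np.empty(n_runs)
    for i, child in enumerate(gen.spawn(n_runs)):
        try:
            pvals[i] = scenario(child)
        except Exception:
            logger.error("scenario failed at run index %d", i)
            raise
    n_reject = int(np.count_nonzero(pvals <= alpha + 1e-12))
    lo, hi = proportion_confint(n_reject, n_runs, alpha=0.05, method="wilson")
    est = SensitivityEstimate(rate=n_reject / n_runs, n_runs=n_runs,
                              wilson_ci=(float(lo), float(hi)), alpha=alpha,
                              scenario_tag=scenario_tag, pvalues=pvals)
    logger.info("scenario %r: rate=%.3f (n=%d, 95%% CI %.3f-%.3f)",
                scenario_tag, est.rate, n_runs, lo, hi)
    return est


def roc_points(null_pvalues: Sequence[float],
               alt_pvalues: Sequence[float]) -> RocCurve:
    """ROC curve of the test viewed as a classifier with threshold alpha.

    For every achievable threshold (the union of the observed p-values)
    the point is (fraction of null p <= alpha, fraction of alternative
    p <= alpha); both coordinates are nondecreasing in alpha.
    """
    null_p = np.asarray(null_pvalues, float)
    alt_p = np.asarray(alt_pvalues, float)
    if len(null_p) == 0 or len(alt_p) == 0:
        raise ValueError("both p-value lists must be non-empty")
    thresholds = np.unique(np.concatenate([null_p, alt_p]))
    null_sorted = np.sort(null_p)
    alt_sorted = np.sort(alt_p)
    fpr = np.searchsorted(null_sorted, thresholds, side="right") / len(null_p)
    tpr = np.searchsorted(alt_sorted, thresholds, side="right") / len(alt_p)
    return RocCurve(points=np.column_stack([fpr, tpr]), thresholds=thresholds)


def uniformity_statistic(pvalues: Sequence[float],
                         n_controls: int) -> UniformityResult:
    """Chi-square GOF of p-values against the discrete uniform on {i/(n+1)}.

    Every p-value must lie on the grid of achievable values of a rank
    test with ``n_controls`` controls; a uniform histogram over the n+1
    grid points is the signature of a valid (exact) discrete p-value.
    """
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    n_bins = n_controls + 1
    scaled = p * n_bins
    idx = np.rint(scaled)
    off = np.abs(scaled - idx) > 1e-6
    if np.any(off):
        raise ValueError(
            f"p-value {p[off][0]!r} is not on the grid {{i/{n_bins}}}")
    idx = idx.astype(int)
    if np.any(idx < 1) or np.any(idx > n_bins):
        raise ValueError("p-values must lie in (0, 1]")
    counts = np.bincount(idx - 1, minlength=n_bins)
    statistic, pvalue = stats.chisquare(counts)
    return UniformityResult(statistic=float(statistic), pvalue=float(pvalue),
                            counts=counts)


def sensitivity_grid(p0_values: Sequence[float], m_values: Sequence[int],
                     scenario: Scenario, n_batches: int = 100,
                     alpha_star: float = 0.05,
                     rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Joint-test sensitivity over a (p0, m) grid.

    For each batch, ``max(m_values)`` independent experiments are
    simulated once and reused across the grid: for every (p0, m) the
    first m per-experiment p-values are combined by the binomial test and
    the batch counts as a rejection when p* <= alpha_star.  Returns a
    DataFrame indexed by p0 with one column per m, holding rejection
    fractions.
    """
    p0_values = list(p0_values)
    m_values = list(m_values)
    if not p0_values or not m_values:
        raise ValueError("p0 and m grids must be non-empty")
    if min(m_values) < 1:
        raise ValueError("m values must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m_max = max(m_values)
    rejections = np.zeros((len(p0_values), len(m_values)))
    for _ in range(n_batches):
        batch_rng = gen.spawn(1)[0]
        pvals = np.array([scenario(child) for child in batch_rng.spawn(m_max)])
        for i, p0 in enumerate(p0_values):
            for j, m in enumerate(m_values):
                res = combine_p_values(pvals[:m], p0=p0)
                if res.p_star <= alpha_star + 1e-12:
                    rejections[i, j] += 1
    grid = pd.DataFrame(rejections / n_batches, index=pd.Index(p0_values, name="p0"),
                        columns=pd.Index(m_values, name="m"))
    return grid
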
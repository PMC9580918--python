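"""Permutation tests for groups of single-molecule trajectories.

Frames within one trajectory are correlated (a molecule dwells in a state
for many frames), so a pointwise permutation test that reassigns frames
individually treats correlated observations as exchangeable and produces
anticonservative p-values — its null distribution of p has excess mass at
small values.  The block permutation test reassigns *whole trajectories*
between the two groups, preserving within-trajectory correlation, and
restores validity.

The test statistic is the difference of the frame-pooled group means,
s = mean(all frames of A) - mean(all frames of B).  The default p-value
estimator is (1 + #{|s_i| >= |s0|}) / (n_perm + 1), which counts the
observed assignment among the permutations and can therefore never be
zero; the raw proportion estimator (strict inequality, no add-one term)
is available via ``add_one=False``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "TrajectoryGroup",
    "PermutationResult",
    "pooled_mean_difference",
    "permutation_test",
    "exact_block_test",
]

logger = logging.getLogger(__name__)

SIDES = ("two", "right", "left")
MODES = ("pointwise", "block")
_EXACT_LIMIT = 100_000


@dataclass
class TrajectoryGroup:
    """A group of per-frame value sequences (e.g. FRET efficiencies)."""

    trajectories: list[np.ndarray] = field(default_factory=list)
    group_label: str = ""

    def __post_init__(self) -> None:
        self.trajectories = [np.atleast_1d(np.asarray(t, float))
                             for t in self.trajectories]
        if any(len(t) < 1 for t in self.trajectories):
            raise ValueError("every trajectory must contain at least one frame")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return int(sum(len(t) for t in self.trajectories))

    def pooled(self) -> np.ndarray:
        """All frames of all trajectories, concatenated (frame-weighted pooling)."""
        if not self.trajectories:
            return np.zeros(0)
        return np.concatenate(self.trajectories)


@dataclass
class PermutationResult:
    """Outcome of a Monte Carlo permutation test."""

    p: float
    s0: float
    s_i: np.ndarray  # (n_perm,) permutation statistics
    mode: str
    n_perm: int
    sided: str
    seed: int | None = None


def pooled_mean_difference(a: TrajectoryGroup, b: TrajectoryGroup) -> float:
    """Difference of frame-pooled means, mean(A frames) - mean(B frames).

    Pooling is frame-weighted: a long trajectory contributes more than a
    short one, exactly as if all frames of a group were one sample.
    """
    pa, pb = a.pooled(), b.pooled()
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both groups must contain at least one data point")
    return float(pa.mean() - pb.mean())


def _count_extreme(s_i: np.ndarray, s0: float, sided: str,
                   strict: bool) -> int:
    # statistics that agree with s0 up to float rounding are genuine ties
    # (discrete data produce them routinely); treat them as such
    tol = 1e-9 * max(abs(s0), 1.0)
    if sided == "two":
        return int(np.count_nonzero(np.abs(s_i) > abs(s0) + tol if strict
                                    else np.abs(s_i) >= abs(s0) - tol))
    if sided == "right":
        return int(np.count_nonzero(s_i > s0 + tol if strict else s_i >= s0 - tol))
    return int(np.count_nonzero(s_i < s0 - tol if strict else s_i <= s0 + tol))


def permutation_test(a: TrajectoryGroup, b: TrajectoryGroup,
                     mode: str = "block", n_perm: int = 1000,
                     sided: str = "two",
                     rng: np.random.Generator | int | None = None,
                     add_one: bool = True) -> PermutationResult:
    """Monte Carlo permutation test of mean(A) == mean(B).

    ``mode="pointwise"`` reassigns individual frames to pseudo-groups of
    the original pooled frame counts; ``mode="block"`` reassigns whole
    trajectories, preserving the trajectory counts per group.  Use block
    mode whenever frames within a trajectory are correlated.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if sided not in SIDES:
        raise ValueError(f"sided must be one of {SIDES}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    s0 = pooled_mean_difference(a, b)
    s_i = np.empty(n_perm)
    if mode == "pointwise":
        pooled = np.concatenate([a.pooled(), b.pooled()])
        n_a = a.n_frames
        total = float(pooled.sum())
        n_b = len(pooled) - n_a
        for i in range(n_perm):
            idx = gen.permutation(len(pooled))
            sum_a = float(pooled[idx[:n_a]].sum())
            s_i[i] = sum_a / n_a - (total - sum_a) / n_b
    else:
        if len(a) + len(b) < 2:
            raise ValueError("block mode needs at least two trajectories in total")
        t_sums = np.array([t.sum() for t in (*a.trajectories, *b.trajectories)])
        t_lens = np.array([len(t) for t in (*a.trajectories, *b.trajectories)],
                          dtype=float)
        n_a_traj = len(a)
        total_sum, total_len = float(t_sums.sum()), float(t_lens.sum())
        for i in range(n_perm):
            idx = gen.permutation(len(t_sums))
            sel = idx[:n_a_traj]
            sum_a, len_a = float(t_sums[sel].sum()), float(t_lens[sel].sum())
            s_i[i] = sum_a / len_a - (total_sum - sum_a) / (total_len - len_a)

    count = _count_extreme(s_i, s0, sided, strict=not add_one)
    p = (1 + count) / (n_perm + 1) if add_one else count / n_perm
    logger.info("%s permutation test: s0=%.4g, n_perm=%d, %s-sided p=%.4g",
                mode, s0, n_perm, sided, p)
    return PermutationResult(p=p, s0=s0, s_i=s_i, mode=mode, n_perm=n_perm,
                             sided=sided, seed=seed)


def exact_block_test(a: TrajectoryGroup, b: TrajectoryGroup,
                     sided: str = "two") -> float:
    """Exact block permutation p-value by full enumeration.

    Enumerates every assignment of the pooled trajectories into groups of
    the original sizes; p is the fraction of assignments whose statistic
    is at least as extreme as the observed one (which is itself one of
    them, so p > 0).  Limited to C(n_A+n_B, n_A) <= 1e5 assignments.
    """
    if sided not in SIDES:
        raise ValueError(f"sided must be one of {SIDES}")
    s0 = pooled_mean_difference(a, b)
    t_sums = np.array([t.sum() for t in (*a.trajectories, *b.trajectories)])
    t_lens = np.array([len(t) for t in (*a.trajectories, *b.trajectories)],
                      dtype=float)
    n_total, n_a = len(t_sums), len(a)
    n_assign = comb(n_total, n_a)
    if n_assign > _EXACT_LIMIT:
        raise ValueError(
            f"{n_assign} assignments exceed the enumeration limit "
            f"({_EXACT_LIMIT}); use the Monte Carlo permutation_test")
    total_sum, total_len = float(t_sums.sum()), float(t_lens.sum())
    stats = np.empty(n_assign)
    for j, sel in enumerate(itertools.combinations(range(n_total), n_a)):
        sel = list(sel)
        sum_a, len_a = float(t_sums[sel].sum()), float(t_lens[sel].sum())
        stats[j] = sum_a / len_a - (total_sum - sum_a) / (total_len - len_a)
    count = _count_extreme(stats, s0, sided, strict=False)
    return count / n_assign
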
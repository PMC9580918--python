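"""Two-state smFRET trajectory simulator.

Generates the correlated single-molecule data used to exercise the
permutation tests in :mod:`clasta.permutation`.  A molecule switches
stochastically between two conformational states with FRET efficiencies
E1 and E2 and exponential dwell times with means tau1 and tau2
(a continuous-time two-state Markov process).  A camera samples the
process with exposure time t_ex and inter-frame delay t_del: the apparent
per-frame efficiency e(t_i) is the exposure-time-weighted mean of the
state efficiencies.  Donor and acceptor brightnesses are then drawn from
lognormal distributions with means n_phot*(1-e) and n_phot*e and standard
deviations given by a linear photon-noise calibration, and the recorded
efficiency is E = a / (d + a).

Because dwell times (default means 2 and 4 time units) are much longer
than the frame period (default 0.3), consecutive frames of one trajectory
are strongly correlated — the feature that invalidates pointwise
permutation tests on pooled frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .permutation import TrajectoryGroup

__all__ = [
    "TwoStateModel",
    "AcquisitionConfig",
    "StateTrajectory",
    "FretTrajectory",
    "GroupConfig",
    "simulate_state_path",
    "sample_apparent_fret",
    "add_detection_noise",
    "simulate_trajectory",
    "simulate_group",
    "sample_trajectory_lengths",
    "lognormal_params_from_moments",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoStateModel:
    """Two-state FRET model: efficiencies E1, E2 and mean lifetimes tau1, tau2."""

    e1: float = 0.2
    e2: float = 0.8
    tau1: float = 2.0
    tau2: float = 4.0

    def __post_init__(self) -> None:
        for name in ("e1", "e2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("state lifetimes must be positive")

    @property
    def stationary(self) -> tuple[float, float]:
        """Long-run occupancies (fraction of time in state 1, state 2)."""
        total = self.tau1 + self.tau2
        return (self.tau1 / total, self.tau2 / total)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera sampling and photon-noise parameters.

    The frame period is ``t_ex + t_del`` (exposure then inter-frame gap);
    times share the (arbitrary) unit of the state lifetimes.  ``n_phot``
    is the mean total photon count per frame; the lognormal brightness
    standard deviation is ``sigma_slope * mean + intercept`` per channel,
    clamped from below at ``sigma_floor`` (the donor intercept makes the
    linear form negative for small means).
    """

    t_ex: float = 0.1
    t_del: float = 0.2
    n_phot: float = 200.0
    sigma_slope: float = 0.3
    sigma_intercept_donor: float = -13.61
    sigma_intercept_acceptor: float = -1.92
    sigma_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.t_ex <= 0:
            raise ValueError("t_ex must be positive")
        if self.t_del < 0:
            raise ValueError("t_del must be >= 0")
        if self.n_phot <= 0:
            raise ValueError("n_phot must be positive")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")

    @property
    def frame_period(self) -> float:
        return self.t_ex + self.t_del

    def sigma_donor(self, mean: np.ndarray) -> np.ndarray:
        return np.maximum(self.sigma_slope * mean + self.sigma_intercept_donor,
                          self.sigma_floor)

    def sigma_acceptor(self, mean: np.ndarray) -> np.ndarray:
        return np.maximum(self.sigma_slope * mean + self.sigma_intercept_acceptor,
                          self.sigma_floor)


@dataclass
class StateTrajectory:
    """Piecewise-constant ground-truth state path.

    ``boundaries`` are segment edges (starting at 0, ending at the total
    duration); ``states`` holds the alternating state label (1 or 2) of
    each segment; ``state_efficiencies`` maps them to (E1, E2).
    """

    boundaries: np.ndarray  # (K+1,)
    states: np.ndarray  # (K,) in {1, 2}
    state_efficiencies: tuple[float, float]

    @property
    def duration(self) -> float:
        return float(self.boundaries[-1])

    @property
    def switch_times(self) -> np.ndarray:
        return self.boundaries[1:-1]

    def efficiency_per_segment(self) -> np.ndarray:
        e1, e2 = self.state_efficiencies
        return np.where(self.states == 1, e1, e2)


@dataclass
class FretTrajectory:
    """Per-frame recorded FRET efficiencies (noise can push them outside [0, 1])."""

    efficiencies: np.ndarray
    frame_period: float
    apparent: np.ndarray | None = None  # pre-noise e(t_i), kept for diagnostics

    def __len__(self) -> int:
        return len(self.efficiencies)


@dataclass(frozen=True)
class GroupConfig:
    """One experimental group: trajectory count, length law, model, acquisition.

    Trajectory lengths (in frames) follow a lognormal distribution
    parameterized by its own mean and standard deviation (defaults 27.1
    and 35.5 frames), rounded to the nearest integer and floored at 1.
    """

    n_trajectories: int = 100
    length_mean: float = 27.1
    length_sd: float = 35.5
    model: TwoStateModel = field(default_factory=TwoStateModel)
    acq: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.length_mean <= 0 or self.length_sd <= 0:
            raise ValueError("length mean and sd must be positive")


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a lognormal with given mean/sd."""
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal mean must be > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_state_path(model: TwoStateModel, duration: float,
                        rng: np.random.Generator) -> StateTrajectory:
    """Simulate the continuous-time two-state Markov path over [0, duration].

    Dwell times are exponential with means tau1/tau2; the initial state is
    drawn from the stationary distribution, so the path is stationary from
    t = 0 on.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    taus = (model.tau1, model.tau2)
    first = 1 if rng.random() < model.stationary[0] else 2
    # draw dwells in chunks until the path covers the requested duration
    mean_dwell = 0.5 * (model.tau1 + model.tau2)
    dwells_parts: list[np.ndarray] = []
    total = 0.0
    offset = 0
    while total < duration:
        chunk = max(int(np.ceil((duration - total) / mean_dwell)) + 8, 16)
        means = np.where((np.arange(offset, offset + chunk) % 2) == 0,
                         taus[first - 1], taus[2 - first])
        draws = rng.exponential(means)
        dwells_parts.append(draws)
        total += float(draws.sum())
        offset += chunk
    dwells = np.concatenate(dwells_parts)
    edges = np.concatenate([[0.0], np.cumsum(dwells)])
    k = int(np.searchsorted(edges, duration, side="left"))  # segments needed
    boundaries = np.concatenate([edges[:k], [duration]])
    states = np.where((np.arange(k) % 2) == 0, first, 3 - first)
    return StateTrajectory(boundaries=boundaries, states=states,
                           state_efficiencies=(model.e1, model.e2))


def sample_apparent_fret(path: StateTrajectory, acq: AcquisitionConfig,
                         n_frames: int) -> np.ndarray:
    """Exposure-averaged apparent FRET per frame, before photon noise.

    Frame i exposes over [i*(t_ex+t_del), i*(t_ex+t_del)+t_ex); the value
    is e(t_i) = (sum_j t_j E_j) / t_ex over the states visited during the
    exposure.  Always lies between min(E1, E2) and max(E1, E2).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if path.duration + 1e-9 < n_frames * acq.frame_period:
        raise ValueError("state path shorter than the requested frames")
    seg_e = path.efficiency_per_segment()
    # cumulative integral of E(t): piecewise linear in t at segment edges
    cum = np.concatenate([[0.0], np.cumsum(np.diff(path.boundaries) * seg_e)])
    starts = np.arange(n_frames) * acq.frame_period
    ends = starts + acq.t_ex
    integ = np.interp(ends, path.boundaries, cum) - np.interp(starts, path.boundaries, cum)
    return integ / acq.t_ex


def _lognormal(mean: np.ndarray, sd: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with the given moments (of the distribution itself)."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = np.zeros(mean.shape)
    pos = mean > 0
    if np.any(pos):
        sigma2 = np.log1p((sd[pos] / mean[pos]) ** 2)
        mu = np.log(mean[pos]) - sigma2 / 2.0
        out[pos] = rng.lognormal(mu, np.sqrt(sigma2))
    return out


def add_detection_noise(e_series: np.ndarray, acq: AcquisitionConfig,
                        rng: np.random.Generator) -> FretTrajectory:
    """Apply lognormal photon noise and recompute the recorded efficiency.

    Donor mean brightness m_don = n_phot*(1-e), acceptor m_acc = n_phot*e;
    sigma = sigma_slope*m + intercept (per channel), clamped below at
    sigma_floor.  Recorded efficiency is E = a / (d + a).
    """
    e = np.asarray(e_series, float)
    if np.any((e < -1e-9) | (e > 1 + 1e-9)):
        raise ValueError("apparent efficiencies must lie in [0, 1]")
    m_don = acq.n_phot * (1.0 - e)
    m_acc = acq.n_phot * e
    raw_sigma_don = acq.sigma_slope * m_don + acq.sigma_intercept_donor
    n_clamped = int(np.count_nonzero((raw_sigma_don < acq.sigma_floor) & (m_don > 0)))
    if n_clamped:
        logger.debug("donor sigma clamped at %.3g for %d of %d frames",
                     acq.sigma_floor, n_clamped, e.size)
    d = _lognormal(m_don, acq.sigma_donor(m_don), rng)
    a = _lognormal(m_acc, acq.sigma_acceptor(m_acc), rng)
    denom = d + a
    eff = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), e)
    return FretTrajectory(efficiencies=eff, frame_period=acq.frame_period,
                          apparent=e)


def sample_trajectory_lengths(n: int, mean: float, sd: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Integer frame counts from a lognormal with the given mean/sd, min 1."""
    mu, sigma = lognormal_params_from_moments(mean, sd)
    lengths = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    return np.maximum(lengths, 1)


def simulate_trajectory(model: TwoStateModel, acq: AcquisitionConfig,
                        n_frames: int, rng: np.random.Generator) -> FretTrajectory:
    """One full trajectory: state path -> exposure sampling -> photon noise."""
    path = simulate_state_path(model, n_frames * acq.frame_period, rng)
    e = sample_apparent_fret(path, acq, n_frames)
    return add_detection_noise(e, acq, rng)


def simulate_group(cfg: GroupConfig, rng: np.random.Generator | None = None,
                   group_label: str = "") -> TrajectoryGroup:
    """Simulate a group of independent trajectories with lognormal lengths."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lengths = sample_trajectory_lengths(cfg.n_trajectories, cfg.length_mean,
                                        cfg.length_sd, rng)
    trajectories = [
        simulate_trajectory(cfg.model, cfg.acq, int(n), rng).efficiencies
        for n in lengths
    ]
    logger.info("simulated group %r: %d trajectories, %d frames total",
                group_label, len(trajectories), int(lengths.sum()))
    return TrajectoryGroup(trajectories=trajectories, group_label=group_label)
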
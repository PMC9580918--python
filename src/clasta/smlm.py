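"""Synthetic two-color SMLM localization maps.

Single molecule localization microscopy (SMLM) produces a list of
coordinates — one entry per *detection*, not per molecule.  Fluorophore
blinking turns every labeled molecule into a small cloud of localizations
scattered by the localization error, which is exactly what makes naive
cluster analysis of such maps unreliable.  This module generates
ground-truth molecule ensembles (monomers or oligomers placed by a spatial
Poisson process), labels them competitively with two colors, applies a
configurable blinking (overcounting) model, localization error, and
unspecific/background signals, and returns the resulting two-color
localization map.

All coordinates are continuous and in nanometres; densities are per µm².
The rectangular region of interest (ROI) is ``[0, W) x [0, H)`` and is
treated as a torus: localizations displaced outside the ROI are wrapped
back, which keeps the per-channel point process stationary on the ROI and
is what makes the toroidal-shift null of :mod:`clasta.cluster_test` exact.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NM_PER_UM",
    "CHANNELS",
    "BlinkModel",
    "SmlmConfig",
    "MoleculeEnsemble",
    "LocalizationMap",
    "simulate_molecules",
    "label_and_blink",
    "render_localizations",
    "simulate_two_color_map",
]

logger = logging.getLogger(__name__)

NM_PER_UM = 1000.0
CHANNELS = ("red", "blue")


@dataclass(frozen=True)
class BlinkModel:
    """Distribution of the number of detections per emitter.

    ``geometric``: detections ~ Geometric on {1, 2, ...} with the given
    mean (every functional label is detected at least once).
    ``empirical``: a user-supplied table mapping detection count to
    probability, e.g. measured per-fluorophore blinking statistics.
    """

    family: str = "geometric"
    mean_detections: float = 5.0
    empirical_counts: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("geometric", "empirical"):
            raise ValueError(f"unknown blink model family: {self.family!r}")
        if self.family == "geometric":
            if not np.isfinite(self.mean_detections) or self.mean_detections < 1:
                raise ValueError("mean_detections must be finite and >= 1")
        else:
            if not self.empirical_counts:
                raise ValueError("empirical blink model requires a count table")
            counts = np.array(sorted(self.empirical_counts), dtype=int)
            probs = np.array([self.empirical_counts[int(k)] for k in counts], float)
            if counts.min() < 1:
                raise ValueError("detection counts must be >= 1")
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("empirical probabilities must be >= 0 and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` detection counts (integers >= 1)."""
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        if self.family == "geometric":
            return rng.geometric(1.0 / self.mean_detections, size=n)
        counts = np.array(sorted(self.empirical_counts), dtype=np.int64)
        probs = np.array([self.empirical_counts[int(k)] for k in counts], float)
        probs = probs / probs.sum()
        return rng.choice(counts, size=n, p=probs)

    @property
    def mean(self) -> float:
        if self.family == "geometric":
            return float(self.mean_detections)
        return float(sum(k * p for k, p in self.empirical_counts.items()))


@dataclass(frozen=True)
class SmlmConfig:
    """Simulation parameters for a two-color SMLM experiment.

    Defaults correspond to a standard membrane-protein scenario: a
    10 x 10 µm ROI at 75 molecules/µm², 40% degree of labeling with a 1:1
    blue:red label ratio, 30 nm localization precision, 5 unspecifically
    bound labels per µm² in each channel and background signal densities
    of 1 (red) and 2 (blue) per µm².
    """

    roi_width: float = 10_000.0  # nm
    roi_height: float = 10_000.0  # nm
    molecule_density: float = 75.0  # molecules per µm²
    oligomer_size: int = 1  # 1=monomer, 2=dimer, ...
    degree_of_labeling: float = 0.4
    label_ratio: float = 0.5  # fraction of labels assigned to "blue"
    localization_precision: float = 30.0  # nm (std. dev. per axis)
    unspecific_density: float = 5.0  # labels per µm² per channel
    background_density_red: float = 1.0  # signals per µm²
    background_density_blue: float = 2.0  # signals per µm²
    blink_model: BlinkModel = field(default_factory=BlinkModel)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.roi_width > 0 and self.roi_height > 0):
            raise ValueError("ROI dimensions must be positive")
        for name in ("molecule_density", "unspecific_density",
                     "background_density_red", "background_density_blue"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.oligomer_size < 1:
            raise ValueError("oligomer_size must be >= 1")
        if not 0.0 <= self.degree_of_labeling <= 1.0:
            raise ValueError("degree_of_labeling must be in [0, 1]")
        if not 0.0 < self.label_ratio < 1.0:
            raise ValueError("label_ratio must be in (0, 1)")
        if self.localization_precision < 0:
            raise ValueError("localization_precision must be >= 0")

    @property
    def roi(self) -> tuple[float, float]:
        return (self.roi_width, self.roi_height)

    @property
    def area_um2(self) -> float:
        return self.roi_width * self.roi_height / NM_PER_UM**2


@dataclass
class MoleculeEnsemble:
    """Ground-truth molecule positions with oligomer membership.

    Molecules sharing an ``oligomer_id`` sit at identical coordinates
    (the oligomer footprint is far below the localization precision).
    """

    positions: np.ndarray  # (N, 2) nm
    oligomer_id: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LocalizationMap:
    """A two-color localization map on a rectangular ROI.

    ``counts`` (optional) records per-channel provenance:
    specific / unspecific / background localization totals.
    """

    coords: np.ndarray  # (N, 2) nm
    channels: np.ndarray  # (N,) of {"red", "blue"}
    roi: tuple[float, float]
    counts: dict | None = None

    def __len__(self) -> int:
        return len(self.coords)

    def points(self, channel: str) -> np.ndarray:
        """Coordinates of all localizations in one channel, shape (n, 2)."""
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel: {channel!r}")
        return self.coords[self.channels == channel]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_nm": self.coords[:, 0], "y_nm": self.coords[:, 1],
             "channel": self.channels}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       roi: tuple[float, float] | None = None) -> "LocalizationMap":
        coords = np.column_stack([np.asarray(df["x_nm"], float),
                                  np.asarray(df["y_nm"], float)])
        channels = np.asarray(df["channel"], dtype=object).astype(str)
        bad = set(np.unique(channels)) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channel label(s): {sorted(bad)}")
        if roi is None:
            # infer a bounding box that strictly contains every point
            roi = (float(np.nextafter(coords[:, 0].max(), np.inf)) if len(coords) else 1.0,
                   float(np.nextafter(coords[:, 1].max(), np.inf)) if len(coords) else 1.0)
        if len(coords) and (
            coords[:, 0].min() < 0 or coords[:, 1].min() < 0
            or coords[:, 0].max() >= roi[0] or coords[:, 1].max() >= roi[1]
        ):
            raise ValueError("localizations outside the stated ROI")
        return cls(coords=coords, channels=np.asarray(channels, dtype=object), roi=roi)


def simulate_molecules(config: SmlmConfig, rng: np.random.Generator) -> MoleculeEnsemble:
    """Place molecules by a homogeneous spatial Poisson process.

    Oligomer seed positions are drawn at density
    ``molecule_density / oligomer_size`` and each seed is replicated
    ``oligomer_size`` times at identical coordinates, so the expected
    molecule count is ``molecule_density * area``.
    """
    seed_density = config.molecule_density / config.oligomer_size
    n_seeds = rng.poisson(seed_density * config.area_um2)
    seeds = rng.uniform((0.0, 0.0), config.roi, size=(n_seeds, 2))
    positions = np.repeat(seeds, config.oligomer_size, axis=0)
    oligomer_id = np.repeat(np.arange(n_seeds), config.oligomer_size)
    logger.info("simulated %d molecules in %d oligomers", len(positions), n_seeds)
    return MoleculeEnsemble(positions=positions, oligomer_id=oligomer_id)


def label_and_blink(ensemble: MoleculeEnsemble, config: SmlmConfig,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Competitive two-color labeling followed by blinking overcounts.

    Each molecule is independently labeled with probability
    ``degree_of_labeling``; labeled molecules are assigned to the blue
    channel with probability ``label_ratio`` and to red otherwise.  Every
    label then emits ``k >= 1`` detections drawn from the blink model, all
    at the molecule's true position.

    Returns a dict ``{channel: (n_detections, 2) array}``.
    """
    n = len(ensemble)
    labeled = rng.random(n) < config.degree_of_labeling
    is_blue = rng.random(n) < config.label_ratio
    out: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        mask = labeled & (is_blue == (channel == "blue"))
        pos = ensemble.positions[mask]
        k = config.blink_model.sample(len(pos), rng)
        out[channel] = np.repeat(pos, k, axis=0)
    logger.info("labeling: %d labels -> %s detections",
                int(labeled.sum()), {c: len(v) for c, v in out.items()})
    return out


def _emitters_with_blinks(density: float, config: SmlmConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniformly placed emitters at the given density, expanded per blink."""
    n = rng.poisson(density * config.area_um2)
    pos = rng.uniform((0.0, 0.0), config.roi, size=(n, 2))
    k = config.blink_model.sample(n, rng)
    return np.repeat(pos, k, axis=0)


def render_localizations(detections: Mapping[str, np.ndarray], config: SmlmConfig,
                         rng: np.random.Generator) -> LocalizationMap:
    """Turn detections into a localization map.

    Adds unspecifically bound labels (per channel) and background signals,
    both blinking like real emitters, then displaces every detection by an
    isotropic Gaussian localization error and wraps positions back into
    the ROI with periodic boundary conditions.
    """
    bg_density = {"red": config.background_density_red,
                  "blue": config.background_density_blue}
    coords_parts: list[np.ndarray] = []
    channel_parts: list[np.ndarray] = []
    counts: dict[str, dict[str, int]] = {}
    for channel in CHANNELS:
        specific = np.asarray(detections.get(channel, np.zeros((0, 2))), float)
        specific = specific.reshape(-1, 2)
        unspecific = _emitters_with_blinks(config.unspecific_density, config, rng)
        background = _emitters_with_blinks(bg_density[channel], config, rng)
        pts = np.concatenate([specific, unspecific, background], axis=0)
        if config.localization_precision > 0 and len(pts):
            pts = pts + rng.normal(0.0, config.localization_precision, size=pts.shape)
        pts = np.mod(pts, config.roi)
        coords_parts.append(pts)
        channel_parts.append(np.full(len(pts), channel, dtype=object))
        counts[channel] = {"specific": len(specific), "unspecific": len(unspecific),
                           "background": len(background)}
    coords = np.concatenate(coords_parts, axis=0)
    channels = np.concatenate(channel_parts, axis=0)
    logger.info("rendered %d localizations: %s", len(coords), counts)
    return LocalizationMap(coords=coords, channels=channels, roi=config.roi,
                           counts=counts)


def simulate_two_color_map(config: SmlmConfig,
                           rng: np.random.Generator | None = None) -> LocalizationMap:
    """End-to-end simulation: molecules -> labels/blinks -> localization map.

    Deterministic for a fixed ``config.seed`` (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ensemble = simulate_molecules(config, rng)
    detections = label_and_blink(ensemble, config, rng)
    return render_localizations(detections, config, rng)
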
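"""Dose-response models for injection planning.

Two saturating relations drive the quantitative protocol design:

* retention vs depth — tissue viscosity seals the needle track with a force
  ``N(d) = k * d**n`` that grows with insertion depth ``d`` (mm), so the
  retained fraction follows ``R(d) = 1 - exp(-beta * d**n)`` where
  ``beta = alpha * k`` lumps the sealing scale with the sensitivity of
  retention to sealing;
* growth vs volume — early graft growth falls with the hypoperfused
  fraction of the implant, ``G(v) = Gmax * (1 - HypoR(v))**gamma`` with the
  main-text exponent ``gamma = 3`` as default.

Depths are in mm (``beta`` in 1/mm, or 1/mm^n when ``n != 1``), volumes in
um^3 as everywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import DEFAULT_MARGIN_UM, hypoperfused_fraction_volume, threshold_volume

__all__ = [
    "SealingParams",
    "RetentionModel",
    "GrowthModel",
    "sealing_force",
    "retention_at_depth",
    "depth_for_retention",
    "growth_rate",
]


@dataclass(frozen=True)
class SealingParams:
    """Sealing-force relation ``N(d) = k * d**n``.

    ``alpha`` (optional) is the retention sensitivity per force unit; with
    ``n = 1`` it implies ``beta = alpha * k`` for the paired retention model.
    """

    k: float
    n: float = 1.0
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be strictly positive")
        if not self.n >= 1:
            raise ValueError("n must be >= 1")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha, if set, must be strictly positive")

    def implied_beta(self) -> float:
        """beta = alpha * k (defined for n = 1 decompositions)."""
        if self.alpha is None:
            raise ValueError("alpha is not set; no implied beta")
        return self.alpha * self.k


@dataclass(frozen=True)
class RetentionModel:
    """Saturating retention-depth model ``R(d) = 1 - exp(-beta * d**n)``."""

    beta: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be strictly positive")
        if not self.n >= 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class GrowthModel:
    """Growth-vs-volume model ``G(v) = g_max * (1 - HypoR(v; margin))**gamma``.

    ``g_max`` is the maximal growth readout (fold-change over the assay
    window) attained when the whole graft is oxygenated; ``gamma`` sets how
    sharply growth collapses as the hypoperfused core grows.
    """

    g_max: float
    gamma: float = 3.0
    margin: float = DEFAULT_MARGIN_UM

    def __post_init__(self) -> None:
        if not self.g_max > 0:
            raise ValueError("g_max must be strictly positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be strictly positive")
        if not self.margin > 0:
            raise ValueError("margin must be strictly positive")

    @property
    def threshold_volume_um3(self) -> float:
        return float(threshold_volume(self.margin))


def _depths(d) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("depth must be non-negative")
    return arr


def _maybe_scalar(x: np.ndarray):
    return float(x) if x.ndim == 0 else x


def sealing_force(d_mm, params: SealingParams):
    """Sealing force (arbitrary units) at depth ``d_mm``: ``k * d**n``."""
    d = _depths(d_mm)
    return _maybe_scalar(params.k * d**params.n)


def retention_at_depth(d_mm, model: RetentionModel):
    """Retained fraction at insertion depth ``d_mm`` (mm); in [0, 1)."""
    d = _depths(d_mm)
    return _maybe_scalar(-np.expm1(-model.beta * d**model.n))


def depth_for_retention(target, model: RetentionModel):
    """Depth (mm) achieving ``target`` retained fraction; inverse of R(d).

    The asymptote at 1 is unreachable, so ``target`` must lie in [0, 1).
    """
    t = np.asarray(target, dtype=float)
    if np.any(t < 0) or np.any(t >= 1):
        raise ValueError("target retention must lie in [0, 1)")
    d = (-np.log1p(-t) / model.beta) ** (1.0 / model.n)
    return _maybe_scalar(d)


def growth_rate(v_um3, model: GrowthModel):
    """Growth readout for a graft of total volume ``v_um3`` (um^3).

    Equals ``g_max`` at or below the threshold volume (no hypoperfused
    core) and decreases strictly beyond it.
    """
    hypor = hypoperfused_fraction_volume(v_um3, model.margin)
    g = model.g_max * (1.0 - np.asarray(hypor)) ** model.gamma
    return _maybe_scalar(np.asarray(g))
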
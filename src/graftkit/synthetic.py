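"""Seeded generators emulating the in-vitro calibration experiments.

Three generators cover the package's observation tables:

* :func:`simulate_retention` — depth-retention assays in soft gel: boluses
  at depths {0.5, 1.5, 3.0} mm with replicate counts (7, 8, 8) plus a
  4-replicate delivered-dose reference group, readout on the retained
  fraction scale;
* :func:`simulate_growth` — volume-growth assays in hydrogel at volumes
  {0.1, 0.25, 0.5, 1.0} uL with counts (8, 7, 4, 4), a fold-change readout
  with multiplicative lognormal noise (heavy-tailed, as photon-count
  viability signals are);
* :func:`simulate_graft_scene` — a 6-day peri-graft imaging scene: static
  neurons inside and outside the 120-um peri-graft circle with a calcium
  time profile that peaks on days 1-2 and rests by day 4, and motile
  microglia whose in-circle occupancy follows a recruitment profile
  peaking on days 2-3.

Every generator is a pure function of its spec (which holds the seed):
the same spec yields an identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import ul_to_um3
from .graft_interface import GraftSite
from .models import GrowthModel, RetentionModel, growth_rate, retention_at_depth

__all__ = [
    "NoiseModel",
    "RetentionSimSpec",
    "GrowthSimSpec",
    "GraftSceneSpec",
    "simulate_retention",
    "simulate_growth",
    "simulate_graft_scene",
]

GAUSSIAN = "gaussian_additive"
LOGNORMAL = "lognormal_multiplicative"


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: additive Gaussian or multiplicative lognormal.

    ``sigma`` is the Gaussian SD on the readout scale, or the SD of the
    log for the lognormal model. ``sigma = 0`` reproduces the model curve
    exactly under either kind.
    """

    kind: str = GAUSSIAN
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (GAUSSIAN, LOGNORMAL):
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        if self.kind == GAUSSIAN:
            return values + rng.normal(0.0, self.sigma, size=values.shape)
        return values * np.exp(rng.normal(0.0, self.sigma, size=values.shape))


@dataclass(frozen=True)
class RetentionSimSpec:
    """Design of a simulated depth-retention assay.

    Defaults mirror the calibration experiment: three depths with 7/8/8
    replicates and a 4-replicate delivered-dose reference group (true
    fraction 1), additive Gaussian noise of SD 0.05 on the fraction scale.
    """

    beta_true: float = 0.24
    depths: Tuple[float, ...] = (0.5, 1.5, 3.0)
    n_per_depth: Tuple[int, ...] = (7, 8, 8)
    n_reference: int = 4
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(GAUSSIAN, 0.05))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beta_true > 0:
            raise ValueError("beta_true must be strictly positive")
        if len(self.depths) != len(self.n_per_depth):
            raise ValueError("depths and n_per_depth lengths differ")


@dataclass(frozen=True)
class GrowthSimSpec:
    """Design of a simulated volume-growth assay.

    Defaults mirror the calibration experiment (four volumes with 8/7/4/4
    replicates); the fold-change ceiling of 4.0 over the assay window is
    the generator's stand-in for an unconstrained expansion of a fast
    neural stem cell line.
    """

    g_max_true: float = 4.0
    gamma_true: float = 3.0
    volumes: Tuple[float, ...] = (0.1, 0.25, 0.5, 1.0)  # uL
    n_per_volume: Tuple[int, ...] = (8, 7, 4, 4)
    margin_um: float = 100.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(LOGNORMAL, 0.15))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.g_max_true > 0 or not self.gamma_true > 0:
            raise ValueError("g_max_true and gamma_true must be strictly positive")
        if len(self.volumes) != len(self.n_per_volume):
            raise ValueError("volumes and n_per_volume lengths differ")


@dataclass(frozen=True)
class GraftSceneSpec:
    """Design of a simulated peri-graft imaging scene.

    ``calcium_profile`` multiplies the peri-graft neurons' resting
    intensity per day (distal neurons stay at 1x); the default peaks on
    days 1-2 and is back near baseline by day 4. ``recruitment_profile``
    is the per-day in-circle occupancy probability of microglia; each day
    exactly ``round(n_microglia * p)`` cells are designated in-circle
    (with persistence across days), so the expected recruitment
    time-course is realised by construction. Microglia move with
    per-cell lognormal step scales ("high cell-to-cell variation");
    ``motility_median_um = 0`` freezes all cells in place.
    """

    n_neurons_peri: int = 10
    n_neurons_distal: int = 8
    calcium_profile: Tuple[float, ...] = (6.0, 10.0, 8.0, 3.0, 1.0, 1.0)
    baseline_intensity: float = 50.0
    background: float = 20.0
    intensity_noise_sd: float = 3.0
    n_microglia: int = 20
    recruitment_profile: Tuple[float, ...] = (0.10, 0.30, 0.80, 0.55, 0.35, 0.20)
    motility_median_um: float = 25.0
    motility_sigma_log: float = 0.5
    cell_scale_sigma_log: float = 0.4
    field_um: Tuple[float, float, float] = (600.0, 600.0, 100.0)
    site_radius_um: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.calcium_profile) != len(self.recruitment_profile):
            raise ValueError("calcium and recruitment profiles must cover the same days")
        if any(p < 0 or p > 1 for p in self.recruitment_profile):
            raise ValueError("recruitment probabilities must lie in [0, 1]")
        if min(self.n_neurons_peri, self.n_neurons_distal, self.n_microglia) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_days(self) -> int:
        return len(self.calcium_profile)


def simulate_retention(spec: RetentionSimSpec) -> pd.DataFrame:
    """Simulate a retention observation table.

    Values are ``clamp_[0,1](R(d; beta_true) + noise)``; the number of
    rows clamped at either boundary is recorded in
    ``df.attrs["n_clamped"]`` so fitters can detect boundary pile-up.
    Reference rows (delivered dose, true fraction 1) carry
    ``value_kind = "reference"`` and no depth; fitters exclude them.
    """
    rng = np.random.default_rng(spec.seed)
    model = RetentionModel(beta=spec.beta_true)
    depth_col, truth = [], []
    for d, n in zip(spec.depths, spec.n_per_depth):
        depth_col.extend([d] * n)
        truth.extend([float(retention_at_depth(d, model))] * n)
    truth.extend([1.0] * spec.n_reference)
    depth_col.extend([math.nan] * spec.n_reference)
    truth_arr = np.asarray(truth)
    noisy = spec.noise.apply(truth_arr, rng)
    clamped = (noisy < 0.0) | (noisy > 1.0)
    values = np.clip(noisy, 0.0, 1.0)
    kinds = ["fraction"] * (len(truth) - spec.n_reference) + ["reference"] * spec.n_reference
    df = pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(len(truth))],
            "depth_mm": depth_col,
            "value": values,
            "value_kind": kinds,
            "qc_pass": True,
        }
    )
    df.attrs["n_clamped"] = int(clamped.sum())
    return df


def simulate_growth(spec: GrowthSimSpec) -> pd.DataFrame:
    """Simulate a growth observation table (fold-change readout)."""
    rng = np.random.default_rng(spec.seed)
    model = GrowthModel(g_max=spec.g_max_true, gamma=spec.gamma_true, margin=spec.margin_um)
    vol_col, truth = [], []
    for v, n in zip(spec.volumes, spec.n_per_volume):
        vol_col.extend([v] * n)
        truth.extend([float(growth_rate(ul_to_um3(v), model))] * n)
    values = spec.noise.apply(np.asarray(truth), rng)
    return pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(len(truth))],
            "volume_ul": vol_col,
            "value": values,
            "value_kind": "growth",
            "qc_pass": True,
        }
    )


def _uniform_in_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _uniform_in_annulus(
    rng: np.random.Generator, n: int, r_in: float, r_out: float
) -> np.ndarray:
    u = rng.uniform(size=n)
    r = np.sqrt(r_in**2 + u * (r_out**2 - r_in**2))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_graft_scene(
    spec: GraftSceneSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, GraftSite]:
    """Simulate tracks, ROI traces and the true implantation site.

    Returns ``(tracks, rois, site)``. ``tracks`` covers both static
    neurons and motile microglia (``cell_type`` column); ``rois`` carries
    the neurons' daily calcium intensities. Microglia occupancy of the
    peri-graft circle follows the recruitment profile exactly (designated
    membership with persistence); their day-to-day moves draw per-cell
    lognormal step lengths, falling back to placement within the
    designated region when the drawn step cannot reach it.
    """
    rng = np.random.default_rng(spec.seed)
    site = GraftSite(center=(0.0, 0.0), radius=spec.site_radius_um)
    days = np.arange(spec.n_days)
    fx, fy, fz = spec.field_um
    r_out = min(fx, fy) / 2.0

    # --- neurons: static positions, peri inside the circle, distal outside
    peri_xy = _uniform_in_disk(rng, spec.n_neurons_peri, 0.9 * site.radius)
    distal_xy = _uniform_in_annulus(rng, spec.n_neurons_distal, 1.4 * site.radius, r_out)
    track_rows, roi_rows = [], []
    neurons = [
        (f"neuron_p{i:02d}", xy, True) for i, xy in enumerate(peri_xy)
    ] + [(f"neuron_d{i:02d}", xy, False) for i, xy in enumerate(distal_xy)]
    for cell_id, (x, y), is_peri in neurons:
        z = rng.uniform(0, fz)
        for day in days:
            mult = spec.calcium_profile[day] if is_peri else 1.0
            signal = spec.baseline_intensity * mult + rng.normal(0, spec.intensity_noise_sd)
            track_rows.append(
                dict(cell_id=cell_id, day=int(day), x_um=x, y_um=y, z_um=z, cell_type="neuron")
            )
            roi_rows.append(
                dict(
                    cell_id=cell_id,
                    day=int(day),
                    roi_mean=spec.background + max(signal, 0.0),
                    background=spec.background,
                )
            )

    # --- microglia: designated in-circle membership realises the profile
    n_mg = spec.n_microglia
    targets = [int(round(n_mg * p)) for p in spec.recruitment_profile]
    scales = (
        spec.motility_median_um
        * np.exp(rng.normal(0.0, spec.cell_scale_sigma_log, size=n_mg))
        if spec.motility_median_um > 0
        else np.zeros(n_mg)
    )
    inside = np.zeros(n_mg, dtype=bool)
    k0 = targets[0]
    order = rng.permutation(n_mg)
    inside[order[:k0]] = True
    pos = np.zeros((n_mg, 3))
    pos[inside, :2] = _uniform_in_disk(rng, int(inside.sum()), site.radius)
    pos[~inside, :2] = _uniform_in_annulus(
        rng, int((~inside).sum()), site.radius * 1.001, r_out
    )
    pos[:, 2] = rng.uniform(0, fz, size=n_mg)

    def record(day: int) -> None:
        for i in range(n_mg):
            track_rows.append(
                dict(
                    cell_id=f"mg{i:02d}",
                    day=int(day),
                    x_um=pos[i, 0],
                    y_um=pos[i, 1],
                    z_um=pos[i, 2],
                    cell_type="microglia",
                )
            )

    record(0)
    for day in days[1:]:
        k = targets[day]
        cur_in = np.flatnonzero(inside)
        cur_out = np.flatnonzero(~inside)
        if k > cur_in.size:  # recruit nearest-agnostic random outsiders
            recruits = rng.choice(cur_out, size=k - cur_in.size, replace=False)
            inside[recruits] = True
        elif k < cur_in.size:
            leavers = rng.choice(cur_in, size=cur_in.size - k, replace=False)
            inside[leavers] = False
        for i in range(n_mg):
            step = (
                scales[i] * math.exp(rng.normal(0.0, spec.motility_sigma_log))
                if scales[i] > 0
                else 0.0
            )
            if step == 0.0:
                continue  # zero-motility cells never move
            placed = False
            for _ in range(40):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pos[i] + step * u
                planar = math.hypot(cand[0], cand[1])
                in_circle = planar <= site.radius
                if in_circle == inside[i] and 0 <= cand[2] <= fz and planar <= r_out:
                    pos[i] = cand
                    placed = True
                    break
            if not placed:  # step cannot reach the designated region: place in it
                if inside[i]:
                    pos[i, :2] = _uniform_in_disk(rng, 1, site.radius)[0]
                else:
                    pos[i, :2] = _uniform_in_annulus(rng, 1, site.radius * 1.001, r_out)[0]
        record(int(day))

    tracks = pd.DataFrame(track_rows)
    rois = pd.DataFrame(roi_rows)
    return tracks, rois, site
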
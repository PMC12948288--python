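"""Model fitting: bounded NLS, site-resampled bootstrap, diagnostics.

Observation tables are plain pandas DataFrames with a small column
contract (UTF-8 delimited text on disk):

retention table
    ``site_id, depth_mm, value, value_kind, qc_pass`` where ``value_kind``
    is ``"fraction"`` (retained fraction in [0, 1]) or ``"signal"`` (raw
    photon flux; requires an explicit delivered-dose ``reference`` to
    convert to fractions). Rows with ``value_kind == "reference"`` (the
    delivered-dose normalisation group) and rows failing QC are excluded
    from fitting.

growth table
    ``site_id, volume_ul, value, value_kind, qc_pass`` where ``value_kind``
    is ``"growth"`` (fold-change readout, fits G(v) = Gmax*(1-HypoR)^gamma)
    or ``"hypor"`` (measured hypoperfused fraction, fits HypoR(v; margin)).

Estimation follows ordinary (unweighted) least squares on the
fraction/readout scale, with bounds, multi-start for the primary fit, and
percentile confidence intervals from a nonparametric bootstrap that
resamples sites (rows), stratified by depth/volume group whenever every
group has at least two rows. Residual diagnostics report R^2 / MAE / RMSE
and a two-sided Spearman trend test of residuals against the predictor
(exact permutation p-value below n = 10, large-sample t approximation
otherwise).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import hypoperfused_fraction_volume, threshold_volume, ul_to_um3
from .models import GrowthModel, RetentionModel, retention_at_depth, growth_rate

__all__ = [
    "FitConfig",
    "FitResult",
    "CandidateFit",
    "fit_retention",
    "fit_growth",
    "goodness_of_fit",
    "residual_trend",
    "bootstrap_ci",
    "model_selection_gamma",
    "sensitivity_sweep",
]

logger = logging.getLogger("graftkit.estimation")

RETENTION_COLUMNS = ("site_id", "depth_mm", "value", "value_kind", "qc_pass")
GROWTH_COLUMNS = ("site_id", "volume_ul", "value", "value_kind", "qc_pass")


# --------------------------------------------------------------------------
# configuration and result containers
# --------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Knobs of the estimation procedure.

    ``n_boot = 0`` skips the bootstrap entirely (useful inside simulation
    ladders); the default 1000 resamples matches the reporting convention
    the models were published with. ``gamma_mode`` is one of ``"fixed:1"``,
    ``"fixed:2"``, ``"fixed:3"``, ``"free"``; ``gmax_mode`` is ``"free"``
    or ``"fixed:<value>"``; ``margin_mode`` (hypor fits) is ``"fixed"`` or
    ``"free"``.
    """

    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    beta_bounds: Tuple[float, float] = (0.0, 50.0)
    gamma_bounds: Tuple[float, float] = (1e-3, 25.0)
    gmax_bounds: Tuple[float, float] = (1e-9, 1e6)
    margin_bounds: Tuple[float, float] = (1.0, 1000.0)
    gamma_mode: str = "fixed:3"
    gmax_mode: str = "free"
    margin_mode: str = "fixed"
    margin_um: float = 100.0
    n_starts: int = 8

    def __post_init__(self) -> None:
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FitResult:
    """Point estimates with bootstrap intervals and diagnostics."""

    estimates: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    r_squared: float
    mae: float
    rmse: float
    residuals: pd.DataFrame
    trend: Dict[str, float]
    n_sites: int
    converged: bool
    flags: List[str] = field(default_factory=list)
    n_boot_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "r_squared": self.r_squared,
            "mae": self.mae,
            "rmse": self.rmse,
            "trend": dict(self.trend),
            "n_sites": self.n_sites,
            "converged": self.converged,
            "flags": list(self.flags),
            "n_boot_failures": self.n_boot_failures,
        }


@dataclass
class CandidateFit:
    """One entry of a model-selection comparison."""

    label: str
    n_free: int
    result: Optional[FitResult] = None
    error: Optional[str] = None


class IllPosedError(ValueError):
    """Raised when the data cannot identify the requested parameters."""


# --------------------------------------------------------------------------
# goodness of fit and residual diagnostics
# --------------------------------------------------------------------------


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float]) -> Dict[str, float]:
    """R^2 (about the observed mean), MAE and RMSE in observation units.

    With zero variance in the observations and nonzero residuals R^2 is
    reported as NaN (undefined), never -inf.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {
        "r_squared": r2,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = rx[perms]  # (n!, n) — Pearson on ranks handles ties correctly
    pc = permuted - permuted.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    denom = np.sqrt(np.sum(pc**2, axis=1) * np.sum(yc**2))
    rhos = (pc @ yc) / np.where(denom > 0, denom, np.inf)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def residual_trend(residuals: Sequence[float], predictor: Sequence[float]) -> Dict[str, float]:
    """Two-sided Spearman trend of residuals against a predictor.

    Ties get average ranks; constant residuals (or predictor) yield
    ``rho = 0`` and are never flagged. ``flagged`` is True when p < 0.05.
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if r.shape != x.shape:
        raise ValueError("residuals and predictor must have equal length")
    if r.size < 3:
        raise ValueError("need at least three residuals for a trend test")
    if np.ptp(r) == 0.0 or np.ptp(x) == 0.0:
        return {"spearman_rho": 0.0, "p_value": 1.0, "flagged": False}
    rho = float(stats.spearmanr(x, r).statistic)
    if r.size < 10:
        p = _spearman_exact_p(x, r, rho)
    else:
        p = float(stats.spearmanr(x, r).pvalue)
    return {"spearman_rho": rho, "p_value": p, "flagged": bool(p < 0.05)}


# --------------------------------------------------------------------------
# optimisation primitives
# --------------------------------------------------------------------------


def _fit_scalar(
    sse: Callable[[float], float],
    bounds: Tuple[float, float],
    n_starts: int = 8,
    x0: Optional[float] = None,
) -> Tuple[float, bool]:
    """Minimise a scalar SSE within bounds.

    Primary fits scan a coarse grid (log-spaced starts) and polish the best
    bracket with bounded Brent; warm-started refits (``x0`` given) go
    straight to Brent over the full bounds.
    """
    lo, hi = bounds
    hi = min(hi, 1e6)
    if x0 is None:
        grid = np.concatenate(
            [[lo], np.geomspace(max(lo, 1e-4), max(hi, 1e-4), max(4 * n_starts, 8)), [hi]]
        )
        grid = np.unique(np.clip(grid, lo, hi))
        vals = np.array([sse(g) for g in grid])
        i = int(np.argmin(vals))
        b_lo = grid[max(i - 1, 0)]
        b_hi = grid[min(i + 1, grid.size - 1)]
        if b_lo == b_hi:
            return float(grid[i]), True
    else:
        b_lo, b_hi = lo, hi
    res = optimize.minimize_scalar(
        sse, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x), bool(res.success)


def _fit_vector(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    bounds: Tuple[np.ndarray, np.ndarray],
    starts: np.ndarray,
) -> Tuple[np.ndarray, float, bool]:
    """Bounded least squares from multiple starts; keep the best optimum."""
    best_x, best_cost, ok = None, np.inf, False
    for x0 in starts:
        try:
            sol = optimize.least_squares(residual_fn, x0, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - optimizer edge failures
            continue
        if sol.cost < best_cost:
            best_x, best_cost, ok = sol.x, float(sol.cost), bool(sol.success)
    if best_x is None:
        raise RuntimeError("all optimizer starts failed")
    return np.asarray(best_x, dtype=float), best_cost, ok


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def _resample_indices(
    groups: np.ndarray, rng: np.random.Generator, n_boot: int
) -> np.ndarray:
    """Site-resampling index matrix (n_boot, n), stratified when possible.

    Stratified by group when every group holds >= 2 rows (preserves the
    experimental design); plain row resampling otherwise.
    """
    n = groups.size
    codes, counts = np.unique(groups, return_counts=True)
    if np.all(counts >= 2) and codes.size > 1:
        cols = []
        for g in codes:
            idx = np.flatnonzero(groups == g)
            cols.append(idx[rng.integers(0, idx.size, size=(n_boot, idx.size))])
        return np.concatenate(cols, axis=1)
    return rng.integers(0, n, size=(n_boot, n))


def bootstrap_ci(
    refit: Callable[[np.ndarray], Dict[str, float]],
    groups: np.ndarray,
    cfg: FitConfig,
    point: Dict[str, float],
) -> Tuple[Dict[str, Tuple[float, float]], int]:
    """Percentile intervals from ``cfg.n_boot`` site-resampled refits.

    ``refit`` maps a row-index array to parameter estimates; replicates
    that raise are counted as failures, and more than 20% failures aborts
    with diagnostics. Reproducible given ``cfg.seed``.
    """
    if cfg.n_boot == 0:
        return {}, 0
    rng = cfg.rng()
    idx = _resample_indices(np.asarray(groups), rng, cfg.n_boot)
    draws: Dict[str, List[float]] = {k: [] for k in point}
    failures = 0
    for b in range(cfg.n_boot):
        try:
            est = refit(idx[b])
        except Exception:
            failures += 1
            continue
        for k in draws:
            draws[k].append(est[k])
    if failures > 0.2 * cfg.n_boot:
        raise RuntimeError(
            f"bootstrap unstable: {failures}/{cfg.n_boot} resample fits failed"
        )
    if failures:
        logger.warning("bootstrap: %d/%d resample fits failed", failures, cfg.n_boot)
    alpha = 1.0 - cfg.ci_level
    ci = {}
    for k, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        ci[k] = (
            float(np.quantile(arr, alpha / 2)),
            float(np.quantile(arr, 1 - alpha / 2)),
        )
    return ci, failures


# --------------------------------------------------------------------------
# retention fit
# --------------------------------------------------------------------------


def _prepare_retention(
    df: pd.DataFrame, reference: Optional[float]
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    missing = set(RETENTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"retention table missing columns: {sorted(missing)}")
    data = df[df["value_kind"] != "reference"].copy()
    n_total = len(data)
    data = data[data["qc_pass"].astype(bool)]
    logger.info("retention: %d rows read, %d excluded by QC", n_total, n_total - len(data))
    if data.empty:
        raise IllPosedError("no observations pass QC")
    kinds = set(data["value_kind"])
    if kinds == {"fraction"}:
        y = data["value"].to_numpy(dtype=float)
    elif kinds == {"signal"}:
        if reference is None or not reference > 0:
            raise ValueError("signal-mode observations require a positive reference")
        y = data["value"].to_numpy(dtype=float) / float(reference)
    else:
        raise ValueError(f"mixed or unknown value_kind in retention table: {sorted(kinds)}")
    if kinds == {"fraction"} and (np.any(y < 0) or np.any(y > 1)):
        raise ValueError("fraction-mode values must lie in [0, 1]")
    d = data["depth_mm"].to_numpy(dtype=float)
    if np.any(d < 0):
        raise ValueError("depths must be non-negative")
    if np.unique(d).size < 2:
        raise IllPosedError("all depths identical; beta is not identifiable")
    return d, y, data


def _beta_hat(d: np.ndarray, y: np.ndarray, cfg: FitConfig, x0: Optional[float] = None) -> float:
    def sse(beta: float) -> float:
        r = y + np.expm1(-beta * d)
        return float(r @ r)

    beta, _ = _fit_scalar(sse, cfg.beta_bounds, cfg.n_starts, x0=x0)
    return beta


def fit_retention(
    df: pd.DataFrame, cfg: Optional[FitConfig] = None, reference: Optional[float] = None
) -> FitResult:
    """Fit ``R(d) = 1 - exp(-beta*d)`` to a retention observation table.

    Minimises the unweighted sum of squared residuals over ``beta`` within
    ``cfg.beta_bounds``; bootstrap CIs resample sites with the seeded
    generator, stratified by depth group when the design allows.
    """
    cfg = cfg or FitConfig()
    d, y, data = _prepare_retention(df, reference)
    beta = _beta_hat(d, y, cfg)
    model = RetentionModel(beta=max(beta, np.finfo(float).tiny))
    pred = retention_at_depth(d, model)
    gof = goodness_of_fit(y, pred)
    residuals = pd.DataFrame(
        {
            "site_id": data["site_id"].to_numpy(),
            "depth_mm": d,
            "observed": y,
            "predicted": pred,
            "residual": y - pred,
        }
    )
    trend = residual_trend(residuals["residual"], d)

    def refit(idx: np.ndarray) -> Dict[str, float]:
        return {"beta": _beta_hat(d[idx], y[idx], cfg, x0=beta)}

    ci, n_fail = bootstrap_ci(refit, d, cfg, {"beta": beta})
    flags: List[str] = []
    converged = math.isfinite(beta)
    lo, hi = cfg.beta_bounds
    if beta >= min(hi, 1e6) - 1e-9:
        flags.append("beta_at_bound")
    return FitResult(
        estimates={"beta": beta},
        ci=ci,
        r_squared=gof["r_squared"],
        mae=gof["mae"],
        rmse=gof["rmse"],
        residuals=residuals,
        trend=trend,
        n_sites=int(len(data)),
        converged=converged,
        flags=flags,
        n_boot_failures=n_fail,
    )


# --------------------------------------------------------------------------
# growth / hypoperfusion fit
# --------------------------------------------------------------------------


def _parse_mode(mode: str, what: str) -> Tuple[bool, Optional[float]]:
    """Return (is_free, fixed_value) for 'free' or 'fixed:<value>' modes."""
    if mode == "free":
        return True, None
    if mode.startswith("fixed"):
        _, _, val = mode.partition(":")
        if what == "margin" and val == "":
            return False, None  # margin value comes from cfg.margin_um
        if val == "":
            raise ValueError(f"{what} fixed mode needs a value, e.g. 'fixed:3'")
        return False, float(val)
    raise ValueError(f"unrecognised {what} mode: {mode!r}")


def _prepare_growth(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame, str]:
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    data = df[df["qc_pass"].astype(bool)].copy()
    logger.info("growth: %d rows read, %d excluded by QC", len(df), len(df) - len(data))
    if data.empty:
        raise IllPosedError("no observations pass QC")
    kinds = set(data["value_kind"])
    if len(kinds) != 1 or kinds - {"growth", "hypor"}:
        raise ValueError(f"growth table value_kind must be homogeneous growth|hypor, got {sorted(kinds)}")
    kind = kinds.pop()
    v = ul_to_um3(data["volume_ul"].to_numpy(dtype=float))
    if np.any(v <= 0):
        raise ValueError("volumes must be strictly positive")
    if np.unique(v).size < 2:
        raise IllPosedError("all volumes identical; model is not identifiable")
    y = data["value"].to_numpy(dtype=float)
    if kind == "hypor" and (np.any(y < 0) or np.any(y > 1)):
        raise ValueError("hypor readouts must lie in [0, 1]")
    return v, y, data, kind


def _fit_growth_params(
    v: np.ndarray, y: np.ndarray, cfg: FitConfig, warm: Optional[Dict[str, float]] = None
) -> Tuple[Dict[str, float], List[str]]:
    """Estimate (gmax, gamma) per cfg modes on the growth readout scale."""
    gamma_free, gamma_fixed = _parse_mode(cfg.gamma_mode, "gamma")
    gmax_free, gmax_fixed = _parse_mode(cfg.gmax_mode, "gmax")
    margin = cfg.margin_um
    hyp = np.asarray(hypoperfused_fraction_volume(v, margin))
    flags: List[str] = []

    if np.all(hyp == 0.0):
        # flat region: gamma has no leverage
        gmax = float(np.mean(y)) if gmax_free else float(gmax_fixed)
        gamma = gamma_fixed if not gamma_free else float("nan")
        if gamma_free:
            flags.append("gamma_unidentifiable")
        return {"gmax": gmax, "gamma": gamma}, flags

    base = 1.0 - hyp  # in (0, 1]

    free_names: List[str] = []
    if gmax_free:
        free_names.append("gmax")
    if gamma_free:
        free_names.append("gamma")

    def predict(gmax: float, gamma: float) -> np.ndarray:
        return gmax * base**gamma

    if not free_names:
        return {"gmax": float(gmax_fixed), "gamma": float(gamma_fixed)}, flags

    if free_names == ["gmax"]:
        # linear in gmax: closed-form OLS, projected to bounds
        g = base**gamma_fixed
        gmax = float(np.clip((g @ y) / (g @ g), *cfg.gmax_bounds))
        return {"gmax": gmax, "gamma": float(gamma_fixed)}, flags

    lo = np.array([cfg.gmax_bounds[0] if n == "gmax" else cfg.gamma_bounds[0] for n in free_names])
    hi = np.array([cfg.gmax_bounds[1] if n == "gmax" else cfg.gamma_bounds[1] for n in free_names])

    def residual_fn(x: np.ndarray) -> np.ndarray:
        params = dict(zip(free_names, x))
        gmax = params.get("gmax", gmax_fixed)
        gamma = params.get("gamma", gamma_fixed)
        return predict(gmax, gamma) - y

    if warm is not None:
        starts = np.array([[warm[n] for n in free_names]])
        starts = np.clip(starts, lo + 1e-12, hi - 1e-12)
    else:
        per_param = []
        for n in free_names:
            if n == "gmax":
                centre = max(float(np.max(y)), 1e-6)
                per_param.append(np.geomspace(centre / 4, centre * 4, cfg.n_starts))
            else:
                per_param.append(np.geomspace(0.25, 8.0, cfg.n_starts))
        starts = np.array(list(itertools.product(*per_param)))
        starts = np.clip(starts, lo + 1e-12, hi - 1e-12)
    x, _, ok = _fit_vector(residual_fn, (lo, hi), starts)
    params = dict(zip(free_names, x))
    gmax = float(params.get("gmax", gmax_fixed))
    gamma = float(params.get("gamma", gamma_fixed))
    if not ok:
        flags.append("optimizer_not_converged")
    if gamma_free and (
        gamma <= cfg.gamma_bounds[0] * (1 + 1e-6) or gamma >= cfg.gamma_bounds[1] * (1 - 1e-6)
    ):
        flags.append("gamma_at_bound")
    return {"gmax": gmax, "gamma": gamma}, flags


def _fit_margin(v: np.ndarray, y: np.ndarray, cfg: FitConfig, x0: Optional[float] = None) -> float:
    def sse(margin: float) -> float:
        r = np.asarray(hypoperfused_fraction_volume(v, margin)) - y
        return float(r @ r)

    margin, _ = _fit_scalar(sse, cfg.margin_bounds, cfg.n_starts, x0=x0)
    return margin


def fit_growth(df: pd.DataFrame, cfg: Optional[FitConfig] = None) -> FitResult:
    """Fit the hypoperfusion-volume family to a growth observation table.

    ``value_kind == "growth"`` fits ``G(v) = Gmax*(1 - HypoR(v))**gamma``
    with Gmax/gamma free or fixed per config; ``value_kind == "hypor"``
    fits ``HypoR(v; margin)`` with the margin free or fixed.
    """
    cfg = cfg or FitConfig()
    v, y, data, kind = _prepare_growth(df)

    if kind == "hypor":
        margin_free = cfg.margin_mode == "free"
        if margin_free:
            margin = _fit_margin(v, y, cfg)
        else:
            margin = cfg.margin_um
        estimates = {"margin": float(margin)}
        pred = np.asarray(hypoperfused_fraction_volume(v, margin))
        flags: List[str] = []

        def refit(idx: np.ndarray) -> Dict[str, float]:
            if margin_free:
                return {"margin": _fit_margin(v[idx], y[idx], cfg, x0=margin)}
            return {"margin": margin}

    else:
        estimates, flags = _fit_growth_params(v, y, cfg, warm=None)
        gm = GrowthModel(
            g_max=max(estimates["gmax"], np.finfo(float).tiny),
            gamma=estimates["gamma"] if math.isfinite(estimates["gamma"]) else 1.0,
            margin=cfg.margin_um,
        )
        if math.isfinite(estimates["gamma"]):
            pred = np.asarray(growth_rate(v, gm))
        else:  # gamma unidentifiable: flat prediction
            pred = np.full_like(y, estimates["gmax"])

        warm = {k: val for k, val in estimates.items() if math.isfinite(val)}

        def refit(idx: np.ndarray) -> Dict[str, float]:
            est, _ = _fit_growth_params(v[idx], y[idx], cfg, warm=warm)
            return est

    gof = goodness_of_fit(y, pred)
    residuals = pd.DataFrame(
        {
            "site_id": data["site_id"].to_numpy(),
            "volume_ul": data["volume_ul"].to_numpy(dtype=float),
            "observed": y,
            "predicted": pred,
            "residual": y - pred,
        }
    )
    trend = residual_trend(residuals["residual"], residuals["volume_ul"])
    point = {k: val for k, val in estimates.items() if math.isfinite(val)}
    ci, n_fail = bootstrap_ci(refit, v, cfg, point)
    return FitResult(
        estimates={k: float(val) for k, val in estimates.items()},
        ci=ci,
        r_squared=gof["r_squared"],
        mae=gof["mae"],
        rmse=gof["rmse"],
        residuals=residuals,
        trend=trend,
        n_sites=int(len(data)),
        converged="optimizer_not_converged" not in flags,
        flags=flags,
        n_boot_failures=n_fail,
    )


# --------------------------------------------------------------------------
# model selection and sensitivity
# --------------------------------------------------------------------------


def _n_free(gamma_mode: str, gmax_mode: str) -> int:
    return int(gamma_mode == "free") + int(gmax_mode == "free")


def model_selection_gamma(
    df: pd.DataFrame,
    candidates: Sequence,
    cfg: Optional[FitConfig] = None,
) -> List[CandidateFit]:
    """Compare candidate growth exponents and rank them.

    ``candidates`` entries are gamma modes (``"fixed:1"``, ``"free"``, ...)
    or bare numbers meaning a fixed exponent. Ranking keeps the simplest
    model whose residuals show no volume dependence: untrended models come
    first, then fewer free parameters, then lower RMSE. Per-candidate fit
    errors are recorded without aborting the others and sort last.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    cfg = cfg or FitConfig()
    results: List[CandidateFit] = []
    for cand in candidates:
        mode = f"fixed:{cand:g}" if isinstance(cand, (int, float)) else str(cand)
        sub = replace(cfg, gamma_mode=mode)
        entry = CandidateFit(label=mode, n_free=_n_free(mode, cfg.gmax_mode))
        try:
            entry.result = fit_growth(df, sub)
        except Exception as exc:
            entry.error = f"{type(exc).__name__}: {exc}"
        results.append(entry)

    def key(c: CandidateFit):
        if c.result is None:
            return (2, 0, math.inf, c.label)
        trended = 1 if c.result.trend["flagged"] else 0
        return (trended, c.n_free, c.result.rmse, c.label)

    return sorted(results, key=key)


def sensitivity_sweep(
    model,
    fraction: float = 0.20,
    n_points: int = 5,
    grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Scale each model parameter through [1-fraction, 1+fraction].

    Returns a tidy, plot-ready table with columns ``parameter``,
    ``multiplier``, ``x`` (depth in mm or volume in um^3) and
    ``prediction``; the multiplier grid always contains the baseline 1.0.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    multipliers = np.unique(np.append(np.linspace(1 - fraction, 1 + fraction, n_points), 1.0))
    rows = []
    if isinstance(model, RetentionModel):
        xs = np.linspace(0.0, 5.0, 51) if grid is None else np.asarray(grid, dtype=float)
        params = {"beta": model.beta}
        for name, value in params.items():
            for m in multipliers:
                pred = retention_at_depth(xs, RetentionModel(beta=value * m, n=model.n))
                rows.extend(
                    {"parameter": name, "multiplier": float(m), "x": float(x), "prediction": float(p)}
                    for x, p in zip(xs, np.atleast_1d(pred))
                )
    elif isinstance(model, GrowthModel):
        xs = (
            np.geomspace(1e6, 2e9, 41) if grid is None else np.asarray(grid, dtype=float)
        )  # 1 nL .. 2 uL
        params = {"g_max": model.g_max, "gamma": model.gamma}
        for name, value in params.items():
            for m in multipliers:
                kwargs = {"g_max": model.g_max, "gamma": model.gamma, "margin": model.margin}
                kwargs[name] = value * m
                pred = growth_rate(xs, GrowthModel(**kwargs))
                rows.extend(
                    {"parameter": name, "multiplier": float(m), "x": float(x), "prediction": float(p)}
                    for x, p in zip(xs, np.atleast_1d(pred))
                )
    else:
        raise TypeError("model must be a RetentionModel or GrowthModel")
    return pd.DataFrame(rows, columns=["parameter", "multiplier", "x", "prediction"])
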
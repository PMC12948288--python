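"""Graft-interface analytics: peri-graft classification, recruitment
counts, calcium-trace normalisation and 3D migration metrics.

Inputs are coordinate/intensity tables produced upstream (manual ROI
drawing and cell re-identification under two-photon imaging); no image
processing happens here.

Track tables carry one row per (cell_id, day) with columns
``cell_id, day, x_um, y_um, z_um`` in a fixed right-handed field-of-view
frame (z grows with imaging depth). ROI tables carry
``cell_id, day, roi_mean, background`` in arbitrary intensity units.

Proximity to the implantation site uses the planar (x, y) distance to the
site centre with an inclusive boundary at the site radius (default
120 um) — the convention of drawing a circle on 2D projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "GraftSite",
    "TRACK_COLUMNS",
    "ROI_COLUMNS",
    "classify_proximity",
    "count_within_radius",
    "migration_metrics",
    "migration_metrics_all",
    "normalize_trace",
    "link_tracks",
]

TRACK_COLUMNS = ("cell_id", "day", "x_um", "y_um", "z_um")
ROI_COLUMNS = ("cell_id", "day", "roi_mean", "background")

PERI = "peri_graft"
DISTAL = "distal"


@dataclass(frozen=True)
class GraftSite:
    """Implantation site: planar centre (um) and peri-graft radius (um)."""

    center: Tuple[float, float]
    radius: float = 120.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("site radius must be strictly positive")


def _require_columns(df: pd.DataFrame, columns) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")


def classify_proximity(points: pd.DataFrame, site: GraftSite) -> pd.DataFrame:
    """Label each (cell, day) row peri_graft or distal.

    Peri-graft iff the planar distance to the site centre is <= radius
    (boundary inclusive); z is ignored. Returns a copy with a ``label``
    column; an empty input yields an empty labelled frame.
    """
    _require_columns(points, ("cell_id", "day", "x_um", "y_um"))
    out = points.copy()
    cx, cy = site.center
    dist = np.hypot(out["x_um"].to_numpy(float) - cx, out["y_um"].to_numpy(float) - cy)
    out["label"] = np.where(dist <= site.radius, PERI, DISTAL)
    return out


def count_within_radius(points: pd.DataFrame, site: GraftSite) -> pd.Series:
    """Per-day count of distinct cells inside the peri-graft circle."""
    _require_columns(points, ("cell_id", "day", "x_um", "y_um"))
    if points.duplicated(subset=["cell_id", "day"]).any():
        raise ValueError("duplicate (cell_id, day) rows in track table")
    labelled = classify_proximity(points, site)
    peri = labelled[labelled["label"] == PERI]
    counts = peri.groupby("day")["cell_id"].nunique()
    return counts.reindex(sorted(labelled["day"].unique()), fill_value=0).astype(int)


def migration_metrics(track: pd.DataFrame) -> Dict[str, object]:
    """Path length, net displacement and per-interval steps of one track.

    ``path_length_um`` sums Euclidean 3D step lengths between consecutive
    sessions; ``net_displacement_um`` is the straight first-to-last
    distance. A single-point track returns zeros with a flag.
    """
    _require_columns(track, TRACK_COLUMNS)
    ids = track["cell_id"].unique()
    if len(ids) != 1:
        raise ValueError("migration_metrics expects a single cell's track")
    t = track.sort_values("day")
    xyz = t[["x_um", "y_um", "z_um"]].to_numpy(float)
    days = t["day"].to_numpy()
    if len(t) < 2:
        return {
            "cell_id": ids[0],
            "path_length_um": 0.0,
            "net_displacement_um": 0.0,
            "steps": pd.DataFrame(columns=["day_from", "day_to", "step_um"]),
            "single_point": True,
        }
    deltas = np.diff(xyz, axis=0)
    step_lengths = np.linalg.norm(deltas, axis=1)
    steps = pd.DataFrame(
        {"day_from": days[:-1], "day_to": days[1:], "step_um": step_lengths}
    )
    return {
        "cell_id": ids[0],
        "path_length_um": float(step_lengths.sum()),
        "net_displacement_um": float(np.linalg.norm(xyz[-1] - xyz[0])),
        "steps": steps,
        "single_point": False,
    }


def migration_metrics_all(points: pd.DataFrame) -> pd.DataFrame:
    """Per-cell migration summary table over a multi-cell track table."""
    _require_columns(points, TRACK_COLUMNS)
    rows = []
    for cell_id, track in points.groupby("cell_id", sort=True):
        m = migration_metrics(track)
        rows.append(
            {
                "cell_id": cell_id,
                "path_length_um": m["path_length_um"],
                "net_displacement_um": m["net_displacement_um"],
                "n_days": len(track),
                "single_point": m["single_point"],
            }
        )
    return pd.DataFrame(rows)


def normalize_trace(
    traces: pd.DataFrame, baseline: Union[str, float] = "final_day_mean"
) -> pd.DataFrame:
    """Background-subtract and normalise ROI intensity traces.

    ``corrected = roi_mean - background``, clipped at 0 with a ``clipped``
    flag when negative. ``normalized = corrected / baseline`` where the
    baseline is either an explicit positive number or the rule
    ``"final_day_mean"`` (mean corrected intensity over all cells on the
    last session day — the convention when activity has returned to rest
    by the end of the observation window).
    """
    _require_columns(traces, ROI_COLUMNS)
    out = traces.copy()
    corrected = out["roi_mean"].to_numpy(float) - out["background"].to_numpy(float)
    out["clipped"] = corrected < 0
    out["corrected"] = np.maximum(corrected, 0.0)
    if isinstance(baseline, str):
        if baseline != "final_day_mean":
            raise ValueError(f"unknown baseline rule: {baseline!r}")
        last_day = out["day"].max()
        base = float(out.loc[out["day"] == last_day, "corrected"].mean())
    else:
        base = float(baseline)
    if not base > 0:
        raise ValueError("baseline must be strictly positive")
    out["normalized"] = out["corrected"] / base
    return out


def link_tracks(points: pd.DataFrame, max_step: float) -> pd.DataFrame:
    """Assign cell identities across days by optimal frame-to-frame matching.

    Convenience linker for synthetic or lightly curated data (manual
    landmark-based identities, when present, should be used verbatim
    instead). Consecutive days are matched by minimising total 3D
    displacement (Hungarian assignment) among pairs within ``max_step``;
    unmatched points start new identities. A match is flagged ambiguous
    when either endpoint had several feasible candidates. Deterministic:
    points are processed in (day, x, y, z) order.
    """
    if not max_step > 0:
        raise ValueError("max_step must be strictly positive")
    _require_columns(points, ("day", "x_um", "y_um", "z_um"))
    pts = points.sort_values(["day", "x_um", "y_um", "z_um"], kind="mergesort").reset_index(
        drop=True
    )
    pts["cell_id"] = -1
    pts["ambiguous"] = False
    days = sorted(pts["day"].unique())
    next_id = 0
    first = pts.index[pts["day"] == days[0]]
    for i in first:
        pts.at[i, "cell_id"] = next_id
        next_id += 1
    big = 1e9
    for prev_day, day in zip(days, days[1:]):
        prev_idx = pts.index[pts["day"] == prev_day].to_numpy()
        cur_idx = pts.index[pts["day"] == day].to_numpy()
        if prev_idx.size and cur_idx.size:
            a = pts.loc[prev_idx, ["x_um", "y_um", "z_um"]].to_numpy(float)
            b = pts.loc[cur_idx, ["x_um", "y_um", "z_um"]].to_numpy(float)
            dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            feasible = dist <= max_step
            cost = np.where(feasible, dist, big)
            ri, ci = linear_sum_assignment(cost)
            matched_cur = set()
            for r, c in zip(ri, ci):
                if not feasible[r, c]:
                    continue
                j = cur_idx[c]
                pts.at[j, "cell_id"] = pts.at[prev_idx[r], "cell_id"]
                if feasible[r].sum() > 1 or feasible[:, c].sum() > 1:
                    pts.at[j, "ambiguous"] = True
                matched_cur.add(j)
        else:
            matched_cur = set()
        for j in cur_idx:
            if j not in matched_cur:
                pts.at[j, "cell_id"] = next_id
                next_id += 1
    return pts
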
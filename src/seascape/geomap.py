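"""Downstream soundscape analysis.

Links classification summaries to GPS positions (nearest fix within one
hour before or after the sound), filters out near-surface records (depth
>= 2 m keeps only observations away from surface wave/current artifacts),
estimates per-class spatial density with a Gaussian kernel (soundscape
maps, computed only for classes with more than 10 located points), and
does the deployment bookkeeping: positioning RMSE against a reference and
data-recovery rates of transmitted vs. directly downloaded records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .deployment import EARTH_RADIUS_M, GpsFix
from .telemetry import ClassificationSummary

ASSOCIATION_WINDOW_S = 3600.0
MIN_KDE_POINTS = 11  # "more than 10 points"
DEPTH_THRESHOLD_M = 2.0


@dataclass(frozen=True)
class GeoTaggedSound:
    summary: ClassificationSummary
    fix: GpsFix
    time_gap_s: float  # fix time minus sound time (signed)


@dataclass
class DensitySurface:
    """Gaussian-KDE density over a lat/lon grid; integrates to ~1."""

    lats: np.ndarray  # grid cell-center latitudes (n_lat,)
    lons: np.ndarray  # grid cell-center longitudes (n_lon,)
    density: np.ndarray  # (n_lat, n_lon), per square degree
    bandwidth: tuple[float, float]
    class_id: int | None
    point_count: int

    def peak(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.lats[i]), float(self.lons[j])

    def integral(self) -> float:
        dlat = self.lats[1] - self.lats[0] if len(self.lats) > 1 else 1.0
        dlon = self.lons[1] - self.lons[0] if len(self.lons) > 1 else 1.0
        return float(self.density.sum() * dlat * dlon)


# ---------------------------------------------------------------------------
# association


def associate_position(t_sound: float, fixes: Sequence[GpsFix]) -> GpsFix | None:
    """Most recent fix within one hour before or after the sound.

    Returns the fix minimizing |fix time - sound time| subject to the
    one-hour window; None if no fix qualifies.  An exact before/after tie
    resolves to the earlier fix (the position observed before the sound).
    """
    times = [f.t for f in fixes]
    if sorted(times) != times:
        raise ValueError("fixes must be sorted by time")
    best: GpsFix | None = None
    best_gap = ASSOCIATION_WINDOW_S
    for f in fixes:
        gap = abs(f.t - t_sound)
        if gap <= best_gap and not (gap == best_gap and best is not None):
            best, best_gap = f, gap
    return best


def associate_sounds(
    summaries: Sequence[ClassificationSummary], fixes: Sequence[GpsFix]
) -> list[GeoTaggedSound]:
    """Geo-tag every summary that has a qualifying fix."""
    out = []
    for s in summaries:
        fix = associate_position(s.t_start, fixes)
        if fix is not None:
            out.append(GeoTaggedSound(s, fix, fix.t - s.t_start))
    return out


# ---------------------------------------------------------------------------
# depth filter


@dataclass
class DepthFilterResult:
    kept: list
    removed: list
    missing_depth: int

    def __iter__(self):
        return iter(self.kept)


def filter_by_depth(records: Sequence, threshold_m: float = DEPTH_THRESHOLD_M) -> DepthFilterResult:
    """Keep records whose depth is at least the threshold ("2 m or deeper").

    Records may be ClassificationSummary, GeoTaggedSound or anything with a
    ``depth_m``.  Records with a missing (None/NaN) depth are excluded and
    counted separately.  Order is preserved.
    """
    kept, removed, missing = [], [], 0
    for rec in records:
        depth = getattr(rec, "depth_m", None)
        if depth is None and hasattr(rec, "summary"):
            depth = rec.summary.depth_m
        if depth is None or (isinstance(depth, float) and math.isnan(depth)):
            removed.append(rec)
            missing += 1
        elif depth >= threshold_m:
            kept.append(rec)
        else:
            removed.append(rec)
    return DepthFilterResult(kept, removed, missing)


# ---------------------------------------------------------------------------
# kernel density


def _scott_bandwidth(values: np.ndarray, n: int, floor: float) -> float:
    sigma = float(np.std(values))
    h = sigma * n ** (-1 / 6)  # Scott's rule, d = 2
    return max(h, floor)


def kde_map(
    points: Sequence[tuple[float, float]],
    grid_bounds: tuple[float, float, float, float] | None = None,
    n_grid: int = 100,
    bandwidth: tuple[float, float] | None = None,
    class_id: int | None = None,
    force: bool = False,
) -> DensitySurface:
    """Gaussian kernel density of located sound points on a lat/lon grid.

    ``points`` are (lat, lon) pairs.  Requires more than 10 points unless
    ``force=True`` (too few points give an unstable density).  Bandwidth
    defaults to Scott's rule per axis, floored so that coincident points
    still produce a finite unimodal surface.  ``grid_bounds`` is
    (lat_min, lat_max, lon_min, lon_max); by default the point bounding box
    padded by five bandwidths so the grid captures essentially all mass.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (lat, lon) pairs")
    n = len(pts)
    if n < MIN_KDE_POINTS and not force:
        raise ValueError(
            f"kernel density needs more than 10 points, got {n}; "
            "pass force=True to override"
        )
    lat, lon = pts[:, 0], pts[:, 1]
    if bandwidth is None:
        # bandwidth floor keeps coincident points finite (~one default cell)
        floor_lat = max((lat.max() - lat.min()) / n_grid, 1e-4)
        floor_lon = max((lon.max() - lon.min()) / n_grid, 1e-4)
        bandwidth = (
            _scott_bandwidth(lat, n, floor_lat),
            _scott_bandwidth(lon, n, floor_lon),
        )
    h_lat, h_lon = bandwidth
    if grid_bounds is None:
        # pad by 5 bandwidths so the Gaussian tails stay on the grid
        grid_bounds = (lat.min() - 5 * h_lat, lat.max() + 5 * h_lat,
                       lon.min() - 5 * h_lon, lon.max() + 5 * h_lon)
    lat_min, lat_max, lon_min, lon_max = grid_bounds
    lats = np.linspace(lat_min, lat_max, n_grid)
    lons = np.linspace(lon_min, lon_max, n_grid)
    # separable Gaussian kernels: density = mean_i N(lat; lat_i, h_lat) N(lon; lon_i, h_lon)
    k_lat = np.exp(-0.5 * ((lats[:, None] - lat[None, :]) / h_lat) ** 2) / (
        h_lat * math.sqrt(2 * math.pi)
    )
    k_lon = np.exp(-0.5 * ((lons[:, None] - lon[None, :]) / h_lon) ** 2) / (
        h_lon * math.sqrt(2 * math.pi)
    )
    density = (k_lat @ k_lon.T) / n
    return DensitySurface(lats, lons, density, (h_lat, h_lon), class_id, n)


def points_for_class(
    tagged: Sequence[GeoTaggedSound], class_id: int, membership: str = "top3"
) -> list[tuple[float, float]]:
    """(lat, lon) points where a class was reported.

    ``membership="top1"`` counts only summaries whose most probable class is
    ``class_id``; ``"top3"`` counts any summary whose transmitted top-3
    includes it (the summary record carries exactly those three classes).
    """
    if membership == "top1":
        keep = lambda s: s.top3[0][0] == class_id
    elif membership == "top3":
        keep = lambda s: class_id in [c for c, _ in s.top3]
    else:
        raise ValueError(f"membership must be 'top1' or 'top3', got {membership!r}")
    return [(g.fix.lat, g.fix.lon) for g in tagged if keep(g.summary)]


# ---------------------------------------------------------------------------
# distances and bookkeeping


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def position_rmse(fixes: Sequence[GpsFix], reference: tuple[float, float]) -> float:
    """Root-mean-square great-circle deviation of fixes from a reference."""
    if len(fixes) == 0:
        raise ValueError("position_rmse needs at least one fix")
    d = [haversine_m(f.lat, f.lon, reference[0], reference[1]) for f in fixes]
    return float(np.sqrt(np.mean(np.square(d))))


def recovery_report(per_deployment: pd.DataFrame) -> pd.Series:
    """Data-recovery bookkeeping over a set of deployments.

    ``per_deployment`` columns: ``transmitted_sound``, ``direct_sound``,
    ``transmitted_position``, ``direct_position``, ``duration_h``.  Recovery
    percentages (100 * transmitted / direct) include only deployments with
    at least one successful transmission; a deployment with zero direct
    records is excluded from that channel's ratio with a warning flag in
    the output.  Both pooled-count and mean-of-per-deployment-ratio modes
    are reported, and duration statistics cover all deployments.
    """
    df = per_deployment.copy()
    needed = ["transmitted_sound", "direct_sound", "transmitted_position", "direct_position"]
    if (df[needed] < 0).any().any():
        raise ValueError("counts must be nonnegative")
    if (df["transmitted_sound"] > df["direct_sound"]).any() or (
        df["transmitted_position"] > df["direct_position"]
    ).any():
        raise ValueError("transmitted counts cannot exceed direct-download counts")
    any_tx = (df["transmitted_sound"] + df["transmitted_position"]) > 0
    inc = df[any_tx]
    out: dict[str, float] = {"n_deployments": len(df), "n_with_transmission": int(any_tx.sum())}
    excluded = 0
    for channel in ("sound", "position"):
        tx, direct = inc[f"transmitted_{channel}"], inc[f"direct_{channel}"]
        valid = direct > 0
        excluded += int((~valid).sum())
        out[f"{channel}_recovery_pooled_pct"] = (
            100.0 * tx[valid].sum() / direct[valid].sum() if valid.any() else float("nan")
        )
        out[f"{channel}_recovery_mean_ratio_pct"] = (
            float(100.0 * (tx[valid] / direct[valid]).mean()) if valid.any() else float("nan")
        )
    out["excluded_zero_direct"] = excluded
    if "duration_h" in df:
        out["duration_mean_h"] = float(df["duration_h"].mean())
        out["duration_sd_h"] = float(df["duration_h"].std(ddof=1)) if len(df) > 1 else 0.0
    return pd.Series(out)
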
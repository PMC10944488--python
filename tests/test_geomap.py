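import math

import numpy as np
import pandas as pd
import pytest

from seascape.deployment import EARTH_RADIUS_M, GpsFix
from seascape.geomap import (
    associate_position,
    associate_sounds,
    filter_by_depth,
    haversine_m,
    kde_map,
    position_rmse,
    recovery_report,
)
from seascape.telemetry import ClassificationSummary


def _fix(t, lat=24.3, lon=124.1):
    return GpsFix(t=t, lat=lat, lon=lon)


def _summary(t, depth=5.0, top=(0, 0.9)):
    return ClassificationSummary(
        t_start=t,
        top3=(top, (1, 0.05), (2, 0.05)),
        depth_m=depth,
        temperature_c=27.0,
        accel_magnitude_g=1.0,
        mag_magnitude_ut=45.0,
    )


def _offset_fix(t, ref, north_m=0.0, east_m=0.0):
    lat = ref[0] + math.degrees(north_m / EARTH_RADIUS_M)
    lon = ref[1] + math.degrees(east_m / (EARTH_RADIUS_M * math.cos(math.radians(ref[0]))))
    return GpsFix(t=t, lat=lat, lon=lon)


# ---------------------------------------------------------------------------
# position association


def test_nearest_fix_within_one_hour_wins():
    t = 10_000.0
    fixes = [_fix(t - 90 * 60), _fix(t - 30 * 60)]
    assert associate_position(t, fixes) is fixes[1]


def test_no_fix_within_window_returns_none():
    t = 10_000.0
    assert associate_position(t, [_fix(t - 2 * 3600), _fix(t + 2 * 3600)]) is None


def test_exact_before_after_tie_prefers_earlier_fix():
    t = 10_000.0
    fixes = [_fix(t - 600), _fix(t + 600)]
    assert associate_position(t, fixes) is fixes[0]


def test_unsorted_fixes_rejected():
    with pytest.raises(ValueError, match="sorted"):
        associate_position(0.0, [_fix(100.0), _fix(50.0)])


def test_association_invariant_under_time_shift():
    fixes = [_fix(t) for t in (100.0, 2000.0, 5000.0)]
    summaries = [_summary(t) for t in (900.0, 4200.0)]
    tagged = associate_sounds(summaries, fixes)
    shift = 12_345.0
    fixes2 = [_fix(f.t + shift) for f in fixes]
    summaries2 = [_summary(s.t_start + shift) for s in summaries]
    tagged2 = associate_sounds(summaries2, fixes2)
    assert [g.time_gap_s for g in tagged] == [g.time_gap_s for g in tagged2]


# ---------------------------------------------------------------------------
# depth filter


def test_depth_filter_boundary_is_inclusive():
    records = [_summary(0, depth=0.5), _summary(1, depth=2.0), _summary(2, depth=3.1)]
    result = filter_by_depth(records, 2.0)
    assert [r.depth_m for r in result.kept] == [2.0, 3.1]


def test_all_shallow_yields_empty_without_error():
    result = filter_by_depth([_summary(0, depth=0.1)], 2.0)
    assert result.kept == []


def test_missing_depth_excluded_and_counted():
    records = [_summary(0, depth=float("nan")), _summary(1, depth=5.0)]
    result = filter_by_depth(records)
    assert len(result.kept) == 1
    assert result.missing_depth == 1


def test_filter_conserves_records():
    rng = np.random.default_rng(0)
    records = [_summary(i, depth=float(d)) for i, d in enumerate(rng.uniform(0, 10, 50))]
    result = filter_by_depth(records)
    assert len(result.kept) + len(result.removed) == 50
    expected_kept = sum(r.depth_m >= 2.0 for r in records)
    assert len(result.kept) == expected_kept


# ---------------------------------------------------------------------------
# kernel density


def test_ten_points_refused_eleven_accepted():
    pts = [(24.3 + 0.001 * i, 124.1) for i in range(10)]
    with pytest.raises(ValueError, match="more than 10"):
        kde_map(pts)
    kde_map(pts, force=True)
    kde_map(pts + [(24.3, 124.1)])


def test_coincident_points_peak_at_their_location():
    surface = kde_map([(24.3, 124.1)] * 11)
    lat, lon = surface.peak()
    assert abs(lat - 24.3) < 1e-3 and abs(lon - 124.1) < 1e-3
    assert surface.integral() == pytest.approx(1.0, abs=0.02)


def test_two_clusters_give_two_local_maxima():
    rng = np.random.default_rng(1)
    a = np.column_stack([24.30 + rng.normal(0, 0.002, 20), 124.10 + rng.normal(0, 0.002, 20)])
    b = np.column_stack([24.40 + rng.normal(0, 0.002, 20), 124.20 + rng.normal(0, 0.002, 20)])
    surface = kde_map(np.vstack([a, b]), bandwidth=(0.004, 0.004))
    # grid argmax within each half of the latitude axis
    half = int(np.searchsorted(surface.lats, 24.35))
    d = surface.density
    for block, row0, (lat_c, lon_c) in (
        (d[:half], 0, (24.30, 124.10)),
        (d[half:], half, (24.40, 124.20)),
    ):
        i, j = np.unravel_index(np.argmax(block), block.shape)
        assert abs(surface.lats[row0 + i] - lat_c) < 0.01
        assert abs(surface.lons[j] - lon_c) < 0.01


@pytest.mark.parametrize("bandwidth", [None, (0.001, 0.001), (0.01, 0.02)])
def test_density_integrates_to_one(bandwidth):
    rng = np.random.default_rng(2)
    pts = np.column_stack(
        [24.3 + rng.normal(0, 0.003, 40), 124.1 + rng.normal(0, 0.005, 40)]
    )
    surface = kde_map(pts, bandwidth=bandwidth)
    assert surface.integral() == pytest.approx(1.0, abs=0.02)


def test_kde_matches_brute_force_evaluation():
    """Grid densities equal a direct double-loop kernel sum."""
    rng = np.random.default_rng(3)
    pts = np.column_stack(
        [24.3 + rng.normal(0, 0.004, 15), 124.1 + rng.normal(0, 0.004, 15)]
    )
    h = 0.003
    surface = kde_map(pts, bandwidth=(h, h), n_grid=12)
    norm = 1.0 / (2 * math.pi * h * h)
    for i, lat in enumerate(surface.lats):
        for j, lon in enumerate(surface.lons):
            expected = np.mean(
                [
                    norm
                    * math.exp(-0.5 * (((lat - p) / h) ** 2 + ((lon - q) / h) ** 2))
                    for p, q in pts
                ]
            )
            assert surface.density[i, j] == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# positioning error


def test_rmse_zero_when_all_fixes_at_reference():
    ref = (24.3, 124.1)
    assert position_rmse([_fix(0.0), _fix(1.0)], ref) == pytest.approx(0.0, abs=1e-9)


def test_rmse_closed_form_for_two_fixes():
    ref = (24.3, 124.1)
    fixes = [_offset_fix(0.0, ref, north_m=3.0), _offset_fix(1.0, ref, east_m=4.0)]
    assert position_rmse(fixes, ref) == pytest.approx(math.sqrt((9 + 16) / 2), rel=1e-4)


def test_rmse_recovers_gaussian_noise_scale():
    """2-D isotropic noise of sigma per axis has RMSE sigma * sqrt(2)."""
    ref = (24.3, 124.1)
    rng = np.random.default_rng(4)
    sigma = 20.0
    fixes = [
        _offset_fix(float(i), ref, north_m=rng.normal(0, sigma), east_m=rng.normal(0, sigma))
        for i in range(4000)
    ]
    assert position_rmse(fixes, ref) == pytest.approx(sigma * math.sqrt(2), rel=0.05)


def test_rmse_requires_fixes():
    with pytest.raises(ValueError, match="at least one"):
        position_rmse([], (0.0, 0.0))


# ---------------------------------------------------------------------------
# recovery bookkeeping


def _deployments(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "transmitted_sound",
            "direct_sound",
            "transmitted_position",
            "direct_position",
            "duration_h",
        ],
    )


def test_full_recovery_is_100_percent():
    df = _deployments([[10, 10, 20, 20, 5.0], [7, 7, 3, 3, 8.0]])
    rep = recovery_report(df)
    assert rep["sound_recovery_pooled_pct"] == pytest.approx(100.0)
    assert rep["position_recovery_mean_ratio_pct"] == pytest.approx(100.0)


def test_two_deployment_hand_computation():
    df = _deployments([[8, 10, 30, 40, 10.0], [2, 10, 10, 40, 20.0]])
    rep = recovery_report(df)
    assert rep["sound_recovery_pooled_pct"] == pytest.approx(100 * 10 / 20)
    assert rep["sound_recovery_mean_ratio_pct"] == pytest.approx(100 * (0.8 + 0.2) / 2)
    assert rep["position_recovery_pooled_pct"] == pytest.approx(100 * 40 / 80)
    assert rep["duration_mean_h"] == pytest.approx(15.0)
    assert rep["duration_sd_h"] == pytest.approx(np.std([10, 20], ddof=1))


def test_deployments_without_transmission_excluded_from_ratios():
    df = _deployments([[5, 10, 5, 10, 1.0], [0, 10, 0, 10, 2.0]])
    rep = recovery_report(df)
    assert rep["n_with_transmission"] == 1
    assert rep["sound_recovery_pooled_pct"] == pytest.approx(50.0)
    assert rep["duration_mean_h"] == pytest.approx(1.5)  # durations cover all


def test_transmitted_exceeding_direct_rejected():
    with pytest.raises(ValueError, match="exceed"):
        recovery_report(_deployments([[11, 10, 0, 0, 1.0]]))


def test_haversine_matches_small_angle_formula():
    ref = (24.3, 124.1)
    f = _offset_fix(0.0, ref, north_m=120.0)
    assert haversine_m(f.lat, f.lon, *ref) == pytest.approx(120.0, rel=1e-4)
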
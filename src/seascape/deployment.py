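"""Simulated tag deployments.

A deployment emulates a tagged sea turtle carrying the logger: a piecewise
dive/surface profile (dives to a uniform-random depth, ~10-s surfacings,
exponential inter-surfacing intervals), duty-cycled audio recordings (5 min
every 30 min by default), 60-s sensor sampling (depth, temperature, 3-axis
acceleration and geomagnetism), GPS fixes only while surfaced, and a
ground-truth sound-event schedule per 5-s recording segment.

The animal drifts around one or more *sites*; each site can restrict which
sound classes occur there, which lets an end-to-end run check that a
site-restricted class maps back to its site.  Audio is rendered lazily per
recording (each recording carries its own seed) so long deployments stay
cheap until waveforms are actually needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import Generator, default_rng

from . import synth
from .prep import SEGMENT_SECONDS
from .synth import SAMPLE_RATE
from .taxonomy import SoundTaxonomy

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class Site:
    """A location the animal frequents, with the classes audible there."""

    lat: float
    lon: float
    class_ids: tuple[int, ...] | None = None  # None = all sound classes


@dataclass(frozen=True)
class DeploymentPlan:
    """Study conditions for one simulated deployment.

    Defaults follow the logger's duty cycle: 5-min (300-s) recordings every
    30 min, sensors every 60 s, ~10-s surfacings.
    """

    total_duration_h: float = 24.0
    recording_length_s: float = 300.0
    recording_interval_min: float = 30.0
    sensor_interval_s: float = 60.0
    surface_duration_mean_s: float = 10.0
    dive_duration_mean_s: float = 360.0
    dive_depth_range_m: tuple[float, float] = (2.0, 15.0)
    gps_success_prob: float = 0.9
    transmit_success_prob: float = 0.9
    event_prob: float = 0.6  # chance a 5-s segment contains a sound event
    snr_db: float = 15.0
    sites: tuple[Site, ...] = (Site(24.33, 124.13),)  # default: one reef site
    walk_sigma_m: float = 100.0
    # per-axis GPS error; 22.6 m per axis gives ~32 m 2-D RMSE, the scale
    # reported for surfacing-triggered fast-fix GPS evaluated in a tank
    gps_sigma_m: float = 22.6

    def __post_init__(self) -> None:
        if not self.total_duration_h > 0:
            raise ValueError(f"total_duration_h must be > 0, got {self.total_duration_h}")
        if self.recording_length_s > self.recording_interval_min * 60:
            raise ValueError("recording_length_s must fit inside the recording interval")
        for name in ("gps_success_prob", "transmit_success_prob", "event_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def n_recordings(self) -> int:
        return int(self.total_duration_h * 60 // self.recording_interval_min)


@dataclass(frozen=True)
class ScheduledEvent:
    """One sound event inside a recording: (segment, class, placement)."""

    segment_index: int
    class_id: int
    offset_s: float  # within the segment
    duration_s: float


@dataclass(frozen=True)
class Recording:
    recording_id: str
    start_time_s: float
    length_s: float
    events: tuple[ScheduledEvent, ...]
    segment_labels: tuple[int, ...]  # truth per 5-s segment (background where empty)
    seed: int  # for lazy audio rendering


@dataclass(frozen=True)
class SensorSample:
    t: float
    depth_m: float
    temperature_c: float
    accel_xyz_g: tuple[float, float, float]
    mag_xyz_ut: tuple[float, float, float]


@dataclass(frozen=True)
class GpsFix:
    t: float
    lat: float
    lon: float


@dataclass
class DeploymentDataset:
    plan: DeploymentPlan
    recordings: list[Recording]
    sensor_samples: list[SensorSample]
    surfacings: list[tuple[float, float]]  # (start, duration)
    gps_fixes: list[GpsFix]
    truth_log: list[tuple[str, int, int]] = field(default_factory=list)
    # truth_log rows: (recording_id, segment_index, class_id)


# ---------------------------------------------------------------------------
# dive profile


def _simulate_dive_profile(
    plan: DeploymentPlan, rng: Generator
) -> tuple[list[tuple[float, float]], list[tuple[float, float, float]]]:
    """Alternating surface/dive bouts.

    Returns (surfacings, dives) where each dive is (start, end, max_depth).
    Depth within a dive ramps down over the first fifth, holds, and ramps
    back up over the last fifth.
    """
    total_s = plan.total_duration_h * 3600
    t = 0.0
    surfacings: list[tuple[float, float]] = []
    dives: list[tuple[float, float, float]] = []
    while t < total_s:
        sdur = float(max(3.0, rng.normal(plan.surface_duration_mean_s, 2.0)))
        surfacings.append((t, min(sdur, total_s - t)))
        t += sdur
        if t >= total_s:
            break
        ddur = float(max(30.0, rng.exponential(plan.dive_duration_mean_s)))
        depth = float(rng.uniform(*plan.dive_depth_range_m))
        dives.append((t, min(t + ddur, total_s), depth))
        t += ddur
    return surfacings, dives


def depth_at(dives: Sequence[tuple[float, float, float]], t: float) -> float:
    """Depth (m) at time t from the piecewise dive profile; 0 at the surface."""
    for start, end, max_depth in dives:
        if start <= t < end:
            dur = end - start
            ramp = dur / 5.0
            if t < start + ramp:
                return max_depth * (t - start) / ramp
            if t > end - ramp:
                return max_depth * (end - t) / ramp
            return max_depth
    return 0.0


def _offset_latlon(lat: float, lon: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    dlat = np.degrees(dy_m / EARTH_RADIUS_M)
    dlon = np.degrees(dx_m / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return lat + dlat, lon + dlon


# ---------------------------------------------------------------------------
# main entry


def simulate_deployment(
    plan: DeploymentPlan, taxonomy: SoundTaxonomy, seed: int = 0
) -> DeploymentDataset:
    """Build one deterministic deployment dataset (audio rendered lazily).

    The number of recordings is floor(total_minutes / interval); sensor
    samples are exactly ``sensor_interval_s`` apart; GPS fixes occur only
    during surfacings.  The animal spends an equal share of the deployment
    at each site, and a segment's event class is drawn from the active
    site's class pool.
    """
    ss = np.random.SeedSequence(seed)
    rng_profile, rng_sched, rng_sensor, rng_gps = (
        default_rng(c) for c in ss.spawn(4)
    )
    total_s = plan.total_duration_h * 3600
    surfacings, dives = _simulate_dive_profile(plan, rng_profile)

    sites = plan.sites

    def site_at(t: float) -> Site:
        i = min(int(t / total_s * len(sites)), len(sites) - 1)
        return sites[i]

    background = taxonomy.background_id

    # recordings + truth schedule
    recordings: list[Recording] = []
    truth_log: list[tuple[str, int, int]] = []
    n_segments = int(plan.recording_length_s // SEGMENT_SECONDS)
    for r in range(plan.n_recordings):
        start = r * plan.recording_interval_min * 60
        site = site_at(start)
        pool = site.class_ids if site.class_ids is not None else taxonomy.sound_class_ids
        events = []
        labels = []
        for s in range(n_segments):
            if rng_sched.random() < plan.event_prob:
                cid = int(rng_sched.choice(pool))
                off, dur = synth.draw_event_placement(rng_sched, SEGMENT_SECONDS)
                events.append(ScheduledEvent(s, cid, off, dur))
                labels.append(cid)
            else:
                labels.append(background)
        rec_id = f"rec{r:04d}"
        rec_seed = int(rng_sched.integers(0, 2**31 - 1))
        recordings.append(
            Recording(rec_id, start, plan.recording_length_s, tuple(events), tuple(labels), rec_seed)
        )
        truth_log.extend((rec_id, s, labels[s]) for s in range(n_segments))

    # sensor samples
    sensor_samples = []
    for t in np.arange(0, total_s, plan.sensor_interval_s):
        accel = tuple(np.array([0.0, 0.0, 1.0]) + rng_sensor.normal(0, 0.05, 3))
        mag = tuple(np.array([31.0, 4.0, 24.0]) + rng_sensor.normal(0, 0.5, 3))
        sensor_samples.append(
            SensorSample(
                t=float(t),
                depth_m=depth_at(dives, float(t)),
                temperature_c=float(27.0 + rng_sensor.normal(0, 0.3)),
                accel_xyz_g=tuple(float(v) for v in accel),
                mag_xyz_ut=tuple(float(v) for v in mag),
            )
        )

    # position track + GPS fixes (only while surfaced)
    gps_fixes = []
    for start, _dur in surfacings:
        if rng_gps.random() < plan.gps_success_prob:
            site = site_at(start)
            dx, dy = rng_gps.normal(0, plan.walk_sigma_m, 2)
            ex, ey = rng_gps.normal(0, plan.gps_sigma_m, 2)
            lat, lon = _offset_latlon(site.lat, site.lon, dx + ex, dy + ey)
            gps_fixes.append(GpsFix(t=float(start), lat=lat, lon=lon))

    return DeploymentDataset(
        plan=plan,
        recordings=recordings,
        sensor_samples=sensor_samples,
        surfacings=surfacings,
        gps_fixes=gps_fixes,
        truth_log=truth_log,
    )


def render_recording(
    recording: Recording, taxonomy: SoundTaxonomy, snr_db: float = 15.0
) -> np.ndarray:
    """Render one recording's waveform (int16) from its event schedule.

    Deterministic per the recording's stored seed: ambient background for
    the full length with each scheduled event mixed into its segment at the
    plan's SNR.
    """
    rng = default_rng(np.random.SeedSequence(recording.seed))
    n = int(round(recording.length_s * SAMPLE_RATE))
    x = synth.background_noise(n, rng)
    for ev in recording.events:
        spec = taxonomy[ev.class_id]
        event = synth.synthesize_event(spec, ev.duration_s, rng)
        lo, hi = synth.nominal_band(spec)
        seg_start = int(ev.segment_index * SEGMENT_SECONDS * SAMPLE_RATE)
        i0 = seg_start + int(round(ev.offset_s * SAMPLE_RATE))
        bg_ref = x[seg_start : seg_start + int(SEGMENT_SECONDS * SAMPLE_RATE)]
        gain = (
            synth._bandpass_rms(bg_ref, lo, hi)
            * 10 ** (snr_db / 20)
            / synth._bandpass_rms(event, lo, hi)
        )
        x[i0 : i0 + len(event)] += gain * event
    return synth._to_int16(x)


def sensor_sample_at(dataset: DeploymentDataset, t: float) -> SensorSample:
    """The sensor sample nearest to (at or before) time t."""
    candidates = [s for s in dataset.sensor_samples if s.t <= t + 1e-9]
    if not candidates:
        return dataset.sensor_samples[0]
    return candidates[-1]
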
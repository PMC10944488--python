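"""Synthetic underwater sound generation.

Every Level-3 class is realized by one of four event archetypes — frequency-
modulated tones (whistles), band-limited pulse trains (fish knocks, pile
driving), harmonic stacks (vessel engine/propeller lines) and shaped noise
bands (rain, waves, crackle) — mixed into a stationary 1/f-tilted Gaussian
ocean background at a requested signal-to-noise ratio.  SNR is defined as
the RMS ratio between event and background measured inside the event's
nominal frequency band.

All waveforms are mono, 44 100 samples/s, returned as int16 (the logger's
16-bit PCM format) or as float components for analysis.  Everything is a
pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, default_rng

from .taxonomy import SoundClassSpec, SoundTaxonomy

SAMPLE_RATE = 44_100
#: observed band of the target sounds: 60 Hz - 20 kHz
BAND_MIN_HZ = 60.0
BAND_MAX_HZ = 20_000.0
#: RMS of the background noise floor relative to full scale
BACKGROUND_RMS = 0.02


@dataclass(frozen=True)
class SynthesisRequest:
    """Request for one labeled clip: class, duration, SNR and seed."""

    class_id: int
    duration: float
    snr_db: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


# ---------------------------------------------------------------------------
# band helpers


def nominal_band(spec: SoundClassSpec) -> tuple[float, float]:
    """Frequency band [lo, hi] that nominally contains the class's energy."""
    p = spec.archetype_params
    if spec.archetype == "tonal_fm":
        half = p["fm_sweep_range_hz"] / 2 + 50.0
        lo, hi = p["center_freq_hz"] - half, p["center_freq_hz"] + half
    elif spec.archetype in ("pulse_train", "noise_band"):
        half = p["bandwidth_hz"] / 2
        lo, hi = p["center_freq_hz"] - half, p["center_freq_hz"] + half
    elif spec.archetype == "harmonic_stack":
        f0 = p["center_freq_hz"]
        lo = 0.8 * f0
        hi = min(1.1 * f0 * p["harmonic_count"], BAND_MAX_HZ)
    elif spec.archetype == "background_noise":
        lo, hi = BAND_MIN_HZ, BAND_MAX_HZ
    else:  # pragma: no cover - taxonomy validates archetypes
        raise ValueError(f"unknown archetype {spec.archetype!r}")
    return max(lo, BAND_MIN_HZ), min(hi, BAND_MAX_HZ)


def _bandpass_rms(x: np.ndarray, lo: float, hi: float) -> float:
    """RMS of x restricted to [lo, hi] Hz (rectangular FFT mask)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / SAMPLE_RATE)
    mask = (freqs >= lo) & (freqs <= hi)
    # Parseval for the one-sided spectrum: interior bins count twice
    weights = np.full(len(freqs), 2.0)
    weights[0] = 1.0
    if len(x) % 2 == 0:
        weights[-1] = 1.0
    power = np.sum(weights[mask] * np.abs(spec[mask]) ** 2) / len(x) ** 2
    return float(np.sqrt(power))


# ---------------------------------------------------------------------------
# background


def background_noise(n_samples: int, rng: Generator, rms: float = BACKGROUND_RMS) -> np.ndarray:
    """Stationary ambient ocean noise: Gaussian with a 1/f spectral tilt.

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to f^-0.5 (power ~ 1/f), flattened below 60 Hz to avoid the
    DC singularity, then scaled to the requested overall RMS.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / SAMPLE_RATE)
    shape = np.ones_like(freqs)
    nz = freqs >= BAND_MIN_HZ
    shape[nz] = (BAND_MIN_HZ / freqs[nz]) ** 0.5
    shape[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * shape, n=n_samples)
    return x * (rms / np.sqrt(np.mean(x**2)))


# ---------------------------------------------------------------------------
# event archetypes (unit-RMS float signals spanning the full duration)


def _envelope(n: int, edge_frac: float = 0.05) -> np.ndarray:
    """Raised-cosine fade-in/out envelope to avoid clicks at clip edges."""
    edge = max(2, int(n * edge_frac))
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    env[:edge] = ramp
    env[-edge:] = ramp[::-1]
    return env


def _tonal_fm(spec: SoundClassSpec, n: int, rng: Generator) -> np.ndarray:
    p = spec.archetype_params
    t = np.arange(n) / SAMPLE_RATE
    # sinusoidal FM contour sweeping center +- sweep/2 a few times per second
    mod_rate = rng.uniform(1.0, 3.0)
    phase0 = rng.uniform(0, 2 * np.pi)
    inst_freq = p["center_freq_hz"] + 0.5 * p["fm_sweep_range_hz"] * np.sin(
        2 * np.pi * mod_rate * t + phase0
    )
    phase = 2 * np.pi * np.cumsum(inst_freq) / SAMPLE_RATE
    return np.sin(phase + rng.uniform(0, 2 * np.pi)) * _envelope(n)


def _gabor_pulse(center_hz: float, bandwidth_hz: float, rng: Generator) -> np.ndarray:
    """Single band-limited click: Gaussian-windowed sinusoid."""
    sigma = 1.0 / (2 * np.pi * max(bandwidth_hz / 2, 20.0))  # seconds
    half = int(4 * sigma * SAMPLE_RATE) + 1
    t = np.arange(-half, half + 1) / SAMPLE_RATE
    return np.exp(-0.5 * (t / sigma) ** 2) * np.cos(
        2 * np.pi * center_hz * t + rng.uniform(0, 2 * np.pi)
    )


def _pulse_train(spec: SoundClassSpec, n: int, rng: Generator) -> np.ndarray:
    p = spec.archetype_params
    rate = p["pulse_rate_hz"]
    pulse = _gabor_pulse(p["center_freq_hz"], p["bandwidth_hz"], rng)
    x = np.zeros(n)
    period = SAMPLE_RATE / rate
    n_pulses = int(np.floor(n / period))
    for k in range(n_pulses):
        center = int((k + 0.5) * period)
        amp = rng.uniform(0.7, 1.0)
        lo = center - len(pulse) // 2
        hi = lo + len(pulse)
        s0, s1 = max(lo, 0), min(hi, n)
        x[s0:s1] += amp * pulse[s0 - lo : s1 - lo]
    return x


def _harmonic_stack(spec: SoundClassSpec, n: int, rng: Generator) -> np.ndarray:
    p = spec.archetype_params
    f0 = p["center_freq_hz"]
    n_harm = int(min(p["harmonic_count"], BAND_MAX_HZ // f0))
    t = np.arange(n) / SAMPLE_RATE
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        detune = 1.0 + rng.normal(0, 2e-4)
        x += (1.0 / h) * np.sin(2 * np.pi * f0 * h * detune * t + rng.uniform(0, 2 * np.pi))
    # slow amplitude throb (engine/propeller modulation)
    throb = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(1.0, 4.0) * t + rng.uniform(0, 2 * np.pi))
    return x * throb * _envelope(n)


def _noise_band(spec: SoundClassSpec, n: int, rng: Generator) -> np.ndarray:
    p = spec.archetype_params
    lo = max(p["center_freq_hz"] - p["bandwidth_hz"] / 2, BAND_MIN_HZ)
    hi = min(p["center_freq_hz"] + p["bandwidth_hz"] / 2, BAND_MAX_HZ)
    white = rng.standard_normal(n)
    fspec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    # raised-cosine band edges, 5% of bandwidth wide
    edge = 0.05 * (hi - lo)
    mask = np.zeros_like(freqs)
    core = (freqs >= lo + edge) & (freqs <= hi - edge)
    mask[core] = 1.0
    rise = (freqs >= lo) & (freqs < lo + edge)
    mask[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - lo) / edge))
    fall = (freqs > hi - edge) & (freqs <= hi)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - (hi - edge)) / edge))
    return np.fft.irfft(fspec * mask, n=n) * _envelope(n)


_ARCHETYPE_FNS = {
    "tonal_fm": _tonal_fm,
    "pulse_train": _pulse_train,
    "harmonic_stack": _harmonic_stack,
    "noise_band": _noise_band,
}


def synthesize_event(spec: SoundClassSpec, duration: float, rng: Generator) -> np.ndarray:
    """Unit-RMS event waveform of the class's archetype spanning `duration`."""
    if spec.archetype == "background_noise":
        raise ValueError("background has no event; use background_noise()")
    n = int(round(duration * SAMPLE_RATE))
    x = _ARCHETYPE_FNS[spec.archetype](spec, n, rng)
    return x / np.sqrt(np.mean(x**2))


# ---------------------------------------------------------------------------
# mixing


def synthesize_components(
    taxonomy: SoundTaxonomy, req: SynthesisRequest
) -> tuple[np.ndarray, np.ndarray]:
    """Return (event, background) float components at the requested SNR.

    The event is scaled so that its RMS inside the class's nominal band
    exceeds the background's in-band RMS by ``req.snr_db`` decibels.  For the
    background class the event component is all-zero.
    """
    spec = taxonomy[req.class_id]
    rng = default_rng(np.random.SeedSequence([req.seed, req.class_id]))
    n = int(round(req.duration * SAMPLE_RATE))
    bg = background_noise(n, rng)
    if spec.is_background:
        return np.zeros(n), bg
    event = synthesize_event(spec, req.duration, rng)
    lo, hi = nominal_band(spec)
    bg_rms = _bandpass_rms(bg, lo, hi)
    ev_rms = _bandpass_rms(event, lo, hi)
    gain = bg_rms * 10 ** (req.snr_db / 20) / ev_rms
    return event * gain, bg


def _to_int16(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak > 0.99:
        x = x * (0.99 / peak)  # uniform rescale preserves SNR
    return np.round(x * 32767).astype(np.int16)


def synthesize_sound(taxonomy: SoundTaxonomy, req: SynthesisRequest) -> np.ndarray:
    """Synthesize one labeled clip as int16 PCM at 44.1 kHz.

    Deterministic per (class_id, seed); the event spans the full duration.
    """
    event, bg = synthesize_components(taxonomy, req)
    return _to_int16(event + bg)


#: event placement inside a 5-s segment, shared by training clips and the
#: deployment scheduler so the two sound distributions match
EVENT_DURATION_RANGE = (1.2, 2.2)
EVENT_EDGE_MARGIN = 0.3


@dataclass(frozen=True)
class TrainingClip:
    """A labeled 5-s clip with its embedded event's placement."""

    waveform: np.ndarray  # int16
    class_id: int
    event_start: float  # seconds; 0 duration for background clips
    event_duration: float

    def best_window_offset(self, n_windows: int = 4) -> float:
        """Offset (s) of the 2-s analysis window best covering the event."""
        if self.event_duration == 0.0:
            return 1.0  # background: any interior window
        overlaps = [
            max(
                0.0,
                min(off + 2.0, self.event_start + self.event_duration)
                - max(off, self.event_start),
            )
            for off in range(n_windows)
        ]
        return float(int(np.argmax(overlaps)))


def draw_event_placement(rng: Generator, segment_seconds: float = 5.0) -> tuple[float, float]:
    """Random (start, duration) of an event inside a segment.

    Duration is uniform in EVENT_DURATION_RANGE and the event keeps an
    EVENT_EDGE_MARGIN clearance from the segment edges; it always occupies
    less than half the segment, so the per-bin temporal median remains a
    background estimate.
    """
    dur = float(rng.uniform(*EVENT_DURATION_RANGE))
    start = float(rng.uniform(EVENT_EDGE_MARGIN, segment_seconds - dur - EVENT_EDGE_MARGIN))
    return start, dur


def synthesize_training_clip(
    taxonomy: SoundTaxonomy,
    class_id: int,
    seed: int,
    snr_db: float = 15.0,
    clip_duration: float = 5.0,
    event_start: float | None = None,
    event_duration: float | None = None,
) -> TrainingClip:
    """A 5-s clip with the event occupying a short sub-interval.

    This mirrors the on-logger geometry: the event covers (most of) one 2-s
    analysis window but less than half of the 5-s segment, so the per-bin
    temporal median still estimates the stationary background and the
    median filter removes noise without erasing the event.  Placement is
    randomized per seed (the same distribution the deployment simulator
    uses) unless given explicitly.  For the background class the clip is
    pure ambient noise.
    """
    spec = taxonomy[class_id]
    rng = default_rng(np.random.SeedSequence([seed, class_id, 1]))
    n = int(round(clip_duration * SAMPLE_RATE))
    bg = background_noise(n, rng)
    if spec.is_background:
        return TrainingClip(_to_int16(bg), class_id, 0.0, 0.0)
    start, dur = draw_event_placement(rng, clip_duration)
    if event_duration is not None:
        dur = event_duration
    if event_start is not None:
        start = event_start
    ev = synthesize_event(spec, dur, rng)
    lo, hi = nominal_band(spec)
    gain = _bandpass_rms(bg, lo, hi) * 10 ** (snr_db / 20) / _bandpass_rms(ev, lo, hi)
    i0 = int(round(start * SAMPLE_RATE))
    x = bg.copy()
    x[i0 : i0 + len(ev)] += gain * ev
    return TrainingClip(_to_int16(x), class_id, start, dur)


def training_image(taxonomy: SoundTaxonomy, clip: TrainingClip):
    """Preprocess a training clip and return the image of its best window."""
    from .prep import preprocess_segment

    images = preprocess_segment(clip.waveform)
    return images[int(clip.best_window_offset(len(images)))]


def make_training_set(
    taxonomy: SoundTaxonomy,
    examples_per_class: int = 40,
    snr_db: float = 15.0,
    seed: int = 0,
):
    """Labeled image set over the full taxonomy: one image per clip.

    Returns (images, labels) with ``examples_per_class`` clips per class,
    each reduced to the 2-s window best covering its event.
    """
    images, labels = [], []
    for cid in taxonomy.class_ids:
        for k in range(examples_per_class):
            clip = synthesize_training_clip(
                taxonomy, cid, seed=seed * 1_000_003 + k, snr_db=snr_db
            )
            images.append(training_image(taxonomy, clip))
            labels.append(cid)
    return images, labels
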
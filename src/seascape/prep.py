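"""On-logger spectrogram pre-processing.

The chain turns a duty-cycled 300-s PCM recording into 192x192 8-bit
spectrogram tiles, the classifier's input unit:

1. split the recording into 5-s segments;
2. per segment, compute a 1024-point STFT (0.5 overlap on the logger; the
   PC-side variant uses 10-s segments with 0.9 overlap), convert to dB and
   resample the frequency axis onto 192 log-spaced bins spanning 60 Hz -
   20 kHz;
3. subtract the per-frequency-bin temporal median to suppress stationary
   background noise;
4. slide a 2-s window in 1-s steps (4 windows per 5-s segment, 9 per 10-s)
   and render each window as a 192x192 image with per-image min-max
   normalization to [0, 255].

A 5-min recording therefore yields 60 x 4 = 240 images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import get_window

from .synth import SAMPLE_RATE

#: dB floor relative to full scale; prevents log-of-zero
DB_FLOOR = -100.0
IMAGE_SIZE = 192
WINDOW_SECONDS = 2.0
WINDOW_STEP_SECONDS = 1.0
SEGMENT_SECONDS = 5.0
PC_SEGMENT_SECONDS = 10.0


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT and log-frequency axis parameters."""

    n_fft: int = 1024
    overlap_ratio: float = 0.5  # 0.5 on the logger, 0.9 in the PC variant
    window_function: str = "hann"
    fmin: float = 60.0
    fmax: float = 20_000.0
    n_freq_bins: int = IMAGE_SIZE

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_ratio < 1:
            raise ValueError(f"overlap_ratio must be in [0, 1), got {self.overlap_ratio}")
        if not 0 < self.fmin < self.fmax <= SAMPLE_RATE / 2:
            raise ValueError(f"need 0 < fmin < fmax <= {SAMPLE_RATE / 2}")

    @property
    def hop(self) -> int:
        return int(self.n_fft * (1 - self.overlap_ratio))

    def log_bin_centers(self) -> np.ndarray:
        """Geometrically spaced bin centers from fmin to fmax."""
        return np.geomspace(self.fmin, self.fmax, self.n_freq_bins)


LOGGER_PARAMS = SpectrogramParams(overlap_ratio=0.5)
PC_PARAMS = SpectrogramParams(overlap_ratio=0.9)


@dataclass
class LogSpectrogram:
    """dB magnitudes on a log-frequency axis; frame_times are frame starts."""

    values: np.ndarray  # (n_freq_bins, n_frames)
    freq_bin_centers: np.ndarray
    frame_times: np.ndarray
    floor: float = DB_FLOOR
    params: SpectrogramParams = field(default_factory=SpectrogramParams)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Nominal covered duration: last frame start + one FFT window."""
        return float(self.frame_times[-1]) + self.params.n_fft / SAMPLE_RATE


@dataclass(frozen=True)
class SpectroImage:
    """One 192x192 8-bit tile: the classifier's input unit."""

    pixels: np.ndarray  # (192, 192) uint8; row 0 = lowest frequency
    segment_index: int = 0
    window_offset: float = 0.0  # seconds within the segment
    source_recording_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")


def _as_float(waveform: np.ndarray) -> np.ndarray:
    x = np.asarray(waveform)
    if np.issubdtype(x.dtype, np.integer):
        return x.astype(np.float64) / 32768.0
    return x.astype(np.float64)


def compute_spectrogram(
    waveform: np.ndarray, params: SpectrogramParams = LOGGER_PARAMS
) -> LogSpectrogram:
    """STFT -> dB magnitudes -> log-frequency axis.

    Frames are hop-spaced windows that fit entirely inside the waveform
    (no padding), so n_frames = floor((N - n_fft) / hop) + 1.  Magnitudes
    are scaled so a full-scale sine reads ~0 dB, floored at DB_FLOOR, and
    linearly interpolated (in dB, over linear frequency) onto the
    geometric bin centers.
    """
    x = _as_float(waveform)
    if len(x) < params.n_fft:
        raise ValueError(f"waveform length {len(x)} shorter than n_fft {params.n_fft}")
    hop = params.hop
    n_frames = (len(x) - params.n_fft) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, params.n_fft)[::hop][:n_frames]
    win = get_window(params.window_function, params.n_fft, fftbins=True)
    spectrum = np.fft.rfft(frames * win, axis=1)
    mag = np.abs(spectrum) * (2.0 / win.sum())
    db = 20.0 * np.log10(np.maximum(mag, 10 ** (DB_FLOOR / 20)))

    lin_freqs = np.fft.rfftfreq(params.n_fft, d=1.0 / SAMPLE_RATE)
    centers = params.log_bin_centers()
    # two-point linear interpolation weights from the linear-frequency grid
    idx = np.searchsorted(lin_freqs, centers) - 1
    idx = np.clip(idx, 0, len(lin_freqs) - 2)
    frac = (centers - lin_freqs[idx]) / (lin_freqs[idx + 1] - lin_freqs[idx])
    values = (1 - frac)[:, None] * db[:, idx].T + frac[:, None] * db[:, idx + 1].T

    frame_times = np.arange(n_frames) * hop / SAMPLE_RATE
    return LogSpectrogram(values, centers, frame_times, DB_FLOOR, params)


def denoise_median(spec: LogSpectrogram) -> LogSpectrogram:
    """Subtract each frequency bin's temporal median; clip below the floor.

    The median over the full input segment estimates the stationary
    background level per bin; subtracting it flattens ambient noise while a
    short transient (occupying a minority of frames) keeps its full
    contrast.  Values that fall to or below the estimated background land
    at the dB floor; output never exceeds input anywhere (the median is
    always at or above the floor).
    """
    if spec.n_frames < 3:
        raise ValueError(f"median filter needs >= 3 frames, got {spec.n_frames}")
    med = np.median(spec.values, axis=1, keepdims=True)
    values = spec.floor + np.maximum(spec.values - med, 0.0)
    return replace(spec, values=values)


def segment_recording(
    waveform: np.ndarray, segment_seconds: float = SEGMENT_SECONDS
) -> list[np.ndarray]:
    """Split a recording into contiguous fixed-length segments.

    The tail shorter than one segment is dropped (the firmware reads fixed
    blocks); recordings shorter than one segment are rejected.
    """
    seg_len = int(round(segment_seconds * SAMPLE_RATE))
    n_segments = len(waveform) // seg_len
    if n_segments < 1:
        raise ValueError(
            f"recording of {len(waveform) / SAMPLE_RATE:.2f} s shorter than "
            f"one {segment_seconds:.0f}-s segment"
        )
    return [waveform[i * seg_len : (i + 1) * seg_len] for i in range(n_segments)]


def slide_windows(seg_spec: LogSpectrogram) -> list[tuple[float, LogSpectrogram]]:
    """Slide a 2-s window in 1-s steps over a segment spectrogram.

    Returns (offset_seconds, window) pairs: 4 windows for a 5-s segment,
    9 for the 10-s PC variant, 1 for a 2-s segment.
    """
    duration = round(seg_spec.duration)
    if duration < WINDOW_SECONDS:
        raise ValueError(f"segment of {seg_spec.duration:.2f} s shorter than a 2-s window")
    n_windows = int((duration - WINDOW_SECONDS) / WINDOW_STEP_SECONDS) + 1
    out = []
    for w in range(n_windows):
        off = w * WINDOW_STEP_SECONDS
        sel = (seg_spec.frame_times >= off - 1e-9) & (
            seg_spec.frame_times < off + WINDOW_SECONDS - 1e-9
        )
        window = replace(
            seg_spec,
            values=seg_spec.values[:, sel],
            frame_times=seg_spec.frame_times[sel] - off,
        )
        out.append((off, window))
    return out


def render_image(
    window: LogSpectrogram,
    segment_index: int = 0,
    window_offset: float = 0.0,
    source_recording_id: str = "",
) -> SpectroImage:
    """Resample a 2-s window to 192 time columns and min-max map to [0, 255].

    A degenerate dynamic range (max == min) renders as uniform mid-gray.
    Row 0 is the lowest frequency bin.
    """
    n_cols = IMAGE_SIZE
    t_targets = (np.arange(n_cols) + 0.5) * WINDOW_SECONDS / n_cols
    resampled = np.empty((window.values.shape[0], n_cols))
    for r in range(window.values.shape[0]):
        resampled[r] = np.interp(t_targets, window.frame_times, window.values[r])
    vmin, vmax = resampled.min(), resampled.max()
    if vmax - vmin < 1e-12:
        pixels = np.full((IMAGE_SIZE, n_cols), 128, dtype=np.uint8)
    else:
        pixels = np.round((resampled - vmin) * (255.0 / (vmax - vmin))).astype(np.uint8)
    return SpectroImage(pixels, segment_index, window_offset, source_recording_id)


def preprocess_segment(
    segment: np.ndarray,
    params: SpectrogramParams = LOGGER_PARAMS,
    segment_index: int = 0,
    source_recording_id: str = "",
) -> list[SpectroImage]:
    """Segment waveform -> spectrogram -> median denoise -> windows -> images."""
    spec = denoise_median(compute_spectrogram(segment, params))
    return [
        render_image(w, segment_index, off, source_recording_id)
        for off, w in slide_windows(spec)
    ]


def preprocess_recording(
    waveform: np.ndarray,
    mode: str = "logger",
    source_recording_id: str = "",
) -> list[SpectroImage]:
    """Full chain for one duty-cycled recording.

    ``mode="logger"``: 5-s segments, 0.5 overlap, 4 windows each — 240
    images for a 300-s recording.  ``mode="pc"``: 10-s segments, 0.9
    overlap, 9 windows each.
    """
    if mode == "logger":
        params, seg_s = LOGGER_PARAMS, SEGMENT_SECONDS
    elif mode == "pc":
        params, seg_s = PC_PARAMS, PC_SEGMENT_SECONDS
    else:
        raise ValueError(f"mode must be 'logger' or 'pc', got {mode!r}")
    images: list[SpectroImage] = []
    for i, seg in enumerate(segment_recording(waveform, seg_s)):
        images.extend(preprocess_segment(seg, params, i, source_recording_id))
    return images
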
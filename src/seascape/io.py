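"""File I/O helpers: WAV, CSV tables, image export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .deployment import DeploymentDataset, GpsFix
from .synth import SAMPLE_RATE
from .telemetry import ClassificationSummary


def write_wav(path, waveform: np.ndarray) -> None:
    """Write mono int16 PCM at 44.1 kHz."""
    wavfile.write(path, SAMPLE_RATE, np.asarray(waveform, dtype=np.int16))


def read_wav(path) -> np.ndarray:
    rate, data = wavfile.read(path)
    if rate != SAMPLE_RATE:
        raise ValueError(f"expected {SAMPLE_RATE} Hz WAV, got {rate} Hz")
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    return data


def sensor_samples_frame(dataset: DeploymentDataset, epoch0: str = "2023-07-01T00:00:00Z") -> pd.DataFrame:
    t0 = pd.Timestamp(epoch0)
    rows = [
        {
            "t": (t0 + pd.Timedelta(seconds=s.t)).isoformat(),
            "depth_m": s.depth_m,
            "temperature_c": s.temperature_c,
            "accel_x_g": s.accel_xyz_g[0],
            "accel_y_g": s.accel_xyz_g[1],
            "accel_z_g": s.accel_xyz_g[2],
            "mag_x_ut": s.mag_xyz_ut[0],
            "mag_y_ut": s.mag_xyz_ut[1],
            "mag_z_ut": s.mag_xyz_ut[2],
        }
        for s in dataset.sensor_samples
    ]
    return pd.DataFrame(rows)


def gps_fixes_frame(fixes: list[GpsFix], epoch0: str = "2023-07-01T00:00:00Z") -> pd.DataFrame:
    t0 = pd.Timestamp(epoch0)
    return pd.DataFrame(
        [
            {
                "t": (t0 + pd.Timedelta(seconds=f.t)).isoformat(),
                "lat": f.lat,
                "lon": f.lon,
            }
            for f in fixes
        ]
    )


def summaries_frame(summaries: list[ClassificationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "t_start": s.t_start,
            "depth_m": s.depth_m,
            "temperature_c": s.temperature_c,
            "accel_magnitude_g": s.accel_magnitude_g,
            "mag_magnitude_ut": s.mag_magnitude_ut,
        }
        for i, (cid, p) in enumerate(s.top3, start=1):
            row[f"top{i}_class"] = cid
            row[f"top{i}_prob"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def save_images_png(images, out_dir) -> pd.DataFrame:
    """Write images as PNG plus a manifest (recording, segment, offset, file)."""
    from matplotlib.image import imsave

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        name = f"img{i:05d}_s{im.segment_index:03d}_w{im.window_offset:.0f}.png"
        imsave(out / name, im.pixels[::-1], cmap="gray", vmin=0, vmax=255)
        rows.append(
            {
                "recording_id": im.source_recording_id,
                "segment_index": im.segment_index,
                "window_offset_s": im.window_offset,
                "file": name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
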
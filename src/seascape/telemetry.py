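"""Data reduction and simulated transmission.

The logger cannot ship 240 raw classification results per 5-min recording
over a breath-hold cellular link, so each recording is reduced to one
summary: per-class probabilities averaged over all images, the top three
classes by mean probability, plus depth, temperature and the vector
magnitudes of acceleration and geomagnetism sampled at the start of the
recording.  Summaries and GPS positions are packed up to 13 records into a
binary packet of at most 560 bytes and transmitted opportunistically while
the animal surfaces; the modem needs 6-10 s to activate, and a record
queue entry is dropped after three consecutive failed attempts.

Byte layout (little-endian):

    header  7 B : magic 'S' (1) | version (1) | device id (2) | sequence (2)
                  | record count (1)
    classification record, 19 B :
        type 0x01 (1) | epoch seconds (4, u32)
        | 3 x [class id (1, u8) | probability (1, u8, /255)]
        | depth (2, u16, cm) | temperature (2, s16, 0.01 degC)
        | acceleration (2, u16, mg) | magnetic field (2, u16, 0.1 uT)
    position record, 14 B :
        type 0x02 (1) | epoch seconds (4, u32)
        | latitude (4, s32, 1e-5 deg) | longitude (4, s32, 1e-5 deg)
        | fix quality (1, u8)

Worst case 7 + 13 x 19 = 254 bytes, comfortably under the 560-byte cap;
the 1-byte class-id field supports up to 256 classes.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.random import default_rng

from .classify import ProbabilityVector

MAX_PACKET_BYTES = 560
MAX_RECORDS_PER_PACKET = 13
MAGIC = 0x53  # 'S'
FORMAT_VERSION = 1
_HEADER = struct.Struct("<BBHHB")
_CLS_BODY = struct.Struct("<BIBBBBBBHhHH")
_POS_BODY = struct.Struct("<BIiiB")
TYPE_CLASSIFICATION = 0x01
TYPE_POSITION = 0x02

ACTIVATION_DELAY_RANGE = (6.0, 10.0)  # seconds for the modem to come up
MAX_CONSECUTIVE_FAILURES = 3


# ---------------------------------------------------------------------------
# summaries


def vector_magnitude(x: float, y: float, z: float) -> float:
    """Euclidean magnitude of a 3-axis sensor sample."""
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise ValueError(f"non-finite component in ({x}, {y}, {z})")
    return math.sqrt(x * x + y * y + z * z)


@dataclass(frozen=True)
class ClassificationSummary:
    """One 5-min record: top-3 mean-probability classes + sensor context."""

    t_start: float  # epoch seconds
    top3: tuple[tuple[int, float], ...]
    depth_m: float
    temperature_c: float
    accel_magnitude_g: float
    mag_magnitude_ut: float


@dataclass(frozen=True)
class PositionRecord:
    t: float  # epoch seconds
    lat: float
    lon: float
    fix_quality: int = 0

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90 or not -180 <= self.lon <= 180:
            raise ValueError(f"coordinates out of range: ({self.lat}, {self.lon})")


def summarize_window(
    prob_vectors: Sequence[ProbabilityVector],
    sensor: "SensorSample",
    t_start: float,
) -> ClassificationSummary:
    """Average probabilities over a recording's images and keep the top 3.

    For a full 300-s recording the list holds 240 vectors.  Mean
    probabilities tie-break toward the lowest class id.  Sensor context
    (depth, temperature, vector magnitudes) is taken from the sample at the
    start of the recording.
    """
    if len(prob_vectors) == 0:
        raise ValueError("cannot summarize an empty list of probability vectors")
    class_ids = prob_vectors[0].class_ids
    mean = np.mean([pv.probs for pv in prob_vectors], axis=0)
    mean_pv = ProbabilityVector(class_ids, mean / mean.sum())
    top3 = tuple(mean_pv.topk(3))
    return ClassificationSummary(
        t_start=t_start,
        top3=top3,
        depth_m=sensor.depth_m,
        temperature_c=sensor.temperature_c,
        accel_magnitude_g=vector_magnitude(*sensor.accel_xyz_g),
        mag_magnitude_ut=vector_magnitude(*sensor.mag_xyz_ut),
    )


# ---------------------------------------------------------------------------
# packet codec


@dataclass(frozen=True)
class Packet:
    payload: bytes
    record_count: int
    sequence_number: int


class PacketDecodeError(ValueError):
    """Malformed payload; carries the byte offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte {offset})")
        self.offset = offset


def _quantize(value: float, scale: float, lo: int, hi: int, name: str) -> int:
    q = int(round(value / scale))
    if not lo <= q <= hi:
        raise ValueError(
            f"field {name!r} value {value} outside fixed-point range "
            f"[{lo * scale}, {hi * scale}]"
        )
    return q


def _encode_record(rec) -> bytes:
    if isinstance(rec, ClassificationSummary):
        top3 = list(rec.top3)
        if len(top3) != 3:
            raise ValueError("classification record needs exactly 3 (class, prob) pairs")
        flat: list[int] = []
        for cid, prob in top3:
            if not 0 <= cid <= 255:
                raise ValueError(f"field 'class_id' value {cid} outside [0, 255]")
            flat += [cid, _quantize(prob, 1 / 255, 0, 255, "probability")]
        return _CLS_BODY.pack(
            TYPE_CLASSIFICATION,
            _quantize(rec.t_start, 1, 0, 2**32 - 1, "t_start"),
            *flat,
            _quantize(rec.depth_m, 0.01, 0, 2**16 - 1, "depth_m"),
            _quantize(rec.temperature_c, 0.01, -(2**15), 2**15 - 1, "temperature_c"),
            _quantize(rec.accel_magnitude_g, 0.001, 0, 2**16 - 1, "accel_magnitude_g"),
            _quantize(rec.mag_magnitude_ut, 0.1, 0, 2**16 - 1, "mag_magnitude_ut"),
        )
    if isinstance(rec, PositionRecord):
        return _POS_BODY.pack(
            TYPE_POSITION,
            _quantize(rec.t, 1, 0, 2**32 - 1, "t"),
            _quantize(rec.lat, 1e-5, -(2**31), 2**31 - 1, "lat"),
            _quantize(rec.lon, 1e-5, -(2**31), 2**31 - 1, "lon"),
            int(rec.fix_quality) & 0xFF,
        )
    raise TypeError(f"cannot encode record of type {type(rec).__name__}")


def encode_packet(records: Sequence, sequence_number: int = 0, device_id: int = 0) -> Packet:
    """Pack 1-13 classification/position records into one binary packet."""
    if not 1 <= len(records) <= MAX_RECORDS_PER_PACKET:
        raise ValueError(
            f"a packet carries 1-{MAX_RECORDS_PER_PACKET} records, got {len(records)}"
        )
    body = b"".join(_encode_record(r) for r in records)
    payload = _HEADER.pack(MAGIC, FORMAT_VERSION, device_id, sequence_number, len(records)) + body
    assert len(payload) <= MAX_PACKET_BYTES
    return Packet(payload=payload, record_count=len(records), sequence_number=sequence_number)


def decode_packet(payload: bytes) -> list:
    """Inverse of :func:`encode_packet` up to fixed-point quantization.

    Integer fields (class ids, epoch seconds, counts) round-trip exactly;
    probabilities to 1/255, depth to 1 cm, temperature to 0.01 degC,
    acceleration to 1 mg, magnetic field to 0.1 uT, lat/lon to 1e-5 deg.
    """
    if len(payload) < _HEADER.size:
        raise PacketDecodeError("payload shorter than header", len(payload))
    magic, version, _device, _seq, count = _HEADER.unpack_from(payload, 0)
    if magic != MAGIC:
        raise PacketDecodeError(f"bad magic 0x{magic:02x}", 0)
    if version != FORMAT_VERSION:
        raise PacketDecodeError(f"unsupported format version {version}", 1)
    records: list = []
    offset = _HEADER.size
    for _ in range(count):
        if offset >= len(payload):
            raise PacketDecodeError("truncated payload: missing record", offset)
        rtype = payload[offset]
        if rtype == TYPE_CLASSIFICATION:
            if offset + _CLS_BODY.size > len(payload):
                raise PacketDecodeError("truncated classification record", offset)
            vals = _CLS_BODY.unpack_from(payload, offset)
            (_, t, c0, p0, c1, p1, c2, p2, depth, temp, accel, mag) = vals
            records.append(
                ClassificationSummary(
                    t_start=float(t),
                    top3=((c0, p0 / 255), (c1, p1 / 255), (c2, p2 / 255)),
                    depth_m=depth * 0.01,
                    temperature_c=temp * 0.01,
                    accel_magnitude_g=accel * 0.001,
                    mag_magnitude_ut=mag * 0.1,
                )
            )
            offset += _CLS_BODY.size
        elif rtype == TYPE_POSITION:
            if offset + _POS_BODY.size > len(payload):
                raise PacketDecodeError("truncated position record", offset)
            _, t, lat, lon, quality = _POS_BODY.unpack_from(payload, offset)
            records.append(
                PositionRecord(
                    t=float(t), lat=lat / 100_000, lon=lon / 100_000, fix_quality=quality
                )
            )
            offset += _POS_BODY.size
        else:
            raise PacketDecodeError(f"unknown record type 0x{rtype:02x}", offset)
    if offset != len(payload):
        raise PacketDecodeError("trailing bytes after last record", offset)
    return records


# ---------------------------------------------------------------------------
# transmission scheduling


@dataclass(frozen=True)
class QueuedPacket:
    packet: Packet
    creation_time: float  # epoch seconds; data becomes eligible from here


@dataclass
class TransmissionLog:
    """Chronological attempt log plus final per-packet outcomes."""

    events: list[tuple[float, int, str]] = field(default_factory=list)  # (t, seq, outcome)
    sent: list[int] = field(default_factory=list)
    discarded: list[int] = field(default_factory=list)
    pending: list[int] = field(default_factory=list)


def schedule_transmissions(
    queue: Sequence[QueuedPacket],
    surfacings: Sequence[tuple[float, float]],
    seed: int = 0,
    failure: float | Callable[[int], bool] = 0.0,
    activation_delays: Sequence[float] | None = None,
) -> TransmissionLog:
    """Replay the logger's opportunistic transmission policy.

    During each surfacing ``(start, duration)`` the modem must first
    activate, which consumes a delay drawn uniformly from 6-10 s before
    every attempt; attempts happen only while they fit inside the
    surfacing.  The oldest unsent packet whose data already exists is tried
    first.  A failure increments the packet's consecutive-failure counter
    (reset on success); at three the packet is discarded and the next one
    is attempted.  No packet is ever sent twice.

    ``failure`` is a per-attempt failure probability, or a callable mapping
    the global attempt index (0-based) to True (fail).  ``activation_delays``
    overrides the sampled delays with a deterministic sequence (for
    replaying a scenario against an oracle).
    """
    order = sorted(range(len(queue)), key=lambda i: queue[i].creation_time)
    if [queue[i].creation_time for i in order] != [q.creation_time for q in queue]:
        raise ValueError("queue must be time-ordered by creation time")
    starts = [s for s, _ in surfacings]
    if sorted(starts) != starts:
        raise ValueError("surfacings must be time-ordered")
    for (s0, d0), (s1, _) in zip(surfacings, surfacings[1:]):
        if s0 + d0 > s1:
            raise ValueError("surfacings must not overlap")

    rng = default_rng(seed)
    delay_iter = iter(activation_delays) if activation_delays is not None else None

    def next_delay() -> float:
        if delay_iter is not None:
            return next(delay_iter)
        return float(rng.uniform(*ACTIVATION_DELAY_RANGE))

    def attempt_fails(index: int) -> bool:
        if callable(failure):
            return bool(failure(index))
        return bool(rng.random() < failure)

    log = TransmissionLog()
    resolved: set[int] = set()
    failures: dict[int, int] = {}
    attempt_index = 0
    for start, duration in surfacings:
        t = start
        end = start + duration
        while True:
            delay = next_delay()
            if t + delay > end:
                break
            t += delay
            candidate = next(
                (
                    qp
                    for qp in queue
                    if qp.packet.sequence_number not in resolved and qp.creation_time <= t
                ),
                None,
            )
            if candidate is None:
                break
            seq = candidate.packet.sequence_number
            if attempt_fails(attempt_index):
                attempt_index += 1
                failures[seq] = failures.get(seq, 0) + 1
                log.events.append((t, seq, "failed"))
                if failures[seq] >= MAX_CONSECUTIVE_FAILURES:
                    log.events.append((t, seq, "discarded"))
                    log.discarded.append(seq)
                    resolved.add(seq)
            else:
                attempt_index += 1
                failures[seq] = 0
                log.events.append((t, seq, "sent"))
                log.sent.append(seq)
                resolved.add(seq)
    log.pending = [
        qp.packet.sequence_number for qp in queue if qp.packet.sequence_number not in resolved
    ]
    return log


def packetize_summaries(
    summaries: Sequence[ClassificationSummary | PositionRecord],
    device_id: int = 0,
    max_records: int = MAX_RECORDS_PER_PACKET,
) -> list[QueuedPacket]:
    """Chunk time-ordered records into packets of at most 13 records.

    Each packet's creation time is the timestamp of its newest record (the
    data exists only once the last record has been measured).
    """
    packets: list[QueuedPacket] = []
    for seq, i in enumerate(range(0, len(summaries), max_records)):
        chunk = list(summaries[i : i + max_records])
        newest = max(r.t_start if isinstance(r, ClassificationSummary) else r.t for r in chunk)
        packets.append(
            QueuedPacket(packet=encode_packet(chunk, seq, device_id), creation_time=newest)
        )
    return packets
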
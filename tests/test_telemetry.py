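import math

import numpy as np
import pytest

from seascape.classify import ProbabilityVector
from seascape.deployment import SensorSample
from seascape.telemetry import (
    MAX_PACKET_BYTES,
    ClassificationSummary,
    PacketDecodeError,
    PositionRecord,
    QueuedPacket,
    decode_packet,
    encode_packet,
    packetize_summaries,
    schedule_transmissions,
    summarize_window,
    vector_magnitude,
)

# ---------------------------------------------------------------------------
# helpers


def _sensor(depth=5.0):
    return SensorSample(
        t=0.0,
        depth_m=depth,
        temperature_c=27.3,
        accel_xyz_g=(0.0, 0.0, 1.0),
        mag_xyz_ut=(30.0, 0.0, 40.0),
    )


def _one_hot(taxonomy, cid):
    p = np.zeros(52)
    p[cid] = 1.0
    return ProbabilityVector(taxonomy.class_ids, p)


def _random_summary(rng, t=None):
    ids = sorted(rng.choice(256, size=3, replace=False))
    probs = sorted(rng.random(3), reverse=True)
    return ClassificationSummary(
        t_start=float(rng.integers(0, 2**31)) if t is None else t,
        top3=tuple((int(c), float(p)) for c, p in zip(ids, probs)),
        depth_m=float(rng.uniform(0, 600)),
        temperature_c=float(rng.uniform(-5, 40)),
        accel_magnitude_g=float(rng.uniform(0, 4)),
        mag_magnitude_ut=float(rng.uniform(0, 80)),
    )


def _random_position(rng, t=None):
    return PositionRecord(
        t=float(rng.integers(0, 2**31)) if t is None else t,
        lat=float(rng.uniform(-90, 90)),
        lon=float(rng.uniform(-180, 180)),
        fix_quality=int(rng.integers(0, 8)),
    )


def _assert_round_trip(orig, back):
    if isinstance(orig, ClassificationSummary):
        assert isinstance(back, ClassificationSummary)
        assert back.t_start == float(int(round(orig.t_start)))
        for (c0, p0), (c1, p1) in zip(orig.top3, back.top3):
            assert c0 == c1
            assert abs(p0 - p1) <= 0.5 / 255
        assert abs(orig.depth_m - back.depth_m) <= 0.005
        assert abs(orig.temperature_c - back.temperature_c) <= 0.005
        assert abs(orig.accel_magnitude_g - back.accel_magnitude_g) <= 0.0005
        assert abs(orig.mag_magnitude_ut - back.mag_magnitude_ut) <= 0.05
    else:
        assert isinstance(back, PositionRecord)
        assert abs(orig.lat - back.lat) <= 1e-5
        assert abs(orig.lon - back.lon) <= 1e-5
        assert orig.fix_quality == back.fix_quality


# ---------------------------------------------------------------------------
# vector magnitude


@pytest.mark.parametrize("xyz,expected", [
    ((0, 0, 0), 0.0),
    ((3, 4, 0), 5.0),
    ((1, 1, 1), math.sqrt(3)),
])
def test_vector_magnitude_closed_forms(xyz, expected):
    assert vector_magnitude(*xyz) == pytest.approx(expected)


def test_vector_magnitude_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        vector_magnitude(1.0, float("nan"), 0.0)


# ---------------------------------------------------------------------------
# summarization


def test_identical_one_hots_summarize_to_that_class(taxonomy):
    pvs = [_one_hot(taxonomy, 9)] * 240
    s = summarize_window(pvs, _sensor(), t_start=0.0)
    assert s.top3[0] == (9, 1.0)
    assert s.depth_m == 5.0
    assert s.accel_magnitude_g == pytest.approx(1.0)
    assert s.mag_magnitude_ut == pytest.approx(50.0)


def test_split_vote_ties_order_by_class_id(taxonomy):
    pvs = [_one_hot(taxonomy, 4)] * 120 + [_one_hot(taxonomy, 2)] * 120
    s = summarize_window(pvs, _sensor(), 0.0)
    assert s.top3[0] == (2, 0.5)
    assert s.top3[1] == (4, 0.5)


def test_top3_matches_brute_force_mean(taxonomy):
    rng = np.random.default_rng(21)
    pvs = [
        ProbabilityVector(taxonomy.class_ids, rng.dirichlet(np.ones(52))) for _ in range(4)
    ]
    s = summarize_window(pvs, _sensor(), 0.0)
    mean = np.mean([pv.probs for pv in pvs], axis=0)
    expect = sorted(range(52), key=lambda c: (-mean[c], c))[:3]
    assert [c for c, _ in s.top3] == expect
    for c, p in s.top3:
        assert p == pytest.approx(mean[c])


def test_empty_window_rejected():
    with pytest.raises(ValueError, match="empty"):
        summarize_window([], _sensor(), 0.0)


# ---------------------------------------------------------------------------
# packet codec


def test_thirteen_worst_case_records_fit_one_packet():
    rng = np.random.default_rng(1)
    records = [_random_summary(rng) for _ in range(13)]  # largest record type
    pkt = encode_packet(records, sequence_number=1)
    assert pkt.record_count == 13
    assert len(pkt.payload) <= MAX_PACKET_BYTES
    assert len(pkt.payload) == 7 + 13 * 19  # documented layout, room to spare


def test_fourteen_records_rejected():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="1-13"):
        encode_packet([_random_summary(rng) for _ in range(14)])
    with pytest.raises(ValueError, match="1-13"):
        encode_packet([])


def test_class_id_field_spans_exactly_256_labels():
    base = _random_summary(np.random.default_rng(3))
    ok = ClassificationSummary(0.0, ((255, 0.5), (0, 0.3), (1, 0.2)),
                               base.depth_m, base.temperature_c,
                               base.accel_magnitude_g, base.mag_magnitude_ut)
    decoded = decode_packet(encode_packet([ok]).payload)[0]
    assert decoded.top3[0][0] == 255
    bad = ClassificationSummary(0.0, ((256, 0.5), (0, 0.3), (1, 0.2)),
                                base.depth_m, base.temperature_c,
                                base.accel_magnitude_g, base.mag_magnitude_ut)
    with pytest.raises(ValueError, match="class_id"):
        encode_packet([bad])


def test_randomized_round_trip(taxonomy):
    rng = np.random.default_rng(4)
    for _ in range(200):
        n = int(rng.integers(1, 14))
        records = [
            _random_summary(rng) if rng.random() < 0.5 else _random_position(rng)
            for _ in range(n)
        ]
        pkt = encode_packet(records, sequence_number=int(rng.integers(0, 2**16)))
        back = decode_packet(pkt.payload)
        assert len(back) == n
        for orig, dec in zip(records, back):
            _assert_round_trip(orig, dec)


def test_lat_lon_quantization_at_range_extremes():
    for lat, lon in [(-90, -180), (90, 180), (0, 0), (89.999994, 179.999991)]:
        rec = PositionRecord(t=0.0, lat=lat, lon=lon)
        back = decode_packet(encode_packet([rec]).payload)[0]
        assert abs(back.lat - lat) <= 1e-5
        assert abs(back.lon - lon) <= 1e-5


def test_out_of_range_field_error_names_the_field():
    rec = ClassificationSummary(0.0, ((0, 0.5), (1, 0.3), (2, 0.2)),
                                depth_m=700.0, temperature_c=20.0,
                                accel_magnitude_g=1.0, mag_magnitude_ut=50.0)
    with pytest.raises(ValueError, match="depth_m"):
        encode_packet([rec])


def test_truncated_payload_raises_structured_error():
    pkt = encode_packet([_random_position(np.random.default_rng(5))])
    with pytest.raises(PacketDecodeError) as err:
        decode_packet(pkt.payload[:-3])
    assert err.value.offset >= 0


def test_bad_magic_and_version_rejected():
    pkt = encode_packet([_random_position(np.random.default_rng(6))])
    with pytest.raises(PacketDecodeError, match="magic"):
        decode_packet(b"\x00" + pkt.payload[1:])
    with pytest.raises(PacketDecodeError, match="version"):
        decode_packet(pkt.payload[:1] + b"\xff" + pkt.payload[2:])


def test_packetize_chunks_into_thirteens():
    rng = np.random.default_rng(7)
    summaries = [_random_summary(rng, t=float(i)) for i in range(14)]
    packets = packetize_summaries(summaries)
    assert [p.packet.record_count for p in packets] == [13, 1]
    assert packets[0].creation_time == 12.0  # newest record in the chunk


# ---------------------------------------------------------------------------
# transmission scheduling


def _queue(n, spacing=100.0):
    rng = np.random.default_rng(8)
    return [
        QueuedPacket(encode_packet([_random_position(rng, t=i * spacing)], i), i * spacing)
        for i in range(n)
    ]


def _oracle_replay(queue, surfacings, delays, fail_flags):
    """Independent step-by-step replay of the documented policy."""
    events, sent, discarded = [], [], []
    resolved, failures = set(), {}
    di = ai = 0
    for start, dur in surfacings:
        t, end = start, start + dur
        while True:
            d = delays[di]
            di += 1
            if t + d > end:
                break
            t += d
            eligible = [
                q for q in queue
                if q.packet.sequence_number not in resolved and q.creation_time <= t
            ]
            if not eligible:
                break
            seq = eligible[0].packet.sequence_number
            failed = fail_flags[ai]
            ai += 1
            if failed:
                failures[seq] = failures.get(seq, 0) + 1
                events.append((t, seq, "failed"))
                if failures[seq] == 3:
                    events.append((t, seq, "discarded"))
                    discarded.append(seq)
                    resolved.add(seq)
            else:
                failures[seq] = 0
                events.append((t, seq, "sent"))
                sent.append(seq)
                resolved.add(seq)
    return events, sent, discarded


def test_surfacings_shorter_than_activation_send_nothing():
    queue = _queue(5)
    surfacings = [(i * 1000.0, 5.0) for i in range(10)]  # all < 6 s
    log = schedule_transmissions(queue, surfacings, seed=0)
    assert log.sent == [] and log.discarded == []
    assert len(log.pending) == 5


def test_always_failing_link_discards_after_three_attempts():
    queue = _queue(2)
    surfacings = [(1000.0 + i * 100.0, 60.0) for i in range(10)]
    log = schedule_transmissions(queue, surfacings, seed=0, failure=1.0)
    for seq in (0, 1):
        outcomes = [o for _, s, o in log.events if s == seq]
        assert outcomes == ["failed", "failed", "failed", "discarded"]
    assert log.discarded == [0, 1]


def test_alternating_link_matches_independent_oracle():
    queue = _queue(20)
    surfacings = [(2000.0 + i * 200.0, 40.0) for i in range(40)]
    delays = [6.0] * 10_000
    fail = lambda i: i % 2 == 0
    log = schedule_transmissions(queue, surfacings, failure=fail, activation_delays=delays)
    events, sent, discarded = _oracle_replay(
        queue, surfacings, delays, [i % 2 == 0 for i in range(10_000)]
    )
    assert log.events == events
    assert log.sent == sent
    assert log.discarded == discarded


def test_every_packet_resolves_exactly_once_and_in_order():
    rng = np.random.default_rng(9)
    for trial in range(20):
        n = int(rng.integers(1, 10))
        queue = _queue(n, spacing=float(rng.integers(10, 500)))
        surfacings = []
        t = 0.0
        for _ in range(int(rng.integers(1, 30))):
            t += float(rng.uniform(20, 400))
            surfacings.append((t, float(rng.uniform(2, 40))))
            t += surfacings[-1][1]
        log = schedule_transmissions(queue, surfacings, seed=trial, failure=0.4)
        resolved = log.sent + log.discarded
        assert len(resolved) == len(set(resolved))
        assert sorted(resolved + log.pending) == list(range(n))
        send_times = [t for t, s, o in log.events if o == "sent"]
        assert send_times == sorted(send_times)


def test_unsorted_inputs_rejected():
    queue = list(reversed(_queue(3)))
    with pytest.raises(ValueError, match="time-ordered"):
        schedule_transmissions(queue, [(0.0, 30.0)])
    with pytest.raises(ValueError, match="overlap"):
        schedule_transmissions(_queue(2), [(0.0, 30.0), (10.0, 30.0)])
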
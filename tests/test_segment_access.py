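"""Byte-range math, segment reads, loading strategies and the prefetch cache."""

from fractions import Fraction

import numpy as np
import pytest

from edflazy.edf_model import TimeRange, digital_to_physical, parse_headers
from edflazy.errors import (
    EmptyRangeError,
    RangeNotSupportedError,
    StrategyError,
)
from edflazy.fixtures import ChannelSpec, FixtureSpec, generate_edf
from edflazy.segment_access import (
    CacheConfig,
    HttpRangeStrategy,
    LocalFileStrategy,
    SegmentCache,
    extract_record_aligned,
    read_segment,
    time_range_to_byte_range,
)

from conftest import CountingStrategy, MemStrategy, random_fixture_spec


@pytest.fixture(scope="module")
def two_sig_truth():
    # 2 signals, 100 and 4 samples/record, 1 s records, 10 records.
    spec = FixtureSpec(
        seed=5,
        duration_s=10.0,
        channels=(
            ChannelSpec("A", 100.0, "gaussian-noise", amplitude=120.0),
            ChannelSpec("B", 4.0, "sine", amplitude=90.0),
        ),
    )
    return generate_edf(spec)


class TestTimeRangeToByteRange:
    def test_derived_example(self, two_sig_truth):
        t = two_sig_truth
        # Brute force: record size = 2*(100+4) = 208; records 2,3,4 cover [2,5).
        record_offsets = [t.rec.header_bytes + r * 208 for r in range(10)]
        br = time_range_to_byte_range(TimeRange(2, 5), t.rec, t.sigs)
        assert br.offset == record_offsets[2] == 768 + 2 * 208 == 1184
        assert br.length == 3 * 208 == 624

    def test_whole_file(self, two_sig_truth):
        t = two_sig_truth
        br = time_range_to_byte_range(
            TimeRange(0, float(t.rec.total_duration_s)), t.rec, t.sigs
        )
        assert br.offset == t.rec.header_bytes
        assert br.length == t.rec.num_records * 208
        assert br.end == len(t.raw_bytes)

    def test_sub_record_range_hits_exactly_record_zero(self, two_sig_truth):
        t = two_sig_truth
        br = time_range_to_byte_range(TimeRange(0.5, 0.6), t.rec, t.sigs)
        assert br.offset == t.rec.header_bytes
        assert br.length == 208

    def test_empty_after_clipping(self, two_sig_truth):
        t = two_sig_truth
        with pytest.raises(EmptyRangeError):
            time_range_to_byte_range(TimeRange(20.0, 30.0), t.rec, t.sigs)

    def test_alignment_invariants(self, two_sig_truth):
        t = two_sig_truth
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform(0, 9.9)
            b = rng.uniform(a + 0.01, 10.0)
            br = time_range_to_byte_range(TimeRange(a, b), t.rec, t.sigs)
            assert br.offset >= t.rec.header_bytes
            assert (br.offset - t.rec.header_bytes) % 208 == 0
            assert br.length % 208 == 0


class TestReadSegment:
    def test_whole_recording_equals_ground_truth(self, psg_truth, psg_strategy):
        series = read_segment(
            psg_strategy,
            TimeRange(0, float(psg_truth.rec.total_duration_s)),
            psg_truth.rec,
            psg_truth.sigs,
        )
        assert len(series) == len(psg_truth.sigs)
        for s in series:
            expected = digital_to_physical(
                psg_truth.digital[s.channel_index], psg_truth.sigs[s.channel_index]
            )
            np.testing.assert_array_equal(s.min_values, expected)
            np.testing.assert_array_equal(s.max_values, expected)
            assert np.all(np.diff(s.timestamps_ms) > 0)

    def test_partial_equals_whole_file_slice(self, psg_truth, psg_strategy):
        whole = read_segment(
            psg_strategy, TimeRange(0, 60), psg_truth.rec, psg_truth.sigs
        )
        part = read_segment(
            psg_strategy, TimeRange(3.25, 7.75), psg_truth.rec, psg_truth.sigs
        )
        for w, p in zip(whole, part):
            # Oracle: per-sample Fraction arithmetic, independent of the
            # implementation's ceil-based index math.
            sig = psg_truth.sigs[w.channel_index]
            fs = sig.sampling_rate_hz(psg_truth.rec.record_duration_s)
            keep = [
                j
                for j in range(len(w.min_values))
                if Fraction(3.25) <= Fraction(j, 1) / fs < Fraction(7.75)
            ]
            np.testing.assert_array_equal(p.min_values, w.min_values[keep])
            np.testing.assert_array_equal(p.timestamps_ms, w.timestamps_ms[keep])

    @pytest.mark.parametrize("seed", range(5))
    def test_partial_read_oracle_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        truth = generate_edf(random_fixture_spec(rng))
        strategy = MemStrategy(truth.raw_bytes)
        total = float(truth.rec.total_duration_s)
        whole = read_segment(strategy, TimeRange(0, total), truth.rec, truth.sigs)
        for _ in range(40):
            a = rng.uniform(0, total * 0.99)
            b = rng.uniform(a + total * 0.005, total)
            part = read_segment(strategy, TimeRange(a, b), truth.rec, truth.sigs)
            for w, p in zip(whole, part):
                mask = (w.timestamps_ms >= truth.rec.start_epoch_ms + a * 1000) & (
                    w.timestamps_ms < truth.rec.start_epoch_ms + b * 1000
                )
                # Boundary-safe comparison: the returned sample count and
                # values must match the timestamp-window slice of the whole
                # parse up to float rounding of the window edges.
                np.testing.assert_array_equal(
                    p.min_values,
                    w.min_values[np.isin(w.timestamps_ms, p.timestamps_ms)],
                )
                assert abs(len(p) - mask.sum()) <= 1

    def test_beyond_end_is_clipped(self, psg_truth, psg_strategy):
        part = read_segment(
            psg_strategy, TimeRange(59.0, 120.0), psg_truth.rec, psg_truth.sigs
        )
        fs0 = 100.0
        assert len(part[0]) == int(fs0)  # exactly the last second

    def test_entirely_beyond_end_errors(self, psg_truth, psg_strategy):
        with pytest.raises(EmptyRangeError):
            read_segment(
                psg_strategy, TimeRange(100.0, 120.0), psg_truth.rec, psg_truth.sigs
            )

    def test_annotation_channels_excluded(self):
        truth = generate_edf(
            FixtureSpec(
                seed=9,
                channels=(
                    ChannelSpec("EEG C4-A1", 10.0),
                    ChannelSpec("EDF Annotations", 10.0, "constant", amplitude=0.0),
                ),
            )
        )
        series = read_segment(
            MemStrategy(truth.raw_bytes), TimeRange(0, 10), truth.rec, truth.sigs
        )
        assert [s.channel_index for s in series] == [0]


class TestStrategies:
    def test_local_read_version_field(self, fixture_dir):
        strategy = LocalFileStrategy(fixture_dir / "psg.edf")
        assert strategy.read(0, 8) == b"0".ljust(8, b" ")

    def test_local_missing_file(self, tmp_path):
        with pytest.raises(StrategyError):
            LocalFileStrategy(tmp_path / "nope.edf")

    def test_http_matches_local_on_random_ranges(self, fixture_dir, http_base):
        local = LocalFileStrategy(fixture_dir / "psg.edf")
        remote = HttpRangeStrategy(f"{http_base}/psg.edf")
        assert remote.size() == local.size()
        rng = np.random.default_rng(1)
        for _ in range(25):
            o = int(rng.integers(0, local.size() - 1))
            l = int(rng.integers(1, min(5000, local.size() - o)))
            assert remote.read(o, l) == local.read(o, l)

    def test_server_without_ranges_is_detected(self, fixture_dir):
        from edflazy.testserver import serve_directory

        with serve_directory(fixture_dir, support_ranges=False) as url:
            strategy = HttpRangeStrategy(f"{url}/psg.edf")
            with pytest.raises(RangeNotSupportedError):
                strategy.read(0, 8)

    def test_concatenation_property(self, psg_strategy):
        o, a, b = 300, 1000, 2000
        assert (
            psg_strategy.read(o, a) + psg_strategy.read(o + a, b)
            == psg_strategy.read(o, a + b)
        )


class TestSegmentCache:
    def _cache(self, truth, counting=False):
        strategy = MemStrategy(truth.raw_bytes)
        if counting:
            strategy = CountingStrategy(strategy)
        return SegmentCache(strategy, truth.rec, truth.sigs), strategy

    def test_fresh_window_covers_plus_minus_two_widths(self, long_truth):
        cache, _ = self._cache(long_truth)
        cache.ensure_window(TimeRange(60, 90))  # W = 30
        assert cache.covered_span_s() == (0.0, 150.0)

    def test_jump_evicts_old_span(self, long_truth):
        cache, _ = self._cache(long_truth)
        cache.ensure_window(TimeRange(60, 90))
        cache.ensure_window(TimeRange(600, 630))
        assert cache.covered_span_s() == (540.0, 690.0)
        assert cache.get_cached(TimeRange(0, 150)) is None

    def test_left_clip_at_file_start(self, long_truth):
        cache, _ = self._cache(long_truth)
        cache.ensure_window(TimeRange(0, 30))
        assert cache.covered_span_s() == (0.0, 90.0)

    def test_repeat_is_noop(self, long_truth):
        cache, strategy = self._cache(long_truth, counting=True)
        cache.ensure_window(TimeRange(60, 90))
        n = len(strategy.reads)
        cache.ensure_window(TimeRange(60, 90))
        assert len(strategy.reads) == n

    def test_viewport_served_without_new_reads(self, long_truth):
        cache, strategy = self._cache(long_truth, counting=True)
        cache.ensure_window(TimeRange(60, 90))
        n = len(strategy.reads)
        series = read_segment(cache, TimeRange(60, 90), long_truth.rec,
                              long_truth.sigs)
        assert len(strategy.reads) == n  # monotone coverage: all cache hits
        assert len(series[0]) == 300

    def test_cache_transparency(self, long_truth):
        cache, _ = self._cache(long_truth)
        plain = MemStrategy(long_truth.raw_bytes)
        cache.ensure_window(TimeRange(100, 130))
        for t in [TimeRange(100, 130), TimeRange(40, 200), TimeRange(0, 700)]:
            a = read_segment(cache, t, long_truth.rec, long_truth.sigs)
            b = read_segment(plain, t, long_truth.rec, long_truth.sigs)
            assert a == b

    def test_scroll_coalesces_reads(self, long_truth):
        cache, strategy = self._cache(long_truth, counting=True)
        cache.ensure_window(TimeRange(60, 90))
        assert len(strategy.reads) == 1  # one contiguous gap
        cache.ensure_window(TimeRange(90, 120))
        assert len(strategy.reads) == 2  # only the right-side extension

    def test_get_cached_returns_record_bytes(self, long_truth):
        cache, _ = self._cache(long_truth)
        cache.ensure_window(TimeRange(60, 90))
        data = cache.get_cached(TimeRange(60, 90))
        rsz = 2 * 10
        offset = long_truth.rec.header_bytes + 60 * rsz
        assert data == long_truth.raw_bytes[offset : offset + 30 * rsz]

    def test_failure_leaves_state_unchanged(self, long_truth):
        class FailingStrategy:
            def read(self, o, l):
                raise StrategyError("boom")

            def size(self):
                return len(long_truth.raw_bytes)

        cache = SegmentCache(FailingStrategy(), long_truth.rec, long_truth.sigs)
        with pytest.raises(StrategyError):
            cache.ensure_window(TimeRange(0, 30))
        assert cache.covered_span_s() is None
        assert cache._blocks == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CacheConfig(viewport_width_s=0)
        with pytest.raises(ValueError):
            CacheConfig(prefetch_multiplier=-1)


class TestExtractRecordAligned:
    def test_excerpt_parses_and_matches(self, psg_truth, psg_strategy):
        data = extract_record_aligned(
            psg_strategy, TimeRange(10.0, 20.0), psg_truth.rec, psg_truth.sigs
        )
        rec, sigs = parse_headers(data)
        assert rec.num_records == 10
        assert rec.start_time.minute == 0 and rec.start_time.second == 10
        excerpt = read_segment(MemStrategy(data), TimeRange(0, 10), rec, sigs)
        original = read_segment(
            psg_strategy, TimeRange(10, 20), psg_truth.rec, psg_truth.sigs
        )
        for a, b in zip(excerpt, original):
            np.testing.assert_array_equal(a.min_values, b.min_values)
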
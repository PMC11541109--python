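import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocodec import GeneratorConfig, compress_channel, decompress_channel, detect_spikes, generate_recording, ssr
from neurocodec.intra_channel_codec import (
    Bitstream,
    SymbolTable,
    ac_decode,
    ac_encode,
    adapt_rice_parameter,
    dpcm2_decode,
    dpcm2_encode,
    golomb_decode,
    golomb_encode,
    map_from_nonneg,
    map_to_nonneg,
    train_symbol_table,
)

sample_series = st.lists(st.integers(-256, 255), min_size=2, max_size=300).map(np.array)


class TestDpcm2:
    def test_constant_series_residuals_zero(self):
        r = dpcm2_encode(np.full(30, 17))
        assert not r.residuals.any()

    def test_linear_series_residuals_zero(self):
        r = dpcm2_encode(np.arange(30))
        assert not r.residuals.any()

    @given(sample_series)
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_exact(self, x):
        assert np.array_equal(dpcm2_decode(dpcm2_encode(x)), x)

    def test_residual_range_invariant(self, rng):
        x = rng.integers(-256, 256, size=2000)
        r = dpcm2_encode(x)
        assert np.abs(r.residuals).max() <= 4 * 256


class TestZigzag:
    @pytest.mark.parametrize("v,expected", [(0, 0), (-1, 1), (1, 2), (-2, 3), (2, 4)])
    def test_interleave_order(self, v, expected):
        assert map_to_nonneg(v) == expected

    def test_bijection_over_working_range(self):
        v = np.arange(-1024, 1025)
        assert np.array_equal(map_from_nonneg(map_to_nonneg(v)), v)


class TestRice:
    def test_zero_with_k0_is_single_bit(self):
        bs = golomb_encode([0], 0)
        assert bs.payload_bits == 1 and bs.payload == b"\x00"

    def test_hand_example_v9_k2(self):
        # quotient 2 -> "110", remainder 1 -> "01"
        bs = golomb_encode([9], 2)
        assert bs.payload_bits == 5
        assert format(bs.payload[0], "08b")[:5] == "11001"

    @given(st.lists(st.integers(0, 2000), max_size=200), st.integers(0, 7))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, values, k):
        bs = golomb_encode(values, k)
        assert golomb_decode(bs, k).tolist() == values

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            golomb_encode([-1], 2)

    def test_truncated_stream_detected(self):
        from neurocodec._bitio import BitstreamError

        bs = golomb_encode([1000], 0)
        clipped = Bitstream(payload=bs.payload[:10], payload_bits=80, rice_k=0)
        with pytest.raises(BitstreamError):
            golomb_decode(clipped, 0)


class TestRiceAdaptation:
    def test_degenerate_all_zero_source(self):
        assert adapt_rice_parameter(1.0) == 0

    def test_table_maximum(self):
        assert adapt_rice_parameter(0.0) == 7

    def test_monotone_nonincreasing_in_zero_fraction(self):
        ks = [adapt_rice_parameter(zf) for zf in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_near_optimal_for_geometric_source(self, rng):
        # geometric with mean 6 (zero fraction 1/7)
        values = rng.geometric(1.0 / 7.0, size=4000) - 1
        zf = np.mean(values == 0)
        chosen = adapt_rice_parameter(zf)
        costs = {k: golomb_encode(values, k).payload_bits for k in range(8)}
        best = min(costs, key=costs.get)
        assert abs(chosen - best) <= 1


class TestSymbolTable:
    def test_single_repeated_symbol_dominates(self):
        table = train_symbol_table([np.full(2000, 5)])
        assert table.counts[5] == table.counts.max()
        assert (np.delete(table.counts, 5) == 1).all()

    def test_serialized_size_is_2048_bytes(self, rng):
        table = train_symbol_table([rng.integers(0, 1024, size=5000)])
        blob = table.serialize()
        assert len(blob) == 2048
        assert SymbolTable.deserialize(blob).counts.tolist() == table.counts.tolist()

    def test_identical_data_identical_tables(self, rng):
        data = rng.integers(0, 200, size=3000)
        t1, t2 = train_symbol_table([data]), train_symbol_table([data.copy()])
        assert np.array_equal(t1.counts, t2.counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_symbol_table([np.array([], dtype=int)])


class TestArithmeticCoder:
    @given(st.lists(st.integers(-256, 255), min_size=0, max_size=300))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_mapped_residuals(self, values):
        mapped = np.asarray(map_to_nonneg(np.array(values, dtype=int)))if values else np.array([], dtype=int)
        table = train_symbol_table([np.arange(1500) % 520])  # generic wide table
        bs = ac_encode(mapped, table)
        assert ac_decode(bs, table, len(values)).tolist() == mapped.tolist()

    def test_escape_path_roundtrip(self):
        table = train_symbol_table([np.zeros(2000, dtype=int)])
        values = [0, 1023, 1024, 3000, 4094, 0]
        bs = ac_encode(values, table)
        assert ac_decode(bs, table, len(values)).tolist() == values

    def test_degenerate_table_codes_repeats_cheaply(self):
        table = train_symbol_table([np.zeros(5000, dtype=int)])
        n = 10_000
        bs = ac_encode(np.zeros(n, dtype=int), table)
        assert bs.payload_bits <= n * 0.02 + 64

    def test_code_length_brackets_empirical_entropy(self, rng):
        # stationary geometric-ish source within the explicit alphabet
        values = np.minimum(rng.geometric(0.25, size=8000) - 1, 1023)
        table = train_symbol_table([values])
        bs = ac_encode(values, table)
        counts = np.bincount(values)
        p = counts[counts > 0] / values.size
        H = -(p * np.log2(p)).sum()
        n = values.size
        assert n * H - 1 <= bs.payload_bits <= n * H + 0.1 * n + 128


class TestChannelCompression:
    @pytest.mark.parametrize("backend", ["gc", "ac"])
    def test_lossless_roundtrip(self, short_recording, backend):
        rec, _ = short_recording
        table = train_symbol_table([dpcm2_encode(rec.channel(0))]) if backend == "ac" else None
        bs = compress_channel(rec, 0, "lossless", backend, table=table)
        assert np.array_equal(decompress_channel(bs, table), rec.channel(0))

    def test_near_lossless_preserves_spikes_and_zeros_rest(self, short_recording):
        rec, _ = short_recording
        events = detect_spikes(rec, 0)
        assert events
        bs = compress_channel(rec, 0, "near_lossless", "gc", events=events)
        out = decompress_channel(bs)
        mask = np.zeros(rec.n_samples, dtype=bool)
        for ev in events:
            assert np.array_equal(out[ev.onset : ev.onset + 64], ev.waveform)
            mask[ev.onset : ev.onset + 64] = True
        assert not out[~mask].any()

    def test_near_lossless_empty_recording_is_tiny(self):
        cfg = GeneratorConfig(duration_s=1.0, firing_rate_hz=0.0, noise_sd=0.0, seed=0)
        rec, _ = generate_recording(cfg, templates=[])
        bs = compress_channel(rec, 0, "near_lossless", "gc", events=[])
        assert bs.payload_bits < rec.n_samples * rec.bit_depth / 100
        assert not decompress_channel(bs).any()

    def test_near_lossless_requires_events(self, short_recording):
        rec, _ = short_recording
        with pytest.raises(ValueError):
            compress_channel(rec, 0, "near_lossless", "gc")

    def test_ac_requires_table(self, short_recording):
        rec, _ = short_recording
        with pytest.raises(ValueError, match="table"):
            compress_channel(rec, 0, "lossless", "ac")

    def test_container_roundtrip(self, short_recording):
        rec, _ = short_recording
        bs = compress_channel(rec, 0, "lossless", "gc")
        back = Bitstream.from_bytes(bs.to_bytes())
        assert back.mode == bs.mode and back.payload_bits == bs.payload_bits
        assert np.array_equal(decompress_channel(back), rec.channel(0))

    def test_dpcm2_reduces_entropy_on_bandlimited_signal(self):
        cfg = GeneratorConfig(duration_s=1.0, firing_rate_hz=0.0, noise_sd=1.0, lfp_amplitude=60.0, seed=4)
        rec, _ = generate_recording(cfg, templates=[])
        x = rec.channel(0)

        def entropy(v):
            _, counts = np.unique(v, return_counts=True)
            p = counts / v.size
            return -(p * np.log2(p)).sum()

        assert entropy(dpcm2_encode(x).residuals) < entropy(x)


class TestSsr:
    def test_no_savings(self):
        assert ssr(1000, 1000) == 0.0

    def test_full_savings(self):
        assert ssr(1000, 0) == 100.0

    def test_arithmetic(self):
        assert ssr(180_000, 16_200) == pytest.approx(91.0)

    def test_zero_original_rejected(self):
        with pytest.raises(ValueError):
            ssr(0, 10)
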
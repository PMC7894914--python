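"""Bandpass filter, padding, scaling and the image encoding."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftrisk import (
    ChannelScaler,
    FilterSpec,
    bandpass_filter,
    decode_image,
    encode_image,
    pad_trial,
)
from liftrisk.preprocessing import (
    IMAGE_SIDE,
    MAX_FRAMES,
    N_PAD_CELLS,
    N_STREAMS,
    LiftTensor,
    rezero_padding,
)
from liftrisk.simulate import N_CHANNELS, RawTrial


def make_trial(frames, zone=1, sr=25.0):
    return RawTrial(subject_id="S01", zone=zone, frames=frames, sample_rate=sr)


def analytic_bandpass_gain(f_hz, spec: FilterSpec) -> float:
    """Closed-form magnitude response of the digital Butterworth band-pass.

    The bilinear transform maps the analog prototype exactly onto the
    digital filter at prewarped frequencies: |H_d(f)| = |H_a(j*w(f))| with
    w(f) = 2*fs*tan(pi*f/fs).  For an order-n band-pass from band edges
    (wl, wh): |H| = 1/sqrt(1 + ((w^2 - wl*wh) / (w*(wh - wl)))^(2n)).
    """
    fs = spec.sample_rate

    def warp(f):
        return 2.0 * fs * np.tan(np.pi * f / fs)

    w, wl, wh = warp(f_hz), warp(spec.low_cut), warp(spec.high_cut)
    x = (w * w - wl * wh) / (w * (wh - wl))
    return 1.0 / np.sqrt(1.0 + x ** (2 * spec.order))


class TestBandpassFilter:
    def test_zero_input_zero_output(self):
        trial = make_trial(np.zeros((200, N_CHANNELS)))
        out = bandpass_filter(trial, FilterSpec())
        assert np.allclose(out.frames, 0.0)

    def test_dc_rejected(self):
        trial = make_trial(np.full((750, N_CHANNELS), 5.0))
        out = bandpass_filter(trial, FilterSpec())
        steady = out.frames[200:550]
        assert np.abs(steady).max() < 0.05  # < 1% of the 5-unit input

    def test_linearity(self, rng):
        spec = FilterSpec()
        x = rng.standard_normal((300, N_CHANNELS))
        y = rng.standard_normal((300, N_CHANNELS))
        fx = bandpass_filter(make_trial(x), spec).frames
        fy = bandpass_filter(make_trial(y), spec).frames
        fxy = bandpass_filter(make_trial(2.5 * x - 1.5 * y), spec).frames
        assert np.allclose(fxy, 2.5 * fx - 1.5 * fy, atol=1e-9)

    @pytest.mark.parametrize("f_probe", [4.0, 7.0, 10.0])
    def test_passband_gain_matches_analytic_response(self, f_probe):
        """A steady sinusoid comes out with the closed-form Butterworth
        gain (applied twice: zero-phase filtering squares the magnitude)."""
        spec = FilterSpec()
        t = np.arange(int(30 * spec.sample_rate)) / spec.sample_rate
        x = np.tile(np.sin(2 * np.pi * f_probe * t)[:, None], (1, N_CHANNELS))
        out = bandpass_filter(make_trial(x), spec).frames[:, 0]
        mid = out[150:600]  # steady state
        tm = t[150:600]
        # amplitude via quadrature demodulation
        amp = 2.0 * np.abs(np.mean(mid * np.exp(-2j * np.pi * f_probe * tm)))
        expected = analytic_bandpass_gain(f_probe, spec) ** 2
        assert amp == pytest.approx(expected, rel=0.02)

    def test_high_cut_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(high_cut=12.5).validate()

    def test_sample_rate_mismatch_rejected(self):
        trial = make_trial(np.zeros((100, N_CHANNELS)), sr=50.0)
        with pytest.raises(ValueError, match="sample rate"):
            bandpass_filter(trial, FilterSpec())


class TestPadTrial:
    def test_full_length_trial_identity(self, rng):
        trial = make_trial(rng.standard_normal((MAX_FRAMES, N_CHANNELS)))
        t = pad_trial(trial)
        assert t.pad_start == MAX_FRAMES
        assert t.data.shape == (N_STREAMS, MAX_FRAMES, 3)

    def test_short_trial_zero_padded(self, rng):
        trial = make_trial(rng.standard_normal((300, N_CHANNELS)))
        t = pad_trial(trial)
        assert t.pad_start == 300
        assert np.allclose(t.data[:, 300:, :], 0.0)
        assert not np.allclose(t.data[:, :300, :], 0.0)

    def test_channel_rearrangement_placement_major(self, rng):
        frames = rng.standard_normal((10, N_CHANNELS))
        t = pad_trial(make_trial(frames))
        for stream in range(N_STREAMS):
            for axis in range(3):
                assert np.array_equal(
                    t.data[stream, :10, axis], frames[:, stream * 3 + axis]
                )

    def test_overlong_trial_refused(self, rng):
        trial = make_trial(rng.standard_normal((800, N_CHANNELS)))
        with pytest.raises(ValueError, match="truncate"):
            pad_trial(trial)

    def test_tensor_value_count_is_27000(self, quick_tensors):
        assert quick_tensors[0].data.size == 27_000


class TestChannelScaler:
    def test_zscore_definition(self, quick_tensors):
        scaler = ChannelScaler("zscore").fit(quick_tensors)
        scaled = scaler.transform_all(quick_tensors)
        values = np.stack([t.data for t in scaled]).transpose(0, 2, 1, 3).reshape(-1, 36)
        assert np.abs(values.mean(axis=0)).max() < 1e-9
        assert np.abs(values.std(axis=0) - 1.0).max() < 1e-9

    def test_minmax_bounds_on_training_data(self, quick_tensors):
        scaler = ChannelScaler("minmax").fit(quick_tensors)
        scaled = scaler.transform_all(quick_tensors)
        values = np.stack([t.data for t in scaled])
        assert values.min() >= -1.0 - 1e-12 and values.max() <= 1.0 + 1e-12

    def test_held_out_data_may_exceed_minmax_bounds(self, quick_tensors):
        scaler = ChannelScaler("minmax").fit(quick_tensors[:4])
        big = LiftTensor(
            data=quick_tensors[0].data * 10.0, pad_start=quick_tensors[0].pad_start
        )
        out = scaler.transform(big)
        assert out.data.max() > 1.0  # same parameters, no re-fitting

    def test_constant_channel_scaled_to_zero_with_warning(self):
        t = LiftTensor(data=np.full((N_STREAMS, MAX_FRAMES, 3), 3.3), pad_start=MAX_FRAMES)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            scaler = ChannelScaler("zscore").fit([t])
        assert np.allclose(scaler.transform(t).data, 0.0)

    def test_fitted_parameters_immutable(self, quick_tensors):
        scaler = ChannelScaler().fit(quick_tensors)
        with pytest.raises(RuntimeError, match="immutable"):
            scaler.fit(quick_tensors)

    def test_rezero_padding_after_scaling(self, quick_tensors):
        scaler = ChannelScaler("zscore").fit(quick_tensors)
        out = rezero_padding(scaler.transform(quick_tensors[0]))
        ps = out.pad_start
        assert np.all(out.data[:, ps:, :] == 0.0)


class TestImageEncoding:
    def test_pad_cell_count(self):
        assert IMAGE_SIDE * IMAGE_SIDE - N_STREAMS * MAX_FRAMES == N_PAD_CELLS == 25
        assert 3 * N_STREAMS * MAX_FRAMES == 27_000

    def test_round_trip(self, rng):
        t = LiftTensor(
            data=rng.standard_normal((N_STREAMS, MAX_FRAMES, 3)), pad_start=MAX_FRAMES
        )
        back = decode_image(encode_image(t))
        assert np.array_equal(back.data, t.data)

    def test_index_arithmetic_oracle(self):
        """Value s + 12f placed at (stream s, frame f) lands at image cell
        (row (s+12f)//95, col (s+12f)%95) — checked over all 9,000 positions."""
        data = np.zeros((N_STREAMS, MAX_FRAMES, 3))
        for s in range(N_STREAMS):
            for f in range(MAX_FRAMES):
                data[s, f, :] = s + 12 * f
        img = encode_image(LiftTensor(data=data, pad_start=MAX_FRAMES)).data
        for axis in range(3):
            for s in range(0, N_STREAMS, 5):
                for f in range(0, MAX_FRAMES, 13):
                    i = s + 12 * f
                    assert img[i // IMAGE_SIDE, i % IMAGE_SIDE, axis] == i
        # full check vectorised over every position
        idx = np.arange(N_STREAMS * MAX_FRAMES)
        flat = img.reshape(-1, 3)
        assert np.array_equal(flat[idx, 0], idx)

    def test_trailing_cells_are_padding(self, rng):
        t = LiftTensor(
            data=rng.standard_normal((N_STREAMS, MAX_FRAMES, 3)), pad_start=MAX_FRAMES
        )
        flat = encode_image(t).data.reshape(-1, 3)
        assert np.all(flat[N_STREAMS * MAX_FRAMES :, :] == 0.0)

    def test_value_multiset_preserved(self, rng):
        t = LiftTensor(
            data=rng.standard_normal((N_STREAMS, MAX_FRAMES, 3)), pad_start=MAX_FRAMES
        )
        img = encode_image(t)
        for axis in range(3):
            assert sorted(t.data[:, :, axis].ravel()) == sorted(
                img.data.reshape(-1, 3)[: N_STREAMS * MAX_FRAMES, axis]
            )

    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="shape|must be"):
            LiftTensor(data=rng.standard_normal((36, 750, 3)), pad_start=750)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=1, max_value=MAX_FRAMES))
def test_pad_then_encode_roundtrip_any_length(f):
    rng = np.random.default_rng(f)
    frames = rng.standard_normal((f, N_CHANNELS))
    trial = RawTrial(subject_id="s", zone=4, frames=frames, sample_rate=25.0)
    t = pad_trial(trial)
    back = decode_image(encode_image(t), pad_start=t.pad_start)
    assert np.array_equal(back.data, t.data)
    assert np.array_equal(back.data[:, :f, :].transpose(1, 0, 2).reshape(f, -1), frames)
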
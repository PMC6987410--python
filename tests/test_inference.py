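"""dF/F computation, noise estimation, and MAP spike decoding."""

import numpy as np
import pytest

from hippocal.errors import BaselineError, ParameterError
from hippocal.inference import (
    classify_active,
    compute_dff,
    estimate_noise,
    infer_spikes,
)
from hippocal.model import DffTrace, IndicatorParams, forward_model

from conftest import make_train, noiseless_dff


class TestComputeDff:
    def test_constant_trace_gives_zeros(self):
        dff = compute_dff(np.full(100, 50.0), frame_rate=15.0)
        assert np.allclose(dff.values, 0.0)
        assert dff.baseline_f0 == 50.0

    def test_hand_example(self):
        dff = compute_dff(np.array([8.0, 10.0, 12.0]), frame_rate=15.0)
        assert dff.baseline_f0 == 10.0
        assert np.allclose(dff.values, [-0.2, 0.0, 0.2])

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        f = 100 + rng.random(200)
        a = compute_dff(f, frame_rate=15.0).values
        b = compute_dff(f * 13.7, frame_rate=15.0).values
        assert np.allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(BaselineError):
            compute_dff(np.array([-1.0, 0.0, 1.0]), frame_rate=15.0)


class TestEstimateNoise:
    def test_gaussian_consistency(self):
        # sigma = 0.02 white noise, 3000 frames: estimate within 10% on
        # >= 95/100 seeds.
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            est = estimate_noise(rng.normal(0, 0.02, 3000))
            hits += 0.018 <= est <= 0.022
        assert hits >= 95

    def test_constant_trace_gives_zero(self):
        assert estimate_noise(np.full(100, 0.3)) == 0.0

    def test_multiplier_is_exact_factor(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 500)
        assert estimate_noise(x, 1.5) == pytest.approx(1.5 * estimate_noise(x), rel=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise(np.zeros(5))


class TestInferSpikes:
    def test_flat_trace_zero_spikes(self):
        dff = DffTrace(values=np.zeros(600), frame_rate=15.0, baseline_f0=1.0)
        res = infer_spikes(dff, params=IndicatorParams(noise_sigma=0.02))
        assert res.spikes.total == 0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_noiseless_isolated_events_exact(self, k):
        # isolated k-AP events >= 1 s apart: exact count recovery
        train = make_train({150: k, 600: 1, 1200: k}, n_frames=1800)
        res = infer_spikes(noiseless_dff(train))
        assert res.spikes.total == train.total
        assert res.spikes.counts[150] == k
        assert res.spikes.counts[1200] == k

    def test_single_ap_timing_within_one_frame(self):
        train = make_train({700: 1}, n_frames=1500)
        res = infer_spikes(noiseless_dff(train))
        assert res.spikes.total == 1
        frame = int(np.nonzero(res.spikes.counts)[0][0])
        assert abs(frame - 700) <= 1

    def test_resynthesis_residual_bounded(self):
        rng = np.random.default_rng(2)
        train = make_train({100: 1, 500: 2, 1000: 1, 2000: 1}, n_frames=3000)
        sigma = 0.02
        y = forward_model(train) + rng.normal(0, sigma, 3000)
        dff = DffTrace(values=y - 1.0, frame_rate=15.0, baseline_f0=1.0)
        res = infer_spikes(dff)
        resynth = forward_model(res.spikes) * res.baseline_path
        rms = np.sqrt(np.mean((y - resynth) ** 2))
        assert rms <= 2 * sigma

    def test_false_positive_rate_under_drift(self):
        # zero-spike traces with +/-3% linear drift and sigma = 0.02:
        # at most 1 spurious spike per 200 s recording.
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 3000
            drift = 1.0 + np.linspace(-0.03, 0.03, n) * rng.choice([-1, 1])
            y = drift + rng.normal(0, 0.02, n)
            dff = DffTrace(values=y - 1.0, frame_rate=15.0, baseline_f0=1.0)
            res = infer_spikes(dff)
            assert res.spikes.total <= 1

    def test_clamp_warns(self):
        train = make_train({100: 6, 101: 6, 102: 6}, n_frames=600)
        with pytest.warns(RuntimeWarning, match="clamped"):
            infer_spikes(noiseless_dff(train))


def test_classify_active():
    assert not classify_active(make_train({}, n_frames=10))
    assert classify_active(make_train({3: 1}, n_frames=10))
    assert classify_active(make_train({3: 4}, n_frames=10))
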
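"""Gait-characteristic estimators: analytic limits, oracle equivalence,
response to structured variability, and the walking-speed identity."""

import math

import numpy as np
import pytest

from gaitq import GaitModelParams, generate_walking_accel
from gaitq.features import (
    FeatureConfig,
    autocorr_at_dominant_period,
    composite_score,
    compute_epoch_features,
    dominant_amplitude,
    dominant_frequency,
    index_of_harmonicity,
    log_divergence_per_stride,
    rms,
    sample_entropy,
    stride_frequency,
    stride_length,
    vertical_excursion,
    COMPOSITE_COMPONENTS,
)
from gaitq.segmentation import Epoch

from _oracles import autocorr_naive, logdiv_naive, sampen_naive

FS = 100.0


def _epoch_vt(params: GaitModelParams, seed: int) -> np.ndarray:
    return generate_walking_accel(params, 12.0, seed).vt[:1000]


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(500, 3.7)) == 0.0

    def test_zero_tolerance_never_raises(self):
        assert math.isnan(sample_entropy(np.full(500, 1.0), r_factor=0.0))

    @pytest.mark.parametrize("m,r", [(2, 0.2), (5, 0.3)])
    def test_matches_pair_counting_oracle(self, rng, m, r):
        x = rng.normal(size=1000)
        assert sample_entropy(x, m, r) == pytest.approx(sampen_naive(x, m, r), abs=1e-8)

    def test_sine_more_regular_than_shuffled_surrogate(self):
        wins = 0
        for s in range(20):
            g = np.random.default_rng(s)
            t = np.arange(1000) / FS
            x = np.sin(2 * np.pi * 2.0 * t) + g.normal(0, 0.05, 1000)
            wins += sample_entropy(x) < sample_entropy(g.permutation(x))
        assert wins >= 17  # sign test, p << 0.01 under a fair coin

    def test_affine_invariance(self, rng):
        x = rng.normal(size=600)
        a = sample_entropy(x)
        b = sample_entropy(4.2 * x - 17.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.zeros(50))


class TestLogDivergence:
    def test_noiseless_periodic_gait_near_zero(self, clean_walk, clean_params):
        lam = log_divergence_per_stride(
            clean_walk.vt[:1000], 2 / clean_params.step_frequency, FS
        )
        assert abs(lam) <= 0.05

    def test_matches_exhaustive_neighbor_oracle(self):
        p = GaitModelParams()
        x = _epoch_vt(p, seed=9)
        cfg = FeatureConfig()
        st = 2 / p.step_frequency
        a = log_divergence_per_stride(x, st, FS, cfg)
        b = logdiv_naive(x, st, FS, cfg)
        assert a == pytest.approx(b, abs=1e-8)

    def test_monotone_in_stride_to_stride_phase_jitter(self):
        means = []
        for level in (0.0, 0.05, 0.1, 0.2):
            vals = []
            for s in range(20):
                p = GaitModelParams(phase_jitter_sd=level, amplitude_jitter_sd=0.03)
                vals.append(
                    log_divergence_per_stride(
                        _epoch_vt(p, 100 + s), 2 / p.step_frequency, FS
                    )
                )
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_undefined_for_bad_stride_time(self, clean_walk):
        assert math.isnan(log_divergence_per_stride(clean_walk.vt[:1000], math.nan, FS))


class TestSpectralMeasures:
    def test_stride_frequency_from_commanded_gait(self):
        p = GaitModelParams(step_frequency=1.8)
        f = stride_frequency(_epoch_vt(p, 4), FS)
        assert f == pytest.approx(0.9, abs=0.05)

    def test_rest_noise_undefined(self, rng):
        assert math.isnan(stride_frequency(rng.normal(0, 0.02, 1000), FS))

    def test_peak_within_natural_resolution(self):
        # zero-padding locates the peak well inside the 0.1 Hz epoch bin
        p = GaitModelParams(step_frequency=1.9, phase_jitter_sd=0, amplitude_jitter_sd=0, sensor_noise_sd=0)
        f = dominant_frequency(_epoch_vt(p, 0), FS)
        assert f == pytest.approx(1.9, abs=0.02)

    def test_index_of_harmonicity_pure_sine(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        assert index_of_harmonicity(x, 1.0, FS) == pytest.approx(1.0, abs=0.01)

    def test_index_of_harmonicity_two_tone(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.0 * t + 0.3)
        assert index_of_harmonicity(x, 1.0, FS) == pytest.approx(0.5, abs=0.02)

    def test_index_of_harmonicity_white_noise_low(self):
        vals = [
            index_of_harmonicity(np.random.default_rng(s).normal(size=1000), 0.95, FS)
            for s in range(20)
        ]
        assert np.mean(vals) < 0.6
        assert all(0 <= v <= 1 for v in vals)

    def test_dominant_amplitude_linear_in_amplitude(self):
        t = np.arange(1000) / FS
        base = np.sin(2 * np.pi * 2.0 * t)
        a1 = dominant_amplitude(0.1 * base, FS)
        a2 = dominant_amplitude(0.2 * base, FS)
        assert a2 == pytest.approx(2 * a1, rel=1e-6)
        assert a1 == pytest.approx(0.1, rel=0.02)

    def test_autocorr_pure_sine_near_one(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 2.5 * t)
        r = autocorr_at_dominant_period(x, FS)
        assert r >= 0.95

    def test_autocorr_matches_shifted_dot_oracle(self):
        p = GaitModelParams()
        x = _epoch_vt(p, 21)
        f = dominant_frequency(x, FS)
        a = autocorr_at_dominant_period(x, FS, dominant_freq=f)
        b = autocorr_naive(x, round(FS / f))
        assert a == pytest.approx(b, abs=1e-8)

    def test_autocorr_undefined_without_peak(self, rng):
        assert math.isnan(autocorr_at_dominant_period(rng.normal(0, 0.02, 1000), FS))


class TestWalkingSpeed:
    def test_stride_length_closed_form(self):
        # l = 0.90 m, h = 0.02 m: step 0.3774 m, stride 0.7548 m
        assert stride_length(0.02, 0.90) == pytest.approx(0.7548, abs=2e-4)

    def test_zero_excursion_zero_length(self):
        assert stride_length(0.0, 0.9) == 0.0

    def test_excursion_at_least_leg_length_rejected(self):
        with pytest.raises(ValueError):
            stride_length(0.9, 0.9)
        with pytest.raises(ValueError):
            stride_length(-0.01, 0.9)

    def test_vertical_excursion_recovers_commanded(self):
        p = GaitModelParams(vertical_excursion=0.02, step_frequency=1.8)
        h = vertical_excursion(_epoch_vt(p, 5), 1.8, FS)
        assert h == pytest.approx(0.02, rel=0.15)

    def test_zero_amplitude_near_zero(self, rng):
        x = 1.0 + rng.normal(0, 1e-5, 1000)
        assert vertical_excursion(x, 2.0, FS) < 1e-3

    def test_undefined_step_frequency_propagates(self, rng):
        assert math.isnan(vertical_excursion(rng.normal(size=1000), math.nan, FS))

    def test_downstream_speed_example(self):
        # h = 0.02 m, l = 0.90 m, f_step = 1.8 Hz -> ~0.679 m/s within 10%
        p = GaitModelParams(
            vertical_excursion=0.02, leg_length=0.90, step_frequency=1.8
        )
        x = _epoch_vt(p, 6)
        f_step = dominant_frequency(x, FS)
        h = vertical_excursion(x, f_step, FS)
        v = (f_step / 2) * stride_length(h, 0.90)
        assert v == pytest.approx(2 * math.sqrt(2 * 0.9 * 0.02 - 0.02**2) * 1.8, rel=0.10)

    def test_speed_identity_in_epoch_features(self, default_walk):
        row = compute_epoch_features(
            default_walk, Epoch(0, 0, 1000), leg_length=0.9
        )
        assert row["walking_speed"] == row["stride_frequency"] * row["stride_length"]


class TestRms:
    def test_sine_closed_form(self):
        t = np.arange(1000) / FS
        x = 0.37 * np.sin(2 * np.pi * 2.0 * t)  # whole cycles in the window
        assert rms(x) == pytest.approx(0.37 / math.sqrt(2), abs=1e-3)

    def test_constant_zero(self):
        assert rms(np.full(100, 5.0)) == 0.0

    def test_matches_direct_recomputation(self, rng):
        x = rng.normal(2.0, 1.3, size=1500)
        c = x - x.mean()
        assert rms(x) == pytest.approx(float(np.sqrt(np.mean(c * c))), abs=1e-12)


class TestComposite:
    def _norm(self):
        return {c: (0.5, 0.2) for c in COMPOSITE_COMPONENTS}

    def test_all_zero_weights(self):
        comp = {c: 0.7 for c in COMPOSITE_COMPONENTS}
        w = {c: 0.0 for c in COMPOSITE_COMPONENTS}
        assert composite_score(comp, weights=w, normalization=self._norm()) == 0.0

    def test_cohort_internal_normalization_centers_at_zero(self, rng):
        import pandas as pd

        from gaitq.features import cohort_normalization

        df = pd.DataFrame(
            {c: rng.normal(size=200) for c in COMPOSITE_COMPONENTS}
        )
        norm = cohort_normalization(df)
        scores = [
            composite_score({c: row[c] for c in COMPOSITE_COMPONENTS}, normalization=norm)
            for _, row in df.iterrows()
        ]
        assert abs(np.mean(scores)) < 1e-10

    def test_one_sd_above_on_each_oriented_component(self):
        from gaitq.features import DEFAULT_ORIENTATION

        norm = self._norm()
        comp = {
            c: norm[c][0] + DEFAULT_ORIENTATION[c] * norm[c][1]
            for c in COMPOSITE_COMPONENTS
        }
        w = {c: 0.25 for c in COMPOSITE_COMPONENTS}
        assert composite_score(comp, weights=w, normalization=norm) == pytest.approx(1.0)

    def test_missing_component_undefined(self):
        comp = {c: 0.5 for c in COMPOSITE_COMPONENTS}
        comp["rms_ml"] = math.nan
        assert math.isnan(composite_score(comp, normalization=self._norm()))


class TestEndToEndRecovery:
    def test_speed_and_stride_frequency_grid(self):
        # 3x3 grid of commanded (step frequency, vertical excursion)
        for f_step in (1.6, 1.9, 2.2):
            for h in (0.02, 0.035, 0.05):
                p = GaitModelParams(step_frequency=f_step, vertical_excursion=h)
                x = _epoch_vt(p, seed=int(f_step * 100 + h * 1000))
                f_est = dominant_frequency(x, FS)
                h_est = vertical_excursion(x, f_est, FS)
                v_est = (f_est / 2) * stride_length(h_est, p.leg_length)
                assert f_est / 2 == pytest.approx(p.stride_frequency, rel=0.10)
                assert v_est == pytest.approx(p.walking_speed, rel=0.10)
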
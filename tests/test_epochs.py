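"""Epoch segmentation, correlation estimators and hyper-parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hypnostats import (
    Hypnogram,
    Recording,
    acf_lag_samples,
    amplitude_histograms,
    autocorrelation,
    crosscorrelation,
    hyperparameter_table,
    hyperparameters,
    pool_by_stage,
    pool_hyperparameters,
    segment_epochs,
)
from hypnostats.epochs import UndefinedStatisticError, epoch_length_samples


def brute_force_acf(y, max_lag):
    """Defining sums of the biased ACF, evaluated term by term."""
    y = np.asarray(y, float)
    n = len(y)
    ybar = sum(y) / n
    var = sum((v - ybar) ** 2 for v in y) / n
    out = []
    for lag in range(max_lag + 1):
        s = sum((y[t] - ybar) * (y[t + lag] - ybar) for t in range(n - lag))
        out.append(s / (n * var))
    return np.array(out)


def brute_force_hypers(y, lag):
    y = np.asarray(y, float)
    n = len(y)
    ybar = sum(y) / n
    var = sum((v - ybar) ** 2 for v in y) / n
    std = var ** 0.5
    kur = sum(((v - ybar) / std) ** 4 for v in y) / n - 3
    ske = sum(((v - ybar) / std) ** 3 for v in y) / n
    acf = sum((y[t] - ybar) * (y[t + lag] - ybar)
              for t in range(n - lag)) / (n * var)
    return std, kur, ske, acf


class TestSegmentation:
    @pytest.mark.parametrize("n_samples,expected_epochs", [
        (3 * 7680, 3),        # exactly three 30-s epochs at 256 Hz
        (7679, 0),            # one sample short of an epoch
        (20000, 2),           # 20000 = 2*7680 + 4640 discarded
    ])
    def test_epoch_counts(self, n_samples, expected_epochs, rng):
        rec = Recording(rng.normal(size=(2, n_samples)), 256.0, ["a", "b"])
        segs = segment_epochs(rec, 30.0)
        assert segs.shape == (2, expected_epochs, 7680)

    def test_non_integer_epoch_length_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            epoch_length_samples(256.01, 30.0)

    def test_segments_are_contiguous_windows(self, rng):
        sig = np.arange(2 * 7680, dtype=float)
        rec = Recording(sig[None, :], 256.0, ["a"])
        segs = segment_epochs(rec)
        assert segs[0, 1, 0] == 7680.0


class TestCorrelation:
    def test_acf_lag0_is_one(self, rng):
        y = rng.normal(size=500)
        assert autocorrelation(y, 10)[0] == pytest.approx(1.0, abs=1e-14)

    def test_white_noise_acf_near_zero(self, rng):
        y = rng.normal(size=7680)
        assert abs(autocorrelation(y, 100)[77]) < 3 / np.sqrt(7680)

    def test_ar1_acf_matches_closed_form(self, rng):
        phi = 0.99
        n = 200_000
        eps = rng.normal(size=n)
        y = np.empty(n)
        y[0] = eps[0] / np.sqrt(1 - phi**2)
        for t in range(1, n):
            y[t] = phi * y[t - 1] + eps[t]
        acf = autocorrelation(y, 20)
        for lag in (1, 5, 10, 20):
            assert acf[lag] == pytest.approx(phi**lag, abs=0.02)

    def test_acf_agrees_with_brute_force(self, rng):
        y = rng.normal(size=32)
        np.testing.assert_allclose(
            autocorrelation(y, 8), brute_force_acf(y, 8), atol=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            autocorrelation(np.ones(100), 5)

    def test_ccf_identity_and_sign(self, rng):
        y = rng.normal(size=1000)
        assert crosscorrelation(y, y, [0])[0] == pytest.approx(1.0, abs=1e-12)
        assert crosscorrelation(y, -y, [0])[0] == pytest.approx(-1.0, abs=1e-12)

    def test_ccf_independent_noise_near_zero(self, rng):
        a, b = rng.normal(size=(2, 7680))
        ccf = crosscorrelation(a, b, [-77, 0, 77])
        assert np.all(np.abs(ccf) < 3 / np.sqrt(7680))

    def test_ccf_negative_lag_mirrors_swapped_channels(self, rng):
        a, b = rng.normal(size=(2, 512))
        fwd = crosscorrelation(a, b, [7])
        rev = crosscorrelation(b, a, [-7])
        np.testing.assert_allclose(fwd, rev, atol=1e-12)


class TestHyperparameters:
    def test_alternating_two_point_segment(self):
        y = np.tile([1.0, -1.0], 50)
        std, kur, ske, _ = hyperparameters(y)
        assert std == pytest.approx(1.0)
        assert kur == pytest.approx(-2.0)   # lower bound, two-point symmetric
        assert ske == pytest.approx(0.0)

    def test_four_point_population_moments(self):
        # population moments of {1,2,3,4}: var 1.25, kurtosis 1.64 (excess -1.36)
        std, kur, ske, _ = hyperparameters(np.array([1.0, 2.0, 3.0, 4.0]),
                                           acf_lag_ms=1000 / 256)
        assert std == pytest.approx(np.sqrt(1.25), abs=1e-12)
        assert ske == pytest.approx(0.0, abs=1e-12)
        assert kur == pytest.approx(-1.36, abs=1e-12)

    def test_gaussian_white_noise_moments(self, rng):
        n = 100_000
        y = rng.normal(size=n)
        _, kur, ske, _ = hyperparameters(y)
        assert abs(kur) < 3 * np.sqrt(24 / n)
        assert abs(ske) < 3 * np.sqrt(6 / n)

    def test_agrees_with_brute_force(self, rng):
        y = rng.normal(size=30)
        lag = 3
        got = hyperparameters(y, acf_lag_ms=lag * 1000 / 256.0)
        expected = brute_force_hypers(y, lag)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_constant_segment_flags_undefined(self):
        std, kur, ske, acf = hyperparameters(np.full(100, 3.3))
        assert std == 0.0
        assert np.isnan(kur) and np.isnan(ske) and np.isnan(acf)

    def test_lag_rounding_300ms_at_256hz(self):
        assert acf_lag_samples(300.0, 256.0) == 77

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(4, 64),
                      elements=st.floats(-1e3, 1e3, allow_nan=False)))
    def test_excess_kurtosis_never_below_minus_two(self, y):
        std, kur, _, _ = hyperparameters(y)
        if std > 0:
            assert kur >= -2.0 - 1e-9


class TestTableAndPooling:
    def test_table_matches_scalar_path(self, small_recording, small_table):
        _, recording, hypnogram, _ = small_recording
        segs = segment_epochs(recording)
        row = small_table[(small_table.epoch == 5)
                          & (small_table.channel == 1)].iloc[0]
        expected = hyperparameters(segs[1, 5], 300.0, 256.0)
        np.testing.assert_allclose(
            [row.STD, row.KUR, row.SKE, row.ACF300], expected, atol=1e-10)

    def test_pool_hyperparameters_partition(self):
        import pandas as pd
        table = pd.DataFrame({
            "epoch": [0, 1, 2], "channel": [0, 0, 0],
            "stage": ["N2", "N2", "N3"],
            "STD": [1.0, 1.0, 1.0], "KUR": [0.0, 0.0, 0.0],
            "SKE": [0.0, 0.0, 0.0], "ACF300": [0.2, 0.4, 0.6],
            "artifact": [False, False, False],
        })
        pooled = pool_hyperparameters(table)
        np.testing.assert_allclose(pooled["N2"]["ACF300"], [0.2, 0.4])
        np.testing.assert_allclose(pooled["N3"]["ACF300"], [0.6])

    def test_pooling_conserves_counts(self, small_recording, small_table):
        _, recording, hypnogram, _ = small_recording
        pooled = pool_hyperparameters(small_table)
        total = sum(len(v["STD"]) for v in pooled.values())
        n_unmasked = (~hypnogram.artifact_mask).sum() * recording.n_channels
        assert total == n_unmasked

    def test_pool_curves_single_stage_is_plain_average(self, rng):
        curves = rng.normal(size=(2, 4, 10))
        hyp = Hypnogram(np.array(["N2"] * 4, dtype=object))
        pooled = pool_by_stage(curves, hyp)
        np.testing.assert_allclose(
            pooled["N2"], curves.reshape(-1, 10).mean(axis=0))
        assert set(pooled) == {"N2"}

    def test_pool_curves_excludes_artifacts(self, rng):
        curves = np.ones((1, 3, 5))
        curves[0, 2] = 99.0
        hyp = Hypnogram(np.array(["N1", "N1", "N1"], dtype=object),
                        np.array([False, False, True]))
        pooled = pool_by_stage(curves, hyp)
        np.testing.assert_allclose(pooled["N1"], np.ones(5))

    def test_stage_std_ordering_follows_base_scale(self, small_recording,
                                                   small_table):
        cfg, _, _, _ = small_recording
        pooled = pool_hyperparameters(small_table)
        means = {s: v["STD"].mean() for s, v in pooled.items()}
        scales = {s: cfg.stage_params[s].base_scale for s in means}
        order_obs = sorted(means, key=means.get)
        order_cfg = sorted(scales, key=scales.get)
        assert order_obs == order_cfg

    def test_histograms_integrate_to_one(self, small_recording):
        _, recording, _, _ = small_recording
        segs = segment_epochs(recording)[:, :5]
        hist, edges = amplitude_histograms(segs)
        widths = np.diff(edges)
        integrals = (hist * widths).sum(axis=2)
        np.testing.assert_allclose(integrals, 1.0, atol=1e-6)
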
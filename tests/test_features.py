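"""Descriptive features: extrema, summaries, imputation, normalization."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import MinMaxScaler

from ccepml.features import (DegenerateSignalError, FeatureParams,
                             MODEL_INPUT_COLUMNS, adf_pvalue,
                             amplitude_summaries, apply_normalizer,
                             build_feature_table, detect_extrema,
                             fit_impute_stats, fit_normalizer, impute_missing)
from ccepml.io_edf import EcogEpoch, LabelledTest
from ccepml.preprocess import PreprocessParams, SmoothedSignal

FP = FeatureParams()


def _sig(values, start=21):
    return SmoothedSignal(values=np.asarray(values, float), start_index=start)


def _bump(n, center, amp, width=5.0, start=21):
    t = start + np.arange(n)
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestAmplitudeSummaries:
    def test_direct(self):
        sigs = [_sig([0, a]) for a in (10, 20, 30)]
        assert amplitude_summaries(sigs) == (30, 20, 10)

    def test_single_channel(self):
        assert amplitude_summaries([_sig([0, 7])]) == (7, 7, 7)


def oracle_extrema(x, start, params=FP):
    """Greedy-by-value extremum search with the distance constraint."""
    def side(y, ref):
        cand = [i for i in range(1, len(y) - 1)
                if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] >= ref]
        kept = []
        for i in sorted(cand, key=lambda i: -y[i]):
            if all(abs(i - j) >= params.peak_min_distance for j in kept):
                kept.append(i)
        kept = sorted(sorted(kept, key=lambda i: -y[i])[:2])
        return [(start + i, x[i]) for i in kept]

    m = x.mean()
    return (side(x, m + params.peak_min_height),
            side(-x, -(m - params.peak_min_height)))


class TestDetectExtrema:
    def test_single_bump(self):
        """One 10 μV bump on a flat baseline -> one maximum, no minima."""
        x = _bump(260, 80, 10.0)
        maxima, minima = detect_extrema(_sig(x))
        assert len(maxima) == 1 and minima == []
        lat, val = maxima[0]
        assert lat == 80
        assert val == pytest.approx(10.0, abs=0.01)

    def test_close_bumps_collapse(self):
        """Two 10 μV bumps 10 ms apart violate the 20 ms spacing: keep one."""
        x = _bump(260, 80, 10.0, width=3) + _bump(260, 90, 9.0, width=3)
        maxima, _ = detect_extrema(_sig(x))
        assert len(maxima) == 1

    def test_low_bump_ignored(self):
        """A 4 μV bump is below the 5 μV height threshold."""
        maxima, _ = detect_extrema(_sig(_bump(260, 80, 4.0)))
        assert maxima == []

    def test_trough_on_negated_signal(self):
        x = -_bump(260, 120, 12.0)
        maxima, minima = detect_extrema(_sig(x))
        assert maxima == [] and len(minima) == 1
        assert minima[0][0] == 120

    def test_latency_ordering_of_two_peaks(self):
        x = _bump(260, 150, 8.0) + _bump(260, 60, 12.0)
        maxima, _ = detect_extrema(_sig(x))
        assert [m[0] for m in maxima] == [60, 150]

    def test_matches_brute_force_on_random_signals(self):
        """Greedy-by-value oracle equivalence on 200 random smooth traces."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            base = rng.normal(0, 4, 60)
            x = np.interp(np.arange(260), np.linspace(0, 259, 60), base)
            sig = _sig(x)
            got_max, got_min = detect_extrema(sig)
            exp_max, exp_min = oracle_extrema(x, sig.start_index)
            assert [m[0] for m in got_max] == [m[0] for m in exp_max]
            assert [m[0] for m in got_min] == [m[0] for m in exp_min]
            for got, exp in ((got_max, exp_max), (got_min, exp_min)):
                assert np.allclose([v for _, v in got], [v for _, v in exp],
                                   rtol=1e-9)


class TestAdf:
    def test_random_walk_rarely_stationary(self):
        rng = np.random.default_rng(5)
        high = sum(adf_pvalue(_sig(np.cumsum(rng.normal(size=280)))) > 0.05
                   for _ in range(100))
        assert high >= 95

    def test_white_noise_mostly_stationary(self):
        rng = np.random.default_rng(6)
        low = sum(adf_pvalue(_sig(rng.normal(size=280))) < 0.05
                  for _ in range(100))
        assert low >= 95

    def test_constant_trace_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            adf_pvalue(_sig(np.zeros(280)))

    def test_excluded_from_model_inputs_by_default(self):
        assert "adf_pvalue" not in MODEL_INPUT_COLUMNS


def _table(rows):
    cols = ["test_id", "patient_id", "target", "max_amp", "mean_amp",
            "min_amp", "signal_mean", "peak1_value", "peak1_latency",
            "peak2_value", "peak2_latency", "trough1_value",
            "trough1_latency", "trough2_value", "trough2_latency"]
    return pd.DataFrame(rows, columns=cols)


def _full_row(tid, **kw):
    base = dict(test_id=tid, patient_id=tid, target=0, max_amp=20.0,
                mean_amp=10.0, min_amp=2.0, signal_mean=1.0, peak1_value=10.0,
                peak1_latency=80.0, peak2_value=5.0, peak2_latency=150.0,
                trough1_value=-8.0, trough1_latency=40.0, trough2_value=-4.0,
                trough2_latency=200.0)
    base.update(kw)
    return base


class TestImputation:
    def test_zeros_scheme(self):
        t = _table([_full_row("a", peak2_value=np.nan, peak2_latency=np.nan)])
        out = impute_missing(t, "zeros")
        assert out.loc[0, "peak2_value"] == 0.0
        assert out.loc[0, "peak2_latency"] == 0.0

    def test_ratio_mean_second_peak(self):
        """Training mean(peak2/peak1) = 0.5, row peak1 = 8 -> peak2 = 4."""
        train = _table([_full_row("a", peak1_value=10.0, peak2_value=4.0),
                        _full_row("b", peak1_value=10.0, peak2_value=6.0)])
        stats = fit_impute_stats(train)
        assert stats.ratios["peak2_value"] == pytest.approx(0.5)
        row = _table([_full_row("c", peak1_value=8.0, peak2_value=np.nan,
                                peak2_latency=np.nan)])
        out = impute_missing(row, "ratio_mean", stats)
        assert out.loc[0, "peak2_value"] == pytest.approx(4.0)
        assert out.loc[0, "peak2_latency"] == pytest.approx(150.0)

    def test_ratio_mean_first_peak_uses_amplitude(self):
        train = _table([_full_row("a", max_amp=20.0, peak1_value=10.0)])
        stats = fit_impute_stats(train)
        row = _table([_full_row("c", max_amp=30.0, peak1_value=np.nan)])
        out = impute_missing(row, "ratio_mean", stats)
        assert out.loc[0, "peak1_value"] == pytest.approx(15.0)

    def test_trough_sign_restored(self):
        train = _table([_full_row("a", max_amp=20.0, trough1_value=-10.0)])
        stats = fit_impute_stats(train)
        row = _table([_full_row("c", max_amp=40.0, trough1_value=np.nan)])
        out = impute_missing(row, "ratio_mean", stats)
        assert out.loc[0, "trough1_value"] == pytest.approx(-20.0)

    @pytest.mark.parametrize("scheme", ["zeros", "ratio_mean"])
    def test_complete_table_unchanged(self, scheme):
        t = _table([_full_row("a"), _full_row("b")])
        stats = fit_impute_stats(t)
        pd.testing.assert_frame_equal(impute_missing(t, scheme, stats), t)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(2)
        rows = [_full_row(f"r{i}") for i in range(20)]
        t = _table(rows)
        mask = rng.random((20, 8)) < 0.3
        ext = ["peak1_value", "peak1_latency", "peak2_value", "peak2_latency",
               "trough1_value", "trough1_latency", "trough2_value",
               "trough2_latency"]
        t.loc[:, ext] = t[ext].mask(mask)
        stats = fit_impute_stats(t)
        for scheme in ("zeros", "ratio_mean"):
            out = impute_missing(t, scheme, stats)
            assert not out[ext].isna().any().any()
            observed = ~t[ext].isna()
            pd.testing.assert_frame_equal(out[ext][observed], t[ext][observed])

    def test_unsupported_extremum_falls_back_to_zeros(self, caplog):
        train = _table([_full_row("a", peak2_value=np.nan)])
        stats = fit_impute_stats(train)
        row = _table([_full_row("c", peak2_value=np.nan)])
        with caplog.at_level(logging.WARNING):
            out = impute_missing(row, "ratio_mean", stats)
        assert out.loc[0, "peak2_value"] == 0.0
        assert "falling back to zeros" in caplog.text


class TestNormalizer:
    def test_endpoints_and_midpoint(self):
        t = _table([_full_row("a", max_amp=2.0), _full_row("b", max_amp=4.0),
                    _full_row("c", max_amp=6.0)])
        stats = fit_normalizer(t, ["max_amp"])
        out = apply_normalizer(t, stats)
        assert list(out["max_amp"]) == [0.0, 0.5, 1.0]

    def test_out_of_sample_extrapolates(self):
        train = _table([_full_row("a", max_amp=2.0), _full_row("b", max_amp=6.0)])
        stats = fit_normalizer(train, ["max_amp"])
        test = _table([_full_row("c", max_amp=8.0)])
        assert apply_normalizer(test, stats).loc[0, "max_amp"] == pytest.approx(1.5)

    def test_constant_training_feature_maps_to_zero(self):
        train = _table([_full_row("a"), _full_row("b")])
        stats = fit_normalizer(train, ["max_amp"])
        test = _table([_full_row("c", max_amp=999.0)])
        assert apply_normalizer(test, stats).loc[0, "max_amp"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(_table([]))

    def test_self_normalization_hits_unit_range(self, feature_table):
        filled = impute_missing(feature_table, "zeros")
        stats = fit_normalizer(filled)
        out = apply_normalizer(filled, stats)
        for col in MODEL_INPUT_COLUMNS:
            if filled[col].nunique() > 1:
                assert out[col].min() == pytest.approx(0.0)
                assert out[col].max() == pytest.approx(1.0)

    def test_matches_sklearn_minmax_on_varying_columns(self, feature_table):
        filled = impute_missing(feature_table, "zeros")
        stats = fit_normalizer(filled)
        ours = apply_normalizer(filled, stats)[MODEL_INPUT_COLUMNS].to_numpy()
        theirs = MinMaxScaler().fit_transform(filled[MODEL_INPUT_COLUMNS])
        assert np.allclose(ours, theirs, rtol=1e-9, atol=1e-12)


class TestBuildFeatureTable:
    def _tests(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(7500) / 25.0
        out = []
        for i in range(n):
            x = rng.normal(0, 2, (8, 7500))
            x[2] += 40 * np.exp(-0.5 * ((t - 80) / 10) ** 2)
            ep = EcogEpoch(f"t{i}", f"p{i % 3}", "pre", x)
            out.append(LabelledTest(f"t{i}", f"p{i % 3}", ep, i % 2))
        return out

    def test_shape_and_columns(self):
        table = build_feature_table(self._tests())
        assert len(table) == 10
        assert list(table.columns)[:3] == ["test_id", "patient_id", "target"]

    def test_row_order_permutation_invariance(self):
        tests = self._tests()
        a = build_feature_table(tests)
        b = build_feature_table(tests[::-1]).iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_worked_epoch_fixture(self):
        """Feature row matches values hand-computed by the naive path."""
        t = np.arange(7500) / 25.0
        x = np.zeros((4, 7500))
        x[3] = (40 * np.exp(-0.5 * ((t - 100) / 10) ** 2)
                - 15 * np.exp(-0.5 * ((t - 40) / 6) ** 2))
        # EcogEpoch requires 8 channels minimum on ingest paths; build 8
        x = np.vstack([x, np.zeros((4, 7500))])
        ep = EcogEpoch("w", "pw", "pre", x)
        table = build_feature_table([LabelledTest("w", "pw", ep, 1)])
        row = table.iloc[0]

        # independent naive recomputation of the selected channel
        binned = np.array([x[3][25 * k:25 * (k + 1)].mean() for k in range(300)])
        smoothed = np.array([binned[j - 20:j].mean() for j in range(20, 301)])
        trimmed = smoothed[1:]  # no artifact: mandatory shift only
        assert row["max_amp"] == pytest.approx(trimmed.max() - trimmed.min())
        assert row["min_amp"] == pytest.approx(0.0)
        assert row["signal_mean"] == pytest.approx(trimmed.mean())
        # trailing-window lag shifts latencies by ~half the 20 ms window
        assert row["peak1_latency"] == pytest.approx(110, abs=1)
        assert row["trough1_latency"] == pytest.approx(50, abs=1)
        assert row["peak1_value"] == pytest.approx(trimmed.max(), abs=1e-9)
        assert np.isnan(row["peak2_value"])
        assert row["target"] == 1

    def test_training_stats_ignore_test_rows(self, feature_table):
        """Imputation and normalization stats are test-set independent."""
        train = feature_table.iloc[:40]
        stats_a = fit_impute_stats(train)
        stats_b = fit_impute_stats(pd.concat([train]))  # no test rows anywhere
        assert stats_a.ratios == stats_b.ratios
        norm_a = fit_normalizer(impute_missing(train, "zeros"))
        full = impute_missing(feature_table, "zeros")
        norm_full = fit_normalizer(full.iloc[:40])
        pd.testing.assert_series_equal(norm_a.mins, norm_full.mins)
        pd.testing.assert_series_equal(norm_a.maxs, norm_full.maxs)
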
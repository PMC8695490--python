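import numpy as np
import pytest
import scipy.signal
import scipy.stats
from sklearn.preprocessing import QuantileTransformer

import spiketongue as st
from spiketongue.dataio import CHANNELS, RawRecording
from spiketongue.preprocess import (
    FilterSpec, PreprocessModel, apply_quantile_map, balance_cycles,
    fit_outlier_stats, fit_quantile_map, highpass_filter, holdout_mask,
    remove_outliers,
)


# ---------------------------------------------------------------- filter
class TestHighpass:
    def test_constant_input_maps_to_zero(self):
        out = highpass_filter(np.full(500, 37.2))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_step_response_matches_continuous_decay(self):
        """A unit step decays as exp(-2*pi*f_p*t) (tau ~ 318 s); the
        discretization agrees with the continuous response within 1%."""
        spec = FilterSpec()
        x = np.concatenate([np.zeros(100), np.ones(2000)])
        out = highpass_filter(x, spec)
        t = np.arange(2000)
        expected = np.exp(-2 * np.pi * spec.pole_hz * t)
        assert np.max(np.abs(out[100:] - expected)) < 0.01
        assert abs(1.0 / (2 * np.pi * spec.pole_hz) - 318.3) < 0.1

    def test_passband_sinusoid_preserved(self):
        # RMS-based amplitude over whole periods (integer sampling of a
        # 0.1 Hz tone never hits the analytic peak)
        spec = FilterSpec()
        t = np.arange(5000)
        x = np.sin(2 * np.pi * 0.1 * t)
        out = highpass_filter(x, spec)
        amp = np.sqrt(2 * np.mean(out[1000:4000] ** 2))
        assert abs(amp - 1.0) < 0.01

    def test_corner_gain_is_sqrt_half(self):
        spec = FilterSpec()
        b, a = spec.coefficients()
        _, h = scipy.signal.freqz(b, a, worN=[spec.pole_hz], fs=1.0)
        assert abs(np.abs(h[0]) - 1 / np.sqrt(2)) < 0.005

    def test_linearity_and_time_invariance(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=300), rng.normal(size=300)
        lhs = highpass_filter(2 * x1 + 3 * x2 - (2 * x1[0] + 3 * x2[0]))
        rhs = 2 * highpass_filter(x1 - x1[0]) + 3 * highpass_filter(x2 - x2[0])
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_empty_and_invalid(self):
        assert highpass_filter(np.array([])).size == 0
        with pytest.raises(ValueError):
            FilterSpec(pole_hz=0.7)  # above Nyquist


# ---------------------------------------------------------------- outliers
class TestOutliers:
    def test_hand_computed_stats(self):
        mean, sd = fit_outlier_stats(np.array([[0.0], [2.0]]))
        assert mean[0] == 1.0 and sd[0] == 1.0  # population SD

    def test_standard_normal_channel(self):
        x = np.random.default_rng(1).normal(size=(20000, 1))
        mean, sd = fit_outlier_stats(x)
        assert abs(mean[0]) < 0.03 and abs(sd[0] - 1.0) < 0.03

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_outlier_stats(np.array([[1.0]]))
        with pytest.raises(ValueError):
            fit_outlier_stats(np.array([[1.0], [1.0]]))

    def test_planted_outlier_removed_boundary_retained(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1000, 2))
        mean, sd = fit_outlier_stats(x)
        x[17, 0] = mean[0] + 5 * sd[0]          # strictly outside
        x[42, 1] = mean[1] + 4 * sd[1]          # exactly on the boundary
        keep = remove_outliers(x, mean, sd)
        assert not keep[17]
        assert keep[42]
        refit = x[np.abs((x - mean) / sd).max(axis=1) <= 4]
        assert remove_outliers(refit, mean, sd).all()  # identity within 4 SD


# ---------------------------------------------------------------- quantile map
class TestQuantileMap:
    def test_grid_anchors(self):
        train = np.random.default_rng(3).normal(size=2001)
        q, g = fit_quantile_map(train, n_quantiles=101)
        assert apply_quantile_map(np.median(train), q, g) == pytest.approx(0.5, abs=1e-6)
        assert apply_quantile_map(train.min(), q, g) == 0.0
        assert apply_quantile_map(train.max(), q, g) == 1.0
        assert apply_quantile_map(train.max() + 10, q, g) == 1.0  # clipped
        assert apply_quantile_map(train.min() - 10, q, g) == 0.0

    def test_uniform_training_data_gives_identity_map(self):
        train = np.random.default_rng(4).uniform(size=5000)
        q, g = fit_quantile_map(train, n_quantiles=1000)
        probe = np.linspace(0.05, 0.95, 50)
        assert np.max(np.abs(apply_quantile_map(probe, q, g) - probe)) < 0.03

    def test_rank_preserved(self):
        train = np.random.default_rng(5).normal(size=1000)
        q, g = fit_quantile_map(train)
        a = np.sort(np.random.default_rng(6).normal(size=200))
        out = apply_quantile_map(a, q, g)
        assert np.all(np.diff(out) >= 0)

    def test_matches_sklearn_quantile_transformer(self):
        """Independent cross-check against sklearn's uniform-output
        quantile transformer on the training data itself."""
        train = np.random.default_rng(7).gamma(2.0, size=3000)
        q, g = fit_quantile_map(train, n_quantiles=1000)
        ours = apply_quantile_map(train, q, g)
        qt = QuantileTransformer(n_quantiles=1000, output_distribution="uniform")
        theirs = qt.fit_transform(train[:, None])[:, 0]
        assert np.max(np.abs(ours - theirs)) < 0.01


# ---------------------------------------------------------------- balancing
def _make_cycle_recording(cycles, session=1, t0=0):
    """cycles: list of list of (label, length) segments."""
    ts, labels, cyc = [], [], []
    t = t0
    for ci, segs in enumerate(cycles):
        for lab, n in segs:
            for _ in range(n):
                ts.append(t)
                labels.append(lab)
                cyc.append(ci)
                t += 1
    vals = np.random.default_rng(0).normal(size=(len(ts), 1))
    return RawRecording(np.array(ts), vals, np.array(labels),
                        np.full(len(ts), session), np.array(cyc), ("COND",))


class TestBalanceCycles:
    def test_incomplete_cycle_removed(self):
        rec = _make_cycle_recording([
            [(0, 5), (1, 5), (2, 5), (3, 5), (4, 5)],
            [(0, 5), (1, 5), (2, 5), (3, 5)],        # missing beverage 4
        ])
        out = balance_cycles(rec, segment_length=300)
        assert set(np.unique(out.cycle)) == {0}
        assert out.n_measurements == 25

    def test_long_segment_truncated(self):
        rec = _make_cycle_recording([
            [(0, 400), (1, 5), (2, 5), (3, 5), (4, 5)],
        ])
        out = balance_cycles(rec, segment_length=300)
        assert (out.labels == 0).sum() == 300
        assert out.timestamps[out.labels == 0].max() == 299  # first 300 s kept

    def test_identity_apart_from_non_beverage(self):
        rec = _make_cycle_recording([
            [(0, 5), (-1, 3), (1, 5), (2, 5), (3, 5), (4, 5)],
        ])
        out = balance_cycles(rec, segment_length=300)
        assert out.n_measurements == 25
        assert (out.labels >= 0).all()

    def test_no_complete_cycle_warns_and_empties(self):
        rec = _make_cycle_recording([[(0, 5), (1, 5)]])
        with pytest.warns(UserWarning):
            out = balance_cycles(rec)
        assert out.n_measurements == 0


# ---------------------------------------------------------------- pipeline
class TestPipeline:
    def test_output_in_unit_interval_and_deterministic(self, fast_processed, fast_config):
        processed, _ = fast_processed
        assert processed.values.min() >= 0.0 and processed.values.max() <= 1.0
        rec = st.generate_dataset(fast_config)
        again, _ = st.preprocess(rec, segment_length=fast_config.segment_length)
        assert again == processed

    def test_training_rows_map_to_uniform(self, fast_processed):
        """Quantile-normalized training data is uniform on [0, 1]."""
        processed, model = fast_processed
        mask = holdout_mask(processed)
        for j in range(processed.n_channels):
            vals = processed.values[mask, j]
            ks = scipy.stats.kstest(vals, "uniform").statistic
            assert ks < 0.02

    def test_no_statistic_uses_test_rows(self, fast_config):
        """Mask audit: perturbing held-out rows leaves every fitted
        statistic unchanged."""
        rec = st.generate_dataset(fast_config)
        balanced = balance_cycles(rec, segment_length=fast_config.segment_length)
        test_sess = balanced.session.max()
        test_cycle = balanced.cycle[balanced.session == test_sess].max()
        # build an explicit mask over the *raw* recording rows
        pos = {(s, t) for s, t, c in zip(balanced.session, balanced.timestamps, balanced.cycle)
               if s == test_sess and c == test_cycle}
        train_mask = np.array([
            (s, t) not in pos for s, t in zip(rec.session, rec.timestamps)
        ])
        _, m1 = st.preprocess(rec, train_mask, segment_length=fast_config.segment_length)
        rec2 = RawRecording(
            rec.timestamps, rec.values + np.where(train_mask, 0.0, 1e3)[:, None],
            rec.labels, rec.session, rec.cycle, rec.channels,
        )
        _, m2 = st.preprocess(rec2, train_mask, segment_length=fast_config.segment_length)
        for key in m1.stats:
            assert m1.stats[key].mean == m2.stats[key].mean
            assert m1.stats[key].sd == m2.stats[key].sd
            assert np.array_equal(m1.stats[key].quantiles, m2.stats[key].quantiles)

    def test_filter_suppresses_offsets(self, fast_config):
        """Offset-dominated input: once a segment has settled for several
        filter time constants, the filtered per-segment level is near zero
        while the raw levels differ by the full beverage offsets."""
        spec = FilterSpec(pole_hz=0.01)          # tau ~16 s << 60 s segments
        tau = 1.0 / (2 * np.pi * spec.pole_hz)
        rec = st.generate_dataset(fast_config)
        balanced = balance_cycles(rec, segment_length=fast_config.segment_length)
        filtered = np.column_stack(
            [highpass_filter(balanced.values[:, j], spec) for j in range(9)]
        )
        settle = int(3 * tau)
        breaks = np.flatnonzero(np.diff(balanced.labels) != 0) + 1
        for seg in np.split(np.arange(balanced.n_measurements), breaks):
            if len(seg) <= settle:
                continue
            tail = seg[settle:]
            for j in range(9):
                step_scale = np.ptp(fast_config.offsets[:, j])
                tol = 0.1 * step_scale + 1.5 * fast_config.noise_sd[j]
                assert abs(filtered[tail, j].mean()) < tol

    def test_model_roundtrip(self, fast_processed, tmp_path):
        _, model = fast_processed
        path = tmp_path / "pp.json"
        model.save(path)
        again = PreprocessModel.load(path)
        assert again.filter_spec.pole_hz == model.filter_spec.pole_hz
        assert set(again.stats) == set(model.stats)
        for key in model.stats:
            assert np.allclose(again.stats[key].quantiles, model.stats[key].quantiles)
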
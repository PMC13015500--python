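"""Design construction, banded ridge, lambda search, and delta_r."""

import numpy as np
import pytest
from scipy import interpolate

from fixnov import encoding as E, synth
from fixnov.encoding import (Band, LagWindow, bspline_expand, build_design,
                             fit_hierarchy, impulse_train, ridge_fit)

LW = LagWindow(-0.05, 0.1, 100.0)   # 16 lags: compact window for unit tests


class TestImpulseTrain:
    def test_sums_and_exact_times(self):
        col = impulse_train([0.5, 1.0, 2.0], duration=3.0, fs=100.0)
        assert col.sum() == 3
        assert col[100] == 1.0

    def test_round_half_even(self):
        # 1.004 s at 100 Hz -> 100.4 -> sample 100
        assert impulse_train([1.004], 2.0, 100.0)[100] == 1.0
        # exact binary .5 ties resolve to the even sample
        assert impulse_train([1.25], 3.0, 2.0)[2] == 1.0   # 2.5 -> 2
        assert impulse_train([1.75], 3.0, 2.0)[4] == 1.0   # 3.5 -> 4


    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            impulse_train([5.0], duration=2.0, fs=100.0)

    def test_nan_values_skipped(self):
        col = impulse_train([0.5, 1.0], 2.0, 100.0,
                            values=np.array([np.nan, 2.0]))
        assert col.sum() == 2.0
        assert col[50] == 0.0


class TestBsplines:
    def test_partition_of_unity_and_count(self, rng):
        vals = rng.gamma(2.0, 2.0, 300)
        basis, knots = bspline_expand(vals)
        assert basis.shape == (300, 5)
        np.testing.assert_allclose(basis.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_cox_de_boor_recursion(self, rng):
        vals = rng.random(100) * 10
        basis, knots = bspline_expand(vals)

        def cox_de_boor(x, k, d, t):
            if d == 0:
                # right-closed at the final knot so the basis sums to 1 there
                if t[k] <= x < t[k + 1] or (x == t[-1] and t[k + 1] == t[-1]
                                            and t[k] < t[k + 1]):
                    return 1.0
                return 0.0
            out = 0.0
            if t[k + d] > t[k]:
                out += (x - t[k]) / (t[k + d] - t[k]) * cox_de_boor(x, k, d - 1, t)
            if t[k + d + 1] > t[k + 1]:
                out += ((t[k + d + 1] - x) / (t[k + d + 1] - t[k + 1])
                        * cox_de_boor(x, k + 1, d - 1, t))
            return out

        for i in range(0, 100, 7):
            x = np.clip(vals[i], knots[0], knots[-1])
            for j in range(5):
                assert basis[i, j] == pytest.approx(
                    cox_de_boor(x, j, 3, knots), abs=1e-9)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            bspline_expand(np.array([1.0, 1.0, 1.0, 2.0]))


class TestBuildDesign:
    def test_scalp_window_has_81_lags(self):
        lw = LagWindow(-0.2, 0.6, 100.0)
        assert lw.n_lags == 81
        X, info = build_design(
            [Band("a", np.array([1.0]), None, "impulse")], 3.0, lw)
        assert X.shape == (300, 81)

    def test_single_pulse_reproduces_shifted_pulses(self):
        X, info = build_design(
            [Band("a", np.array([1.0]), None, "impulse")], 2.0, LW)
        lags = LW.lag_samples
        for j, s in enumerate(lags):
            expected = np.zeros(200)
            expected[100 + s] = 1.0
            np.testing.assert_array_equal(X[:, j], expected)

    def test_prediction_equals_event_summation_oracle(self, rng):
        times = np.sort(rng.uniform(0.3, 4.5, 30))
        vals = rng.standard_normal(30)
        bands = [Band("imp", times, None, "impulse"),
                 Band("lin", times, vals, "linear")]
        X, info = build_design(bands, 5.0, LW)
        w = rng.standard_normal(X.shape[1])
        pred = X @ w
        expected = np.zeros(500)
        lags = LW.lag_samples
        for b, v_per_event in (("imp", np.ones(30)), ("lin", vals)):
            sl = info.band(b).sl
            wb = w[sl]
            for t0, v in zip(times, v_per_event):
                i = int(np.rint(t0 * 100))
                for j, s in enumerate(lags):
                    if 0 <= i + s < 500:
                        expected[i + s] += v * wb[j]
        np.testing.assert_allclose(pred, expected, atol=1e-12)


class TestRidge:
    def _problem(self, rng, n=500, p_bands=3):
        times = np.sort(rng.uniform(0.2, n / 100 - 0.2, 40))
        bands = [Band("imp", times, None, "impulse")]
        for k in range(p_bands - 1):
            bands.append(Band(f"f{k}", times, rng.standard_normal(40), "linear"))
        X, info = build_design(bands, n / 100, LW)
        return X, info

    def test_equal_lambda_matches_single_penalty_oracle(self, rng):
        X, info = self._problem(rng)
        y = rng.standard_normal(X.shape[0])
        lam = 7.3
        w = ridge_fit(X, y, {b.name: lam for b in info.bands}, info)
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y)
        assert np.abs(w - oracle).max() <= 1e-8

    def test_huge_lambda_kills_band(self, rng):
        X, info = self._problem(rng)
        y = rng.standard_normal(X.shape[0])
        lam = {b.name: 1.0 for b in info.bands}
        lam["f0"] = 1e12
        w = ridge_fit(X, y, lam, info)
        assert np.linalg.norm(w[info.band("f0").sl]) < 1e-6

    def test_noiseless_recovery_small_lambda(self, rng):
        X, info = self._problem(rng)
        w_true = rng.standard_normal(X.shape[1])
        y = X @ w_true
        w = ridge_fit(X, y, {b.name: 1e-8 for b in info.bands}, info)
        assert np.abs(w - w_true).max() / np.abs(w_true).max() < 1e-4

    def test_gradient_optimality(self, rng):
        X, info = self._problem(rng)
        y = rng.standard_normal(X.shape[0])
        lam = {b.name: float(v) for b, v in zip(info.bands, [0.5, 20.0, 3.0])}
        w = ridge_fit(X, y, lam, info)
        pen = np.concatenate([np.full(b.sl.stop - b.sl.start, lam[b.name])
                              for b in info.bands])
        grad = 2 * (X.T @ (X @ w - y) + pen * w)
        assert np.linalg.norm(grad) < 1e-6 * np.linalg.norm(X.T @ y)


class TestLambdaSearch:
    def _session(self, seed=3, duration=120.0, channels=1):
        cfg = synth.SynthConfig(seed=seed, duration_s=duration,
                                n_channels=channels, n_modulated=channels)
        _, truth = synth.generate_gaze(cfg)
        feats = synth.generate_feature_table(cfg, truth)
        rec = synth.generate_neural(cfg, truth, feats, snr=1.0)
        return cfg, truth, feats, rec

    def test_single_band_matches_exhaustive_sweep(self, rng):
        cfg, truth, feats, rec = self._session()
        bands = [Band("fixation_onset", truth.events["fixation_onset"].to_numpy(),
                      None, "impulse")]
        grid = np.logspace(-2, 5, 15)
        ts = E.make_trial_slices(rec.data.shape[-1], 5)
        model, res = fit_hierarchy(bands, rec.data, cfg.lag_window, ts, grid)
        # exhaustive oracle: refit each lambda independently on two-point grids
        scores = []
        for lam in grid:
            m2, r2 = fit_hierarchy(bands, rec.data, cfg.lag_window, ts,
                                   np.array([lam]))
            scores.append(np.nanmean(r2.r_per_fold[:, :, 0]))
        assert model.lambda_per_band["fixation_onset"] == pytest.approx(
            grid[int(np.argmax(scores))])

    def test_tie_broken_to_smallest_lambda(self):
        # constructed tie: duplicate grid values give identical CV r
        cfg, truth, feats, rec = self._session()
        bands = [Band("fixation_onset", truth.events["fixation_onset"].to_numpy(),
                      None, "impulse")]
        grid = np.array([1.0, 1.0, 10.0, 10.0])
        ts = E.make_trial_slices(rec.data.shape[-1], 4)
        model, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts, grid)
        chosen = model.lambda_per_band["fixation_onset"]
        m2, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts,
                              np.array([chosen]))
        # the first occurrence (smallest index) of the best value is used
        assert chosen in (1.0, 10.0)
        grid_rev = np.array([10.0, 1.0])
        m3, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts,
                              np.array([1.0, 10.0]))
        m4, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts, grid_rev)
        # ascending grid: ties resolve to the smaller lambda
        assert m3.lambda_per_band["fixation_onset"] <= m4.lambda_per_band[
            "fixation_onset"]

    def test_duplicate_feature_adds_nothing(self):
        cfg, truth, feats, rec = self._session()
        nov = feats["novelty"].to_numpy()
        fix = truth.events["fixation_onset"].to_numpy()
        bands = [Band("fixation_onset", fix, None, "impulse"),
                 Band("novelty", fix, nov, "linear"),
                 Band("novelty_copy", fix, nov.copy(), "linear")]
        ts = E.make_trial_slices(rec.data.shape[-1], 5)
        _, res = fit_hierarchy(bands, rec.data, cfg.lag_window, ts)
        assert abs(res.delta_r_for("novelty_copy")[0]) < 5e-3
        assert res.delta_r_for("novelty")[0] > 0.01

    def test_delta_r_telescopes(self):
        cfg, truth, feats, rec = self._session(channels=2)
        bands = E.bands_from_events(
            truth.events, {c: feats[c].to_numpy() for c in feats.columns},
            [E.RegressorSpec("fixation_onset", "fixation_onset", "impulse"),
             E.RegressorSpec("amplitude", "saccade_onset", "linear"),
             E.RegressorSpec("novelty", "fixation_onset", "linear")])
        ts = E.make_trial_slices(rec.data.shape[-1], 5)
        _, res = fit_hierarchy(bands, rec.data, cfg.lag_window, ts)
        np.testing.assert_allclose(
            res.r_per_stage[:, -1],
            res.r_per_stage[:, 0] + res.delta_r.sum(axis=1), atol=1e-12)

    def test_null_feature_delta_r_near_zero(self):
        """Pure-noise response: every delta_r is statistically zero."""
        drs = []
        for s in range(12):
            cfg = synth.SynthConfig(seed=400 + s, duration_s=60.0,
                                    n_channels=1, n_modulated=0)
            _, truth = synth.generate_gaze(cfg)
            feats = synth.generate_feature_table(cfg, truth)
            rng = np.random.default_rng(500 + s)
            y = rng.standard_normal(int(60.0 * 100))
            bands = E.bands_from_events(
                truth.events, {c: feats[c].to_numpy() for c in feats.columns},
                [E.RegressorSpec("fixation_onset", "fixation_onset", "impulse"),
                 E.RegressorSpec("novelty", "fixation_onset", "linear")])
            ts = E.make_trial_slices(len(y), 5)
            _, res = fit_hierarchy(bands, y, cfg.lag_window, ts)
            drs.append(res.delta_r_for("novelty")[0])
        drs = np.asarray(drs)
        se = drs.std(ddof=1) / np.sqrt(len(drs))
        assert abs(drs.mean()) < 2 * se + 1e-4


class TestExtractTrf:
    def test_impulse_band_noiseless_recovery(self):
        cfg = synth.SynthConfig(seed=19, duration_s=200.0, n_channels=2,
                                n_modulated=2)
        _, truth = synth.generate_gaze(cfg)
        feats = synth.generate_feature_table(cfg, truth)
        rec = synth.generate_neural(cfg, truth, feats, snr=1e9)
        bands = E.bands_from_events(
            truth.events, {c: feats[c].to_numpy() for c in feats.columns},
            [E.RegressorSpec("saccade_onset", "saccade_onset", "impulse"),
             E.RegressorSpec("fixation_onset", "fixation_onset", "impulse"),
             E.RegressorSpec("amplitude", "saccade_onset", "linear"),
             E.RegressorSpec("luminance", "fixation_onset", "linear"),
             E.RegressorSpec("novelty", "fixation_onset", "linear")])
        ts = E.make_trial_slices(rec.data.shape[-1], 5)
        model, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts,
                                 np.array([1e-6]))
        fix = E.extract_trf(model, "fixation_onset")[:, 0, :]
        for c in range(2):
            r = np.corrcoef(fix[c], truth.true_trfs["fixation_onset"][c])[0, 1]
            assert r > 0.999

    def test_zero_band_recovered_small(self):
        cfg = synth.SynthConfig(seed=23, duration_s=200.0, n_channels=1,
                                n_modulated=0)
        _, truth = synth.generate_gaze(cfg)
        feats = synth.generate_feature_table(cfg, truth)
        rec = synth.generate_neural(cfg, truth, feats, snr=2.0)
        bands = E.bands_from_events(
            truth.events, {c: feats[c].to_numpy() for c in feats.columns},
            [E.RegressorSpec("fixation_onset", "fixation_onset", "impulse"),
             E.RegressorSpec("novelty", "fixation_onset", "linear")])
        ts = E.make_trial_slices(rec.data.shape[-1], 5)
        model, _ = fit_hierarchy(bands, rec.data, cfg.lag_window, ts)
        nov = E.extract_trf(model, "novelty")[0, 0]
        fix = E.extract_trf(model, "fixation_onset")[0, 0]
        assert np.linalg.norm(nov) < 0.2 * np.linalg.norm(fix)

    def test_bspline_reconstruction_shape(self, rng):
        times = np.sort(rng.uniform(0.3, 50.0, 150))
        amp = rng.gamma(2.0, 2.0, 150)
        y = rng.standard_normal(int(51.0 * 100))
        bands = [Band("fixation_onset", times, None, "impulse"),
                 Band("amplitude", times, amp, "bspline")]
        ts = E.make_trial_slices(len(y), 4)
        model, _ = fit_hierarchy(bands, y, LagWindow(-0.1, 0.3, 100.0), ts,
                                 np.array([10.0]))
        curves = E.extract_trf(model, "amplitude")
        assert curves.shape == (1, 5, 41)
        recon = E.extract_trf(model, "amplitude", at_values=np.array([2.0, 6.0]))
        assert recon.shape == (1, 2, 41)


def test_compare_alignments_fixation_locked_generator():
    cfg = synth.SynthConfig(seed=31, duration_s=240.0, n_channels=1,
                            n_modulated=1)
    _, truth = synth.generate_gaze(cfg)
    feats = synth.generate_feature_table(cfg, truth)
    rec = synth.generate_neural(cfg, truth, feats, snr=1.0)
    ts = E.make_trial_slices(rec.data.shape[-1], 5)
    out = E.compare_alignments(
        truth.events,
        {"amplitude": feats["amplitude"].to_numpy(),
         "novelty": feats["novelty"].to_numpy()},
        rec.data, cfg.lag_window, ts)
    # novelty is generated fixation-locked: its increment appears there
    assert (out["fixation_onset"].delta_r_for("novelty")[0]
            >= out["saccade_onset"].delta_r_for("novelty")[0] - 5e-3)
    assert out["fixation_onset"].delta_r_for("novelty")[0] > 0

    # degenerate case: identical alignment times -> identical results
    ev2 = truth.events.copy()
    ev2["saccade_onset"] = ev2["fixation_onset"]
    out2 = E.compare_alignments(
        ev2, {"amplitude": feats["amplitude"].to_numpy(),
              "novelty": feats["novelty"].to_numpy()},
        rec.data, cfg.lag_window, ts)
    np.testing.assert_allclose(out2["saccade_onset"].r_per_stage,
                               out2["fixation_onset"].r_per_stage, atol=1e-12)
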
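"""Patch geometry, the feature battery, embeddings, and novelty."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fixnov import features as F, synth
from fixnov.features import (Embedding, ScreenGeometry, ToyEncoder,
                             embed_patch, extract_patch, novelty,
                             spectrum_slope)

GEOM = ScreenGeometry(width_px=1920, height_px=1080, width_cm=53.0,
                      height_cm=30.0, viewing_distance_cm=60.0)


class TestGeometryAndPatch:
    def test_ppd_matches_trigonometric_oracle(self):
        expected = 2 * 60.0 * np.tan(np.deg2rad(0.5)) * (1920 / 53.0)
        assert GEOM.pixels_per_degree == pytest.approx(expected)

    def test_uniform_frame_gives_uniform_patch(self):
        frame = np.full((400, 600, 3), 0.3)
        p = extract_patch(frame, (300, 200), GEOM, out_res=50)
        assert p.valid
        np.testing.assert_allclose(p.pixels, 0.3, atol=1e-6)

    def test_centered_marker_stays_centered(self):
        side = int(round(5 * GEOM.pixels_per_degree))
        frame = np.zeros((801, 801, 3))
        frame[398:403, 398:403] = 1.0
        p = extract_patch(frame, (400, 400), GEOM, out_res=101)
        com = np.array(np.unravel_index(np.argmax(p.pixels[..., 0]),
                                        p.pixels.shape[:2]))
        assert np.all(np.abs(com - 50) <= 2)

    def test_offscreen_gaze_invalid(self):
        frame = np.zeros((100, 100, 3))
        assert not extract_patch(frame, (500, 50), GEOM).valid
        # near-corner gaze: mostly filled -> invalid
        assert not extract_patch(frame, (1, 1), GEOM).valid


class TestLuminanceColor:
    def test_white_and_black(self):
        white = F.luminance_color_features(np.ones((16, 16, 3)))
        assert white["luminance"] == pytest.approx(100.0, abs=0.01)
        assert white["a_star"] == pytest.approx(0.0, abs=0.05)
        assert white["b_star"] == pytest.approx(0.0, abs=0.05)
        black = F.luminance_color_features(np.zeros((16, 16, 3)))
        assert black["luminance"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_patch_degenerate_moments(self):
        out = F.luminance_color_features(np.full((16, 16, 3), 0.5))
        assert out["luminance_skew"] == 0.0
        assert out["luminance_kurtosis"] == 0.0


class TestContrastEnergy:
    def test_constant_patch(self):
        out = F.contrast_energy_features(np.full((32, 32, 3), 0.4))
        assert out["michelson_contrast"] == 0.0
        assert out["rms_contrast"] == pytest.approx(0.0, abs=1e-12)
        assert out["orientation_bias"] == 0.0

    def test_checkerboard_michelson_one(self):
        board = np.indices((32, 32)).sum(0) % 2
        patch = np.repeat(board[..., None].astype(float), 3, -1)
        out = F.contrast_energy_features(patch)
        assert out["michelson_contrast"] == pytest.approx(1.0, abs=1e-6)

    def test_vertical_grating_orientation(self):
        x = np.arange(64)
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * x / 8)
        patch = np.repeat(np.tile(grating, (64, 1))[..., None], 3, -1)
        out = F.contrast_energy_features(patch)
        assert out["orientation_bias"] > 0.5
        assert out["horizontal_energy"] < 0.05 * out["vertical_energy"]


class TestSpectrumSlope:
    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        est = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(50):
                g = 0.5 + 0.1 * rng.standard_normal((100, 100))
                est.append(spectrum_slope(np.repeat(np.clip(g, 0, 1)[..., None],
                                                    3, -1), ppd=20.0))
        assert abs(np.mean(est)) < 0.15

    @pytest.mark.parametrize("alpha", [1.0, 1.5])
    def test_onef_texture_recovery(self, alpha):
        rng = np.random.default_rng(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = [spectrum_slope(
                np.repeat(synth.onef_texture(100, alpha, rng)[..., None], 3, -1),
                ppd=20.0) for _ in range(15)]
        assert np.mean(est) == pytest.approx(alpha, abs=0.1)

    def test_intensity_scaling_invariance(self):
        # the log-log fit is invariant under multiplicative scaling of the
        # Fourier magnitude (an intensity-contrast rescaling of the patch)
        rng = np.random.default_rng(2)
        tex = synth.onef_texture(64, 1.0, rng, contrast=0.05, mean=0.4)
        fy = np.fft.fftfreq(64)[:, None] * 20.0
        fx = np.fft.fftfreq(64)[None, :] * 20.0
        fr = np.hypot(fy, fx)
        edges = np.geomspace(0.1, 10, 9)
        def slope_of(Fm):
            mags, cents = [], []
            for lo, hi in zip(edges[:-1], edges[1:]):
                sel = (fr >= lo) & (fr < hi)
                if sel.any():
                    mags.append(Fm[sel].mean())
                    cents.append(np.sqrt(lo * hi))
            return -np.polyfit(np.log10(cents), np.log10(mags), 1)[0]
        base = np.abs(np.fft.fft2(tex))
        assert slope_of(base) == pytest.approx(slope_of(base * 3.0), abs=1e-12)

    def test_too_small_patch_raises(self):
        with pytest.raises(ValueError):
            spectrum_slope(np.zeros((8, 8, 3)), ppd=20.0)


class TestTextureShape:
    def test_constant_patch_glcm_and_blobs(self):
        out = F.texture_shape_features(np.full((32, 32, 3), 0.5))
        assert out["glcm_contrast"] == 0.0
        assert out["glcm_homogeneity"] == pytest.approx(1.0)
        assert out["glcm_asm"] == pytest.approx(1.0)
        assert out["blob_count"] == 0.0   # strict > mean convention

    def test_single_circle_blob(self):
        yy, xx = np.mgrid[:64, :64]
        disk = (np.hypot(yy - 32, xx - 32) < 15).astype(float)
        out = F.texture_shape_features(np.repeat(disk[..., None], 3, -1))
        assert out["blob_count"] == 1.0
        assert out["blob_solidity"] > 0.95

    def test_glcm_matches_bruteforce_cooccurrence(self):
        rng = np.random.default_rng(3)
        g = rng.random((6, 6)) * 0.9
        patch = np.repeat(g[..., None], 3, -1)
        out = F.texture_shape_features(patch)
        # brute-force co-occurrence at offset 1, four directions, symmetric
        from skimage import color
        lab = color.rgb2lab(patch)[..., 0] / 100.0
        q = np.clip((lab * 32).astype(int), 0, 31)
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
        contrasts = []
        for dy, dx in offsets:
            pairs = []
            for i in range(6):
                for j in range(6):
                    i2, j2 = i + dy, j + dx
                    if 0 <= i2 < 6 and 0 <= j2 < 6:
                        pairs.append((q[i, j], q[i2, j2]))
                        pairs.append((q[i2, j2], q[i, j]))
            P = np.zeros((32, 32))
            for a, b in pairs:
                P[a, b] += 1
            P /= P.sum()
            contrasts.append(sum(P[a, b] * (a - b) ** 2
                                 for a in range(32) for b in range(32)))
        assert out["glcm_contrast"] == pytest.approx(np.mean(contrasts))


class TestSaliency:
    def test_uniform_frame_zero(self):
        out = F.saliency_features(np.full((128, 128, 3), 0.5), (64, 64))
        vals = [v for k, v in out.items() if k != "deepgaze"]
        np.testing.assert_allclose(vals, 0.0, atol=1e-9)
        assert np.isnan(out["deepgaze"])

    def test_bright_disk_intensity_positive_color_zero(self):
        yy, xx = np.mgrid[:128, :128]
        disk = (np.hypot(yy - 64, xx - 64) < 10).astype(float)
        frame = np.repeat((0.2 + 0.8 * disk)[..., None], 3, -1)
        out = F.saliency_features(frame, (64, 64))
        inten = [v for k, v in out.items() if k.startswith("sal_intensity")]
        col = [v for k, v in out.items()
               if k.startswith("sal_rg") or k.startswith("sal_by")]
        assert max(inten) > 0.01
        np.testing.assert_allclose(col, 0.0, atol=1e-9)

    def test_plugin_injection(self):
        out = F.saliency_features(np.zeros((64, 64, 3)), (10, 10),
                                  deepgaze=lambda f, g: 0.42)
        assert out["deepgaze"] == 0.42


class TestOpticalFlow:
    def test_still_images_zero(self):
        assert F.optical_flow_feature(None, None, (0, 10, 0, 10), 1.0) == 0.0

    def test_global_translation_magnitude(self):
        flow = np.zeros((10, 20, 20, 2))
        flow[..., 0] = 2.0        # 2 px/frame everywhere
        times = np.arange(10) / 10.0
        got = F.optical_flow_feature(flow, times, (0, 200, 0, 200), 0.9)
        assert got == pytest.approx(2.0)

    def test_window_straddling_motion_onset(self):
        # 5 frames at 0.0..0.4 s; motion starts at frame 3
        flow = np.zeros((5, 4, 4, 2))
        flow[3:, ..., 1] = 1.0
        times = np.arange(5) * 0.1
        # saccade at 0.55 -> window [0.30, 0.50] covers frames 3 and 4
        got = F.optical_flow_feature(flow, times, (0, 40, 0, 40), 0.55)
        assert got == pytest.approx(1.0)
        # saccade at 0.45 -> window [0.20, 0.40] covers frames 2, 3, 4
        got2 = F.optical_flow_feature(flow, times, (0, 40, 0, 40), 0.45)
        assert got2 == pytest.approx(2.0 / 3.0)

    def test_window_before_recording_missing(self):
        flow = np.zeros((3, 4, 4, 2))
        times = np.array([1.0, 1.1, 1.2])
        assert np.isnan(F.optical_flow_feature(flow, times, (0, 4, 0, 4), 0.5))


class TestEmbeddingNovelty:
    def test_deterministic_and_layout_invariant(self):
        rng = np.random.default_rng(4)
        patch = rng.random((100, 100, 3))
        e1 = embed_patch(patch)
        e2 = embed_patch(np.asfortranarray(patch))
        np.testing.assert_array_equal(e1.vector, e2.vector)
        assert novelty(e1, e2) == 0.0

    def test_resized_ramp_stays_ramp(self):
        ramp = np.tile(np.linspace(0, 1, 100), (100, 1))
        from skimage.transform import resize
        big = resize(np.repeat(ramp[..., None], 3, -1), (224, 224), order=3)
        rows = big[..., 0].mean(axis=0)
        fit = np.polyfit(np.arange(224), rows, 1)
        resid = rows - np.polyval(fit, np.arange(224))
        assert np.abs(resid).max() < 0.02

    def test_analytic_novelty_values(self):
        a = Embedding(np.array([1.0, 0.0]), "x")
        b = Embedding(np.array([0.0, 2.0]), "x")
        assert novelty(a, a) == 0.0
        assert novelty(a, b) == 1.0
        assert novelty(a, Embedding(np.array([-3.0, 0.0]), "x")) == 2.0

    def test_novelty_errors_and_invariances(self):
        a = Embedding(np.array([1.0, 1.0]), "x")
        with pytest.raises(ValueError):
            novelty(a, Embedding(np.zeros(2), "x"))
        with pytest.raises(ValueError):
            novelty(a, Embedding(np.ones(3), "x"))
        with pytest.raises(ValueError):
            novelty(a, Embedding(np.ones(2), "y"))
        b = Embedding(np.array([0.3, -0.8]), "x")
        assert novelty(a, b) == pytest.approx(novelty(b, a))
        scaled = Embedding(7.3 * b.vector, "x")
        assert novelty(a, scaled) == pytest.approx(novelty(a, b))

    def test_redraw_pairs_more_novel_than_duplicates(self):
        cfg = synth.SynthConfig(seed=5)
        pairs, dup = synth.generate_patch_pair_sequence(cfg, n_pairs=60)
        enc = ToyEncoder()
        nov = np.array([novelty(embed_patch(a, enc), embed_patch(b, enc))
                        for a, b in pairs])
        assert nov[~dup].mean() > nov[dup].mean()
        assert (nov[~dup][:, None] > nov[dup][None, :]).mean() >= 0.95


class TestCorrelationClustering:
    def test_duplicated_column_adjacent(self, rng):
        df = pd.DataFrame(rng.standard_normal((200, 4)),
                          columns=list("abcd"))
        df["a2"] = df["a"]
        corr, order, link = F.feature_correlation_clustering(df)
        cols = list(corr.columns)
        assert abs(cols.index("a") - cols.index("a2")) == 1
        assert corr.loc["a", "a2"] == pytest.approx(1.0)

    def test_independent_columns_low_offdiag(self, rng):
        df = pd.DataFrame(rng.standard_normal((5000, 6)))
        df.columns = [f"f{i}" for i in range(6)]
        corr, _, _ = F.feature_correlation_clustering(df)
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_planted_blocks_contiguous(self, rng):
        n = 500
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = z1 + 0.3 * rng.standard_normal(n)
        for i in range(3):
            cols[f"b{i}"] = z2 + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame(cols).sample(frac=1, axis=1,
                                       random_state=1)  # shuffle columns
        corr, order, _ = F.feature_correlation_clustering(df)
        names = list(corr.columns)
        ai = sorted(names.index(f"a{i}") for i in range(3))
        bi = sorted(names.index(f"b{i}") for i in range(3))
        assert ai[-1] - ai[0] == 2 and bi[-1] - bi[0] == 2

    def test_zero_variance_column_excluded(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        df["const"] = 1.0
        with pytest.warns(UserWarning):
            corr, _, _ = F.feature_correlation_clustering(df)
        assert "const" not in corr.columns


def test_feature_extractors_are_pure(rng):
    patch = rng.random((64, 64, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = F.patch_feature_battery(patch, ppd=20.0)
        f2 = F.patch_feature_battery(patch.copy(), ppd=20.0)
    assert f1 == f2
    assert len(f1) == 7 + 9 + 1 + 12
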
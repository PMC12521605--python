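"""Color-appearance-model brightness predictions."""

import numpy as np
import pytest

from chromaglare.cam import (
    CamSettings,
    CamStimulus,
    M_CAM15U,
    cam15u_brightness,
    cam16_hellwig_brightness,
    cam18sl_brightness,
    compare_conditions,
    hk_hue_dependency,
    normalize_to_luminance,
)
from chromaglare.colorimetry import ColorSummary


def _stim(X, Y, Z):
    t = X + Y + Z
    return CamStimulus.from_color(ColorSummary(X, Y, Z, X / t, Y / t, Y))


class TestNormalize:
    def test_halves_components_and_preserves_ratios(self, sun_stimuli):
        s = _stim(1200.0, 2000.0, 900.0)
        n = normalize_to_luminance(s, 1000.0)
        assert n.L == pytest.approx(1000.0, rel=1e-12)
        np.testing.assert_allclose(n.color.xyz, s.color.xyz / 2.0, rtol=1e-12)
        np.testing.assert_allclose(n.cone.lms / np.linalg.norm(n.cone.lms),
                                   s.cone.lms / np.linalg.norm(s.cone.lms),
                                   rtol=1e-12)
        assert n.color.x == pytest.approx(s.color.x, abs=1e-12)
        assert n.color.y == pytest.approx(s.color.y, abs=1e-12)

    def test_nonpositive_luminance_rejected(self):
        s = _stim(0.0, 1e-300, 0.0)
        with pytest.raises(ValueError):
            normalize_to_luminance(_stim(1.0, 1.0, 1.0), 0.0)


class TestCam15u:
    def test_matches_independent_equation_transcription(self, sun_stimuli):
        """Literal re-evaluation of the model equations, separate code path."""
        for s in sun_stimuli.values():
            rho, gam, bet = np.clip(M_CAM15U @ s.color.xyz, 0, None) ** (1 / 3)
            A = 3.22 * (2 * rho + gam + bet / 20)
            a = rho - 12 * gam / 11 + bet / 11
            b = 0.117 * (rho + gam - 2 * bet)
            M = 135.52 * np.hypot(a, b)
            Q = A + 2.559 * M ** 0.561
            p = cam15u_brightness(s)
            assert p.Q == pytest.approx(Q, rel=1e-12)
            assert p.M == pytest.approx(M, rel=1e-12)

    def test_brightness_increases_with_luminance(self, sun_stimuli):
        s = sun_stimuli["neutral"]
        q1 = cam15u_brightness(normalize_to_luminance(s, 500.0)).Q
        q2 = cam15u_brightness(normalize_to_luminance(s, 1000.0)).Q
        assert q2 > q1

    def test_saturated_stimuli_brighter_than_neutral_at_equal_luminance(
            self, sun_stimuli):
        q = {c: cam15u_brightness(s).Q for c, s in sun_stimuli.items()}
        assert min(q["red"], q["blue"]) > q["neutral"]

    def test_validity_flag(self, sun_stimuli):
        hot = normalize_to_luminance(sun_stimuli["neutral"], 5e4)
        assert not cam15u_brightness(hot).valid


class TestCam18sl:
    def test_matches_independent_equation_transcription(self, sun_stimuli):
        Lb = 200.0
        sig = 291.20 + 71.8 * Lb ** 0.78
        for s in sun_stimuli.values():
            lms = np.clip(M_CAM15U @ s.color.xyz, 0, None)
            comp = lms ** 0.58 / (lms ** 0.58 + sig ** 0.58)
            rho, gam, bet = comp
            A = 0.937e3 * (2 * rho + gam + bet / 20) / 3.05
            a = rho - 12 * gam / 11 + bet / 11
            b = 0.117 * (rho + gam - 2 * bet)
            M = 3260.0 * np.hypot(a, b)
            p = cam18sl_brightness(s, Lb)
            assert p.Q == pytest.approx(A + 2.559 * M ** 0.561, rel=1e-12)
            assert p.M == pytest.approx(M, rel=1e-12)

    def test_stimulus_matching_gray_background_is_near_achromatic(self):
        # equal-energy stimulus on the model's own gray background
        s = _stim(100.0, 100.0, 100.0)
        p = cam18sl_brightness(s, background_L=100.0)
        assert p.M < 0.03 * p.Q

    def test_above_1e4_flagged_out_of_validity(self, sun_stimuli):
        hot = normalize_to_luminance(sun_stimuli["neutral"], 5e4)
        assert not cam18sl_brightness(hot, 200.0).valid
        assert cam18sl_brightness(
            normalize_to_luminance(sun_stimuli["neutral"], 1000.0), 200.0).valid

    def test_brighter_background_dims_the_stimulus(self, sun_stimuli):
        s = sun_stimuli["neutral"]
        assert cam18sl_brightness(s, 400.0).Q < cam18sl_brightness(s, 100.0).Q


class TestCam16Hellwig:
    def test_white_point_stimulus_is_achromatic_with_no_hk_shift(
            self, sun_stimuli, cam_settings):
        p = cam16_hellwig_brightness(sun_stimuli["neutral"], cam_settings)
        assert p.M == pytest.approx(0.0, abs=1e-9)
        assert p.Q == pytest.approx(p.Q_no_hk, rel=1e-9)

    def test_hk_term_widens_equal_luminance_brightness_spread(
            self, sun_stimuli, cam_settings):
        with_hk, without = [], []
        for s in sun_stimuli.values():
            p = cam16_hellwig_brightness(s, cam_settings)
            with_hk.append(p.Q)
            without.append(p.Q_no_hk)
        assert np.ptp(without) < np.ptp(with_hk)

    def test_hue_dependency_strongest_for_blue_weakest_for_yellow(self):
        assert hk_hue_dependency(270.0) > hk_hue_dependency(0.0) > \
            hk_hue_dependency(90.0)

    def test_chromatic_stimulus_against_independent_transcription(self, cam_settings):
        """Step-by-step re-evaluation of the forward model, separate path."""
        s = _stim(700.0, 1000.0, 1800.0)
        M16 = np.array([[0.401288, 0.650173, -0.051461],
                        [-0.250268, 1.204414, 0.045854],
                        [-0.002079, 0.048952, 0.953127]])
        F, c, N_c = 1.0, 0.69, 1.0
        Yw = cam_settings.white_point.L
        xyz = s.color.xyz / Yw * 100
        xyzw = cam_settings.white_point.xyz / Yw * 100
        rgbw = M16 @ xyzw
        drgb = 100.0 / rgbw       # D = 1
        LA = 200.0
        k = 1 / (5 * LA + 1)
        FL = 0.2 * k ** 4 * 5 * LA + 0.1 * (1 - k ** 4) ** 2 * (5 * LA) ** (1 / 3)
        Nbb = 0.725 * 0.2 ** -0.2

        def comp(rgb):
            t = (FL * np.abs(rgb) / 100) ** 0.42
            return np.sign(rgb) * 400 * t / (t + 27.13) + 0.1

        ra_w = comp(drgb * rgbw)
        Aw = (2 * ra_w[0] + ra_w[1] + 0.05 * ra_w[2] - 0.305) * Nbb
        ra = comp(drgb * (M16 @ xyz))
        a = ra[0] - 12 * ra[1] / 11 + ra[2] / 11
        b = (ra[0] + ra[1] - 2 * ra[2]) / 9
        h = np.degrees(np.arctan2(b, a)) % 360
        et = 0.25 * (np.cos(np.radians(h) + 2) + 3.8)
        A = (2 * ra[0] + ra[1] + 0.05 * ra[2] - 0.305) * Nbb
        J = 100 * (A / Aw) ** (c * (1.48 + np.sqrt(0.2)))
        M = 43 * N_c * et * np.hypot(a, b)
        C = 35 * M / Aw
        Jhk = J + hk_hue_dependency(h) * C ** 0.587
        Q = (2 / c) * (Jhk / 100) * Aw
        p = cam16_hellwig_brightness(s, cam_settings)
        assert p.Q == pytest.approx(Q, rel=1e-12)
        assert p.M == pytest.approx(M, rel=1e-12)
        assert p.hue_deg == pytest.approx(h, abs=1e-9)


class TestCompareConditions:
    def test_neutral_row_is_unity_for_every_model(self, sun_stimuli, cam_settings):
        df = compare_conditions(sun_stimuli, cam_settings)
        neutral = df[df.color == "neutral"]
        assert np.allclose(neutral["Q_normalized"], 1.0)
        assert len(df) == 12

    def test_hk_models_rank_saturated_red_blue_above_green_neutral(
            self, sun_stimuli, cam_settings):
        df = compare_conditions(sun_stimuli, cam_settings)
        for model in ("CAM18sl", "CAM16-Hellwig"):
            q = df[df.model == model].set_index("color")["Q_normalized"]
            assert min(q["red"], q["blue"]) > max(q["green"], q["neutral"])

    def test_conclusions_robust_to_background_luminance(self, sun_stimuli):
        for bg in (100.0, 200.0, 400.0):
            settings = CamSettings(white_point=sun_stimuli["neutral"].color,
                                   background_luminance=bg)
            df = compare_conditions(sun_stimuli, settings)
            for model in ("CAM18sl", "CAM16-Hellwig"):
                q = df[df.model == model].set_index("color")["Q_normalized"]
                assert min(q["red"], q["blue"]) > max(q["green"], q["neutral"])

    def test_missing_color_rejected(self, sun_stimuli, cam_settings):
        partial = {k: v for k, v in sun_stimuli.items() if k != "red"}
        with pytest.raises(ValueError, match="red"):
            compare_conditions(partial, cam_settings)


def test_hk_property_brightness_grows_with_colorfulness_within_hue(sun_stimuli,
                                                                   cam_settings):
    """Desaturating a stimulus toward the white point at fixed luminance
    lowers colorfulness and, with it, predicted brightness (the H-K term)."""
    white = sun_stimuli["neutral"].color
    for color in ("red", "blue", "green"):
        s = sun_stimuli[color].color
        qs, ms, hk16 = [], [], []
        for w in (0.0, 0.4, 0.8):
            xyz = (1 - w) * s.xyz + w * white.xyz
            t = xyz.sum()
            mixed = CamStimulus.from_color(
                ColorSummary(*xyz, xyz[0] / t, xyz[1] / t, xyz[1]))
            mixed = normalize_to_luminance(mixed, 1000.0)
            for fn in (lambda st: cam18sl_brightness(st, 200.0),
                       lambda st: cam16_hellwig_brightness(st, cam_settings)):
                p = fn(mixed)
                qs.append(p.Q)
                ms.append(p.M)
                if p.Q_no_hk is not None:
                    hk16.append(p.Q - p.Q_no_hk)
        q18, m18 = qs[0::2], ms[0::2]
        assert np.all(np.diff(q18) < 0) and np.all(np.diff(m18) < 0)
        # CAM16: the H-K increment Q − Q_no_hk tracks colorfulness (the base
        # brightness J also shifts slightly with the mixture, so Q itself need
        # not be monotone for every hue)
        assert np.all(np.diff(hk16) < 0) and np.all(np.diff(ms[1::2]) < 0)
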
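"""Color-appearance-model brightness predictions for the colored sun.

Luminance-based glare metrics assume brightness additivity, which fails for
saturated stimuli (the Helmholtz-Kohlrausch effect: at equal luminance, more
colorful looks brighter). This module implements the comparison procedure
that probes that failure: scale each colored-sun stimulus to a common
luminance of 1000 cd/m² — inside every model's well-behaved range, leaving
chromaticity (cone-response ratios) untouched — and predict its brightness Q
and colorfulness M with three models that include a chromatic contribution
to brightness:

* **CAM15u** — unrelated self-luminous stimuli seen in darkness; power-law
  cone compression, no chromatic adaptation, brightness
  Q = A + 2.559·M^0.561.
* **CAM18sl** — self-luminous stimuli on a gray background of variable
  luminance; Michaelis-Menten cone compression whose semisaturation tracks
  the background, same brightness structure.
* **CAM16 with the Hellwig H-K extension** — the general-purpose appearance
  model with chromatic adaptation to a reference white, extended with a
  hue- and chroma-driven Helmholtz-Kohlrausch term on lightness/brightness
  (J_HK = J + f(h)·C^0.587).

Model equations and fitted constants are transcribed from the models'
publications. Stimuli outside a model's stated luminance validity are
flagged, never clipped: the Michaelis-Menten saturation of CAM18sl/CAM16 at
sun-like luminances is a mathematical artifact, which is exactly why the
comparison normalizes to 1000 cd/m² first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colorimetry import ColorSummary, ConeResponse, xyz_to_cone

__all__ = [
    "CamStimulus",
    "CamSettings",
    "BrightnessPrediction",
    "normalize_to_luminance",
    "cam15u_brightness",
    "cam18sl_brightness",
    "cam16_hellwig_brightness",
    "compare_conditions",
    "hk_hue_dependency",
]


@dataclass(frozen=True)
class CamStimulus:
    """One stimulus as absolute tristimulus plus cone excitations."""

    color: ColorSummary
    cone: ConeResponse

    @classmethod
    def from_color(cls, color: ColorSummary,
                   matrix_choice: str = "cat16") -> "CamStimulus":
        return cls(color, xyz_to_cone(color, matrix_choice))

    @property
    def L(self) -> float:
        return self.color.L


@dataclass(frozen=True)
class CamSettings:
    """Viewing-condition inputs of the appearance models.

    ``white_point`` is the adaptation reference for CAM16 (here: the sun seen
    through the neutral glazing at 1000 cd/m²). ``background_luminance`` is
    the gray-world background (cd/m²) used by CAM18sl. Surround and degree
    of chromatic adaptation D follow the comparison procedure's defaults
    ("average", D = 1).
    """

    white_point: ColorSummary
    background_luminance: float = 200.0
    surround: str = "average"
    degree_of_adaptation: float = 1.0
    adapting_luminance: float | None = None   # L_A; background luminance if None

    def __post_init__(self):
        if self.white_point.L <= 0:
            raise ValueError("white point must have positive luminance")
        if self.surround not in _SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")
        if not (0.0 <= self.degree_of_adaptation <= 1.0):
            raise ValueError("degree of adaptation must lie in [0, 1]")


@dataclass(frozen=True)
class BrightnessPrediction:
    """Brightness Q and colorfulness M of one stimulus under one model."""

    model: str
    Q: float
    M: float
    valid: bool                     # inside the model's luminance validity
    Q_normalized: float | None = None
    hue_deg: float | None = None
    Q_no_hk: float | None = None    # CAM16 only: brightness with the H-K term off


def normalize_to_luminance(stim: CamStimulus, L_target: float = 1000.0) -> CamStimulus:
    """Scale a stimulus to a target luminance, preserving chromaticity.

    All tristimulus and cone components are multiplied by L_target/L, so
    cone-response ratios (and x, y) are untouched.
    """
    if stim.L <= 0:
        raise ValueError("stimulus luminance must be positive")
    if L_target <= 0:
        raise ValueError("target luminance must be positive")
    k = L_target / stim.L
    return CamStimulus(stim.color.scaled(k),
                       ConeResponse(*(stim.cone.lms * k)))


# --------------------------------------------------------------------------
# CAM15u / CAM18sl: shared cone front end
# --------------------------------------------------------------------------

#: XYZ → (ρ, γ, β) cone transform of the CAM15u/CAM18sl family (rows sum to
#: ≈0.985, so an equal-energy stimulus maps to near-equal cone signals).
M_CAM15U = np.array([[0.211831, 0.815789, -0.042472],
                     [-0.492493, 1.378921, 0.098745],
                     [0.0, 0.0, 0.985188]])

_CAM15U_VALID_L = (0.0, 2.0e4)
_CAM18SL_VALID_L = (0.0, 1.0e4)
_CAM16_VALID_L = (0.0, 1.0e6)


def _opponent(rc: float, gc: float, bc: float) -> tuple[float, float]:
    """Red-green and yellow-blue opponent signals from compressed cones."""
    a = rc - 12.0 * gc / 11.0 + bc / 11.0
    b = 0.117 * (rc + gc - 2.0 * bc)
    return a, b


def cam15u_brightness(stim: CamStimulus) -> BrightnessPrediction:
    """CAM15u brightness/colorfulness of an unrelated self-luminous stimulus.

    Cube-root compressed cone signals feed an achromatic channel
    A = 3.22·(2ρ' + γ' + β'/20) and opponent channels; colorfulness
    M = 135.52·√(a² + b²) and brightness Q = A + 2.559·M^0.561. The model has
    no background or adaptation input: its achromatic point is fixed, the
    property the comparison exposes.
    """
    rho, gam, bet = np.clip(M_CAM15U @ stim.color.xyz, 0.0, None)
    rc, gc, bc = rho ** (1.0 / 3.0), gam ** (1.0 / 3.0), bet ** (1.0 / 3.0)
    A = 3.22 * (2.0 * rc + gc + bc / 20.0)
    a, b = _opponent(rc, gc, bc)
    M = 135.52 * float(np.hypot(a, b))
    Q = A + 2.559 * M ** 0.561
    valid = _CAM15U_VALID_L[0] < stim.L <= _CAM15U_VALID_L[1]
    return BrightnessPrediction("CAM15u", float(Q), M, valid,
                                hue_deg=float(np.degrees(np.arctan2(b, a)) % 360.0))


def cam18sl_brightness(stim: CamStimulus, background_L: float = 200.0
                       ) -> BrightnessPrediction:
    """CAM18sl brightness/colorfulness on a gray background.

    Cone signals are compressed by a Michaelis-Menten stage
    ρ' = ρ^0.58/(ρ^0.58 + σ^0.58) whose semisaturation
    σ = 291.20 + 71.8·L_bg^0.78 tracks the background luminance, so the model
    darkens and desaturates stimuli as the background brightens. Outputs
    follow the same achromatic + colorfulness structure as CAM15u with the
    model's own scaling (A normalized to [0, 1] and rescaled by 937;
    M = 3260·√(a² + b²)). The Michaelis-Menten stage saturates for stimuli
    around 10⁴ cd/m²; such inputs are flagged as outside validity.
    """
    if background_L < 0:
        raise ValueError("background luminance must be nonnegative")
    sig = 291.20 + 71.8 * background_L ** 0.78
    rho, gam, bet = np.clip(M_CAM15U @ stim.color.xyz, 0.0, None)

    def mm(v):
        t = v ** 0.58
        return t / (t + sig ** 0.58)

    rc, gc, bc = mm(rho), mm(gam), mm(bet)
    A = 0.937e3 * (2.0 * rc + gc + bc / 20.0) / 3.05
    a, b = _opponent(rc, gc, bc)
    M = 3260.0 * float(np.hypot(a, b))
    Q = A + 2.559 * M ** 0.561
    valid = _CAM18SL_VALID_L[0] < stim.L <= _CAM18SL_VALID_L[1]
    return BrightnessPrediction("CAM18sl", float(Q), M, valid,
                                hue_deg=float(np.degrees(np.arctan2(b, a)) % 360.0))


# --------------------------------------------------------------------------
# CAM16 + Hellwig H-K extension
# --------------------------------------------------------------------------

#: CAT16 sharpened cone transform of CAM16.
M_CAT16 = np.array([[0.401288, 0.650173, -0.051461],
                    [-0.250268, 1.204414, 0.045854],
                    [-0.002079, 0.048952, 0.953127]])

_SURROUNDS = {"average": (1.0, 0.69, 1.0),
              "dim": (0.9, 0.59, 0.9),
              "dark": (0.8, 0.525, 0.8)}


def hk_hue_dependency(hue_deg: float) -> float:
    """Hue weighting of the Helmholtz-Kohlrausch brightness term.

    Largest around blue/purple hues, smallest around yellow — the classic
    hue dependence of the H-K effect.
    """
    h = np.radians(hue_deg)
    return float(-0.160 * np.cos(h) + 0.132 * np.cos(2 * h)
                 - 0.405 * np.sin(h) + 0.080 * np.sin(2 * h) + 0.792)


def _cam16_compress(rgb: np.ndarray, F_L: float) -> np.ndarray:
    t = (F_L * np.abs(rgb) / 100.0) ** 0.42
    return np.sign(rgb) * 400.0 * t / (t + 27.13) + 0.1


def cam16_hellwig_brightness(stim: CamStimulus, settings: CamSettings,
                             include_hk: bool = True) -> BrightnessPrediction:
    """CAM16 brightness with the Hellwig Helmholtz-Kohlrausch extension.

    Standard CAM16 front end (CAT16 adaptation toward the settings' white
    point with degree D, luminance-level adaptation F_L, post-adaptation
    compression), followed by the revised brightness Q = (2/c)·(J/100)·A_w
    and colorfulness M = 43·N_c·e_t·√(a² + b²), and the H-K term
    J_HK = J + f(h)·C^0.587 with the hue weighting of
    :func:`hk_hue_dependency` and C = 35·M/A_w. ``include_hk=False`` returns
    the unextended brightness, under which equal-luminance stimuli of
    different hue collapse toward a common value.
    """
    F, c, N_c = _SURROUNDS[settings.surround]
    Y_w = settings.white_point.L
    L_A = settings.adapting_luminance
    if L_A is None:
        L_A = settings.background_luminance
    if L_A <= 0:
        raise ValueError("adapting luminance must be positive")
    # relative colorimetry: white scaled to Y = 100
    xyz = stim.color.xyz / Y_w * 100.0
    xyz_w = settings.white_point.xyz / Y_w * 100.0

    rgb_w = M_CAT16 @ xyz_w
    D = settings.degree_of_adaptation
    d_rgb = D * 100.0 / rgb_w + 1.0 - D
    k = 1.0 / (5.0 * L_A + 1.0)
    F_L = 0.2 * k ** 4 * 5.0 * L_A + 0.1 * (1 - k ** 4) ** 2 * (5.0 * L_A) ** (1.0 / 3.0)
    n = 0.2                      # background of 20% of the reference white
    z = 1.48 + np.sqrt(n)
    N_bb = 0.725 * n ** -0.2

    rgb_aw = _cam16_compress(d_rgb * rgb_w, F_L)
    A_w = (2.0 * rgb_aw[0] + rgb_aw[1] + 0.05 * rgb_aw[2] - 0.305) * N_bb

    rgb_a = _cam16_compress(d_rgb * (M_CAT16 @ xyz), F_L)
    a = rgb_a[0] - 12.0 * rgb_a[1] / 11.0 + rgb_a[2] / 11.0
    b = (rgb_a[0] + rgb_a[1] - 2.0 * rgb_a[2]) / 9.0
    h = float(np.degrees(np.arctan2(b, a)) % 360.0)
    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    A = (2.0 * rgb_a[0] + rgb_a[1] + 0.05 * rgb_a[2] - 0.305) * N_bb
    J = 100.0 * np.sign(A) * (np.abs(A) / A_w) ** (c * z)
    M = 43.0 * N_c * e_t * float(np.hypot(a, b))
    C = 35.0 * M / A_w
    J_hk = J + hk_hue_dependency(h) * C ** 0.587 if include_hk else J
    Q = (2.0 / c) * (J_hk / 100.0) * A_w
    Q_plain = (2.0 / c) * (J / 100.0) * A_w
    valid = _CAM16_VALID_L[0] < stim.L <= _CAM16_VALID_L[1]
    return BrightnessPrediction("CAM16-Hellwig", float(Q), float(M), valid,
                                hue_deg=h, Q_no_hk=float(Q_plain))


# --------------------------------------------------------------------------
# The comparison procedure
# --------------------------------------------------------------------------

_MODELS = ("CAM15u", "CAM18sl", "CAM16-Hellwig")


def compare_conditions(stimuli: dict[str, CamStimulus], settings: CamSettings,
                       L_target: float = 1000.0,
                       reference_color: str = "neutral") -> pd.DataFrame:
    """Per-model brightness of the four colored-sun stimuli at equal luminance.

    Each stimulus is normalized to ``L_target`` (default 1000 cd/m²), run
    through the three models, and its brightness divided by the
    reference (neutral-glazing) brightness of the same model, so the neutral
    bar is 1 by construction. Returns a tidy frame with one row per
    model × color: Q, M, Q_normalized, valid.
    """
    required = {"red", "green", "blue", "neutral"}
    missing = required - set(stimuli)
    if missing:
        raise ValueError(f"missing stimuli for colors: {sorted(missing)}")

    rows = []
    for color, stim in stimuli.items():
        s = normalize_to_luminance(stim, L_target)
        preds = (cam15u_brightness(s),
                 cam18sl_brightness(s, settings.background_luminance),
                 cam16_hellwig_brightness(s, settings))
        for p in preds:
            rows.append({"model": p.model, "color": color, "Q": p.Q, "M": p.M,
                         "valid": p.valid, "hue_deg": p.hue_deg})
    df = pd.DataFrame(rows)
    ref = df[df.color == reference_color].set_index("model")["Q"]
    df["Q_normalized"] = df.apply(lambda r: r.Q / ref[r.model], axis=1)
    return df.sort_values(["model", "color"]).reset_index(drop=True)
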
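"""Synthetic stimuli for the colored-sun glare experiment.

The study exposes a seated observer to the sun disc seen through a colored
windowpane (the "sun window") while the remaining panes stay color-neutral.
This module synthesizes those stimuli: parametric glazing transmittance
curves scaled to a prescribed photopic transmittance τ_v, sun-through-glazing
spectra, and fisheye luminance maps with a rendered sun disc, a window band
and a background, calibrated so the vertical eye illuminance E_v matches a
target.

Geometry follows the measurement setup: an equidistant fisheye projection
(r ∝ θ) with a 160° field of view, view axis toward the façade.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorimetry import (
    STANDARD_GRID,
    ChromaticityUndefinedError,
    ColorSummary,
    SpectralDistribution,
    load_cmfs,
    planckian_spd,
    spd_to_color,
)

__all__ = [
    "GlazingSpec",
    "SunModel",
    "SceneCondition",
    "LuminanceMap",
    "make_glazing",
    "transmit",
    "disc_solid_angle",
    "build_scene",
    "sun_stimulus_color",
    "visible_transmittance",
    "GLAZING_SHAPES",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Parametric passband shapes emulating the measured glazing curves: narrow
#: bands in distinct parts of the visible spectrum plus a flat neutral.
#: (kind, params) — params are config-exposed, not measurements.
GLAZING_SHAPES = {
    "blue": ("gaussian", {"center_nm": 450.0, "sigma_nm": 30.0}),
    "green": ("gaussian", {"center_nm": 530.0, "sigma_nm": 30.0}),
    "red": ("longpass", {"cuton_nm": 600.0, "width_nm": 15.0}),
    "neutral": ("flat", {}),
}

GLAZING_COLORS = ("red", "green", "blue", "neutral")


@functools.lru_cache(maxsize=1)
def _d65() -> SpectralDistribution:
    arr = np.genfromtxt(_DATA_DIR / "d65_5nm.csv", delimiter=",", names=True)
    return SpectralDistribution(arr["wavelength_nm"], arr["value"], "relative")


def _reference_illuminant(name: str) -> SpectralDistribution:
    if name == "d65":
        return _d65()
    if name == "ee":
        return SpectralDistribution(STANDARD_GRID, np.ones(STANDARD_GRID.size), "relative")
    raise ValueError(f"unknown reference illuminant {name!r}")


@dataclass(frozen=True)
class GlazingSpec:
    """A glazing's spectral transmittance and its photopic transmittance τ_v."""

    color_name: str
    tau_curve: SpectralDistribution  # values in [0, 1]
    tau_v: float

    def __post_init__(self):
        if np.any(self.tau_curve.values > 1.0 + 1e-12):
            raise ValueError("transmittance must not exceed 1")
        if not (0.0 <= self.tau_v <= 1.0):
            raise ValueError("tau_v must lie in [0, 1]")

    def to_csv(self, path) -> None:
        self.tau_curve.to_csv(path)


@dataclass(frozen=True)
class SunModel:
    """Solar stimulus: relative source spectrum plus angular sizes.

    ``disc_diameter_deg`` is the apparent sun disc (0.533°);
    ``measure_aperture_deg`` the 1° aperture of the spectroradiometer that
    measured the sun's spectrum in the experiment.
    """

    source_spd: SpectralDistribution = field(
        default_factory=lambda: planckian_spd(5778.0))
    disc_diameter_deg: float = 0.533
    measure_aperture_deg: float = 1.0

    def __post_init__(self):
        if self.disc_diameter_deg <= 0:
            raise ValueError("disc diameter must be positive")
        if self.measure_aperture_deg < self.disc_diameter_deg:
            raise ValueError("measurement aperture must cover the sun disc")


@dataclass(frozen=True)
class SceneCondition:
    """One experimental condition's photometric targets.

    ``sigma_deg`` is the angular distance of the sun from the line of sight,
    ``tau_deg`` the angle from vertical of the plane containing source and
    sightline (the two Guth angles).
    """

    color: str
    level: str                      # "low" | "high" transmittance group
    sun_luminance: float            # cd/m^2
    sigma_deg: float
    tau_deg: float
    ev_target: float                # lux
    background_luminance: float = 100.0

    def __post_init__(self):
        if self.sun_luminance < 0:
            raise ValueError("sun luminance must be nonnegative")
        if not (0.0 <= self.sigma_deg < 80.0):
            raise ValueError("sun must lie inside the 160 deg field of view")
        if self.ev_target <= 0:
            raise ValueError("ev_target must be positive")


class LuminanceMap:
    """Per-direction luminance over an equidistant fisheye projection.

    A square grid of luminances (cd/m²) with analytic per-pixel direction
    vectors and solid angles. For the equidistant mapping θ = k·r the solid
    angle of a unit pixel at radius r is k²·sin θ/θ (k² on axis), which sums
    to the spherical cap of the field of view to within the pixelization of
    the rim.

    ``regions`` carries per-region metadata (boolean mask and chromaticity of
    the transmitted spectrum) attached by :func:`build_scene`.
    """

    def __init__(self, values: np.ndarray, fov_deg: float = 160.0,
                 regions: dict | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("luminance map must be a square 2-D grid")
        if np.any(values < 0):
            raise ValueError("luminances must be nonnegative")
        if not (0 < fov_deg <= 180):
            raise ValueError("field of view must be in (0, 180] degrees")
        self.values = values
        self.fov_deg = float(fov_deg)
        self.regions = regions or {}
        n = values.shape[0]
        c = (n - 1) / 2.0
        radius_px = n / 2.0
        self._k = np.radians(self.fov_deg / 2.0) / radius_px  # rad per pixel
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        dx = jj - c          # image right
        dy = c - ii          # image up
        r = np.hypot(dx, dy)
        theta = self._k * r
        self.inside = theta <= np.radians(self.fov_deg / 2.0) + 1e-12
        self.theta = theta
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(theta > 0, np.sin(theta) / np.where(theta > 0, theta, 1.0), 1.0)
        self.omega = np.where(self.inside, self._k ** 2 * sinc, 0.0)
        with np.errstate(invalid="ignore"):
            er = np.where(r > 0, dx / np.where(r > 0, r, 1.0), 0.0)
            eu = np.where(r > 0, dy / np.where(r > 0, r, 1.0), 0.0)
        st = np.sin(theta)
        # direction unit vectors: x right, y up, z along the view axis
        self.directions = np.stack([st * er, st * eu, np.cos(theta)], axis=-1)

    @property
    def resolution(self) -> int:
        return self.values.shape[0]

    @property
    def cos_theta(self) -> np.ndarray:
        return self.directions[..., 2]

    # -- CSV matrix + JSON sidecar round trip ---------------------------------
    def to_files(self, csv_path, sidecar_path) -> None:
        np.savetxt(csv_path, self.values, delimiter=",", fmt="%.6g")
        meta = {
            "projection": "equidistant",
            "fov_deg": self.fov_deg,
            "view_direction": [0.0, 0.0, 1.0],
            "pixel_solid_angle_mode": "analytic",
            "regions": {
                name: {k: v for k, v in info.items() if k != "mask"}
                for name, info in self.regions.items()
            },
        }
        with open(sidecar_path, "w") as f:
            json.dump(meta, f, indent=2)

    @classmethod
    def from_files(cls, csv_path, sidecar_path) -> "LuminanceMap":
        values = np.loadtxt(csv_path, delimiter=",")
        with open(sidecar_path) as f:
            meta = json.load(f)
        if meta.get("projection") != "equidistant":
            raise ValueError("only the equidistant projection is supported")
        return cls(values, fov_deg=meta["fov_deg"], regions=meta.get("regions", {}))


def visible_transmittance(tau: SpectralDistribution,
                          reference_illuminant: str = "d65") -> float:
    """Photopic transmittance τ_v = ∫τ·S·V dλ / ∫S·V dλ (V = ȳ of 1931 2°)."""
    ref = _reference_illuminant(reference_illuminant)
    wl = ref.wavelengths_nm
    _, _, ybar, _ = load_cmfs()
    cw = load_cmfs()[0]
    v = np.interp(wl, cw, ybar, left=0.0, right=0.0)
    t = np.interp(wl, tau.wavelengths_nm, tau.values, left=0.0, right=0.0)
    w = ref.values * v
    return float(np.sum(t * w) / np.sum(w))


def _shape_curve(kind: str, params: dict, wl: np.ndarray) -> np.ndarray:
    if kind == "gaussian":
        c, s = params["center_nm"], params["sigma_nm"]
        return np.exp(-0.5 * ((wl - c) / s) ** 2)
    if kind == "longpass":
        # logistic rise; width_nm is the 10-90% transition width
        scale = params["width_nm"] / (2.0 * np.log(9.0))
        return 1.0 / (1.0 + np.exp(-(wl - params["cuton_nm"]) / scale))
    if kind == "flat":
        return np.ones_like(wl)
    raise ValueError(f"unknown glazing shape {kind!r}")


def make_glazing(color: str, target_tau_v: float,
                 shape_params: dict | None = None,
                 reference_illuminant: str = "d65") -> GlazingSpec:
    """Parametric glazing curve scaled to a prescribed photopic transmittance.

    Shapes (config-exposed via ``shape_params``): Gaussian passbands for blue
    (450/30 nm) and green (530/30 nm), a logistic long-pass for red (cut-on
    600 nm, 15 nm transition), a flat curve for neutral. The unit-amplitude
    shape is scaled so its D65/V(λ)-weighted transmittance equals
    ``target_tau_v``; a scale that would push τ(λ) above 1 raises.
    """
    if color not in GLAZING_SHAPES:
        raise ValueError(f"unknown glazing color {color!r}")
    if not (0.0 < target_tau_v < 1.0):
        raise ValueError("target tau_v must lie in (0, 1)")
    kind, default_params = GLAZING_SHAPES[color]
    params = {**default_params, **(shape_params or {})}
    wl = STANDARD_GRID
    shape = _shape_curve(kind, params, wl)
    unit = SpectralDistribution(wl, shape, "relative")
    tau_v_unit = visible_transmittance(unit, reference_illuminant)
    amplitude = target_tau_v / tau_v_unit
    if amplitude * shape.max() > 1.0 + 1e-9:
        raise ValueError(
            f"target tau_v={target_tau_v} unreachable for {color} shape "
            f"(needs amplitude {amplitude:.3f})")
    curve = SpectralDistribution(wl, amplitude * shape, "relative")
    return GlazingSpec(color, curve, visible_transmittance(curve, reference_illuminant))


def transmit(spd: SpectralDistribution, g: GlazingSpec) -> SpectralDistribution:
    """Filter a spectrum through a glazing (pointwise product on the spd grid)."""
    t = np.interp(spd.wavelengths_nm, g.tau_curve.wavelengths_nm,
                  g.tau_curve.values, left=0.0, right=0.0)
    return SpectralDistribution(spd.wavelengths_nm, spd.values * t, spd.quantity)


def disc_solid_angle(diameter_deg: float) -> float:
    """Solid angle of a circular disc: ω = 2π(1 − cos(∅/2))."""
    if not (0.0 < diameter_deg <= 180.0):
        raise ValueError("diameter must lie in (0, 180] degrees")
    return 2.0 * np.pi * (1.0 - np.cos(np.radians(diameter_deg / 2.0)))


def sun_stimulus_color(sun: SunModel, g: GlazingSpec,
                       target_L: float | None = None) -> ColorSummary:
    """Chromaticity of the sun seen through a glazing, optionally at a set luminance.

    The transmitted spectrum's chromaticity is luminance-invariant; with
    ``target_L`` the tristimulus values are scaled so L equals the target
    exactly (the normalization the appearance-model comparison uses).
    """
    spd_t = transmit(sun.source_spd, g)
    if not np.any(spd_t.values > 0):
        raise ChromaticityUndefinedError(
            f"glazing {g.color_name!r} blocks the entire source spectrum")
    c = spd_to_color(spd_t, absolute=False)
    if target_L is None:
        return c
    if target_L <= 0:
        raise ValueError("target luminance must be positive")
    return c.scaled(target_L / c.L)


# Window band of the façade in the fisheye frame (polar angle range, deg).
_WINDOW_BAND = (12.0, 45.0)


def build_scene(cond: SceneCondition, sun: SunModel,
                sun_glazing: GlazingSpec, view_glazing: GlazingSpec,
                resolution: int = 1024, fov_deg: float = 160.0) -> LuminanceMap:
    """Render a condition as a luminance map with a calibrated E_v.

    The map holds (i) the sun disc at ``cond.sun_luminance`` placed at the
    Guth angles (σ, τ), (ii) a window band whose luminance is solved linearly
    so the computed vertical illuminance Σ L·ω·cosθ equals ``ev_target``, and
    (iii) a uniform background. Region chromaticities (sun through the sun
    glazing, windows through the neutral view glazing) are attached as
    metadata for the chromatic glare metrics.

    The sun disc (0.533°) spans only a few pixels at realistic resolutions,
    so it is rendered as the set of pixels nearest the sun direction whose
    cumulative solid angle best matches the analytic disc solid angle; the
    rendered disc's ω is then correct to within half a pixel. A resolution at
    which fewer than 4 pixels represent the disc is rejected.
    """
    lm = LuminanceMap(np.zeros((resolution, resolution)), fov_deg=fov_deg)
    sigma = np.radians(cond.sigma_deg)
    tau = np.radians(cond.tau_deg)
    sun_dir = np.array([np.sin(sigma) * np.sin(tau),
                        np.sin(sigma) * np.cos(tau),
                        np.cos(sigma)])
    sun_mask = np.zeros_like(lm.inside)
    if cond.sun_luminance > 0:
        omega_disc = disc_solid_angle(sun.disc_diameter_deg)
        cosang = (lm.directions @ sun_dir)
        cosang[~lm.inside] = -1.0
        # candidate pixels near the sun, sorted by angular distance
        near = np.argsort(cosang, axis=None)[::-1][:4096]
        cum = np.cumsum(lm.omega.ravel()[near])
        k = int(np.argmin(np.abs(cum - omega_disc))) + 1
        if k < 4:
            raise ValueError(
                f"resolution {resolution} too coarse: sun disc covers "
                f"{k} pixels (< 4)")
        sun_mask.ravel()[near[:k]] = True
    theta_deg = np.degrees(lm.theta)
    win_mask = (theta_deg >= _WINDOW_BAND[0]) & (theta_deg <= _WINDOW_BAND[1]) \
        & lm.inside & ~sun_mask
    bg_mask = lm.inside & ~sun_mask & ~win_mask

    proj = lm.omega * lm.cos_theta
    ev_sun = cond.sun_luminance * float(proj[sun_mask].sum())
    g_win = float(proj[win_mask].sum())
    g_bg = float(proj[bg_mask].sum())
    ev_bg = cond.background_luminance * g_bg
    l_win = (cond.ev_target - ev_sun - ev_bg) / g_win
    if l_win < 0:
        raise ValueError(
            f"ev_target {cond.ev_target} lx infeasible: sun and background "
            f"alone contribute {ev_sun + ev_bg:.1f} lx")

    values = np.zeros_like(lm.values)
    values[bg_mask] = cond.background_luminance
    values[win_mask] = l_win
    values[sun_mask] = cond.sun_luminance

    sun_color = sun_stimulus_color(sun, sun_glazing)
    view_color = sun_stimulus_color(sun, view_glazing)
    regions = {
        "sun": {"mask": sun_mask,
                "chromaticity": (float(sun_color.x), float(sun_color.y)),
                "luminance": float(cond.sun_luminance)},
        "window": {"mask": win_mask,
                   "chromaticity": (float(view_color.x), float(view_color.y)),
                   "luminance": float(l_win)},
        "background": {"mask": bg_mask,
                       "chromaticity": (float(view_color.x), float(view_color.y)),
                       "luminance": float(cond.background_luminance)},
    }
    return LuminanceMap(values, fov_deg=fov_deg, regions=regions)
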
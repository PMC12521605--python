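"""Glare-source detection and discomfort-glare metrics from luminance maps.

Implements the evaluation chain applied to the experiment's HDR imagery:
vertical eye illuminance, threshold-based glare-source extraction (connected
components above 2000 cd/m², the default of standard glare-evaluation
software), the Guth position index, and the DGP and CGI indices

    DGP = 5.87·10⁻⁵·E_v + 9.18·10⁻²·log₁₀(1 + Σᵢ L²_{s,i}·ω_i /
          (E_v^1.87·P_i²)) + 0.16
    CGI = 8·log₁₀[ 2·(1 + E_d/500)/(E_d + E_i) · Σᵢ L²_{s,i}·ω_i/P_i² ]

with L_s the source luminance (cd/m²), ω its solid angle (sr), P its Guth
position index, E_v the vertical illuminance at the eye, and E_d/E_i its
direct (from sources) and indirect parts.

These formula implementations are exercised both on rendered scenes and on
analytic source descriptions; no attempt is made to reproduce the full
feature set (task areas, source splitting, smoothing) of Evalglare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scene import LuminanceMap

__all__ = [
    "GlareSource",
    "GlareResult",
    "DEFAULT_SOURCE_THRESHOLD",
    "vertical_illuminance",
    "detect_glare_sources",
    "guth_position_index",
    "dgp",
    "cgi",
    "peak_luminance",
    "evaluate_map",
]

#: Default luminance threshold for glare-source detection (cd/m²).
DEFAULT_SOURCE_THRESHOLD = 2000.0

#: E_v (lux) below which the DGP's validity is doubtful (low-light regime).
DGP_LOW_LIGHT_EV = 320.0

#: σ (deg) beyond which the Guth position-index formula is extrapolated.
GUTH_SIGMA_VALIDITY_DEG = 60.0


@dataclass(frozen=True)
class GlareSource:
    """One detected glare source entering the DGP/CGI sums."""

    L_s: float                  # mean luminance, cd/m²
    omega: float                # solid angle, sr
    P: float                    # Guth position index, >= 1
    direction: np.ndarray       # unit vector, view frame (x right, y up, z axis)
    sigma_deg: float            # angle from the line of sight
    tau_deg: float              # angle from vertical of the source/sight plane
    chromaticity: tuple[float, float] | None = None

    @property
    def E_d(self) -> float:
        """Direct illuminance contribution L·ω·cosθ (lux)."""
        return self.L_s * self.omega * float(self.direction[2])


@dataclass(frozen=True)
class GlareResult:
    """Glare metrics of one scene."""

    DGP: float
    CGI: float | None
    E_v: float
    E_d: float
    E_i: float
    sources: tuple[GlareSource, ...]


def vertical_illuminance(lum_map: LuminanceMap) -> float:
    """E_v = Σ L·ω·cosθ over the forward hemisphere (lux)."""
    w = lum_map.omega * np.clip(lum_map.cos_theta, 0.0, None)
    return float(np.sum(lum_map.values * w))


def direction_to_guth_angles(direction: np.ndarray) -> tuple[float, float]:
    """(σ, τ) in degrees from a unit direction in the view frame."""
    x, y, z = direction
    sigma = np.degrees(np.arccos(np.clip(z, -1.0, 1.0)))
    tau = np.degrees(np.arctan2(abs(x), y)) if (x, y) != (0.0, 0.0) else 0.0
    return float(sigma), float(tau)


def guth_position_index(sigma_deg: float, tau_deg: float) -> float:
    """Guth position index P(σ, τ), the off-axis penalty of a glare source.

    σ is the angle between source and line of sight, τ the angle from
    vertical of the plane containing both; both in degrees. P = 1 on axis
    and grows as the source moves off axis. Angles σ > 60° lie outside the
    validity of the underlying experimental data and are flagged with a
    warning (the value is still the formula's extrapolation).
    """
    if sigma_deg < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma_deg > GUTH_SIGMA_VALIDITY_DEG:
        warnings.warn(
            f"position index extrapolated beyond its validity (sigma="
            f"{sigma_deg:.1f} deg > {GUTH_SIGMA_VALIDITY_DEG:.0f} deg)",
            stacklevel=2)
    t = abs(tau_deg)
    s = sigma_deg
    expo = ((35.2 - 0.31889 * t - 1.22 * np.exp(-2.0 * t / 9.0)) * 1e-3 * s
            + (21.0 + 0.26667 * t - 0.002963 * t * t) * 1e-5 * s * s)
    return float(np.exp(expo))


def detect_glare_sources(lum_map: LuminanceMap,
                         threshold: float = DEFAULT_SOURCE_THRESHOLD
                         ) -> list[GlareSource]:
    """Connected components (8-connectivity) of pixels above the threshold.

    Per component: ω = Σ pixel solid angles, L_s = ω-weighted mean luminance,
    position index evaluated at the ω-weighted centroid direction. Sources
    inherit a region chromaticity from the map metadata when their centroid
    falls inside a tagged region.
    """
    mask = (lum_map.values > threshold) & lum_map.inside
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sources = []
    for lab in range(1, n + 1):
        m = labels == lab
        w = lum_map.omega[m]
        omega = float(w.sum())
        L_s = float(np.sum(lum_map.values[m] * w) / omega)
        centroid = (lum_map.directions[m] * w[:, None]).sum(axis=0)
        centroid /= np.linalg.norm(centroid)
        sigma, tau = direction_to_guth_angles(centroid)
        chrom = None
        for info in lum_map.regions.values():
            rm = info.get("mask")
            if rm is not None and (m & rm).sum() * 2 > m.sum():
                chrom = tuple(info["chromaticity"])
                break
        sources.append(GlareSource(L_s, omega, guth_position_index(sigma, tau),
                                   centroid, sigma, tau, chrom))
    sources.sort(key=lambda s: s.L_s * s.L_s * s.omega, reverse=True)
    return sources


def _source_sum(sources, ev_term: float | None = None) -> float:
    """Σ L²·ω/P² (CGI) or Σ L²·ω/(E_v^1.87·P²) (DGP, with ev_term)."""
    tot = 0.0
    for s in sources:
        tot += s.L_s ** 2 * s.omega / s.P ** 2
    if ev_term is not None:
        tot /= ev_term
    return tot


def dgp(E_v: float, sources: list[GlareSource] | tuple[GlareSource, ...]) -> float:
    """Daylight Glare Probability.

    No low-light correction is applied (all study conditions exceed
    1000 lx); a warning is emitted for E_v below 320 lx where the
    uncorrected formula is not trustworthy.
    """
    if E_v <= 0:
        raise ValueError("E_v must be positive")
    if E_v < DGP_LOW_LIGHT_EV:
        warnings.warn(f"DGP evaluated at low E_v={E_v:.0f} lx without "
                      "low-light correction", stacklevel=2)
    s = _source_sum(sources, ev_term=E_v ** 1.87)
    return 5.87e-5 * E_v + 9.18e-2 * np.log10(1.0 + s) + 0.16


def cgi(E_d: float, E_i: float,
        sources: list[GlareSource] | tuple[GlareSource, ...]) -> float:
    """CIE Glare Index (Einhorn's formula).

    ``E_d`` is the direct illuminance from the glare sources, ``E_i`` the
    indirect remainder (E_v − E_d), supplied by the caller.
    """
    if len(sources) == 0:
        raise ValueError("CGI undefined for an empty source list")
    if E_d + E_i <= 0:
        raise ValueError("E_d + E_i must be positive")
    s = _source_sum(sources)
    return 8.0 * np.log10(2.0 * (1.0 + E_d / 500.0) / (E_d + E_i) * s)


def peak_luminance(lum_map: LuminanceMap) -> float:
    """Highest in-field pixel luminance (the sun-disc luminance extractor)."""
    vals = lum_map.values[lum_map.inside]
    if vals.size == 0:
        raise ValueError("map has no pixels inside the field of view")
    return float(vals.max())


def evaluate_map(lum_map: LuminanceMap,
                 threshold: float = DEFAULT_SOURCE_THRESHOLD) -> GlareResult:
    """Full metric set of one map: E_v, sources, E_d/E_i split, DGP, CGI."""
    E_v = vertical_illuminance(lum_map)
    sources = detect_glare_sources(lum_map, threshold)
    E_d = float(sum(s.E_d for s in sources))
    E_i = E_v - E_d
    return GlareResult(
        DGP=dgp(E_v, sources),
        CGI=cgi(E_d, E_i, sources) if sources else None,
        E_v=E_v, E_d=E_d, E_i=E_i, sources=tuple(sources))
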
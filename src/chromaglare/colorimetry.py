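"""Spectral-to-colorimetric conversions.

Everything downstream — glazing transmittance, glare-source chromaticity,
color-appearance-model inputs, equivalent luminance — reduces spectra to CIE
1931 2° tristimulus values. This module holds that machinery: spectral
distributions on a regular wavelength grid, rectangle-rule integration against
the 2° color matching functions, correlated color temperature by exhaustive
Planckian-locus search (CIE 1960 uv distance, Ohno-style parabolic
refinement), cone responses via published linear transforms, and a Planckian
radiator as the solar stimulus stand-in.

Photometric quantities use V(λ) = ȳ of the CIE 1931 2° observer, the
convention of luminance cameras and of glare-evaluation software. The 1988
short-wavelength-corrected V(λ) is shipped alongside as data for plotting and
sensitivity checks only (see :func:`load_v1988`).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "SpectralDistribution",
    "ColorSummary",
    "ConeResponse",
    "CCTResult",
    "ChromaticityUndefinedError",
    "STANDARD_GRID",
    "MAX_LUMINOUS_EFFICACY",
    "load_cmfs",
    "load_v1988",
    "spd_to_color",
    "cct_from_xy",
    "xyz_to_cone",
    "planckian_spd",
    "xy_to_uv1960",
]

#: Default wavelength grid (nm) for synthesized spectra.
STANDARD_GRID = np.arange(380.0, 781.0, 5.0)

#: Maximum luminous efficacy K_m (lm/W) converting radiometric to photometric units.
MAX_LUMINOUS_EFFICACY = 683.0

_DATA_DIR = Path(__file__).parent / "data"

Quantity = Literal["radiance", "irradiance", "relative"]


class ChromaticityUndefinedError(ValueError):
    """Raised when chromaticity is requested for a zero-energy stimulus."""


@dataclass(frozen=True)
class SpectralDistribution:
    """A spectral curve on a strictly ascending, equispaced wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Grid in nanometres, step ≤ 5 nm, covering (a subset of) 380–780 nm.
    values
        Nonnegative spectral values, same length as the grid.
    quantity
        ``"radiance"`` (W·m⁻²·sr⁻¹·nm⁻¹), ``"irradiance"`` (W·m⁻²·nm⁻¹) or
        ``"relative"`` (unitless shape).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    quantity: Quantity = "relative"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 samples")
        if v.shape != wl.shape:
            raise ValueError("values and wavelengths must have equal length")
        steps = np.diff(wl)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid must be strictly ascending and equispaced")
        if steps[0] > 5.0 + 1e-9:
            raise ValueError("wavelength step must be <= 5 nm")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        if self.quantity not in ("radiance", "irradiance", "relative"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def scaled(self, k: float) -> "SpectralDistribution":
        return SpectralDistribution(self.wavelengths_nm, self.values * k, self.quantity)

    # -- CSV dialect: two columns `wavelength_nm,value`, comma separated ------
    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write("wavelength_nm,value\n")
            for w, v in zip(self.wavelengths_nm, self.values):
                f.write(f"{w:g},{v:.10g}\n")

    @classmethod
    def from_csv(cls, path, quantity: Quantity = "relative") -> "SpectralDistribution":
        arr = np.genfromtxt(path, delimiter=",", names=True)
        return cls(arr["wavelength_nm"], arr["value"], quantity)


@dataclass(frozen=True)
class ColorSummary:
    """Tristimulus reduction of one stimulus.

    ``X, Y, Z`` are absolute for radiance/irradiance input (Y in cd·m⁻² resp.
    lux) and relative otherwise; ``L`` equals Y for radiance input. ``cct`` is
    attached when the chromaticity lies near the Planckian locus.
    """

    X: float
    Y: float
    Z: float
    x: float
    y: float
    L: float
    cct: "CCTResult | None" = None

    def scaled(self, k: float) -> "ColorSummary":
        """Scale tristimulus by ``k``; chromaticity (and CCT) are unchanged."""
        return ColorSummary(self.X * k, self.Y * k, self.Z * k,
                            self.x, self.y, self.L * k, self.cct)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class ConeResponse:
    """Long/medium/short cone excitations on the same scale as Y."""

    Lc: float
    Mc: float
    Sc: float

    @property
    def lms(self) -> np.ndarray:
        return np.array([self.Lc, self.Mc, self.Sc])


@dataclass(frozen=True)
class CCTResult:
    """Correlated color temperature with distance-from-locus diagnostics."""

    cct_k: float
    duv: float          # CIE 1960 uv distance to the nearest Planckian point
    in_range: bool      # duv within the configured maximum (default 0.05)


@functools.lru_cache(maxsize=1)
def load_cmfs() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CIE 1931 2° color matching functions (380–780 nm, 5 nm tabulation)."""
    arr = np.genfromtxt(_DATA_DIR / "cie1931_2deg_5nm.csv", delimiter=",", names=True)
    return (arr["wavelength_nm"], arr["xbar"], arr["ybar"], arr["zbar"])


@functools.lru_cache(maxsize=1)
def load_v1988() -> tuple[np.ndarray, np.ndarray]:
    """1988 short-wavelength-corrected photopic V(λ). Plotting/sensitivity only."""
    arr = np.genfromtxt(_DATA_DIR / "v1988_2deg_5nm.csv", delimiter=",", names=True)
    return arr["wavelength_nm"], arr["value"]


def _cmfs_on_grid(wl: np.ndarray) -> np.ndarray:
    """Linearly interpolate the packaged CMFs onto ``wl``; zero outside 380–780."""
    cw, xb, yb, zb = load_cmfs()
    out = np.empty((3, wl.size))
    for i, bar in enumerate((xb, yb, zb)):
        out[i] = np.interp(wl, cw, bar, left=0.0, right=0.0)
    return out


def spd_to_color(spd: SpectralDistribution, absolute: bool | None = None,
                 attach_cct: bool = True) -> ColorSummary:
    """Integrate a spectral distribution against the CIE 1931 2° CMFs.

    Rectangle-rule integration on the spd's own grid (CMFs linearly resampled
    onto it). With ``absolute`` (default for radiance/irradiance input) the
    result is multiplied by K_m = 683 lm/W, so Y is luminance in cd·m⁻² for
    radiance input and illuminance in lux for irradiance input.

    Raises
    ------
    ChromaticityUndefinedError
        For an all-zero spectrum (x, y would be 0/0).
    """
    if absolute is None:
        absolute = spd.quantity in ("radiance", "irradiance")
    bars = _cmfs_on_grid(spd.wavelengths_nm)
    X, Y, Z = bars @ spd.values * spd.step_nm
    if absolute:
        X, Y, Z = (MAX_LUMINOUS_EFFICACY * c for c in (X, Y, Z))
    total = X + Y + Z
    if total <= 0:
        raise ChromaticityUndefinedError("all-zero spectrum: chromaticity undefined")
    x, y = X / total, Y / total
    cct = cct_from_xy(x, y) if attach_cct else None
    return ColorSummary(X, Y, Z, x, y, L=Y, cct=cct)


def xy_to_uv1960(x: float, y: float) -> tuple[float, float]:
    """CIE 1931 (x, y) → CIE 1960 (u, v)."""
    d = -2.0 * x + 12.0 * y + 3.0
    return 4.0 * x / d, 6.0 * y / d


_C2 = 1.4388e-2  # second radiation constant, m·K (ITS-90)


def _planck_values(wl_nm: np.ndarray, T: float) -> np.ndarray:
    lam = wl_nm * 1e-9
    return lam ** -5.0 / np.expm1(_C2 / (lam * T))


def planckian_spd(T: float, wavelengths_nm: np.ndarray | None = None) -> SpectralDistribution:
    """Planck's law on the standard grid, normalized to unit maximum.

    Valid for 1000 K ≤ T ≤ 30000 K (the range the CCT search covers).
    """
    if not (1000.0 <= T <= 30000.0):
        raise ValueError(f"temperature {T} K outside supported range 1000-30000 K")
    wl = STANDARD_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    v = _planck_values(wl, T)
    return SpectralDistribution(wl, v / v.max(), "relative")


@functools.lru_cache(maxsize=1)
def _planckian_locus() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(T, u, v) table of the Planckian locus at 1 K steps, 1000–30000 K."""
    T = np.arange(1000.0, 30001.0, 1.0)
    wl, xb, yb, zb = load_cmfs()
    lam = wl * 1e-9
    # (nT, nwl) Planck matrix; relative scale is irrelevant for chromaticity
    B = lam[None, :] ** -5.0 / np.expm1(_C2 / (lam[None, :] * T[:, None]))
    X = B @ xb
    Y = B @ yb
    Z = B @ zb
    d = X + 15.0 * Y + 3.0 * Z
    return T, 4.0 * X / d, 6.0 * Y / d


def cct_from_xy(x: float, y: float, max_duv: float = 0.05) -> CCTResult:
    """CCT of the Planckian-locus point nearest in CIE 1960 uv.

    Exhaustive 1 K-step search over 1000–30000 K with local parabolic
    refinement of the squared distance. Chromaticities further than
    ``max_duv`` from the locus are flagged (``in_range=False``) rather than
    rejected; the polynomial shortcuts common in colorimetry toolboxes are
    avoided because the bluest scenes here sit near 18000 K, outside their
    validity.
    """
    u0, v0 = xy_to_uv1960(x, y)
    T, u, v = _planckian_locus()
    d2 = (u - u0) ** 2 + (v - v0) ** 2
    i = int(np.argmin(d2))
    if 0 < i < T.size - 1:
        # parabola through the three nearest squared distances
        a, b, c = d2[i - 1], d2[i], d2[i + 1]
        denom = a - 2.0 * b + c
        shift = 0.5 * (a - c) / denom if denom > 0 else 0.0
        cct = T[i] + shift * (T[1] - T[0])
        dmin = max(b - 0.125 * (a - c) * shift, 0.0)
    else:
        cct, dmin = T[i], d2[i]
    duv = float(np.sqrt(dmin))
    return CCTResult(float(cct), duv, duv <= max_duv)


#: Hunt–Pointer–Estevez cone transform (von Kries normalization).
M_HPE = np.array([[0.38971, 0.68898, -0.07868],
                  [-0.22981, 1.18340, 0.04641],
                  [0.0, 0.0, 1.0]])

#: CAT16 transform used by CAM16-family appearance models.
M_CAT16 = np.array([[0.401288, 0.650173, -0.051461],
                    [-0.250268, 1.204414, 0.045854],
                    [-0.002079, 0.048952, 0.953127]])

_CONE_MATRICES = {"hpe": M_HPE, "cat16": M_CAT16}


def xyz_to_cone(color: ColorSummary, matrix_choice: str = "cat16") -> ConeResponse:
    """Linear cone excitations from tristimulus via a published matrix.

    Luminance-preserving up to the matrix's row sums (both shipped matrices
    have row sums within 2% of unity, so an equal-energy stimulus maps to
    nearly equal L, M, S).
    """
    try:
        m = _CONE_MATRICES[matrix_choice.lower()]
    except KeyError:
        raise ValueError(f"unknown cone matrix {matrix_choice!r}") from None
    lms = m @ color.xyz
    return ConeResponse(*lms)
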
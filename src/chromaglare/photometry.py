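"""Supplementary photometry: equivalent luminance and a chromaticity-aware DGP.

The supplementary system of photometry for colored lighting replaces
luminance with an *equivalent luminance* L_eq that folds the
Helmholtz-Kohlrausch effect in via the stimulus chromaticity: L_eq is the
luminance of a reference stimulus that matches the test stimulus in
brightness. The conventional reference is 555 nm monochromatic light; here
the reference is re-anchored to the equal-energy white point (x, y) =
(1/3, 1/3), so a white glare source keeps its photopic luminance and only
chromatic saturation moves L_eq away from L:

    L_eq = L · f(x, y) / f(x_ref, y_ref)

with f the brightness/luminance ratio at a chromaticity. The shipped f is
the Ware-Cowan polynomial

    log10(B/L) = 0.256 − 0.184·y − 2.527·x·y + 4.656·x³·y + 4.657·x·y⁴

behind a pluggable backend, since the re-referencing step — not the choice
of brightness model — is what changes the glare prediction.

``modified_dgp`` recomputes the DGP with each glare source's luminance
replaced by its equivalent luminance, which raises predicted discomfort for
saturated (blue, red) sources relative to neutral ones of equal luminance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .glare import GlareResult, GlareSource, dgp

__all__ = [
    "EquivalentLuminance",
    "ware_cowan_factor",
    "hk_factor",
    "equivalent_luminance",
    "modified_dgp",
    "EEW_CHROMATICITY",
    "MONO555_CHROMATICITY",
]

#: Equal-energy white point.
EEW_CHROMATICITY = (1.0 / 3.0, 1.0 / 3.0)

#: Chromaticity of 555 nm monochromatic light (spectral locus), the
#: conventional reference of the supplementary system.
MONO555_CHROMATICITY = (0.33741, 0.65460)


@dataclass(frozen=True)
class EquivalentLuminance:
    """Equivalent luminance of one stimulus.

    ``f_hk`` is the brightness/luminance ratio at the stimulus chromaticity;
    ``L_eq = L·f_hk/f_ref`` with ``f_ref`` the ratio at the reference
    chromaticity, so L_eq = L exactly when the stimulus sits on the
    reference.
    """

    L: float
    f_hk: float
    reference: str
    L_eq: float


def ware_cowan_factor(x: float, y: float) -> float:
    """Ware-Cowan brightness/luminance ratio B/L at a chromaticity."""
    log_bl = (0.256 - 0.184 * y - 2.527 * x * y
              + 4.656 * x ** 3 * y + 4.657 * x * y ** 4)
    return float(10.0 ** log_bl)


_BACKENDS: dict[str, Callable[[float, float], float]] = {
    "ware_cowan": ware_cowan_factor,
}


def hk_factor(x: float, y: float, backend: str = "ware_cowan") -> float:
    """Brightness/luminance ratio at (x, y) via the selected backend.

    Chromaticities must be physically plausible (inside the unit triangle);
    points outside raise, since the polynomial is unconstrained there.
    """
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0 and x + y <= 1.0):
        raise ValueError(f"chromaticity ({x}, {y}) outside the unit triangle")
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown brightness backend {backend!r}") from None
    return fn(x, y)


def equivalent_luminance(L: float, x: float, y: float,
                         reference: Literal["eew", "mono555"] = "eew",
                         backend: str = "ware_cowan") -> EquivalentLuminance:
    """Equivalent luminance of a stimulus of luminance L at chromaticity (x, y).

    ``reference="eew"`` (the modification studied here) anchors to the
    equal-energy white; ``"mono555"`` to 555 nm monochromatic light, the
    conventional anchor.
    """
    if L <= 0:
        raise ValueError("luminance must be positive")
    ref_xy = EEW_CHROMATICITY if reference == "eew" else MONO555_CHROMATICITY
    f = hk_factor(x, y, backend)
    f_ref = hk_factor(*ref_xy, backend)
    return EquivalentLuminance(L, f, reference, L * f / f_ref)


def modified_dgp(result: GlareResult,
                 chromaticities: dict[int, tuple[float, float]] | None = None,
                 mode: Literal["sources_only", "sources_and_ev"] = "sources_only",
                 reference: Literal["eew", "mono555"] = "eew",
                 backend: str = "ware_cowan") -> float:
    """DGP with source luminances replaced by equivalent luminances.

    ``chromaticities`` maps source index → (x, y); omitted indices fall back
    to the chromaticity carried by the source itself (attached during scene
    rendering). Every source must end up with one. ``sources_only`` (default)
    leaves E_v untouched — in the experiment E_v was dominated by the
    color-neutral view windows; ``sources_and_ev`` also rescales the direct
    part of E_v, for sensitivity analysis.
    """
    chromaticities = chromaticities or {}
    new_sources = []
    ev = result.E_v
    for i, s in enumerate(result.sources):
        xy = chromaticities.get(i, s.chromaticity)
        if xy is None:
            raise ValueError(f"no chromaticity for glare source {i}")
        leq = equivalent_luminance(s.L_s, *xy, reference=reference,
                                   backend=backend)
        scale = leq.L_eq / s.L_s
        new_sources.append(GlareSource(leq.L_eq, s.omega, s.P, s.direction,
                                       s.sigma_deg, s.tau_deg, tuple(xy)))
        if mode == "sources_and_ev":
            ev += s.E_d * (scale - 1.0)
    return dgp(ev, new_sources)
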
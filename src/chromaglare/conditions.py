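"""The eight experimental conditions' printed descriptive statistics.

A 2 × 4 mixed factorial: glazing transmittance level (low ≈ 0.37%,
high ≈ 2.5%; between subjects, 28 + 28 participants) crossed with glazing
color (red / green / blue / neutral; within subjects, order counterbalanced).
The per-condition means and standard deviations below are the study's
published descriptive table; they serve as calibration targets for the
synthetic generators and as the input of the comparability checks. They are
data, not model output.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConditionSummary", "STUDY_CONDITIONS", "EXCEEDANCE_TARGETS",
           "COLORS", "LEVELS", "VIEW_WINDOW_TAU_V"]

COLORS = ("red", "green", "blue", "neutral")
LEVELS = ("low", "high")

#: Visible transmittance of the color-neutral view windows.
VIEW_WINDOW_TAU_V = 0.0828


@dataclass(frozen=True)
class ConditionSummary:
    """Published per-condition descriptive statistics."""

    color: str
    level: str
    n: int
    tau_v: float                 # sun-window photopic transmittance
    cct_k: float                 # mean scene CCT at eye level
    ev_mean: float               # mean vertical illuminance, lux
    ev_sd: float
    sun_luminance_mean: float    # cd/m²
    sun_luminance_sd: float
    dgp_mean: float
    dgp_sd: float
    cgi_mean: float
    cgi_sd: float
    position_index_mean: float
    viewing_angle_mean_deg: float


def _c(color, level, n, tau_v, cct, ev, ev_sd, lsun_m, lsun_sd,
       dgp, dgp_sd, cgi, cgi_sd, pidx, angle):
    return ConditionSummary(color, level, n, tau_v, cct, ev, ev_sd,
                            lsun_m * 1e6, lsun_sd * 1e6, dgp, dgp_sd,
                            cgi, cgi_sd, pidx, angle)


STUDY_CONDITIONS: dict[tuple[str, str], ConditionSummary] = {
    ("blue", "low"): _c("blue", "low", 25, 0.0039, 17790, 1115, 109,
                        3.43, 0.57, 0.38, 0.016, 38.7, 1.66, 2.8, 26.5),
    ("green", "low"): _c("green", "low", 26, 0.0040, 6350, 1100, 140,
                         3.89, 0.50, 0.38, 0.02, 39.5, 2.09, 2.8, 26.7),
    ("red", "low"): _c("red", "low", 25, 0.0033, 5160, 1035, 120,
                       2.48, 0.27, 0.36, 0.019, 37.3, 2.11, 2.7, 26.2),
    ("neutral", "low"): _c("neutral", "low", 26, 0.0038, 6890, 1090, 127,
                           3.41, 0.46, 0.38, 0.017, 39.5, 1.87, 2.7, 26.7),
    ("blue", "high"): _c("blue", "high", 25, 0.0225, 18926, 2290, 129,
                         22.1, 4.26, 0.50, 0.02, 48.7, 1.76, 2.8, 26.9),
    ("green", "high"): _c("green", "high", 26, 0.0267, 6060, 2430, 169,
                          26.1, 4.15, 0.51, 0.02, 49.3, 1.96, 2.8, 26.8),
    ("red", "high"): _c("red", "high", 25, 0.0248, 5240, 2350, 133,
                        22.3, 3.08, 0.50, 0.02, 48.9, 1.73, 2.8, 27.0),
    ("neutral", "high"): _c("neutral", "high", 27, 0.0237, 7970, 2370, 143,
                            25.8, 4.42, 0.51, 0.02, 49.5, 2.09, 2.8, 26.6),
}

#: Published probabilities of reporting "disturbing or intolerable" glare
#: (ordinal vote ≥ 3) per color × transmittance level. The low-level blue and
#: neutral entries are recovered from the published pooled proportions
#: (blue 42%, neutral 22%) under equal level weights.
EXCEEDANCE_TARGETS: dict[tuple[str, str], float] = {
    ("red", "low"): 0.48, ("red", "high"): 0.88,
    ("blue", "low"): 0.21, ("blue", "high"): 0.63,
    ("green", "low"): 0.04, ("green", "high"): 0.23,
    ("neutral", "low"): 0.22, ("neutral", "high"): 0.22,
}
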
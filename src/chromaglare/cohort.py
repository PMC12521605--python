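"""Synthetic participant cohort with the study's response structure.

No raw response data is deposited with the study, so the analysis pipeline
runs on a generative stand-in: a latent-variable (proportional-odds style)
ordinal response model with participant random intercepts, calibrated so its
expected exceedance probabilities P(vote ≥ "disturbing") reproduce the
published per-condition percentages. The binary and 0-10 votes derive from
the same latent variable, which emulates the published high internal
consistency across questionnaire items without a separate mechanism.

The generator also produces per-exposure photometric "measurements" (draws
around the published condition means, plus an image-derived E_v with a
configurable calibration bias) and per-exposure weather records for the
cleaning filters. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .conditions import COLORS, EXCEEDANCE_TARGETS, LEVELS, STUDY_CONDITIONS
from .stats import RESPONSE_COLUMNS, WeatherRecord

__all__ = [
    "CohortDesign",
    "ResponseModelParams",
    "assign_design",
    "calibrate_defaults",
    "expected_exceedance",
    "generate_responses",
    "generate_measurements",
    "generate_weather",
]


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: two transmittance groups, four within-subject colors."""

    n_participants: int = 56
    group_split: tuple[int, int] = (28, 28)
    colors: tuple[str, ...] = COLORS
    counterbalance: bool = True

    def __post_init__(self):
        if sum(self.group_split) != self.n_participants:
            raise ValueError("group sizes must sum to n_participants")


@dataclass(frozen=True)
class ResponseModelParams:
    """Latent-variable ordinal response model.

    latent = shift(color, level) + participant intercept + logistic noise;
    the 4-point vote is the latent's bin among ``cutpoints``, the binary vote
    is latent > ``binary_cut``, and the 0-10 vote is a clipped rounded affine
    map. ``latent_shift`` is calibrated so the *marginal* exceedance
    P(vote ≥ 3) matches the published percentages.
    """

    latent_shift: dict[tuple[str, str], float]
    cutpoints: tuple[float, float, float] = (-2.2, 0.0, 2.5)
    noise_scale: float = 1.0
    intercept_sd: float = 1.0
    binary_cut: float = -1.0
    numeric_slope: float = 1.4
    numeric_intercept: float = 4.0

    def __post_init__(self):
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError("cutpoints must be strictly increasing")
        if self.noise_scale <= 0:
            raise ValueError("noise scale must be positive")


# Williams square for 4 conditions: each color appears once per participant,
# equally often in each presentation position, balanced for first-order
# carryover.
_WILLIAMS_4 = np.array([[0, 1, 3, 2],
                        [1, 2, 0, 3],
                        [2, 3, 1, 0],
                        [3, 0, 2, 1]])


def assign_design(design: CohortDesign) -> pd.DataFrame:
    """Participant × condition table with counterbalanced presentation order.

    One row per exposure (participant × color) carrying the transmittance
    group, the presentation position 1-4 and a per-exposure session id.
    Within each group, participants cycle through the rows of a Williams
    square, so each color occupies each position n_group/4 times (±1 when the
    group size is not a multiple of 4).
    """
    rows = []
    pid = 0
    for level, n_group in zip(LEVELS, design.group_split):
        for i in range(n_group):
            order = (_WILLIAMS_4[i % 4] if design.counterbalance
                     else np.arange(4))
            for pos, color_idx in enumerate(order, start=1):
                color = design.colors[color_idx]
                rows.append({
                    "participant_id": f"p{pid:03d}",
                    "group": level,
                    "color": color,
                    "presentation_order": pos,
                    "session_id": f"p{pid:03d}_e{pos}",
                })
            pid += 1
    return pd.DataFrame(rows)


# -- calibration ------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _marginal_exceedance(shift: float, cut: float, intercept_sd: float,
                         noise_scale: float) -> float:
    """P(shift + b + ε > cut), b ~ N(0, sd²), ε ~ Logistic(0, s)."""
    b = _GH_NODES * intercept_sd
    p = 1.0 / (1.0 + np.exp(-(shift + b - cut) / noise_scale))
    return float(np.sum(_GH_WEIGHTS * p))


def expected_exceedance(params: ResponseModelParams,
                        color: str, level: str) -> float:
    """Model-expected P(vote ≥ 3 | color, level)."""
    return _marginal_exceedance(params.latent_shift[(color, level)],
                                params.cutpoints[1], params.intercept_sd,
                                params.noise_scale)


def calibrate_defaults(targets: dict[tuple[str, str], float] | None = None
                       ) -> ResponseModelParams:
    """Solve the latent shifts so expected exceedances hit the published values.

    For each (color, level) the shift is found by root-solving the marginal
    exceedance (Gauss-Hermite integration over the participant intercept) at
    the second cutpoint against the published percentage; the match is exact
    to the solver tolerance, well inside half a percentage point.
    """
    targets = EXCEEDANCE_TARGETS if targets is None else targets
    base = ResponseModelParams(latent_shift={})
    shifts = {}
    for key, p_target in targets.items():
        f = lambda s: _marginal_exceedance(
            s, base.cutpoints[1], base.intercept_sd, base.noise_scale) - p_target
        shifts[key] = float(optimize.brentq(f, -30.0, 30.0, xtol=1e-10))
    return replace(base, latent_shift=shifts)


# -- generation -------------------------------------------------------------

def generate_responses(design_table: pd.DataFrame,
                       params: ResponseModelParams,
                       seed: int) -> pd.DataFrame:
    """Draw glare votes for every exposure in the design table.

    Returns a response table (fixed column set, one row per exposure) with
    the 4-point ordinal vote, the binary vote, the 0-10 numeric vote and a
    coarse discomfort-degree vote derived from the same latent variable.
    The ``valid`` flag is set to True; cleaning may revoke it.
    """
    rng = np.random.default_rng(seed)
    df = design_table.copy()
    participants = df["participant_id"].unique()
    intercepts = dict(zip(participants,
                          rng.normal(0.0, params.intercept_sd,
                                     participants.size)))
    shift = np.array([params.latent_shift[(c, g)]
                      for c, g in zip(df["color"], df["group"])])
    b = np.array([intercepts[p] for p in df["participant_id"]])
    noise = rng.logistic(0.0, params.noise_scale, len(df))
    latent = shift + b + noise
    cuts = np.array(params.cutpoints)
    df["glare_ordinal"] = 1 + np.searchsorted(cuts, latent)
    df["glare_binary"] = (latent > params.binary_cut).astype(int)
    df["glare_numeric"] = np.clip(
        np.rint(params.numeric_intercept + params.numeric_slope * latent),
        0, 10).astype(int)
    # Q6-style degree vote: same bins shifted half a category upward
    df["discomfort_degree"] = 1 + np.searchsorted(cuts + 0.5, latent)
    df["valid"] = True
    return df[RESPONSE_COLUMNS]


def generate_measurements(design_table: pd.DataFrame, seed: int,
                          scene_targets=None,
                          image_ev_bias: float = 0.075,
                          image_ev_noise: float = 0.02) -> pd.DataFrame:
    """Per-exposure photometric draws around the published condition means.

    E_v and sun luminance are Gaussian around the condition's mean/SD,
    truncated at zero. A paired image-derived E_v is the measured value times
    (1 + bias + noise), emulating the HDR-photometry agreement analysis
    (defaults: +7.5% bias, 2% noise).
    """
    scene_targets = STUDY_CONDITIONS if scene_targets is None else scene_targets
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in design_table.iterrows():
        c = scene_targets[(r["color"], r["group"])]
        ev = max(rng.normal(c.ev_mean, c.ev_sd), 0.0)
        lsun = max(rng.normal(c.sun_luminance_mean, c.sun_luminance_sd), 0.0)
        ev_img = ev * (1.0 + image_ev_bias + rng.normal(0.0, image_ev_noise))
        rows.append({"session_id": r["session_id"],
                     "participant_id": r["participant_id"],
                     "color": r["color"], "group": r["group"],
                     "ev_measured": ev, "ev_image": ev_img,
                     "sun_luminance": lsun})
    return pd.DataFrame(rows)


def generate_weather(session_ids, seed: int,
                     stability_mix: float = 0.085,
                     n_samples: int = 40,
                     hidden_sun_fraction: float = 0.3
                     ) -> dict[str, WeatherRecord]:
    """Per-exposure GHI series and sun-visibility flags.

    A fraction ``stability_mix`` of exposures is unstable: their GHI deviation
    (max−min)/mean exceeds the 25% cleaning threshold, and a
    ``hidden_sun_fraction`` of those additionally has the sun obscured for a
    span. Stable exposures keep the deviation well under threshold with the
    sun visible throughout, so the cleaning filter discards exactly the
    unstable fraction in expectation.
    """
    if not (0.0 <= stability_mix <= 1.0):
        raise ValueError("stability_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    for sid in session_ids:
        base = rng.uniform(500.0, 950.0)
        unstable = rng.random() < stability_mix
        if unstable:
            ghi = base * (1.0 + rng.normal(0.0, 0.02, n_samples))
            dip = rng.uniform(0.4, 0.7)          # a passing cloud
            i0 = rng.integers(0, n_samples - 5)
            ghi[i0:i0 + 5] *= dip
            visible = np.ones(n_samples, bool)
            if rng.random() < hidden_sun_fraction:
                visible[i0:i0 + 5] = False
        else:
            ghi = base * (1.0 + rng.normal(0.0, 0.015, n_samples))
            # keep the deviation safely under the 25% threshold
            ghi = np.clip(ghi, base * 0.93, base * 1.07)
            visible = np.ones(n_samples, bool)
        out[sid] = WeatherRecord(sid, np.clip(ghi, 0.0, None), visible)
    return out
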
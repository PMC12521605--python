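"""Full-analysis orchestration: scenes → metrics → cohort → statistics → tables.

``run_all`` reproduces the study's computational chain on synthetic data and
writes four report tables (per-condition photometrics; pairwise ordinal
statistics; CAM brightness comparison; original-vs-modified DGP) plus a JSON
manifest with the seed, a config hash and package version, so every table is
regenerable byte-for-byte from config + seed.

Sign convention of the pairwise table: delta > 0 means the *second* group of
the pair was rated higher, matching the published table's convention of
positive effect sizes for "red/blue rated above neutral/green" pairs listed
as (neutral, red), (green, blue), etc.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cam import CamSettings, CamStimulus, compare_conditions
from .cohort import (CohortDesign, assign_design, calibrate_defaults,
                     generate_measurements, generate_responses,
                     generate_weather)
from .colorimetry import SpectralDistribution, spd_to_color
from .conditions import COLORS, LEVELS, STUDY_CONDITIONS, VIEW_WINDOW_TAU_V
from .glare import evaluate_map, peak_luminance
from .photometry import modified_dgp
from .scene import (SceneCondition, SunModel, build_scene, make_glazing,
                    sun_stimulus_color, transmit)
from .stats import (agreement, clean_sessions, cliffs_delta, cronbach_alpha,
                    dunn_posthoc, friedman_test)

__all__ = ["RunConfig", "RunReport", "run_all", "verify_comparability",
           "scene_photometrics", "pairwise_table"]

log = logging.getLogger("chromaglare")


@dataclass(frozen=True)
class RunConfig:
    """Machine-validated configuration of a full run."""

    seed: int = 0
    n_participants: int = 56
    resolution: int = 1024
    stability_mix: float = 0.085
    source_threshold: float = 2000.0
    dgp_tolerance: float = 0.11
    cgi_tolerance: float = 0.08
    ev_factor: float = 1.5
    dgp_mode: str = "sources_only"
    cam_background_luminance: float = 200.0
    cam_normalization_luminance: float = 1000.0
    delta_thresholds: tuple[float, float, float] = (0.147, 0.33, 0.474)
    solar_temperature_k: float = 5778.0

    def __post_init__(self):
        if self.n_participants % 2:
            raise ValueError("n_participants must split into two equal groups")
        if self.dgp_mode not in ("sources_only", "sources_and_ev"):
            raise ValueError(f"unknown dgp_mode {self.dgp_mode!r}")
        for name in ("stability_mix",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        if "delta_thresholds" in raw:
            raw["delta_thresholds"] = tuple(raw["delta_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    """All report tables of one run plus provenance."""

    photometrics: pd.DataFrame
    comparability: dict
    pairwise: pd.DataFrame
    cam_table: pd.DataFrame
    modified_dgp_table: pd.DataFrame
    friedman: dict
    agreement: dict
    cronbach_alpha: float
    manifest: dict


def _solar_model(config: RunConfig) -> SunModel:
    from .colorimetry import planckian_spd
    return SunModel(source_spd=planckian_spd(config.solar_temperature_k))


def scene_photometrics(config: RunConfig) -> pd.DataFrame:
    """Render each of the eight conditions and compute its metric set.

    The scene CCT is taken from the eye-level spectrum, modeled as the
    transmitted sun and view-window spectra mixed in proportion to their
    vertical-illuminance contributions.
    """
    sun = _solar_model(config)
    view = make_glazing("neutral", VIEW_WINDOW_TAU_V)
    rows = []
    for (color, level), c in STUDY_CONDITIONS.items():
        g = make_glazing(color, c.tau_v)
        cond = SceneCondition(color, level, c.sun_luminance_mean,
                              c.viewing_angle_mean_deg, 0.0, c.ev_mean)
        lum_map = build_scene(cond, sun, g, view, resolution=config.resolution)
        res = evaluate_map(lum_map, config.source_threshold)
        # eye-level spectral mixture weighted by luminous contributions
        s_sun = transmit(sun.source_spd, g)
        s_view = transmit(sun.source_spd, view)
        c_sun = spd_to_color(s_sun, absolute=False, attach_cct=False)
        c_view = spd_to_color(s_view, absolute=False, attach_cct=False)
        ev_sun = res.E_d
        mix = SpectralDistribution(
            s_sun.wavelengths_nm,
            s_sun.values / c_sun.L * ev_sun
            + s_view.values / c_view.L * max(res.E_v - ev_sun, 0.0),
            "relative")
        scene_color = spd_to_color(mix, absolute=False)
        src = res.sources[0]
        rows.append({
            "color": color, "level": level, "tau_v": c.tau_v,
            "ev": res.E_v, "sun_luminance": peak_luminance(lum_map),
            "dgp": res.DGP, "cgi": res.CGI,
            "position_index": src.P, "viewing_angle_deg": src.sigma_deg,
            "scene_cct_k": scene_color.cct.cct_k,
            "sun_x": src.chromaticity[0], "sun_y": src.chromaticity[1],
        })
        log.info("scene %s_%s: Ev=%.0f lx DGP=%.3f CGI=%.1f",
                 color, level, res.E_v, res.DGP, res.CGI)
    return pd.DataFrame(rows)


def verify_comparability(photometrics: pd.DataFrame,
                         dgp_tol: float = 0.11, cgi_tol: float = 0.08,
                         ev_factor: float = 1.5) -> dict:
    """Check that, within each transmittance group, conditions are perceptually
    comparable: max relative DGP difference < ``dgp_tol``, max relative CGI
    difference < ``cgi_tol`` (the one-category-change thresholds), and max
    E_v ratio < ``ev_factor`` (the noticeable-lighting-change threshold).
    """
    required = {"level", "dgp", "cgi", "ev"}
    if not required <= set(photometrics.columns):
        raise ValueError(f"photometrics table missing {required - set(photometrics.columns)}")
    violations = []
    detail = {}
    for level, grp in photometrics.groupby("level"):
        d = {}
        for col, tol, kind in (("dgp", dgp_tol, "rel"), ("cgi", cgi_tol, "rel"),
                               ("ev", ev_factor, "ratio")):
            v = grp[col].to_numpy(float)
            if kind == "rel":
                spread = float((v.max() - v.min()) / v.min())
                ok = spread < tol
            else:
                spread = float(v.max() / v.min())
                ok = spread < tol
            d[col] = spread
            if not ok:
                violations.append(f"{level}:{col} spread {spread:.3f} >= {tol}")
        detail[level] = d
    return {"comparable": not violations, "violations": violations,
            "max_spread": detail}


def pairwise_table(responses: pd.DataFrame,
                   delta_thresholds=(0.147, 0.33, 0.474)) -> pd.DataFrame:
    """Dunn + Bonferroni + Cliff's delta over the six color pairs.

    One row per pair: (group1, group2, n1, n2, p, p_adj, delta, magnitude),
    with delta > 0 when group2 is rated higher.
    """
    rv = responses[responses["valid"]]
    groups = {c: rv.loc[rv.color == c, "glare_ordinal"].to_numpy(float)
              for c in COLORS}
    dunn = {frozenset(t.groups): t for t in dunn_posthoc(groups)}
    order = [("neutral", "green"), ("neutral", "blue"), ("neutral", "red"),
             ("green", "blue"), ("green", "red"), ("blue", "red")]
    rows = []
    for g1, g2 in order:
        t = dunn[frozenset((g1, g2))]
        eff = cliffs_delta(groups[g2], groups[g1], delta_thresholds)
        rows.append({"group1": g1, "group2": g2,
                     "n1": groups[g1].size, "n2": groups[g2].size,
                     "p": t.p_value, "p_adj": t.p_adjusted,
                     "delta": eff.delta, "magnitude": eff.magnitude})
    return pd.DataFrame(rows)


def _cam_table(config: RunConfig) -> pd.DataFrame:
    sun = _solar_model(config)
    stimuli = {}
    for color in COLORS:
        tau_v = STUDY_CONDITIONS[(color, "low")].tau_v
        g = make_glazing(color, tau_v)
        stimuli[color] = CamStimulus.from_color(
            sun_stimulus_color(sun, g, config.cam_normalization_luminance))
    settings = CamSettings(
        white_point=stimuli["neutral"].color,
        background_luminance=config.cam_background_luminance)
    return compare_conditions(stimuli, settings,
                              L_target=config.cam_normalization_luminance)


def _modified_dgp_table(config: RunConfig) -> pd.DataFrame:
    """Original vs equivalent-luminance DGP.

    Per transmittance level, the four colors are evaluated at the *same*
    luminous scene (group-mean sun luminance and E_v) so that any DGP spread
    is purely chromatic, mirroring the equal-stimulus comparison of the
    glare models.
    """
    sun = _solar_model(config)
    view = make_glazing("neutral", VIEW_WINDOW_TAU_V)
    rows = []
    for level in LEVELS:
        conds = [STUDY_CONDITIONS[(c, level)] for c in COLORS]
        lsun = float(np.mean([c.sun_luminance_mean for c in conds]))
        ev = float(np.mean([c.ev_mean for c in conds]))
        sigma = float(np.mean([c.viewing_angle_mean_deg for c in conds]))
        for color in COLORS:
            g = make_glazing(color, STUDY_CONDITIONS[(color, level)].tau_v)
            cond = SceneCondition(color, level, lsun, sigma, 0.0, ev)
            res = evaluate_map(build_scene(cond, sun, g, view,
                                           resolution=config.resolution),
                               config.source_threshold)
            rows.append({"color": color, "level": level,
                         "dgp": res.DGP,
                         "dgp_modified": modified_dgp(res, mode=config.dgp_mode)})
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir=None) -> RunReport:
    """Run the full chain; optionally write tables + manifest to ``outdir``."""
    log.info("run_all: seed=%d hash=%s", config.seed, config.config_hash())

    log.info("stage 1/5: scene photometrics (resolution %d)", config.resolution)
    photometrics = scene_photometrics(config)
    comparability = verify_comparability(photometrics, config.dgp_tolerance,
                                         config.cgi_tolerance, config.ev_factor)

    log.info("stage 2/5: cohort simulation (n=%d)", config.n_participants)
    half = config.n_participants // 2
    design = assign_design(CohortDesign(config.n_participants, (half, half)))
    params = calibrate_defaults()
    responses = generate_responses(design, params, seed=config.seed)
    weather = generate_weather(responses["session_id"], seed=config.seed + 1,
                               stability_mix=config.stability_mix)
    responses = clean_sessions(responses, weather)
    measurements = generate_measurements(design, seed=config.seed + 2)

    log.info("stage 3/5: ordinal statistics")
    rv = responses[responses["valid"]]
    piv = rv.pivot_table(index="participant_id", columns="color",
                         values="glare_ordinal")
    fr = friedman_test(piv.to_numpy(float))
    pairwise = pairwise_table(responses, config.delta_thresholds)
    # internal consistency across the three graded glare questions
    alpha = cronbach_alpha(rv[["glare_ordinal", "discomfort_degree",
                               "glare_numeric"]].to_numpy(float))
    agr = agreement(measurements["ev_image"], measurements["ev_measured"])

    log.info("stage 4/5: CAM brightness comparison")
    cam_table = _cam_table(config)

    log.info("stage 5/5: equivalent-luminance DGP")
    mdgp = _modified_dgp_table(config)

    manifest = {
        "package": "chromaglare", "version": __version__,
        "seed": config.seed, "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_valid_responses": int(responses["valid"].sum()),
        "tables": ["photometrics.csv", "pairwise.csv", "cam_comparison.csv",
                   "modified_dgp.csv"],
    }
    report = RunReport(
        photometrics=photometrics, comparability=comparability,
        pairwise=pairwise, cam_table=cam_table, modified_dgp_table=mdgp,
        friedman={"chi2": fr.statistic, "df": fr.df, "p": fr.p_value,
                  "n_blocks": int(piv.dropna().shape[0])},
        agreement={"rmse": agr.rmse, "nrmse": agr.nrmse, "nbias": agr.nbias},
        cronbach_alpha=alpha, manifest=manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        photometrics.to_csv(outdir / "photometrics.csv", index=False)
        pairwise.to_csv(outdir / "pairwise.csv", index=False)
        cam_table.to_csv(outdir / "cam_comparison.csv", index=False)
        mdgp.to_csv(outdir / "modified_dgp.csv", index=False)
        responses.to_csv(outdir / "responses.csv", index=False)
        measurements.to_csv(outdir / "measurements.csv", index=False)
        full = dict(manifest, comparability=comparability,
                    friedman=report.friedman, agreement=report.agreement,
                    cronbach_alpha=alpha)
        with open(outdir / "manifest.json", "w") as f:
            json.dump(full, f, indent=2)
        log.info("report written to %s", outdir)
    return report
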
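# chromaglare

Tools for studying discomfort glare from **colored daylight** — the situation
where a low-transmittance colored windowpane (electrochromic glass, colored
BIPV façades) turns the visible sun disc red, green or blue. Standard glare
metrics reduce every glare source to its photopic luminance

* **DGP** = 5.87·10⁻⁵·E_v + 9.18·10⁻²·log₁₀(1 + Σᵢ L²ₛ,ᵢωᵢ / (E_v^1.87 Pᵢ²)) + 0.16
* **CGI** = 8·log₁₀[2·(1 + E_d/500)/(E_d + E_i) · Σᵢ L²ₛ,ᵢωᵢ/Pᵢ²]

with L_s the source luminance, ω its solid angle, P its Guth position index
and E_v the vertical eye illuminance. Because luminance weights the spectrum
with V(λ), two suns of equal luminance but different color get identical
DGP/CGI — yet observers report markedly more glare behind saturated red and
blue glazing. That is a Helmholtz-Kohlrausch (H-K) effect: at equal
luminance, more saturated looks brighter (and, apparently, more glaring).

The package implements the full computational chain needed to study this on
synthetic data, for lighting researchers and visual-comfort modelers:

1. **colorimetry** — spectral distributions, CIE 1931 2° tristimulus
   integration, CCT by exhaustive Planckian-locus search, cone transforms.
2. **scene** — parametric colored-glazing curves scaled to a prescribed
   photopic transmittance τ_v, sun-through-glazing spectra, and fisheye
   luminance maps (equidistant projection, 160° FOV) calibrated to a target
   E_v.
3. **glare** — Evalglare-style source detection (2000 cd/m² threshold),
   E_v, Guth position index, DGP, CGI.
4. **cam** — brightness predictions from three color appearance models that
   include a chromatic brightness term: CAM15u, CAM18sl, and CAM16 with the
   Hellwig H-K extension.
5. **photometry** — equivalent luminance re-anchored to equal-energy white
   (Ware-Cowan brightness/luminance ratio) and a chromaticity-adjusted DGP.
6. **stats** — Friedman, Dunn + Bonferroni, Cliff's delta, Cronbach's alpha,
   two-sample K-S, RMSE/bias agreement, and sky-stability data cleaning,
   implemented from their formulas with mid-rank tie handling.
7. **cohort** — a calibrated latent-variable generator of ordinal glare
   votes for a 2 (transmittance) × 4 (color) mixed factorial with 56
   participants, so the whole analysis runs without human-subject data.
8. **pipeline / cli** — one-command orchestration producing the report
   tables.

## Worked example

```python
from chromaglare import (SunModel, SceneCondition, make_glazing, build_scene,
                         evaluate_map, modified_dgp)

sun = SunModel()                                   # Planckian 5778 K source
blue = make_glazing("blue", 0.0039)                # tau_v = 0.39 %
view = make_glazing("neutral", 0.0828)             # color-neutral view panes
cond = SceneCondition("blue", "low", sun_luminance=3.43e6,
                      sigma_deg=26.5, tau_deg=0.0, ev_target=1115.0)
scene = build_scene(cond, sun, blue, view)
res = evaluate_map(scene)
print(f"E_v={res.E_v:.0f} lx  DGP={res.DGP:.3f}  CGI={res.CGI:.1f}")
print(f"modified DGP={modified_dgp(res):.3f}")
```

prints

```
E_v=1115 lx  DGP=0.434  CGI=43.0
modified DGP=0.477
```

The rendered sun disc (0.533°, 3.43 million cd/m² behind blue glazing at a
viewing angle of 26.5°) plus the window band calibrated to E_v = 1115 lx
give DGP 0.434 — "disturbing" territory. Replacing the source luminance with
its equal-energy-referenced equivalent luminance raises the prediction to
0.477: the blue sun's chromatic saturation adds the brightness (and glare)
boost that plain DGP cannot see. Running the same scene with neutral glazing
of equal luminance leaves the modified DGP at the original value.

The full pipeline:

```sh
chromaglare run-all --seed 1 --out report/
```

writes the per-condition photometrics table, the six pairwise ordinal
comparisons (Dunn z, Bonferroni-adjusted p, Cliff's delta), the
appearance-model brightness table and the original-vs-modified DGP table,
plus a manifest with the config hash and seed.

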
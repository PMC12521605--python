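# Methods

## The problem

A seated observer faces a daylit façade in which one windowpane — the "sun
window" — filters the visible sun disc through saturated red, green, blue or
color-neutral glazing, at one of two photopic transmittance levels
(τ_v ≈ 0.37% or ≈ 2.5%). The remaining panes stay neutral (τ_v = 8.28%) so
the interior color rendering is preserved and the vertical eye illuminance
E_v is dominated by neutral light. Because the four colored conditions are
engineered to near-equal luminance photometry, any difference in reported
glare must come from color — a channel the standard luminance-based metrics
(DGP, CGI) cannot express. The package simulates those stimuli, computes the
classic and chromaticity-aware metrics, and runs the ordinal statistics used
on 4-point glare votes.

## Colorimetry

All photometric quantities use V(λ) = ȳ of the CIE 1931 2° observer — the
convention of luminance cameras and glare-evaluation software. The CMFs are
shipped as the standard 4-decimal abridged 5 nm tabulation; an internal
consistency check (equal-energy stimulus integrates to x = y = 1/3 to
5 decimals; ȳ(555) = 1 gives 683 cd/m² per unit radiance) guards the table.
The 1988 short-wavelength-corrected V(λ) is shipped as data for sensitivity
plots only and enters no computation.

CCT uses an exhaustive 1 K-step Planckian-locus table (1000–30000 K,
computed from the shipped CMFs) with CIE 1960 uv distance and parabolic
refinement, rather than a polynomial approximation: the bluest scenes sit
near 18000 K, far outside polynomial validity. Chromaticities further than
Δuv = 0.05 from the locus carry an `in_range=False` flag. Round trips
through Planckian spectra are exact to ±2 K across 2000–20000 K; D65
(0.3127, 0.3290) resolves to 6506 K and the shipped D65 table itself
integrates to the canonical white point.

## Scene synthesis

The solar source is a Planckian radiator at 5778 K normalized to unit peak —
a reproducible stand-in for the measured solar spectrum. Glazing curves are
parametric: Gaussian passbands for blue (450/30 nm) and green (530/30 nm), a
logistic long-pass for red (cut-on 600 nm, 10–90% width 15 nm), flat for
neutral; each shape is scaled so its D65- and V(λ)-weighted transmittance
equals the prescribed τ_v (reference illuminant switchable to equal-energy).
The measured curves these emulate are not published as tables, so the shapes
are config-exposed parameters, not data.

Luminance maps use the camera's geometry: an equidistant fisheye (θ = k·r),
160° FOV, square grid. Per-pixel solid angles are analytic
(ω = k²·sinθ/θ per unit pixel area) and sum to the spherical cap within the
rim pixelization. The 0.533° sun disc subtends only a few pixels at
realistic resolutions, so it is rendered as the nearest-pixel set whose
cumulative solid angle best matches the analytic disc ω — correct to within
half a pixel (≈5% at the default 1024²; the default is 1024 rather than a
coarser grid precisely so that at least 4 pixels carry the disc). Window
luminance is then solved linearly so that Σ L·ω·cosθ hits the condition's
E_v target exactly. Scene CCT is evaluated on the eye-level spectrum modeled
as the sun- and view-window spectra mixed by their illuminance
contributions.

One deviation from the published descriptive pattern is expected here: the
synthetic scenes order scene CCT as blue > green > neutral > red, whereas
the study measured neutral above green (6890 K vs 6350 K in the low group).
The parametric 530 nm green band nudges the mixture's correlated temperature
slightly above the 5778 K neutral stand-in; the measured glazing and sky
spectra evidently did the opposite. The robust ends of the ordering (blue
highest, red lowest) are reproduced and tested.

## Glare metrics

Glare sources are 8-connected components of pixels above 2000 cd/m² (the
default threshold of standard glare software); each component carries its
ω-weighted mean luminance, summed solid angle, centroid direction and Guth
position index

P = exp[(35.2 − 0.31889τ − 1.22e^(−2τ/9))·10⁻³·σ + (21 + 0.26667τ − 0.002963τ²)·10⁻⁵·σ²]

(σ, τ in degrees; σ > 60° flagged as extrapolation). DGP and CGI follow
their published formulas; no low-light DGP correction is applied (all
conditions exceed 1000 lx) and a warning fires below 320 lx. The absolute
DGP/CGI of rendered scenes (≈0.43 at the low level) intentionally exceeds
the study's Evalglare-on-HDR means (≈0.38): peak-luminance disc rendering
and a three-region radiance model are not an HDR camera pipeline, and no
claim is made to reproduce those absolute values. What is reproduced — and
tested — is the formula arithmetic (against independent oracles), the
metric *comparability* of the published means (both groups spread < 8%),
and every qualitative ordering.

## Appearance models

The three models are implemented from their publications and validated by
independent in-test re-transcription plus structural properties (achromatic
identities, monotonicity, robustness to the assumed background of
100–400 cd/m²); no third-party colorimetric reference implementation exists
in the dependency set, so cross-library checks are not available.

* **CAM15u** (unrelated self-luminous stimuli): XYZ → (ρ, γ, β) through the
  model's CMF matrix, cube-root compression, achromatic signal
  A = 3.22(2ρ′ + γ′ + β′/20), opponent signals a = ρ′ − 12γ′/11 + β′/11 and
  b = 0.117(ρ′ + γ′ − 2β′), colorfulness M = 135.52√(a² + b²), brightness
  Q = A + 2.559·M^0.561. No background or adaptation input.
* **CAM18sl**: the same front end with Michaelis-Menten compression
  ρ′ = ρ^0.58/(ρ^0.58 + σ_b^0.58), σ_b = 291.20 + 71.8·L_bg^0.78 tracking a
  gray background; outputs on the model's own scales (A normalized and
  rescaled by 937, M = 3260√(a² + b²)). Stimuli above 10⁴ cd/m² are flagged:
  the compression saturates there, a mathematical artifact, which is why the
  comparison normalizes all stimuli to 1000 cd/m² first (preserving
  chromaticity exactly — every component scaled by L_target/L).
* **CAM16 + Hellwig H-K extension**: the standard CAM16 forward path
  (CAT16 adaptation with D = 1 toward the reference white, F_L, surround
  "average", Y_b/Y_w = 0.2), the revised brightness Q = (2/c)(J/100)A_w and
  colorfulness M = 43·N_c·e_t·√(a² + b²), and the H-K lightness term
  J_HK = J + f(h)·C^0.587 with C = 35·M/A_w and a sinusoidal hue weighting
  that peaks around blue and bottoms around yellow. The reference white is
  the neutral-glazing sun at 1000 cd/m², so the neutral stimulus is
  achromatic by construction and the H-K term vanishes for it.

With the four synthetic stimuli at 1000 cd/m², CAM18sl and CAM16-Hellwig
rank red and blue strictly above green and neutral — the behavior that
motivates chromatic glare metrics — and disabling the H-K term shrinks the
equal-luminance brightness spread. CAM15u's reported failure signature
(red ≈ neutral with green dimmest) does **not** emerge here: that signature
requires the *measured* neutral-sun stimulus to be as colorful as the red
one in CAM15u's adaptation-free space, whereas the synthetic Planckian
neutral sits at the model's achromatic point (M ≈ 10 vs ≈ 540 for red). The
acceptance test records this clause as failing, by design; the package does
not adjust stimuli to force it.

## Equivalent luminance

The supplementary-photometry layer computes L_eq = L·f(x, y)/f(x_ref, y_ref)
with f the Ware-Cowan brightness/luminance polynomial, behind a pluggable
backend — the re-anchoring of the reference from 555 nm monochromatic light
to equal-energy white is the methodological point, and it is
backend-independent. A white source keeps L_eq = L exactly; saturated blue
and red sources gain ≈70% and ≈30%. `modified_dgp` substitutes each source's
L_eq into the DGP sum (E_v untouched by default, since the experiment's E_v
was dominated by neutral window light; a `sources_and_ev` mode rescales the
direct component for sensitivity analysis). On equal-luminance scenes this
orders blue > red > neutral ≈ green — including the known overestimate of
blue relative to red observers' reports.

## Synthetic cohort

The response generator is explicitly a stand-in (the study specifies no
response model): latent = shift(color, level) + participant intercept
(N(0, 1)) + logistic noise (scale 1); the 4-point vote bins the latent at
cutpoints (−2.2, 0, 2.5), the binary vote thresholds it at −1, and the 0–10
vote is a clipped rounded affine map (4 + 1.4·latent). Deriving all items
from one latent variable reproduces the study's high internal consistency
(α ≈ 0.81 across the three graded items) without extra machinery. The
shifts are calibrated by root-solving the marginal exceedance
P(vote ≥ "disturbing") — Gauss-Hermite integration over the intercept — to
the eight published percentages (red 48/88, blue 21/63, green 4/23, neutral
22/22, in % for low/high; the two low-level values not printed directly are
recovered from the published pooled proportions under equal level weights).

Presentation order is counterbalanced with a Williams square (each color in
each position 7× per 28-participant group). Photometric "measurements" are
truncated-Gaussian draws around the published condition means with a paired
image-derived E_v at +7.5% bias and 2% multiplicative noise, emulating the
HDR-vs-sensor agreement analysis. Weather records give each exposure a
40-sample GHI series; a configurable fraction (default 8.5%) is unstable
(range/mean > 25%, sometimes with the sun obscured), so the cleaning filter
discards that fraction in expectation.

What the generator does *not* emulate: order/carry-over effects, response
styles, skew or overdispersion beyond the logistic family, correlations
between photometry draws and votes, and any pupil/chronotype covariates.
Passing tests therefore show that the analysis chain recovers the published
effect structure from data *with that structure* — not that real cohorts
behave this way.

## Problem sizes and numerical choices

Scenes render at 1024² (the coarsest grid giving a ≥4-pixel sun disc);
recovery statistics use 200 replicates of the 56-participant design;
calibration fidelity uses a 5000-participant draw; the cleaning-rate check
uses 1000 exposures. Mid-ranks and tie-corrected variances are used in every
rank statistic (4-point data is tie-dominated); the Friedman χ² is compared
against an exact within-block permutation distribution in its inferential
regime, where the asymptotic approximation is adequate (deep right-tail
p-values of tiny discrete statistics are knowingly coarse). Cliff's-delta
magnitude cuts default to 0.147/0.33/0.474 and are configurable — the
study's labels imply a different, unstated convention (it calls 0.30
"moderate"), and the published pairwise table's deltas are reported here
with positive sign meaning "second group rated higher", matching its layout.

## Known limitations

* The CAM constant sets are transcribed from the publications without an
  independent software cross-check (none exists in the dependency set);
  structural tests would not catch a wrong fitted constant that preserves
  monotonicity and the achromatic identity.
* The glazing shapes and the Planckian sun are parametric emulations;
  absolute scene CCTs and CAM colorfulness magnitudes depend on them.
* Absolute DGP/CGI of rendered scenes are not comparable to HDR-derived
  values (see above); only orderings, spreads and formula arithmetic are.
* The equivalent-luminance backend is the Ware-Cowan polynomial; other
  brightness models plug in but are not shipped.
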
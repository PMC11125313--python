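# Methods

`mipsense` implements the analytics for quantifying tartrazine (the azo food
dye E102) with molecularly imprinted polymer (MIP) films grafted on PET
plates: the plate adsorbs the dye, turns yellow in proportion to the adsorbed
amount, and a smartphone photograph of the plate is converted into a
concentration estimate by multivariate calibration. The package also covers
the batch-adsorption characterization of such plates — kinetics, isotherms,
MIP-vs-NIP selectivity, and reuse.

## Digital-image colorimetry

A plate image contributes one sample. Up to two 16×16-pixel regions of
interest are averaged per channel and the mean RGB triplet is expanded to a
10-channel descriptor (R, G, B, C, M, Y, K, H, S, V) using:

- CMYK: C = 1 − R/255, M = 1 − G/255, Y = 1 − B/255, K = min(C, M, Y).
  Note that K is the plain minimum — the common (1 − K) renormalization of
  C, M, Y is deliberately **not** applied, so C, M, Y stay interpretable as
  per-channel complements.
- HSV: V = max(R, G, B) **kept on the 0–255 count scale**, S = 1 − min/V
  (dimensionless, 0 when V = 0), and the standard piecewise hue in degrees.
  The mixed scales (V in counts, S a ratio) are intentional; standardization
  removes the scale anyway, and exports keep the raw values.

Degenerate-input conventions: an achromatic pixel (max = min) gets H = 0 so
blank plates produce complete feature rows, and ties in the dominant channel
resolve in the order R, then G, then B (matching the order of the hue's
piecewise cases). ROI coordinates are 0-based, row-major, origin top-left,
half-open ranges.

## PLS calibration

Features and concentration are autoscaled (mean 0, SD 1, denominator n−1;
constant columns are dropped and recorded). The regression is a univariate
partial least squares (PLS1) computed by NIPALS: per component the weight
vector is X′y normalized, the score t = Xw, loadings p = X′t/t′t and
q = y′t/t′t, followed by deflation of X and y. For a single response each
component is exact in one pass (no inner iteration). Weight signs follow the
convention that the first non-zero element of each weight vector is
positive, so loadings are reproducible. At full rank the PLS solution
coincides with ordinary least squares; the test suite asserts this
equivalence against an OLS oracle and cross-checks predictions against an
independent reference PLS implementation.

Default latent dimension is 4, overridable and guarded against exceeding the
rank of X.

**Validation.** Cross-validation is leave-one-out — the standard choice for
calibration sets of ~20–40 samples — with the autoscaling re-estimated
inside each fold so the held-out sample never leaks into preprocessing.

**Working range.** The plate response is linear only at low loading; at
higher concentrations the finite adsorption capacity of the film bends the
response. Candidate upper bounds (default 5, 7, 10, 14, 20 mg/L) are each
refit and cross-validated, and the chosen range maximizes a lexicographic
score: slope of cross-validated predicted-vs-measured closest to 1, then
highest R², then lowest RMSECV. A deterministic rule is required for
software even though a human would eyeball the metric curves; all
candidates' metrics are always reported.

**LOD/LOQ.** LOD = 3.3·s/|m| and LOQ = 10·s/|m|, where s is the SD of the
out-of-fold residuals inside the working range and m the cross-validated
slope. The LOQ is additionally floored at the lowest non-zero calibration
standard — quantification cannot be claimed below the lowest level actually
calibrated — and the report records whether the floor was active, along
with the unfloored value. The scanned range and the LOQ-floored working
range are reported separately rather than conflated.

**Biplot.** The first two latent components supply scores and variable
loadings; alongside them the signed Pearson correlation of each raw channel
with concentration is reported. On the default synthetic calibration the
signs are: concentration correlates positively with H, S and Y and
negatively with V, R and G — a yellowing plate loses blue first, so the
yellow-complement channel rises while brightness and the primary channels
fall.

## Batch adsorption

Removal % defaults to 100·(Co − Ce)/Co, the convention under which removal
is bounded by 100 when Ce ≤ Co. An alternative form dividing by Ce instead
of Co is available behind `convention="as_printed"` for fidelity with a
written variant of the equation; every report names the convention used.
Capacity is Q = (Co − Ce)·V/A in mg/cm².

Kinetic and isotherm constants are obtained from the field's standard
linearizations (base-10 logs throughout; the 2.303 factor is ln 10 to four
significant figures, which is why the recovered pseudo-first-order rate is
exact only to that rounding):

| model | linearization | constants |
|---|---|---|
| pseudo-first-order | log₁₀(Qe − Qt) vs t | k1 = −2.303·slope, Q_cal = 10^intercept |
| pseudo-second-order | t/Qt vs t | Qe = 1/slope, k2 = slope²/intercept |
| intraparticle diffusion | Qt vs √t, window 10–60 min | kid = slope, C = intercept |
| Langmuir | Ce/Qe vs Ce | Qm = 1/slope, b = slope/intercept |
| Freundlich | log₁₀Qe vs log₁₀Ce | n = 1/slope, Kf = 10^intercept |

The quoted R² of each fit is computed on the linearized axes (that is what
the conventional parameter tables describe). A nonlinear least-squares refit
of the closed form is reported alongside. **Model comparison uses the R² of
the refit in the untransformed Q space**: R² values from differently
transformed axes (a log axis, a t/Qt axis, a windowed √t axis) are not
mutually comparable, and ranking by them systematically favors whichever
transformation compresses its residuals most.

The pseudo-first-order linearization needs an equilibrium capacity Qe; the
default is the last (plateau) observation, overridable with an independently
measured value. Points where Qe − Qt ≤ 0 (log undefined) are dropped with a
warning; the fit errors only when fewer than three usable points remain.
Because the default plateau estimate sits on the curve itself, the late
log-residuals are ill-conditioned under noise — passing a measured
equilibrium capacity that exceeds all observations, when available, is
strongly preferable, and the untransformed-axis refit is robust either way.

Selectivity: imprinting factor α = removal(MIP)/removal(NIP) per dye, and
selectivity factor β = α(template)/α(interferent), with β(template) ≡ 1.
Reusability: per-cycle removal with the drop cycle defined as the first
cycle whose removal falls below (1 − δ) of the first cycle's, δ = 0.10 by
default.

## Synthetic data generator

The generator produces the inputs the analyses assume, so the whole chain is
testable without laboratory data.

**Plate images.** A calibration plate exposed to concentration C (mg/L) in
volume V (default 3 mL) on area A (default 1 cm²) is assumed to adsorb the
whole aliquot, giving surface loading q = C·V/A (mg/cm²). Each RGB channel
attenuates decadically — ch(q) = base_ch·10^(−att_ch·q) — which keeps
channels in [0, 255] at any loading and is the reflectance analogue of
Beer–Lambert absorption. Blue attenuates fastest (att_B = 10 per mg/cm²),
green next (1.2), red least (0.5), so loaded plates yellow; the blank plate
is slightly warm white, (235, 230, 225). The complete-uptake assumption
fails as loading approaches the film's capacity, so the effective loading
saturates smoothly: q_eff = q_max·tanh(q/q_max) with q_max = 0.03 mg/cm².
This saturation is what makes the upper calibration range genuinely
nonlinear and is the structural reason the working-range scan prefers a
truncated range. A linear illumination gradient across the plate (default
2% peak-to-peak, centered so the plate mean is unchanged) stands in for
lighting non-uniformity, and i.i.d. Gaussian pixel noise (SD 2 counts) for
sensor noise. All generator parameters were fixed once as a package
convention; the channel-vs-loading law is not a measured camera model and
no claim about any physical device follows from it.

**Adsorption data.** Kinetics and isotherms come from the corresponding
closed forms (PFO/PSO/IPD, Langmuir/Freundlich) with optional multiplicative
Gaussian noise; the round trip generator → fitter recovers parameters to
≤10⁻⁶ relative error on noise-free data, which is the package's principal
correctness check for the fitters. The command-line fixture uses 0.5%
relative noise for kinetics — representative of UV–vis absorbance precision,
and the level at which competing uptake models remain distinguishable on a
10–120 min grid — and 2% for isotherms, whose equilibrium scatter is
characteristically larger. Selectivity fixtures are constructed inversely:
requested removal percentages are converted to Ce = Co·(1 − removal/100).

**What the generator does not emulate:** camera optics and JPEG artifacts,
device color profiles, white-balance drift, plate-to-plate coating
variability, competitive adsorption, or pH effects (pH is metadata only).
Passing tests therefore demonstrate the correctness of the computational
chain under the stated response model, not the field performance of any
physical sensing platform.

## Determinism and problem sizes

Every stochastic generator takes an explicit seed; per-image seeds derive
deterministically from the master seed, so fixture sets are byte-identical
across runs. The default calibration series is 21 concentrations (0–20 mg/L,
1 mg/L steps) × 2 replicates at 64×64 px — small enough that the full
simulate → calibrate → quantify chain runs in seconds while preserving the
sample-to-feature ratio the calibration design implies. Kinetics use a
10–120 min grid (step 10), isotherms Ce = 10–100 mg/L (step 10).

## Known limitations

- PLS1 only; no multi-response PLS2, no variable selection, no nonlinear
  calibration.
- Kinetics: no Elovich or Temkin-type models, no diffusion PDEs, no
  thermodynamic (ΔG/ΔH) analysis.
- The hue convention (0° for achromatic input) and the tie-breaking order
  are package conventions; other software may differ on exactly gray pixels.
- The linearized fitters inherit the classical weighting biases of their
  transformations (e.g. log-axis fits overweight small residual capacities);
  the nonlinear refit is reported for exactly this reason.
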
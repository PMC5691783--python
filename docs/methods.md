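# Methods

## Spectral representation

All spectral quantities live on a canonical grid of 300–700 nm at 1 nm
(401 samples, both endpoints included). Native spectrometer output is
finer (≈0.34 nm); reduction to the canonical grid takes, for each grid
point, the average of the piecewise-linear interpolant of the source over
the 1 nm bin centred on that point. This is a bin mean — it suppresses
fine-grid instrument noise exactly as averaging the raw samples would —
but it is insensitive to where the source samples happen to fall inside
the bin, and it degrades gracefully to plain linear interpolation when the
source is sparser than the target grid. Edge bins are truncated to the
source range; a source that does not cover the full 300–700 nm span is an
error. Negative reflectances (measurement noise around dark standards)
are clipped to zero with a logged warning. Repeated measurements of one
specimen (six per larva in the spectrometric experiments) are averaged
**as spectra**, before any visual modelling, so each specimen has a single
canonical spectral representation; downstream summaries of a specimen are
summaries of its mean spectrum.

## Visual model

The viewer is a tetrachromatic (UVS-type) bird with single cones UV, SW,
MW, LW and a double cone DD for luminance. Quantum catches are discrete
sums `Q_i = Σ_λ R(λ) I(λ) S_i(λ) Δλ` with Δλ = 1 nm; no von Kries
adaptation is applied by default, because the discriminability metric uses
log catch *ratios*, which are invariant to any receptor-wise scaling
shared by the two stimuli (adaptation to a common illuminant cancels). An
optional floor (10⁻⁶ × the largest catch) can replace zero catches, since
the metric takes logs; the default is to raise an error so silent
degeneracies cannot pass unnoticed.

Receptor noise follows the neural-noise scaling `e_i = ν / √(η_i/η_max)`
with relative densities η = {UV 0.3704, SW 0.7111, MW 0.9926, LW 1.0} and
base Weber fraction ν = 0.05, so the most abundant cone (LW) has
`e = 0.05` and rarer cones are noisier. The chromatic distance between
stimuli a and b, in JND units, is the tetrachromat receptor-noise formula
on `Δf_i = ln(Q_i^a/Q_i^b)`:

```
ΔS² = Σ_{pairs (i,j)} (e_k e_l)² (Δf_i − Δf_j)²  /  Σ_{triples} (e_i e_j e_k)²
```

where (k, l) is the pair complementary to (i, j). This is algebraically a
weighted Euclidean norm of the component of Δf orthogonal to the intensity
direction in noise-whitened space; the test suite exploits that identity
as an independent oracle (the implementation and the oracle never share
code). Consequences verified as properties: ΔS is a metric (symmetry,
identity, triangle inequality), invariant to a common intensity scaling of
either stimulus, and monotone in any single log-contrast. With all
`e = 0.05` and a single contrast `Δf = (0,0,0,0.05)` the formula reduces
analytically to ΔS = √3/2.

Luminance discriminability uses the double cone alone:
`ΔL = |ln(Q_DD^a/Q_DD^b)| / e_DD`. The double-cone Weber fraction is not
separately estimated anywhere we can recover; it defaults to 0.05 (the
chromatic base value), configurable via `ReceptorSet.dd_weber`.

JND categories follow the standard reading: < 1 indiscriminable, 1–3
(closed interval) discriminable only under good viewing conditions, > 3
discriminable. Values exactly 1.0 or 3.0 fall in the middle class.

The illuminant defaults to the CIE standard illuminant D65 (embedded 10 nm
tabulation, 300–700 nm, linearly interpolated to the grid); a flat
equal-energy illuminant is available. Only the illuminant's shape matters:
JNDs are scale-invariant.

## Tetrahedral colour space

Relative catches (each single-cone catch divided by their sum) are mapped
barycentrically onto a regular tetrahedron with centroid at the origin and
vertices at distance 0.75: equal stimulation of all four cones lands at
the origin, exclusive stimulation of one cone at that cone's vertex. The
UV vertex sits on the +z axis; the other three lie 120° apart on the
z = −0.25 plane. Orientation is a plotting convention only — every
distance is rotation-invariant. Chromatic "greenness" is the opponency
ratio `MW/(MW+LW)` in [0, 1].

## Photographic pathway

The heterogeneous-environment experiment scores larvae from photographs
rather than spectra. An image is calibrated by scaling each channel so the
embedded grey standard reads 18% reflectance; per-channel scaling also
neutralises global colour casts (a scalar mode that preserves casts is
available). Linearisation is a pluggable first step (identity for
linear-light inputs such as the synthetic fixtures; an inverse gamma-2.2
transfer is provided for gamma-encoded images). Greenness is
`G/(R+G+B) × 100` per ROI, averaged over the six dorso-lateral ROIs
(left/right of the 3rd thoracic, 2nd and 6th abdominal segments). These
device-referred RGB values are deliberately **not** passed through the
avian visual model. ROI geometry is supplied by the user (YAML); the
synthetic image generator embeds its own known ROI locations.

## Reaction norms and group tests

Polynomial models of order 1–4 are fitted by OLS in a shifted/scaled
variable (the stimulus mapped to [−1, 1]) for conditioning; coefficients
and their covariance are transformed back to the raw stimulus scale, so
reported coefficients, standard errors and t-based confidence intervals
all refer to raw polynomial terms. An order that would need more distinct
stimulus values than the design provides (fewer than order + 2 levels) is
skipped with a warning — with five treatment levels the quartic is
reported as unfittable rather than saturated.

Successive orders are compared by extra-sum-of-squares F tests
`F = [(RSS_s − RSS_b)/Δdf] / [RSS_b/df_b]`. Residual sums of squares below
10⁻¹² × the total sum of squares are treated as numerically zero: a
perfect higher-order fit is reported as F = ∞ with a degeneracy flag, and
two perfect fits compare as F = 0. Model selection takes the **lowest**
order that no higher fitted order improves significantly (α = 0.05),
reporting adjusted R² and residual sign-runs diagnostics alongside; the
original criterion also weighed visual fit of the plotted curves, which is
not automatable and is explicitly not part of the rule. Idealised
reference curves accompany each fit: the straight line joining the two
extreme (stimulus, response) means (continuous reaction norm) and a step
function switching at the stimulus midpoint (two-state polyphenism).

Group-level machinery:

* **One-way ANOVA** from explicit sums of squares, with per-group n,
  mean, variance and median, and a degeneracy flag when within-group
  variance is exactly zero (F = ∞ or 0 rather than NaN).
* **Nested ANOVA** for designs with replicate boxes nested in treatments:
  treatment is tested against the box-within-treatment mean square with
  (k − 1, B − k) degrees of freedom — for balanced designs this equals a
  one-way ANOVA on box means, and it is the expected-mean-squares
  equivalent of a random-intercept mixed model for such designs. A single
  box per treatment falls back to one-way ANOVA with a warning.
* **Brown–Forsythe test** (Levene centred on group medians): one-way
  ANOVA on absolute deviations from each group's median. The
  drop-most-variable retest removes the group with the largest sample
  variance (ties broken toward the first label in sorted order) and
  re-runs the test.

α = 0.05 throughout, two-sided, no multiple-testing correction. The
Brown–Forsythe test is known to be mildly conservative (empirical level
slightly below nominal, increasingly so with more groups); the calibration
check therefore uses the two-group case, where the empirical level sits
closest to nominal. scipy's implementations of both tests serve as
independent cross-checks in the unit tests.

`PolynomialReactionNorm` wraps the fit/compare/select chain as a
scikit-learn estimator (`fit`, `predict`, `get_params`; fitted attributes
`order_`, `coef_`, `r2_`, `fits_`, `comparison_`, `selection_`) so it
composes with sklearn pipelines and model selection.

## Synthetic-data generators

No spectra or photographs were deposited, so generators stand in for every
input, with known ground truth and all randomness drawn from one seeded
`numpy` generator per call.

**Viewer fixture.** Receptor sensitivities are visual-pigment nomogram
templates (A1 alpha + beta band) peak-normalised to 1, with λmax defaults
371/448/503/563 nm for UV/SW/MW/LW and 563 nm for the double cone — a
plausible UVS-passerine arrangement, configurable, and never claimed to be
measured blue-tit curves. A plain Gaussian shape is available behind the
same interface. Because the true sensitivity tables of the original
analysis are unrecoverable, all JND outputs are fixture-dependent and no
printed JND from the original dataset is a reproduction target.

**Dowels.** The achromatic series is spectrally flat at reflectance
levels Bl/BW1/BW2/BW3/Wh = 0.05/0.15/0.30/0.50/0.80 (monotone double-cone
catches, spanning near-black to white). The green endmember is a low
baseline plus a Gaussian bump at 550 nm; the brown endmember is a
monotone logistic ramp toward 700 nm whose amplitude is set so the two
endmembers are approximately luminance-matched to the fixture viewer
(achromatic JND ≈ 0) while clearly differing in colour — the isoluminant
design condition of the colour experiment. Paint mixtures are convex
combinations of the two endmembers.

**Cohorts.** Each larva's true response is a polynomial reaction norm of
its dowel's stimulus summary (relative double-cone luminance, or chromatic
greenness) plus independent Gaussian noise (SD 0.05 on the luminance
scale; 0.012 on the greenness scale in the pipeline chains) and an
optional box-level offset (default SD 0: the default generator attributes
all variation to individuals; box effects are a parameter for nested-
design studies). The default luminance norm is the cubic
`f(x) = 0.5 + 0.3(x − 0.5) + 4(x − 0.5)³` — steep near the extremes,
shallow at intermediate luminance. Larval reflectance spectra are
reconstructed by blending two endmember spectra (black/white flats, or the
brown/green pair) with the blend weight solved by monotone bisection
(tolerance 10⁻⁹) so the spectrum's visual-model summary equals the
simulated response; responses outside the achievable range clamp to an
endmember. Design defaults follow the study: 25 larvae per box, 3 boxes
per treatment (5 for the two-treatment colour experiment).

**Specialiser mixtures.** In heterogeneous environments each larva
independently specialises green with probability `p_green`, brown
otherwise, and draws its photographic greenness from that component's
normal distribution — components at 38% and 56% greenness with SD 3, six
generator-SDs apart, and deliberately **no** intermediate component. This
encodes the qualitative signature under test: cohort mean greenness tracks
`p_green` while mixed treatments have inflated between-individual
variance.

**Images.** Photograph fixtures are linear-light arrays with six specimen
patches at stated RGB values and an 18% grey patch, under a global
per-channel gain (the unknown cast the calibration must undo) and optional
Gaussian pixel noise.

What the generators do **not** emulate: radiometrically realistic paint or
bark spectra, spatial texture and patterning, specular highlights, camera
sensor effects beyond linear gain + noise, developmental dynamics of
colour change, and observation error in the spectrometer beyond what the
resampling/cleaning steps absorb. Passing tests therefore demonstrate that
the machinery is correct and that the qualitative signatures are
recoverable under the stated noise model — not that any particular
biological dataset would yield particular values.

## Problem sizes and numerical choices

The shipped verification runs use: 1,000 random catch pairs and triples
for the metric checks; 200 replicate cohorts (5 treatments × 3 boxes × 20
larvae) for cubic-norm recovery; 5,000 two-group null simulations (n = 50
per group) for test calibration; 100 replicate five-treatment mixture
cohorts for the variance-signature power check; and duplicate full runs of
all four experiment chains for determinism. Tolerances: 10⁻¹⁰ for oracle
agreement, 10⁻¹² for closed-form and geometric identities, 10⁻⁶ for the
photographic round trip, ±0.01 for Monte-Carlo rejection rates.

Other numerical conventions: bisection tolerance 10⁻⁹ on blend weights;
relative-catch normalisation requires strictly positive totals; category
boundaries are closed on the middle interval; variance ties in the
drop-retest break deterministically by sorted label; all result tables are
written with a fixed float format and sorted keys so identical
config + seed reruns are byte-identical.

## Known limitations

* JNDs depend on the sensitivity fixtures; they are internally consistent
  but not comparable to values computed with other sensitivity tables.
* The nested ANOVA's equivalence to the mixed model holds for balanced
  designs; strongly unbalanced box structures would need true REML, which
  is out of scope.
* "Visual fit" of reaction-norm curves is not automated; order selection
  is purely the sequential F rule.
* The photographic pathway assumes the grey standard and specimen share
  the illuminant, and that linearisation is known; raw camera response
  recovery is out of scope.
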
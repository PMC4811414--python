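# Methods

This note documents the models, conventions and defaults behind
`colourpref`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Colour representation

All statistics run on CIE LCh, the cylindrical form of CIE 1976 L\*a\*b\*.
The Lab transform uses the standard compressive nonlinearity
f(t) = t^(1/3) for t > (6/29)³ and f(t) = (841/108)·t + 4/29 below, with
L = 116·f(Y/Yn) − 16, a = 500·(f(X/Xn) − f(Y/Yn)), b = 200·(f(Y/Yn) −
f(Z/Zn)). The reference white (Xn, Yn, Zn) is an explicit, required
parameter of every conversion: in the experimental setting it is the
measured white background the colour patches were shown against, not a
standard illuminant. Achromatic colours (a = b = 0) are assigned hue 0 by
convention; the convention is inert because categorisation never consults
the hue of a colour at or below the achromatic chroma cut-off.

Two input routes exist. Measured xyY chromaticity/luminance converts
exactly (X = x·Y/y, Z = (1 − x − y)·Y/y). Device RGB converts through a
`DisplayModel` — primaries' chromaticities, white point, transfer function
(sRGB piecewise curve or a pure gamma exponent) — with the 3×3 matrix
derived so that (255, 255, 255) maps exactly to the model's white point.
The default model is sRGB/D65. A display model is an *approximation* of
per-monitor colorimetry: photometric measurement of an actual display is
not reproducible in software, so reports carry a provenance note whenever
colours came through the RGB route, and measured xyY is always preferred
when both are present. Chromatic-adaptation transforms and gamut mapping
are out of scope.

## Hue categories

Hue angles are binned into eight chromatic categories (red, orange,
yellow, yellow-green, green, green-blue, blue, purple) plus achromatic.
Category arcs are half-open and lower-inclusive, [lo, hi): a hue at a
printed shared boundary (e.g. 40°, red/orange) belongs to the category
whose arc starts there. Lower-inclusivity is a package convention chosen
for a deterministic partition — published boundary tables do not state
inclusivity. The achromatic cut-off is C ≤ 5 (inclusive); prose
descriptions sometimes say "chroma < 5", but the tabulated "≤ 5" is taken
as normative. The scheme is data, not code: alternative schemes load from
JSON, and `validate_scheme` checks analytically that the chromatic arcs
partition the circle exactly once (no overlap, total width 360°).

## Bootstrap pairwise comparisons and letters

For one preference × context condition with observed category counts
(n participants, k = 9 categories), B = 100 000 resamples are drawn as
multinomial(n, p̂) from the empirical proportions p̂ — the resampling unit
is the individual categorical choice, and conditions are resampled
independently (no attempt to preserve within-participant correlation
across conditions). For each of the k(k−1)/2 = 36 unordered pairs the
percentile interval of p_i − p_j places tail mass α_c = α/(k(k−1)) =
0.05/72 on each side; a pair differs significantly iff the interval
strictly excludes zero.

Why tails of α_c each rather than α_c/2: a CI with tail mass α_c per side
has two-sided level 2α_c = α/36, which is the exact Bonferroni correction
for the 36 unordered pairs at familywise α = 0.05. This reading makes the
familywise error calibration come out at ≤ α by construction (verified by
simulation under a uniform null in the test suite), and it reproduces the
published letter pattern of the embedded fixture on 214 of 216 pairwise
calls. The two irreproducible calls both involve the red/blue pair in the
general conditions and sit exactly on a resampling knife edge: the
bootstrap difference distribution has an atom at zero whose CDF straddles
α_c within Monte-Carlo error, and in one case a zero observed count makes
the resampled difference non-negative with probability one. No percentile
convention resolves both, so the acceptance tests assert the robust
subset of the partition and leave the knife-edge pair unasserted.

Significance patterns are rendered as a compact letter display via
insert-and-absorb: starting from one group holding all categories, each
significant pair splits every group containing both members, subsets are
absorbed, and surviving groups receive lowercase letters in display
order. Sharing a letter is then exactly equivalent to "not significantly
different" (fuzz-tested against random significance patterns). Letter
*glyphs* depend on display order and are not comparable across software;
only the sharing structure is meaningful.

## Stuart–Maxwell test

Marginal homogeneity of a k×k paired contingency table is tested with
χ² = dᵀS⁻¹d, where d is the vector of row-minus-column marginal
differences with one category dropped and S is the covariance of d under
the null: S_ii = n_i· + n_·i − 2n_ii, S_ij = −(n_ij + n_ji). This
classical form is invariant to which category is dropped. Categories
carrying no off-diagonal information are removed first; if S is still
singular, a pseudo-inverse is used and the effective degrees of freedom
equal rank(S), otherwise df = k − 1. Note that some implementations (e.g.
statsmodels) estimate S without imposing the null, subtracting the
marginal-difference outer product; the statistics differ slightly in
finite samples. The 2×2 case reduces exactly to McNemar's
(b − c)²/(b + c).

## Wilcoxon signed-rank test

Zero differences are dropped and tied absolute differences mid-ranked;
V is the sum of positive-signed ranks. The two-sided p-value uses the
normal approximation Z = (V − n(n+1)/4) / σ with the tie-corrected
variance σ² = n(n+1)(2n+1)/24 − Σ(t³ − t)/48, without continuity
correction. For small untied samples an exact path enumerates the null
distribution of V by convolution (equivalent to all 2ⁿ sign patterns).

## Within-subject ANOVA

The 2 (preference) × 3 (context) fully within-subject ANOVA decomposes
each measure into main effects and interaction, each tested against its
own subject-interaction error term (MS_effect / MS_effect×subject).
Partial η² = SS_effect / (SS_effect + SS_error). Greenhouse–Geisser ε is
computed from the double-centred covariance matrix of the relevant
subject-by-level scores — context levels averaged over preference for the
context effect, per-context preference difference scores for the
interaction — as (Σλ)² / ((k−1)Σλ²), bounded to [1/(k−1), 1], and applied
multiplicatively to both degrees of freedom for the corrected p-value.
ε is always reported and applied for the 2-df effects regardless of a
sphericity pre-test; the 1-df preference effect has ε = 1 identically.
Sums of squares that are pure floating-point residue of exactly-null
effects (below 10⁻¹² of the total SS) are clamped to zero so constant
data yield F = 0 rather than a 0/0 artefact. Post-hocs are paired t-tests
on condition (or cell) means with p-values multiplied by the number of
comparisons and capped at 1.

## Picker engine

The simulator reproduces the sequential colour picker as a deterministic
state machine in CIELab. A session starts with nine palette patches (the
eight focal hues at L = 60, C = 60, plus mid-grey; the original starting
RGB values are appendix-only and these defaults are stand-ins). After the
single palette click, refinement frames surround the centre patch with up
to eight variations: ±L (lightness), ±C (radial chroma), and ±a / ±b (the
red–green and yellow–blue opponent axes) — the original tool's axes were
related to but not identical with Lab axes, and exact step sizes are
unrecoverable, so clean Lab moves are used. Every refine click (outer or
centre) multiplies all step sizes by the shrink factor; clicking the
centre refines without moving. Patches whose clipped difference from the
centre falls below the termination threshold are omitted; when none
survive, the centre is proposed as final, and clicking it reopens
refinement at the last visible step sizes.

Defaults: initial steps 25 Lab units per axis, shrink 0.85, termination
threshold 2.0, gamut modelled as the cylinder L ∈ [0, 100], C ≤ 128.
A slower shrink than the obvious 1/2 is deliberate: total travel per axis
is s₀/(1 − γ), and with γ = 0.5 the 50-unit budget cannot reach extreme
in-gamut targets (e.g. near-black) from the L = 60 palette, breaking the
convergence guarantee. With γ = 0.85 the budget is ≈ 167 units per axis.
Analytic bounds: at most ⌈log(threshold/s₀)/log γ⌉ = 16 refine clicks per
visit, and greedy zero-noise agents empirically finish within
threshold/(1 − γ) ≈ 13.3 Lab units of any in-gamut target (observed
maxima are below 2 units). Because every refine click shrinks the steps,
a non-reopening session always takes exactly 1 + 16 clicks with these
defaults; click-count variability in synthetic data therefore comes from
the generator's click model, not the zero-noise agent. Simulated
"seconds" are clicks × log-normal per-click latency and are never claimed
to model real reaction times.

Agents are greedy: at each frame they click the available patch (centre
included) minimising Euclidean Lab distance to a target colour, with
optional i.i.d. Gaussian noise on the comparisons; ties break on patch
order, and everything is deterministic given a seed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
per participant × preference × context:

* **Hue category** sampled from per-condition weights; defaults are the
  embedded published frequency table normalised by its n = 85. Hue is
  then uniform within the category's arc — published records give only
  category frequencies, so uniform is the maximum-entropy stand-in.
* **Lightness and chroma** from truncated normals (L on [0, 100]; C on
  (5, 128] for chromatic draws, so the sampled category is preserved;
  achromatic draws force C uniform on [0, 5]). Default means encode the
  qualitative published pattern — most-preferred wall colours light
  (L ≈ 75), t-shirt dark (L ≈ 42), general most-preferred chromatic
  (C ≈ 55) — with SDs of 10–20 units chosen as realistic within-condition
  spread; the exact values are stand-ins exposed in the config, not
  published quantities.
* **Associations**: object/concept/none probabilities per preference
  (defaults 0.55/0.25/0.20 for most, 0.20/0.33/0.47 for least), valence
  from truncated normals on [0, 45] (most, mean 18) and [−45, 0] (least,
  mean −18), missing exactly when no association is given. These encode
  direction (more and more object-based associations with positive
  ratings for liked colours), not figure-level magnitudes, which are not
  printed as numbers anywhere and are deliberately non-authoritative.
* **Process measures**: clicks = 1 + Poisson(mean − 1) with higher mean
  for most-preferred (18 vs 13); time = clicks × log-normal latency.

A second mode draws a target colour the same way and lets a (possibly
noisy) greedy agent navigate the picker, so final colours and click
counts arise mechanistically.

What passing tests show — and do not. Parameter recovery on generated
data (hue weights within binomial error at n = 850, correct lightness
ordering and interaction sign, valence sign separation) demonstrates that
the pipeline is an unbiased reader of data with this structure. It cannot
validate the generator's distributional assumptions against real
behaviour: real choices are correlated within participant across
conditions, hue is not uniform within categories, and valences are not
sign-separated by construction. Conclusions about real data rest on the
pipeline, not the generator.

## Problem sizes and determinism

Bootstrap runs use B = 100 000 resamples (as in the published procedure)
where a single condition is analysed, and B = 20 000 per replicate inside
the 500-replicate familywise-error simulation, where the corrected tail
(α_c ≈ 6.9·10⁻⁴) still leaves ≈ 14 resamples beyond the quantile;
parameter-recovery runs use 850 synthetic participants (ten times the
study's 85). All stochastic components take explicit seeds; a seeded run
is bit-reproducible, and the analysis report embeds seed, bootstrap size,
α, scheme and package version in its provenance block.

## Known limitations

* The bootstrap treats each condition independently; joint inference
  across conditions (e.g. the omnibus association models for correlated
  multinomial responses, or multilevel logistic regressions per hue) is
  out of scope.
* The display model cannot recover per-monitor colorimetry; RGB-route
  conversions are flagged approximations.
* Letter displays are minimal for the insert-and-absorb order used but
  not guaranteed globally minimal in letter count.
* The exact Wilcoxon path requires untied absolute differences.
* The picker's step schedule and palette are plausible reconstructions,
  not measured instrument parameters.
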
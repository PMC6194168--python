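# Methods

## The measurement problem

A participant rates the emotional valence of unimodal and bimodal stimuli on
a bounded bipolar scale (−100…+100). Functional measurement treats each
rating as the output of three maps: valuation (physical stimulus Φ →
subjective value Ψ), integration (several Ψ → one internal response), and a
response map onto the scale. The design crosses an audio factor (five voice
morphs from anger to joy) with a tactile factor (three air-jet intensities),
keeps both unimodal margins, and repeats every cell six times — 23 cells,
138 trials per subject. The package estimates the valuation (marginal-mean
Ψ), diagnoses the integration rule from the factorial geometry, and fits the
averaging model per subject.

## Integration rules and their signatures

For a cell with active cues i the candidate rules are

- averaging: R = (w₀s₀ + Σ wᵢsᵢ) / (w₀ + Σ wᵢ)
- adding:    R = w₀s₀ + Σ wᵢsᵢ
- multiplying: R = w₀s₀ + 100·Π(sᵢ/100) (a package convention keeping the
  product in rating units; the rule is simulated but never fitted)

Both averaging (with equal weights) and adding are additive over the bimodal
subdesign, so both predict parallel bimodal lines (zero interaction). They
separate on the unimodal line: under adding, a cue's contribution has the
same sign everywhere, so the unimodal line sits on one side of each bimodal
line; under averaging with near-neutral unimodal values the single cue is
pulled toward the scale midpoint, making the unimodal line *cross* the
bimodal fan. The decision table is: parallelism supported + crossover →
averaging; parallelism supported, no crossover → adding; parallelism
rejected → inconclusive (differential weighting flagged).

### Crossover detection

The detector compares the unimodal line with each bimodal line at the shared
abscissa points, ignores differences within a tolerance τ (default 1 rating
unit) of zero, and counts sign changes of the remainder. A line counts as
crossed only when its clear signs change **exactly once** — a single
monotone crossing, which is what the averaging geometry produces. Alternating
signs (two or more changes) are classified as noise around zero; without
this rule, cohorts generated by a pure adding rule acquire false "crossover"
verdicts whenever the neutral tactile line hovers at ±τ.

## Repeated-measures ANOVA

Implemented with orthonormal within-subject contrasts: for an effect with
contrast matrix M, per-subject scores z = M′y give SS_effect = n‖z̄‖²,
SS_error = Σ‖z − z̄‖², df = (d, d(n−1)) — identical to the classical
effect × subject partitioning. Greenhouse–Geisser ε = tr(S)²/(d·tr(S²)) with
S the score covariance; corrected p uses F at (εd₁, εd₂); ε is clipped to
[1/d, 1]. Partial η² = F·df₁/(F·df₁ + df₂). Huynh–Feldt is deliberately not
implemented. Zero-error-variance inputs return an explicit degenerate flag
instead of an F ratio. The study's two factorial "views" are reproduced: the
audio view treats the audio-unimodal margin as a fourth tactile level (5×4),
the tactile view treats the tactile margin as a sixth audio level (6×3); the
parallelism test drops both margins (5×3). Printed degrees of freedom in the
source literature are occasionally inconsistent with this design (e.g. an
interaction reported with df₂ = 120 where the layout gives 220); the package
always computes dfs from the data.

## Fitting the averaging model

Per subject, over the 23 cell means, least squares on

    minimize Σ_cells (mean − R(cell; θ))²

with θ = (s₀, w_audio, w_tactile, 5 audio scales, 3 tactile scales) for the
equal-weight model (EAM; 11 parameters) or per-level weights for the
differential variant (DAM; 17). Identification: weights are ratio-scale
(scaling all weights including w₀ changes nothing), so w₀ is pinned to 1;
ratios and importances are invariant to that choice (tested by re-fitting
under w₀ = 2.5).

Numerical strategy — variable projection: with the weights fixed, the scale
values enter linearly, so the outer optimizer (L-BFGS-B, bounds [0, 10],
20 Latin-hypercube restarts, seeded, sse tolerance 1e−10) searches weight
space only and an inner bounded linear solve recovers the scales. Bounding
the inner solve matters: with unbounded scales the averaging model contains
the adding model in its closure (w → 0, s → ∞ with w·s finite makes the
denominator constant), and the fit of adding-rule data becomes vacuously
perfect. Scales are bounded to ±150 — 1.5× the rating bound: wide enough
that estimation noise around near-extreme true values is not truncated
(truncation biases the residual ANOVAs), tight enough that mimicking an
adding pattern forces a detectable set-size misfit. Boundary weight
solutions (w = 0) are representable because the constraint is a box, not a
reparameterization. All-constant data leaves weights unidentified and
returns an explicitly degenerate result.

Unimodal margins are required: on bimodal cells alone the denominator is
constant and the weights are not identifiable at all.

### Model selection and goodness of fit

BIC = n·ln(sse/n) + k·ln(n) with n = 23 cells and k the structural
parameter count (the pinned w₀ excluded; the σ² term cancels in
comparisons). sse is floored at 1e−8 so noiseless ties resolve by parameter
count. Two caveats are inherent to a 23-cell BIC: the EAM-vs-DAM sse ratio
under EAM truth is scale-free in the noise level, so the EAM selection rate
is ≈80% at any nonzero noise and reaches 100% only toward the noiseless
limit; and it is statistically flat in the number of repetitions (cell means
are the fitted observations regardless of how many trials produced them).

Goodness of fit follows the residual-ANOVA convention: subtract each
subject's fitted predictions from their cell means and run the two factorial
views on the residuals; the model is retained when no effect is significant.
Because the per-subject fit absorbs 11 of 23 cell degrees of freedom, these
tests are conservative — calibration on equal-weight cohorts sits at or
above the nominal 95% pass rate.

## Clustering and population statistics

Subjects are clustered on their 23-vector of cell means (canonical cell
order) with centroid-linkage agglomerative clustering on Euclidean
distances; k is always a user decision, supported by the merge-height
profile — the package never auto-selects it. Standardizing cells across
subjects is available but off by default.

Effect sizes follow the conventions of the source literature: paired
d = t/√n, independent d = t·√(1/n₁ + 1/n₂), with confidence intervals from
inverting the noncentral-t CDF in the noncentrality parameter and rescaling
to d units. Fiducial limits treat the post-data effect as
δ = mean_diff + se·T(df): the two-sided magnitude limit is the smallest L
with P(|δ| < L) = level (by root-finding on the CDF difference), the
one-sided lower limit is mean_diff + se·t_{1−level}. Bonferroni corrections
always take an explicit family size.

## The synthetic world

`make_paper_like_config` states the cohort the pipeline is exercised on:
23 subjects, an 80/20 mixture of audio-dominant (wA:wT = 1.5:0.5, ratio 3)
versus balanced (1.0:1.2) equal-weight averagers, w₀ = 1, s₀ ~ N(0, 5),
audio scale values −100/−50/0/+50/+100 and tactile +80/0/−90 (full-range,
near-neutral midpoints — the configuration in which the crossover signature
is expressible), between-subject jitter of 10% CV on weights and 8 rating
units on scales, Gaussian i.i.d. trial noise (default SD 10, matching
printed cell SDs) applied before clipping at ±100. Weight magnitudes are
anchored on the *ratio* scale because absolute "units of weight" in the
source analyses depend on that software's internal normalization. For the
adding rule the weights shrink (0.6/0.25 and 0.35/0.45) so latent responses
stay inside the scale and clipping cannot fake non-additivity. The generator
does not simulate reaction times, order or block effects, drift, or
subject-level variance components estimated from real data — population SDs
are package defaults, so a green recovery or calibration test establishes
internal consistency of the method on its stated world, not fidelity to any
particular participant sample.

Clipping at the bounds mimics a track bar pinned at its ends and biases cell
means toward zero for cells whose latent response approaches ±100; the
default world keeps latents inside the bounds except in the tails of the
noise distribution.

## Known limitations

- Weight recovery at trial-noise SD 10 with 6 repetitions is information-
  limited: the Cramér–Rao bound for the audio:tactile weight ratio in this
  design is ≈20–30% relative SE per subject, so median recovery errors of
  ~20% are the attainable floor, not an optimizer deficiency (the fitter is
  verified to reach sse at or below the truth-weight profile).
- The cell-mean BIC is weak evidence at 23 cells (see above); importance
  profiles and weight ratios are the robust per-subject summaries.
- Ratings are treated as continuous; any instrument quantization is ignored.
- Missing cells are flagged, and fitters refuse incomplete subjects rather
  than imputing.
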
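# Methods

## Model and assumptions

The unit of analysis is the eye. Each eye contributes one longitudinal
series per index — structural (global or sector RNFLT, µm) and functional
(SAP mean sensitivity, dB) — observed at visits t₀ = 0 < t₁ < … (months from
baseline). Progression on one index is modelled as a linear trend,
yᵢ = a + b·tᵢ + εᵢ with i.i.d. Gaussian errors, fitted by ordinary least
squares over the first k visits for each analysed series length k. The
worsening test is one-tailed: p = P(T_{k−2} ≤ b̂/SE(b̂)), so a truly stable
eye produces a Uniform(0, 1) p-value and the single-index test holds its
nominal specificity exactly under the model. Fits across series lengths are
independent refits of nested prefixes; no sequential or multiplicity
adjustment across lengths is applied, because specificity is fixed per
length, not familywise.

Time is calendar time (months from baseline) by default because real series
are unequally spaced; a visit-rank axis can be used by constructing
`EyeSeries` with ranks as times. Affine changes of time unit leave t, df and
p unchanged and rescale slope and SE together. No aging correction is
applied: the progression definition is deterioration relative to a flat
baseline, not relative to expected age-related decline.

Degenerate series are resolved as t-test limits: a perfect fit (zero
residual variance) yields p = 0 when the slope worsens, 1 when it improves,
0.5 when exactly flat; prefixes shorter than 3 visits or with zero time
variance are errors, never silent NaNs.

## Joint criteria and calibration

A criterion is a finite boolean tree whose leaves are per-index trend tests
and whose internal nodes are ALL (conjunction) or ANY (disjunction) over at
least two children; duplicate leaf indices are rejected. All leaves share
one marginal significance level α, and a leaf fires on strict inequality
p < α. Under the null with independent leaves, the firing probability is
computed exactly by recursion (ALL: product; ANY: complement of the product
of complements). Calibration solves firing(α) = 1 − S for the target
specificity S: closed forms for flat trees, otherwise bisection on the
strictly increasing polynomial to an α-tolerance of 1e-13 (the round-trip
firing probability is reproduced to better than 1e-10, which the property
tests assert for random trees).

A single shared α is used for all leaves — per-leaf weighting is a
deliberate non-feature, matching how the published calibration table is
stated. Independence of leaf p-values under the null is the calibration
assumption; with positively correlated structural/functional noise the
realised specificity of an ALL rule rises above nominal and that of an ANY
rule falls below it. The simulator exposes a noise-correlation parameter so
users can quantify this for their own noise model; no universal bound is
asserted.

One arithmetic note: at a naive per-leaf α = 0.05 the two-index rules have
specificities 1 − 0.05² = 99.75% (ALL) and (1 − 0.05)² = 90.25% (ANY). A
figure of 89.75% sometimes quoted for the ANY rule corresponds to adding
rather than subtracting the intersection term in inclusion–exclusion and is
inconsistent with the ANY calibration α = 1 − S^(1/k); this package reports
the inclusion–exclusion value.

## Mean sensitivity

Pointwise 24-2 sensitivities are converted to the linear
differential-light-sensitivity scale as 10^(dB/10), averaged, and converted
back: MS = 10·log₁₀(mean 10^(dB/10)). Linear-scale averaging weights deep
defects less than arithmetic dB averaging, so MS is always ≥ the arithmetic
dB mean (Jensen, concavity of log). The two blind-spot-adjacent locations
(±(15, 3) and (15, −3) in right-eye coordinates) are always excluded,
leaving 52 informative points; a global MS requires all 52 unless partial
grids are explicitly allowed. Sensitivities below 0 dB are clamped to 0
before linearisation (perimeter floor; optionally rejected instead). Left
eyes are mirrored to right-eye orientation (x → −x) before sector lookup so
a single canonical sector map suffices.

Sector definitions: the optic-disc sector assignment (IT, ST, T, N, IN, SN)
ships as an editable CSV transcribed from the published Garway-Heath map —
the figure-to-table transcription is ours and users with their own
transcription can load it via `sector_map_from_csv`. The "central" region is
the 16 points with |x| ≤ 9° and |y| ≤ 9°. Reliability screening fails a
field when false positives, false negatives or fixation losses reach 33%
(strict "< 33%" criterion), failing closed on missing metrics.

## Evaluation metrics

Positive rate is 100·(flagged/n) with a Wilson score 95% CI by default
(Clopper–Pearson optional) — Wilson because rates near 0%/100% occur
routinely at short series lengths and Wald intervals degenerate there.
Agreement is Cohen's unweighted kappa on the 2×2 cross-classification, with
the conventional bands (slight ≤ 0.20, fair ≤ 0.40, moderate ≤ 0.60,
substantial ≤ 0.80, almost perfect ≤ 1); kappa is reported as undefined
(NaN, logged) when both classifications are constant and identical.
Time-to-detection uses the product-limit estimator: the event is the first
analysed series length k at which a criterion flags the eye, timed at that
k-th visit's month; never-flagged eyes are censored at their last analysed
visit; the median is the earliest time with survival ≤ 0.5 and is undefined
when the curve never crosses it. Timing at the flagging visit (rather than
the midpoint of the detection interval) is a documented convention choice;
eyes are treated as independent units even when patients contribute two.

## Synthetic cohorts

The generator draws, per eye: visit intervals uniform on a configured range
(default 3–9 months, giving ~4 years over 9 visits, inside the 2–36-month
spacing window the QC filter enforces); per-index baselines (defaults
RNFLT 85 ± 10 µm, MS 27 ± 2 dB); progression status (a configured fraction,
with slopes drawn per index from truncated-at-zero Gaussians, defaults
−0.15 ± 0.05 µm/month and −0.05 ± 0.02 dB/month); and Gaussian measurement
noise (defaults 2 µm and 1 dB), independent across visits, equicorrelated
across indices within a visit by ρ (default 0). All defaults are invented,
clinically plausible scales — not estimates fitted to any cohort. A single
seeded generator drives everything; identical seeds give identical cohorts.

What this emulates: the series structure, noise-limited trend detection, and
the null behaviour the calibration relies on. What it does not: floor
effects in either index, autocorrelated or heteroscedastic noise,
visit-density informative of disease, correlated fellow eyes, and
co-occurrence of structural and functional progression beyond noise
correlation. Passing specificity tests therefore demonstrates correctness of
the calibration arithmetic under the stated model, not robustness to those
real-data departures.

Problem sizes used in the validation harnesses: 10,000 simulated eyes for
empirical-specificity checks (binomial SE ≈ 0.22% at S = 95%, so a 3·SE
acceptance band of ±0.65%), 5,000 series for p-value uniformity
(Kolmogorov–Smirnov at the 0.01 level), and 10⁶ uniform draws per tree for
Monte-Carlo verification of nested-tree calibration.

## Input handling

Cohort CSVs are normalised to a long schema (eye_id, visit, month,
index_name, value). A column map accommodates arbitrary layouts, including
wide per-visit rows with one column per index and separate ISO-8601 test
dates per modality; dates become fractional months from each eye's first
visit (mean Gregorian month, 30.4375 days). Optional QC excludes whole eyes
— never silently — for insufficient visits (default minimum 9), consecutive
spacing outside 2–36 months, or same-visit structural/functional tests more
than 30 days apart; every exclusion is reported with its reason and logged,
and retained + excluded counts always reconcile with the input. The
assessment path is fully deterministic; randomness exists only in the
simulator.

## Known limitations

Calibration is exact only under cross-index independence of null p-values;
the Gaussian-error OLS t-test is the model, so heavy-tailed measurement
error will shift realised specificity; kappa between criteria sharing an
index is inflated by construction (the shared test appears in both rules);
and the survival analysis treats detection-interval timing coarsely (visit
resolution). Event-based (guided progression analysis style) leaves and
permutation-of-residuals p-values are out of scope.
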
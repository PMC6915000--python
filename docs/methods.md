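# Methods

## Model

The symmetry function (SF) compares two cyclic joint-angle waveforms on a
common percent-cycle grid:

SF(t) = (x₁(t) − x₂(t)) / (0.5 · (Range(x₁) + Range(x₂))) · 100%,
t ∈ {0, 1, …, 100} %CT.

Range(x) is read as the *scalar* max − min of the curve over the whole
cycle, so the denominator is a constant per comparison. This is the only
reading under which the index's defining properties hold: a constant 1°
side difference maps to exactly 20% at mean ROM 5° and 2% at mean ROM 50°,
and equal-range curves spanning [0, R] and [−R, 0] with simultaneous
opposite extremes reach exactly ±200%.

Assumptions: both curves describe the same joint and degree of freedom in
degrees, each covers exactly one gait cycle (initial contact to initial
contact of the same foot), and cycle segmentation happened upstream. SF is
invariant to a common additive shift and to a common positive scaling of
both curves; adding δ to one side only shifts SF by the constant
δ/(0.5·(r₁+r₂))·100. These identities double as test oracles.

### Sign conventions

Sign = first curve minus second. The three comparison modes fix the order:
right − left for healthy left/right comparison, uninvolved − involved for
patient side comparison, and normative reference − involved for patient
versus norm. Positive SF therefore always means "first/reference side
dominates".

### Degenerate ranges

SF is a ratio index and blows up as the mean ROM approaches zero. When
0.5·(r₁+r₂) < 1e-6°, `symmetry_function` raises `DegenerateRangeError`
instead of returning a huge finite value; the CLI maps this to exit
code 3. The 1e-6° threshold is far below any measurable joint excursion,
so it only catches genuinely constant traces.

## Time normalization

Cycles are resampled to 101 points (1%CT step) by local Lagrange
interpolation: for each grid time, the 4 nearest samples define a cubic
interpolant evaluated in barycentric form. Local windows (clamped at the
cycle ends) were chosen over a single global polynomial, which oscillates
badly (Runge) at ~100 samples. The evaluation is anchored at the window's
first value so that constants are reproduced exactly and evaluation at a
time bitwise-equal to a sample time is bit-identical to that sample;
cubic exactness holds for polynomial traces, and a 120 Hz sine over a
1.1 s cycle is reproduced to better than 1e-4°. No detrending or
smoothing is applied — within one cycle, the waveform is the signal.
Grid endpoints are pinned to the first and last samples of the cycle
(0 and 100%CT).

## Parameterization and phase localisation

Every curve (angle or SF) is summarised by Peak^min, Peak^max, their times
t_min/t_max in %CT (first occurrence on the grid breaks ties, ascending),
and ROM = Peak^max − Peak^min. Peak times are mapped to Perry's phases —
LR 0–10, MSt 10–30, TSt 30–50, TDSt 50–60, ISw 60–73, MSw 73–87,
TSw 87–100 %CT — treated as half-open intervals [start, end) with 100%CT
assigned to TSw; initial contact (0–2%CT) overlaps LR and is reported as a
flag rather than a ninth phase. Asymmetry is classified from the SF
parameters: the default statistic is max(|Peak^min|, |Peak^max|) (a
`mean_abs` alternative is provided), with symmetric < 10% ≤ borderline
< 15% ≤ asymmetric.

## Aggregation

Angle parameters are extracted per cycle, averaged within subject, then
summarised as mean ± unbiased SD across subjects — subjects are weighted
equally regardless of cycle count; single-subject cells report SD as
missing with n = 1 visible. Peak times are averaged linearly in %CT (no
circular statistics), which can smear peaks that sit near the cycle
boundary; this limitation is documented rather than resolved.

Cohort SF supports two aggregation modes, and they genuinely differ: *per
subject* (SF per cycle pair matched by cycle index, SF curves averaged
within subject, then parameterized — peaks of averages) and *mean curve*
(SF of the ensemble-mean side curves). Neither is canonical; reports carry
both. In patient-vs-norm mode the reference is the ensemble mean of all
normative curves for the joint, compared against each patient cycle.

## Statistics

Side comparisons use paired t-tests (both limbs of the same subjects);
group comparisons use Welch's two-sample t-test, preferred over the pooled
variant because patient cohorts show visibly larger variance than
controls. α = 0.05 throughout, no multiple-testing correction (one test
per parameter is reported as-is). Each sample is screened with
Shapiro-Wilk; a failure flags the result as "parametric assumption
violated" but does not switch to a nonparametric test — the protocol is
deliberately parametric and the flag is informational. Identical
zero-variance samples, where the t statistic is 0/0, are reported as
t = 0, p = 1. The paired pipeline's type-I error at n = 12 is calibrated
to [0.04, 0.06] over 10⁴ null replicates in the acceptance suite.

## Synthetic gait generator

Templates are truncated Fourier series (≤ 6 harmonics, here 1–2 per
joint), periodic over the cycle by construction. Normal-group defaults are
calibrated to slow-walking adult magnitudes: hip ROM ≈ 42° (min ≈ −7° in
terminal stance, max ≈ +36° near terminal swing), knee ROM ≈ 60° (swing
flexion peak), ankle ROM ≈ 29°, pelvic tilt ROM ≈ 1° about a 7.4°
anterior-tilt baseline with the double oscillation per stride. The ~1°
pelvic range mirrors the calibration targets for the speed-matched
control group this generator emulates; a literature-typical ~3° pelvis is
available via `pelvis_rom="typical"`.

Asymmetry mechanisms applied to one side: amplitude scale *about the
template mean* (separable from offset by construction), phase shift in
%CT (|shift| < 50), constant offset in degrees, and iid Gaussian
measurement noise on both sides. Each mechanism has a closed-form SF —
offset: constant δ/r·100; scale a: 100·(a−1)·(x(t)−x̄)/(0.5·(a+1)·r);
phase shift Δ: 100·(x(t)−x(t−Δ))/mean range — which the pipeline must
reproduce to 1e-9 at zero noise. For those exactness checks the cycle is
sampled commensurately with the %CT grid (1 s cycle, 201 samples) so that
resampling is node-exact; the default sampling (120 Hz, 1.1 s cycle,
off-grid) emulates a real capture system and is used everywhere else.

Presets draw subjects with 5% CV on template amplitudes plus documented
jitter on each asymmetry field. `normal` produces near-symmetric gait
(median per-subject peak |SF| well under the 10% threshold for every
joint). `uTHR` is calibrated to the early post-operative pattern: hip ROM
reduced to ≈19° uninvolved / ≈12.6° involved with a ~16%CT timing shift
and a small involved-side elevation; pelvic tilt baseline raised to
≈16.4° with ≈4.8° ROM and a ≈49%CT (near-antiphase) shift between sides —
which is what drives pelvic SF peaks of roughly ±100%, the largest of any
joint; knee and ankle ranges are larger on the involved side (≈46 vs 34°
and ≈40 vs 30°). Cohort sizes in examples and tests follow the emulated
study: 12 patients vs 13 controls, 9 cycles (3 trials × 3 cycles) each by
default; the acceptance suite uses 3 cycles per subject to keep runtimes
comfortable, which leaves the cohort-level ordering unchanged.

What the generator does *not* emulate: inter-cycle waveform variability
beyond white noise (real gait has correlated, phase-dependent variance),
cycle-duration variability, marker/soft-tissue artefacts, and any
kinetics. Passing tests therefore demonstrate correctness of the
*pipeline* under known ground truth, not clinical validity on real
motion-capture data.

## Numerical choices

- Grid: 101 points, float %CT; all curve lengths validated before SF.
- Extreme-time ties: first occurrence, ascending %CT.
- Degenerate SF denominator: error at 1e-6° (see above).
- SD: ddof = 1 everywhere; pointwise ensemble SD of a single curve is 0.
- CSV: UTF-8, '.' decimal, '\n' line endings; floats parsed with the
  round-trip parser so write→read is bit-exact.
- Determinism: every stochastic routine takes a seed (or Generator);
  identical seeds give identical cohorts across runs.

## Known limitations

SF is not normalised across joints — values are only comparable within
one joint and degree of freedom, and small-ROM joints (pelvic tilt)
produce large SF from small absolute differences; report the absolute
difference alongside. Peak-time averages near the cycle boundary are
linear, not circular. Gait-event detection, 3D kinematic modelling and
C3D ingestion are out of scope: the package starts from segmented
joint-angle cycles.
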
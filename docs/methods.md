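# Methods

This note records the models, conventions and numerical choices behind
the package, the way an analysis library should: what is computed, what
was genuinely open and how it was decided, and what the synthetic data
do and do not establish.

## Randomness indices

A sequence is an ordered list of digits from a finite alphabet
(default 1–9, length ~100). Erroneous responses are excluded upstream;
only retained responses are scored.

**Turning points.** A pair direction is the sign of the step between
consecutive responses. Ties (equal neighbours) carry the last non-zero
direction forward, so a plateau can host at most one turn, recorded at
its far end; this matches the classical turning-point definition
extended to sequences with ties and keeps the index defined on real
data, where repeated digits are common.

**TPI normalization.** The Turning Point Index is the observed count as
a percent of the iid-uniform expectation. For continuous data the
expectation is (2/3)(n−2), but digits from an alphabet of size A tie
with probability 1/A, and under the carry-forward rule the exact
expectation is

    E[T] = (2A−1) / (3(A−1)) · ((n−1)(A−1)/A − 1),

which recovers (2/3)(n−2) as A → ∞. Derivation: compressing tie runs
leaves a Markov chain whose next state is uniform on the other A−1
digits; a stationarity argument gives a per-interior-position turn
probability of (2A−1)/(3(A−1)), and the expected number of interior
compressed positions is (n−1)(A−1)/A − 1. For n=100, A=9 this predicts
61.625 turns; simulation over 20,000 uniform sequences gives 61.624.
The discrete form is the default because it is what makes the index a
calibrated percentage — uniform random sequences average exactly 100.
`expectation="continuous"` selects the classical form, and `expected_n`
pins the expectation to a nominal length instead of the realized one
(both lengths 100–110 occur when participants make errors; the realized
length is the self-consistent default).

**Other indices.** Adjacency counts ascending and descending ±1 steps
jointly, with no 9↔1 wraparound. The Runs index is the n−1 sample
variance of the gaps between consecutive turning points; segments before
the first and after the last turning point are not phases and are
excluded; with fewer than three turning points the index is undefined
and reported as missing (later group-mean imputed). Redundancy is
100·(1 − H/log₂A) with H the empirical Shannon entropy (0·log 0 ≡ 0).
The Coupon scan restarts after every completed pass through the
alphabet; with no completed pass the sequence length is returned with a
`coupon_complete=False` flag (a censored maximum — the participant never
used all alternatives). The Mean Repetition Gap uses positional distance
(immediate repeat = 1) by default; `convention="intervening"` counts
intervening responses instead (immediate repeat = 0).

**Summary scores.** The inhibition score (z(TPI) − z(Adjacency) +
z(Runs))/3 and updating score (−z(RI) − z(Coupon) + z(MRG))/3
standardize their ingredients before averaging because the raw indices
live on incommensurable scales (percent, variance, counts); the
reference sample for z is injected by the caller so the referencing
scheme remains a downstream decision. Note the sign with which Runs
enters: higher phase-length variability counts as better inhibition.
That is the printed convention of the index family and is implemented
as such, though its direction is less intuitive than the other terms.

## Task measures

Six further measures come from five tasks: Stroop interference
(color − colorword)/color (may be negative; retained), 2-back correct
decisions, plus–minus shifting cost C − (A+B)/2 (symmetric in the two
baselines), verbal-fluency total over six conditions (three phonemic,
three semantic; repetitions/errors excluded upstream), and two WCST
scores taken as given — the perseverative-error percentage (flexibility)
and the non-perseverative error count (inhibition). Card-by-card WCST
administration is deliberately out of scope: deck sequence and feedback
protocol are administration details, not scoring ones.

Each measure carries a declared orientation flag (higher-is-better or
higher-is-worse), so the minus signs in the composite formulas are data,
not code.

## Composites

Three steps: (1) z-score the eight measures against the reference
sample (n−1 SD convention throughout); (2) average the relevant z's with
orientation signs — inhibition over {RNG-inhibition, Stroop, WCST
non-perseverative errors}, shifting over {WCST error score, plus–minus,
fluency}, updating over {2-back, RNG-updating}; (3) z-score the mean
composites again against the same reference. Under the younger-reference
scheme both references are the younger group, making younger composites
mean 0 / SD 1 and older scores read as deviations from the young norm;
under the pooled scheme both are the whole sample.

The WCST ingredient of the shifting composite is configurable. The two
WCST scores are assigned to flexibility (perseverative %) and inhibition
(non-perseverative count) by the task description, yet the printed
shifting formula names the non-perseverative score; the default
(`corrected`) follows the task-level assignment and `literal` reproduces
the printed formula. The discrepancy is surfaced rather than silently
resolved.

Missing cells (the study design contains four) are replaced by the mean
of the participant's age × genotype cell *before* step-1 z-scoring (the
ordering is not dictated anywhere; imputing raw measures keeps the
imputation scheme independent of the referencing scheme). Imputation is
idempotent and preserves group means exactly; a cell whose whole group
is missing on a measure is an error.

## Statistics

Standard tests are delegated to scipy behind the module surface
(pooled/Welch t from summaries via `ttest_ind_from_stats`, Mann-Whitney
with tie-corrected normal approximation, Pearson χ² without continuity
correction, Shapiro-Wilk, mean-centered Levene). Two-group contrasts
are computed first-minus-second (younger − older in the pipeline).

The mixed (split-plot) ANOVA is implemented directly. The between
stratum is a one-way ANOVA on subject means (scaled by the number of
within levels), testing group against subject-within-group. The within
stratum works on deviations from subject means with sum-to-zero coding
and model-comparison sums of squares, i.e. Type III — the convention of
mainstream ANOVA GUIs — so unequal group sizes are handled the way
practitioners expect. With one between and one within factor the
between-stratum SS agree with any type; the within-factor SS can differ
from weighted-means implementations (pingouin's, for instance) by design.
Cross-checks in the test suite: hand sum-of-squares decomposition on a
balanced toy (1e−10), exact agreement with pingouin for the group and
interaction effects, and a null simulation showing the group test's
type-I rate at α=.05 stays within [0.036, 0.064] over 1,000 cohorts.

Sphericity uses the pooled within-group covariance of the within levels
(the split-plot convention), orthonormalized contrasts, Mauchly's W with
the standard χ² approximation on df = w(w−1)/2 − 1, Greenhouse-Geisser
ε from the contrast-covariance eigenvalues and the Huynh-Feldt
small-sample adjustment ε̃ = (Nbε̂ − 2)/(b(N − g − bε̂)) capped at 1
(b = w−1, g groups). In the study design (N=100, g=6, w=3) this formula
maps ε̂ = 0.886 to ε̃ = 0.950, matching the published pair for that
design. Corrected p values multiply both df by ε; for F > 1 the
correction can only be conservative (for F < 1 it need not be — the
common "corrected p ≥ raw p" claim holds only on the rejection side).

Bonferroni post-hocs compare the g×w cell means. Within-group
(paired-type) contrasts use the within residual mean square with its df;
cross-group contrasts use the Cochran-combined error
(MS_subject + (w−1)MS_within)/w with Satterthwaite df. The family
defaults to all cell pairs corrected together (153 for 6×3, the
behaviour of GUI post-hocs on an interaction) and can be restricted to
within-measure families (15 pairs per measure).

Effect sizes: η² = t²/(t²+df) for two-group contrasts; both classical
(SS/SS_total) and partial (SS/(SS+SS_error)) η² are emitted for every
ANOVA effect since published reports rarely say which was meant. Cohen's
f = √(η²/(1−η²)) and d = 2f for two groups. The sensitivity analysis
solves, by bisection to 1e−6, for the smallest f whose noncentral-F
power (λ = f²N) reaches the target; power defaults to 0.80 since the
convention is near-universal. Note that at N=100, k=6, α=.05 the
minimal detectable f at 0.80 power is 0.369; an f of 0.30 for this
design corresponds to a power of about 0.59, so published sensitivity
claims of f=.30 imply a lower implicit power level.

One reported diagnostic is deliberately not reproduced: a Mauchly χ²
with 5 df cannot arise from a three-level within factor (df =
3·2/2 − 1 = 2); the standard df is used.

## Synthetic cohorts

The generator emulates the study design, not key-press behaviour:

* **Design constants** — 55 younger / 45 older; genotype cells 21/17/17
  and 15/12/18; per-cell sex counts as published; ages uniform on 18–30
  and 60–75; education and global-cognition scores drawn from the
  published group means/SDs (the screening scale only for older
  participants, clipped to its plausible range).
* **Six Gaussian measures** — drawn at the measure level around group
  means with a shared latent ability factor giving a configurable
  performance-oriented cross-measure correlation (default 0.3, a typical
  between-task correlation for executive batteries), then unpacked into
  the raw ingredients the scoring pipeline expects (Stroop counts,
  subtest times, per-condition fluency counts). Rounding to realistic
  units is applied last, so the committed calibration constants already
  absorb its small variance effects.
* **RNG sequences** — the one task with a raw-data definition precise
  enough to simulate. A Markov generator perturbs the next-digit
  log-weights with four human-like biases, each drawn per participant
  from group-level distributions: repeat avoidance, adjacency (±1)
  preference, run continuation (seriation), and a fixed per-participant
  digit-preference pattern whose strength raises redundancy and coupon
  scores and lowers the repetition gap. All biases zero gives uniform
  iid sequences (mean TPI 100, mean adjacency 100·16/81 — the null
  calibrations asserted in the tests).
* **Missingness** — exactly k cells (default 4, the study's count) are
  blanked uniformly at random among the six directly simulated measures.
* **Genotype effects** — null by default; an optional
  `valval_inhibition_deficit` worsens the Gaussian inhibition
  ingredients of older Val/Val carriers by a configurable number of
  younger-SDs, mimicking a genotype-specific ageing effect. It defaults
  to 0 because the per-cell means needed to calibrate it were never
  published.

**Calibration.** The older group's parameters target the published
composite deviations under the younger-reference scheme: inhibition
−1.42, updating −0.49, shifting −0.44. Sequence biases were fixed first
at values producing oriented RNG-score shifts of ≈ −0.8 SD (inhibition)
and ≈ −0.55 SD (updating); `scripts/calibrate.py` then iterated the
Gaussian older-mean offsets through the real pipeline (40–60 cohorts per
round) until the expected composite deviations matched, and the
resulting constants were committed as the defaults. Over 200 fresh
cohorts the defaults give mean older deviations of about −1.39 / −0.47 /
−0.42. One seeded generator drives every draw in a cohort, so identical
config + seed means identical output.

**What passing tests do and do not show.** The generator reproduces the
design's first- and second-moment structure and the RNG task's raw-data
pathway; it does not reproduce item-level task dynamics, skewed or
heavy-tailed real-data distributions, age-correlated variance patterns
beyond the configured SD inflation, or genotype effects. Pipeline
results on synthetic cohorts therefore validate the machinery
(standardization, imputation, test statistics, calibration targets), not
substantive claims about ageing or COMT.

## Problem sizes

Defaults keep everything desk-scale: cohorts of 100 participants with
100-digit sequences; 200 cohorts for the calibration check (~15 s);
10,000 sequences for the null calibrations; 1,000 cohorts for the
type-I simulation; 30,000 replicates for the Monte-Carlo power check.

## Known limitations

* The split-plot post-hoc error terms use the Cochran/Satterthwaite
  approximation for cross-group comparisons; exact multivariate
  approaches (or mixed models) would differ slightly under strong
  non-sphericity.
* The Mann-Whitney p is asymptotic (tie-corrected); exact enumeration is
  used only as a test oracle at small n.
* `coupon` on sequences with no completed pass returns a censored value;
  downstream z-scores treat it like any observation, which slightly
  compresses the upper tail for very non-random sequences.
* Sequences are simulated at a fixed length of 100 (no error process),
  so the realized-n vs nominal-n TPI distinction is inert on synthetic
  data.
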
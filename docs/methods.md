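# Methods

## The two-parameter critical-intensity models

Both models are ordinary least-squares lines with an intercept, with time as
the independent variable:

* **Critical speed.** Distance (m) is regressed on stopwatch time (s) over
  the maximal efforts of one participant-session. The slope is CS (m·s⁻¹,
  also reported ×60 as m·min⁻¹), the intercept D′ (m). This is the linear
  work–time form of the critical-power model applied to walking.
* **Critical heart rate.** The total number of heartbeats of an effort,
  HB = mean(5-s-average HR) × duration in minutes, is regressed on time in
  minutes. The slope is CHR (b·min⁻¹), the intercept HB′ (beats).

No weighting is applied: the protocol yields one point per distance, and the
published use of the model reports simple regression slopes and R². The
intercepts are named with the standard critical-power nomenclature (D′,
HB′) even though field use of the protocol rarely reports them; they are
required model outputs (prediction, domain checks) and are always returned.

An alternative parameterization, mean speed = D′·(1/t) + CS, is provided as
`fit_inverse_time_form` purely as a cross-check: it is algebraically
identical on noiseless data (asserted to 1e-9 in tests) but weights timing
noise differently, so on real data the two estimates disagree slightly.
Both are reported; they are never averaged or reconciled.

Degenerate inputs: fewer than 2 efforts and identical times raise a
`FitError`; exactly 2 efforts are accepted with a warning, since the
protocol prescribes 3 distances and a 2-point "fit" has no residual
information. On 3 collinear points both routines recover slope and
intercept to machine precision (tested).

### Effort metrics and duration screening

Mean HR is the unweighted arithmetic mean of the window-average samples,
not a time-weighted integral — that is what "average 5-s HR" denotes, and
it keeps HB = mean HR × minutes an exact identity (asserted to 1e-9). All
samples from the start of the effort are included; the on-kinetic rise is
not trimmed. Sample timestamps mark the *end* of their averaging window.
Any uniform sampling interval is accepted and recorded; 5 s is the default.
Gaps are reported, never imputed — imputation would silently change HB.

Efforts are screened against the practical recommendation that each last
**3–12 minutes** (inclusive); trials outside it are flagged, not rejected —
e.g. a 16-min 1200-m walk still enters the fit but carries
`duration_valid=False` and triggers a CLI warning. Two older windows from
the critical-power literature (8–20 min, 12–15 min) are reported as
informational flags only; the package's own validity judgement uses the
3–12 min rule.

## Reliability battery

For each metric (time and HB per distance, fitted CS and CHR) measured in
two sessions:

* **Paired comparison**: two-sided paired t (scipy); if the differences have
  zero variance the p-value is reported as its limit (0 or 1) with a
  `degenerate` flag rather than NaN.
* **Cohen's d**: mean difference over the pooled SD of the two sessions
  (√ of the mean of the two session variances); a `dz` variant (SD of
  differences) is available by configuration. Bands implement the half-open
  rule small (|d| ≤ 0.20), moderate (≤ 0.50), large (≤ 0.80), very large
  (> 0.80) *literally*. Note this labels d = 0.85 "very large" where much of
  the literature writes "large ≥ 0.8"; the rule is stated prominently
  because it inverts that convention, and it is applied uniformly.
* **Typical error**: SD of the difference scores (n−1) divided by √2.
* **CV%**: 100·TE/grand-mean by default; the log-scale variant
  100·(exp(SD(Δlog)/√2) − 1) by configuration. The ratio method is the
  default because the computation behind published CV% values of this
  protocol is unstated and the ratio form is the more common one.
* **ICC**: from the two-way participant × session mean squares.
  ICC(2,1) (two-way random, absolute agreement, single measurement) is the
  primary form and ICC(3,1) (consistency) is always reported alongside,
  because published uses of the battery rarely state the form; reporting
  both avoids silent misinterpretation. Zero between-participant variance
  makes the ratio undefined: NaN with a warning. For two sessions these
  closed forms equal the pingouin ANOVA implementation to 1e-9 (tested).
* **SEM = SD·√(1 − ICC)** and **MDC = SEM·1.96·√2**. The SD entering SEM is
  the pooled two-session SD by default (first-session SD by configuration);
  which SD published batteries use is ambiguous, and the pooled choice is
  symmetric in the sessions. Both identities are exact by construction and
  asserted to 1e-9 on every generated report.

No multiple-testing correction is applied across the per-distance tests by
default, matching how such batteries are usually reported; a Holm step-down
helper exists for callers who want it.

## Training-effect panel

Pre/post comparisons reuse the paired machinery. Sign conventions are
asserted in tests: effort-time improvements are negative changes, and
six-minute-walk gains positive. Percent change uses the mean-of-sessions
convention 100·(mean_post − mean_pre)/mean_pre. Participants must attend at
least 90% of the 16 training sessions (8 weeks × 2) to enter the analysis;
the attendance table is data, the threshold and denominator configuration.
The session anchoring the baseline is configurable (`baseline_session`),
since a protocol may anchor intensity prescription on a different visit
than the statistical baseline. The training program itself (warm-up,
calisthenics, walking progression 20→30 min) appears only as report
metadata; no dose–response physiology is modelled.

## Synthetic cohorts

The generator exists so that every pipeline stage can be checked against a
known truth; its defaults are the study conditions, not tuning knobs.

* **Pacing**: a maximal effort over d takes (d − D′)/CS seconds times a
  unit-mean multiplicative lognormal factor with CV 2% — noise scales with
  duration (heteroskedastic in absolute terms), and generator and fitted
  model share one truth, which is what makes recovery tests meaningful.
* **HR kinetics**: HR(t) = rest + amplitude·(1 − e^(−t/τ)) + drift·t/60,
  clipped at the age-predicted maximum (Tanaka, 208 − 0.7·age, by default;
  Fox 220 − age and Gellish 207 − 0.7·age selectable). This is the simplest
  form reproducing the observed rise-and-plateau shape with cardiovascular
  drift; parameters are exposed, not asserted as physiology. Samples hold
  the model at the window midpoint, stamped at the window end.
* **Ground truth for CHR/HB′**: because HB from these kinetics is not
  exactly linear in time, each participant's true CHR and HB′ are *defined*
  as the least-squares line through the noiseless HB values at the protocol
  distances, computed inside the generator from the normal equations —
  deliberately independent of the scipy-based fitting path, so zero-noise
  recovery is an end-to-end consistency check rather than a tautology.
  A consequence worth knowing: with positive drift HB is mildly convex in
  time, so HB′ is typically *negative*, and the CHR slope sits slightly
  above the kinetic plateau (by roughly drift × mean effort duration); the
  participant validator bounds CHR by rest + amplitude + 30 min of drift
  plus 1 b·min⁻¹ of sampling slack.
* **Cohort defaults** (one set, chosen once): n = 15; distances
  400/800/1200 m, shuffled within each session; CS ~ N(1.25, 0.1875) m·s⁻¹
  (15% between-participant CV, floored at 0.7 m·s⁻¹ to keep durations in a
  plausible field-test range); D′ ~ N(30, 10) m; age ~ N(72, 7); resting HR
  ~ N(75, 8); the kinetic plateau targets 70% of predicted HRmax (the
  intensity such walking protocols elicit); τ ~ N(45, 12) s within (10,
  120); drift ~ N(0.5, 0.3) b·min⁻¹·min⁻¹, non-negative; timing noise
  CV 2%; 5-s sampling. The training design (n = 8, the adherent subset
  size) shortens times by 8/4/2% at 400/800/1200 m with unchanged HR
  kinetics, so HB falls essentially proportionally to time — mirroring the
  qualitative pattern the protocol is meant to detect: clear effects at the
  short distances, a borderline one at 1200 m, HB down everywhere, CS and
  CHR nearly unchanged.
* **Reproducibility**: one seed per run; per-participant substreams are
  spawned from a single `SeedSequence`, so identical seed + config produce
  byte-identical datasets (tested at file level).

What the generator does *not* emulate: freezing-of-gait or other episodic
gait events, medication-state (ON/OFF) dynamics, pacing drift within an
effort, HR measurement error and artefacts, or any physiological response
to training beyond the planted time reductions. Passing recovery tests
therefore shows the *analysis* is correct and well-calibrated under the
stated noise model — not that the protocol behaves this way in any real
cohort.

## Reference cohort table

The packaged table ships the 15 individual rows of a published
validation-study cohort (sex, age, anthropometrics, disease scales, timed
cognitive/mobility tests) with 8 participants flagged as the training-arm
subset. Recomputing the group means/SDs (sample SD, n−1; display rounding
half-up at the printed precision) reproduces 32 of the 40 printed group
cells exactly. The remaining 8 printed cells are internally inconsistent
with their own columns (five of them match truncation rather than half-up
rounding, suggesting a mixed convention at typesetting; the two training-arm
trail-making means match neither). These are recorded as annotations in
`data/pd_cohort_printed_summary.json` and asserted to stay discrepant —
they are never forced to match, and nothing downstream depends on them.

## Problem sizes

Monte-Carlo checks use 200 replicates for the reliability-recovery and
sensitivity studies (standard error on a proportion ≈ 1.5–3.5 points),
200 inner replicates per participant for the injected-noise reference,
1,000 instances for the OLS-oracle sweep, and n = 500 pairs for the
analytic-ICC convergence test. These sizes put sampling error comfortably
below the margins being asserted while keeping the full suite fast.

## Known limitations

* The reliability battery assumes two sessions; the ICC closed forms are
  written for the general two-way layout but the battery builder only
  pairs test/retest.
* CV% (ratio method) is undefined for zero grand mean and misleading for
  metrics that can change sign (not the case for any protocol metric).
* The inverse-time cross-check is reported, not reconciled; no errors-in-
  variables correction is attempted for timing noise in the regressor.
* `relative_intensity` restricts age to 18–100 years and refuses other
  inputs rather than extrapolating the HRmax formulas.
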
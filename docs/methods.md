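# Methods

`floodmark` implements a damage-severity marker-gene selection pipeline for
woody crops under waterlogging (soil flooding causing root-zone hypoxia),
modelled on a grapevine study design: one control (CK) and one waterlogged
(CT) composite RNA-seq library, a qRT-PCR time course over an 8-point grid
(0, 12, 24, 48, 72, 96, 120, 144 h), a recovery assay in which plants are
drained after each of 7 waterlogging durations (0–144 h, step 24) and scored
for survival, and per-timepoint leaf symptom counts.

## Replicate-free differential expression

Each condition is a single pooled sample, so per-gene biological dispersion
cannot be estimated.  The model is the random-sampling one: the count of
gene *g* in a library of *n* mapped reads is Binomial(*n*, *p_g*), and under
the null both libraries share *p_g*.  On the MA plot
(M = log2 k1 − log2 k2, A = (log2 k1 + log2 k2)/2), the delta method gives
log2 C ≈ Normal(log2 np, (1−p)/(np ln²2)); conditioning M on A = a and
plugging in the moment estimate p̂ = 2^a/√(n1 n2) yields

    E[M | A=a]   = log2(n1/n2)
    Var[M | A=a] = 4 (1 − p̂) / (ln²2 · (n1 + n2) · p̂)

and z = (M − E[M|A]) / sd, with a two-sided normal p-value.  The normal
approximation is never trusted on its own: the package carries an exact
conditional oracle — given T = k1 + k2, k1 ~ Binomial(T, n1/(n1+n2)) with a
two-sided minimum-likelihood p-value — and the test suite requires Spearman
rank agreement ≥ 0.99 between the two on the 1–50 count grid and ≤ 10%
relative log-p disagreement at moderate counts.

Genes observed in only one library are reported as presence classes
(ck_only / ct_only) rather than fold changes, with the exact conditional
test supplying their p-value; log2 of a zero count is undefined and the
z-path is not applicable.

Expression level is summarized as RPKM = 10⁹·k/(n·L).  Multiple testing is
controlled with Benjamini–Hochberg step-up q-values (the standard reading of
an "FDR" threshold).  A gene is called differentially expressed when
|log2FC| ≥ 1 (treated over control — positive means higher under stress) and
q < 0.001; both thresholds are estimator parameters (a laxer q < 0.005
convention also circulates for this design and is available by setting
`q_threshold`).

## qPCR quantification

Relative expression is 2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per
replicate well, ΔΔCt subtracts the mean ΔCt of the calibrator sample, and
replicates are aggregated as mean ± SE of the replicate 2^−ΔΔCt values (SE
on the linear scale, matching means ± s.e. reporting; no outlier rejection).
The calibrator defaults to the treated sample at 0 h — stress onset — so
every series starts at 1 and trends read directly as change under stress;
calibrating to time-matched controls instead is a parameter
(`DeltaDeltaCt(calibrator_condition="CK", ...)`), since either convention is
defensible for this design.  The 2^−ΔΔCt path assumes 100% amplification
efficiency (base 2).  Efficiency is instead measured on the standard-curve
path: Ct regressed on log10 input copies, E = 10^(−1/slope) − 1, with R²
reported (a perfect 10-fold series has slope −3.32193 and E = 1.0).

## Trend screening

"Continual" (monotone) behaviour is formalized with a Mann–Kendall-style
pairwise concordance: S = Σ_{i<j} sign(rel_j − rel_i), τ = S/(T(T−1)/2),
ties contributing 0.  Defaults: a series is continual_up when τ ≥ 0.8, the
overall swing is at least a_min = 1 log2 unit (2-fold), and no adjacent
decrease exceeds z_adj = 2 times the combined SE of its endpoints
(continual_down symmetric); a swing below a_min is flat; anything else is
non-continual.  τ_min = 0.8 tolerates at most two discordant pairs on an
8-point grid — strict monotonicity up to isolated noise inversions.  No
p-value is attached: the screen is a deterministic filter, and with T = 8
points a formal Mann–Kendall test would have little resolution anyway.

Monotone profiles that collapse to a floor within the first k_sat = 2 steps
and are indistinguishable across later times ("saturating") are flagged by
the discriminability check (no noise-significant adjacent pair from point
k_sat onward) and excluded from the continual classes: they cannot resolve
stress duration, which is the whole point of a severity marker.

## Recovery assay and critical time

Survival fractions per duration are thresholded by a majority rule: the
critical time t_c is the largest duration whose fraction is ≥ 0.5.  Observed
fractions at n = 10 plants are noisy, so non-monotone sequences are first
projected onto non-increasing ones by isotonic regression weighted by plants
treated (survival is treated as monotone in stress duration); the projection
is idempotent and leaves monotone schedules untouched.  t_c is reported on
the sampled grid without interpolation, because the assay itself is
grid-valued.  A t_c of 0 h (majority lost by the first nonzero duration)
carries a warning flag.

A parametric summary fits survived ~ Binomial(n, 1/(1+exp((d−t50)/s))) by
maximum likelihood, implemented as a binomial GLM in (1, d) and mapped back
via t50 = −b0/b1, s = −1/b1 with delta-method standard errors.  Complete
separation (fractions all 0 or 1) returns the boundary fit — t50 at the
midpoint of the gap, s = 0 flagging an infinitely steep step — with NaN SEs.

## Sharp signals and marker designation

A sharp signal is the largest adjacent log2 step of a series, accepted when
|Δlog2| ≥ θ = 1 (a 2-fold jump between consecutive samplings) and its
contrast — |Δlog2| over the median |log2 step| of the rest of the series —
is ≥ 2.  The contrast floor keeps steep-but-uniform series (e.g. geometric
growth, whose every step equals the maximum) from alarming.

Markers are genes whose sharp signal lands in the alarm window
(t_c, t_c + Δ] with Δ = 48 h by default (two sampling intervals, covering
signals at both 72 h and 96 h when t_c = 48 h), and whose pre-signal
behaviour is consistent: elevated or rising through t_c for up-markers, or
slowly declining — less than 1 log2 unit in total before t_c — for
down-markers.  Candidacy is screened on the series restricted to t ≤ t_c
(≥ 4 points on the 8-point grid): the post-critical collapse itself breaks
full-series monotonicity for exactly the genes the rule is after, so the
full-series trend call cannot be the gate.  Fast decliners fail candidacy
twice over (saturating, and a pre-critical drop beyond 1 log2).

The alarm direction is learned from the training panel and recorded in the
rule, not assumed: descriptions of such signals are often ambiguous between
"a sharp change in an up-trending gene" and "a sharp increase", and keying
on the trained direction resolves that operationally.  Prediction re-detects
sharp signals per marker gene on a new panel; an alarm fires when direction
and window match, and ≥ m alarms (default m = 2 of 3; m = 3 gives the
strictly conjunctive rule) declare the plant irrecoverable, zero alarms
recoverable, anything between indeterminate.

## Synthetic data

The generators emulate the study conditions and nothing more:

* **Counts** — per-gene baseline proportions are log-normal (σ = 1.5),
  normalized to sum 1 per library; a `de_fraction` of genes (default 10%)
  has the treated proportion scaled by 2^±effect with |effect| ~
  N(2, 0.5²) log2 units; counts are Poisson(lib_size × proportion) — Poisson
  rather than negative binomial because each condition is one composite
  sample, which is exactly the random-sampling model the DE test assumes.
  Default library sizes 2×10⁷ / 3×10⁷ reads.  An expected-counts mode
  (counts = rounded expectations) supports exact round-trip tests; the truth
  table records both the drawn and the realized (renormalized) effect.
* **qPCR panels** — latent log2 curves are piecewise-linear on the time
  grid, the simplest family reproducing the observed profile shapes:
  continual rise/fall to ±3 log2, saturating fall (floor by the third
  point), transient (rise then fall), flat.  The default panel of 30 genes
  plants 6 continual_up, 3 continual_down, 6 saturating_down, 12 transient
  and 3 flat.  Ct(t) = C0 − log2 x(t) + ε with ε ~ N(0, 0.15²) cycles per
  well, a constant-Ct reference gene with the same noise, 3 technical
  replicates, and a control condition at x(t) = 1.
* **Recovery** — survivors ~ Binomial(10, p(d)) with logistic p(d),
  t50 = 60 h and s = 10 h, consistent with a majority surviving at 48 h
  (p = 0.77) and a majority dead at 72 h (p = 0.23).
* **Symptoms** — symptomatic leaves ~ Binomial(52, q(t)) with the
  nondecreasing default q taken from the published treated-row fractions.
* **Marker scenario** — a fixed 9-gene panel on the 8-point grid with the
  three marker shapes (rise-to-48 h then −3 log2 collapse at 72 h;
  rise-to-72 h then collapse at 96 h; slow −0.6 log2 decline then sharp drop
  at 72 h) plus non-marker profiles (a gene staying high, three plateau
  genes, two fast decliners), in "collapsed" and "rescued" variants.

What the generators do **not** emulate: gene-length/GC biases, mapping
artifacts, overdispersion between biological replicates (there are none in
this design), amplification-efficiency differences between genes, or
correlated noise across time points.  Passing tests therefore demonstrate
that the pipeline's logic and calibration are correct under its own model
assumptions, not that the assumptions hold for any particular real dataset.

All randomness flows from one integer seed; each generator draws from its
own numbered substream so generators are independent and call order never
matters.

## Numerical and design notes

* Exact conditional p-values sum pmf terms with a 1+1e−12 relative tolerance
  when comparing likelihoods, so floating-point ties do not drop outcomes.
* p̂ in the z-test variance is capped below 1 to keep the variance positive
  for genes that dominate a library.
* Report percentages round half-up (two decimals for DEG/annotation
  summaries, one for symptom percentages), via `decimal` to avoid banker's
  rounding.
* Problem sizes in the test suite (5 000-gene count tables at 2–3 M reads,
  20–50 seed replications, 200 logistic-fit replicates) were chosen as the
  smallest scales at which the calibration statements being tested are
  statistically meaningful.

## Known limitations

* The DE test inherits the limits of replicate-free designs: it tests
  sampling variability only, so q-values understate uncertainty about
  biological effects.
* The trend screen's thresholds (τ_min, a_min, z_adj) are calibrated on
  synthetic panels; real panels with different noise or grid density may
  need retuning.
* The marker rule assumes the new panel is sampled on a grid covering the
  alarm window; sparser field sampling would need a wider window and
  re-validation.
* Survival modelling is per-duration binomial; plant-level covariates and
  censoring are out of scope.
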
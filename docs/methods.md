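# Methods

## Scoring model

The unit of record is the field-season: one field on one farm in one year,
with its area (ha), crop, and the set of practices applied. Scores build up
in four stages.

**1. Annual practice scores.** Each practice has a scoring mode chosen for
how it can physically be implemented:

- *area-proportional* (default): applied area ÷ total recorded area that
  year. The denominator is the recorded block area — fields absent from the
  dataset are outside the assessed block by definition.
- *binary-rotational*: 1 if the practice appears on at least one field.
  Used for rotational practices (herbal leys, farmyard-manure addition) that
  occupy only one or a few fields in any year; an area share would
  structurally cap them far below 1 and misread rotation as inconsistency.
- *diversity-scaled*: (distinct non-empty crops − 1)/(field count − 1),
  clipped to [0, 1]. Scaling by field count avoids penalizing small farms
  that cannot grow many crops at once. A single-field farm scores 0, not
  undefined: no within-farm diversity is expressible. At most one practice
  per configuration may use this mode.

**2. Principle scores.** A principle's annual score is the unweighted
arithmetic mean over all practices mapped to it; a mapped practice applied
nowhere that year contributes 0. Practices serving several principles
(cover crops serve soil cover, diversity and living roots) contribute
independently to each. Consequences: each principle is bounded by 1, reached
exactly at full implementation of all constituents, and principles sharing
practices have positively correlated scores (see Limitations).

**3. Recency weighting.** Annual principle scores over a window of
*Y* years (default 5) are averaged with non-decreasing weights, newest year
heaviest. The default is linear, *w*<sub>*k*</sub> = *k*/Σ<sub>*j*≤*Y*</sub>*j*
(for *Y* = 5: 1/15 … 5/15); an exponential scheme is available
(`exponential_recency_weights`, rate 0.5 by default). Linear was chosen as
the simplest monotone scheme with no extra parameter; any non-decreasing
normalized vector is accepted. Years with no rows are treated as *missing*,
not as "no practices": weights are renormalized over observed years and each
weighted score carries its window coverage. The alternative — imputing
zero — would conflate data gaps with management choices.

**4. Combined score.** The sum of the five weighted principle scores
(range 0–5). The sum rather than the mean keeps one principle's change worth
the same amount of combined score regardless of how many principles exist;
the normalized mean is reported alongside for cross-configuration
comparison.

Invariants maintained (and property-tested): all practice/principle scores
in [0, 1]; combined in [0, P]; adding a practice application never decreases
any score; shifting implementation toward the present never decreases a
weighted score; results invariant to row/field order.

## Fingerprints and clustering

The fingerprint cell (farm, practice) is the fraction of window years *with
data* in which the practice was applied on ≥ 1 field. Presence is binary per
year for every practice, including area-scored ones: the fingerprint
answers "how consistently is this practice part of the system", not "how
much land does it cover" — the graded information lives in the scores.
A year with no data is excluded from the denominator rather than counted as
non-implementation, consistent with the missing-year policy above.

Clustering is agglomerative with Euclidean distance and average linkage —
the standard choice for continuous profiles on [0, 1]; both are
configurable. Farms are sorted by id before linkage so ties break
deterministically; cluster labels are renumbered in order of first
appearance, making the partition invariant to input order.

## Synthetic landscape generator

The generator emulates a farmer-enrolled quasi-experiment: 60 ha blocks in
one of three groups — control (conventional), long-term regenerative, and
farms transitioning from 2023 — replicated 4× per group in each of two
landscapes, plus one extra block (25 total; the balanced 24-block variant
and the extra block's group are configurable), with practice histories over
2018–2022 and 3–10 fields per block (Dirichlet area split, fixed across
years).

Group archetypes are annual per-practice adoption probabilities: 0.1 for
controls (0.5 for residue retention and 0.4 for compaction reduction, which
conventional farms commonly practise), 0.9 for regenerative farms (0.8 for
no-till — ploughing is still occasionally needed to terminate leys), and
control-like switching to regenerative-like at the transition year for
transition farms. Year-to-year persistence (probability 0.3 of carrying last
year's state) adds temporal autocorrelation. An adopted practice lands on a
uniform-random non-empty subset of fields; crop rotations draw from a short
conventional list, widened for regenerative archetypes and whenever crop
diversification is active.

Because the three archetypes separate farms into clusters, *all* principle
scores are strongly correlated across the landscape (r ≈ 0.9). That is
realistic for group contrasts but makes univariate regressions unable to
attribute an outcome to a specific principle. `gradient_farms` therefore
generates the complementary population — each farm draws its own adoption
probability per practice, uniform on (0.05, 0.95) — mirroring the observed
baseline situation where every farm sits somewhere on a practice-adoption
spectrum. Slope-identification analyses and their tests use this gradient
population.

Outcomes follow a linear-additive model in the weighted principle scores:
*y* = α + Σ<sub>*p*</sub> *b*<sub>*p*</sub>·*S*<sub>*p*</sub> + ε,
ε ~ N(0, σ²). Defaults: earthworm density in worms/site, α = 5,
slopes 13.4 (soil cover), 11.1 (minimize disturbance), 3 (living roots),
2 (diversity), 1 (livestock), σ = 5 — soil cover and disturbance as the
dominant earthworm drivers, with moderate ecological noise. The linear form
is the simplest model consistent with fitting straight lines to
score–outcome scatter; lagged or saturating responses are not modelled.

BACI panels give each farm a persistent level set by its *baseline* scores
plus i.i.d. annual noise, and add the treatment effect δ to transition farms
from the transition year on. Holding the score-driven level at baseline
isolates the design's estimand (the treatment effect) from practice drift,
and makes δ exactly recoverable at σ = 0.

Seeding: one user seed expands via `numpy.random.SeedSequence` into
per-farm child seeds indexed by enrolment order, so the same seed always
reproduces the same farms and generating *more* farms never changes existing
ones. Auxiliary streams (field counts, outcome noise, bootstrap) use fixed
distinct sub-keys of the same seed.

### What the generator does not emulate

No spatial autocorrelation between neighbouring blocks, no weather or soil
covariates, no farmer decision feedback (e.g. dropping a practice after a
bad year), no yield/economic outcomes, and practice adoption is independent
across practices given the archetype, whereas real adoption is bundled
(no-till with cover crops). Tests passing on synthetic data therefore
validate the *pipeline arithmetic and statistical calibration*, not the
ecological claims themselves.

## Score–outcome linkage

Univariate OLS per principle plus the combined score, mirroring a
one-panel-per-principle comparison; a multivariate fit is deliberately not
the default because with nine practices and ~25 farms it would be poorly
conditioned. Raw p-values are reported by default so borderline results
remain visible as trends (0.05 ≤ p < 0.10 flagged separately from p < 0.05);
Holm adjustment is available by flag. R² is defined as 0 when the outcome is
constant (no variance to explain). The BACI estimator is a plain
difference-in-differences of farm-level before/after means with a
farm-level block bootstrap (default 1000 resamples, seeded) and a normal
approximation for the p-value; richer mixed-effects formulations are out of
scope.

## Numerical and testing choices

- Scoring equivalence is checked against an independent per-record loop
  reference to 1e-12 on randomized small farms (≤ 5 fields, ≤ 5 years).
- Monotonicity is exercised on 1000 random perturbations plus
  hypothesis-driven cases; weighted-score recency monotonicity on 200
  random series.
- Parameter recovery uses 20 datasets of 200 gradient farms (slope 13 on
  soil cover, σ = 2): at least 17/20 individual 2-SE hits (nominal coverage
  95%) and the pooled mean within 2 standard errors of the mean.
- Type-I error uses one fixed 24-farm design with 500 noise-only outcome
  redraws; the rejection rate at α = 0.05 must sit inside the binomial 95%
  band. Redrawing only the noise (not the farms) matches the fixed-design
  assumption of the t-test.
- The qualitative regression ordering (|β, soil cover| > |β, disturbance| >
  |β, combined|) is asserted as ≥ 7 of 10 replicate gradient datasets of
  150 farms: the generating slopes differ by only 2.3 worms/site, so single
  finite samples occasionally swap the two leading coefficients.
- Cluster recovery: three flat archetypes (adoption 0.9/0.5/0.1, 8 farms
  each, persistence 0) must be recovered with adjusted Rand ≥ 0.8.

Problem sizes throughout (150–200 farms, 10–20 replicates, 500 null
replicates, 1000 bootstrap resamples) were chosen to keep each statistical
check's own sampling error well below the margins being asserted while the
full suite runs in well under a minute.

## Known limitations

- Scores measure implementation consistency, not outcome magnitude or
  efficacy; weighting practices by expected impact is a natural extension
  and deliberately not included.
- Shared practices induce correlated principle scores; univariate slopes on
  clustered populations mostly reflect the overall regenerative contrast,
  and should be interpreted mechanistically only on populations with
  independent practice variation.
- The area denominator is the recorded block, so under-reporting fields
  inflates area-proportional scores.
- The bundled nine-practice map encodes one (UK arable/mixed) context;
  transferring the system to other contexts is done by editing the map, and
  score values are only comparable under a fixed map and weight scheme.
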
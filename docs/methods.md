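# Methods

## The monitoring model

`benchcycle` monitors the outcomes of one surgical procedure against
externally published benchmark cut-offs. The unit of analysis is the
*index operation*: every outcome (a readmission, a complication grade, a
length of stay) is treated as an attribute of the operation and dated by
the surgery date, never by the date the outcome event occurred. This
matches how benchmark cut-offs are defined (per-operation outcome medians
of reference centres) and makes window membership unambiguous.

**Windows.** The study period is divided into overlapping rolling windows
of `length_months` (default 18) advanced by `step_months` (default 6),
labelled p1, p2, …. Windows are half-open calendar intervals
`[start, start + length)` computed with exact month arithmetic, so steps
never drift and a window boundary date belongs to exactly the later
window. The window count is `floor((span − length)/step) + 1`; a 72-month
study with the default geometry yields 10 periods, and every interior
date falls in exactly `length/step = 3` consecutive windows.

**Per-window statistic.** Continuous outcomes use the sample median
(even counts: mean of the two middle order statistics) — robust to the
outliers and right skew typical of LOS or operative time. Binary outcomes
use the event proportion ("moving rate"), since a median is meaningless
for 0/1 data. A window with fewer than `min_n` contributing patients
(default 1, i.e. only truly empty windows) yields an *undefined* point,
never an artificial zero; records missing the outcome value are excluded
from that point's `n` with a logged count.

**Comparison and flagging.** A benchmark entry carries a cut-off, the
span of reference-centre medians (display context only), and a direction.
Rates are stored in percentage points, the scale on which cut-offs are
published; series rates in [0, 1] are scaled at comparison time. A defined
point *deviates* iff it is strictly on the worse side of the cut-off —
equality is compliant, because cut-offs are defined as achievable
best-quartile performance. A *signal* is a maximal run of ≥ k consecutive
deviating periods (default k = 2, the smallest run distinguishable from an
isolated spike; configurable). Undefined points break runs: a signal
cannot assert sustained deviation across a period where nothing could be
measured. No control limits, CUSUM or funnel plots are computed — the run
rule is deliberately the only inferential element layered on the plotted
series, and the plots keep the cut-off (solid) and centre-median range
(dotted) as the visual frame.

**Stratification.** The ideal/non-ideal split is a pure conjunction of
per-field predicates evaluated record by record; the packaged LAR set
encodes the published definition with literal bounds (age ∈ [18, 80),
BMI ∈ [20, 35), albumin ≥ 3.0 g/dL, ASA < 3, pT ≤ 3 with pT0/pTis
counting as ≤ 3, all risk booleans false). A missing value on any
criterion field classifies the record as non-ideal with a warning:
"ideal" certifies verified low risk, so unverifiable records must not
dilute the low-risk stratum. "No recent history of smoking" is a single
boolean; what "recent" means is an ingest-time decision for the data
owner, not a classifier parameter. Bleeding disorder and anticoagulation
are kept as separate booleans even though some registries only record the
latter.

**Follow-up completeness.** Windows whose end plus the follow-up horizon
(default 6 months) extends past the configured analysis date are marked
*provisional* in every export and hatched in plots. The flag records —
rather than resolves — the fact that late-window outcome ascertainment
may still be incomplete.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `length_months` | 18 | months | pools enough patients per period for a stable rate at typical LAR volumes |
| `step_months` | 6 | months | half-yearly re-evaluation cadence |
| `k` | 2 | periods | smallest run distinguishable from a one-off spike; "several consecutive periods" is otherwise a judgement call |
| `min_n` | 1 | patients | report every period that has any data; raise to suppress tiny-denominator points |
| `follow_up_months` | 6 | months | horizon within which the binary outcomes must be ascertainable |
| quantile convention (`derive_benchmark`) | linear interpolation | — | explicit and overridable; published cut-offs are consumed as authoritative constants, never re-derived |

## Synthetic cohorts

The generator (`benchcycle.synthetic`) emulates a single-centre elective
LAR series at aggregate level: monthly operation counts Poisson at
`monthly_volume` (default 1.4/month over 2018–2023, ≈ 100 operations),
ideal fraction 0.163, anastomotic leak 8% in both strata, 3-month
readmission 15%/20% (ideal/non-ideal), CDC ≥ 3a at discharge 0%/18%,
lymph-node yield ≥ 12 in 94%/96%, and log-normal LOS and operative time
with stratum medians 7/8 days and 313/343 minutes. Log-normal is the
natural default for strictly positive, right-skewed hospital durations,
and parameterising the median directly lets published aggregate medians
serve as inputs. Baseline fields are drawn *consistently with the
assigned stratum*: ideal records satisfy every packaged criterion;
non-ideal records violate a random non-empty criterion subset weighted
toward single violations (55/25/12/8% for 1–4 violations), reflecting
that real non-ideal groups span one-criterion to heavily comorbid
patients. Step changes in any rate or continuous location can be injected
at a chosen date, per stratum or overall. One root seed drives a
splittable stream (a dedicated substream per record), so cohorts are
byte-reproducible.

What the generator does **not** emulate: correlations between
comorbidities, surgeon or season effects, within-patient correlation
between outcomes, or survival time. Passing pipeline tests on these
cohorts therefore demonstrates correctness of the computation and the
run-rule behaviour under idealised independence — not that any particular
real-world series will show the same false-alarm rate.

## Run-rule characterisation (`benchcycle.experiments`)

Two seeded replicate studies summarise the scheme's operating
characteristics; both are recomputed by the test suite and by
`scripts/acceptance.py`, and no number below is asserted anywhere without
being recomputed:

* **Detection**: readmission steps 15% → 35% at the study midpoint in a
  centre operating ~20 patients/month. Detection = a k = 2 signal whose
  run overlaps at least one window ending after the change date, in
  either stratum. This gross deterioration is detected in ≥ 90% of 200
  replicates (in practice every one).
* **Null calibration**: a compliant centre with every nominal rate
  strictly better than its cut-off — lower-is-better rates at roughly
  half the cut-off, the higher-is-better lymph-node yield midway between
  cut-off and 100% — at 14 patients/month, so even the ideal stratum
  (16.3%) averages ≥ 40 patients per 18-month window. The frequency of
  ≥ 1 spurious signal anywhere in a whole cycle (7 outcome × stratum
  series, 10 windows) is reported and must stay below 50%; it is roughly
  a third of replicates at these margins. The rate is highly sensitive to
  the rate-to-cut-off gap in the small ideal stratum: a centre sitting
  *just* inside a cut-off will be flagged often, which is the intended
  behaviour of a review-triggering (not a hypothesis-testing) rule.

## Numerical and design choices

* Half-open intervals everywhere (study period, windows); ties at a
  boundary go to the later window.
* Even-count medians average the middle two order statistics.
* Deviation uses strict inequality; magnitudes are reported signed toward
  "worse" (positive = deviating) in registry units.
* The registry validates `range_low ≤ cutoff ≤ range_high` and rejects
  duplicate (procedure, outcome, stratum) keys at load time.
* Deviations that stay inside the published centre-median range are not
  graded differently from those outside it: flagging is on the cut-off
  only, and the range is rendered as context.
* The CLI exit status is 1 iff any signal fired (2 for configuration
  errors), so `benchcycle run` can gate a review meeting in automation.
* Problem sizes in the shipped studies (≈ 2,000-patient characteristic
  cohorts, 200 replicates per run-rule study) were chosen to estimate
  binomial proportions to within a few percentage points while keeping a
  full re-run around a minute on one CPU.

## Known limitations

* No risk adjustment beyond the ideal/non-ideal split, and no multiplicity
  control across outcomes — the run rule is a triage device for human
  review, not a test with a guaranteed family-wise error rate.
* Overlapping windows share patients, so consecutive deviations are
  positively correlated by construction; run lengths must not be read as
  independent evidence counts.
* The CCI is consumed as a given per-patient number when declared as a
  continuous outcome; it is never computed from individual complications.
* Cut-off provenance is whatever the registry file states; the package
  ships the published LAR values verbatim and cannot verify the quantile
  convention their authors used.
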
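# Methods

## The classification problem

Direct self-report of menopause is unreliable for women who have had
interventions that alter menstrual bleeding without (necessarily) altering
ovarian function: hysterectomy without bilateral oophorectomy ends bleeding
while ovulation may continue, and menopausal hormone therapy (MHT) can cause
bleeding after menopause. Bilateral oophorectomy, by contrast, *causes*
menopause at the surgery age. `menoderive` derives menopausal status at a
single survey time point from: the self-reported menopause response (no /
not sure / periods irregular / yes), MHT use (never / former / current),
hysterectomy and bilateral oophorectomy (yes / no), current hormonal
contraception, and the ages at baseline and at each reported event.

## Decision-table classifier (detailed status)

The classifier is a total, deterministic function of one record and a
policy object. Ordering of events decides masking: an intervention dated
*before* the reported menopause masks it; one dated after is post-menopausal
and irrelevant. The rules, in evaluation order:

1. Any missing core response (menopause, MHT, hysterectomy, oophorectomy) →
   `unknown` + `MISSING_CORE`; any event age exceeding baseline age by more
   than the slack (default 1.0 year, a reporting-lag tolerance) → `unknown` +
   `INCONSISTENT`. Inconsistency is handled here, at classification — the
   reader flags but never rejects rows.
2. Self-reported **yes**: masking interventions are checked in the
   precedence oophorectomy → hysterectomy → MHT (causal strength: an
   oophorectomy causes menopause, a hysterectomy physically ends periods,
   MHT only obscures them; the order is configurable). An oophorectomy at or
   before the reported menopause age (tolerance default 0 years, i.e. `≤`)
   is `menopause_from_oophorectomy`; a hysterectomy or MHT start *strictly*
   before it is `no_periods_hysterectomy` / `mht_before_periods_stopped`
   (a same-age surgery or MHT start is treated as following the final
   period, which is common practice). A reported intervention whose age —
   or the menopause age needed to order it — is absent makes the order
   undecidable: `unknown` + `MISSING_EVENT_AGE`. Otherwise
   `natural_menopause`; a missing menopause age alone is flagged but does
   not demote the status unless `natural_menopause_requires_age` is set.
3. Self-reported **no**: hysterectomy → `no_periods_hysterectomy`; else
   current MHT → `mht_before_periods_stopped`; else `pre_menopause` — with
   the `ASSUMED_UNILATERAL_OOPH` flag when a bilateral oophorectomy was also
   reported, since "no menopause" contradicts a bilateral procedure and is
   reconciled by assuming it was unilateral.
4. **Irregular periods**: current MHT → `mht_before_periods_stopped` (MHT
   itself causes bleeding); a reported hysterectomy or oophorectomy
   contradicts ongoing periods → `unknown` + `INCONSISTENT`; otherwise
   `peri_menopause`. Both surgery targets are policy-overridable.
5. **Not sure**: the respondent cannot date menopause, so interventions are
   consulted in the priority order bilateral oophorectomy → current MHT →
   hysterectomy (configurable); with none of the three, the default target
   is `peri_menopause` (the arithmetic of the published consolidated counts
   is only consistent with not-sure women without interventions flowing to
   peri-menopause; `unknown` is selectable instead).

Former MHT masks only under self-reported **yes** (where the start age can
be ordered); under **no**/**not sure** only *current* MHT masks. Every
`unknown` carries at least one machine-readable reason flag.

## Age thresholds

All three estimators run on the intervention-free subcohort (never MHT, no
hysterectomy, no oophorectomy, not currently using hormonal contraception)
and scan integer ages 45–100, returning the smallest age satisfying their
criterion together with the full scan table; an unattainable cut-point is
an explicit `NOT_ATTAINED` result, which the consolidation stage refuses.

* **Reference** — cumulative share of reported menopause ages strictly below
  the candidate age, among women additionally aged ≥ 55 at baseline (younger
  women may misread a temporary irregularity as menopause) with derived
  natural menopause and a reported menopause age. "Below" is strict, so a
  distribution whose 90th percentile is 54.7 yields 55.
* **Conservative** — per single-year baseline-age group (floor of the
  fractional age), share self-reporting menopause ("yes" only in the
  numerator; not-sure/irregular/no/missing stay in the denominator);
  threshold is the smallest age from which *every* group of at least
  `min_group_n` (default 50, suppressing noisy extreme-age groups) meets the
  cut-point.
* **Least conservative** — share of derived natural menopause among all
  eligible women at or above the candidate age.

The cut-point defaults to 0.90 and is configurable; raising it can never
lower a threshold (tested). Fractional baseline ages are compared as-is
against the integer threshold (age ≥ a).

## Consolidation

`natural_menopause` → post; `menopause_from_oophorectomy` *with*
self-reported menopause → post unconditionally (the self-report confirms the
surgery was bilateral and causal); peri and pre carry over and are never
re-classified. The masked statuses — and, when `reclassify_unknown` is set
(default), detailed `unknown` — become post when baseline age ≥ threshold
("aged ≥ a years at baseline") and unknown otherwise. A record without a
baseline age cannot be compared to the threshold and stays unknown, flagged.

## Synthetic cohort generator

The generator emulates the published cohort's structure so every stage is
testable without the access-restricted source data. Latent history per
woman: baseline age from a two-piece normal matched to median 59.9 and IQR
52.8–69.0 (each side keeps probability ½ via a truncated half-normal, so
the median is exact; truncation at 45 compresses the lower tail, so the
sample lower quartile sits nearer 54 than 52.8); age at natural menopause
from a truncated normal with location 50.0, scale 3.7 on support 35–60. A
symmetric family cannot match the published median of 50 *and* the
right-skewed IQR of 48–53 simultaneously; the location is set to reproduce
the median, the quantity that drives the reference threshold (the model's
90th percentile is 54.7, hence a reference threshold of 55), at the cost of
a model IQR of 47.5–52.5.

Interventions: no interventions with probability 0.469; the remaining mass
is split uniformly over the 11 intervention combinations (per-category
frequencies of the source cohort are not published; any simplex can be
configured). Surgery ages are uniform on (35, baseline); bilateral
oophorectomy sets the latent menopause age to min(natural age, surgery
age); MHT initiation clusters within ±5 years of the latent final period.
A woman is *masked* when her hysterectomy or MHT start precedes her latent
menopause or she currently uses MHT; masked women answer "not sure" with
probability 0.6, otherwise everyone reports her latent state (yes /
irregular within the 2-year peri window / no), with menopause age reported
to one decimal when the answer is yes.

Corruption, applied after reporting: each event age is blanked independently
with probability 0.05; a core response is blanked with probability 0.03 —
the menopause response in 80% of those events and one intervention response
in 20%, a split chosen so the empirical no-intervention share still recovers
the 0.469 parameter within binomial tolerance while the incomplete category
is still exercised; with probability 0.01 one present event age is replaced
by baseline + 5 years to inject an inconsistency. Current hormonal
contraception is assigned independently at 2%.

Deliberately **not** emulated: integer-rounded recalled ages (real
respondents report whole years; reported ages here keep one decimal),
correlation between intervention history and age, secular trends,
demographics, and non-random missingness. Passing recovery tests therefore
shows the algorithm's logic is correct under the stated statistical
structure, not that real-survey misreporting is handled.

The latent truth (state at baseline, menopause age, masked flag) is
returned in a separate table and never written into record fields, so
classifiers provably see only the public schema.

## Numerical and interface choices

* Display rounding is decimal half-up to one decimal, applied exactly once
  on unrounded ratios; counts and proportions are exact integer/float
  arithmetic before that.
* Ages are floats throughout; no rounding on ingest; file round-trips are
  bit-exact (float `repr`).
* Problem sizes in the test and acceptance runs (cohorts of 2,000–50,000;
  20 seeds for threshold-recovery checks; 200 random cohorts ≤ 1,000 for
  oracle equivalence) were chosen to keep sampling noise several standard
  errors away from every asserted bound.
* The pipeline writes a run-metadata file (version, config hash, seed);
  identical configurations produce byte-identical outputs.

## Known limitations

* The intervention mix default is uniform, so synthetic category frequencies
  do not match any real cohort's (only the no-intervention share does).
* The derived status cannot be validated against hormone measurements; the
  truth-recovery metrics are recoveries of the *generator's* latent state.
* The conservative threshold is sensitive to single borderline age groups
  and fluctuates by ±1 year across seeds at realistic sizes; the reference
  threshold is stable.
* Cohorts including women under 45 are out of scope (the threshold logic
  classifies toward post-menopause only).
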
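"""Estimate the three age thresholds for likely post-menopause.

On a default synthetic cohort the reference method (cumulative distribution
of reported menopause ages among intervention-free women aged 55+) lands on
55 years; the conservative method (every single-year age group at least 90%
post-menopausal) is typically a year higher, and the least-conservative
method (tail share of natural menopause) several years lower.
"""

from menoderive import (
    GeneratorParams,
    classify_cohort_detailed,
    estimate_all_thresholds,
    generate_cohort,
)

cohort = generate_cohort(GeneratorParams(n=30_000, seed=1))
results = classify_cohort_detailed(cohort.records)
thresholds = estimate_all_thresholds(cohort.records, results, cut_point=0.90)

for method, tr in thresholds.items():
    print(f"{method.value:<20} threshold age {tr.threshold_age}  "
          f"(n eligible = {tr.n_eligible})")

reference = thresholds[list(thresholds)[0]]
print("\nreference cumulative table around the threshold:")
print("age  below_age  eligible  proportion")
for age, num, den, prop in reference.cumulative_table:
    if 52 <= age <= 57:
        print(f"{age:>3}  {num:>9}  {den:>8}  {prop:.3f}")

# The threshold is the smallest age at which the cumulative share of
# reported menopause ages below it first reaches the 90% cut-point; women
# with masked or unknown status at or above this baseline age are highly
# likely to be post-menopausal.
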
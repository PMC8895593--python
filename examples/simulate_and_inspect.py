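"""Generate a synthetic cohort and tabulate intervention combinations.

Builds a 20,000-woman cohort with the default parameters (median baseline
age 59.9, ~46.9% with no menopause-masking interventions) and prints the
13-category intervention frequency table.
"""

from menoderive import GeneratorParams, generate_cohort, tabulate_categories

cohort = generate_cohort(GeneratorParams(n=20_000, seed=7))
table = tabulate_categories(cohort.records)

print(f"{'category':<24}{'count':>8}{'percent':>9}")
for category, (count, proportion) in table.items():
    print(f"{category.value:<24}{count:>8}{100 * proportion:>8.1f}%")

# Each row is one combination of MHT use, hysterectomy and bilateral
# oophorectomy; 'none' is the share of women whose menopausal status no
# intervention can mask, and 'incomplete' collects records missing one or
# more of the three responses.
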
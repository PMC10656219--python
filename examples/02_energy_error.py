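"""Meal-level energy percent error and bounds concordance.

Simulates the default study, sums kcal per meal over items logged in
both modes, and prints the two aggregate error measures: mean of
per-meal percent errors (the per-stratum table statistic) and
elevation-of-means (the headline "x% higher than weighed" number).
"""

from mealaudit import (
    Mode,
    default_study_config,
    elevation_of_means,
    generate,
    meal_totals,
    summarize_overall,
)

ds, _ = generate(default_study_config(seed=1))
meals = meal_totals(ds)  # items omitted in either mode excluded everywhere
s = summarize_overall(meals)

print(f"meals: {s.n}")
print(f"weighed kcal      {s.weighed_mean:6.0f} +/- {s.weighed_sd:.0f}")
print(f"automated kcal    {s.auto_mean:6.0f} +/- {s.auto_sd:.0f}")
print(f"semiautomated kcal{s.semi_mean:6.0f} +/- {s.semi_sd:.0f}")
for mode in Mode:
    elev = elevation_of_means(meals, mode)
    within10 = s.pct_within(10, mode)
    within25 = s.pct_within(25, mode)
    print(
        f"{mode.value:14s} estimates are {elev:5.1f}% above weighed; "
        f"{within10:.0f}% of meals within +/-10%, {within25:.0f}% within +/-25%"
    )
print("(positive percent error = overestimation relative to the weighed record)")
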
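"""Bland-Altman agreement between app estimates and weighed meals.

The proportional-bias test regresses (estimated - weighed) on the pair
mean: a positive slope with a small p-value means bigger meals carry
bigger absolute error, which is exactly what a multiplicative error
model produces.  The calibration line (estimated = a + b * weighed)
shows how fast estimates grow per served calorie.
"""

from mealaudit import (
    Mode,
    bland_altman,
    calibration_ols,
    default_study_config,
    generate,
    meal_totals,
)

ds, _ = generate(default_study_config(seed=1))
meals = meal_totals(ds)

for mode in Mode:
    pairs = [(m.weighed_kcal_total, m.total(mode)) for m in meals]
    ba = bland_altman(pairs)
    cal = calibration_ols(pairs)
    print(f"{mode.value} (n={ba.n} meals)")
    print(
        f"  mean difference {ba.mean_diff:6.0f} kcal, "
        f"95% limits of agreement [{ba.loa_low:.0f}, {ba.loa_high:.0f}]"
    )
    print(
        f"  proportional bias: slope {ba.bias_slope:.2f} "
        f"(p={ba.bias_p:.2g}, R^2={ba.bias_r2:.2f})"
    )
    print(
        f"  calibration: {cal.slope:.2f} kcal logged per served kcal "
        f"(intercept {cal.intercept:.0f}, R^2={cal.r2:.2f})"
    )
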
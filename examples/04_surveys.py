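"""Score the two usability instruments across participants.

CSUQ: 19 items, 7-point scale, lower = more favorable; the overall score
is the mean of each participant's item mean.  USS: 5 items, 6-point
scale, higher = more favorable, reported per question.
"""

from mealaudit import default_study_config, generate, score_csuq, score_uss

_, surveys = generate(default_study_config(seed=1))

for s in score_csuq(surveys):
    print(f"CSUQ {s.item_label:22s} {s.mean:.1f} +/- {s.sd:.1f}  (n={s.n})")
print()
for s in score_uss(surveys):
    print(f"USS  {s.mean:.1f} +/- {s.sd:.1f}  {s.item_label}")
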
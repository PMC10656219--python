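"""Classify logged foods against served foods via the FNDDS hierarchy.

A cheeseburger (FNDDS 27510170, group 2) logged as itself is an exact
match; logged as a turkey burger (27545110) it shares only the first
digit (far match); logged as a croissant sandwich (58127310, group 5)
the major food group differs (intrusion); never scanned, it is an
omission and drops out of every denominator.
"""

from mealaudit import LogEntry, Mode, classify_match, parse_fndds_code

served = parse_fndds_code("27510170")

entries = {
    "logged as cheeseburger (27510170)": LogEntry(
        Mode.AUTOMATED, logged_code=parse_fndds_code("27510170"), estimated_kcal=310
    ),
    "logged as turkey burger (27545110)": LogEntry(
        Mode.AUTOMATED, logged_code=parse_fndds_code("27545110"), estimated_kcal=280
    ),
    "logged as croissant sandwich (58127310)": LogEntry(
        Mode.AUTOMATED, logged_code=parse_fndds_code("58127310"), estimated_kcal=400
    ),
    "not scanned": LogEntry(Mode.AUTOMATED, scanned=False),
}

print(f"served: cheeseburger ({served}), major group {served.group.id} "
      f"({served.group.label})")
for label, entry in entries.items():
    print(f"  {label:42s} -> {classify_match(served, entry).value}")
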
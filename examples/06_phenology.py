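"""Dormancy phenology: forcing assays and Utah chilling accumulation.

Scores budbreak-forcing outcomes (released at >= 50% open) and
accumulates Utah chill units over a synthetic winter temperature
record.
"""

import numpy as np

import singlebud as sb

print("budbreak-forcing calls (opened/total -> ratio, call):")
for opened, total in [(0, 60), (12, 60), (29, 60), (48, 100), (50, 100),
                      (58, 60)]:
    ratio, call = sb.budbreak_ratio(opened, total)
    print(f"  {opened:3d}/{total}: {100 * ratio:5.1f}% -> {call}")
print("(the 48% case is the transition-stage situation: about half the "
      "buds open, but the stage is still formally dormant)\n")

# synthetic winter: hourly temperatures cycling around a slowly cooling mean
rng = np.random.default_rng(0)
hours = np.arange(90 * 24)
temps = (9.0 - 4.0 * hours / hours.size        # seasonal cooling
         + 6.0 * np.sin(2 * np.pi * hours / 24)  # diurnal cycle
         + rng.normal(0, 1.5, hours.size))
series = sb.utah_chill_units(temps)
cu = np.asarray(series.cu)
print(f"90 synthetic winter days -> {series.total:.0f} chill units (CU)")
for target in (300, 600):
    idx = np.argmax(cu >= target)
    if cu[idx] >= target:
        print(f"  {target} CU reached after {idx / 24:.0f} days")
print("(warm afternoon hours subtract chill; cold nights accumulate it)")
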
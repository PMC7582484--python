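"""Score the eight QuickScreen physiological fall-risk factors and map the
count onto the four-level risk category."""

from gaitq.quickscreen import ITEMS, assess, categorize, items_from_measurements

measurements = {
    "previous_falls": True,
    "n_medications": 6,                # >= 4 -> polypharmacy risk factor
    "psychoactive_medication": False,
    "visual_acuity": 0.4,              # below 0.5 -> impaired
    "tactile_threshold": 3.0,
    "sit_to_stand_s": 14.0,            # slower than 12 s -> fail
    "near_tandem_s": 12.0,
    "alternate_step_s": 9.0,
}
items = items_from_measurements(measurements)
result = assess(items)

for name in ITEMS:
    print(f"  {name:30s} {'RISK' if items[name] else 'ok'}")
print(f"risk factors: {result.risk_factor_count}/8 -> {result.category} fall risk")
print("category boundaries:", {k: str(categorize(k)) for k in range(9)})
# 0-1 factors = very low, 2-3 = low, 4 = moderate, >= 5 = high risk.
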
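"""Screen one batch of submissions and read a flagged case study.

Builds a small synthetic batch (a valid cohort plus one blatant spam
wave), runs the full default protocol, and prints the decision summary,
the detector's performance against ground truth, and the evidence lines
for one invalidated submission.
"""
from surveyscreen import (
    CohortScenario,
    RuleConfig,
    SpamWave,
    confusion_metrics,
    default_geo_table,
    generate_cohort,
    proportion_invalid,
    run_protocol,
)

scenario = CohortScenario(
    n_valid=60,
    waves=[SpamWave(start_day=2, n=40, profile="naive")],
    seed=11,
)
records, labels = generate_cohort(scenario)
decisions = run_protocol(records, [RuleConfig()], default_geo_table())

# percent invalid: share of submissions rejected outright (>= 3 strikes or partial)
print(f"submissions: {len(decisions)}   invalid: {proportion_invalid(decisions)}%")
s = confusion_metrics(decisions, labels)
print(f"sensitivity (spam caught): {s.sensitivity:.3f}   "
      f"specificity (valid kept): {s.specificity:.3f}")

worst = max(decisions, key=lambda d: d.strike_count)
print(f"\ncase study {worst.submission_id} ({worst.status.value}, "
      f"{worst.strike_count} strikes):")
for strike in worst.strikes[:6]:
    print(f"  [{strike.category.value}] {strike.rule_id}: {strike.evidence}")
print("  ...")
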
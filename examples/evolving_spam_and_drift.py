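"""Watch spam evolve and catch it with the drift monitor.

An early wave of blatant spam (implausible ages, PSA, Gleason) is
followed by an evolved wave whose clinical answers are drawn from the
valid distributions — only metadata conventions remain (one email shape
at one host, chained start times, early-morning completion). The drift
monitor compares per-rule hit rates among flagged submissions across
weekly windows and alerts when a rule's rate jumps.
"""
from surveyscreen import (
    CohortScenario,
    RuleConfig,
    SpamWave,
    default_geo_table,
    generate_cohort,
    monitor_drift,
    run_protocol,
)

scenario = CohortScenario(
    n_valid=0,
    waves=[
        SpamWave(start_day=0, n=20, profile="naive"),
        SpamWave(start_day=7, n=20, profile="evolved"),
    ],
    seed=2,
)
records, labels = generate_cohort(scenario)
config = RuleConfig()
decisions = run_protocol(records, [config], default_geo_table())

invalid = sum(1 for d in decisions if d.status.value == "invalid")
print(f"spam records: {len(decisions)}; still caught as invalid: {invalid}")

report = monitor_drift(decisions, config)
for i, w in enumerate(report.windows):
    probe = {r: round(w.rates.get(r, 0.0), 2)
             for r in ("age_at_diagnosis", "psa_implausible", "email_convention")}
    print(f"window {i} (from {w.start}): {w.n_flagged} flagged, hit rates {probe}")

# an alert = a rule whose share among flagged submissions jumped > drift_delta
print("alerts:")
for a in report.alerts:
    print(f"  {a.rule_id}: {a.previous:.2f} -> {a.current:.2f}")
print("clinical rules collapsed while the email convention persisted: the spam "
      "evolved, but the metadata signature still identifies it.")
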
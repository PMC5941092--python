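# surveyscreen

Deduplication, cross-validation and spam screening for small web-survey
studies.

Web surveys of small, hidden, hard-to-recruit populations — the design
case here is older gay and bisexual prostate-cancer survivors surveyed
with a 45–60 minute instrument — attract fraudulent submissions the
moment compensation is advertised, and a majority of submissions can be
spam. With no practical way to verify identities externally, data quality
rests on a written deduplication and cross-validation protocol:
dataset-level duplicate signals, per-record plausibility checks, and
conservative adjudication with a human in the loop. `surveyscreen` is
that protocol as a tested, configurable toolkit, for study staff and
methodologists who need to screen a submissions CSV, justify every
rejection, and notice when the spam changes shape mid-study.

## What it implements

- **Dedup signals** (batch-level): duplicate IPs; email handles following
  one convention at one host (run-length character-class signatures, so
  `abc123@…` and `xyz456@…` cluster); submissions starting seconds after
  another ended (chains propagate); early-morning completion (local
  clock, half-open 00:00–05:00); identical improbable values across
  respondents (e.g. a shared birth date).
- **Plausibility rules** (per record): speeding (< 30 min on a 45–60 min
  instrument); IP-region vs zip-region mismatch from an offline lookup
  table; clinical coherence (age at diagnosis < 40, PSA > 20, Gleason > 6,
  forgotten clinical data, impossible treatment sequences, treatment/
  provider mismatches, disclosure-gated rehab, peripheral-only
  discrimination profiles); response style (straight-lining, item
  nonresponse, blank/gibberish/duplicated text, all-options-selected,
  failed verification items). The registry maps these onto the eight
  classic characteristics of suspicious survey submissions.
- **Adjudication**: the *k*-strikes rule (default 3; `k < 2` is refused —
  no single indicator can invalidate), incomplete ⇒ invalid, a manual
  review queue for 1..k−1 strikes, versioned protocol eras, a
  retrospective uniform re-adjudication pass, and a drift monitor that
  alerts when a rule's hit rate among flagged submissions jumps between
  time windows.
- **Simulator**: synthetic cohorts with ground-truth labels — valid
  respondents (age ~ truncated normal, mean 63.42 y, SD 8.19 y; 69.4%
  successfully treated), blatant "naive" spam (≥ 3 indicators each by
  construction), "evolved" spam (clinically plausible, metadata
  signatures intact), and the dual-link diversion scenario.
- **Evaluation & audit**: invalid-proportion arithmetic, confusion
  metrics against ground truth (sensitivity/specificity/PPV, spam =
  positive), cohort summaries, and a deterministic per-record case-study
  audit report (Markdown + JSON).

## Worked example

```python
from surveyscreen import (
    CohortScenario, SpamWave, RuleConfig, default_geo_table,
    generate_cohort, run_protocol, confusion_metrics, proportion_invalid,
)

scenario = CohortScenario(
    n_valid=60, waves=[SpamWave(start_day=2, n=40, profile="naive")], seed=11,
)
records, labels = generate_cohort(scenario)
decisions = run_protocol(records, [RuleConfig()], default_geo_table())

print(f"submissions: {len(decisions)}   invalid: {proportion_invalid(decisions)}%")
s = confusion_metrics(decisions, labels)
print(f"sensitivity: {s.sensitivity:.3f}   specificity: {s.specificity:.3f}")
```

prints

```
submissions: 100   invalid: 40.0%
sensitivity: 1.000   specificity: 1.000
```

— all 40 spam records accrued at least three strikes and were rejected
(40.0% of the batch), and none of the 60 genuine respondents was
invalidated. A flagged record's decision carries its full evidence trail:

```
case study N000000 (invalid, 17 strikes):
  [dedup] duplicate_ip: ip_address 100.64.14.240 shared by 14 submissions
  [dedup] email_convention: email_address xzz439@me.example matches a handle
          convention shared by 40 submissions at one host
  [metadata] completion_time: duration_minutes 23.4 < absolute minimum 30
  ...
```

The `examples/` directory has one short script per capability:
screening a batch (`screen_a_batch.py`), drift monitoring as spam evolves
(`evolving_spam_and_drift.py`), the dual-link diversion
(`dual_link_diversion.py`), and the retrospective uniform pass
(`retrospective_uniform_pass.py`).

There is also a thin CLI:

```bash
surveyscreen simulate --n-valid 50 --naive 20 --seed 3 --out subs.csv
surveyscreen validate --in subs.csv --out decisions.csv --audit audit/
```

## Layout

```
src/surveyscreen/     model, config, geo, io, dedup, rules,
                      adjudicate, simulate, report, cli
tests/                unit + property tests, brute-force oracles,
                      end-to-end acceptance checks
examples/             narrative scripts, one per capability
docs/methods.md       the model, defaults, numerical choices, limits
```
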
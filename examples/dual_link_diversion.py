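"""Divert genuine recruits to a restricted link while spam hits the old one.

After a spam attack is recognized, the compromised survey link is left
open as a honeypot and newly recruited valid respondents are routed to a
restricted replacement link. The routing rule guarantees the restricted
channel stays spam-free.
"""
from collections import Counter

from surveyscreen import CohortScenario, SpamWave, make_dual_link_scenario

base = CohortScenario(
    n_valid=60,
    waves=[SpamWave(start_day=2, n=30, profile="naive")],
    seed=7,
)
channel_a, channel_b, labels = make_dual_link_scenario(base, diversion_day=21, seed=7)

count_a = Counter(labels[r.submission_id] for r in channel_a)
count_b = Counter(labels[r.submission_id] for r in channel_b)
print(f"original link  (kept open): {dict(count_a)}")
print(f"restricted link (day >= 21): {dict(count_b)}")
print("the restricted link received zero spam-labeled records; the study can "
      "finish recruiting there while the old link absorbs the attack.")
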
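# Methods

## The screening model

`surveyscreen` operationalizes a deduplication and cross-validation
protocol for small web-survey studies in which fraudulent ("spam")
submissions must be separated from genuine respondents without any
external identity verification. The design target is a study of older
North American gay and bisexual prostate-cancer survivors — a small,
hidden, hard-to-recruit population surveyed with a 45–60 minute
instrument — but every threshold is configuration, not code.

The protocol is rule-based with human adjudication, deliberately not a
learned classifier: study staff must be able to read, explain and defend
every rejection. It has three layers.

**Dataset-level deduplication signals** require seeing the whole batch:
shared IP addresses; email handles following one mechanical convention at
one host (the handle is reduced to a run-length character-class signature,
so `abc123` and `xyz456` cluster as `L3D3` while `john.smith` does not);
submissions that start within seconds of another submission's end
(all ordered pairs with gap in `(0, adjacency_gap_seconds]`, chains
propagating); completion in the early hours of the morning (half-open
local-clock window, default 00:00–05:00); and identical improbable values
shared across respondents (default field: birth date). All signals are
order-invariant and monotone under batch growth, and each equals a
brute-force all-pairs reference on small inputs — the test suite checks
both properties directly.

**Per-record plausibility rules** cover metadata (duration under an
absolute floor, default 30 min on a 45–60 min instrument, with an optional
cohort-relative test at a configurable fraction of the batch median;
IP-region vs zip-region disagreement via a purely offline lookup table),
clinical coherence (age at diagnosis below 40 — prostate cancer this young
is rarer than 1 in 10,000; PSA above 20 ng/mL; Gleason total above 6;
all core clinical items "forgotten" on a complete survey; forbidden
ordered treatment transitions such as prostatectomy followed by watchful
waiting, or definitive therapy followed by "diet"; treatment/provider
mismatches such as radiation delivered by a urologist;
disclosure-dependent rehabilitation aids reported without disclosure to
the provider; discrimination reported only on peripheral attributes like
weight/height/appearance with no core attribute), and response style
(straight-lining — differentiation index `distinct/answered ≤ 0.2` on
grids of ≥ 5 items; item nonresponse above 20%; blank, gibberish or
verbatim-duplicated free text; all options of a multi-response block
selected; failed instructed-response verification items).

Every rule belongs to the registry, which maps the per-record rules onto
the eight classic characteristics of suspicious survey submissions
(short completion, all-items-selected, bogus answers, internal
inconsistency, low differentiation, item nonresponse, verification
failure, gibberish text); the dataset-level dedup signals form their own
categories alongside. Each sub-rule emits at most one strike per record,
so no single pathological field can dominate.

**Adjudication** applies the k-strikes rule: incomplete submissions are
invalid unconditionally; `k` or more strikes (default `k=3`) are invalid;
1 to `k−1` go to a manual review queue; zero strikes are valid. The
configuration refuses `k<2`, encoding the principle that no single
indicator is ever sufficient to reject a survey. Protocol *eras* — a list
of configurations with non-overlapping effective windows, matched on each
record's end date — model a dynamic protocol that tightens as spam
evolves; the retrospective pass then re-adjudicates everything under a
single final configuration so the analysis set reflects one uniform
standard. The drift monitor computes, per time window (default 7 days),
each rule's hit rate among flagged submissions and alerts when a rate
jumps by more than `drift_delta` (default 0.3) between consecutive
windows. Rates are computed among *flagged* submissions, not all
submissions, so a change in spam style stays visible while spam volume
fluctuates.

## The synthetic cohort generator

No raw submissions from any real study are available or distributable, so
validation rests on a simulator that emulates the study conditions with
ground-truth labels.

Valid respondents: age is drawn from a truncated normal on [40, 95] whose
*truncated* mean and SD are exactly 63.42 and 8.19 years — the parent
normal's parameters are solved numerically from the truncation moment
equations, since naively truncating N(63.42, 8.19²) would shift the mean
by about +0.05 y and shrink the SD to about 8.11 y. Age at diagnosis is
age minus Uniform(0, 10) years, floored at 40; PSA is Uniform(3, 15)
ng/mL; Gleason totals 3–6; 69.4% report successfully treated cancer;
completion takes Uniform(45, 60) minutes at daytime local hours; emails
are personalized (eight handle patterns over 24 host domains — enough
shape diversity that run-length-signature collisions of three or more at
one host are rare at desk scale); IPs are consistent with the respondent's
zip region in the bundled geo table; grids are varied (at least three
distinct values enforced — a differentiated responder, not an artifact of
uniform sampling); verification items pass; free text is non-empty
generated prose.

Naive spam: duration Uniform(5, 25) min, age at diagnosis Uniform{18..35},
PSA > 20 or missing, Gleason 7–10, an impossible four-step treatment
sequence with mismatched providers, disclosure-gated rehab without
disclosure, peripheral-only discrimination, straight-lined grids, failed
verification, blank text, convention emails (`L3D3`) at one host,
three shared IPs per wave, geo-mismatched IP vs zip, a shared 1901-01-01
birth date, and chained submissions in the 00:00–05:00 window (up to 10
per night, ~5–30 s gaps). Each naive record triggers far more than three
default indicators *by construction*, so naive-wave sensitivity is 1.0
under defaults — a property test, not an empirical claim.

Evolved spam: clinical and style fields are drawn from the valid
distributions (zero clinical strikes under a clinical-rules-only
configuration), while at least three metadata signatures persist,
default {email_convention, adjacency, odd_hour} with geo_mismatch as the
fourth option. Chain lengths are capped (4 per night when both adjacency
and the odd-hour window must hold with 45–60 min durations) so every
chained record genuinely ends inside the window. Scenario validation
rejects combinations that cannot realize their signatures (an evolved
wave of n<3 cannot form an email cluster; n<2 cannot chain) and fewer
than three distinct signatures.

Randomness is split per record: each record draws from a generator seeded
by (seed, stream, index), so adding a spam wave never perturbs the valid
cohort at a fixed seed, and fixed seeds give byte-identical CSV output.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: IP masking and VPNs beyond a simple region
mismatch, reCAPTCHA or browser-fingerprint evasion, human spammers who
adapt *within* a wave, legitimate couples sharing one IP, genuine
respondents with atypical clinical histories (a real Gleason 7 patient is
common; the protocol deliberately relies on strike accumulation so such a
record alone can never be rejected), and free-text semantics beyond a
vowel heuristic. Detector performance on the synthetic waves is a check
of internal consistency and of the protocol's logic, not an estimate of
field accuracy.

## Numerical and design choices

- **Duration** is always recomputed from the two timestamps; a supplied
  duration column is ignored (single source of truth). Timestamps keep
  their UTC offset; odd-hour logic reads the submission's own local clock.
  Naive timestamps are treated as UTC.
- **Adjacency** is defined over all ordered pairs (gap in
  `(0, gap_seconds]`), not only nearest predecessors: this makes the
  signal order-invariant and monotone, and the implementation (sorted
  end-times + binary search) provably equals the quadratic reference.
- **Boundaries**: the speeding floor is a strict inequality (exactly 30
  minutes does not strike); the odd-hour window is half-open (ending at
  exactly 05:00 does not strike); the differentiation threshold uses `≤`.
- **All-options rule**: the multi-response block checked is the
  discrimination-attributes block (fires when the entire peripheral ∪
  core vocabulary is selected). The eligibility screener itself is four
  mandatory checkboxes that every genuine entrant must tick, so
  "all checked" carries no information there.
- **Geo lookups are total**: unknown IP prefixes or zips yield
  "unverifiable" audit notes, never strikes — absence of evidence is not
  evidence.
- **Rounding** is half-up and presentation-only (via `decimal`), with a
  configurable digit count; internal values keep full precision. Note
  that 289/478 = 60.460%, so the canonical worked example rounds to 60.5%
  at one decimal even though it is usually quoted as 60.4%.
- **Era bookkeeping** assigns each record to the configuration covering
  its end date (a submission becomes adjudicable on completion); the
  dedup context is built once per batch using the latest era's thresholds,
  since dataset-level groups are not meaningfully era-scoped.
- **Review is not invalid** in the confusion matrix by default (the
  manual protocol resolved review cases by contacting respondents); a
  strict mode counts review as invalid behind a flag.
- **Decision tables** round-trip statuses, strike counts and reason codes
  exactly; evidence strings live in the audit report (Markdown + JSON),
  which is byte-deterministic given identical inputs.

## Problem sizes

The test suite exercises cohorts of 200–400 valid records plus waves of
10–40 spam records (protocol runs complete in milliseconds), brute-force
oracle comparisons at ≤ 50 records, and one 100,000-record cohort for
demographic parameter recovery (mean age within ±0.1 y of 63.42, SD
within ±0.1 y of 8.19; generation takes ~30 s). The acceptance script
regenerates the 100,000-record cohort from scratch at the given seed.

## Known limitations

- Per-attempt screener snapshots are not modeled: one screener state is
  stored per submission, so repeated entry attempts with changed screening
  answers are not reconstructed.
- The gibberish heuristic (vowel-bearing token fraction plus verbatim
  duplication) is intentionally crude and pluggable; flagging
  numeral-only answers as gibberish is a known false-positive mode.
- IP grouping is exact-string by default; /24-prefix grouping exists as a
  switch but near-duplicate IPs across prefixes are invisible.
- The simulator guarantees within-region unique valid IPs only up to
  ~480 records per region; much larger cohorts can contain coincidental
  duplicate-IP pairs (harmless to the shipped analyses, which use large
  cohorts only for demographic summaries).
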